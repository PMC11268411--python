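"""Reading, writing and assembling the inputs of a BDNN analysis.

File dialects are deliberately plain: tab-separated tables with a header row,
ages in Ma before present (larger = older), Newick trees with branch lengths.
The occurrence table has columns ``taxon``, ``min_age``, ``max_age`` and
``status`` (``extinct`` or ``extant``); each row is one fossil occurrence whose
true age is only known to lie within ``[min_age, max_age]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import dendropy

__all__ = [
    "TaxonRecord",
    "OccurrenceDataset",
    "PredictorTensor",
    "PhyloEigenvectors",
    "read_occurrences",
    "write_occurrences",
    "read_traits",
    "write_traits",
    "read_time_series",
    "write_time_series",
    "resample_ages",
    "build_predictor_tensor",
    "phylo_eigenvectors",
    "default_time_bins",
]


@dataclass
class TaxonRecord:
    """One taxon: a unique name, its dated occurrences and an extant flag.

    Each occurrence is an ``(min_age, max_age)`` interval in Ma; a point age is
    an interval with equal endpoints.
    """

    name: str
    occurrences: List[Tuple[float, float]]
    extant: bool = False

    def __post_init__(self):
        if not self.occurrences:
            raise ValueError(f"taxon {self.name!r} has no occurrences")
        occs = []
        for lo, hi in self.occurrences:
            lo, hi = float(lo), float(hi)
            if lo < 0 or hi < 0:
                raise ValueError(f"taxon {self.name!r}: negative occurrence age")
            if lo > hi:
                raise ValueError(
                    f"taxon {self.name!r}: min_age {lo} exceeds max_age {hi}"
                )
            occs.append((lo, hi))
        self.occurrences = occs

    @property
    def ages(self) -> np.ndarray:
        """Point ages (interval midpoints when endpoints differ)."""
        return np.array([(lo + hi) / 2.0 for lo, hi in self.occurrences])


@dataclass
class OccurrenceDataset:
    """A validated collection of taxa with dated occurrences.

    ``time_bins`` are strictly decreasing boundary ages (Ma, last entry 0)
    defining the grid on which rates are allowed to vary.
    """

    taxa: List[TaxonRecord]
    time_bins: Optional[np.ndarray] = None

    def __post_init__(self):
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate taxon names: {dupes}")
        if self.time_bins is None:
            self.time_bins = default_time_bins(self.oldest_age())
        self.time_bins = np.asarray(self.time_bins, dtype=float)
        if self.time_bins.ndim != 1 or len(self.time_bins) < 2:
            raise ValueError("time_bins must hold at least two boundary ages")
        if np.any(np.diff(self.time_bins) >= 0):
            raise ValueError("time_bins must be strictly decreasing")

    @property
    def names(self) -> List[str]:
        return [t.name for t in self.taxa]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def oldest_age(self) -> float:
        return max(hi for t in self.taxa for _, hi in t.occurrences)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t.name, lo, hi, "extant" if t.extant else "extinct")
            for t in self.taxa
            for lo, hi in t.occurrences
        ]
        return pd.DataFrame(rows, columns=["taxon", "min_age", "max_age", "status"])


def default_time_bins(oldest_age: float, width: float = 1.0) -> np.ndarray:
    """Decreasing 1-Myr (by default) bin boundaries covering ``[0, oldest]``."""
    top = max(width, np.ceil(oldest_age / width) * width)
    n = int(round(top / width))
    return np.linspace(top, 0.0, n + 1)


REQUIRED_COLUMNS = ("taxon", "min_age", "max_age", "status")


def read_occurrences(path, time_bins=None) -> OccurrenceDataset:
    """Parse a tab-separated occurrence table into a validated dataset.

    Malformed or invalid rows raise ``ValueError`` naming the offending line
    (1-based, counting the header as line 1).  Row order is preserved within
    each taxon; taxa appear in order of first occurrence row.
    """
    with open(path) if isinstance(path, (str,)) else _as_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"occurrence table is missing columns: {missing}")
        idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
        occ: Dict[str, List[Tuple[float, float]]] = {}
        extant: Dict[str, bool] = {}
        order: List[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < len(header):
                raise ValueError(f"line {lineno}: expected {len(header)} fields")
            name = parts[idx["taxon"]].strip()
            try:
                lo = float(parts[idx["min_age"]])
                hi = float(parts[idx["max_age"]])
            except ValueError:
                raise ValueError(f"line {lineno}: unparseable age") from None
            status = parts[idx["status"]].strip().lower()
            if status not in ("extinct", "extant"):
                raise ValueError(
                    f"line {lineno}: status must be 'extinct' or 'extant', got {status!r}"
                )
            if lo < 0 or hi < 0:
                raise ValueError(f"line {lineno}: negative age")
            if lo > hi:
                raise ValueError(f"line {lineno}: min_age exceeds max_age")
            if name not in occ:
                occ[name] = []
                order.append(name)
                extant[name] = status == "extant"
            elif extant[name] != (status == "extant"):
                raise ValueError(f"line {lineno}: conflicting status for taxon {name!r}")
            occ[name].append((lo, hi))
    taxa = [TaxonRecord(n, occ[n], extant[n]) for n in order]
    return OccurrenceDataset(taxa, time_bins=time_bins)


def _as_text(obj):
    if hasattr(obj, "read"):
        return obj
    return open(obj)


def write_occurrences(dataset: OccurrenceDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def read_traits(path) -> pd.DataFrame:
    """Species-by-trait table; first column holds species names."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="species")


def read_time_series(path) -> pd.DataFrame:
    """Time series table with columns ``bin_top_age`` and ``value``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("bin_top_age", "value"):
        if col not in df.columns:
            raise ValueError(f"time series table is missing column {col!r}")
    return df


def write_time_series(ages, values, path) -> None:
    pd.DataFrame({"bin_top_age": ages, "value": values}).to_csv(
        path, sep="\t", index=False
    )


def resample_ages(dataset: OccurrenceDataset, seed) -> OccurrenceDataset:
    """Draw one point age per occurrence, uniformly within its interval.

    Deterministic given ``seed``; degenerate intervals stay fixed.  Used to
    propagate fossil dating uncertainty across replicated analyses.
    """
    rng = np.random.default_rng(seed)
    taxa = []
    for t in dataset.taxa:
        occs = []
        for lo, hi in t.occurrences:
            a = lo if lo == hi else float(rng.uniform(lo, hi))
            occs.append((a, a))
        taxa.append(TaxonRecord(t.name, occs, t.extant))
    return OccurrenceDataset(taxa, time_bins=dataset.time_bins.copy())


# ---------------------------------------------------------------------------
# predictor tensor


@dataclass
class PhyloEigenvectors:
    """Leading principal-coordinate axes of the patristic distance matrix."""

    species: List[str]
    coords: np.ndarray  # (n_species, k)
    eigenvalues: np.ndarray  # (k,), decreasing

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.coords.shape[0] != len(self.species):
            raise ValueError("coords rows must match species")
        if self.coords.shape[1] != len(self.eigenvalues):
            raise ValueError("one eigenvalue per coordinate axis required")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be in decreasing order")

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class PredictorTensor:
    """Predictor rows ``x(i, t)`` for every (species, time bin) cell.

    ``values`` has shape ``(n_species, n_bins, n_predictors)``.  Continuous
    predictors (including time, eigenvectors and environmental series) are
    z-transformed; binary and one-hot indicators are left on their 0/1 scale.
    ``standardization`` records the (mean, sd) applied per predictor so that
    grids and new data can be placed on the same scale.
    """

    values: np.ndarray
    predictor_names: List[str]
    predictor_kinds: List[str]
    standardization: Dict[str, Tuple[float, float]]
    species: List[str]
    bin_edges: np.ndarray  # decreasing boundary ages, len n_bins + 1
    groups: Dict[str, List[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (species, bins, predictors)")
        s, b, j = self.values.shape
        if s != len(self.species):
            raise ValueError("species axis mismatch")
        if j != len(self.predictor_names) or j != len(self.predictor_kinds):
            raise ValueError("predictor axis mismatch")
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if len(self.bin_edges) != b + 1:
            raise ValueError("bin_edges must have n_bins + 1 entries")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_predictors(self) -> int:
        return self.values.shape[2]

    @property
    def matrix(self) -> np.ndarray:
        """Flattened (species*bins, J) view of the tensor."""
        s, b, j = self.values.shape
        return self.values.reshape(s * b, j)

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def column_index(self, name: str) -> int:
        try:
            return self.predictor_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown predictor {name!r}; available: {self.predictor_names}"
            ) from None

    def standardize(self, name: str, raw):
        mean, sd = self.standardization.get(name, (0.0, 1.0))
        return (np.asarray(raw, dtype=float) - mean) / (sd if sd > 0 else 1.0)

    def destandardize(self, name: str, z):
        mean, sd = self.standardization.get(name, (0.0, 1.0))
        return np.asarray(z, dtype=float) * (sd if sd > 0 else 1.0) + mean

    def copy(self) -> "PredictorTensor":
        return PredictorTensor(
            self.values.copy(),
            list(self.predictor_names),
            list(self.predictor_kinds),
            dict(self.standardization),
            list(self.species),
            self.bin_edges.copy(),
            {k: list(v) for k, v in self.groups.items()},
        )


def _is_binary(col: pd.Series) -> bool:
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def build_predictor_tensor(
    dataset: OccurrenceDataset,
    traits: Optional[pd.DataFrame] = None,
    time_series: Optional[Dict[str, np.ndarray]] = None,
    eigenvectors: Optional[PhyloEigenvectors] = None,
    time_bins=None,
    categorical: Sequence[str] = (),
) -> PredictorTensor:
    """Assemble and standardize the (species, bin, predictor) tensor.

    The first column is time itself (bin midpoints, z-transformed like any
    continuous predictor).  Trait columns are constant across bins; series
    columns are constant across species.  Categorical columns (non-numeric, or
    named in ``categorical``) with more than two states are one-hot encoded
    with the full indicator set; two-state columns become a single 0/1 column.
    Zero-variance continuous columns are kept as all-zero so predictor indices
    stay stable for the importance ranking.
    """
    edges = np.asarray(
        time_bins if time_bins is not None else dataset.time_bins, dtype=float
    )
    species = dataset.names
    n_s, n_b = len(species), len(edges) - 1
    mids = (edges[:-1] + edges[1:]) / 2.0

    columns: List[np.ndarray] = []  # each (n_s, n_b)
    names: List[str] = []
    kinds: List[str] = []
    standardization: Dict[str, Tuple[float, float]] = {}
    groups: Dict[str, List[int]] = {}

    def add(name, kind, grid, z: bool):
        if z:
            mean = float(grid.mean())
            sd = float(grid.std())
            standardization[name] = (mean, sd)
            grid = (grid - mean) / sd if sd > 0 else np.zeros_like(grid)
        names.append(name)
        kinds.append(kind)
        columns.append(grid)

    add("time", "time", np.broadcast_to(mids, (n_s, n_b)).copy(), z=True)

    if traits is not None:
        missing = [s for s in species if s not in traits.index]
        if missing:
            raise ValueError(f"species missing from trait table: {missing}")
        traits = traits.loc[species]
        for col in traits.columns:
            series = traits[col]
            is_cat = col in categorical or not pd.api.types.is_numeric_dtype(series)
            if is_cat:
                states = sorted(map(str, pd.unique(series.astype(str))))
                if len(states) <= 2:
                    ind = (series.astype(str) == states[-1]).to_numpy(float)
                    add(col, "binary", np.repeat(ind[:, None], n_b, axis=1), z=False)
                else:
                    start = len(names)
                    for st in states:
                        ind = (series.astype(str) == st).to_numpy(float)
                        add(
                            f"{col}={st}",
                            "one-hot-group",
                            np.repeat(ind[:, None], n_b, axis=1),
                            z=False,
                        )
                    groups[col] = list(range(start, len(names)))
            elif _is_binary(series):
                vals = series.to_numpy(float)
                add(col, "binary", np.repeat(vals[:, None], n_b, axis=1), z=False)
            else:
                vals = series.to_numpy(float)
                add(col, "continuous", np.repeat(vals[:, None], n_b, axis=1), z=True)

    if time_series:
        for name, vals in time_series.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n_b,):
                raise ValueError(
                    f"series {name!r} has {vals.shape} values, expected ({n_b},): "
                    "one value per time bin"
                )
            add(name, "series", np.broadcast_to(vals, (n_s, n_b)).copy(), z=True)

    if eigenvectors is not None:
        lookup = {sp: i for i, sp in enumerate(eigenvectors.species)}
        missing = [s for s in species if s not in lookup]
        if missing:
            raise ValueError(f"species missing from eigenvectors: {missing}")
        rows = np.array([lookup[s] for s in species])
        for j in range(eigenvectors.k):
            vals = eigenvectors.coords[rows, j]
            add(
                f"phylo_ev{j + 1}",
                "eigenvector",
                np.repeat(vals[:, None], n_b, axis=1),
                z=True,
            )

    values = np.stack(columns, axis=-1)
    return PredictorTensor(
        values, names, kinds, standardization, species, edges, groups
    )


# ---------------------------------------------------------------------------
# phylogenetic eigenvectors


def _patristic_matrix(tree: dendropy.Tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, d


def load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" in text and ")" in text:
        return dendropy.Tree.get(data=text, schema="newick")
    return dendropy.Tree.get(path=text, schema="newick")


def phylo_eigenvectors(tree, k: int) -> PhyloEigenvectors:
    """Principal-coordinate decomposition of tip-to-tip patristic distances.

    The distance matrix is Gower-centered as ``-1/2 J D J``; because patristic
    distances on a tree with positive branch lengths form an additive metric,
    this matrix is positive semidefinite and the full set of coordinates
    reconstructs the distances exactly (``||y_i - y_j||^2 = d_ij``).  The top
    ``k`` axes (by decreasing eigenvalue, scaled by sqrt(eigenvalue)) are
    returned as species-level predictors proxying phylogenetic relatedness.
    Signs are fixed by making each axis's largest-magnitude loading positive.
    """
    t = load_tree(tree)
    labels, d = _patristic_matrix(t)
    n = len(labels)
    if n < 3:
        raise ValueError("tree must have at least 3 tips")
    if k < 1:
        raise ValueError("k must be >= 1")
    center = np.eye(n) - np.full((n, n), 1.0 / n)
    g = -0.5 * center @ d @ center
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals.max(), 0.0) * 1e-9 + 1e-12
    n_pos = int(np.sum(evals > tol))
    if k > n_pos:
        raise ValueError(
            f"requested {k} eigenvectors but only {n_pos} positive eigenvalues"
        )
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return PhyloEigenvectors(labels, coords, evals[:k])
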