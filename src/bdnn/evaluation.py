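"""Accuracy, coverage and rate-variation-detection metrics.

These compare inferred lineage-time rates against the generating truth of the
benchmark simulator: the median absolute relative error (MARE) of the
species-specific rates at their (inferred) origination/extinction times, the
share of lineages whose 95% credible interval covers the true rate, and a
coefficient-of-variation (CV) test that rejects rate constancy when the
heterogeneity of the inferred rates exceeds a threshold calibrated on
constant-rate simulations at a chosen specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .likelihood import interval_bin_overlap
from .mcmc import PosteriorTrace

__all__ = [
    "mare",
    "coverage",
    "rate_cv",
    "cv_rate_variation_test",
    "calibrate_threshold",
    "rates_through_time",
    "species_rate_estimates",
    "evaluate_against_truth",
]


def mare(true_rates, inferred_rates) -> float:
    """Median absolute relative error, ``median(|r - rhat| / r)``.

    Uses the midpoint of the two central order statistics for even lengths.
    Entries with a zero true rate cannot be scored on a relative scale and
    are excluded with a warning.
    """
    r = np.asarray(true_rates, dtype=float)
    rh = np.asarray(inferred_rates, dtype=float)
    if r.shape != rh.shape:
        raise ValueError("true and inferred rate vectors must align")
    nonzero = r != 0
    if not np.all(nonzero):
        warnings.warn(
            f"excluding {np.sum(~nonzero)} lineages with zero true rate from MARE",
            stacklevel=2,
        )
        r, rh = r[nonzero], rh[nonzero]
    if len(r) == 0:
        raise ValueError("no scorable lineages")
    return float(np.median(np.abs(r - rh) / r))


def coverage(true_rates, posterior_rate_samples, level: float = 0.95) -> float:
    """Share of lineages whose equal-tailed credible interval holds the truth.

    ``posterior_rate_samples`` has shape (n_samples, n_lineages).
    """
    r = np.asarray(true_rates, dtype=float)
    samples = np.asarray(posterior_rate_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != len(r):
        raise ValueError("posterior samples must be (n_samples, n_lineages)")
    a = (1 - level) / 2
    lo = np.quantile(samples, a, axis=0)
    hi = np.quantile(samples, 1 - a, axis=0)
    return float(np.mean((r >= lo) & (r <= hi)))


def rate_cv(rate_matrix, mask=None) -> float:
    """Coefficient of variation (sd / mean) of a rate matrix.

    ``mask`` optionally restricts to cells within lineage lifespans.
    """
    x = np.asarray(rate_matrix, dtype=float)
    if mask is not None:
        x = x[np.asarray(mask, dtype=bool)]
    m = x.mean()
    if not m > 1e-12:
        raise ValueError("CV undefined: mean rate is ~0")
    return float(x.std() / m)


def trace_cvs(trace: PosteriorTrace, cells: str = "all") -> Tuple[float, float]:
    """CVs of the posterior-mean lineage-time rate matrices (lambda, mu).

    ``cells='alive'`` restricts to bins overlapping each lineage's posterior
    mean lifespan; ``'all'`` pools the full species-by-bin grid.
    """
    lam_mean, mu_mean = trace.posterior_mean_rates()
    mask = None
    if cells == "alive":
        mask = (
            interval_bin_overlap(
                trace.e.mean(axis=0), trace.s.mean(axis=0), trace.bin_edges
            )
            > 0
        )
    elif cells != "all":
        raise ValueError("cells must be 'all' or 'alive'")
    return rate_cv(lam_mean, mask), rate_cv(mu_mean, mask)


def cv_rate_variation_test(
    trace: PosteriorTrace,
    thresholds: Tuple[float, float],
    cells: str = "all",
) -> Dict[str, Union[float, bool]]:
    """Reject rate constancy when the CV of inferred rates exceeds the
    calibrated threshold, separately for speciation and extinction."""
    cv_l, cv_m = trace_cvs(trace, cells=cells)
    thr_l, thr_m = thresholds
    return {
        "cv_lambda": cv_l,
        "cv_mu": cv_m,
        "reject_lambda": bool(cv_l > thr_l),
        "reject_mu": bool(cv_m > thr_m),
    }


def calibrate_threshold(
    constant_rate_traces: Sequence,
    specificity: float = 0.95,
    cells: str = "all",
    min_fits: int = 20,
) -> Tuple[float, float]:
    """Specificity-quantile of CVs across constant-rate fits.

    Accepts either fitted traces or precomputed ``(cv_lambda, cv_mu)`` pairs;
    at least ``min_fits`` fits are required for a usable quantile.
    """
    items = list(constant_rate_traces)
    if len(items) < min_fits:
        raise ValueError(f"need >= {min_fits} constant-rate fits, got {len(items)}")
    cvs = np.array(
        [
            trace_cvs(t, cells=cells) if isinstance(t, PosteriorTrace) else tuple(t)
            for t in items
        ]
    )
    # smallest observed CV below which >= `specificity` of the fits fall:
    # exactly the (ceil(specificity * n))-th order statistic
    n = len(items)
    idx = max(int(np.ceil(specificity * n)) - 1, 0)
    srt = np.sort(cvs, axis=0)
    return float(srt[idx, 0]), float(srt[idx, 1])


def rates_through_time(
    trace: PosteriorTrace, time_grid=None, level: float = 0.95
) -> pd.DataFrame:
    """Overall rate trajectories: per bin, the posterior mean and CI of the
    average rate over lineages alive in that bin (per MCMC sample).

    Bins in which no lineage is alive in a sample are skipped for that
    sample; bins empty in every sample are flagged with NaN.
    """
    edges = np.asarray(time_grid if time_grid is not None else trace.bin_edges)
    n, S = trace.s.shape
    nb = len(edges) - 1
    lam_tt = np.full((n, nb), np.nan)
    mu_tt = np.full((n, nb), np.nan)
    mids = (edges[:-1] + edges[1:]) / 2
    src_mids = (trace.bin_edges[:-1] + trace.bin_edges[1:]) / 2
    # map requested bins onto the trace's rate grid
    col = np.array(
        [int(np.argmin(np.abs(src_mids - m))) for m in mids]
    )
    for i in range(n):
        alive = interval_bin_overlap(trace.e[i], trace.s[i], edges) > 0
        lam_i = trace.lam[i][:, col]
        mu_i = trace.mu[i][:, col]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lam_tt[i] = np.where(
                alive.any(axis=0),
                np.nanmean(np.where(alive, lam_i, np.nan), axis=0),
                np.nan,
            )
            mu_tt[i] = np.where(
                alive.any(axis=0),
                np.nanmean(np.where(alive, mu_i, np.nan), axis=0),
                np.nan,
            )
    a = (1 - level) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = pd.DataFrame(
            {
                "bin_mid_age": mids,
                "lambda_mean": np.nanmean(lam_tt, axis=0),
                "lambda_lo": np.nanquantile(lam_tt, a, axis=0),
                "lambda_hi": np.nanquantile(lam_tt, 1 - a, axis=0),
                "mu_mean": np.nanmean(mu_tt, axis=0),
                "mu_lo": np.nanquantile(mu_tt, a, axis=0),
                "mu_hi": np.nanquantile(mu_tt, 1 - a, axis=0),
            }
        )
    out["empty"] = np.all(np.isnan(lam_tt), axis=0)
    return out


def species_rate_estimates(trace: PosteriorTrace):
    """Posterior samples of each lineage's speciation rate at its sampled
    origination and extinction rate at its sampled extinction; the quantities
    entering MARE and coverage."""
    return trace.rates_at_event_times()


def evaluate_against_truth(
    trace: PosteriorTrace,
    true_lambda,
    true_mu,
    thresholds: Optional[Tuple[float, float]] = None,
) -> Dict[str, float]:
    """One-stop accuracy report for a benchmark replicate."""
    lam_ev, mu_ev = species_rate_estimates(trace)
    report = {
        "mare_lambda": mare(true_lambda, lam_ev.mean(axis=0)),
        "mare_mu": mare(true_mu, mu_ev.mean(axis=0)),
        "coverage_lambda": coverage(true_lambda, lam_ev),
        "coverage_mu": coverage(true_mu, mu_ev),
    }
    cv_l, cv_m = trace_cvs(trace)
    report["cv_lambda"] = cv_l
    report["cv_mu"] = cv_m
    if thresholds is not None:
        report["reject_lambda"] = float(cv_l > thresholds[0])
        report["reject_mu"] = float(cv_m > thresholds[1])
    return report
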