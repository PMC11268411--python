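import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import make_trace

from bdnn.core import NetworkWeights
from bdnn.data_io import PredictorTensor
from bdnn.xai import (
    PDCurve,
    build_importance_table,
    consensus_rank,
    partial_dependence,
    pd_fold_change,
    pd_posterior_difference,
    permutation_importance,
    shap_values,
)


def make_tensor(rng, n_species=4, n_bins=5, n_pred=5):
    values = rng.normal(size=(n_species, n_bins, n_pred))
    return PredictorTensor(
        values,
        [f"p{j}" for j in range(n_pred)],
        ["continuous"] * n_pred,
        {},
        [f"sp{i}" for i in range(n_species)],
        np.linspace(n_bins, 0, n_bins + 1),
    )


def random_net(rng, J, scale=0.5, hidden=(4, 3)):
    return NetworkWeights.random(J, hidden, True, rng, scale)


def net_ignoring(rng, J, dead_col, scale=0.5, hidden=(4, 3)):
    w = random_net(rng, J, scale, hidden)
    w.w1[dead_col, :] = 0.0
    return w


def simple_trace(tensor, nets_l, nets_m, t_regs):
    S = tensor.n_species
    s = np.full(S, tensor.bin_edges[0] - 0.5)
    e = np.zeros(S)
    extant = np.ones(S, dtype=bool)
    return make_trace(tensor, nets_l, nets_m, t_regs, s, e, extant)


class TestPartialDependence:
    def test_null_predictor_gives_flat_curve(self, rng):
        tensor = make_tensor(rng)
        nets = [net_ignoring(rng, 5, dead_col=2) for _ in range(3)]
        trace = simple_trace(tensor, nets, nets, [0.9, 0.8, 1.0])
        curve = partial_dependence(trace, tensor, "lambda", "p2", n_grid=7)
        assert np.ptp(curve.samples, axis=1) == pytest.approx(np.zeros(3), abs=1e-12)
        assert pd_fold_change(curve) == pytest.approx(1.0)

    def test_single_sample_pd_matches_brute_force_row_rebuild(self, rng):
        tensor = make_tensor(rng)
        net = random_net(rng, 5)
        trace = simple_trace(tensor, [net], [net], [0.7])
        v = 0.31
        curve = partial_dependence(trace, tensor, "lambda", "p1", grid=[v])
        # brute force: rebuild every row with p1 = v, push through the network
        # and the regularizer with its constants frozen at the observed grid
        from bdnn.core import forward_baseline

        base_obs = forward_baseline(net, tensor.matrix)
        c = base_obs.mean() / (base_obs**0.7).mean()
        vals = tensor.values.copy()
        vals[:, :, 1] = v
        base = forward_baseline(net, vals.reshape(-1, 5))
        expected = (base**0.7 * c).mean()
        assert curve.samples[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_pair_grid_covers_cartesian_product(self, rng):
        tensor = make_tensor(rng)
        net = random_net(rng, 5)
        trace = simple_trace(tensor, [net], [net], [1.0])
        curve = partial_dependence(
            trace, tensor, "lambda", ("p0", "p1"), n_grid=9
        )
        assert len(curve.grid) == len({g for g in curve.grid})
        assert all(isinstance(g, tuple) for g in curve.grid)

    def test_unknown_predictor_rejected(self, rng):
        tensor = make_tensor(rng)
        net = random_net(rng, 5)
        trace = simple_trace(tensor, [net], [net], [1.0])
        with pytest.raises(KeyError, match="unknown predictor"):
            partial_dependence(trace, tensor, "lambda", "nope")


class TestPDPosteriorDifference:
    def test_flat_curve_scores_half(self):
        curve = PDCurve("x", [0, 1, 2], np.ones((5, 3)))
        assert pd_posterior_difference(curve) == 0.5

    def test_monotone_samples_score_one(self):
        samples = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1)) * np.arange(1, 5)[:, None]
        curve = PDCurve("x", [0, 1, 2], samples)
        assert pd_posterior_difference(curve) == 1.0

    def test_hand_built_three_sample_enumeration(self):
        # mean curve: [1.0, 1.2] -> argmax = 1, argmin = 0
        samples = np.array([[1.0, 2.0], [1.5, 1.0], [0.5, 0.6]])
        curve = PDCurve("x", [0, 1], samples)
        # samples where rate(argmax) > rate(argmin): rows 0 and 2 -> 2/3
        assert pd_posterior_difference(curve) == pytest.approx(2 / 3)

    def test_requires_two_grid_points(self):
        with pytest.raises(ValueError, match="grid points"):
            pd_posterior_difference(PDCurve("x", [0], np.ones((2, 1))))


class TestPermutationImportance:
    def test_constant_column_scores_exactly_zero(self, rng):
        tensor = make_tensor(rng)
        tensor.values[:, :, 3] = 0.7  # constant across species and bins
        net = random_net(rng, 5)
        trace = simple_trace(tensor, [net], [net], [0.9])
        score = permutation_importance(
            trace, None, tensor, "p3", n_permutations=4, seed=0
        )
        assert score == 0.0

    def test_treg_zero_posterior_makes_all_scores_zero(self, rng):
        tensor = make_tensor(rng)
        net = random_net(rng, 5)
        trace = simple_trace(tensor, [net], [net], [0.0])
        for name in ("p0", "p4"):
            assert permutation_importance(
                trace, None, tensor, name, n_permutations=3, seed=1
            ) == pytest.approx(0.0, abs=1e-9)

    def test_causal_predictor_outranks_pure_noise_column(self, rng):
        # rates depend strongly on p0 only; permuting p0 must hurt the
        # birth-death fit more than permuting the dead column p2
        tensor = make_tensor(rng, n_species=8)
        net = net_ignoring(rng, 5, dead_col=2, scale=1.2)
        trace = simple_trace(tensor, [net], [net], [1.0])
        s_causal = permutation_importance(trace, None, tensor, "p0", seed=2)
        s_dead = permutation_importance(trace, None, tensor, "p2", seed=2)
        assert s_dead == pytest.approx(0.0, abs=1e-12)
        assert abs(s_causal) > 1e-3

    def test_pair_interaction_of_independent_additive_nets_is_small(self, rng):
        tensor = make_tensor(rng)
        net = net_ignoring(rng, 5, dead_col=2)
        trace = simple_trace(tensor, [net], [net], [1.0])
        inter = permutation_importance(
            trace, None, tensor, ("p2", "p3"), n_permutations=6, seed=3
        )
        single = permutation_importance(
            trace, None, tensor, "p3", n_permutations=6, seed=3
        )
        # p2 is dead: the joint drop must equal the single-p3 drop
        assert inter == pytest.approx(0.0, abs=max(1e-8, 1e-6 * abs(single)))


class TestShap:
    def test_dummy_predictor_gets_zero_attribution(self, rng):
        tensor = make_tensor(rng)
        net = net_ignoring(rng, 5, dead_col=1)
        trace = simple_trace(tensor, [net], [net], [0.8])
        for method in ("exact", "kernel"):
            res = shap_values(
                trace, tensor, method=method, n_rows=10, background_size=10, seed=0
            )
            assert np.all(np.abs(res.phi[:, 1]) < 1e-10)

    def test_local_accuracy(self, rng):
        tensor = make_tensor(rng)
        net = random_net(rng, 5, scale=0.8)
        trace = simple_trace(tensor, [net], [net], [0.6])
        for method in ("exact", "kernel"):
            res = shap_values(
                trace, tensor, method=method, n_rows=12, background_size=15, seed=1
            )
            np.testing.assert_allclose(
                res.base + res.phi.sum(axis=1), res.rates, atol=1e-6
            )

    def test_symmetry_for_duplicated_predictor(self, rng):
        tensor = make_tensor(rng)
        tensor.values[:, :, 4] = tensor.values[:, :, 0]  # identical columns
        net = random_net(rng, 5)
        net.w1[4, :] = net.w1[0, :]  # identical weights
        trace = simple_trace(tensor, [net], [net], [0.9])
        res = shap_values(
            trace, tensor, method="exact", n_rows=10, background_size=12, seed=2
        )
        np.testing.assert_allclose(res.phi[:, 0], res.phi[:, 4], atol=1e-10)

    def test_kernel_tracks_exact_enumeration(self):
        # pairwise-Moebius estimator vs full 2^J enumeration at J = 5,
        # averaged over independently drawn networks: the per-predictor
        # importance ordering (what the consensus ranking consumes) must
        # agree, and the per-row attributions must correlate strongly
        row_rho, agg_rho = [], []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            tensor = make_tensor(rng, n_species=6)
            net = random_net(rng, 5, scale=0.9)
            trace = simple_trace(tensor, [net], [net], [1.0])
            kw = dict(rows=np.arange(15), background_size=20, seed=3)
            exact = shap_values(trace, tensor, method="exact", **kw)
            kernel = shap_values(trace, tensor, method="kernel", **kw)
            row_rho.append(spearmanr(exact.phi.ravel(), kernel.phi.ravel()).statistic)
            agg_rho.append(spearmanr(exact.mean_abs(), kernel.mean_abs()).statistic)
        assert np.mean(agg_rho) > 0.95
        assert np.mean(row_rho) > 0.9

    def test_kappa_exceeding_predictors_rejected(self, rng):
        tensor = make_tensor(rng, n_pred=2)
        net = random_net(rng, 2)
        trace = simple_trace(tensor, [net], [net], [1.0])
        with pytest.raises(ValueError, match="kappa"):
            shap_values(trace, tensor, kappa=3)


class TestConsensusRank:
    def test_unanimous_metrics(self):
        table = pd.DataFrame(
            {"m1": [3.0, 2.0, 1.0], "m2": [30, 20, 10], "m3": [0.9, 0.5, 0.1]},
            index=["A", "B", "C"],
        )
        assert consensus_rank(table) == ["A", "B", "C"]

    def test_majority_wins_first_place(self):
        # metric ranks: (A,B,C), (A,C,B), (A,B,C) -> A first
        table = pd.DataFrame(
            {
                "m1": [3.0, 2.0, 1.0],
                "m2": [3.0, 1.0, 2.0],
                "m3": [3.0, 2.0, 1.0],
            },
            index=["A", "B", "C"],
        )
        order = consensus_rank(table)
        assert order[0] == "A"
        assert order == ["A", "B", "C"]

    @staticmethod
    def _kendall(order_a, order_b):
        pos = {x: i for i, x in enumerate(order_b)}
        d = 0
        for x, y in itertools.combinations(order_a, 2):
            if pos[x] > pos[y]:
                d += 1
        return d

    def test_matches_brute_force_kemeny_on_near_consistent_tables(self, rng):
        items = list("ABCDE")
        for _ in range(8):
            base = rng.permutation(5)
            metrics = {}
            for m in range(3):
                scores = 5 - base.astype(float)
                j = rng.integers(4)  # one adjacent swap per metric
                order = np.argsort(-scores)
                scores[order[j]], scores[order[j + 1]] = (
                    scores[order[j + 1]],
                    scores[order[j]],
                )
                metrics[f"m{m}"] = scores
            table = pd.DataFrame(metrics, index=items)
            got = consensus_rank(table)
            metric_orders = [
                [items[i] for i in np.argsort(-table[c].to_numpy(), kind="stable")]
                for c in table.columns
            ]
            best, best_cost = None, np.inf
            for perm in itertools.permutations(items):
                cost = sum(self._kendall(list(perm), mo) for mo in metric_orders)
                if cost < best_cost:
                    best, best_cost = list(perm), cost
            got_cost = sum(self._kendall(got, mo) for mo in metric_orders)
            assert got_cost == best_cost


class TestImportanceTable:
    def test_table_ranks_every_predictor_once(self, rng):
        tensor = make_tensor(rng, n_species=5, n_bins=4, n_pred=4)
        net = random_net(rng, 4)
        trace = simple_trace(tensor, [net, net], [net, net], [0.9, 0.8])
        table = build_importance_table(
            trace,
            None,
            tensor,
            n_grid=5,
            n_permutations=2,
            n_shap_rows=8,
            background_size=8,
        )
        assert sorted(table.index) == ["p0", "p1", "p2", "p3"]
        assert sorted(table["consensus_rank"]) == [1, 2, 3, 4]
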