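import math

import dendropy
import numpy as np
import pytest

from bdnn.simulator import (
    ScenarioSpec,
    SimulatedClade,
    scenario_rates,
    simulate_clade,
    simulate_dataset,
    simulate_preservation,
    synthetic_temperature,
)


class TestScenarioRates:
    def test_constant_scenario(self):
        assert scenario_rates(ScenarioSpec(1), 17.3, 2.0, 1) == (0.2, 0.1)

    def test_logistic_midpoints_and_asymptotes(self):
        spec = ScenarioSpec(2)
        lam_mid, _ = scenario_rates(spec, 20.0)
        assert lam_mid == pytest.approx((0.4 + 0.1) / 2)
        _, mu_mid = scenario_rates(spec, 15.0)
        assert mu_mid == pytest.approx((0.05 + 0.4) / 2)
        lam_old, mu_old = scenario_rates(spec, 60.0)
        lam_now, mu_now = scenario_rates(spec, 0.0)
        assert lam_old == pytest.approx(0.4, abs=1e-5)
        assert mu_old == pytest.approx(0.05, abs=1e-5)
        assert lam_now < 0.11 and mu_now > 0.35

    def test_shift_scenario_piecewise_values(self):
        spec = ScenarioSpec(3)
        assert scenario_rates(spec, 25.0) == (0.4, 0.05)
        assert scenario_rates(spec, 12.0) == (0.1, 0.3)
        assert scenario_rates(spec, 5.0) == (0.01, 0.01)

    def test_temperature_bell_and_inversion(self):
        spec = ScenarioSpec(4)
        lam0, mu0 = scenario_rates(spec, 10.0, temp=0.0, cat_state=0)
        assert (lam0, mu0) == (0.5, 0.4)
        lam_inv, _ = scenario_rates(spec, 10.0, temp=0.0, cat_state=1)
        assert lam_inv == 0.0
        lam_dev, _ = scenario_rates(spec, 10.0, temp=1.2, cat_state=0)
        assert lam_dev == pytest.approx(0.5 * math.exp(-0.5))

    def test_state_multiplier_scenario(self):
        spec = ScenarioSpec(5)
        lam1, mu1 = scenario_rates(spec, 35.0, cat_state=0)
        assert (lam1, mu1) == (0.1, 0.01)
        lam1b, mu1b = scenario_rates(spec, 0.0, cat_state=0)
        assert mu1b == pytest.approx(0.1)  # linear rise meets speciation
        lam2, mu2 = scenario_rates(spec, 0.0, cat_state=1)
        assert lam2 == pytest.approx(5 * lam1b) and mu2 == pytest.approx(5 * mu1b)

    def test_trait_bell_calibrations(self):
        spec = ScenarioSpec(6)
        assert scenario_rates(spec, 5.0, 0.0) == (0.5, 0.4)
        lam, mu = scenario_rates(spec, 5.0, spec.trait_sd)
        assert lam == pytest.approx(0.5 * 0.3)
        assert mu == pytest.approx(0.4 * 0.3)
        alt = ScenarioSpec(6, bell_calibration="reach20")
        lam2, _ = scenario_rates(alt, 5.0, 2 * alt.trait_sd)
        assert lam2 == pytest.approx(0.5 * 0.2)

    def test_interaction_scenarios_invert_the_bell(self):
        spec7 = ScenarioSpec(7)
        lam, _ = scenario_rates(spec7, 5.0, 0.0, cat_state=1)
        assert lam == 0.0
        far = scenario_rates(spec7, 5.0, 10 * spec7.trait_sd, cat_state=1)[0]
        assert far == pytest.approx(0.5, abs=1e-3)
        spec8 = ScenarioSpec(8)
        before, _ = scenario_rates(spec8, 20.0, 0.0)
        after, _ = scenario_rates(spec8, 10.0, 0.0)
        assert before == 0.5 and after == 0.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            ScenarioSpec(10)


class TestSyntheticTemperature:
    def test_scaling_determinism_autocorrelation(self):
        a = synthetic_temperature(3)
        b = synthetic_temperature(3)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.std() == pytest.approx(1.0, abs=1e-9)
        v = a.values
        lag1 = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert lag1 > 0.9


class TestSimulateClade:
    def test_pure_birth_matches_yule_expectation(self):
        lam = 0.2
        T = 10.0
        spec = ScenarioSpec(
            1,
            root_age=T,
            target_richness=(1, 10**6),
            rate_override=lambda t, x, st, temp: (
                np.full_like(t, lam),
                np.zeros_like(t),
            ),
        )
        counts = [simulate_clade(spec, seed).n_species for seed in range(500)]
        expected = math.exp(lam * T)
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3.5 * se

    def test_no_events_leaves_single_extant_root(self):
        spec = ScenarioSpec(
            1,
            root_age=5.0,
            target_richness=(1, 10),
            rate_override=lambda t, x, st, temp: (
                np.zeros_like(t),
                np.zeros_like(t),
            ),
        )
        clade = simulate_clade(spec, 0)
        assert clade.n_species == 1
        assert clade.extant[0]
        assert clade.s[0] == 5.0 and clade.e[0] == 0.0

    def test_richness_window_enforced(self):
        spec = ScenarioSpec(1, target_richness=(50, 150), max_retries=500)
        for seed in range(3):
            clade = simulate_clade(spec, seed)
            assert 50 <= clade.n_species <= 150

    def test_true_rates_reproducible_from_stored_traits(self):
        spec = ScenarioSpec(6, target_richness=(30, 120), max_retries=500)
        clade = simulate_clade(spec, 3)
        k = np.arange(clade.n_steps)
        ages = spec.root_age - k * spec.dt
        for i in (0, clade.n_species // 2, clade.n_species - 1):
            valid = ~np.isnan(clade.lam_true[i])
            lam, mu = scenario_rates(
                spec, ages[valid], clade.traits[i, :-1][valid], clade.state[i]
            )
            np.testing.assert_allclose(clade.lam_true[i][valid], lam, atol=1e-12)
            np.testing.assert_allclose(clade.mu_true[i][valid], mu, atol=1e-12)

    def test_scenario5_state2_rates_exactly_fivefold(self):
        spec = ScenarioSpec(5, target_richness=(30, 120), max_retries=500)
        clade = simulate_clade(spec, 4)
        assert set(np.unique(clade.state)) == {0, 1}
        k = np.arange(clade.n_steps)
        base_mu = 0.01 + 0.09 * (k * spec.dt) / spec.root_age
        for i in range(clade.n_species):
            valid = ~np.isnan(clade.mu_true[i])
            mult = 5.0 if clade.state[i] else 1.0
            np.testing.assert_allclose(
                clade.mu_true[i][valid], mult * base_mu[valid], atol=1e-12
            )

    def test_child_origination_during_parent_lifespan(self):
        spec = ScenarioSpec(1, target_richness=(30, 120), max_retries=500)
        clade = simulate_clade(spec, 9)
        for i in range(1, clade.n_species):
            p = clade.parent[i]
            assert clade.s[i] < clade.s[p]
            assert clade.s[i] >= clade.e[p]


class TestTree:
    def _divergence_oracle(self, clade, i, j):
        """MRCA age on a budding tree from the parent chains alone."""

        def chain(i):
            out = []
            while i >= 0:
                out.append(i)
                i = clade.parent[i]
            return out

        ci, cj = chain(i), chain(j)
        si = set(ci)
        a = next(x for x in cj if x in si)  # most recent common ancestral lineage
        up_i = ci[: ci.index(a)]
        up_j = cj[: cj.index(a)]
        t_i = clade.s[up_i[-1]] if up_i else clade.e[i] if clade.death_step[i] >= 0 else 0.0
        t_j = clade.s[up_j[-1]] if up_j else clade.e[j] if clade.death_step[j] >= 0 else 0.0
        return max(t_i, t_j)

    def test_newick_patristic_distances_match_parent_chain_oracle(self, rng):
        spec = ScenarioSpec(1, target_richness=(20, 60), max_retries=500)
        clade = simulate_clade(spec, 6)
        tree = dendropy.Tree.get(data=clade.newick(), schema="newick")
        assert len(tree.leaf_nodes()) == clade.n_species
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        pairs = rng.choice(clade.n_species, size=(15, 2))
        ends = np.where(clade.extant, 0.0, clade.e)
        for i, j in pairs:
            if i == j:
                continue
            T = self._divergence_oracle(clade, i, j)
            expected = (T - ends[i]) + (T - ends[j])
            got = pdm.patristic_distance(taxa[clade.names[i]], taxa[clade.names[j]])
            assert got == pytest.approx(expected, abs=1e-4)


class TestPreservation:
    def test_occurrences_inside_lifespans(self):
        spec = ScenarioSpec(1, target_richness=(50, 150), max_retries=500)
        clade = simulate_clade(spec, 8)
        ds = simulate_preservation(clade, seed=1)
        for taxon in ds.taxa:
            i = clade.index_of(taxon.name)
            assert np.all(taxon.ages <= clade.s[i] + 1e-9)
            assert np.all(taxon.ages >= clade.e[i] - 1e-9)

    def test_poisson_mean_oracle_at_fixed_rate(self):
        spec = ScenarioSpec(
            1,
            root_age=10.0,
            target_richness=(1, 10),
            rate_override=lambda t, x, st, temp: (np.zeros_like(t), np.zeros_like(t)),
        )
        clade = simulate_clade(spec, 0)  # one lineage spanning 10 Myr
        counts = [
            len(simulate_preservation(clade, seed=s, q=1.0, alpha=np.inf).taxa[0].ages)
            for s in range(1000)
        ]
        # E[K | K >= 1] = r / (1 - e^-r) for r = 10
        expected = 10.0 / (1 - math.exp(-10.0))
        assert np.mean(counts) == pytest.approx(expected, abs=3.5 * np.std(counts) / math.sqrt(len(counts)))

    def test_observed_trait_is_mean_at_occurrence_times(self):
        spec = ScenarioSpec(6, target_richness=(30, 120), max_retries=500)
        sim = simulate_dataset(spec, 7)
        taxon = sim.dataset.taxa[0]
        i = sim.clade.index_of(taxon.name)
        expected = np.mean([sim.clade.trait_at(i, a) for a in taxon.ages])
        assert sim.traits.loc[taxon.name, "cont_trait"] == pytest.approx(expected)

    def test_scenario9_withholds_causal_trait(self):
        sim = simulate_dataset(
            ScenarioSpec(9, target_richness=(30, 120), max_retries=500), 2
        )
        assert "cont_trait" not in sim.traits.columns
        assert "noise_trait" in sim.traits.columns


class TestSimulateDataset:
    def test_bundle_is_consistent(self):
        sim = simulate_dataset(
            ScenarioSpec(5, target_richness=(40, 140), max_retries=500), 3
        )
        assert sim.dataset.n_taxa == len(sim.traits)
        assert sim.eigenvectors is not None
        assert sim.eigenvectors.coords.shape == (sim.dataset.n_taxa, 2)
        assert len(sim.true_lambda) == sim.dataset.n_taxa
        assert np.all(sim.true_lambda > 0) and np.all(sim.true_mu > 0)

    def test_scenario4_bundle_includes_temperature_series(self):
        sim = simulate_dataset(
            ScenarioSpec(4, target_richness=(30, 140), max_retries=500), 4
        )
        assert sim.time_series is not None
        assert len(sim.time_series["temperature"]) == len(sim.dataset.time_bins) - 1
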