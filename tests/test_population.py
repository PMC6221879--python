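"""Base populations, Mendelian inheritance, pair matching, cohort engine."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from igevar.errors import MatchingError, StateError
from igevar.model_core import EffectSet, Individual, scenario_params
from igevar.population import (
    assign_groups,
    make_offspring,
    match_pairs,
    sample_base_population,
    sample_effects,
    simulate_cohort,
)

EFFECTS = ("A_GR", "E_p_GR", "A_D", "E_D", "A_I", "E_I")


class TestSampleEffects:
    def test_zero_variance_gives_zero_effects(self, rng, small_params):
        p = small_params(3, var_A_GR=0, var_Ep_GR=0, var_Et_GR=0,
                         var_AD=0, var_AI=0, var_ED=0, var_EI=0)
        eff = sample_effects(p, 500, rng)
        for name in EFFECTS:
            assert np.all(getattr(eff, name) == 0.0)

    def test_base_variances_and_independence(self, rng):
        p = scenario_params(3)
        n = 20_000
        eff = sample_effects(p, n, rng)
        assert np.var(eff.A_GR, ddof=1) == pytest.approx(1.0, rel=0.05)
        assert np.var(eff.A_D, ddof=1) == pytest.approx(0.225e-3, rel=0.05)
        # i.i.d. draws: all 15 pairwise correlations within 3/sqrt(n) of zero
        mat = np.corrcoef(np.vstack([getattr(eff, k) for k in EFFECTS]))
        off_diag = mat[np.triu_indices(6, k=1)]
        assert np.abs(off_diag).max() < 3 / np.sqrt(n)


class TestMakeOffspring:
    def test_midpoint_exact_without_sampling_variance(self, rng, small_params):
        p = small_params(3, var_A_GR=0)
        sire = Individual(id=1, effects=EffectSet(A_GR=0.02))
        dam = Individual(id=2, effects=EffectSet(A_GR=0.04))
        child = make_offspring(sire, dam, p, rng)
        assert child.effects.A_GR == pytest.approx(0.03, abs=1e-15)
        assert (child.sire_id, child.dam_id) == (1, 2)

    def test_mendelian_sampling_variance_is_half_additive(self, rng, small_params):
        """Within one full-sib family, Var(A) around the midpoint is sigma2/2."""
        p = small_params(3)
        sire = Individual(id=1, effects=EffectSet(A_GR=0.5))
        dam = Individual(id=2, effects=EffectSet(A_GR=-0.3))
        n = 30_000
        a = np.array([make_offspring(sire, dam, p, rng).effects.A_GR for _ in range(n)])
        assert a.mean() == pytest.approx(0.1, abs=4 * np.sqrt(0.5 / n))
        assert a.var(ddof=1) == pytest.approx(0.5, rel=4 * np.sqrt(2.0 / n))

    def test_offspring_variance_across_families_restores_base(self, rng, small_params):
        """1/4 sigma2 (sire) + 1/4 sigma2 (dam) + 1/2 sigma2 (Mendelian) = sigma2."""
        p = small_params(3)
        n = 5_000
        sires = sample_effects(p, n, rng)
        dams = sample_effects(p, n, rng)
        offspring = np.array([
            make_offspring(
                Individual(id=1, effects=EffectSet(A_GR=float(sires.A_GR[k]))),
                Individual(id=2, effects=EffectSet(A_GR=float(dams.A_GR[k]))),
                p, rng,
            ).effects.A_GR
            for k in range(n)
        ])
        assert offspring.var(ddof=1) == pytest.approx(1.0, rel=5 * np.sqrt(2.0 / n))


class TestMatchPairs:
    def test_every_individual_in_exactly_one_pair(self, rng):
        pairs = match_pairs(np.zeros(40, dtype=int), rng, policy="random")
        assert pairs.shape == (20, 2)
        assert sorted(pairs.ravel().tolist()) == list(range(40))

    def test_odd_count_rejected(self, rng):
        with pytest.raises(MatchingError):
            match_pairs(np.zeros(5, dtype=int), rng)

    def test_uniform_over_all_matchings_of_six(self, rng):
        """All 15 perfect matchings of 6 individuals occur uniformly."""
        counts = Counter()
        for _ in range(10_000):
            pairs = match_pairs(np.arange(6), rng, policy="random")
            key = tuple(sorted(tuple(sorted(p)) for p in pairs.tolist()))
            counts[key] += 1
        assert len(counts) == 15
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-4

    def test_non_sib_policy_forbids_shared_sires(self, rng):
        sires = np.repeat(np.arange(10), 20)  # 10 sires x 20 offspring
        for _ in range(5):
            pairs = match_pairs(sires, rng, policy="non-sib")
            assert (sires[pairs[:, 0]] != sires[pairs[:, 1]]).all()

    def test_non_sib_infeasible_raises(self, rng):
        with pytest.raises(MatchingError):
            match_pairs(np.zeros(8, dtype=int), rng, policy="non-sib")

    def test_assign_groups_object_api(self, rng):
        inds = [Individual(id=k, effects=EffectSet(A_D=0.01 * k), sire_id=k)
                for k in range(4)]
        groups = assign_groups(inds, rng, policy="random", b_bar=-0.05)
        assert len(groups) == 2
        seen = sorted(g.member_i.id for g in groups) + sorted(g.member_j.id for g in groups)
        assert sorted(seen) == [0, 1, 2, 3]
        for g in groups:
            assert g.b_ij == pytest.approx(
                -0.05 + g.member_i.effects.A_D + g.member_j.effects.A_I
            )


class TestBasePopulation:
    def test_structure_and_pairing_invariants(self, rng, small_params):
        p = small_params(3)
        cohort = sample_base_population(p, rng)
        assert cohort.n == 2 * p.n_groups == 500
        assert cohort.n_groups == p.n_groups
        # every individual in exactly one group
        assert sorted(cohort.pair_members.ravel().tolist()) == list(range(cohort.n))
        # pedigree links resolve to the parent panels
        assert set(cohort.sire_ids) <= set(cohort.sires.ids)
        assert set(cohort.dam_ids) <= set(cohort.dams.ids)
        # non-sib grouping respected
        s = cohort.sire_ids
        assert (s[cohort.pair_members[:, 0]] != s[cohort.pair_members[:, 1]]).all()

    def test_zero_variances_give_zero_effects_everywhere(self, rng, small_params):
        p = small_params(3, var_A_GR=0, var_Ep_GR=0, var_Et_GR=0,
                         var_AD=0, var_AI=0, var_ED=0, var_EI=0)
        cohort = sample_base_population(p, rng)
        for name in EFFECTS:
            assert np.all(getattr(cohort.effects, name) == 0.0)
        assert np.all(cohort.b_own == p.b_bar)

    def test_offspring_genetic_variance_near_base(self, rng):
        p = scenario_params(3, n_sires=100, n_dams_per_sire=10,
                            n_offspring_per_dam=2, n_groups=1000)
        cohort = sample_base_population(p, rng)
        # Var over 2000 offspring of 100 sires; clustering widens the CI, so 10%
        assert np.var(cohort.effects.A_GR, ddof=1) == pytest.approx(1.0, rel=0.15)
        # A_D vs A_GR independent; family clustering inflates Var(r_hat) to
        # ~(1 + 19 * 0.25^2)/n ~= 2.2/n for 20-member half-sib families
        r = np.corrcoef(cohort.effects.A_D, cohort.effects.A_GR)[0, 1]
        assert abs(r) < 3 * np.sqrt(2.2 / cohort.n)

    def test_pair_b_variance_is_sum_of_components(self, rng):
        p = scenario_params(3)
        cohort = sample_base_population(p, rng)
        # Var(b) = var_AD + var_ED + var_AI + var_EI = 9e-4 under the defaults
        assert np.var(cohort.b_own, ddof=1) == pytest.approx(9e-4, rel=0.1)

    def test_start_weights_distribution(self, rng, small_params):
        p = small_params(3)
        cohort = sample_base_population(p, rng)
        w0 = cohort.weights[:, 0]
        assert w0.mean() == pytest.approx(10.0, abs=4 * p.start_weight_sd / np.sqrt(cohort.n))
        assert w0.std(ddof=1) == pytest.approx(p.start_weight_sd, rel=0.15)


class TestSimulateCohort:
    def test_array_engine_matches_object_engine_when_deterministic(self, rng, small_params):
        """The vectorized update and the per-group update are the same model."""
        from igevar.model_core import simulate_group_trajectory

        p = small_params(1, var_Et_GR=0)  # noise-free growth, heterogeneous b
        cohort = sample_base_population(p, rng)
        object_groups = list(cohort.groups())      # snapshot before simulation
        simulate_cohort(cohort, p, rng)
        sub_rng = np.random.default_rng(0)
        for g, (i, j) in zip(object_groups[:25], cohort.pair_members[:25]):
            simulate_group_trajectory(g, p, sub_rng)
            np.testing.assert_allclose(g.member_i.weights, cohort.weights[i], rtol=1e-12)
            np.testing.assert_allclose(g.member_j.weights, cohort.weights[j], rtol=1e-12)

    def test_trajectory_shape_and_reproducibility(self, small_params):
        p = small_params(2)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            runs.append(simulate_cohort(sample_base_population(p, rng), p, rng).weights)
        assert runs[0].shape == (500, p.n_time_points + 1)
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_double_simulation_rejected(self, rng, small_params):
        p = small_params(3)
        cohort = simulate_cohort(sample_base_population(p, rng), p, rng)
        with pytest.raises(StateError):
            simulate_cohort(cohort, p, rng)


class TestWriters:
    def test_tidy_table_round_trip(self, rng, small_params, tmp_path):
        import pandas as pd

        p = small_params(3)
        cohort = simulate_cohort(sample_base_population(p, rng), p, rng)
        path = tmp_path / "cohort.tsv"
        cohort.write_table(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == cohort.n * (p.n_time_points + 1)
        assert {"generation", "id", "group", "time_point", "weight", "b_value"} <= set(df.columns)
        one = df[df["id"] == df["id"].iloc[0]].sort_values("time_point")
        np.testing.assert_allclose(one["weight"].to_numpy(), cohort.weights[0], rtol=1e-6)

    def test_pedigree_uses_zero_for_unknown(self, toy_cohort, tmp_path):
        import pandas as pd

        cohort = toy_cohort([[10.0], [11.0]], [[0, 1]])
        path = tmp_path / "ped.tsv"
        cohort.write_pedigree(path)
        ped = pd.read_csv(path, sep="\t")
        assert list(ped.columns) == ["id", "sire", "dam"]
        assert (ped["sire"] == 0).all() and (ped["dam"] == 0).all()
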