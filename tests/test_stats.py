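"""Differential-correlation statistics and the permutation test."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hubmod as hm
from hubmod.stats import CorrelationProfile, _anova_f


class TestPairCorrelation:
    def test_perfect_linear_dependence(self):
        x = [1, 2, 3, 4]
        assert hm.pair_correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # centred dot product 4 over sqrt(5*5)
        assert hm.pair_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == \
            pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert math.isnan(hm.pair_correlation([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_too_few_complete_pairs_undefined(self):
        x = [1.0, 2.0, np.nan, np.nan]
        y = [1.0, 2.0, 3.0, 4.0]
        assert math.isnan(hm.pair_correlation(x, y))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hm.pair_correlation([1, 2, 3], [1, 2])

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_scipy_on_random_vectors(self, method):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = rng.standard_normal((2, 15))
            ours = hm.pair_correlation(x, y, method=method)
            ref = (sps.pearsonr(x, y).statistic if method == "pearson"
                   else sps.spearmanr(x, y).statistic)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_pairwise_complete_matches_scipy_on_masked(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal((2, 20))
        x[3] = np.nan
        y[7] = np.nan
        mask = np.isfinite(x) & np.isfinite(y)
        ref = sps.pearsonr(x[mask], y[mask]).statistic
        assert hm.pair_correlation(x, y) == pytest.approx(ref, abs=1e-12)


class TestModuleProfile:
    def _dataset(self, rho_a, rho_b, n=12, k=5, seed=3):
        design = hm.SimulationDesign(
            modules=[hm.ModuleSpec(hub_id="H", n_partners=k,
                                   rho={"A": rho_a, "B": rho_b})],
            samples_per_condition={"A": n, "B": n}, seed=seed)
        return hm.simulate_dataset(design)

    def test_planted_perfect_correlation(self):
        sim = self._dataset(1.0, 1.0)
        module = hm.identify_hubs(sim.network, sim.expression, 5)[0]
        profile = hm.module_profile(sim.expression, sim.labels, module)
        assert np.allclose(profile.corr, 1.0)

    def test_matches_per_pair_scipy_oracle(self):
        sim = self._dataset(0.7, -0.2)
        module = hm.identify_hubs(sim.network, sim.expression, 5)[0]
        profile = hm.module_profile(sim.expression, sim.labels, module)
        assert profile.corr.shape == (5, 2)
        for j, pid in enumerate(profile.partner_ids):
            for ci, cond in enumerate(profile.conditions):
                cols = [s for s in sim.expression.sample_ids
                        if sim.labels.assignment[s] == cond]
                ref = sps.pearsonr(sim.expression.data.loc["H", cols],
                                   sim.expression.data.loc[pid, cols]).statistic
                assert profile.corr[j, ci] == pytest.approx(ref, abs=1e-12)

    def test_partner_constant_in_one_condition_dropped(self):
        sim = self._dataset(0.5, 0.5)
        # make one partner flat within condition A only
        a_cols = [s for s in sim.expression.sample_ids
                  if sim.labels.assignment[s] == "A"]
        sim.expression.data.loc["H_P03", a_cols] = 7.0
        module = hm.identify_hubs(sim.network, sim.expression, 5)[0]
        profile = hm.module_profile(sim.expression, sim.labels, module)
        assert "H_P03" not in profile.partner_ids
        assert profile.n_dropped == 1

    def test_all_partners_dropped_excludes_module(self):
        sim = self._dataset(0.5, 0.5, k=2)
        sim.expression.data.loc["H_P01"] = 1.0
        sim.expression.data.loc["H_P02"] = 2.0
        module = hm.identify_hubs(sim.network, sim.expression, 2)[0]
        with pytest.raises(hm.DegenerateModuleError):
            hm.module_profile(sim.expression, sim.labels, module)


def _profile(corr, conditions=None):
    corr = np.asarray(corr, dtype=float)
    conditions = tuple(conditions or
                       (f"C{i}" for i in range(corr.shape[1])))
    return CorrelationProfile(hub="H", partner_ids=tuple(
        f"P{i}" for i in range(corr.shape[0])), conditions=conditions,
        corr=corr)


class TestStatistics:
    def test_two_condition_null_is_zero(self):
        assert hm.two_condition_statistic(
            _profile([[0.4, 0.4], [0.1, 0.1]])) == 0.0

    def test_two_condition_hand_value_and_symmetry(self):
        p = _profile([[0.9, 0.1], [0.7, -0.1]])
        assert hm.two_condition_statistic(p) == pytest.approx(0.8, abs=1e-12)
        swapped = _profile([[0.1, 0.9], [-0.1, 0.7]])
        assert hm.two_condition_statistic(swapped) == \
            pytest.approx(hm.two_condition_statistic(p), abs=1e-15)

    def test_two_condition_rejects_other_counts(self):
        with pytest.raises(ValueError, match="f_statistic"):
            hm.two_condition_statistic(_profile([[0.1, 0.2, 0.3]] * 2))

    def test_f_hand_computed_anova(self):
        # groups [0.8,0.6], [0.2,0.0], [0.5,0.3]: SSB=0.36/2df, SSW=0.06/3df
        p = _profile([[0.8, 0.2, 0.5], [0.6, 0.0, 0.3]])
        assert hm.f_statistic(p) == pytest.approx(9.0, abs=1e-9)

    def test_f_zero_when_all_equal(self):
        assert hm.f_statistic(_profile([[0.5, 0.5, 0.5]] * 3)) == 0.0

    def test_f_infinite_when_within_variance_zero(self):
        assert hm.f_statistic(_profile([[0.2, 0.8], [0.2, 0.8]])) == math.inf

    def test_f_equals_squared_pooled_t_for_two_groups(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            corr = rng.uniform(-1, 1, size=(6, 2))
            f = hm.f_statistic(_profile(corr))
            t = sps.ttest_ind(corr[:, 0], corr[:, 1], equal_var=True).statistic
            assert f == pytest.approx(t ** 2, abs=1e-10)

    def test_f_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(6)
        corr = rng.uniform(-1, 1, size=(7, 4))
        ref = sps.f_oneway(*[corr[:, j] for j in range(4)]).statistic
        assert hm.f_statistic(_profile(corr)) == pytest.approx(ref, rel=1e-12)


def _toy_44(seed=21, k=5, rho_a=0.9, rho_b=0.0):
    design = hm.SimulationDesign(
        modules=[hm.ModuleSpec(hub_id="H", n_partners=k,
                               rho={"A": rho_a, "B": rho_b})],
        samples_per_condition={"A": 4, "B": 4}, seed=seed)
    return hm.simulate_dataset(design)


def exhaustive_oracle_p(X, n_a):
    """Brute-force enumeration of all C(n, n_a) group-A choices using
    scipy correlations; independent of the package's permutation code."""
    n = X.shape[1]

    def statistic(a_cols):
        b_cols = [i for i in range(n) if i not in a_cols]
        means = []
        for cols in (list(a_cols), b_cols):
            rs = [sps.pearsonr(X[0, cols], X[j, cols]).statistic
                  for j in range(1, X.shape[0])]
            means.append(np.mean(rs))
        return abs(means[0] - means[1])

    observed = statistic(tuple(range(n_a)))
    values = [statistic(c) for c in itertools.combinations(range(n), n_a)]
    return sum(v >= observed for v in values) / len(values)


class TestPermutationTest:
    def test_exhaustive_matches_enumeration_oracle(self):
        sim = _toy_44()
        module = hm.identify_hubs(sim.network, sim.expression, 5)[0]
        plan = hm.PermutationPlan(seed=0, mode="exhaustive")
        res = hm.permutation_test(sim.expression, sim.labels, module, plan)
        X = sim.expression.data.loc[["H"] + list(module.partners)].to_numpy()
        assert res.n_permutations == 70
        assert res.p_value == exhaustive_oracle_p(X, 4)

    def test_identical_conditions_give_p_one(self):
        # condition B duplicates condition A sample-for-sample: the
        # observed statistic is exactly 0, so every permutation is >= it
        rng = np.random.default_rng(9)
        block = rng.standard_normal((6, 4))
        data = pd.DataFrame(np.hstack([block, block]),
                            index=["H"] + [f"P{i}" for i in range(5)],
                            columns=[f"a{i}" for i in range(4)]
                                    + [f"b{i}" for i in range(4)])
        expr = hm.ExpressionMatrix(data)
        labels = hm.ConditionLabels(
            {f"a{i}": "A" for i in range(4)} |
            {f"b{i}": "B" for i in range(4)})
        module = hm.NetworkModule("H", tuple(f"P{i}" for i in range(5)))
        res = hm.permutation_test(expr, labels, module,
                                  hm.PermutationPlan(seed=1,
                                                     n_permutations=99))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_extreme_effect_hits_permutation_floor(self):
        design = hm.SimulationDesign(
            modules=[hm.ModuleSpec(hub_id="H", n_partners=8,
                                   rho={"A": 0.95, "B": -0.95})],
            samples_per_condition={"A": 15, "B": 15}, seed=4)
        sim = hm.simulate_dataset(design)
        module = hm.identify_hubs(sim.network, sim.expression, 8)[0]
        res = hm.permutation_test(
            sim.expression, sim.labels, module,
            hm.PermutationPlan(seed=5, n_permutations=99))
        assert res.p_value == pytest.approx(1 / 100)

    def test_sampled_consistent_with_exhaustive(self):
        sim = _toy_44(seed=30, rho_a=0.8, rho_b=-0.3)
        module = hm.identify_hubs(sim.network, sim.expression, 5)[0]
        exact = hm.permutation_test(
            sim.expression, sim.labels, module,
            hm.PermutationPlan(seed=0, mode="exhaustive")).p_value
        b = 5000
        sampled = hm.permutation_test(
            sim.expression, sim.labels, module,
            hm.PermutationPlan(seed=17, n_permutations=b)).p_value
        se = math.sqrt(exact * (1 - exact) / b)
        assert abs(sampled - exact) <= 3 * se + 1 / (b + 1)

    def test_exhaustive_cap_enforced(self):
        design = hm.SimulationDesign(
            modules=[hm.ModuleSpec(hub_id="H", n_partners=3,
                                   rho={"A": 0.5, "B": 0.5})],
            samples_per_condition={"A": 12, "B": 12}, seed=1)
        sim = hm.simulate_dataset(design)
        module = hm.identify_hubs(sim.network, sim.expression, 3)[0]
        with pytest.raises(ValueError, match="cap"):
            hm.permutation_test(sim.expression, sim.labels, module,
                                hm.PermutationPlan(seed=0, mode="exhaustive"))


class TestIdentifySignificantHubs:
    def test_planted_module_attains_smallest_p(self, small_sim):
        res = hm.identify_significant_hubs(
            small_sim.expression, small_sim.labels, small_sim.network,
            min_partners=5, plan=hm.PermutationPlan(seed=8,
                                                    n_permutations=199))
        assert len(res) == 4
        best = min(res, key=lambda r: r.p_value)
        assert best.hub == "DYS001"

    def test_three_conditions_dispatch_to_f(self):
        design = hm.SimulationDesign(
            modules=[hm.ModuleSpec(hub_id="H", n_partners=5,
                                   rho={"A": 0.8, "B": 0.8, "C": 0.0})],
            samples_per_condition={"A": 8, "B": 8, "C": 8}, seed=2)
        sim = hm.simulate_dataset(design)
        res = hm.identify_significant_hubs(
            sim.expression, sim.labels, sim.network, min_partners=5,
            plan=hm.PermutationPlan(seed=3, n_permutations=49))
        assert res and all(r.statistic_kind == "anova_f" for r in res)

    def test_deterministic_under_fixed_seed(self, small_sim):
        kwargs = dict(min_partners=5,
                      plan=hm.PermutationPlan(seed=8, n_permutations=99))
        r1 = hm.identify_significant_hubs(
            small_sim.expression, small_sim.labels, small_sim.network,
            **kwargs)
        r2 = hm.identify_significant_hubs(
            small_sim.expression, small_sim.labels, small_sim.network,
            **kwargs)
        assert r1 == r2

    def test_seed_required(self, small_sim):
        with pytest.raises(ValueError):
            hm.identify_significant_hubs(
                small_sim.expression, small_sim.labels, small_sim.network)


class TestInvariances:
    def test_affine_transform_of_rows(self, small_sim):
        plan = hm.PermutationPlan(seed=13, n_permutations=99)
        base = hm.identify_significant_hubs(
            small_sim.expression, small_sim.labels, small_sim.network,
            min_partners=5, plan=plan)
        rng = np.random.default_rng(14)
        data = small_sim.expression.data.copy()
        scales = rng.uniform(0.5, 3.0, size=len(data))
        offsets = rng.uniform(-10, 10, size=len(data))
        transformed = hm.ExpressionMatrix(
            data.mul(scales, axis=0).add(offsets, axis=0))
        after = hm.identify_significant_hubs(
            transformed, small_sim.labels, small_sim.network,
            min_partners=5, plan=plan)
        for r1, r2 in zip(base, after):
            assert r1.hub == r2.hub
            assert r1.statistic == pytest.approx(r2.statistic, abs=1e-8)
            assert r1.p_value == pytest.approx(r2.p_value, abs=1e-8)

    def test_condition_swap(self, small_sim):
        plan = hm.PermutationPlan(seed=13, n_permutations=99)
        base = hm.identify_significant_hubs(
            small_sim.expression, small_sim.labels, small_sim.network,
            min_partners=5, plan=plan)
        swap = {"A": "B", "B": "A"}
        swapped_labels = hm.ConditionLabels(
            {s: swap[c] for s, c in small_sim.labels.assignment.items()},
            conditions=["A", "B"])
        after = hm.identify_significant_hubs(
            small_sim.expression, swapped_labels, small_sim.network,
            min_partners=5, plan=plan)
        for r1, r2 in zip(base, after):
            assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
            assert r1.p_value == r2.p_value

    def test_condition_renaming(self, small_sim):
        plan = hm.PermutationPlan(seed=13, n_permutations=99)
        base = hm.identify_significant_hubs(
            small_sim.expression, small_sim.labels, small_sim.network,
            min_partners=5, plan=plan)
        renamed = hm.ConditionLabels(
            {s: f"cond_{c}" for s, c in small_sim.labels.assignment.items()})
        after = hm.identify_significant_hubs(
            small_sim.expression, renamed, small_sim.network,
            min_partners=5, plan=plan)
        for r1, r2 in zip(base, after):
            assert r1.statistic == r2.statistic
            assert r1.p_value == r2.p_value
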