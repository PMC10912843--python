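import numpy as np
import pytest

from hmmdyn.metrics import SubjectDynamics
from hmmdyn.stats import (assign_cognitive_groups, compare_metric, fdr_adjust,
                          partial_spearman, permutation_test_transitions)


def _dyn(sid, fo=None, lifetime=None, interval=None, sr=0.1, probs=None, K=3):
    return SubjectDynamics(
        subject_id=sid, n_states=K, tr_seconds=2.0,
        fractional_occupancy=np.asarray(fo if fo is not None else np.full(K, 1 / K), float),
        mean_lifetime=np.asarray(lifetime if lifetime is not None else np.full(K, 4.0), float),
        mean_interval=np.asarray(interval if interval is not None else np.full(K, 8.0), float),
        switching_rate=sr,
        transition_counts=np.zeros((K, K), int),
        transition_probs=np.asarray(probs if probs is not None else np.full((K, K), 1 / K), float),
    )


class TestCompareMetric:
    def test_identical_groups_give_t0_p1(self):
        group = [_dyn(f"s{i}", lifetime=[3.0 + i, 4.0, 5.0]) for i in range(5)]
        other = [_dyn(f"t{i}", lifetime=[3.0 + i, 4.0, 5.0]) for i in range(5)]
        for c in compare_metric(group, other, "lifetime")[:1]:
            assert c.t_statistic == pytest.approx(0.0, abs=1e-12)
            assert c.p_raw == pytest.approx(1.0)

    def test_pooled_variance_formula_on_printed_vectors(self):
        a = [_dyn(f"a{i}", lifetime=[v, v, v]) for i, v in enumerate([1.0, 2.0, 3.0])]
        b = [_dyn(f"b{i}", lifetime=[v, v, v]) for i, v in enumerate([4.0, 5.0, 6.0])]
        c = compare_metric(a, b, "lifetime", variant="student")[0]
        # hand: diff -3, pooled var 1, se sqrt(2/3) -> t = -3.674, df = 4
        assert c.t_statistic == pytest.approx(-3.674, abs=1e-3)
        assert c.p_raw == pytest.approx(0.0214, abs=1e-3)
        assert c.df == 4
        assert c.group_means == (2.0, 5.0)

    def test_welch_variant_differs_under_unequal_variance(self, rng):
        a = [_dyn(f"a{i}", lifetime=np.full(3, v))
             for i, v in enumerate(rng.normal(0, 5, 12))]
        b = [_dyn(f"b{i}", lifetime=np.full(3, v))
             for i, v in enumerate(rng.normal(0, 0.5, 6))]
        student = compare_metric(a, b, "lifetime", variant="student")[0]
        welch = compare_metric(a, b, "lifetime", variant="welch")[0]
        assert welch.df < student.df

    def test_nan_values_dropped_pairwise_with_recorded_n(self):
        a = [_dyn(f"a{i}", interval=[np.nan, 4.0, 5.0]) for i in range(4)]
        a += [_dyn("a9", interval=[2.0, 4.0, 5.0])]
        b = [_dyn(f"b{i}", interval=[3.0, 4.0 + i, 5.0]) for i in range(4)]
        res = compare_metric(a, b, "interval")
        assert res[0].n_per_group == (1, 4)      # state 1: only one finite in A
        assert np.isnan(res[0].p_raw)            # insufficient -> excluded
        assert res[1].n_per_group == (5, 4)

    def test_switching_rate_is_single_global_test(self):
        a = [_dyn(f"a{i}", sr=0.1 + 0.01 * i) for i in range(5)]
        b = [_dyn(f"b{i}", sr=0.2 + 0.01 * i) for i in range(5)]
        res = compare_metric(a, b, "switching_rate")
        assert len(res) == 1
        assert res[0].state == "global"
        assert res[0].q_fdr == pytest.approx(res[0].p_raw)


class TestFDR:
    def test_hand_applied_step_up(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_q_never_below_p_and_monotone(self, rng):
        p = rng.uniform(0, 1, 25)
        q = fdr_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestPermutationTest:
    def _groups(self, rng, n=12, K=3, shift=0.0):
        def draw(tag, delta):
            out = []
            for i in range(n):
                P = rng.dirichlet(np.ones(K) * 5, size=K)
                P[0, 1] += delta
                P /= P.sum(axis=1, keepdims=True)
                out.append(_dyn(f"{tag}{i}", probs=P, K=K))
            return out
        return draw("a", shift), draw("b", 0.0)

    def test_identical_multisets_give_p1(self):
        probs = np.full((3, 3), 1 / 3)
        a = [_dyn(f"a{i}", probs=probs) for i in range(6)]
        b = [_dyn(f"b{i}", probs=probs) for i in range(6)]
        for c in permutation_test_transitions(a, b, n_permutations=99, seed=0):
            assert c.observed_diff == pytest.approx(0.0)
            assert c.p_perm == pytest.approx(1.0)

    def test_group_swap_reflects_sign_keeps_p(self, rng):
        a, b = self._groups(rng, shift=0.1)
        r1 = permutation_test_transitions(a, b, n_permutations=1999, seed=5)
        r2 = permutation_test_transitions(b, a, n_permutations=1999, seed=5)
        for c1, c2 in zip(r1, r2):
            assert c1.observed_diff == pytest.approx(-c2.observed_diff, abs=1e-12)
        p1 = np.array([c.p_perm for c in r1])
        p2 = np.array([c.p_perm for c in r2])
        # identical exchangeable null up to Monte-Carlo noise in the sampled
        # permutations (sd ~ sqrt(p(1-p)/2000) ~ 0.011)
        assert np.abs(p1 - p2).max() <= 0.05

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        a, b = self._groups(rng, n=15, shift=0.25)
        res = permutation_test_transitions(a, b, n_permutations=99, seed=1)
        pmin = min(c.p_perm for c in res)
        assert pmin >= 1 / 100
        assert all(c.p_perm <= 1.0 for c in res)

    def test_deterministic_given_seed(self, rng):
        a, b = self._groups(rng)
        r1 = permutation_test_transitions(a, b, n_permutations=99, seed=7)
        r2 = permutation_test_transitions(a, b, n_permutations=99, seed=7)
        assert [c.p_perm for c in r1] == [c.p_perm for c in r2]

    def test_t_statistic_variant_runs(self, rng):
        a, b = self._groups(rng, shift=0.15)
        res = permutation_test_transitions(a, b, n_permutations=99, seed=0,
                                           statistic="t")
        target = next(c for c in res if c.from_state == 1 and c.to_state == 2)
        assert target.direction == "increase"


class TestPartialSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        r = partial_spearman(x, np.exp(x))
        assert r.rho == pytest.approx(1.0)

    def test_hand_ranks_example(self):
        # ranks d^2 sum = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        r = partial_spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.rho == pytest.approx(0.8)
        from scipy.stats import spearmanr
        ref = spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.rho == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_independent_normals_near_zero(self, rng):
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0, 1, 2000)
        r = partial_spearman(x, y)
        assert abs(r.rho) < 0.06

    def test_agrees_with_pingouin_partial_corr(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 60
        cov = rng.normal(0, 1, (n, 2))
        x = cov[:, 0] + rng.normal(0, 1, n)
        y = 0.5 * x + cov[:, 1] + rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                                    method="spearman")
        r = partial_spearman(x, y, cov, covariate_names=["c1", "c2"])
        assert r.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert r.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_rank_deficient_covariates_rejected(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        cov = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            partial_spearman(x, y, cov)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="complete observations"):
            partial_spearman([1, 2], [2, 1])


class TestCognitiveGrouping:
    def test_cutoff_boundary_goes_to_unimpaired(self):
        impaired, n_boundary = assign_cognitive_groups([20, 25.9, 26, 27, 30])
        np.testing.assert_array_equal(impaired, [True, True, False, False, False])
        assert n_boundary == 1
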