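import numpy as np
import pytest
from scipy import stats

from lsanet.data_io import ReplicatedSeries
from lsanet.lsa_core import LsaParams, local_similarity
from lsanet.significance import (
    InferenceParams,
    _estimate_pi0,
    bootstrap_ci,
    pearson,
    permutation_pvalue,
    storey_qvalues,
)
from lsanet.summarize import normal_score, summarize


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        out = pearson(x, 2 * x + 1)
        assert out.r == pytest.approx(1.0) and out.p == pytest.approx(0.0)

    def test_hand_example(self):
        # r = 0.8, t = 0.8 * sqrt(2 / 0.36), two-sided t CDF with 2 df
        out = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert out.r == pytest.approx(0.8)
        t = 0.8 * np.sqrt(2 / 0.36)
        assert out.p == pytest.approx(2 * stats.t.sf(t, df=2), abs=1e-12)
        assert out.p == pytest.approx(0.1998, abs=5e-4)

    def test_orthogonal_profiles_give_p_one(self):
        x = np.tile([1.0, -1.0], 5)
        y = np.tile([1.0, 1.0, -1.0, -1.0], 5)[:10]
        y = y - y.mean()
        y = y - (x @ y) / (x @ x) * x  # force exact orthogonality
        out = pearson(x, y)
        assert out.r == pytest.approx(0.0, abs=1e-12)
        assert out.p == pytest.approx(1.0)

    def test_matches_scipy_reference(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            ours = pearson(x, y)
            ref_r, ref_p = stats.pearsonr(x, y)
            assert ours.r == pytest.approx(ref_r, abs=1e-12)
            assert ours.p == pytest.approx(ref_p, abs=1e-10)

    def test_zero_variance_warns(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = pearson(np.ones(5), np.arange(5.0))
        assert (out.r, out.p) == (0.0, 1.0)


class TestPermutation:
    def test_constant_profile_gives_p_one(self):
        zx = np.zeros(10)
        zy = normal_score(np.arange(10.0))
        p = permutation_pvalue(zx, zy, 0.0, LsaParams(2), InferenceParams(num_permutations=100))
        assert p == 1.0

    def test_strong_association_gives_small_p(self, rng):
        x = normal_score(rng.standard_normal(20))
        p = permutation_pvalue(
            x, x, local_similarity(x, x, LsaParams(3)).magnitude,
            LsaParams(3), InferenceParams(num_permutations=200),
        )
        assert p <= 0.02

    def test_zero_permutations_reports_missing(self):
        out = permutation_pvalue(np.ones(5), np.ones(5), 1.0, LsaParams(0),
                                 InferenceParams(num_permutations=0))
        assert out is None

    def test_seeded_reproducibility(self):
        zx = normal_score(np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0]))
        zy = normal_score(np.array([2.0, 7.0, 1.0, 8.0, 2.5, 8.5]))
        inf = InferenceParams(num_permutations=500, rng_seed=42)
        p1 = permutation_pvalue(zx, zy, 0.3, LsaParams(1), inf)
        p2 = permutation_pvalue(zx, zy, 0.3, LsaParams(1), inf)
        assert p1 == p2

    def test_exchangeability_of_which_series_is_shuffled(self, rng):
        # on any one pair the conditional permutation distributions differ,
        # but across null pairs, shuffling X or shuffling Y yields the same
        # p-value distribution
        inf = InferenceParams(num_permutations=200)
        p_xy, p_yx = [], []
        for _ in range(120):
            zx = normal_score(rng.standard_normal(12))
            zy = normal_score(rng.standard_normal(12))
            mag = local_similarity(zx, zy, LsaParams(2)).magnitude
            p_xy.append(permutation_pvalue(zx, zy, mag, LsaParams(2), inf, rng=rng))
            p_yx.append(permutation_pvalue(zy, zx, mag, LsaParams(2), inf, rng=rng))
        ks = stats.ks_2samp(p_xy, p_yx)
        assert ks.pvalue > 0.01

    def test_conservative_estimator(self):
        zx = np.zeros(6)
        zy = np.ones(6)
        p = permutation_pvalue(zx, zy, 0.0, LsaParams(0),
                               InferenceParams(num_permutations=99), conservative=True)
        assert p == pytest.approx(1.0)


class TestBootstrap:
    def test_single_replicate_degenerates_to_point(self, rng):
        x = ReplicatedSeries(rng.standard_normal((12, 1)))
        y = ReplicatedSeries(rng.standard_normal((12, 1)))
        zx = normal_score(summarize(x.values, "simple"))
        zy = normal_score(summarize(y.values, "simple"))
        observed = local_similarity(zx, zy, LsaParams(2)).score
        for B in (1, 10, 57):
            ci = bootstrap_ci(x, y, "simple", LsaParams(2),
                              InferenceParams(num_bootstraps=B))
            assert ci[0] == pytest.approx(observed, abs=1e-12)
            assert ci[1] == pytest.approx(observed, abs=1e-12)

    def test_zero_bootstraps_reports_missing(self, rng):
        x = ReplicatedSeries(rng.standard_normal((6, 2)))
        assert bootstrap_ci(x, x, "simple", LsaParams(1),
                            InferenceParams(num_bootstraps=0)) is None

    def test_interval_brackets_point_estimate(self, rng):
        n, m = 15, 5
        latent = rng.standard_normal(n)
        x = ReplicatedSeries(latent[:, None] + rng.normal(0, 0.1, (n, m)))
        y = ReplicatedSeries(latent[:, None] + rng.normal(0, 0.1, (n, m)))
        zx = normal_score(summarize(x.values, "simple"))
        zy = normal_score(summarize(y.values, "simple"))
        observed = local_similarity(zx, zy, LsaParams(2)).score
        lo, hi = bootstrap_ci(x, y, "simple", LsaParams(2),
                              InferenceParams(num_bootstraps=300, rng_seed=1))
        assert lo <= hi
        assert lo - 0.05 <= observed <= hi + 0.05

    def test_seeded_reproducibility(self, rng):
        x = ReplicatedSeries(rng.standard_normal((8, 3)))
        y = ReplicatedSeries(rng.standard_normal((8, 3)))
        inf = InferenceParams(num_bootstraps=50, rng_seed=9)
        assert bootstrap_ci(x, y, "simple", LsaParams(1), inf) == \
            bootstrap_ci(x, y, "simple", LsaParams(1), inf)


class TestStoreyQvalues:
    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(storey_qvalues(np.ones(50)), np.ones(50))

    def test_single_pvalue_bounded_by_p(self):
        for p in (0.01, 0.2, 0.9):
            q = storey_qvalues([p])
            assert 0 <= q[0] <= p + 1e-12

    def test_mixture_matches_independent_stepup(self):
        p = np.concatenate([np.full(10, 0.001), np.full(290, 0.5)])
        q = storey_qvalues(p)
        # independent step-up evaluation with the same (frozen) pi0
        pi0 = _estimate_pi0(p)
        N = p.size
        order = np.argsort(p, kind="stable")
        expected = np.empty(N)
        for pos, idx in enumerate(order, start=1):
            candidates = [
                pi0 * N * p[order[j - 1]] / j for j in range(pos, N + 1)
            ]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert (q[:10] < 0.05).all()

    def test_monotone_in_p(self, rng):
        p = rng.random(200)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= 0.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])
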