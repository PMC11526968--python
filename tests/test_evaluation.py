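import itertools

import numpy as np
import pytest

from gecnet.core_data import RegionalTimeSeries
from gecnet.evaluation import (
    CognitiveMapBank,
    cognitive_matching,
    fc_fit,
    fc_ssim,
    identifiability,
    paired_comparison,
)


def _sym(rng, n=8):
    m = rng.standard_normal((n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return m


class TestFCFit:
    def test_identity(self, rng):
        m = _sym(rng)
        assert fc_fit(m, m) == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        m = _sym(rng)
        assert fc_fit(m, -m) == pytest.approx(-1.0)

    def test_matches_vectorized_brute_force(self, rng):
        a, b = _sym(rng), _sym(rng)
        iu = np.triu_indices(8, 1)
        brute = np.corrcoef(a[iu], b[iu])[0, 1]
        assert fc_fit(a, b) == pytest.approx(brute, abs=1e-14)


class TestFCSSIM:
    def test_identity(self, rng):
        m = _sym(rng)
        assert fc_ssim(m, m) == pytest.approx(1.0)

    def test_mean_shift_hits_luminance_only(self, rng):
        m = _sym(rng)
        shifted = m + 0.5
        x, y = m.ravel(), shifted.ravel()
        rng_joint = max(x.max(), y.max()) - min(x.min(), y.min())
        c1 = (0.01 * rng_joint) ** 2
        lum = (2 * x.mean() * y.mean() + c1) / (x.mean() ** 2 + y.mean() ** 2 + c1)
        assert lum < 1.0
        # contrast and structure are untouched by a mean shift
        assert fc_ssim(m, shifted) == pytest.approx(lum, abs=1e-12)

    def test_matches_independent_recomputation(self, rng):
        a, b = _sym(rng), _sym(rng)
        x, y = a.ravel(), b.ravel()
        joint = max(x.max(), y.max()) - min(x.min(), y.min())
        c1, c2 = (0.01 * joint) ** 2, (0.03 * joint) ** 2
        lum = (2 * x.mean() * y.mean() + c1) / (x.mean() ** 2 + y.mean() ** 2 + c1)
        c3 = c2 / 2
        sx, sy = x.std(), y.std()
        sxy = np.mean((x - x.mean()) * (y - y.mean()))
        contrast = (2 * sx * sy + c2) / (sx ** 2 + sy ** 2 + c2)
        structure = (sxy + c3) / (sx * sy + c3)
        assert fc_ssim(a, b) == pytest.approx(lum * contrast * structure, abs=1e-12)


class TestIdentifiability:
    def test_matched_lists(self, rng):
        fcs = [_sym(rng) for _ in range(4)]
        res = identifiability(fcs, fcs)
        assert res.i_self == pytest.approx(1.0)
        assert res.i_diff > 0.0
        assert res.i_diff == pytest.approx(res.i_self - res.i_others)

    def test_identical_subjects_no_structure(self, rng):
        m = _sym(rng)
        res = identifiability([m] * 3, [m] * 3)
        assert res.i_diff == pytest.approx(0.0, abs=1e-12)

    def test_three_subject_fixture_hand_value(self, rng):
        emp = [_sym(rng) for _ in range(3)]
        sim = [_sym(rng) for _ in range(3)]
        res = identifiability(emp, sim)
        hand = np.array([[fc_fit(sim[i], emp[j]) for j in range(3)]
                         for i in range(3)])
        assert res.i_self == pytest.approx(hand.trace() / 3)
        assert res.i_others == pytest.approx(
            (hand.sum() - hand.trace()) / 6)

    def test_region_permutation_invariance(self, rng):
        emp = [_sym(rng) for _ in range(3)]
        sim = [_sym(rng) for _ in range(3)]
        perm = rng.permutation(8)
        permuted = identifiability([m[np.ix_(perm, perm)] for m in emp],
                                   [m[np.ix_(perm, perm)] for m in sim])
        assert permuted.i_diff == pytest.approx(
            identifiability(emp, sim).i_diff, abs=1e-12)


class TestCognitiveMatching:
    def test_activity_equal_to_map(self, rng):
        maps = rng.standard_normal((20, 4))
        bank = CognitiveMapBank(maps, [f"m{i}" for i in range(4)])
        ts = RegionalTimeSeries(np.tile(maps[:, 2], (30, 1)), tr_seconds=1.0)
        _, scan = cognitive_matching(ts, bank)
        assert scan == pytest.approx(1.0)

    def test_all_negative_floored_to_zero(self):
        maps = np.linspace(0, 1, 10)[:, None]
        bank = CognitiveMapBank(maps, ["ramp"])
        ts = RegionalTimeSeries(np.tile(-maps[:, 0], (5, 1)), tr_seconds=1.0)
        per_volume, scan = cognitive_matching(ts, bank)
        assert scan == 0.0
        assert np.all(per_volume == 0.0)

    def test_matches_brute_force_max_of_correlations(self, rng):
        n, k, t = 100, 20, 15
        maps = rng.standard_normal((n, k))
        bank = CognitiveMapBank(maps, [f"m{i}" for i in range(k)])
        act = rng.standard_normal((t, n))
        per_volume, scan = cognitive_matching(
            RegionalTimeSeries(act, tr_seconds=1.0), bank)
        brute = np.array([
            max(0.0, max(np.corrcoef(act[i], maps[:, j])[0, 1]
                         for j in range(k)))
            for i in range(t)
        ])
        np.testing.assert_allclose(per_volume, brute, atol=1e-12)
        assert scan == pytest.approx(brute.mean())

    def test_map_affine_rescaling_invariance(self, rng):
        maps = rng.standard_normal((30, 3))
        act = rng.standard_normal((10, 30))
        ts = RegionalTimeSeries(act, tr_seconds=1.0)
        base = cognitive_matching(ts, CognitiveMapBank(maps, list("abc")))[0]
        rescaled = maps * np.array([2.0, 5.0, 0.3]) + np.array([1.0, -2.0, 0.5])
        again = cognitive_matching(ts, CognitiveMapBank(rescaled, list("abc")))[0]
        np.testing.assert_allclose(base, again, atol=1e-12)


class TestPairedComparison:
    def test_identical_vectors(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = paired_comparison(a, a, n_resamples=100)
        assert rep.t_statistic == 0.0
        assert rep.p_resampled == 1.0
        assert rep.hedges_g == 0.0

    def test_constant_shift_smallest_p(self, rng):
        b = rng.standard_normal(8)
        rep = paired_comparison(b + 1.0, b, n_resamples=20000, seed=1)
        # only all-same-sign flips tie the infinite statistic: p ~ 2/2^8
        assert rep.p_resampled < 0.05
        assert rep.p_resampled == pytest.approx(2 / 2 ** 8, rel=0.5)
        assert rep.hedges_g > 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        a = rng.standard_normal(10) + 0.5
        b = rng.standard_normal(10)
        d = a - b

        def tstat(v):
            return v.mean() / (v.std(ddof=1) / np.sqrt(v.size))

        t_obs = abs(tstat(d))
        exact = np.mean([
            abs(tstat(d * np.array(signs))) >= t_obs
            for signs in itertools.product([-1.0, 1.0], repeat=10)
        ])
        rep = paired_comparison(a, b, n_resamples=20000, seed=2)
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert rep.p_resampled == pytest.approx(exact, abs=max(4 * se, 5e-4))

    def test_hedges_g_hand_formula(self):
        a = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.5, 2.0, 4.5, 4.0, 5.0])
        s = 5
        s_pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        expected = (a.mean() - b.mean()) / s_pooled * (1 - 3 / (4 * (2 * s - 2) - 1))
        rep = paired_comparison(a, b, n_resamples=500, seed=0)
        assert rep.hedges_g == pytest.approx(expected, abs=1e-12)

    def test_null_p_values_roughly_uniform(self):
        # type-I calibration: fraction of p < 0.05 under the null
        rng = np.random.default_rng(11)
        hits = 0
        n_reps = 400
        for _ in range(n_reps):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8)
            rep = paired_comparison(a, b, n_resamples=199,
                                    seed=int(rng.integers(2 ** 31)))
            hits += rep.p_resampled <= 0.05
        rate = hits / n_reps
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_reps))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0], [0.5, 1.0])
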