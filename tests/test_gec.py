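import numpy as np
import pytest

from gecnet.core_data import RegionalTimeSeries, StructuralConnectome
from gecnet.gec import (
    FCStatistics,
    GECModel,
    fc_statistics,
    fc_statistics_linear,
    fit_gec,
    gec_step,
    negative_edge_fraction,
)
from gecnet.hopf import HopfParameters


def _stats_like(fc, fwd=None, rev=None, lag=1):
    n = fc.shape[0]
    fwd = fc if fwd is None else fwd
    rev = fc if rev is None else rev
    return FCStatistics(fc=fc, fc_forward=fwd, fc_reversal=rev, lag_trs=lag)


class TestFCStatistics:
    def test_perfect_lead_lag(self, rng):
        x = rng.standard_normal(500)
        values = np.column_stack([x[1:], x[:-1]])  # col0(t) = x(t+1), col1(t) = x(t)
        ts = RegionalTimeSeries(values, tr_seconds=1.0)
        stats = fc_statistics(ts, lag_trs=1)
        # col1(t+1) equals col0(t) exactly: perfect forward correlation
        assert stats.fc_forward[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_forward_matches_reversal(self, rng):
        ts = RegionalTimeSeries(rng.standard_normal((20000, 4)), tr_seconds=1.0)
        stats = fc_statistics(ts, lag_trs=1)
        assert np.max(np.abs(stats.fc_forward - stats.fc_reversal)) < 0.05

    def test_fc_symmetric_unit_diagonal(self, rng):
        ts = RegionalTimeSeries(rng.standard_normal((300, 5)), tr_seconds=1.0)
        stats = fc_statistics(ts)
        np.testing.assert_allclose(stats.fc, stats.fc.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(stats.fc), 1.0, atol=1e-12)

    def test_constant_column_flagged(self, rng):
        v = rng.standard_normal((100, 3))
        v[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            fc_statistics(RegionalTimeSeries(v, tr_seconds=1.0))


class TestGECStep:
    def test_update_arithmetic(self):
        gec = np.array([[0.0, 0.1], [0.1, 0.0]])
        emp = _stats_like(np.array([[1.0, 0.5], [0.5, 1.0]]))
        sim = _stats_like(np.array([[1.0, 0.0], [0.0, 1.0]]))
        out = gec_step(gec, emp, sim, epsilon=2e-4, epsilon_prime=0.0)
        assert out[0, 1] == pytest.approx(0.1001)

    def test_clamp_to_zero(self):
        gec = np.full((2, 2), 1e-5)
        np.fill_diagonal(gec, 0.0)
        emp = _stats_like(np.zeros((2, 2)))
        sim = _stats_like(np.full((2, 2), 5.0))  # update = -0.001
        out = gec_step(gec, emp, sim, epsilon=2e-4, epsilon_prime=0.0,
                       allow_negative=False)
        assert out[0, 1] == 0.0
        out2 = gec_step(gec, emp, sim, epsilon=2e-4, epsilon_prime=0.0,
                        allow_negative=True)
        assert out2[0, 1] == pytest.approx(-0.00099)

    def test_fixed_point_when_matched(self, rng):
        gec = rng.normal(0, 0.1, (5, 5))
        fc = rng.normal(0, 0.3, (5, 5))
        stats = _stats_like(fc, fwd=rng.normal(0, 0.3, (5, 5)))
        out = gec_step(gec, stats, stats)
        np.testing.assert_array_equal(out, gec)

    def test_mask_respected(self):
        gec = np.zeros((3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 1] = True
        emp = _stats_like(np.ones((3, 3)))
        sim = _stats_like(np.zeros((3, 3)))
        out = gec_step(gec, emp, sim, epsilon=1e-3, epsilon_prime=0.0, mask=mask)
        assert out[0, 1] != 0.0
        assert np.count_nonzero(out) == 1

    def test_permutation_equivariance(self, rng):
        n = 6
        gec = rng.normal(0, 0.1, (n, n))
        emp = _stats_like(rng.normal(0, 0.3, (n, n)),
                          fwd=rng.normal(0, 0.3, (n, n)),
                          rev=rng.normal(0, 0.3, (n, n)))
        sim = _stats_like(rng.normal(0, 0.3, (n, n)),
                          fwd=rng.normal(0, 0.3, (n, n)),
                          rev=rng.normal(0, 0.3, (n, n)))
        perm = rng.permutation(n)

        def p(m):
            return m[np.ix_(perm, perm)]

        direct = p(gec_step(gec, emp, sim))
        permuted = gec_step(
            p(gec),
            _stats_like(p(emp.fc), p(emp.fc_forward), p(emp.fc_reversal)),
            _stats_like(p(sim.fc), p(sim.fc_forward), p(sim.fc_reversal)),
        )
        np.testing.assert_allclose(direct, permuted, atol=1e-15)


class TestNegativeEdgeFraction:
    def test_values(self, rng):
        m = np.abs(rng.normal(0, 1, (6, 6)))
        np.fill_diagonal(m, 0.0)
        assert negative_edge_fraction(m) == 0.0
        m[0, 1] = m[1, 0] = -1.0  # 2 of 30 off-diagonal entries
        assert negative_edge_fraction(m) == pytest.approx(2 / 30)

    def test_binomial_rate(self, rng):
        signs = np.where(rng.random(1000) < 0.3, -1.0, 1.0)
        m = np.zeros((1001, 1001))
        m[0, 1:] = signs
        frac = np.count_nonzero(m[0, 1:] < 0) / 1000
        assert frac == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 1000))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            negative_edge_fraction(np.zeros((3, 3)))


@pytest.fixture(scope="module")
def linear_fixture():
    """A small stable signed coupling and its exact (linear-regime) statistics."""
    rng = np.random.default_rng(7)
    n = 10
    w = np.abs(rng.normal(0, 1, (n, n)))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    w[w < np.quantile(w, 0.5)] = 0.0  # sparsify
    neg = (rng.random((n, n)) < 0.25) & (w > 0)
    neg = np.triu(neg, 1)
    neg = neg | neg.T
    w = np.where(neg, -0.3 * w, w)
    from gecnet.hopf import scale_to_stability_margin

    w = scale_to_stability_margin(w, a=-0.02, margin=0.01)
    params = HopfParameters(tr_seconds=0.72)
    emp = fc_statistics_linear(w, params, lag_trs=1)
    return w, params, emp


class TestFitGEC:
    def test_self_consistency(self, linear_fixture):
        """Empirical stats generated from the initial SC itself: fit is high fast."""
        w, params, emp = linear_fixture
        sc = StructuralConnectome(w, directed=True)
        res = fit_gec(sc, emp, params, allow_negative=True, engine="linear",
                      max_iter=20)
        assert res.fit_correlation >= 0.9

    def test_deterministic_linear_engine(self, linear_fixture):
        w, params, emp = linear_fixture
        sc = StructuralConnectome(np.abs(w))
        a = fit_gec(sc, emp, params, engine="linear", max_iter=30, seed=3)
        b = fit_gec(sc, emp, params, engine="linear", max_iter=30, seed=3)
        np.testing.assert_array_equal(a.gec, b.gec)
        assert a.fit_history == b.fit_history

    def test_cooperative_constraint_and_ordering(self, linear_fixture):
        """The sign-constrained fit stays nonnegative and fits a signed target worse."""
        w, params, emp = linear_fixture
        sc = StructuralConnectome(np.abs(w))
        free = fit_gec(sc, emp, params, allow_negative=True, engine="linear",
                       max_iter=800, tol=1e-7, patience=100)
        clamped = fit_gec(sc, emp, params, allow_negative=False, engine="linear",
                          max_iter=800, tol=1e-7, patience=100)
        assert np.all(clamped.gec >= 0.0)
        assert free.negative_edge_fraction > 0.0
        assert clamped.fit_correlation < free.fit_correlation

    def test_fit_history_monotone(self, linear_fixture):
        w, params, emp = linear_fixture
        res = fit_gec(StructuralConnectome(np.abs(w)), emp, params,
                      engine="linear", max_iter=50)
        fits = [f for _, f in res.fit_history]
        assert all(b >= a for a, b in zip(fits, fits[1:]))

    def test_gec_zero_outside_mask(self, linear_fixture):
        w, params, emp = linear_fixture
        res = fit_gec(StructuralConnectome(np.abs(w)), emp, params,
                      engine="linear", max_iter=30)
        assert np.all(res.gec[~res.mask] == 0.0)

    def test_summary_mentions_variant(self, linear_fixture):
        w, params, emp = linear_fixture
        res = fit_gec(StructuralConnectome(np.abs(w)), emp, params,
                      engine="linear", max_iter=5, allow_negative=False)
        assert "cooperative-only" in res.summary()
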