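import numpy as np
import pytest

from gecnet.core_data import RegionalTimeSeries
from gecnet.phiid import (
    ATOM_NAMES,
    LaggedPairCovariance,
    gaussian_mi,
    lagged_pair_covariance,
    phiid_mmi,
    synergy_profile,
)


def _random_psd4(rng):
    a = rng.standard_normal((4, 6))
    cov = a @ a.T / 6 + 0.1 * np.eye(4)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _coupled_ar_cov(a, c=0.1, phi=0.0):
    """Exact lag-1 covariance of the two-parameter coupled AR process.

    x_{t+1} = a y_t + e_x,  y_{t+1} = a x_t + e_y, with innovation
    correlation c (an optional self-coupling phi generalizes the family).
    Stationary covariance solved exactly.
    """
    A = np.array([[phi, a], [a, phi]])
    Q = np.array([[1.0, c], [c, 1.0]])
    # vectorized discrete Lyapunov: S = A S A' + Q
    from scipy.linalg import solve_discrete_lyapunov

    S = solve_discrete_lyapunov(A, Q)
    lag = A @ S  # cov(z_{t+1}, z_t)
    top = np.hstack([S, lag.T])
    bot = np.hstack([lag, S])
    return np.vstack([top, bot])  # order: (x_{t-1}, y_{t-1}, x_t, y_t)


class TestGaussianMI:
    def test_independent_pair_zero(self):
        assert gaussian_mi(np.eye(2), [0], [1]) == 0.0

    def test_bivariate_closed_form(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert gaussian_mi(cov, [0], [1]) == pytest.approx(-0.5 * np.log(0.75))

    def test_block_mi_matches_entropy_difference(self, rng):
        cov = _random_psd4(rng)

        def entropy(idx):
            sub = cov[np.ix_(idx, idx)]
            k = len(idx)
            return 0.5 * np.log((2 * np.pi * np.e) ** k * np.linalg.det(sub))

        brute = entropy([0, 1]) + entropy([2, 3]) - entropy([0, 1, 2, 3])
        assert gaussian_mi(cov, [0, 1], [2, 3]) == pytest.approx(brute, abs=1e-12)

    def test_overlapping_indices_rejected(self):
        with pytest.raises(ValueError):
            gaussian_mi(np.eye(3), [0, 1], [1, 2])


class TestLaggedPairCovariance:
    def test_identical_series_perfect_blocks(self, rng):
        x = rng.standard_normal(500)
        ts = RegionalTimeSeries(np.column_stack([x, x]), tr_seconds=1.0)
        cov = lagged_pair_covariance(ts, 0, 1, 1).cov
        assert cov[0, 1] == pytest.approx(1.0, abs=0.02)
        assert cov[2, 3] == pytest.approx(1.0, abs=0.02)

    def test_white_noise_cross_lag_near_zero(self, rng):
        ts = RegionalTimeSeries(rng.standard_normal((20000, 2)), tr_seconds=1.0)
        cov = lagged_pair_covariance(ts, 0, 1, 1).cov
        assert abs(cov[0, 2]) < 0.03  # past-x vs future-x
        assert abs(cov[0, 3]) < 0.03

    def test_ar1_autocovariance(self, rng):
        phi = 0.6
        t = 50000
        x = np.zeros(t)
        eps = rng.standard_normal(t)
        for i in range(1, t):
            x[i] = phi * x[i - 1] + eps[i]
        ts = RegionalTimeSeries(
            np.column_stack([x, rng.standard_normal(t)]), tr_seconds=1.0)
        cov = lagged_pair_covariance(ts, 0, 1, 1).cov
        assert cov[0, 2] == pytest.approx(phi, abs=0.02)


class TestPhiIDMMI:
    def test_atoms_sum_to_tdmi_many_covariances(self, rng):
        for _ in range(200):
            cov = LaggedPairCovariance(_random_psd4(rng), 1)
            atoms = phiid_mmi(cov)
            assert sum(atoms.atoms.values()) == pytest.approx(atoms.tdmi, abs=1e-10)

    def test_redundancy_is_four_way_minimum(self, rng):
        cov = LaggedPairCovariance(_random_psd4(rng), 1)
        atoms = phiid_mmi(cov)
        c = cov.cov
        four = [gaussian_mi(c, [0], [2]), gaussian_mi(c, [0], [3]),
                gaussian_mi(c, [1], [2]), gaussian_mi(c, [1], [3])]
        # cumulative redundancy at the lattice bottom equals the printed minimum
        bottom = (atoms.atoms["{1}{2}->{1}{2}"]
                  + 0.0)  # bottom atom IS the cumulative at the bottom pair
        assert bottom == pytest.approx(min(four), abs=1e-10)

    def test_marginal_consistency_single_target(self, rng):
        cov = LaggedPairCovariance(_random_psd4(rng), 1)
        atoms = phiid_mmi(cov)
        c = cov.cov
        # atoms below ({1}{2} -> {1}) accumulate to the single-target MMI
        # redundancy min(I(X_past; X_t), I(Y_past; X_t))
        acc = atoms.atoms["{1}{2}->{1}{2}"] + atoms.atoms["{1}{2}->{1}"]
        expected = min(gaussian_mi(c, [0], [2]), gaussian_mi(c, [1], [2]))
        assert acc == pytest.approx(expected, abs=1e-10)

    def test_uncoupled_ar_pair_zero_synergy(self):
        # a = 0, c = 0: fully independent series, every atom vanishes
        atoms = phiid_mmi(LaggedPairCovariance(_coupled_ar_cov(0.0, c=0.0), 1))
        assert atoms.tdmi == pytest.approx(0.0, abs=1e-12)
        assert atoms.synergy_persistent == pytest.approx(0.0, abs=1e-10)
        for v in atoms.atoms.values():
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_independent_self_coupled_pair_closed_form(self):
        # independent AR(1) processes WITH self-coupling: the crossed-min MMI
        # convention assigns persistent synergy 2*min(self-MI) — the known
        # artifact of minimum-MI redundancy with a multivariate target — while
        # unique self-information carries the rest of the TDMI
        cov4 = np.eye(4)
        cov4[0, 2] = cov4[2, 0] = 0.6
        cov4[1, 3] = cov4[3, 1] = 0.4
        atoms = phiid_mmi(LaggedPairCovariance(cov4, 1))
        mx = -0.5 * np.log(1 - 0.36)
        my = -0.5 * np.log(1 - 0.16)
        assert atoms.tdmi == pytest.approx(mx + my, abs=1e-12)
        assert atoms.synergy_persistent == pytest.approx(2 * my, abs=1e-10)
        assert atoms.atoms["{1}->{1}"] == pytest.approx(mx, abs=1e-10)
        assert atoms.atoms["{2}->{2}"] == pytest.approx(my, abs=1e-10)

    def test_synergy_monotone_in_coupling(self):
        values = [
            phiid_mmi(LaggedPairCovariance(_coupled_ar_cov(a), 1)).synergy_persistent
            for a in (0.0, 0.1, 0.2, 0.3, 0.4)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_scale_invariance_via_standardization(self, rng):
        t = 2000
        v = rng.standard_normal((t, 2)).cumsum(axis=0) * 0.01 + rng.standard_normal((t, 2))
        ts = RegionalTimeSeries(v, tr_seconds=1.0)
        scaled = RegionalTimeSeries(v * np.array([3.0, 0.1]), tr_seconds=1.0)
        a = phiid_mmi(lagged_pair_covariance(ts, 0, 1, 1))
        b = phiid_mmi(lagged_pair_covariance(scaled, 0, 1, 1))
        for name in ATOM_NAMES:
            assert a.atoms[name] == pytest.approx(b.atoms[name], abs=1e-10)


class TestSynergyProfile:
    def test_two_regions_reduces_to_pair(self, rng):
        ts = RegionalTimeSeries(rng.standard_normal((800, 2)), tr_seconds=1.0)
        syn, mean = synergy_profile(ts, 1)
        pair = phiid_mmi(lagged_pair_covariance(ts, 0, 1, 1)).synergy_persistent
        assert syn[0, 1] == pytest.approx(pair)
        assert mean == pytest.approx(pair)

    def test_permutation_equivariance(self, rng):
        v = rng.standard_normal((600, 4))
        syn, _ = synergy_profile(RegionalTimeSeries(v, tr_seconds=1.0), 1)
        perm = np.array([2, 0, 3, 1])
        syn_p, _ = synergy_profile(
            RegionalTimeSeries(v[:, perm], tr_seconds=1.0), 1)
        np.testing.assert_allclose(syn_p, syn[np.ix_(perm, perm)], atol=1e-12)
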