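"""Networks of stochastic Stuart-Landau (Hopf normal form) oscillators.

Each region n obeys, in Cartesian coordinates z_n = x_n + i y_n,

    dx_n/dt = (a_n - x_n^2 - y_n^2) x_n - w_n y_n + sum_p G_np (x_p - x_n) + b e_n(t)
    dy_n/dt = (a_n - x_n^2 - y_n^2) y_n + w_n x_n + sum_p G_np (y_p - y_n) + b e'_n(t)

with bifurcation parameter a_n (a_n < 0: damped noisy fluctuations; a_n > 0:
limit cycle of radius sqrt(a_n)), angular frequency w_n = 2 pi f_n, diffusive
coupling through the (possibly signed) matrix G, and independent unit-variance
Gaussian noise of standard deviation b per node and component.  The x
component sampled at the repetition time serves as the BOLD proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from gecnet.core_data import RegionalTimeSeries, bandpass

DEFAULT_A = -0.02
DEFAULT_BETA = 0.01


@dataclass(frozen=True)
class HopfParameters:
    """Parameters of a coupled Hopf-oscillator simulation.

    ``a`` and ``omega`` may be scalars (broadcast to all nodes) or N-vectors.
    ``dt`` is a target integration step; the actual step divides ``tr_seconds``
    exactly so output samples land on the TR grid.
    """

    a: float | np.ndarray = DEFAULT_A
    omega: float | np.ndarray = 2.0 * np.pi * 0.05
    beta: float = DEFAULT_BETA
    dt: float = 0.1
    tr_seconds: float = 0.72
    duration_seconds: float = 500.0
    burn_in_seconds: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.dt > self.tr_seconds:
            raise ValueError("dt must not exceed tr_seconds")
        if self.beta < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.duration_seconds <= self.burn_in_seconds:
            raise ValueError("duration must exceed burn-in")

    def vectors(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        a = np.broadcast_to(np.asarray(self.a, dtype=float), (n,)).copy()
        omega = np.broadcast_to(np.asarray(self.omega, dtype=float), (n,)).copy()
        return a, omega

    @property
    def steps_per_tr(self) -> int:
        return max(1, int(round(self.tr_seconds / self.dt)))

    @property
    def effective_dt(self) -> float:
        return self.tr_seconds / self.steps_per_tr


@dataclass(frozen=True)
class SimulatedBOLD:
    """Output of one simulation: sampled x-components plus provenance."""

    ts: RegionalTimeSeries
    params: HopfParameters
    coupling_used: np.ndarray = field(repr=False, default=None)


def simulate(coupling: np.ndarray, params: HopfParameters,
             initial_state: np.ndarray | None = None,
             noise: np.ndarray | None = None) -> SimulatedBOLD:
    """Integrate the coupled Hopf system by Euler-Maruyama.

    Negative entries of ``coupling`` enter the same diffusive term and invert
    the neighbour's influence (competitive interaction).  A fixed seed gives a
    bit-identical trajectory.  ``noise`` optionally injects the standard-normal
    increments (total_steps x 2 x N), used to couple runs at different step
    sizes through a common Brownian path in integration-accuracy checks.
    """
    G = np.asarray(coupling, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("coupling must be square")
    if not np.all(np.isfinite(G)):
        raise ValueError("coupling contains non-finite entries")
    n = G.shape[0]
    a, omega = params.vectors(n)
    dt = params.effective_dt
    noise_scale = params.beta * np.sqrt(dt)
    row_sum = G.sum(axis=1)

    rng = np.random.default_rng(params.seed)
    if initial_state is None:
        state = rng.uniform(-0.1, 0.1, size=(2, n))
    else:
        state = np.array(initial_state, dtype=float).reshape(2, n)
    x, y = state[0], state[1]

    steps_per_tr = params.steps_per_tr
    n_burn = int(round(params.burn_in_seconds / params.tr_seconds))
    n_keep = int(round((params.duration_seconds - params.burn_in_seconds)
                       / params.tr_seconds))
    out = np.empty((n_keep, n))
    kept = 0
    total_trs = n_burn + n_keep
    noisy = params.beta > 0
    for tr_idx in range(total_trs):
        if noisy:
            if noise is None:
                block = rng.standard_normal((steps_per_tr, 2, n))
            else:
                start = tr_idx * steps_per_tr
                block = noise[start:start + steps_per_tr]
            block = block * noise_scale
        for k in range(steps_per_tr):
            r2 = x * x + y * y
            shrink = a - r2
            dx = (shrink * x - omega * y + G @ x - row_sum * x) * dt
            dy = (shrink * y + omega * x + G @ y - row_sum * y) * dt
            if noisy:
                dx += block[k, 0]
                dy += block[k, 1]
            x = x + dx
            y = y + dy
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise FloatingPointError(
                f"simulation overflowed at TR index {tr_idx}"
            )
        if tr_idx >= n_burn:
            out[kept] = x
            kept += 1
    ts = RegionalTimeSeries(out, tr_seconds=params.tr_seconds)
    return SimulatedBOLD(ts=ts, params=params, coupling_used=G)


def _jacobian(G: np.ndarray, a: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """2N x 2N Jacobian of the system linearized at the origin."""
    n = G.shape[0]
    C = G - np.diag(G.sum(axis=1))
    A = np.diag(a) + C
    J = np.zeros((2 * n, 2 * n))
    J[:n, :n] = A
    J[:n, n:] = -np.diag(omega)
    J[n:, :n] = np.diag(omega)
    J[n:, n:] = A
    return J


def linearized_covariance(coupling: np.ndarray, params: HopfParameters,
                          lag_seconds: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Stationary covariance of the linearized system via the Lyapunov equation.

    Returns the x-block of the zero-lag covariance and of the lag-tau
    cross-covariance L with L[n, p] = cov(x_n(t), x_p(t + tau)).  Valid only
    while the origin is stable (all Jacobian eigenvalues in the left half
    plane); a marginal or unstable Jacobian raises, signalling coupling too
    strong for the linear regime.
    """
    G = np.asarray(coupling, dtype=float)
    n = G.shape[0]
    a, omega = params.vectors(n)
    J = _jacobian(G, a, omega)
    eig = np.linalg.eigvals(J)
    if np.max(eig.real) >= -1e-12:
        raise ValueError(
            f"linearization unstable: max Re(eigenvalue) = {np.max(eig.real):.3g}"
        )
    Q = params.beta ** 2 * np.eye(2 * n)
    # J S + S J^T = -Q
    S = linalg.solve_continuous_lyapunov(J, -Q)
    S = 0.5 * (S + S.T)
    if lag_seconds == 0.0:
        lagged = S
    else:
        # cov(z(t), z(t+tau)) = S expm(J tau)^T
        lagged = S @ linalg.expm(J * lag_seconds).T
    return S[:n, :n], lagged[:n, :n]


def scale_to_stability_margin(coupling: np.ndarray, a: float = DEFAULT_A,
                              margin: float = 0.01,
                              fallback_max: float = 0.2) -> np.ndarray:
    """Rescale a signed coupling matrix to a fixed linear-stability margin.

    The linearized system has eigenvalues a + s*eig(C) with
    C = G - diag(rowsum G); scaling chooses s so the spectral abscissa sits at
    ``-margin``, keeping the network in the near-critical noisy regime however
    strong its competitive edges.  A matrix whose C cannot destabilize (e.g.
    all-positive, Laplacian-like) is instead scaled to max weight
    ``fallback_max``.
    """
    if margin <= 0 or margin >= abs(a):
        raise ValueError("margin must lie in (0, |a|)")
    G = np.asarray(coupling, dtype=float)
    C = G - np.diag(G.sum(axis=1))
    abscissa = float(np.max(np.linalg.eigvals(C).real))
    if abscissa <= 1e-12:
        peak = np.max(np.abs(G))
        if peak == 0.0:
            raise ValueError("cannot scale an all-zero matrix")
        return G * (fallback_max / peak)
    return G * ((abs(a) - margin) / abscissa)


def estimate_intrinsic_frequencies(ts: RegionalTimeSeries,
                                   band_hz: tuple[float, float]) -> np.ndarray:
    """Peak frequency (Hz) of each region's power spectrum within the band.

    The input is band-pass filtered to ``band_hz`` first unless it already
    carries that band.  Cohort averaging across subjects is left to the caller.
    """
    low, high = band_hz
    if ts.band_hz is None or tuple(ts.band_hz) != (low, high):
        ts = bandpass(ts, low, high)
    freqs, psd = signal.periodogram(ts.values, fs=1.0 / ts.tr_seconds, axis=0)
    in_band = (freqs >= low) & (freqs <= high)
    if not np.any(in_band):
        raise ValueError("band empty at this spectral resolution; series too short")
    band_freqs = freqs[in_band]
    band_psd = psd[in_band, :]
    return band_freqs[np.argmax(band_psd, axis=0)]
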