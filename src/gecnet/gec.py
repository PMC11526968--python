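"""Generative effective connectivity (GEC) estimation.

A signed coupling matrix is initialized at the anatomical connectome and
iteratively updated so a network of Hopf oscillators reproduces the empirical
functional connectivity and its lagged (forward minus time-reversed)
structure:

    GEC_np <- GEC_np + eps (FC_np^emp - FC_np^sim)
                     - eps' ([FCf_np^emp - FCr_np^emp] - [FCf_np^sim - FCr_np^sim])

applied only to anatomically existing connections.  Two variants are fitted:
*cooperative-only*, where updates that would cross zero are clamped at zero,
and *cooperative+competitive*, where connections may turn negative.

The estimation API follows the Model/Results convention: build a
:class:`GECModel` from a connectome and empirical FC statistics, call
``fit()``, and inspect the returned :class:`GECResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from gecnet.core_data import RegionalTimeSeries, StructuralConnectome
from gecnet.hopf import HopfParameters, linearized_covariance, simulate

DEFAULT_EPSILON = 2e-4
DEFAULT_EPSILON_PRIME = 4e-5


@dataclass(frozen=True)
class FCStatistics:
    """Zero-lag, forward-shifted and reversed-shifted correlation matrices.

    ``fc_forward[n, p]`` = corr(x_n(t), x_p(t + lag)); ``fc_reversal`` is the
    same statistic computed after reversing the time axis of every region.
    """

    fc: np.ndarray
    fc_forward: np.ndarray
    fc_reversal: np.ndarray
    lag_trs: int = 1

    def __post_init__(self):
        for m in (self.fc, self.fc_forward, self.fc_reversal):
            if m.shape != self.fc.shape or m.ndim != 2:
                raise ValueError("FC matrices must share a square shape")

    @property
    def n_regions(self) -> int:
        return self.fc.shape[0]


def _lagged_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """corr matrix C[n, p] = corr(a[:, n], b[:, p]) over aligned rows."""
    az = (a - a.mean(axis=0)) / a.std(axis=0)
    bz = (b - b.mean(axis=0)) / b.std(axis=0)
    return az.T @ bz / a.shape[0]


def fc_statistics(ts: RegionalTimeSeries, lag_trs: int = 1) -> FCStatistics:
    """Compute the three correlation matrices the GEC update matches."""
    v = ts.values
    if v.shape[0] <= lag_trs + 2:
        raise ValueError("time series too short for this lag")
    flat = np.where(v.std(axis=0) == 0.0)[0]
    if flat.size:
        raise ValueError(
            f"constant regions (correlation undefined): {[ts.labels[i] for i in flat]}"
        )
    fc = np.corrcoef(v.T)
    fwd = _lagged_corr(v[:-lag_trs], v[lag_trs:])
    r = v[::-1]
    rev = _lagged_corr(r[:-lag_trs], r[lag_trs:])
    return FCStatistics(fc=fc, fc_forward=fwd, fc_reversal=rev, lag_trs=lag_trs)


def fc_statistics_linear(coupling: np.ndarray, params: HopfParameters,
                         lag_trs: int = 1) -> FCStatistics:
    """Noise-free FC statistics from the linearized (Lyapunov) solution.

    For a stationary linear Gaussian process the reversed-time lagged
    correlation is the transpose of the forward one, which this exploits.
    """
    tau = lag_trs * params.tr_seconds
    cov0, covl = linearized_covariance(coupling, params, lag_seconds=tau)
    d = np.sqrt(np.diag(cov0))
    denom = np.outer(d, d)
    fc = cov0 / denom
    fwd = covl / denom
    return FCStatistics(fc=fc, fc_forward=fwd, fc_reversal=fwd.T, lag_trs=lag_trs)


def gec_step(gec: np.ndarray, emp: FCStatistics, sim: FCStatistics,
             epsilon: float = DEFAULT_EPSILON,
             epsilon_prime: float = DEFAULT_EPSILON_PRIME,
             mask: np.ndarray | None = None,
             allow_negative: bool = True) -> np.ndarray:
    """One heuristic gradient update of the GEC matrix.

    Only masked entries move; with ``allow_negative=False`` entries that would
    become negative are clamped to zero (they may later re-grow positive).
    """
    for m in (gec, emp.fc, sim.fc):
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite input to gec_step")
    delta = epsilon * (emp.fc - sim.fc) - epsilon_prime * (
        (emp.fc_forward - emp.fc_reversal) - (sim.fc_forward - sim.fc_reversal)
    )
    out = gec.copy()
    if mask is None:
        mask = np.ones_like(gec, dtype=bool)
        np.fill_diagonal(mask, False)
    out[mask] = gec[mask] + delta[mask]
    if not allow_negative:
        out[mask] = np.clip(out[mask], 0.0, None)
    return out


def negative_edge_fraction(gec) -> float:
    """Fraction of masked (anatomically existing) connections that are negative."""
    if isinstance(gec, GECResults):
        matrix, mask = gec.gec, gec.mask
    else:
        matrix = np.asarray(gec)
        mask = matrix != 0.0
        np.fill_diagonal(mask, False)
    n_masked = int(np.count_nonzero(mask))
    if n_masked == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(matrix[mask] < 0.0) / n_masked)


def _upper_corr(a: np.ndarray, b: np.ndarray) -> float:
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.corrcoef(a[iu], b[iu])[0, 1])


@dataclass
class GECResults:
    """Fitted generative effective connectivity with its fit trajectory.

    ``fit_history`` is monotone-smoothed (running best FC correlation);
    ``raw_history`` keeps the per-iteration values.  The stored ``gec`` is the
    best iterate encountered, not necessarily the last.
    """

    gec: np.ndarray
    allow_negative: bool
    mask: np.ndarray
    fit_history: list[tuple[int, float]]
    raw_history: list[tuple[int, float]] = field(default_factory=list)
    epsilon: float = DEFAULT_EPSILON
    epsilon_prime: float = DEFAULT_EPSILON_PRIME
    converged: bool = False
    seed: int = 0
    model: "GECModel | None" = field(default=None, repr=False)

    def __post_init__(self):
        if not self.fit_history:
            raise ValueError("fit_history must be non-empty")
        if not self.allow_negative and np.any(self.gec < 0):
            raise AssertionError("cooperative-only GEC contains negative weights")
        if np.any(self.gec[~self.mask] != 0.0):
            raise AssertionError("GEC nonzero outside the anatomical mask")

    @property
    def fit_correlation(self) -> float:
        return self.fit_history[-1][1]

    @property
    def n_iterations(self) -> int:
        return self.raw_history[-1][0] if self.raw_history else self.fit_history[-1][0]

    @property
    def negative_edge_fraction(self) -> float:
        return negative_edge_fraction(self)

    def simulate(self, duration_seconds: float | None = None,
                 seed: int | None = None) -> RegionalTimeSeries:
        """Forward-simulate BOLD from the fitted GEC (stochastic engine)."""
        if self.model is None:
            raise ValueError("results detached from their model")
        p = self.model.params
        p = replace(
            p,
            duration_seconds=(duration_seconds + p.burn_in_seconds
                              if duration_seconds is not None else p.duration_seconds),
            seed=self.seed if seed is None else seed,
        )
        return simulate(self.gec, p).ts

    def summary(self) -> str:
        variant = ("cooperative+competitive" if self.allow_negative
                   else "cooperative-only")
        lines = [
            "Generative Effective Connectivity Results",
            "=" * 45,
            f"Variant:                {variant}",
            f"Regions:                {self.gec.shape[0]}",
            f"Masked connections:     {int(np.count_nonzero(self.mask))}",
            f"Iterations:             {self.n_iterations}",
            f"Converged:              {self.converged}",
            f"FC fit correlation:     {self.fit_correlation:.4f}",
            f"Negative edge fraction: {self.negative_edge_fraction:.4f}",
            f"epsilon / epsilon':     {self.epsilon:g} / {self.epsilon_prime:g}",
            f"Seed:                   {self.seed}",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Plot the FC-fit trajectory over iterations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.raw_history:
            it, r = zip(*self.raw_history)
            ax.plot(it, r, lw=0.8, alpha=0.5, label="per-iteration")
        it, r = zip(*self.fit_history)
        ax.plot(it, r, lw=1.5, label="running best")
        ax.set_xlabel("iteration")
        ax.set_ylabel("FC fit correlation")
        ax.legend(frameon=False)
        return ax


class GECModel:
    """Model object tying a connectome, empirical FC statistics and Hopf parameters.

    Parameters
    ----------
    sc : StructuralConnectome
        Prepared (symmetrized/thresholded/scaled) anatomical connectome; its
        nonzero entries define the update mask and the initial weights.
    emp : FCStatistics or RegionalTimeSeries
        Empirical statistics to match; a time series is reduced with
        :func:`fc_statistics` at ``lag_trs``.
    params : HopfParameters
        Node dynamics and simulation settings shared by every iteration.
    allow_negative : bool
        False reproduces the cooperative-only variant (nonnegativity clamp).
    engine : {"stochastic", "linear"}
        Per-iteration forward model: stochastic Euler-Maruyama simulation, or
        the deterministic linearized-covariance fast path.
    sim_duration_trs : int
        Post-burn-in length of each stochastic iteration's simulation.
    homotopic_pairs : sequence of (int, int), optional
        Extra region pairs added to the mask with unit initial weight
        (left/right homotopic augmentation).
    """

    def __init__(self, sc: StructuralConnectome,
                 emp: FCStatistics | RegionalTimeSeries,
                 params: HopfParameters,
                 allow_negative: bool = True,
                 lag_trs: int = 1,
                 epsilon: float = DEFAULT_EPSILON,
                 epsilon_prime: float = DEFAULT_EPSILON_PRIME,
                 engine: Literal["stochastic", "linear"] = "stochastic",
                 sim_duration_trs: int = 500,
                 homotopic_pairs=None):
        if isinstance(emp, RegionalTimeSeries):
            emp = fc_statistics(emp, lag_trs=lag_trs)
        if emp.n_regions != sc.n_regions:
            raise ValueError("connectome and FC statistics disagree on N")
        self.sc = sc
        self.emp = emp
        self.params = params
        self.allow_negative = allow_negative
        self.lag_trs = lag_trs
        self.epsilon = epsilon
        self.epsilon_prime = epsilon_prime
        if engine not in ("stochastic", "linear"):
            raise ValueError(f"unknown engine {engine!r}")
        self.engine = engine
        self.sim_duration_trs = sim_duration_trs

        mask = sc.weights != 0.0
        np.fill_diagonal(mask, False)
        init = sc.weights.copy()
        if homotopic_pairs:
            for i, j in homotopic_pairs:
                for r, c in ((i, j), (j, i)):
                    if not mask[r, c]:
                        mask[r, c] = True
                        init[r, c] = 1.0
        if not allow_negative and np.any(init < 0):
            raise ValueError("cooperative-only fit needs a nonnegative initial SC")
        self.mask = mask
        self.initial_gec = init

    # -- forward model ------------------------------------------------------
    def _simulate_statistics(self, gec: np.ndarray, seed: int) -> FCStatistics:
        if self.engine == "linear":
            return fc_statistics_linear(gec, self.params, lag_trs=self.lag_trs)
        tr = self.params.tr_seconds
        p = replace(
            self.params,
            duration_seconds=self.sim_duration_trs * tr + self.params.burn_in_seconds,
            seed=seed,
        )
        return fc_statistics(simulate(gec, p).ts, lag_trs=self.lag_trs)

    def fit(self, max_iter: int = 200, tol: float = 1e-3, patience: int = 10,
            seed: int = 0) -> GECResults:
        """Iterate simulate -> FC statistics -> heuristic update until convergence.

        Convergence: the running-best FC correlation has not improved by more
        than ``tol`` for ``patience`` consecutive iterations.  Divergence (fit
        strictly decreasing for ``patience`` consecutive iterations, or loss
        of linear-regime stability) returns the best iterate with
        ``converged=False``.
        """
        rng = np.random.default_rng(seed)
        gec = self.initial_gec.copy()
        best_gec = gec.copy()
        best_fit = -np.inf
        last_improve = 0
        raw_history: list[tuple[int, float]] = []
        converged = False
        diverging = 0
        prev_fit = -np.inf

        for it in range(1, max_iter + 1):
            iter_seed = int(rng.integers(0, 2 ** 31 - 1))
            try:
                sim = self._simulate_statistics(gec, iter_seed)
            except (ValueError, FloatingPointError):
                break  # left the stable regime; keep best-so-far
            fit = _upper_corr(self.emp.fc, sim.fc)
            raw_history.append((it, fit))
            if fit > best_fit + tol:
                last_improve = it
            if fit > best_fit:
                best_fit = fit
                best_gec = gec.copy()
            diverging = diverging + 1 if fit < prev_fit else 0
            prev_fit = fit
            if it - last_improve >= patience:
                converged = True
                break
            if diverging >= patience and self.engine == "linear":
                break
            gec = gec_step(gec, self.emp, sim, self.epsilon, self.epsilon_prime,
                           mask=self.mask, allow_negative=self.allow_negative)
        if not self.allow_negative:
            assert np.all(best_gec >= 0.0)
        running_best = np.maximum.accumulate([f for _, f in raw_history])
        fit_history = [(i, float(b)) for (i, _), b in zip(raw_history, running_best)]
        return GECResults(
            gec=best_gec, allow_negative=self.allow_negative, mask=self.mask,
            fit_history=fit_history, raw_history=raw_history,
            epsilon=self.epsilon, epsilon_prime=self.epsilon_prime,
            converged=converged, seed=seed, model=self,
        )


def fit_gec(sc: StructuralConnectome, emp: FCStatistics | RegionalTimeSeries,
            params: HopfParameters, allow_negative: bool = True,
            lag_trs: int = 1, engine: str = "stochastic",
            epsilon: float = DEFAULT_EPSILON,
            epsilon_prime: float = DEFAULT_EPSILON_PRIME,
            sim_duration_trs: int = 500, max_iter: int = 200,
            tol: float = 1e-3, patience: int = 10, seed: int = 0) -> GECResults:
    """Functional one-call wrapper around :class:`GECModel` + ``fit``."""
    model = GECModel(sc, emp, params, allow_negative=allow_negative,
                     lag_trs=lag_trs, epsilon=epsilon,
                     epsilon_prime=epsilon_prime, engine=engine,
                     sim_duration_trs=sim_duration_trs)
    return model.fit(max_iter=max_iter, tol=tol, patience=patience, seed=seed)
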