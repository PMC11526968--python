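"""Integrated information decomposition (Gaussian MMI solver) for region pairs.

The time-delayed mutual information between a pair of processes
(X, Y) — I(X_{t-tau}, Y_{t-tau}; X_t, Y_t) — is decomposed into 16 atoms
indexed by a (past antichain -> future antichain) pair over the redundancy
lattice {{1}{2}, {1}, {2}, {12}}.  Redundancy follows the minimum-mutual-
information (MMI) convention: the double-redundancy of a pair of antichains
is the minimum Gaussian mutual information over all crossed source/target
subsets, and the atoms are recovered by Moebius inversion over the product
partial order.  The headline statistic is the temporally persistent synergy,
the {12}->{12} atom: information carried only jointly, in both past and
future.

Everything is computed from 4x4 lagged covariances under a joint-Gaussian
assumption, in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

from gecnet.core_data import RegionalTimeSeries

logger = logging.getLogger(__name__)

# Antichains over two sources, each a tuple of variable-index subsets.
# Order: bottom {1}{2}, then {1}, {2}, top {12}.
_ANTICHAINS: tuple[tuple[tuple[int, ...], ...], ...] = (
    ((0,), (1,)),   # {1}{2}
    ((0,),),        # {1}
    ((1,),),        # {2}
    ((0, 1),),      # {12}
)
_NAMES = ("{1}{2}", "{1}", "{2}", "{12}")

# leq[i][j]: antichain i precedes (is below) antichain j in the redundancy
# lattice {1}{2} < {1},{2} < {12}, with {1} and {2} incomparable.
_LEQ = np.array([
    [1, 1, 1, 1],
    [0, 1, 0, 1],
    [0, 0, 1, 1],
    [0, 0, 0, 1],
], dtype=bool)

ATOM_NAMES = tuple(
    f"{_NAMES[i]}->{_NAMES[j]}" for i, j in product(range(4), repeat=2)
)

# zeta[(i,j),(i',j')] = 1 iff (i',j') <= (i,j) in the product order
_ZETA = np.array([
    [float(_LEQ[ip, i] and _LEQ[jp, j])
     for ip, jp in product(range(4), repeat=2)]
    for i, j in product(range(4), repeat=2)
])
_MOEBIUS = np.linalg.inv(_ZETA)

_JITTER = 1e-10


def _logdet(m: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(m)
    if sign <= 0:
        m = m + _JITTER * np.eye(m.shape[0])
        logger.debug("regularized a non-PD covariance block with jitter %g", _JITTER)
        sign, val = np.linalg.slogdet(m)
        if sign <= 0:
            raise ValueError("covariance block not positive definite")
    return float(val)


def gaussian_mi(cov: np.ndarray, idx_a, idx_b) -> float:
    """Mutual information (nats) between two disjoint blocks of a Gaussian vector.

    I(A; B) = 1/2 log( det S_A det S_B / det S_AB ).
    """
    idx_a, idx_b = list(idx_a), list(idx_b)
    if not idx_a or not idx_b or set(idx_a) & set(idx_b):
        raise ValueError("index sets must be disjoint and non-empty")
    cov = np.asarray(cov, dtype=float)
    ab = idx_a + idx_b
    mi = 0.5 * (
        _logdet(cov[np.ix_(idx_a, idx_a)])
        + _logdet(cov[np.ix_(idx_b, idx_b)])
        - _logdet(cov[np.ix_(ab, ab)])
    )
    return max(mi, 0.0)


@dataclass(frozen=True)
class LaggedPairCovariance:
    """4x4 covariance of (X_{t-tau}, Y_{t-tau}, X_t, Y_t) for one region pair."""

    cov: np.ndarray
    tau_trs: int
    pair: tuple[int, int] = (0, 1)

    def __post_init__(self):
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (4, 4):
            raise ValueError("lagged pair covariance must be 4x4")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "cov", 0.5 * (c + c.T))


def lagged_pair_covariance(ts: RegionalTimeSeries, n: int, p: int,
                           tau_trs: int = 1) -> LaggedPairCovariance:
    """Sample covariance of the stacked past/future 4-vector, columns standardized."""
    v = ts.values
    if v.shape[0] <= tau_trs + 3:
        raise ValueError("time series too short for this lag")
    x, y = v[:, n], v[:, p]
    for col, idx in ((x, n), (y, p)):
        if col.std() == 0.0:
            raise ValueError(f"constant region {idx}")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    stacked = np.column_stack([x[:-tau_trs], y[:-tau_trs], x[tau_trs:], y[tau_trs:]])
    return LaggedPairCovariance(np.cov(stacked.T), tau_trs=tau_trs, pair=(n, p))


@dataclass(frozen=True)
class PhiIDAtoms:
    """The 16 MMI-PhiID atoms (nats) for one region pair."""

    atoms: dict[str, float]
    tdmi: float

    def __post_init__(self):
        if set(self.atoms) != set(ATOM_NAMES):
            raise ValueError("atoms must carry all 16 antichain pairs")
        if abs(sum(self.atoms.values()) - self.tdmi) > 1e-8:
            raise AssertionError("atoms do not sum to the TDMI")

    @property
    def redundancy(self) -> float:
        """Persistent redundancy, the {1}{2}->{1}{2} atom."""
        return self.atoms["{1}{2}->{1}{2}"]

    @property
    def synergy_persistent(self) -> float:
        """Persistent synergy, the {12}->{12} atom."""
        return self.atoms["{12}->{12}"]


def _double_redundancy(cov: np.ndarray, alpha, beta) -> float:
    """MMI double redundancy: min crossed MI between past subsets and future subsets."""
    return min(
        gaussian_mi(cov, list(a), [v + 2 for v in b])
        for a in alpha for b in beta
    )


def phiid_mmi(cov: LaggedPairCovariance) -> PhiIDAtoms:
    """Decompose one pair's TDMI into the 16 MMI-PhiID atoms.

    (i) evaluate the double-redundancy function on all 16 antichain pairs,
    (ii) Moebius-invert over the product order, (iii) check the atoms sum to
    the time-delayed mutual information.
    """
    c = cov.cov
    cumulative = np.array([
        _double_redundancy(c, _ANTICHAINS[i], _ANTICHAINS[j])
        for i, j in product(range(4), repeat=2)
    ])
    atoms = _MOEBIUS @ cumulative
    tdmi = gaussian_mi(c, [0, 1], [2, 3])
    return PhiIDAtoms(
        atoms={name: float(v) for name, v in zip(ATOM_NAMES, atoms)},
        tdmi=tdmi,
    )


def synergy_profile(ts: RegionalTimeSeries,
                    tau_trs: int = 1) -> tuple[np.ndarray, float]:
    """Persistent synergy for every unordered region pair, plus the pair mean.

    Pairs whose decomposition fails (degenerate covariance) are logged and
    excluded from the mean.
    """
    n = ts.n_regions
    if n < 2:
        raise ValueError("need at least two regions")
    syn = np.zeros((n, n))
    values = []
    failures = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                atoms = phiid_mmi(lagged_pair_covariance(ts, i, j, tau_trs))
            except (ValueError, np.linalg.LinAlgError) as exc:
                failures += 1
                logger.warning("PhiID failed for pair (%d, %d): %s", i, j, exc)
                syn[i, j] = syn[j, i] = np.nan
                continue
            syn[i, j] = syn[j, i] = atoms.synergy_persistent
            values.append(atoms.synergy_persistent)
    if failures:
        logger.warning("%d pairs excluded from the synergy mean", failures)
    if not values:
        raise ValueError("no pair yielded a valid decomposition")
    return syn, float(np.mean(values))
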