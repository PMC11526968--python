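"""Model evaluation: fit metrics, identifiability, cognitive matching, statistics.

Differential identifiability treats each simulated subject as a candidate
"fingerprint" for each empirical subject: the mean self-match minus the mean
cross-match similarity of FC matrices.  Cognitive matching scores momentary
activity patterns against a bank of canonical activation maps.  Group
comparisons use a resampling (sign-flip) paired t-test with Hedges' g effect
sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from gecnet.core_data import RegionalTimeSeries

logger = logging.getLogger(__name__)


def fc_fit(fc_emp: np.ndarray, fc_sim: np.ndarray) -> float:
    """Pearson correlation between the strict upper triangles of two FC matrices."""
    if fc_emp.shape != fc_sim.shape:
        raise ValueError("FC matrices must share a shape")
    iu = np.triu_indices(fc_emp.shape[0], k=1)
    a, b = fc_emp[iu], fc_sim[iu]
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero-variance upper triangle")
    return float(np.corrcoef(a, b)[0, 1])


def fc_ssim(fc_emp: np.ndarray, fc_sim: np.ndarray) -> float:
    """Global (single-window) structural similarity index between two matrices.

    The standard luminance/contrast/structure product with stabilizers
    C1 = (0.01 L)^2, C2 = (0.03 L)^2 where L is the joint value range.
    """
    if fc_emp.shape != fc_sim.shape:
        raise ValueError("matrices must share a shape")
    x, y = fc_emp.ravel(), fc_sim.ravel()
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    data_range = hi - lo
    if data_range == 0.0:
        raise ValueError("zero joint value range")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cxy = np.mean((x - mx) * (y - my))
    return float(
        ((2 * mx * my + c1) * (2 * cxy + c2))
        / ((mx * mx + my * my + c1) * (vx + vy + c2))
    )


@dataclass(frozen=True)
class IdentifiabilityResult:
    """Similarity matrix (simulated rows x empirical columns) and its summary."""

    similarity: np.ndarray
    i_self: float
    i_others: float
    i_diff: float


def identifiability(emp_fcs, sim_fcs) -> IdentifiabilityResult:
    """Differential identifiability I_diff = <A_ii> - <A_ij> of a cohort.

    A[i, j] is the upper-triangle correlation between simulated subject i and
    empirical subject j.
    """
    emp_fcs, sim_fcs = list(emp_fcs), list(sim_fcs)
    if len(emp_fcs) != len(sim_fcs):
        raise ValueError("need one simulated FC per empirical FC")
    s = len(emp_fcs)
    if s < 2:
        raise ValueError("identifiability needs at least two subjects")
    A = np.array([[fc_fit(sim_fcs[i], emp_fcs[j]) for j in range(s)]
                  for i in range(s)])
    off = ~np.eye(s, dtype=bool)
    i_self = float(np.mean(np.diag(A)))
    i_others = float(np.mean(A[off]))
    return IdentifiabilityResult(
        similarity=A, i_self=i_self, i_others=i_others,
        i_diff=i_self - i_others,
    )


@dataclass(frozen=True)
class CognitiveMapBank:
    """K spatial maps over the same N regions as the activity being scored."""

    maps: np.ndarray
    names: list[str]

    def __post_init__(self):
        m = np.asarray(self.maps, dtype=float)
        if m.ndim != 2 or m.shape[1] < 1:
            raise ValueError("maps must be an N x K matrix with K >= 1")
        if np.any(m.std(axis=0) == 0.0):
            raise ValueError("constant map column")
        if len(self.names) != m.shape[1]:
            raise ValueError("one name per map required")
        object.__setattr__(self, "maps", m)

    @property
    def n_maps(self) -> int:
        return self.maps.shape[1]


def cognitive_matching(ts: RegionalTimeSeries,
                       bank: CognitiveMapBank) -> tuple[np.ndarray, float]:
    """Best positive spatial correlation with any map, per volume, and its scan mean.

    Volumes where every map correlates negatively (or that are constant) score
    0; their count is logged.
    """
    if bank.maps.shape[0] != ts.n_regions:
        raise ValueError("map bank regions do not align with the time series")
    v = ts.values
    maps = bank.maps
    mz = (maps - maps.mean(axis=0)) / maps.std(axis=0)
    sd = v.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    sd[constant] = 1.0
    vz = (v - v.mean(axis=1, keepdims=True)) / sd
    corr = vz @ mz / ts.n_regions  # T x K spatial correlations
    best = corr.max(axis=1)
    floored = np.count_nonzero(best < 0.0) + np.count_nonzero(constant)
    best = np.where(constant, 0.0, np.maximum(best, 0.0))
    if floored:
        logger.info("%d volumes floored to 0 (no positive match)", floored)
    return best, float(best.mean())


@dataclass(frozen=True)
class ComparisonReport:
    """Paired comparison of one metric between two model variants."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_resampled: float
    hedges_g: float
    n_pairs: int
    n_resamples: int
    seed: int


def paired_comparison(a, b, n_resamples: int = 10_000,
                      seed: int = 0) -> ComparisonReport:
    """Resampling-based paired t-test (sign-flip, two-sided) with Hedges' g.

    The null distribution flips the sign of each paired difference at random;
    the p-value is the two-sided exceedance of |t| with the add-one rule.
    Hedges' g = (mean_a - mean_b) / s_pooled * (1 - 3 / (4(2S - 2) - 1)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length vectors")
    s = a.size
    if s < 3:
        raise ValueError("need at least three pairs")
    d = a - b
    sd_d = d.std(ddof=1)
    if np.allclose(d, d[0]) and d[0] == 0.0:
        t_obs, p = 0.0, 1.0
    else:
        if sd_d == 0.0:
            # constant nonzero shift: t is infinite, p is resampled below
            t_obs = np.inf * np.sign(d[0])
        else:
            t_obs = float(d.mean() / (sd_d / np.sqrt(s)))
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_resamples, s))
        flipped = flips * d
        means = flipped.mean(axis=1)
        sds = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(sds == 0.0, np.inf * np.sign(means),
                              means / (sds / np.sqrt(s)))
        exceed = np.count_nonzero(np.abs(t_null) >= abs(t_obs))
        p = float((1 + exceed) / (1 + n_resamples))
    s_pooled = np.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
    if s_pooled == 0.0:
        g = 0.0
    else:
        correction = 1.0 - 3.0 / (4.0 * (2 * s - 2) - 1.0)
        g = float((a.mean() - b.mean()) / s_pooled * correction)
    return ComparisonReport(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t_statistic=float(t_obs), p_resampled=p, hedges_g=g,
        n_pairs=s, n_resamples=n_resamples, seed=seed,
    )
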