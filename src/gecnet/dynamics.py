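"""Dynamical signatures: synchrony/metastability, ignition and irreversibility.

All three operate on band-limited regional signals.  Phases come from the
analytic signal (Hilbert transform); the Kuramoto order parameter (KOP)
summarizes instantaneous phase alignment; metastability is its temporal
standard deviation.  Intrinsic-driven ignition measures how broadly a
region's spontaneous supra-threshold events co-occur with events elsewhere,
and temporal irreversibility contrasts forward against time-reversed lagged
correlations, the "arrow of time" of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from gecnet.core_data import RegionalTimeSeries

EDGE_TRIM_FRACTION = 0.05


@dataclass(frozen=True)
class PhaseData:
    """Instantaneous phase and amplitude per region, plus the edge-trim slice."""

    phases: np.ndarray
    amplitudes: np.ndarray
    edge_samples: int  # samples flagged as Hilbert edge-affected at each end

    @property
    def interior(self) -> slice:
        return slice(self.edge_samples, self.phases.shape[0] - self.edge_samples)


@dataclass(frozen=True)
class KOPSeries:
    """Kuramoto order parameter over time with its summary statistics."""

    kop: np.ndarray
    metastability: float
    max_sync: float


@dataclass(frozen=True)
class IgnitionResult:
    """Event raster, per-event ignition breadths, and the local-global hierarchy."""

    event_raster: np.ndarray
    per_event_breadth: list[tuple[int, int, int]]  # (driver region, time, breadth)
    mean_idi: np.ndarray  # NaN for regions with no driver events
    hierarchy: float


@dataclass(frozen=True)
class IrreversibilityResult:
    """Forward/reversed lagged-correlation structure and its hierarchy."""

    c_forward: np.ndarray
    c_reversed: np.ndarray
    fs_forward: np.ndarray
    fs_reversed: np.ndarray
    fs_diff: np.ndarray
    pair_irreversibility: np.ndarray
    hierarchy: float
    region_mean_fs_diff: np.ndarray = field(default=None)
    region_hierarchy: float = float("nan")


def extract_phases(ts: RegionalTimeSeries) -> PhaseData:
    """Analytic-signal phase and amplitude of each band-passed region.

    The input must carry its band (i.e. have been band-pass filtered); the
    first and last 5% of samples are flagged as edge-affected so downstream
    statistics can trim them.
    """
    if ts.band_hz is None:
        raise ValueError("extract_phases requires band-passed input (band_hz set)")
    centred = ts.values - ts.values.mean(axis=0)
    analytic = signal.hilbert(centred, axis=0)
    edge = int(np.floor(EDGE_TRIM_FRACTION * ts.n_volumes))
    return PhaseData(
        phases=np.angle(analytic),
        amplitudes=np.abs(analytic),
        edge_samples=edge,
    )


def kuramoto(phases: PhaseData, trim_edges: bool = True) -> KOPSeries:
    """KOP_t = |mean_k exp(i phi_k(t))|; metastability = population SD over time."""
    ph = phases.phases
    if ph.shape[1] < 2:
        raise ValueError("KOP needs at least two regions")
    kop = np.abs(np.exp(1j * ph).mean(axis=1))
    retained = kop[phases.interior] if trim_edges else kop
    return KOPSeries(
        kop=kop,
        metastability=float(np.std(retained)),  # population SD
        max_sync=float(np.max(retained)),
    )


def _event_raster(values: np.ndarray, z_threshold: float) -> np.ndarray:
    """Upward threshold crossings of the per-region z-scored signal."""
    sd = values.std(axis=0)
    if np.any(sd == 0.0):
        raise ValueError("constant region: z-scoring undefined")
    z = (values - values.mean(axis=0)) / sd
    above = z > z_threshold
    raster = np.zeros_like(above)
    raster[1:] = above[1:] & ~above[:-1]
    raster[0] = above[0]
    return raster


def ignition(ts: RegionalTimeSeries, z_threshold: float = 1.0,
             window_trs: int = 4) -> IgnitionResult:
    """Intrinsic-driven ignition and its across-region hierarchy.

    A driver event is an upward crossing of z > ``z_threshold``.  For each
    driver event at (region i, time t) the active set is every region with an
    event inside the window [t, t + window - 1]; all active regions co-occur
    pairwise, so the largest connected component of the co-occurrence matrix
    is the active set itself and the ignition breadth is its size.  The
    hierarchy is the population SD, across regions with at least one driver
    event, of their mean breadth.
    """
    T, n = ts.values.shape
    if window_trs >= T:
        raise ValueError("window must be shorter than the series")
    if n < 2:
        raise ValueError("ignition needs at least two regions")
    raster = _event_raster(ts.values, z_threshold)
    events_any = raster.any(axis=1)
    breadths: list[tuple[int, int, int]] = []
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for t in np.nonzero(events_any)[0]:
        window = raster[t:t + window_trs]
        active = np.nonzero(window.any(axis=0))[0]
        breadth = int(active.size)
        for i in np.nonzero(raster[t])[0]:
            breadths.append((int(i), int(t), breadth))
            sums[i] += breadth
            counts[i] += 1
    if not breadths:
        raise ValueError("no threshold crossings: ignition undefined")
    mean_idi = np.full(n, np.nan)
    has = counts > 0
    mean_idi[has] = sums[has] / counts[has]
    hierarchy = float(np.std(mean_idi[has]))  # population SD, active regions only
    return IgnitionResult(
        event_raster=raster, per_event_breadth=breadths,
        mean_idi=mean_idi, hierarchy=hierarchy,
    )


_CORR_CAP = 1.0 - 1e-12


def _fs_from_corr(c: np.ndarray) -> np.ndarray:
    """Gaussian mutual information of a correlation: -1/2 log(1 - c^2)."""
    c2 = np.minimum(c * c, _CORR_CAP)
    return -0.5 * np.log1p(-c2)


def irreversibility(ts: RegionalTimeSeries, lag_trs: int = 1) -> IrreversibilityResult:
    """Temporal-irreversibility structure at the given lag.

    ``pair_irreversibility`` = |c_forward - c_reversed|; the FS matrices map
    the lagged correlations to Gaussian mutual information, and
    ``fs_diff`` = (FS_forward - FS_reversed)^2.  The headline hierarchy is the
    population SD of the off-diagonal fs_diff entries; the SD of per-region
    mean fs_diff (the send-receive view) is also returned.
    """
    from gecnet.gec import fc_statistics

    stats = fc_statistics(ts, lag_trs=lag_trs)
    c_fwd, c_rev = stats.fc_forward, stats.fc_reversal
    fs_fwd = _fs_from_corr(c_fwd)
    fs_rev = _fs_from_corr(c_rev)
    fs_diff = (fs_fwd - fs_rev) ** 2
    off = ~np.eye(fs_diff.shape[0], dtype=bool)
    region_mean = (fs_diff * off).sum(axis=1) / (fs_diff.shape[0] - 1)
    return IrreversibilityResult(
        c_forward=c_fwd, c_reversed=c_rev,
        fs_forward=fs_fwd, fs_reversed=fs_rev, fs_diff=fs_diff,
        pair_irreversibility=np.abs(c_fwd - c_rev),
        hierarchy=float(np.std(fs_diff[off])),
        region_mean_fs_diff=region_mean,
        region_hierarchy=float(np.std(region_mean)),
    )
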