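"""Core containers, file I/O, connectome preparation and band-pass filtering.

Connectomes live on disk as dense numeric CSV (N rows x N columns, optional
header) with an optional one-label-per-line sidecar; regional time series as
TSV with a header row of region labels and one row per volume.  Internally
region indexing is 0-based; user-facing reports use the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy import signal

logger = logging.getLogger(__name__)

_SYMMETRY_ATOL = 1e-12


def _default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


@dataclass(frozen=True)
class StructuralConnectome:
    """An N-region anatomical coupling matrix with labels and optional coordinates.

    ``weights`` is the coupling matrix G (row n, column p = weight of the
    connection from p into n under diffusive coupling); units are arbitrary.
    ``coords`` are region centroids in mm used only for edge-length statistics.
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None
    directed: bool = False
    species_tag: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome matrix must be square, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome contains non-finite entries")
        if np.any(np.diag(w) != 0.0):
            logger.info("forcing nonzero connectome diagonal to zero")
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)
        labels = list(self.labels) if self.labels else _default_labels(w.shape[0])
        if len(labels) != w.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for a {w.shape[0]}-region connectome"
            )
        object.__setattr__(self, "labels", labels)
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (w.shape[0], 3):
                raise ValueError(f"coords must be N x 3, got {c.shape}")
            object.__setattr__(self, "coords", c)
        if not self.directed and not np.allclose(w, w.T, atol=_SYMMETRY_ATOL):
            raise ValueError("undirected connectome is not symmetric")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class RegionalTimeSeries:
    """A T x N table of regional signals sampled every ``tr_seconds``."""

    values: np.ndarray
    tr_seconds: float
    band_hz: tuple[float, float] | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be a T x N matrix")
        if v.shape[0] < 2:
            raise ValueError("need at least two time points")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains missing or non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)
        labels = list(self.labels) if self.labels else _default_labels(v.shape[1])
        if len(labels) != v.shape[1]:
            raise ValueError("label count does not match number of regions")
        object.__setattr__(self, "labels", labels)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Sidecar metadata describing one (possibly simulated) acquisition."""

    tr_seconds: float
    n_volumes: int
    band_hz: tuple[float, float] | None = None
    subject_id: str = ""
    seed: int | None = None

    def validate_against(self, ts: RegionalTimeSeries) -> None:
        if abs(self.tr_seconds - ts.tr_seconds) > 1e-9:
            raise ValueError("meta TR does not match time series TR")
        if self.n_volumes != ts.n_volumes:
            raise ValueError("meta volume count does not match time series")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_labels(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_connectome(
    path: str | Path,
    labels_path: str | Path | None = None,
    coords_path: str | Path | None = None,
) -> StructuralConnectome:
    """Read a dense N x N CSV connectome (header row optional).

    A matrix with any asymmetric pair is loaded as ``directed=True``.
    """
    path = Path(path)
    first = path.open().readline()
    has_header = any(
        tok and not _is_number(tok) for tok in first.strip().split(",")
    )
    df = pd.read_csv(path, header=0 if has_header else None)
    try:
        w = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"connectome in {path} is not square: {w.shape}")
    labels = _read_labels(labels_path) if labels_path else (
        [str(c) for c in df.columns] if has_header else []
    )
    coords = None
    if coords_path is not None:
        cdf = pd.read_csv(coords_path)
        coords = cdf[["x", "y", "z"]].to_numpy(dtype=float)
    directed = not np.allclose(w, w.T, atol=_SYMMETRY_ATOL)
    return StructuralConnectome(w, labels=labels, coords=coords, directed=directed)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_connectome(sc: StructuralConnectome, path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    """Write weights as full-precision CSV (no header), labels as a sidecar."""
    np.savetxt(path, sc.weights, delimiter=",", fmt="%.15g")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(sc.labels) + "\n")


def read_timeseries(path: str | Path,
                    meta_path: str | Path | None = None) -> RegionalTimeSeries:
    """Read a T x N TSV (header = region labels), optionally with a YAML sidecar."""
    df = pd.read_csv(path, sep="\t")
    tr, band = 1.0, None
    if meta_path is not None:
        meta = yaml.safe_load(Path(meta_path).read_text())
        tr = float(meta["tr_seconds"])
        if meta.get("band_hz"):
            band = tuple(float(b) for b in meta["band_hz"])
    return RegionalTimeSeries(
        df.to_numpy(dtype=float), tr_seconds=tr, band_hz=band,
        labels=[str(c) for c in df.columns],
    )


def write_timeseries(ts: RegionalTimeSeries, path: str | Path,
                     meta_path: str | Path | None = None,
                     meta: AcquisitionMeta | None = None) -> None:
    pd.DataFrame(ts.values, columns=ts.labels).to_csv(
        path, sep="\t", index=False, float_format="%.15g"
    )
    if meta_path is not None:
        record = {
            "tr_seconds": float(ts.tr_seconds),
            "n_volumes": int(ts.n_volumes),
            "band_hz": list(ts.band_hz) if ts.band_hz else None,
        }
        if meta is not None:
            record["subject_id"] = meta.subject_id
            record["seed"] = meta.seed
        Path(meta_path).write_text(yaml.safe_dump(record))


# ---------------------------------------------------------------------------
# Connectome preparation
# ---------------------------------------------------------------------------

def symmetrize(sc: StructuralConnectome) -> StructuralConnectome:
    """Average the matrix with its transpose; the result is undirected."""
    w = 0.5 * (sc.weights + sc.weights.T)
    return replace(sc, weights=w, directed=False)


def threshold_density(sc: StructuralConnectome, density: float) -> StructuralConnectome:
    """Keep the strongest edges by absolute weight down to the target density.

    Density is measured graph-theoretically: edges relative to all
    upper-triangle slots.  The budget is ceil(density * N(N-1)/2), capped at
    the current edge count, which makes the operation idempotent and a no-op
    on graphs already at or below the target density.  Removal is symmetric
    so the output stays undirected.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if sc.directed:
        raise ValueError("threshold an undirected (symmetrized) connectome")
    n = sc.n_regions
    iu, ju = np.triu_indices(n, k=1)
    upper = sc.weights[iu, ju]
    keep = min(int(np.ceil(density * upper.size)),
               int(np.count_nonzero(upper)))
    order = np.argsort(np.abs(upper))[::-1]
    kept_idx = order[:keep]
    w = np.zeros_like(sc.weights)
    w[iu[kept_idx], ju[kept_idx]] = upper[kept_idx]
    w = w + w.T
    return replace(sc, weights=w)


def scale_coupling(sc: StructuralConnectome, target_max: float = 0.2) -> StructuralConnectome:
    """Rescale weights so the largest absolute weight equals ``target_max``."""
    peak = np.max(np.abs(sc.weights))
    if peak == 0.0:
        raise ValueError("cannot scale an all-zero connectome")
    return replace(sc, weights=sc.weights * (target_max / peak))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

_FILTER_ORDER = 2


def bandpass(ts: RegionalTimeSeries, low_hz: float, high_hz: float) -> RegionalTimeSeries:
    """Zero-phase second-order Butterworth band-pass, applied per region.

    Columns are linearly detrended first; the filter is run forward and
    backward (``filtfilt``) so it introduces no phase distortion.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not 0.0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyquist:.4g}) Hz"
        )
    b, a = signal.butter(_FILTER_ORDER, [low_hz, high_hz], btype="band", fs=1.0 / ts.tr_seconds)
    padlen = 3 * max(len(a), len(b))
    if ts.n_volumes <= padlen:
        raise ValueError(f"need more than {padlen} samples to band-pass filter")
    detrended = signal.detrend(ts.values, axis=0, type="linear")
    filtered = signal.filtfilt(b, a, detrended, axis=0)
    return replace(ts, values=filtered, band_hz=(low_hz, high_hz))
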