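"""Synthetic ground truths and cohorts for exercising the whole pipeline.

The generator emulates the structural premises the analyses rely on: a
modular backbone of strong positive couplings, a sparse set of weak,
long-range, cross-module negative couplings, per-subject multiplicative
jitter, and band-limited noisy oscillatory BOLD at species-like repetition
times.  It deliberately does not try to mimic any real dataset's FC
distribution — it targets the statistical premises, not dataset mimicry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gecnet.core_data import (
    AcquisitionMeta,
    RegionalTimeSeries,
    StructuralConnectome,
    bandpass,
    write_connectome,
    write_timeseries,
)
from gecnet.evaluation import CognitiveMapBank
from gecnet.hopf import HopfParameters, scale_to_stability_margin, simulate

#: species-style presets: repetition time (s) and filtering band (Hz)
SPECIES_PRESETS = {
    "human": (0.72, (0.008, 0.09)),
    "macaque": (2.6, (0.008, 0.09)),
    "mouse": (1.0, (0.01, 0.1)),
}


@dataclass(frozen=True)
class GroundTruthSpec:
    """Parameters of the signed ground-truth effective connectivity generator."""

    n_regions: int = 30
    n_modules: int = 3
    fraction_negative: float = 0.3
    pos_weight_range: tuple[float, float] = (0.5, 1.0)
    between_weight_range: tuple[float, float] = (0.1, 0.3)
    neg_weight_scale: float = 0.5
    neg_min_distance_quantile: float = 0.6
    density: float = 0.25
    between_positive_share: float = 0.15
    geometry: str = "unit-cube"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_negative < 1.0:
            raise ValueError("fraction_negative must lie in [0, 1)")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        if self.geometry not in ("unit-cube", "ring"):
            raise ValueError("geometry must be 'unit-cube' or 'ring'")
        if self.n_modules < 1 or self.n_regions < 2 * self.n_modules:
            raise ValueError("need at least two regions per module")


def _module_labels(n: int, n_modules: int) -> np.ndarray:
    sizes = np.full(n_modules, n // n_modules)
    sizes[: n % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def _coords(spec: GroundTruthSpec, modules: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Module-clustered centroids (mm): tight modules, well-separated centres."""
    if spec.geometry == "ring":
        angles = 2 * np.pi * modules / spec.n_modules
        angles = angles + rng.uniform(-0.3, 0.3, size=modules.size)
        return np.column_stack([
            50 + 40 * np.cos(angles), 50 + 40 * np.sin(angles),
            rng.uniform(40, 60, modules.size),
        ])
    centres = []
    while len(centres) < spec.n_modules:
        cand = rng.uniform(15, 85, size=3)
        if all(np.linalg.norm(cand - c) >= 40 for c in centres):
            centres.append(cand)
    centres = np.array(centres)
    return centres[modules] + rng.uniform(-10, 10, size=(modules.size, 3))


def make_ground_truth(spec: GroundTruthSpec) -> tuple[StructuralConnectome, np.ndarray]:
    """Generate a signed, symmetric, zero-diagonal ground-truth connectome.

    Positive couplings are dense and strong within modules with a weak sparse
    between-module remainder; negative couplings are drawn from the longest
    cross-module pairs with magnitudes scaled down by ``neg_weight_scale``.
    Returns the connectome (with coordinates) and the module label vector.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    modules = _module_labels(n, spec.n_modules)
    coords = _coords(spec, modules, rng)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))

    iu, ju = np.triu_indices(n, k=1)
    within = modules[iu] == modules[ju]
    n_pairs = iu.size
    n_edges = int(round(spec.density * n_pairs))
    n_neg = int(round(spec.fraction_negative * n_edges))
    n_pos = n_edges - n_neg

    # positive edges: prefer within-module slots, plus a weak between share
    n_between_pos = min(int(round(spec.between_positive_share * n_pos)),
                        int(np.count_nonzero(~within)))
    n_within_pos = n_pos - n_between_pos
    within_idx = np.nonzero(within)[0]
    between_idx = np.nonzero(~within)[0]
    if n_within_pos > within_idx.size:
        # spill extra positives into between-module slots
        n_between_pos += n_within_pos - within_idx.size
        n_within_pos = within_idx.size
    pos_within = rng.choice(within_idx, size=n_within_pos, replace=False)
    pos_between = rng.choice(between_idx, size=n_between_pos, replace=False)

    # negative edges: cross-module, long-range, not already positive
    taken = set(pos_within) | set(pos_between)
    threshold = np.quantile(dist[iu, ju], spec.neg_min_distance_quantile)
    candidates = [k for k in between_idx
                  if k not in taken and dist[iu[k], ju[k]] >= threshold]
    if len(candidates) < n_neg:
        raise ValueError(
            f"infeasible spec: {n_neg} negative edges requested but only "
            f"{len(candidates)} long-range cross-module slots available"
        )
    neg = rng.choice(np.asarray(candidates, dtype=int), size=n_neg, replace=False)

    w = np.zeros((n, n))
    lo, hi = spec.pos_weight_range
    blo, bhi = spec.between_weight_range
    w[iu[pos_within], ju[pos_within]] = rng.uniform(lo, hi, n_within_pos)
    w[iu[pos_between], ju[pos_between]] = rng.uniform(blo, bhi, n_between_pos)
    w[iu[neg], ju[neg]] = -spec.neg_weight_scale * rng.uniform(lo, hi, n_neg)
    w = w + w.T

    realized = np.count_nonzero(w[iu, ju] < 0) / max(np.count_nonzero(w[iu, ju]), 1)
    if abs(realized - spec.fraction_negative) > 0.05:
        raise AssertionError("realized negative fraction drifted from the spec")
    sc = StructuralConnectome(w, coords=coords, directed=False,
                              species_tag="synthetic")
    return sc, modules


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject: jittered coupling, band-passed BOLD, metadata."""

    gec: np.ndarray
    ts: RegionalTimeSeries
    meta: AcquisitionMeta


@dataclass(frozen=True)
class SyntheticCohort:
    """A ground truth plus per-subject couplings and simulated recordings."""

    ground_truth: StructuralConnectome
    module_labels: np.ndarray
    subjects: list[SubjectRecord]
    tr_seconds: float
    band_hz: tuple[float, float]
    roles: dict[str, list[int]]
    map_bank: CognitiveMapBank
    hopf_params: HopfParameters = None
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _map_bank(modules: np.ndarray, ground_truth: np.ndarray,
              rng: np.random.Generator, n_random_maps: int = 8) -> CognitiveMapBank:
    """Module-indicator maps plus connectivity-smoothed random patterns."""
    n = modules.size
    pos = np.clip(ground_truth, 0.0, None)
    smooth = np.eye(n) + pos / max(pos.max(), 1e-12)
    maps, names = [], []
    for m in range(modules.max() + 1):
        maps.append((modules == m).astype(float))
        names.append(f"module_{m}")
    for k in range(n_random_maps):
        maps.append(smooth @ rng.standard_normal(n))
        names.append(f"pattern_{k}")
    return CognitiveMapBank(np.column_stack(maps), names)


def make_cohort(spec: GroundTruthSpec, n_subjects: int = 5,
                subject_jitter_sd: float = 0.1,
                hopf_params: HopfParameters | None = None,
                species: str = "human", n_volumes: int = 1200,
                stability_margin: float = 0.01,
                seed: int | None = None) -> SyntheticCohort:
    """Simulate a cohort of band-passed BOLD recordings from one ground truth.

    The signed ground truth is rescaled to a fixed linear-stability margin so
    the network sits just below its bifurcation whatever its competitive-edge
    content (an all-positive ground truth falls back to max weight 0.2).  Per
    subject the coupling magnitudes receive multiplicative lognormal jitter
    (sign-preserving, so edge signs are stable across subjects) and a fresh
    noise seed drives the Hopf simulation at the species-style TR.  Roles:
    module 0 plays "visual", module 1 "somatomotor".
    """
    tr, band = SPECIES_PRESETS[species]
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sc, modules = make_ground_truth(spec)
    if hopf_params is not None and tr != hopf_params.tr_seconds:
        tr = hopf_params.tr_seconds
    a_param = float(np.mean((hopf_params or HopfParameters(tr_seconds=tr)).vectors(spec.n_regions)[0]))
    sc = replace(sc, weights=scale_to_stability_margin(
        sc.weights, a=a_param, margin=stability_margin))
    if hopf_params is None:
        hopf_params = HopfParameters(tr_seconds=tr)
    params = hopf_params
    duration = n_volumes * params.tr_seconds + params.burn_in_seconds

    subjects = []
    for s in range(n_subjects):
        jitter = np.exp(subject_jitter_sd * rng.standard_normal(sc.weights.shape))
        jitter = np.triu(jitter, 1)
        jitter = jitter + jitter.T  # keep the coupling symmetric
        gec_s = sc.weights * np.where(jitter == 0, 1.0, jitter)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        p = replace(params, duration_seconds=duration, seed=sub_seed)
        try:
            bold = simulate(gec_s, p).ts
        except FloatingPointError as exc:
            raise ValueError(
                "simulation unstable at the requested coupling; lower "
                "coupling_max or the jitter SD"
            ) from exc
        filtered = bandpass(bold, *band)
        meta = AcquisitionMeta(tr_seconds=params.tr_seconds,
                               n_volumes=filtered.n_volumes, band_hz=band,
                               subject_id=f"sub-{s + 1:02d}", seed=sub_seed)
        subjects.append(SubjectRecord(gec=gec_s, ts=filtered, meta=meta))

    roles = {
        "visual": [int(i) for i in np.nonzero(modules == 0)[0]],
        "somatomotor": [int(i) for i in np.nonzero(modules == 1 % (modules.max() + 1))[0]],
    }
    bank = _map_bank(modules, sc.weights, rng)
    return SyntheticCohort(
        ground_truth=sc, module_labels=modules, subjects=subjects,
        tr_seconds=params.tr_seconds, band_hz=band, roles=roles,
        map_bank=bank, hopf_params=params, seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohort directory layout (consumed by the CLI subcommands)
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_connectome(cohort.ground_truth, out / "ground_truth.csv",
                     labels_path=out / "labels.txt")
    if cohort.ground_truth.coords is not None:
        pd.DataFrame({
            "label": cohort.ground_truth.labels,
            "x": cohort.ground_truth.coords[:, 0],
            "y": cohort.ground_truth.coords[:, 1],
            "z": cohort.ground_truth.coords[:, 2],
        }).to_csv(out / "coords.csv", index=False)
    pd.DataFrame(cohort.map_bank.maps, columns=cohort.map_bank.names).to_csv(
        out / "map_bank.csv", index=False
    )
    meta = {
        "tr_seconds": float(cohort.tr_seconds),
        "band_hz": list(cohort.band_hz),
        "seed": int(cohort.seed),
        "modules": [int(m) for m in cohort.module_labels],
        "roles": cohort.roles,
        "n_subjects": cohort.n_subjects,
    }
    (out / "cohort.yaml").write_text(yaml.safe_dump(meta))
    for s, rec in enumerate(cohort.subjects, start=1):
        stem = out / f"sub-{s:02d}"
        np.savetxt(f"{stem}_gec.csv", rec.gec, delimiter=",", fmt="%.15g")
        write_timeseries(rec.ts, f"{stem}_ts.tsv", meta_path=f"{stem}_meta.yaml",
                         meta=rec.meta)


def read_cohort(cohort_dir: str | Path) -> SyntheticCohort:
    from gecnet.core_data import read_connectome, read_timeseries

    d = Path(cohort_dir)
    meta = yaml.safe_load((d / "cohort.yaml").read_text())
    sc = read_connectome(d / "ground_truth.csv", labels_path=d / "labels.txt",
                         coords_path=d / "coords.csv" if (d / "coords.csv").exists() else None)
    bank_df = pd.read_csv(d / "map_bank.csv")
    bank = CognitiveMapBank(bank_df.to_numpy(dtype=float),
                            [str(c) for c in bank_df.columns])
    subjects = []
    for s in range(1, meta["n_subjects"] + 1):
        stem = d / f"sub-{s:02d}"
        gec = np.loadtxt(f"{stem}_gec.csv", delimiter=",")
        ts = read_timeseries(f"{stem}_ts.tsv", meta_path=f"{stem}_meta.yaml")
        sub_meta = yaml.safe_load(Path(f"{stem}_meta.yaml").read_text())
        subjects.append(SubjectRecord(
            gec=gec, ts=ts,
            meta=AcquisitionMeta(
                tr_seconds=ts.tr_seconds, n_volumes=ts.n_volumes,
                band_hz=ts.band_hz, subject_id=sub_meta.get("subject_id", ""),
                seed=sub_meta.get("seed"),
            ),
        ))
    return SyntheticCohort(
        ground_truth=sc, module_labels=np.asarray(meta["modules"]),
        subjects=subjects, tr_seconds=float(meta["tr_seconds"]),
        band_hz=tuple(meta["band_hz"]), roles=meta["roles"], map_bank=bank,
        hopf_params=HopfParameters(tr_seconds=float(meta["tr_seconds"])),
        seed=int(meta.get("seed", 0)),
    )
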