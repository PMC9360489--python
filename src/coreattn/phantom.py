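"""Synthetic CT brain phantoms with ASPECTS-style regional anatomy.

The phantom emulates the measurement situation of hemispheric stroke CT:
two mirror-symmetric hemispheres, each partitioned into the ten ASPECTS
regions (caudate C, lentiform L, internal capsule IC, insula I, and the
cortical MCA territories M1-M6); normal parenchyma in the 21-50 HU band;
a spatially coherent ischemic lesion that lowers attenuation on one side;
sub-band (CSF-like) and supra-band (calcification-like) confounders; a
non-contrast CT (NCCT) and a higher-lesion-contrast CTA-source rendition
of the same subject; and paired rCBF-ratio / TTP-delay surrogate maps
whose thresholded core is the ground-truth lesion mask.

No CT physics is modelled (no beam hardening, partial volume, or
inter-subject anatomical variability); the phantom reproduces only the
statistical structure the downstream analysis relies on.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Canonical region order used for all 10-vectors in this package.
REGION_ORDER: tuple[str, ...] = ("C", "L", "IC", "I", "M1", "M2", "M3", "M4", "M5", "M6")

SIDES: tuple[str, str] = ("left", "right")

#: Small symmetric per-region offsets (HU) added to the cohort baseline so
#: regions are not all identical; deep grey slightly denser than cortex.
REGION_BASE_OFFSET: dict[str, float] = {
    "C": 1.5, "L": 1.2, "IC": -0.8, "I": 0.6,
    "M1": -0.3, "M2": 0.0, "M3": -0.6, "M4": 0.2, "M5": -0.2, "M6": -0.5,
}

#: HU values assigned to confounder voxels (outside the 21-50 HU band).
CSF_HU = 10.0
CALCIFICATION_HU = 80.0

MIN_REGION_VOXELS = 200

_MODALITIES = ("ncct", "cta")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AspectsAtlas:
    """Integer label volume naming the 10 ASPECTS regions per hemisphere.

    Labels 1-10 are the left-side regions in :data:`REGION_ORDER`, labels
    11-20 the right-side homologues; 0 is background.  Axis 0 of the label
    array runs left-to-right with the midline at the central sagittal
    plane, so mirroring is the pure index reflection ``labels[::-1]``.
    """

    labels: np.ndarray
    regions: pd.DataFrame  # columns: code, region, side
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        lookup = {(row.region, row.side): int(row.code)
                  for row in self.regions.itertuples()}
        if len(lookup) != 2 * len(REGION_ORDER):
            raise ValueError("region table must name all 10 regions on both sides")
        object.__setattr__(self, "_code_lookup", lookup)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        return np.diag([*self.spacing, 1.0])

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def code_for(self, region: str, side: str) -> int:
        """Label code for a region/side pair, resolved via the region table."""
        try:
            return self._code_lookup[(region, side)]
        except KeyError:
            raise KeyError(f"no atlas entry for region {region!r} on side {side!r}") from None

    def region_mask(self, region: str, side: str) -> np.ndarray:
        return self.labels == self.code_for(region, side)

    def side_mask(self, side: str) -> np.ndarray:
        codes = [self.code_for(r, side) for r in REGION_ORDER]
        return np.isin(self.labels, codes)


@dataclass(frozen=True)
class CtVolume:
    """A CT-like intensity volume in Hounsfield units."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    modality: str  # "ncct" | "cta"

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("CT intensities must be finite")


@dataclass(frozen=True)
class PerfusionSurrogate:
    """Voxelwise rCBF ratio and TTP delay relative to the contralateral side.

    ``rcbf_ratio`` is 1.0 and ``ttp_delay`` 0.0 everywhere outside the
    lesion; inside, the ratio drops below and the delay rises above the
    core-defining thresholds.
    """

    rcbf_ratio: np.ndarray
    ttp_delay: np.ndarray
    brain_mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.any(self.rcbf_ratio < 0) or np.any(self.ttp_delay < 0):
            raise ValueError("rCBF ratio and TTP delay must be non-negative")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one simulated subject."""

    lesion_mask: np.ndarray
    affected_side: str
    involvement: dict[str, float]  # region -> fraction of region voxels lesioned
    severity: float  # mean HU decrement inside the lesion (NCCT)
    volume_ml: float


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    window: str  # "<=4.5h" | ">4.5h"
    ncct: CtVolume
    cta: CtVolume
    perfusion: PerfusionSurrogate
    truth: PhantomTruth


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults target a 73-subject cohort with roughly 30% of cores at or
    above 70 ml and a slight majority imaged within 4.5 h of onset, with
    severity (the mean HU decrement of lesioned tissue) larger in the
    late window.
    """

    n: int = 73
    large_core_frac: float = 0.301
    early_frac: float = 0.534
    severity_mean: float = 5.0          # HU decrement, early window
    severity_sd: float = 1.5            # absolute HU scatter across subjects
    late_severity_scale: float = 1.3
    noise_sd: float = 2.0               # per-voxel HU noise
    cta_gain: float = 1.5               # lesion decrement multiplier on CTA-source
    csf_frac: float = 0.05
    calc_frac: float = 0.005
    base_hu: float = 36.0
    small_core_median_ml: float = 20.0  # log-normal median of sub-70 ml cores
    small_core_sigma: float = 1.0
    small_core_range_ml: tuple[float, float] = (0.5, 68.0)
    large_core_range_ml: tuple[float, float] = (72.0, 220.0)
    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2 subjects")
        for name in ("large_core_frac", "early_frac", "csf_frac", "calc_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.severity_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.cta_gain <= 0:
            raise ValueError("cta_gain must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shape", "spacing", "small_core_range_ml", "large_core_range_ml"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

def _left_hemisphere_boxes(shape: tuple[int, int, int]) -> dict[str, tuple[slice, slice, slice]]:
    """Axis-aligned boxes for the 10 left-side regions.

    Deep structures (C, L, IC, I) occupy a paramedian slab at mid-depth;
    the cortical territories M1-M3 (lower slices) and M4-M6 (upper
    slices) occupy a larger lateral slab, so region sizes are deliberately
    unequal, mimicking the disproportional territory weights of the
    ASPECTS template.
    """
    nx, ny, nz = shape
    half = nx // 2
    deep_x = slice(int(0.60 * half), int(0.92 * half))
    cort_x = slice(int(0.12 * half), int(0.60 * half))
    deep_z = slice(nz // 3, (2 * nz) // 3)
    lo_z, hi_z = slice(0, nz // 2), slice(nz // 2, nz)

    deep_y_cuts = [0, int(0.30 * ny), int(0.55 * ny), int(0.75 * ny), ny]
    cort_y_cuts = [0, int(0.38 * ny), int(0.70 * ny), ny]

    boxes: dict[str, tuple[slice, slice, slice]] = {}
    for name, (y0, y1) in zip(("C", "L", "IC", "I"), zip(deep_y_cuts, deep_y_cuts[1:])):
        boxes[name] = (deep_x, slice(y0, y1), deep_z)
    for k, (y0, y1) in enumerate(zip(cort_y_cuts, cort_y_cuts[1:])):
        boxes[f"M{k + 1}"] = (cort_x, slice(y0, y1), lo_z)
        boxes[f"M{k + 4}"] = (cort_x, slice(y0, y1), hi_z)
    return boxes


def build_atlas(
    shape: tuple[int, int, int] = (64, 64, 32),
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0),
) -> AspectsAtlas:
    """Build the deterministic mirror-symmetric ASPECTS label atlas.

    Left-side regions are carved as axis-aligned boxes in the left half of
    axis 0 and reflected across the midsagittal plane to produce exact
    right-side homologues (left codes 1-10, right codes 11-20).

    Raises
    ------
    ValueError
        If the grid is too small to give every region at least
        ``MIN_REGION_VOXELS`` voxels; the smallest violating region is
        named in the message.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise ValueError(f"need a 3-D grid with every axis >= 2, got {shape}")
    labels = np.zeros(shape, dtype=np.int16)
    for idx, name in enumerate(REGION_ORDER):
        box = _left_hemisphere_boxes(shape)[name]
        labels[box] = idx + 1
    # Exact mirror: right hemisphere is the reflection of the left.
    reflected = labels[::-1]
    right = np.where(reflected > 0, reflected + 10, 0).astype(np.int16)
    if np.any((labels > 0) & (right > 0)):
        raise ValueError("hemisphere slabs overlap the midline; enlarge axis 0")
    labels = labels + right

    counts = {name: int(np.count_nonzero(labels == i + 1)) for i, name in enumerate(REGION_ORDER)}
    worst = min(counts, key=counts.get)
    if counts[worst] < MIN_REGION_VOXELS:
        raise ValueError(
            f"grid {shape} too small: region {worst!r} has {counts[worst]} voxels "
            f"(< {MIN_REGION_VOXELS})"
        )

    rows = []
    for side in SIDES:
        for idx, name in enumerate(REGION_ORDER):
            rows.append({"code": idx + 1 + (10 if side == "right" else 0),
                         "region": name, "side": side})
    table = pd.DataFrame(rows)
    return AspectsAtlas(labels=labels, regions=table, spacing=tuple(float(s) for s in spacing))


# ---------------------------------------------------------------------------
# Lesion geometry
# ---------------------------------------------------------------------------

def _grow_blob(
    allowed: np.ndarray, start: tuple[int, int, int], n_target: int
) -> np.ndarray:
    """Grow a 6-connected blob of exactly ``n_target`` voxels inside ``allowed``.

    Breadth-first growth from ``start`` with a fixed neighbour order, so
    the blob is deterministic given the start voxel.
    """
    if n_target <= 0:
        return np.zeros_like(allowed, dtype=bool)
    if not allowed[start]:
        raise ValueError("blob start voxel lies outside the allowed mask")
    capacity = int(np.count_nonzero(allowed))
    if n_target > capacity:
        raise ValueError(f"requested {n_target} voxels but mask holds only {capacity}")
    shape = allowed.shape
    mask = np.zeros(shape, dtype=bool)
    queue: deque[tuple[int, int, int]] = deque([start])
    seen = {start}
    taken = 0
    offsets = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    while queue and taken < n_target:
        x, y, z = queue.popleft()
        mask[x, y, z] = True
        taken += 1
        for dx, dy, dz in offsets:
            nxt = (x + dx, y + dy, z + dz)
            if (0 <= nxt[0] < shape[0] and 0 <= nxt[1] < shape[1]
                    and 0 <= nxt[2] < shape[2] and nxt not in seen and allowed[nxt]):
                seen.add(nxt)
                queue.append(nxt)
    if taken < n_target:  # pragma: no cover - capacity checked above per component
        raise ValueError("allowed mask is too fragmented to host the requested blob")
    return mask


def _lesion_from_involvement(
    atlas: AspectsAtlas, side: str, involvement: Mapping[str, float], rng: np.random.Generator
) -> np.ndarray:
    mask = np.zeros(atlas.shape, dtype=bool)
    for region, frac in involvement.items():
        if region not in REGION_ORDER:
            raise KeyError(f"unknown region {region!r}")
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"involvement fraction for {region} must be in [0, 1]")
        region_mask = atlas.region_mask(region, side)
        n_target = int(round(frac * np.count_nonzero(region_mask)))
        if n_target == 0:
            continue
        coords = np.argwhere(region_mask)
        start = tuple(coords[rng.integers(len(coords))])
        mask |= _grow_blob(region_mask, start, n_target)
    return mask


def _lesion_from_volume(
    atlas: AspectsAtlas, side: str, target_ml: float, rng: np.random.Generator
) -> np.ndarray:
    """Grow one contiguous blob across the hemisphere to hit a target volume."""
    if target_ml < 0:
        raise ValueError("target volume must be non-negative")
    n_target = int(round(target_ml * 1000.0 / atlas.voxel_volume_mm3))
    if n_target == 0:
        return np.zeros(atlas.shape, dtype=bool)
    hemi = atlas.side_mask(side)
    # Seed in the insula: the deep MCA territory where cores start clinically.
    coords = np.argwhere(atlas.region_mask("I", side))
    start = tuple(coords[rng.integers(len(coords))])
    return _grow_blob(hemi, start, n_target)


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    atlas: AspectsAtlas,
    seed: int,
    *,
    side: str = "left",
    severity: float = 5.0,
    involvement: Mapping[str, float] | None = None,
    target_volume_ml: float | None = None,
    noise_sd: float = 2.0,
    cta_gain: float = 1.5,
    csf_frac: float = 0.05,
    calc_frac: float = 0.005,
    base_hu: float = 36.0,
) -> tuple[CtVolume, CtVolume, PerfusionSurrogate, PhantomTruth]:
    """Simulate one subject: NCCT + CTA-source volumes, perfusion maps, truth.

    The lesion is either specified by per-region ``involvement`` fractions
    (one contiguous blob per region) or by a ``target_volume_ml`` (one
    blob grown across the hemisphere); exactly one of the two may be
    given, and neither means no lesion.  The lesion lowers HU by
    ``severity`` on NCCT and ``severity * cta_gain`` on the CTA-source
    rendition; both renditions share geometry and confounder positions.
    """
    if side not in SIDES:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if involvement is not None and target_volume_ml is not None:
        raise ValueError("give either involvement or target_volume_ml, not both")
    if severity < 0:
        raise ValueError("severity must be non-negative")
    min_base = base_hu + min(REGION_BASE_OFFSET.values())
    if min_base - severity * max(cta_gain, 1.0) < 0:
        raise ValueError(
            f"severity {severity} (CTA gain {cta_gain}) would push lesion HU below 0"
        )

    rng = np.random.default_rng(seed)
    if involvement is not None:
        lesion = _lesion_from_involvement(atlas, side, involvement, rng)
    elif target_volume_ml is not None:
        lesion = _lesion_from_volume(atlas, side, target_volume_ml, rng)
    else:
        lesion = np.zeros(atlas.shape, dtype=bool)

    brain = atlas.brain_mask
    base = np.full(atlas.shape, -1000.0)  # air outside the head
    for name in REGION_ORDER:
        value = base_hu + REGION_BASE_OFFSET[name]
        for s in SIDES:
            base[atlas.region_mask(name, s)] = value

    # Confounders: scattered CSF-like and calcification-like voxels, drawn
    # once over the whole brain so some land inside lesioned regions.
    brain_idx = np.flatnonzero(brain.ravel())
    n_csf = int(round(csf_frac * brain_idx.size))
    n_calc = int(round(calc_frac * brain_idx.size))
    picked = rng.choice(brain_idx, size=n_csf + n_calc, replace=False) if n_csf + n_calc else np.empty(0, int)
    csf_idx, calc_idx = picked[:n_csf], picked[n_csf:]

    volumes: dict[str, np.ndarray] = {}
    for modality, gain in (("ncct", 1.0), ("cta", cta_gain)):
        img = base.copy()
        img[lesion] -= severity * gain
        flat = img.ravel()
        flat[csf_idx] = CSF_HU
        flat[calc_idx] = CALCIFICATION_HU
        if noise_sd > 0:
            img[brain] += rng.normal(0.0, noise_sd, size=int(brain.sum()))
        volumes[modality] = img

    # Perfusion surrogates: normal everywhere, beyond-threshold inside lesion.
    rcbf = np.ones(atlas.shape)
    ttp = np.zeros(atlas.shape)
    n_lesion = int(lesion.sum())
    if n_lesion:
        rcbf[lesion] = rng.uniform(0.05, 0.24, size=n_lesion)
        ttp[lesion] = rng.uniform(5.5, 12.0, size=n_lesion)

    inv = {
        name: float(np.count_nonzero(lesion & atlas.region_mask(name, side))
                    / np.count_nonzero(atlas.region_mask(name, side)))
        for name in REGION_ORDER
    }
    truth = PhantomTruth(
        lesion_mask=lesion,
        affected_side=side,
        involvement=inv,
        severity=float(severity),
        volume_ml=float(n_lesion * atlas.voxel_volume_mm3 / 1000.0),
    )
    perf = PerfusionSurrogate(rcbf_ratio=rcbf, ttp_delay=ttp, brain_mask=brain,
                              spacing=atlas.spacing)
    ncct = CtVolume(volumes["ncct"], atlas.spacing, "ncct")
    cta = CtVolume(volumes["cta"], atlas.spacing, "cta")
    return ncct, cta, perf, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _draw_core_volume(rng: np.random.Generator, large: bool, cfg: CohortConfig) -> float:
    if large:
        return float(rng.uniform(*cfg.large_core_range_ml))
    lo, hi = cfg.small_core_range_ml
    v = float(np.exp(rng.normal(np.log(cfg.small_core_median_ml), cfg.small_core_sigma)))
    return float(np.clip(v, lo, hi))


def simulate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
) -> tuple[AspectsAtlas, list[SimulatedSubject], pd.DataFrame]:
    """Simulate a cohort of subjects and its manifest.

    Per-subject seeds are derived from the master seed, so a fixed config
    reproduces the cohort byte-for-byte.  When ``out_dir`` is given, all
    volumes are written as NIfTI (.nii.gz) and the manifest as
    ``manifest.csv`` with file paths filled in.
    """
    atlas = build_atlas(config.shape, config.spacing)
    master = np.random.default_rng(config.seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=config.n)

    subjects: list[SimulatedSubject] = []
    rows = []
    for i in range(config.n):
        sid = f"S{i + 1:03d}"
        side = "left" if master.uniform() < 0.5 else "right"
        early = master.uniform() < config.early_frac
        window = "<=4.5h" if early else ">4.5h"
        large = master.uniform() < config.large_core_frac
        target_ml = _draw_core_volume(master, large, config)
        sev_mean = config.severity_mean * (1.0 if early else config.late_severity_scale)
        severity = max(0.0, float(master.normal(sev_mean, config.severity_sd)))
        ncct, cta, perf, truth = simulate_subject(
            atlas, int(subject_seeds[i]), side=side, severity=severity,
            target_volume_ml=target_ml, noise_sd=config.noise_sd,
            cta_gain=config.cta_gain, csf_frac=config.csf_frac,
            calc_frac=config.calc_frac, base_hu=config.base_hu,
        )
        subjects.append(SimulatedSubject(sid, window, ncct, cta, perf, truth))
        rows.append({
            "subject_id": sid, "side": side, "window": window,
            "true_core_ml": truth.volume_ml,
            "ncct_path": "", "cta_path": "", "rcbf_path": "", "ttp_path": "",
        })
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(atlas.labels.astype(np.uint16), atlas.affine),
                 out / "atlas.nii.gz")
        atlas.regions.to_csv(out / "atlas_regions.csv", index=False)
        for subj, row in zip(subjects, rows):
            for key, arr in (
                ("ncct", subj.ncct.intensities), ("cta", subj.cta.intensities),
                ("rcbf", subj.perfusion.rcbf_ratio), ("ttp", subj.perfusion.ttp_delay),
            ):
                path = out / f"{subj.subject_id}_{key}.nii.gz"
                nib.save(nib.Nifti1Image(arr.astype(np.float32), atlas.affine), path)
                row[f"{key}_path"] = str(path)
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out / "manifest.csv", index=False)
        logger.info("wrote %d subjects to %s", config.n, out)
    return atlas, subjects, manifest
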