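"""Regional attenuation statistics: filtered means and the rHU vector.

For each ASPECTS region the mean attenuation of band-retained voxels
(21-50 HU inclusive) is computed on the ischemic side and on its
contralateral homologue; their ratio is the relative HU

    rHU_r = mean HU (ischemic side) / mean HU (contralateral side).

The band filter removes cerebrospinal fluid and chronic infarcts (below
21 HU) and calcification (above 50 HU) so the ratio reflects parenchymal
water uptake.  The ischemic side is supplied by the caller — in the
clinical workflow it is known from CTA — and never inferred here.  Means
are taken over full 3-D region volumes, and the contralateral homologue
is located by atlas label pairing, not by reflecting the image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import REGION_ORDER, SIDES, AspectsAtlas, CtVolume

logger = logging.getLogger(__name__)

HU_BAND_LOW = 21.0
HU_BAND_HIGH = 50.0


@dataclass(frozen=True)
class RegionMeasurement:
    region: str
    mean_ipsi: float
    mean_contra: float
    rhu: float
    n_ipsi: int
    n_contra: int
    degenerate: bool


@dataclass(frozen=True)
class RegionMeasurements:
    """Per-region filtered means and rHU ratios for one subject/modality."""

    ischemic_side: str
    modality: str
    measurements: dict[str, RegionMeasurement]

    def __post_init__(self) -> None:
        missing = set(REGION_ORDER) - set(self.measurements)
        if missing:
            raise ValueError(f"measurements missing regions: {sorted(missing)}")


def attenuation_filter(volume: CtVolume | np.ndarray) -> np.ndarray:
    """Boolean mask of voxels retained by the 21-50 HU analysis band.

    Voxels strictly below 21 HU or strictly above 50 HU are discarded;
    the band boundaries themselves are retained.
    """
    hu = volume.intensities if isinstance(volume, CtVolume) else np.asarray(volume)
    return (hu >= HU_BAND_LOW) & (hu <= HU_BAND_HIGH)


def region_means(
    ct: CtVolume,
    atlas: AspectsAtlas,
    ischemic_side: str,
    *,
    apply_filter: bool = True,
) -> RegionMeasurements:
    """Filtered mean HU per region on each side, and their rHU ratios.

    A region with zero retained voxels on either side is flagged
    degenerate and assigned rHU = 1.0 (treated as uninformative rather
    than aborting the subject).  ``apply_filter=False`` bypasses the HU
    band, which is only meaningful for scale-invariance checks.
    """
    if ischemic_side not in SIDES:
        raise ValueError(f"ischemic_side must be 'left' or 'right', got {ischemic_side!r}")
    if ct.intensities.shape != atlas.shape:
        raise ValueError(
            f"CT grid {ct.intensities.shape} does not match atlas grid {atlas.shape}"
        )
    contra = "right" if ischemic_side == "left" else "left"
    retained = attenuation_filter(ct) if apply_filter else np.ones(atlas.shape, dtype=bool)
    hu = ct.intensities

    out: dict[str, RegionMeasurement] = {}
    for name in REGION_ORDER:
        ipsi_mask = atlas.region_mask(name, ischemic_side) & retained
        contra_mask = atlas.region_mask(name, contra) & retained
        n_i, n_c = int(ipsi_mask.sum()), int(contra_mask.sum())
        if n_i == 0 or n_c == 0:
            logger.warning(
                "region %s degenerate (retained voxels ipsi=%d contra=%d); rHU set to 1.0",
                name, n_i, n_c,
            )
            out[name] = RegionMeasurement(name, float("nan"), float("nan"), 1.0, n_i, n_c, True)
            continue
        m_i = float(hu[ipsi_mask].mean())
        m_c = float(hu[contra_mask].mean())
        out[name] = RegionMeasurement(name, m_i, m_c, m_i / m_c, n_i, n_c, False)
    return RegionMeasurements(ischemic_side=ischemic_side, modality=ct.modality,
                              measurements=out)


def rhu_vector(measurements: RegionMeasurements) -> np.ndarray:
    """The rHU values as a length-10 vector in canonical region order."""
    return np.array([measurements.measurements[name].rhu for name in REGION_ORDER])
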