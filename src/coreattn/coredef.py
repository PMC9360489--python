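"""Ischemic-core definition from perfusion surrogate maps.

The core is the set of voxels with relative cerebral blood flow strictly
below 25% of the contralateral value AND a time-to-peak delay strictly
greater than 5 s, restricted to a cleanup mask (brain parenchyma minus
the subtentorial compartment).  A core volume of 70 ml or more defines a
"large core", the infarction-extent criterion used for reperfusion
triage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import PerfusionSurrogate

logger = logging.getLogger(__name__)

RCBF_RATIO_THRESHOLD = 0.25
TTP_DELAY_THRESHOLD_S = 5.0
LARGE_CORE_ML = 70.0


@dataclass(frozen=True)
class CoreResult:
    core_mask: np.ndarray
    volume_ml: float
    n_voxels: int


def cleanup_mask(brain_mask: np.ndarray, subtentorial_mask: np.ndarray) -> np.ndarray:
    """Restrict the analysis to supratentorial parenchyma.

    Removes the subtentorial compartment from the brain mask; applying the
    operation twice is a no-op.  An empty result is allowed but logged.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    subtentorial_mask = np.asarray(subtentorial_mask, dtype=bool)
    if brain_mask.shape != subtentorial_mask.shape:
        raise ValueError(
            f"mask grids differ: {brain_mask.shape} vs {subtentorial_mask.shape}"
        )
    out = brain_mask & ~subtentorial_mask
    if not out.any():
        logger.warning("cleanup mask is empty (subtentorial mask covers the brain)")
    return out


def segment_core(perfusion: PerfusionSurrogate, cleanup: np.ndarray) -> CoreResult:
    """Threshold the perfusion surrogates into the ischemic core.

    A voxel belongs to the core iff ``rcbf_ratio < 0.25`` and
    ``ttp_delay > 5 s`` and it lies inside ``cleanup``; both inequalities
    are strict, so voxels exactly at a threshold are excluded.
    """
    cleanup = np.asarray(cleanup, dtype=bool)
    if perfusion.rcbf_ratio.shape != perfusion.ttp_delay.shape:
        raise ValueError("rCBF and TTP maps are on different grids")
    if cleanup.shape != perfusion.rcbf_ratio.shape:
        raise ValueError(
            f"cleanup mask grid {cleanup.shape} does not match perfusion grid "
            f"{perfusion.rcbf_ratio.shape}"
        )
    mask = (
        (perfusion.rcbf_ratio < RCBF_RATIO_THRESHOLD)
        & (perfusion.ttp_delay > TTP_DELAY_THRESHOLD_S)
        & cleanup
    )
    n = int(mask.sum())
    volume_ml = float(n * np.prod(perfusion.spacing) / 1000.0)
    return CoreResult(core_mask=mask, volume_ml=volume_ml, n_voxels=n)


def label_large_core(volume_ml: float, threshold_ml: float = LARGE_CORE_ML) -> bool:
    """True iff the core volume is equal to or greater than the threshold."""
    if not np.isfinite(volume_ml):
        raise ValueError("core volume must be finite")
    if volume_ml < 0:
        raise ValueError(f"core volume must be non-negative, got {volume_ml}")
    return bool(volume_ml >= threshold_ml)
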