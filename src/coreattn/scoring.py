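"""wHU-ASPECTS scoring and the automated-ASPECTS comparator.

The weighted attenuation score is

    wHU-ASPECTS = sum over the 10 regions of beta_r * rHU_r,

where the weights beta_r are the slope coefficients of an ordinary
least-squares regression of ischemic core volume (ml) on the 10 regional
rHU values.  The regression weights each region in proportion to how
strongly its attenuation asymmetry tracks core volume, compensating for
the unequal territory sizes that the 10-point ASPECTS scale ignores.
Weights are fitted per modality (NCCT and CTA-source separately) and the
fitted intercept is stored as metadata but excluded from the score: it is
an additive constant and cannot change the ranking of subjects.

The automated-ASPECTS comparator mimics threshold-based commercial
scoring: each region pair is classified normal/abnormal from its
directional mean-HU ratio, the involved hemisphere is *detected* from
the abnormal counts (never taken from the caller), and the score is
10 minus the abnormal count on the detected side.  Because the side is
inferred, the comparator can mistake the ischemic side — the failure
mode that motivates comparing it against the side-informed wHU score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .phantom import REGION_ORDER, AspectsAtlas, CtVolume
from .regionstats import attenuation_filter

logger = logging.getLogger(__name__)

DEFAULT_ABNORMALITY_TAU = 0.95


@dataclass(frozen=True)
class WeightVector:
    """Per-region regression weights for one modality."""

    beta: np.ndarray          # slopes, canonical region order
    modality: str
    n: int
    intercept: float
    resid_sd: float
    stderr: np.ndarray        # slope standard errors

    def __post_init__(self) -> None:
        if len(self.beta) != len(REGION_ORDER):
            raise ValueError(f"expected {len(REGION_ORDER)} weights, got {len(self.beta)}")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("weights must be finite")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "modality": self.modality,
            "weights": {r: float(b) for r, b in zip(REGION_ORDER, self.beta)},
            "fit": {"n": self.n, "intercept": self.intercept, "resid_sd": self.resid_sd,
                    "stderr": {r: float(s) for r, s in zip(REGION_ORDER, self.stderr)}},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightVector":
        payload = json.loads(Path(path).read_text())
        return cls(
            beta=np.array([payload["weights"][r] for r in REGION_ORDER]),
            modality=payload["modality"],
            n=payload["fit"]["n"],
            intercept=payload["fit"]["intercept"],
            resid_sd=payload["fit"]["resid_sd"],
            stderr=np.array([payload["fit"]["stderr"][r] for r in REGION_ORDER]),
        )


@dataclass(frozen=True)
class WhuScore:
    value: float
    modality: str


@dataclass(frozen=True)
class AutoAspectsResult:
    score: int
    detected_side: str
    abnormal: dict[str, dict[str, bool]]  # side -> region -> abnormal flag


def fit_weights(rhu_matrix: np.ndarray, core_volumes_ml: np.ndarray, modality: str) -> WeightVector:
    """Fit the per-region weighting factors by multivariable OLS.

    Regresses core volume (ml) on the 10 rHU covariates plus an
    intercept.  Requires more subjects than parameters and a full-rank
    design; collinear or constant regions are named in the error.
    """
    X = np.asarray(rhu_matrix, dtype=float)
    y = np.asarray(core_volumes_ml, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(REGION_ORDER):
        raise ValueError(f"rHU matrix must be n x {len(REGION_ORDER)}, got {X.shape}")
    if y.shape != (X.shape[0],):
        raise ValueError("core volume vector length does not match rHU matrix")
    n = X.shape[0]
    if n <= len(REGION_ORDER) + 1:
        raise ValueError(f"need more than {len(REGION_ORDER) + 1} subjects to fit, got {n}")
    constant = [REGION_ORDER[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
    if constant:
        raise ValueError(f"constant rHU columns (cannot be weighted): {constant}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        _, r = np.linalg.qr(design)
        bad = [REGION_ORDER[j - 1] for j in range(1, design.shape[1])
               if abs(r[j, j]) < 1e-10 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient design; collinear regions: {bad or 'intercept-related'}")
    fit = sm.OLS(y, design).fit()
    return WeightVector(
        beta=np.asarray(fit.params[1:]),
        modality=modality,
        n=n,
        intercept=float(fit.params[0]),
        resid_sd=float(np.sqrt(fit.scale)),
        stderr=np.asarray(fit.bse[1:]),
    )


def whu_aspects(rhu: np.ndarray, weights: WeightVector) -> WhuScore:
    """The weighted attenuation score: dot product of weights and rHU."""
    rhu = np.asarray(rhu, dtype=float)
    if rhu.shape != weights.beta.shape:
        raise ValueError(f"rHU vector length {rhu.shape} != weights {weights.beta.shape}")
    return WhuScore(value=float(np.dot(weights.beta, rhu)), modality=weights.modality)


def auto_aspects(
    ct: CtVolume,
    atlas: AspectsAtlas,
    tau: float = DEFAULT_ABNORMALITY_TAU,
) -> AutoAspectsResult:
    """Threshold-based automated ASPECTS with side detection.

    For every region pair the directional mean-HU ratios (left/right and
    right/left, band-filtered) are computed; a region on side ``s`` is
    abnormal when its ratio against the homologue falls below ``tau``.
    The detected side is the one with more abnormal regions (ties broken
    toward the side with the lower summed ratio, i.e. the globally more
    hypodense hemisphere), and the score is 10 minus the abnormal count
    on that side.  Degenerate region pairs (no retained voxels) count as
    normal with ratio 1.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"abnormality threshold tau must lie in (0, 1), got {tau}")
    if ct.intensities.shape != atlas.shape:
        raise ValueError("CT and atlas grids differ")
    retained = attenuation_filter(ct)
    hu = ct.intensities

    ratios: dict[str, dict[str, float]] = {"left": {}, "right": {}}
    for name in REGION_ORDER:
        means = {}
        for side in ("left", "right"):
            m = atlas.region_mask(name, side) & retained
            means[side] = float(hu[m].mean()) if m.any() else float("nan")
        if not np.isfinite(means["left"]) or not np.isfinite(means["right"]):
            logger.warning("auto-ASPECTS: region %s degenerate; treated as normal", name)
            ratios["left"][name] = ratios["right"][name] = 1.0
        else:
            ratios["left"][name] = means["left"] / means["right"]
            ratios["right"][name] = means["right"] / means["left"]

    abnormal = {s: {r: ratios[s][r] < tau for r in REGION_ORDER} for s in ("left", "right")}
    counts = {s: sum(abnormal[s].values()) for s in ("left", "right")}
    if counts["left"] != counts["right"]:
        detected = max(counts, key=counts.get)
    else:
        sums = {s: sum(ratios[s].values()) for s in ("left", "right")}
        detected = min(sums, key=lambda s: (sums[s], s))
    return AutoAspectsResult(
        score=10 - counts[detected],
        detected_side=detected,
        abnormal=abnormal,
    )


def classify_large_core(score: float, cutoff: float, direction: str) -> bool:
    """Apply a directional cutoff to a marker value.

    ``direction`` is ``">"`` for markers that increase with core size at
    the chosen cutoff (the wHU scores) and ``"<="`` for markers that
    decrease (ASPECTS); mirrors how ROC cutoffs are printed.
    """
    if not (np.isfinite(score) and np.isfinite(cutoff)):
        raise ValueError("score and cutoff must be finite")
    if direction == ">":
        return bool(score > cutoff)
    if direction == "<=":
        return bool(score <= cutoff)
    raise ValueError(f"direction must be '>' or '<=', got {direction!r}")
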