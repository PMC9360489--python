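"""Diagnostic statistics: Spearman bands, empirical ROC, Youden cutoffs,
paired DeLong tests, and bootstrap confidence intervals.

Conventions
-----------
* Labels are boolean with ``True`` = positive (large core).
* All ROC machinery assumes higher score = more positive; markers that
  run the other way (ASPECTS) are negated by the caller before entry.
* The empirical AUC is the Mann-Whitney statistic: concordant pairs plus
  half the tied pairs over all positive-negative pairs.
* Cutoffs define a positive call as ``score > cutoff``.
* The paired DeLong test uses placement values (structural components);
  it is the standard nonparametric comparison of correlated AUCs.
* Bootstrap intervals are unstratified case resamples with percentile
  endpoints; resamples that lose a class are redrawn (and counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Verbal interpretation bands for |rho|, half-open below, closed at 1.
RHO_BANDS: tuple[tuple[float, str], ...] = (
    (0.2, "slight"), (0.4, "fair"), (0.6, "moderate"), (0.8, "substantial"), (1.0, "almost perfect"),
)

DEFAULT_BOOTSTRAP_SAMPLES = 500
DEFAULT_BOOTSTRAP_SEED = 20220726


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    band: str
    n: int


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    j: float


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    auc_diff: float
    z: float
    p: float


# ---------------------------------------------------------------------------
# Spearman correlation with verbal bands
# ---------------------------------------------------------------------------

def band_label(rho: float) -> str:
    """Verbal band for a correlation: slight/fair/moderate/substantial/almost perfect."""
    a = abs(rho)
    if not a <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    for upper, name in RHO_BANDS:
        if a < upper:
            return name
    return RHO_BANDS[-1][1]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for small n (enumeration over pairings)."""
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    count = 0
    total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x: np.ndarray, y: np.ndarray, *, method: str = "t") -> SpearmanResult:
    """Spearman rank correlation with a t-approximation p-value.

    Ties receive mid-ranks.  ``method="exact"`` enumerates all pairings
    (only feasible for n <= 8); the default t-approximation matches the
    sample sizes this analysis targets (n in the dozens).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        p = _exact_spearman_p(x, y, rho)
    elif method == "t":
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpearmanResult(rho=rho, p=p, band=band_label(rho), n=n)


# ---------------------------------------------------------------------------
# Empirical ROC / AUC
# ---------------------------------------------------------------------------

def _check_scores_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D vectors of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical AUC (Mann-Whitney): higher score = more positive."""
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> YoudenResult:
    """Cutoff maximizing the Youden index J = Se + Sp - 1.

    Every distinct score value (plus -inf) is evaluated as a threshold
    with positivity ``score > cutoff``.  Ties in J are broken toward
    higher sensitivity, then toward the lower cutoff.  Sensitivity and
    specificity are returned in percent, unrounded.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    thresholds = np.concatenate(([-np.inf], np.unique(scores)))
    # score > c : count via searchsorted on sorted class scores
    se = 1.0 - np.searchsorted(pos, thresholds, side="right") / pos.size
    sp = np.searchsorted(neg, thresholds, side="right") / neg.size
    j = se + sp - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best_se = se[candidates].max()
    candidates = candidates[se[candidates] >= best_se - 1e-12]
    pick = candidates[np.argmin(thresholds[candidates])]
    return YoudenResult(
        cutoff=float(thresholds[pick]),
        sensitivity=float(se[pick] * 100.0),
        specificity=float(sp[pick] * 100.0),
        j=float(j[pick]),
    )


def youden_index(sensitivity_pct: float, specificity_pct: float) -> float:
    """J = Se + Sp - 1 from percentages."""
    return sensitivity_pct / 100.0 + specificity_pct / 100.0 - 1.0


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and placement values (V10 per positive, V01 per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    cmp_matrix = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    return float(cmp_matrix.mean()), v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Empirical AUC and its DeLong variance estimate."""
    scores, labels = _check_scores_labels(scores, labels)
    auc, v10, v01 = _placements(scores, labels)
    var = float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)
    return auc, var


def delong_auc_ci(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation CI for a single AUC from the DeLong variance."""
    auc, var = delong_variance(scores, labels)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray) -> DelongResult:
    """Paired DeLong test for two markers measured on the same subjects.

    Comparing a marker with itself (or any strictly monotone transform of
    itself) gives z = 0, p = 1.  Zero variance with a nonzero AUC
    difference is an error (degenerate design).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired markers must have equal length")
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, _ = _check_scores_labels(scores_b, labels)
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    n_pos, n_neg = v10_a.size, v01_a.size
    var_a = np.var(v10_a, ddof=1) / n_pos + np.var(v01_a, ddof=1) / n_neg
    var_b = np.var(v10_b, ddof=1) / n_pos + np.var(v01_b, ddof=1) / n_neg
    cov = (np.cov(v10_a, v10_b, ddof=1)[0, 1] / n_pos
           + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n_neg)
    diff = auc_a - auc_b
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 1e-15:
        if abs(diff) < 1e-12:
            return DelongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = diff / float(np.sqrt(var_diff))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, float(diff), float(z), p)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = DEFAULT_BOOTSTRAP_SAMPLES,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC over case resamples.

    Unstratified resampling with replacement; resamples containing a
    single class are redrawn and counted in the log.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap samples")
    rng = np.random.default_rng(seed)
    n = scores.size
    aucs = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
            redraws += 1
            if redraws > 1000 * n_boot:
                raise RuntimeError("bootstrap cannot find two-class resamples")
        aucs[b] = roc_auc(scores[idx], lab)
    if redraws:
        logger.info("bootstrap redrew %d degenerate single-class resamples", redraws)
    lower, upper = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lower), float(upper)
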