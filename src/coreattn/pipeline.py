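"""End-to-end analysis: simulate -> segment -> measure -> fit -> score -> evaluate.

``run_analysis`` reproduces the skeleton of the clinical analysis on a
synthetic cohort: Spearman correlations of the wHU scores with core
volume (overall and per onset-time window), ROC comparisons of the wHU
scores against the automated-ASPECTS comparator on the side-correct
subsets, the NCCT-vs-CTA comparison of the wHU scores on the full
cohort, bootstrap confidence intervals, and the side-mistake
bookkeeping.

Subset semantics: an automated-ASPECTS value whose detected side is
wrong is invalid, so marker-vs-ASPECTS comparisons run on the subjects
with a correct side detection for that modality (paired DeLong design),
while the NCCT-vs-CTA comparison of the side-informed wHU scores uses
the whole cohort.  All statistics are computed unrounded; rounding is
applied only when rendering tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import coredef, regionstats, scoring, statlab
from .phantom import (
    REGION_ORDER,
    AspectsAtlas,
    CohortConfig,
    CtVolume,
    PerfusionSurrogate,
    PhantomTruth,
    SimulatedSubject,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

WINDOWS = ("<=4.5h", ">4.5h")
_MODALITIES = ("ncct", "cta")


@dataclass
class SubjectRecord:
    """One analyzed subject: scores, labels, and side bookkeeping."""

    subject_id: str
    window: str
    true_side: str
    core_ml: float
    large_core: bool
    rhu: dict[str, np.ndarray]          # modality -> 10-vector
    whu: dict[str, float]               # modality -> score (filled after fit)
    aspects: dict[str, int]             # modality -> automated ASPECTS
    detected_side: dict[str, str]       # modality -> detected side
    side_mistake: dict[str, bool]       # modality -> detected != true


# ---------------------------------------------------------------------------
# Cohort measurement
# ---------------------------------------------------------------------------

def proportion_pct(count: int, total: int) -> float:
    """A proportion as a percentage rounded to 1 decimal for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def measure_cohort(
    atlas: AspectsAtlas,
    subjects: list[SimulatedSubject],
    tau: float = scoring.DEFAULT_ABNORMALITY_TAU,
) -> list[SubjectRecord]:
    """Segment cores, measure rHU vectors, and run the ASPECTS comparator."""
    records = []
    cleanup = coredef.cleanup_mask(atlas.brain_mask, np.zeros(atlas.shape, dtype=bool))
    for subj in subjects:
        core = coredef.segment_core(subj.perfusion, cleanup)
        rhu = {}
        aspects = {}
        detected = {}
        for modality, ct in (("ncct", subj.ncct), ("cta", subj.cta)):
            meas = regionstats.region_means(ct, atlas, subj.truth.affected_side)
            rhu[modality] = regionstats.rhu_vector(meas)
            auto = scoring.auto_aspects(ct, atlas, tau=tau)
            aspects[modality] = auto.score
            detected[modality] = auto.detected_side
        records.append(SubjectRecord(
            subject_id=subj.subject_id,
            window=subj.window,
            true_side=subj.truth.affected_side,
            core_ml=core.volume_ml,
            large_core=coredef.label_large_core(core.volume_ml),
            rhu=rhu,
            whu={},
            aspects=aspects,
            detected_side=detected,
            side_mistake={m: detected[m] != subj.truth.affected_side for m in _MODALITIES},
        ))
    return records


def exclude_side_mistakes(
    records: list[SubjectRecord], modality: str
) -> tuple[list[SubjectRecord], int]:
    """Drop records whose ASPECTS side detection was wrong for ``modality``."""
    if modality not in _MODALITIES:
        raise ValueError(f"modality must be one of {_MODALITIES}")
    kept = [r for r in records if not r.side_mistake[modality]]
    return kept, len(records) - len(kept)


def _fit_and_score(
    records: list[SubjectRecord], cross_fit: int = 0
) -> dict[str, scoring.WeightVector]:
    """Fit weights per modality and fill each record's wHU scores.

    With ``cross_fit=k`` (k >= 2) the reported per-subject scores are
    k-fold out-of-sample (weights refitted without the scored fold); the
    returned weights are always the full-cohort fit.
    """
    volumes = np.array([r.core_ml for r in records])
    weights = {}
    for modality in _MODALITIES:
        X = np.vstack([r.rhu[modality] for r in records])
        weights[modality] = scoring.fit_weights(X, volumes, modality)
        if cross_fit and cross_fit >= 2:
            folds = np.arange(len(records)) % cross_fit
            for k in range(cross_fit):
                train = folds != k
                w_k = scoring.fit_weights(X[train], volumes[train], modality)
                for i in np.flatnonzero(~train):
                    records[i].whu[modality] = scoring.whu_aspects(X[i], w_k).value
        else:
            for i, r in enumerate(records):
                r.whu[modality] = scoring.whu_aspects(X[i], weights[modality]).value
    return weights


# ---------------------------------------------------------------------------
# Statistics blocks
# ---------------------------------------------------------------------------

def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 2654435761 + salt) % (2**31 - 1))


def _roc_block(
    scores: np.ndarray,
    labels: np.ndarray,
    *,
    marker_kind: str,
    n_boot: int,
    boot_seed: int,
) -> dict:
    """AUC with DeLong and bootstrap CIs plus the maximum-Youden operating point.

    ``marker_kind`` is ``"continuous_gt"`` for markers positive above the
    cutoff (wHU) or ``"score_le"`` for integer scores positive at or
    below it (ASPECTS, negated internally so one AUC convention serves
    both directions).
    """
    if marker_kind == "score_le":
        oriented = -scores
    elif marker_kind == "continuous_gt":
        oriented = scores
    else:
        raise ValueError(f"unknown marker kind {marker_kind!r}")
    auc = statlab.roc_auc(oriented, labels)
    ci_delong = statlab.delong_auc_ci(oriented, labels)
    yr = statlab.youden_cutoff(oriented, labels)
    if marker_kind == "score_le":
        cutoff = float(-yr.cutoff - 1) if np.isfinite(yr.cutoff) else float(max(scores))
        direction = "<="
    else:
        cutoff = yr.cutoff
        direction = ">"
    block = {
        "n": int(labels.size),
        "auc": auc,
        "ci_delong": list(ci_delong),
        "cutoff": cutoff,
        "direction": direction,
        "sensitivity_pct": yr.sensitivity,
        "specificity_pct": yr.specificity,
        "youden_j": yr.j,
    }
    if n_boot:
        block["ci_bootstrap"] = list(
            statlab.bootstrap_auc_ci(oriented, labels, n_boot=n_boot, seed=boot_seed)
        )
    return block


def _delong_block(res: statlab.DelongResult) -> dict:
    return {"auc_a": res.auc_a, "auc_b": res.auc_b, "auc_diff": res.auc_diff,
            "z": res.z, "p": res.p}


def _spearman_block(x: np.ndarray, y: np.ndarray) -> dict:
    res = statlab.spearman(x, y)
    return {"n": res.n, "rho": res.rho, "p": res.p, "band": res.band}


# ---------------------------------------------------------------------------
# The full analysis
# ---------------------------------------------------------------------------

def run_analysis(
    cohort: CohortConfig | str | Path,
    *,
    n_boot: int = statlab.DEFAULT_BOOTSTRAP_SAMPLES,
    by_window: bool = True,
    cross_fit: int = 0,
    tau: float = scoring.DEFAULT_ABNORMALITY_TAU,
) -> dict:
    """Run the complete analysis on a simulated (or saved) cohort.

    Returns a JSON-serializable report with cohort summary proportions,
    correlation tables, the marker-vs-ASPECTS ROC comparison per
    modality (on the side-correct subsets), the NCCT-vs-CTA comparison
    on the full cohort, and per-subject rows.  Strata that lack a class
    or enough subjects are skipped with an explicit reason, never
    silently.
    """
    if isinstance(cohort, CohortConfig):
        config = cohort
        atlas, subjects, _ = simulate_cohort(config)
        config_dict = config.to_dict()
        seed = config.seed
    else:
        atlas, subjects, manifest = load_cohort(cohort)
        config_dict = {"loaded_from": str(cohort), "n": len(subjects)}
        seed = 0

    records = measure_cohort(atlas, subjects, tau=tau)
    if len(records) < 2:
        raise ValueError("analysis needs at least 2 subjects")
    weights = _fit_and_score(records, cross_fit=cross_fit)

    labels_all = np.array([r.large_core for r in records])
    volumes = np.array([r.core_ml for r in records])
    n = len(records)
    skips: list[str] = []

    report: dict = {
        "config": config_dict,
        "options": {"n_boot": n_boot, "by_window": by_window, "cross_fit": cross_fit,
                    "tau": tau},
        "cohort": {
            "n": n,
            "n_large_core": int(labels_all.sum()),
            "pct_large_core": proportion_pct(int(labels_all.sum()), n),
            "n_early_window": sum(r.window == WINDOWS[0] for r in records),
            "pct_early_window": proportion_pct(
                sum(r.window == WINDOWS[0] for r in records), n),
            "median_core_ml": float(np.median(volumes)),
            "iqr_core_ml": [float(np.percentile(volumes, 25)), float(np.percentile(volumes, 75))],
            "side_mistakes": {
                m: {
                    "n": sum(r.side_mistake[m] for r in records),
                    "pct": proportion_pct(sum(r.side_mistake[m] for r in records), n),
                }
                for m in _MODALITIES
            },
        },
        "weights": {
            m: {
                "regions": {r: float(b) for r, b in zip(REGION_ORDER, weights[m].beta)},
                "intercept": weights[m].intercept,
                "resid_sd": weights[m].resid_sd,
                "n": weights[m].n,
            }
            for m in _MODALITIES
        },
    }

    # --- correlations of wHU with core volume, overall and per window -----
    correlation: dict = {}
    for m in _MODALITIES:
        whu = np.array([r.whu[m] for r in records])
        strata: dict = {"overall": _spearman_block(whu, volumes)}
        if by_window:
            for w in WINDOWS:
                idx = np.array([r.window == w for r in records])
                try:
                    strata[w] = _spearman_block(whu[idx], volumes[idx])
                except ValueError as err:
                    strata[w] = {"skipped": str(err)}
                    skips.append(f"correlation {m} {w}: {err}")
        correlation[m] = strata
    report["correlation"] = correlation

    # --- wHU vs automated ASPECTS on side-correct subsets ----------------
    marker_vs_aspects: dict = {}
    for salt, m in enumerate(_MODALITIES):
        kept, n_excl = exclude_side_mistakes(records, m)
        labels = np.array([r.large_core for r in kept])
        entry: dict = {
            "n": len(kept),
            "n_side_mistakes": n_excl,
            "side_mistake_pct": proportion_pct(n_excl, n),
        }
        if labels.size < 2 or labels.all() or not labels.any():
            reason = f"side-correct {m} subset lacks both classes (n={labels.size})"
            entry["skipped"] = reason
            skips.append(reason)
        else:
            whu = np.array([r.whu[m] for r in kept])
            aspects = np.array([float(r.aspects[m]) for r in kept])
            entry["whu"] = _roc_block(whu, labels, marker_kind="continuous_gt",
                                      n_boot=n_boot, boot_seed=_derived_seed(seed, salt))
            entry["aspects"] = _roc_block(aspects, labels, marker_kind="score_le",
                                          n_boot=0, boot_seed=0)
            try:
                entry["delong_whu_vs_aspects"] = _delong_block(
                    statlab.delong_test(whu, -aspects, labels)
                )
            except ValueError as err:
                entry["delong_whu_vs_aspects"] = {"skipped": str(err)}
                skips.append(f"delong {m}: {err}")
        marker_vs_aspects[m] = entry
    report["marker_vs_aspects"] = marker_vs_aspects

    # --- wHU on NCCT vs CTA, full cohort ----------------------------------
    if labels_all.all() or not labels_all.any():
        reason = "cohort has a single large-core class; NCCT-vs-CTA ROC skipped"
        report["ncct_vs_cta"] = {"skipped": reason}
        skips.append(reason)
    else:
        whu_n = np.array([r.whu["ncct"] for r in records])
        whu_c = np.array([r.whu["cta"] for r in records])
        report["ncct_vs_cta"] = {
            "n": n,
            "whu_ncct": _roc_block(whu_n, labels_all, marker_kind="continuous_gt",
                                   n_boot=n_boot, boot_seed=_derived_seed(seed, 101)),
            "whu_cta": _roc_block(whu_c, labels_all, marker_kind="continuous_gt",
                                  n_boot=n_boot, boot_seed=_derived_seed(seed, 102)),
            "delong_ncct_vs_cta": _delong_block(
                statlab.delong_test(whu_n, whu_c, labels_all)
            ),
        }

    report["subjects"] = [
        {
            "subject_id": r.subject_id,
            "window": r.window,
            "true_side": r.true_side,
            "core_ml": r.core_ml,
            "large_core": bool(r.large_core),
            "whu_ncct": r.whu["ncct"],
            "whu_cta": r.whu["cta"],
            "aspects_ncct": r.aspects["ncct"],
            "aspects_cta": r.aspects["cta"],
            "detected_side_ncct": r.detected_side["ncct"],
            "detected_side_cta": r.detected_side["cta"],
            "side_mistake_ncct": bool(r.side_mistake["ncct"]),
            "side_mistake_cta": bool(r.side_mistake["cta"]),
            "rhu_ncct": [float(v) for v in r.rhu["ncct"]],
            "rhu_cta": [float(v) for v in r.rhu["cta"]],
        }
        for r in records
    ]
    report["warnings"] = skips
    for s in skips:
        logger.warning("%s", s)
    return report


# ---------------------------------------------------------------------------
# Saved-cohort loading
# ---------------------------------------------------------------------------

def load_cohort(cohort_dir: str | Path) -> tuple[AspectsAtlas, list[SimulatedSubject], pd.DataFrame]:
    """Load a cohort written by ``simulate_cohort(config, out_dir=...)``."""
    d = Path(cohort_dir)
    manifest = pd.read_csv(d / "manifest.csv").fillna("")
    labels_img = nib.load(d / "atlas.nii.gz")
    labels = np.asarray(labels_img.dataobj).astype(np.int16)
    spacing = tuple(float(s) for s in labels_img.header.get_zooms()[:3])
    regions = pd.read_csv(d / "atlas_regions.csv")
    atlas = AspectsAtlas(labels=labels, regions=regions, spacing=spacing)
    cleanup = atlas.brain_mask

    subjects = []
    for _, row in manifest.iterrows():
        vols = {k: np.asarray(nib.load(row[f"{k}_path"]).dataobj, dtype=float)
                for k in ("ncct", "cta", "rcbf", "ttp")}
        perf = PerfusionSurrogate(rcbf_ratio=vols["rcbf"], ttp_delay=vols["ttp"],
                                  brain_mask=cleanup, spacing=spacing)
        core = coredef.segment_core(perf, cleanup)
        truth = PhantomTruth(
            lesion_mask=core.core_mask, affected_side=row["side"],
            involvement={}, severity=float("nan"), volume_ml=core.volume_ml,
        )
        subjects.append(SimulatedSubject(
            subject_id=row["subject_id"], window=row["window"],
            ncct=CtVolume(vols["ncct"], spacing, "ncct"),
            cta=CtVolume(vols["cta"], spacing, "cta"),
            perfusion=perf, truth=truth,
        ))
    return atlas, subjects, manifest


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(~labels)
    tpr = np.concatenate(([0.0], tps / max(tps[-1], 1)))
    fpr = np.concatenate(([0.0], fps / max(fps[-1], 1)))
    return fpr, tpr


def render_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write the report as JSON, display-rounded CSV tables, and ROC plots.

    Rounding follows the reporting style of the tables the analysis
    mirrors: AUC to 3 decimals, sensitivity/specificity to 2, cohort
    percentages to 1; the JSON keeps full precision.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "roc").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2))

    corr_rows = []
    for m, strata in report.get("correlation", {}).items():
        for stratum, blk in strata.items():
            if "skipped" in blk:
                corr_rows.append({"modality": m, "stratum": stratum, "skipped": blk["skipped"]})
            else:
                corr_rows.append({"modality": m, "stratum": stratum, "n": blk["n"],
                                  "rho": round(blk["rho"], 3), "p": blk["p"],
                                  "band": blk["band"], "skipped": ""})
    paths["correlation"] = out / "tables" / "correlation.csv"
    pd.DataFrame(corr_rows).to_csv(paths["correlation"], index=False)

    roc_rows = []

    def _add_roc_row(analysis: str, marker: str, blk: dict) -> None:
        roc_rows.append({
            "analysis": analysis, "marker": marker, "n": blk["n"],
            "auc": round(blk["auc"], 3),
            "ci_delong": f"{blk['ci_delong'][0]:.3f}-{blk['ci_delong'][1]:.3f}",
            "ci_bootstrap": (f"{blk['ci_bootstrap'][0]:.3f}-{blk['ci_bootstrap'][1]:.3f}"
                             if "ci_bootstrap" in blk else ""),
            "cutoff": f"{blk['direction']}{blk['cutoff']:g}",
            "sensitivity_pct": round(blk["sensitivity_pct"], 2),
            "specificity_pct": round(blk["specificity_pct"], 2),
            "youden_j": round(blk["youden_j"], 3),
        })

    for m, entry in report.get("marker_vs_aspects", {}).items():
        if "whu" in entry:
            _add_roc_row(f"vs_aspects_{m}", f"whu_{m}", entry["whu"])
            _add_roc_row(f"vs_aspects_{m}", f"aspects_{m}", entry["aspects"])
    nc = report.get("ncct_vs_cta", {})
    for key in ("whu_ncct", "whu_cta"):
        if key in nc:
            _add_roc_row("ncct_vs_cta", key, nc[key])
    paths["roc_table"] = out / "tables" / "roc.csv"
    pd.DataFrame(roc_rows).to_csv(paths["roc_table"], index=False)

    subjects = pd.DataFrame(report.get("subjects", []))
    paths["subjects"] = out / "tables" / "subjects.csv"
    subjects.to_csv(paths["subjects"], index=False)

    if len(subjects):
        labels = subjects["large_core"].to_numpy(dtype=bool)
        if labels.any() and not labels.all():
            for m in _MODALITIES:
                ok = ~subjects[f"side_mistake_{m}"].to_numpy(dtype=bool)
                fig, ax = plt.subplots(figsize=(5, 5))
                for name, scores, subset in (
                    (f"wHU-{m.upper()}", subjects[f"whu_{m}"].to_numpy(), ok),
                    (f"ASPECTS-{m.upper()}", -subjects[f"aspects_{m}"].to_numpy(dtype=float), ok),
                ):
                    if labels[subset].any() and not labels[subset].all():
                        fpr, tpr = _roc_curve_points(scores[subset], labels[subset])
                        auc = statlab.roc_auc(scores[subset], labels[subset])
                        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
                ax.plot([0, 1], [0, 1], "k--", lw=0.8)
                ax.set_xlabel("1 - specificity")
                ax.set_ylabel("sensitivity")
                ax.set_title(f"Large core (>=70 ml): {m.upper()}, side-correct subset")
                ax.legend(loc="lower right")
                path = out / "roc" / f"marker_vs_aspects_{m}.png"
                fig.savefig(path, dpi=100, bbox_inches="tight")
                plt.close(fig)
                paths[f"roc_plot_{m}"] = path
    return paths
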