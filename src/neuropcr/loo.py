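"""Leave-one-out evaluation of the PCR decoder, with nested feature selection.

For each held-out subject the entire fitting chain — group Z maps, ROI
selection, PC extraction, weights regression, and the pseudoinverse model
map — is recomputed from the remaining subjects only. This nesting is the
central correctness property of the evaluation: nothing about the held-out
subject's scores (or scans) may influence the fold's fitted artifacts.

Diagnostic metrics follow the usual clinical definitions: sensitivity
100.TP/(TP+FN), specificity 100.TN/(TN+FP), agreement 100.(TP+TN)/n, plus the
Pearson correlation between predicted and measured scores. Percentages are
reported at one decimal place alongside the exact integer fractions, so a
rounded figure is never ambiguous. Agreement is also tested against chance
with an exact binomial test (p = 1/2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.stats

from .first_level import ContrastSet
from .group_roi import RoiConfig, RoiMask, assemble_features, group_zmaps, select_roi
from .pcr import (
    ClassifierConfig,
    ModelMap,
    PCBasis,
    PredictedScores,
    classify_attachment,
    classify_depression,
    extract_pcs,
    fit_model_map,
    predict_scores,
    subject_weights,
)
from .volumes_io import SubjectRecord

__all__ = [
    "FoldResult",
    "EvaluationReport",
    "run_loo",
    "confusion_metrics",
    "score_correlation",
    "evaluate",
    "report_to_json",
]

logger = logging.getLogger(__name__)

#: Measured AAI below this is insecure attachment (the scale's own banding).
AAI_INSECURE_MEASURED = 4.0


@dataclass
class FoldResult:
    """Outcome of one leave-one-out fold."""

    held_out_id: str
    roi_size: int
    predicted: PredictedScores
    depressed_pred: bool
    insecure_pred: bool
    mask: RoiMask = field(repr=False)
    basis: PCBasis = field(repr=False)
    model: ModelMap = field(repr=False)


@dataclass
class EvaluationReport:
    """Cohort-level diagnostic metrics plus the per-subject fold results."""

    depression: dict
    attachment: dict
    pearson_r_bdi: float
    pearson_r_aai: float
    per_subject: list[dict]


def run_loo(
    contrast_sets: dict[str, ContrastSet],
    records: list[SubjectRecord],
    roi_cfg: RoiConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    n_components: int = 2,
) -> list[FoldResult]:
    """Run the full leave-one-out loop over a cohort.

    Per fold: the n-1 sample subjects alone determine the Z maps, the ROI,
    the PC basis and the model map; the held-out subject is then projected
    and scored. Returns one :class:`FoldResult` per subject, in cohort order.
    """
    if len(records) < 5:
        raise ValueError(f"leave-one-out needs at least 5 subjects, got {len(records)}")
    roi_cfg = roi_cfg or RoiConfig()
    clf_cfg = clf_cfg or ClassifierConfig()
    results: list[FoldResult] = []
    for i, held in enumerate(records):
        sample = records[:i] + records[i + 1 :]
        try:
            zmaps = group_zmaps(contrast_sets, sample)
            mask = select_roi(zmaps, roi_cfg)
            F_sample = assemble_features(contrast_sets, mask, sample)
            F_test = assemble_features(contrast_sets, mask, [held])
            basis = extract_pcs(F_sample, k=n_components)
            W = np.vstack([subject_weights(F_sample[j], basis) for j in range(len(sample))])
            Y = np.array([[r.bdi, r.aai] for r in sample], dtype=np.float64)
            model = fit_model_map(W, Y)
            w_test = subject_weights(F_test[0], basis)
            pred = predict_scores(w_test, model)
        except ValueError as exc:
            raise ValueError(f"fold for held-out subject {held.subject_id}: {exc}") from exc
        if not (np.isfinite(pred.bdi_pred) and np.isfinite(pred.aai_pred)):
            raise ValueError(f"fold for held-out subject {held.subject_id}: non-finite prediction")
        results.append(
            FoldResult(
                held_out_id=held.subject_id,
                roi_size=len(mask),
                predicted=pred,
                depressed_pred=classify_depression(pred, clf_cfg),
                insecure_pred=classify_attachment(pred, clf_cfg),
                mask=mask,
                basis=basis,
                model=model,
            )
        )
        logger.info(
            "fold %s: ROI %d voxels, predicted BDI %.2f, AAI %.2f",
            held.subject_id,
            len(mask),
            pred.bdi_pred,
            pred.aai_pred,
        )
    return results


def confusion_metrics(
    predicted_labels: Sequence[bool], true_labels: Sequence[bool]
) -> dict:
    """Confusion counts and the standard percentage metrics.

    Returns tp/fp/tn/fn, sensitivity, specificity and agreement in percent
    (None where a denominator is zero, never a silent 0/0), the exact
    fractions behind each percentage, and the two-sided exact binomial
    p-value of the agreement against chance (p = 1/2).
    """
    pred = [bool(p) for p in predicted_labels]
    true = [bool(t) for t in true_labels]
    if len(pred) != len(true):
        raise ValueError(f"{len(pred)} predictions vs {len(true)} true labels")
    if not pred:
        raise ValueError("empty label lists")
    tp = sum(p and t for p, t in zip(pred, true))
    tn = sum((not p) and (not t) for p, t in zip(pred, true))
    fp = sum(p and (not t) for p, t in zip(pred, true))
    fn = sum((not p) and t for p, t in zip(pred, true))
    n = len(pred)

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "n": n,
        "sensitivity_pct": pct(tp, tp + fn),
        "specificity_pct": pct(tn, tn + fp),
        "agreement_pct": pct(tp + tn, n),
        "sensitivity_fraction": [tp, tp + fn],
        "specificity_fraction": [tn, tn + fp],
        "agreement_fraction": [tp + tn, n],
        "binomial_p_vs_chance": float(scipy.stats.binomtest(tp + tn, n, 0.5).pvalue),
    }


def score_correlation(predicted: Sequence[float], measured: Sequence[float]) -> float:
    """Pearson product-moment correlation between predicted and measured scores."""
    x = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(measured, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 scores")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate(folds: list[FoldResult], records: list[SubjectRecord]) -> EvaluationReport:
    """Assemble the cohort evaluation report from per-fold results.

    Depression ground truth is the subject's diagnostic group; attachment
    ground truth is measured AAI < 4 (insecure). The attachment block is
    annotated as secondary: the method's attachment prediction is reported
    but not claimed significant unless its binomial test says so.
    """
    by_id = {r.subject_id: r for r in records}
    if [f.held_out_id for f in folds] != [r.subject_id for r in records]:
        raise ValueError("fold order does not match cohort order")
    dep_true = [by_id[f.held_out_id].group == "depressed" for f in folds]
    dep_pred = [f.depressed_pred for f in folds]
    ins_true = [by_id[f.held_out_id].aai < AAI_INSECURE_MEASURED for f in folds]
    ins_pred = [f.insecure_pred for f in folds]
    bdi_pred = [f.predicted.bdi_pred for f in folds]
    bdi_true = [float(by_id[f.held_out_id].bdi) for f in folds]
    aai_pred = [f.predicted.aai_pred for f in folds]
    aai_true = [float(by_id[f.held_out_id].aai) for f in folds]
    per_subject = [
        {
            "subject_id": f.held_out_id,
            "roi_size": f.roi_size,
            "bdi_measured": by_id[f.held_out_id].bdi,
            "bdi_predicted": f.predicted.bdi_pred,
            "aai_measured": by_id[f.held_out_id].aai,
            "aai_predicted": f.predicted.aai_pred,
            "depressed_measured": by_id[f.held_out_id].group == "depressed",
            "depressed_predicted": f.depressed_pred,
            "insecure_measured": by_id[f.held_out_id].aai < AAI_INSECURE_MEASURED,
            "insecure_predicted": f.insecure_pred,
        }
        for f in folds
    ]
    return EvaluationReport(
        depression=confusion_metrics(dep_pred, dep_true),
        attachment=confusion_metrics(ins_pred, ins_true),
        pearson_r_bdi=score_correlation(bdi_pred, bdi_true),
        pearson_r_aai=score_correlation(aai_pred, aai_true),
        per_subject=per_subject,
    )


def report_to_json(report: EvaluationReport, path: str | Path | None = None) -> str:
    """Deterministic JSON serialization of a report (optionally written to disk)."""
    payload = {
        "depression": report.depression,
        "attachment": report.attachment,
        "pearson_r_bdi": report.pearson_r_bdi,
        "pearson_r_aai": report.pearson_r_aai,
        "per_subject": report.per_subject,
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(text)
    return text
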