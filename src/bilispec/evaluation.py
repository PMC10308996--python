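"""Diagnostic-test statistics and reproduction of the published test set.

``sensitivity = TP/(TP+FN) * 100`` and ``specificity = TN/(FP+TN) * 100``;
percentages are reported to one decimal (half-up), overall accuracy to the
nearest integer, matching clinical reporting conventions.

"Correct prediction" for a test-set row is operationalized as: the alpha
routing (under the chosen comparison mode) agrees with the laboratory value's
side of 10 mg/dl AND the predicted concentration falls in the laboratory
value's clinical band (<10, 10-15, >15 mg/dl).  The reproduction report
states this rule in its header because it is a package convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from . import model as hm
from .published import TestSampleRow, load_reference_testset

__all__ = [
    "ConfusionStats",
    "RowResult",
    "ReproductionReport",
    "confusion_stats",
    "alpha_validity_count",
    "beta_validity_count",
    "reproduce_reference_testset",
    "audit_medium_model_offset",
]


def _round_half_up(x: float, ndigits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionStats:
    """Confusion counts with percentage sensitivity/specificity (1 dp)."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity_pct: float | None
    specificity_pct: float | None


def confusion_stats(predicted_positive, actual_positive) -> ConfusionStats:
    """Tally a binary test against truth and compute sensitivity/specificity."""
    pred = [bool(p) for p in predicted_positive]
    act = [bool(a) for a in actual_positive]
    if len(pred) != len(act) or not pred:
        raise ValueError("predicted and actual must be non-empty and equal length")
    tp = sum(p and a for p, a in zip(pred, act))
    fn = sum((not p) and a for p, a in zip(pred, act))
    tn = sum((not p) and (not a) for p, a in zip(pred, act))
    fp = sum(p and (not a) for p, a in zip(pred, act))
    sens = _round_half_up(100.0 * tp / (tp + fn), 1) if (tp + fn) else None
    spec = _round_half_up(100.0 * tn / (fp + tn), 1) if (fp + tn) else None
    return ConfusionStats(tp, fn, tn, fp, sens, spec)


def alpha_validity_count(rows: list[TestSampleRow], params: hm.ModelParams) -> int:
    """Rows whose alpha routing matches the laboratory side of 10 mg/dl."""
    n = 0
    for row in rows:
        branch = hm.classify_stage1(row.alpha, params)
        truth = hm.GE10 if row.lab_conc_mgdl >= 10 else hm.LOW
        n += branch == truth
    return n


def beta_validity_count(rows: list[TestSampleRow], params: hm.ModelParams) -> int:
    """Rows (with beta) whose beta routing matches the 15 mg/dl boundary."""
    n = 0
    for row in rows:
        if row.beta is None:
            continue
        branch = hm.classify_stage2(row.beta, params)
        truth = hm.HIGH if row.lab_conc_mgdl > 15 else hm.MEDIUM
        n += branch == truth
    return n


@dataclass(frozen=True)
class RowResult:
    serial: int
    lab_conc_mgdl: float
    routing_branch: str
    routing_correct: bool
    prediction_mgdl: float | None
    prediction_in_lab_band: bool | None
    counts_correct: bool | None


@dataclass(frozen=True)
class ReproductionReport:
    """Per-row outcomes and the three headline counts on the shipped test set."""

    rule: str
    rows: tuple[RowResult, ...]
    alpha_valid_count: int
    beta_valid_count: int
    correct_prediction_count: int
    accuracy_pct: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([r.__dict__ for r in self.rows])


def _predict_row(row: TestSampleRow, params: hm.ModelParams,
                 use_printed_predictions: bool) -> float | None:
    if use_printed_predictions:
        return row.predicted_mgdl
    if row.i492 is not None and params.low_model is not None:
        return hm.predict_quadratic(row.i492, params.low_model)
    if row.i468 is not None and params.medium_model is not None:
        return hm.predict_quadratic(row.i468, params.medium_model)
    return None


def reproduce_reference_testset(
    params: hm.ModelParams | None = None,
    use_printed_predictions: bool = True,
) -> ReproductionReport:
    """Re-run the hierarchy's bookkeeping on the shipped 20-sample test set.

    Alpha/beta validity counts use the comparison mode carried by ``params``.
    A row with a prediction counts correct iff its alpha routing matches the
    laboratory side of 10 mg/dl and the prediction lies in the laboratory
    value's clinical band.  ``use_printed_predictions=False`` recomputes
    predictions from the shipped calibration curves instead of echoing the
    published ones (identical to 2 dp for the low cohort).
    """
    if params is None:
        params = hm.ModelParams.published_defaults()
    rows = load_reference_testset()
    results: list[RowResult] = []
    n_correct = 0
    n_with_pred = 0
    for row in rows:
        branch = hm.classify_stage1(row.alpha, params)
        truth_side = hm.GE10 if row.lab_conc_mgdl >= 10 else hm.LOW
        routing_ok = branch == truth_side
        pred = _predict_row(row, params, use_printed_predictions)
        if pred is None:
            results.append(RowResult(row.serial, row.lab_conc_mgdl, branch,
                                     routing_ok, None, None, None))
            continue
        in_band = (hm.label_from_concentration(pred)
                   == hm.label_from_concentration(row.lab_conc_mgdl))
        ok = routing_ok and in_band
        n_with_pred += 1
        n_correct += ok
        results.append(RowResult(row.serial, row.lab_conc_mgdl, branch,
                                 routing_ok, pred, in_band, ok))
    acc = int(_round_half_up(100.0 * n_correct / n_with_pred, 0)) if n_with_pred else 0
    rule = (
        f"comparison_mode={params.comparison_mode}; correct := alpha routing matches "
        "lab side of 10 mg/dl AND prediction in lab clinical band (<10, 10-15, >15)"
    )
    return ReproductionReport(
        rule=rule,
        rows=tuple(results),
        alpha_valid_count=alpha_validity_count(rows, params),
        beta_valid_count=beta_validity_count(rows, params),
        correct_prediction_count=n_correct,
        accuracy_pct=acc,
    )


def audit_medium_model_offset(
    rows: list[TestSampleRow] | None = None,
    model: hm.QuadraticModel | None = None,
) -> tuple[dict[int, float], float]:
    """Residuals of printed medium-cohort predictions against the shipped curve.

    Returns per-serial residuals (printed prediction minus curve output at the
    printed 468 nm feature) and their mean.  On the shipped test set the
    residual is a near-constant ~+2.0 mg/dl — a documented inconsistency of
    the published medium-cohort calibration, surfaced rather than patched.
    """
    if rows is None:
        rows = load_reference_testset()
    if model is None:
        model = hm.ModelParams.published_defaults().medium_model
    residuals: dict[int, float] = {}
    for row in rows:
        if row.i468 is None or row.predicted_mgdl is None:
            continue
        residuals[row.serial] = row.predicted_mgdl - hm.predict_quadratic(row.i468, model)
    mean = sum(residuals.values()) / len(residuals)
    return residuals, mean
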