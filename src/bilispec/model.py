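"""Hierarchical two-threshold bilirubin model with per-cohort quadratic curves.

The decision hierarchy routes a self-referenced whole-blood transmission
spectrum in two stages and then reads the concentration off a cohort-specific
calibration curve:

1. alpha = (I[675] - I[645]) / I[660], a differential slope around the
   deoxyhemoglobin band.  alpha <= ~0.0125 indicates the low cohort
   (< 10 mg/dl); larger alpha indicates >= 10 mg/dl.
2. beta = (I[560] - I[500]) / 60, the slope across the methemoglobin band,
   splits the >= 10 mg/dl group at ~0.0014 into medium (10-15 mg/dl) and
   high (> 15 mg/dl).
3. A degree-2 polynomial maps the band-averaged normalized intensity at
   492 +/- 5 nm (low cohort) or 468 +/- 5 nm (medium cohort) to mg/dl.  No
   high-cohort curve exists; high-cohort predictions carry no number.

``I[l]`` denotes the band average (+/- 5 nm) of the min-max-normalized,
reference-renormalized intensity.  Two threshold-comparison conventions are
supported: ``strict`` (branch iff statistic > threshold) and
``round_to_threshold_precision`` (alpha rounded to 3 significant figures,
beta to 2, branch iff rounded value >= threshold) — the published headline
counts arise under mixed conventions, so both are first-class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .preprocess import BandSpec, NormalizedSpectrum, band_average

__all__ = [
    "LOW", "MEDIUM", "HIGH", "GE10",
    "label_from_concentration",
    "QuadraticModel", "ModelParams", "FeatureVector", "Prediction", "DecisionStep",
    "round_to_sig_figs",
    "compute_alpha", "compute_beta",
    "classify_stage1", "classify_stage2",
    "predict_quadratic", "predict_sample", "compute_features",
    "fit_cohort_model", "calibrate_threshold",
    "UndefinedStatisticError", "UnderdeterminedFitError", "NonSeparableWarning",
    "STRICT", "ROUND",
    "ALPHA_BANDS_NM", "BETA_BANDS_NM", "LOW_FEATURE_NM", "MEDIUM_FEATURE_NM",
]

LOW = "LOW"
MEDIUM = "MEDIUM"
HIGH = "HIGH"
GE10 = "GE10"  # stage-1 branch for >= 10 mg/dl, before beta resolves it

STRICT = "strict"
ROUND = "round_to_threshold_precision"

ALPHA_BANDS_NM = (645.0, 660.0, 675.0)
BETA_BANDS_NM = (500.0, 560.0)
LOW_FEATURE_NM = 492.0
MEDIUM_FEATURE_NM = 468.0


class UndefinedStatisticError(ZeroDivisionError):
    """A slope statistic's denominator band averaged to zero."""


class UnderdeterminedFitError(ValueError):
    """Fewer than 3 distinct abscissa values for a quadratic fit."""


class NonSeparableWarning(UserWarning):
    """All calibration values identical; no threshold separates the classes."""


def label_from_concentration(c: float) -> str:
    """Clinical cohort of a laboratory concentration: <10, 10-15, >15 mg/dl."""
    if c < 10:
        return LOW
    if c <= 15:
        return MEDIUM
    return HIGH


def round_to_sig_figs(x: float, n: int) -> float:
    """Round half-up to ``n`` significant figures (decimal, not binary)."""
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    shift = n - 1 - int(math.floor(math.log10(abs(x))))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class QuadraticModel:
    """Cohort calibration curve ``y = a2 x^2 + a1 x + a0`` (y in mg/dl)."""

    a2: float
    a1: float
    a0: float
    feature_band_center_nm: float
    r_squared: float | None = None

    def __call__(self, x: float) -> float:
        return predict_quadratic(x, self)


@dataclass(frozen=True)
class ModelParams:
    """Everything the hierarchy needs: thresholds, curves, band geometry."""

    alpha_threshold: float = 0.0125
    beta_threshold: float = 0.0014
    comparison_mode: str = STRICT
    low_model: QuadraticModel | None = None
    medium_model: QuadraticModel | None = None
    high_model: QuadraticModel | None = None
    ref_center_nm: float = 605.0
    band_half_width_nm: float = 5.0
    feature_stage: str = "ref_renormalized"

    def __post_init__(self) -> None:
        if self.comparison_mode not in (STRICT, ROUND):
            raise ValueError(f"unknown comparison_mode {self.comparison_mode!r}")
        if not (math.isfinite(self.alpha_threshold) and math.isfinite(self.beta_threshold)):
            raise ValueError("thresholds must be finite")
        if not 340 <= self.ref_center_nm <= 1060:
            raise ValueError("ref_center_nm outside the 340-1060 nm recorded range")

    @classmethod
    def published_defaults(cls, comparison_mode: str = STRICT) -> "ModelParams":
        """The parameter set of the original clinical calibration.

        Low-cohort curve (492 nm, R^2 = 0.88): y = -78.019 x^2 + 45.675 x + 4.4615.
        Medium-cohort curve (468 nm, R^2 = 0.92): y = -79.709 x^2 + 88.443 x + 7.4801.
        """
        return cls(
            alpha_threshold=0.0125,
            beta_threshold=0.0014,
            comparison_mode=comparison_mode,
            low_model=QuadraticModel(-78.019, 45.675, 4.4615, LOW_FEATURE_NM, 0.88),
            medium_model=QuadraticModel(-79.709, 88.443, 7.4801, MEDIUM_FEATURE_NM, 0.92),
            high_model=None,
        )


@dataclass(frozen=True)
class FeatureVector:
    """Band statistics of one sample's self-referenced spectrum."""

    alpha: float
    beta: float | None = None
    i492: float | None = None
    i468: float | None = None
    i_ref_check: float = 1.0


@dataclass(frozen=True)
class DecisionStep:
    statistic: str
    value: float
    threshold: float
    mode: str
    branch: str


@dataclass(frozen=True)
class Prediction:
    """Routing outcome plus (for low/medium cohorts) a concentration."""

    cohort: str
    concentration_mgdl: float | None
    trace: tuple[DecisionStep, ...] = field(default_factory=tuple)


def _bands(params: ModelParams | None = None) -> float:
    return params.band_half_width_nm if params is not None else 5.0


def compute_alpha(nspec: NormalizedSpectrum, half_width_nm: float = 5.0) -> float:
    """Differential slope statistic around 660 nm.

    ``alpha = (I[675] - I[645]) / I[660]`` with band-averaged intensities.
    Invariant under rescaling of the whole spectrum, hence insensitive to the
    choice of reference normalization.
    """
    i645, i660, i675 = (
        band_average(nspec, BandSpec(c, half_width_nm)) for c in ALPHA_BANDS_NM
    )
    if i660 == 0:
        raise UndefinedStatisticError("band average at 660 nm is zero; alpha undefined")
    return (i675 - i645) / i660


def compute_beta(nspec: NormalizedSpectrum, half_width_nm: float = 5.0) -> float:
    """Slope across the methemoglobin band: ``(I[560] - I[500]) / 60``.

    The divisor is the fixed 60 nm span between the band centers.  Unlike
    alpha this is not scale-invariant, which is why it is computed on the
    reference-renormalized spectrum.
    """
    i500, i560 = (band_average(nspec, BandSpec(c, half_width_nm)) for c in BETA_BANDS_NM)
    return (i560 - i500) / 60.0


def classify_stage1(alpha: float, params: ModelParams) -> str:
    """First split: LOW (< 10 mg/dl) vs GE10 (>= 10 mg/dl) on alpha."""
    if params.comparison_mode == STRICT:
        return GE10 if alpha > params.alpha_threshold else LOW
    rounded = round_to_sig_figs(alpha, 3)
    return GE10 if rounded >= params.alpha_threshold - 1e-12 else LOW


def classify_stage2(beta: float, params: ModelParams) -> str:
    """Second split: MEDIUM (10-15 mg/dl) vs HIGH (> 15 mg/dl) on beta."""
    if params.comparison_mode == STRICT:
        return HIGH if beta > params.beta_threshold else MEDIUM
    rounded = round_to_sig_figs(beta, 2)
    return HIGH if rounded >= params.beta_threshold - 1e-12 else MEDIUM


def predict_quadratic(x: float, model: QuadraticModel) -> float:
    """Evaluate a cohort calibration curve; no clamping is applied."""
    return model.a2 * x * x + model.a1 * x + model.a0


def compute_features(nspec: NormalizedSpectrum, params: ModelParams | None = None) -> FeatureVector:
    """All band statistics of a reference-renormalized spectrum at once."""
    hw = _bands(params)
    ref_c = params.ref_center_nm if params is not None else 605.0
    alpha = compute_alpha(nspec, hw)
    beta = compute_beta(nspec, hw)
    i492 = band_average(nspec, BandSpec(LOW_FEATURE_NM, hw))
    i468 = band_average(nspec, BandSpec(MEDIUM_FEATURE_NM, hw))
    ref_check = band_average(nspec, BandSpec(ref_c, hw))
    return FeatureVector(alpha=alpha, beta=beta, i492=i492, i468=i468, i_ref_check=ref_check)


def predict_sample(nspec: NormalizedSpectrum, params: ModelParams) -> Prediction:
    """Route one spectrum through the hierarchy and predict, with a trace."""
    hw = params.band_half_width_nm
    alpha = compute_alpha(nspec, hw)
    branch1 = classify_stage1(alpha, params)
    trace = [DecisionStep("alpha", alpha, params.alpha_threshold,
                          params.comparison_mode, branch1)]
    if branch1 == LOW:
        conc = None
        if params.low_model is not None:
            x = band_average(nspec, BandSpec(params.low_model.feature_band_center_nm, hw))
            conc = predict_quadratic(x, params.low_model)
        return Prediction(LOW, conc, tuple(trace))
    beta = compute_beta(nspec, hw)
    branch2 = classify_stage2(beta, params)
    trace.append(DecisionStep("beta", beta, params.beta_threshold,
                              params.comparison_mode, branch2))
    if branch2 == MEDIUM:
        conc = None
        if params.medium_model is not None:
            x = band_average(nspec, BandSpec(params.medium_model.feature_band_center_nm, hw))
            conc = predict_quadratic(x, params.medium_model)
        return Prediction(MEDIUM, conc, tuple(trace))
    conc = None
    if params.high_model is not None:
        x = band_average(nspec, BandSpec(params.high_model.feature_band_center_nm, hw))
        conc = predict_quadratic(x, params.high_model)
    return Prediction(HIGH, conc, tuple(trace))


def fit_cohort_model(points, band_center: float) -> QuadraticModel:
    """Ordinary least-squares degree-2 fit of concentration on a band feature.

    Parameters
    ----------
    points : sequence of (x, y)
        Band-averaged normalized intensity and laboratory concentration.
    band_center : float
        The feature band the abscissa was measured at, kept as metadata.

    R^2 is ``1 - SSres/SStot`` with SStot about the mean of y.  If SStot is 0
    (constant y) the convention is R^2 = 1 for a perfect fit, else 0.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or np.unique(pts[:, 0]).size < 3:
        raise UnderdeterminedFitError(
            "a quadratic fit needs at least 3 points with 3 distinct x values"
        )
    x, y = pts[:, 0], pts[:, 1]
    poly = np.polynomial.Polynomial.fit(x, y, deg=2).convert()
    a0, a1, a2 = (float(c) for c in poly.coef)
    resid = y - poly(x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # constant y: call the fit perfect only if residuals vanish (to rounding)
        r2 = 1.0 if ss_res <= 1e-12 * max(1.0, float(y @ y)) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return QuadraticModel(a2, a1, a0, band_center, r2)


def calibrate_threshold(values, is_upper_cohort) -> float:
    """Best midpoint threshold for the rule ``value > threshold -> upper``.

    Exhaustively scores every midpoint between adjacent sorted values (plus
    the extremes), maximizing training accuracy; among equally accurate
    splits the one with the largest margin wins, then the lower threshold.
    Deterministic and order-independent.
    """
    import warnings

    v = np.asarray(list(values), dtype=float)
    lab = np.asarray(list(is_upper_cohort), dtype=bool)
    if v.size != lab.size or v.size == 0:
        raise ValueError("values and labels must be non-empty and equal length")
    if not (lab.any() and (~lab).any()):
        raise ValueError("both cohorts must be represented")
    order = np.argsort(v, kind="stable")
    vs = v[order]
    if vs[0] == vs[-1]:
        warnings.warn("all values identical; classes not separable", NonSeparableWarning)
        return float(vs[0])
    uniq = np.unique(vs)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    margins = np.concatenate(([0.0], uniq[1:] - uniq[:-1], [0.0]))
    best_t, best_acc, best_margin = None, -1.0, -1.0
    for t, m in zip(candidates, margins):
        acc = float(((v > t) == lab).mean())
        if acc > best_acc or (acc == best_acc and m > best_margin):
            best_t, best_acc, best_margin = float(t), acc, float(m)
    return best_t
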