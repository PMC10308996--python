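"""Model/Results workflow: fit the hierarchy to labelled samples.

`HierarchicalBilirubinModel` holds labelled sample records and the
preprocessing configuration; :meth:`fit` calibrates both thresholds and the
per-cohort quadratic curves and returns a
:class:`HierarchicalBilirubinResults` carrying the fitted
:class:`~bilispec.model.ModelParams`, per-cohort fit diagnostics and a
``summary()`` table, with ``predict()`` for new spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import model as hm
from .preprocess import BandSpec, NormalizedSpectrum, minmax_normalize, renormalize_to_reference
from .spectra import SampleRecord, Spectrum, read_manifest

__all__ = [
    "CohortSizeError",
    "preprocess_spectrum",
    "record_features",
    "HierarchicalBilirubinModel",
    "HierarchicalBilirubinResults",
]


class CohortSizeError(ValueError):
    """A cohort that must be modelled has too few samples to fit a curve."""


def preprocess_spectrum(spec: Spectrum, ref_center_nm: float = 605.0,
                        band_half_width_nm: float = 5.0,
                        feature_stage: str = "ref_renormalized") -> NormalizedSpectrum:
    """Min-max normalize and (by default) self-reference a raw spectrum."""
    nspec = minmax_normalize(spec)
    if feature_stage == "ref_renormalized":
        nspec = renormalize_to_reference(nspec, BandSpec(ref_center_nm, band_half_width_nm))
    elif feature_stage != "minmax":
        raise ValueError(f"unknown feature_stage {feature_stage!r}")
    return nspec


def record_features(record: SampleRecord, params: hm.ModelParams) -> hm.FeatureVector:
    """Features of a sample record, computed from its 0-minute spectrum."""
    if 0.0 not in record.spectra:
        raise ValueError(f"{record.sample_id}: no 0-minute spectrum")
    nspec = preprocess_spectrum(
        record.spectra[0.0], params.ref_center_nm, params.band_half_width_nm,
        params.feature_stage,
    )
    return hm.compute_features(nspec, params)


@dataclass
class _CohortFit:
    n: int
    model: hm.QuadraticModel | None


class HierarchicalBilirubinModel:
    """Hierarchical bilirubin model built from labelled sample records.

    Parameters
    ----------
    records : list of SampleRecord
        Each needs a 0-minute spectrum and a laboratory concentration.
    comparison_mode : {'strict', 'round_to_threshold_precision'}
        Threshold convention carried into the fitted parameters.
    ref_center_nm, band_half_width_nm, feature_stage
        Preprocessing configuration (see :mod:`bilispec.preprocess`).
    min_cohort_n : int
        Minimum samples required to fit a cohort curve (default 3).
    """

    def __init__(self, records: list[SampleRecord], *,
                 comparison_mode: str = hm.STRICT,
                 ref_center_nm: float = 605.0,
                 band_half_width_nm: float = 5.0,
                 feature_stage: str = "ref_renormalized",
                 min_cohort_n: int = 3) -> None:
        labelled = [r for r in records if r.lab_total_bilirubin_mgdl is not None]
        if not labelled:
            raise ValueError("no labelled records to fit")
        self.records = labelled
        self.comparison_mode = comparison_mode
        self.ref_center_nm = ref_center_nm
        self.band_half_width_nm = band_half_width_nm
        self.feature_stage = feature_stage
        self.min_cohort_n = min_cohort_n

    @classmethod
    def from_manifest(cls, path: str | Path, **kwargs) -> "HierarchicalBilirubinModel":
        """Build the model from a manifest of spectrum files (see spectra I/O)."""
        return cls(read_manifest(path), **kwargs)

    def fit(self) -> "HierarchicalBilirubinResults":
        """Calibrate thresholds and cohort curves from the training records.

        The alpha threshold is the accuracy-maximizing midpoint split of the
        training alphas against the 10 mg/dl laboratory boundary; the beta
        threshold is calibrated the same way on the >= 10 mg/dl subset
        against the 15 mg/dl boundary.  Each represented cohort with at
        least ``min_cohort_n`` samples gets an OLS quadratic curve; the low
        and medium cohorts are mandatory, the high cohort is optional.
        """
        base = hm.ModelParams(
            comparison_mode=self.comparison_mode,
            ref_center_nm=self.ref_center_nm,
            band_half_width_nm=self.band_half_width_nm,
            feature_stage=self.feature_stage,
        )
        feats, labs = [], []
        for rec in self.records:
            feats.append(record_features(rec, base))
            labs.append(rec.lab_total_bilirubin_mgdl)
        labs = np.asarray(labs, dtype=float)
        alphas = np.array([f.alpha for f in feats])
        betas = np.array([f.beta for f in feats])

        alpha_thr = hm.calibrate_threshold(alphas, labs >= 10)
        ge10 = labs >= 10
        if ge10.sum() >= 2 and (labs[ge10] > 15).any() and (labs[ge10] <= 15).any():
            beta_thr = hm.calibrate_threshold(betas[ge10], labs[ge10] > 15)
        else:
            beta_thr = base.beta_threshold  # not calibratable; keep default

        cohort_fits: dict[str, _CohortFit] = {}
        specs = ((hm.LOW, labs < 10, "i492", hm.LOW_FEATURE_NM, True),
                 (hm.MEDIUM, (labs >= 10) & (labs <= 15), "i468", hm.MEDIUM_FEATURE_NM, True),
                 (hm.HIGH, labs > 15, "i468", hm.MEDIUM_FEATURE_NM, False))
        for cohort, mask, feat_name, center, required in specs:
            n = int(mask.sum())
            pts = [(getattr(feats[i], feat_name), labs[i])
                   for i in np.flatnonzero(mask)]
            curve = None
            if n >= self.min_cohort_n and len({p[0] for p in pts}) >= 3:
                curve = hm.fit_cohort_model(pts, center)
            elif required:
                raise CohortSizeError(
                    f"cohort {cohort}: {n} sample(s), need >= {self.min_cohort_n} "
                    "with 3 distinct feature values to fit a calibration curve"
                )
            cohort_fits[cohort] = _CohortFit(n, curve)

        params = hm.ModelParams(
            alpha_threshold=float(alpha_thr),
            beta_threshold=float(beta_thr),
            comparison_mode=self.comparison_mode,
            low_model=cohort_fits[hm.LOW].model,
            medium_model=cohort_fits[hm.MEDIUM].model,
            high_model=cohort_fits[hm.HIGH].model,
            ref_center_nm=self.ref_center_nm,
            band_half_width_nm=self.band_half_width_nm,
            feature_stage=self.feature_stage,
        )
        return HierarchicalBilirubinResults(self, params, feats, labs, cohort_fits)


class HierarchicalBilirubinResults:
    """Fitted hierarchy: parameters, diagnostics, prediction and summary."""

    def __init__(self, model: HierarchicalBilirubinModel, params: hm.ModelParams,
                 features: list[hm.FeatureVector], labs: np.ndarray,
                 cohort_fits: dict[str, _CohortFit]) -> None:
        self.model = model
        self.params = params
        self.features = features
        self.labs = labs
        self.cohort_fits = cohort_fits

    # -- diagnostics -----------------------------------------------------

    def training_routing(self) -> tuple[list[str], float]:
        """Routed cohort per training sample and overall routing accuracy."""
        routed = []
        for f in self.features:
            b1 = hm.classify_stage1(f.alpha, self.params)
            if b1 == hm.LOW:
                routed.append(hm.LOW)
            else:
                routed.append(hm.classify_stage2(f.beta, self.params))
        truth = [hm.label_from_concentration(c) for c in self.labs]
        acc = float(np.mean([r == t for r, t in zip(routed, truth)]))
        return routed, acc

    def predict(self, sample: Spectrum | SampleRecord | NormalizedSpectrum) -> hm.Prediction:
        """Route and predict one sample with the fitted parameters."""
        if isinstance(sample, SampleRecord):
            sample = sample.spectra[0.0]
        if isinstance(sample, Spectrum):
            sample = preprocess_spectrum(
                sample, self.params.ref_center_nm, self.params.band_half_width_nm,
                self.params.feature_stage,
            )
        return hm.predict_sample(sample, self.params)

    def summary(self) -> str:
        """Human-readable fit summary in the style of statistical model fits."""
        _, acc = self.training_routing()
        p = self.params
        lines = [
            "Hierarchical bilirubin model — fit summary",
            "=" * 58,
            f"Samples: {len(self.labs)}   feature stage: {p.feature_stage}   "
            f"ref: {p.ref_center_nm:g} nm (+/- {p.band_half_width_nm:g} nm)",
            f"alpha threshold: {p.alpha_threshold:.5g}   "
            f"beta threshold: {p.beta_threshold:.5g}   mode: {p.comparison_mode}",
            f"training routing accuracy: {100 * acc:.1f}%",
            "-" * 58,
            f"{'cohort':<8}{'n':>4}{'band nm':>9}{'a2':>12}{'a1':>12}{'a0':>10}{'R^2':>8}",
        ]
        for cohort in (hm.LOW, hm.MEDIUM, hm.HIGH):
            fit = self.cohort_fits[cohort]
            if fit.model is None:
                lines.append(f"{cohort:<8}{fit.n:>4}{'—':>9}{'(no curve fitted)':>42}")
            else:
                m = fit.model
                lines.append(
                    f"{cohort:<8}{fit.n:>4}{m.feature_band_center_nm:>9.0f}"
                    f"{m.a2:>12.4g}{m.a1:>12.4g}{m.a0:>10.4g}{m.r_squared:>8.3f}"
                )
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_calibration(self, ax=None):
        """Scatter of feature vs laboratory value with the fitted curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cohort, feat_name, color in ((hm.LOW, "i492", "tab:blue"),
                                         (hm.MEDIUM, "i468", "tab:orange")):
            fit = self.cohort_fits[cohort]
            if fit.model is None:
                continue
            mask = [hm.label_from_concentration(c) == cohort for c in self.labs]
            xs = np.array([getattr(f, feat_name) for f, m in zip(self.features, mask) if m])
            ys = self.labs[np.asarray(mask)]
            ax.scatter(xs, ys, s=18, color=color, label=f"{cohort} (R^2={fit.model.r_squared:.2f})")
            grid = np.linspace(xs.min(), xs.max(), 100)
            ax.plot(grid, [fit.model(x) for x in grid], color=color)
        ax.set_xlabel("band-averaged normalized intensity")
        ax.set_ylabel("total bilirubin (mg/dl)")
        ax.legend()
        return ax
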