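"""YAML round-trip for model parameters and synthetic study conditions.

A params file mirrors :class:`~bilispec.model.ModelParams` one key per
field; cohort curves are nested maps with ``a2, a1, a0, band_center_nm`` and
optional ``r_squared``.  A ``synthetic:`` key may carry overrides for
:class:`~bilispec.synthetic.SynthConfig`.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import ModelParams, QuadraticModel

__all__ = ["params_to_dict", "params_from_dict", "save_params", "load_params",
           "load_synthetic_overrides"]


def _quad_to_dict(q: QuadraticModel | None):
    if q is None:
        return None
    d = {"a2": q.a2, "a1": q.a1, "a0": q.a0, "band_center_nm": q.feature_band_center_nm}
    if q.r_squared is not None:
        d["r_squared"] = q.r_squared
    return d


def _quad_from_dict(d) -> QuadraticModel | None:
    if d is None:
        return None
    return QuadraticModel(float(d["a2"]), float(d["a1"]), float(d["a0"]),
                          float(d["band_center_nm"]), d.get("r_squared"))


def params_to_dict(params: ModelParams) -> dict:
    return {
        "alpha_threshold": params.alpha_threshold,
        "beta_threshold": params.beta_threshold,
        "comparison_mode": params.comparison_mode,
        "ref_center_nm": params.ref_center_nm,
        "band_half_width_nm": params.band_half_width_nm,
        "feature_stage": params.feature_stage,
        "low_model": _quad_to_dict(params.low_model),
        "medium_model": _quad_to_dict(params.medium_model),
        "high_model": _quad_to_dict(params.high_model),
    }


def params_from_dict(d: dict) -> ModelParams:
    base = ModelParams.published_defaults()
    return ModelParams(
        alpha_threshold=float(d.get("alpha_threshold", base.alpha_threshold)),
        beta_threshold=float(d.get("beta_threshold", base.beta_threshold)),
        comparison_mode=d.get("comparison_mode", base.comparison_mode),
        low_model=_quad_from_dict(d.get("low_model", params_to_dict(base)["low_model"])),
        medium_model=_quad_from_dict(d.get("medium_model", params_to_dict(base)["medium_model"])),
        high_model=_quad_from_dict(d.get("high_model")),
        ref_center_nm=float(d.get("ref_center_nm", base.ref_center_nm)),
        band_half_width_nm=float(d.get("band_half_width_nm", base.band_half_width_nm)),
        feature_stage=d.get("feature_stage", base.feature_stage),
    )


def save_params(params: ModelParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def load_params(path: str | Path) -> ModelParams:
    return params_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def load_synthetic_overrides(path: str | Path) -> dict:
    """The ``synthetic:`` block of a config file, empty if absent."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return dict(doc.get("synthetic", {}))
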