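"""Published reference test set shipped with the package.

Twenty neonatal whole-blood samples from the clinical evaluation of the
hierarchical model: laboratory total bilirubin, the alpha and beta slope
statistics, the band-averaged normalized intensity used for regression
(492 +/- 5 nm for the low cohort, 468 +/- 5 nm for the medium cohort), and the
model's predicted concentration.  High-cohort samples (18-20) carry no
regression feature or prediction because no high-cohort calibration curve
exists.  Samples 1-6 predate the beta stage of the hierarchy, so beta is
absent for them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TestSampleRow", "load_reference_testset"]


@dataclass(frozen=True)
class TestSampleRow:
    """One row of the published reference test set."""

    serial: int
    lab_conc_mgdl: float
    alpha: float
    beta: float | None
    i492: float | None
    i468: float | None
    predicted_mgdl: float | None

    def __post_init__(self) -> None:
        if not 1 <= self.serial <= 20:
            raise ValueError("serial must be 1..20")
        if (self.i492 is not None) and (self.i468 is not None):
            raise ValueError("at most one regression feature per sample")
        if (self.predicted_mgdl is not None) != (
            self.i492 is not None or self.i468 is not None
        ):
            raise ValueError("prediction present iff a regression feature is present")


# serial, lab mg/dl, alpha, beta, i492, i468, predicted mg/dl
_ROWS = (
    (1, 9.6, -0.0476, None, 0.12161, None, 8.86),
    (2, 9.1, -3.6952e-4, None, 0.14443, None, 9.43),
    (3, 6.41, 0.04074, None, 0.12773, None, 9.02),
    (4, 9.2, 0.00209, None, 0.21509, None, 10.67),
    (5, 6.4, -0.02099, None, 0.05157, None, 6.61),
    (6, 8.9, -0.06989, None, 0.10838, None, 8.49),
    (7, 14.4, -0.01421, 0.00322, None, 0.13154, 19.75),
    (8, 12.1, 0.04826, 7.30125e-4, None, 0.03963, 12.86),
    (9, 10.2, 0.02115, 8.66687e-4, None, 0.01175, 10.51),
    (10, 12.6, 0.01246, 6.00172e-4, None, 0.02351, 11.52),
    (11, 11.7, 0.06474, 4.30757e-4, None, 0.01832, 11.07),
    (12, 12.1, 0.05962, 1.91689e-4, None, 0.02969, 12.04),
    (13, 12.5, 0.04656, 2.7896e-4, None, 0.02845, 11.93),
    (14, 11.0, 0.08559, 2.7938e-4, None, 0.0185, 11.09),
    (15, 13.3, 0.01692, 1.39385e-4, None, 0.05925, 14.44),
    (16, 11.3, 0.10341, 1.81991e-4, None, 0.01929, 11.16),
    (17, 12.7, 0.01455, 6.95115e-4, None, 0.0338, 12.38),
    (18, 21.5, 0.05585, 0.0014, None, None, None),
    (19, 19.0, 0.23111, 0.00214, None, None, None),
    (20, 15.6, 0.028, 0.00135, None, None, None),
)


def load_reference_testset() -> list[TestSampleRow]:
    """Return the 20 published test samples, in serial order."""
    return [TestSampleRow(*row) for row in _ROWS]
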