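"""Calibration of measured delta shifts against labeled in-house standards.

Standards are characterised at the bulk level (EA-IRMS) and converted to
fragment-level calculated shifts via delta mass balance; measured shifts are
regressed on calculated ones (the instrument slope may deviate from unity),
or mapped through a two-point line when only two standards are run per
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .chem import MoleculeDef, SMX, fragment_calc_from_bulk
from .errors import ProcessingError, ValidationError

__all__ = [
    "StandardDefinition",
    "CalibrationModel",
    "build_regression",
    "two_point_calibrate",
    "apply_calibration",
    "principle_of_identical_treatment_check",
]

_MIN_SLOPE = 0.05


@dataclass(frozen=True)
class StandardDefinition:
    """A labeled in-house standard with its EA-IRMS-derived bulk shift.

    ``delta_calc`` per (fragment, element) is non-zero only at the labeled
    position and follows from the bulk shift by mass balance.
    """

    standard_id: str
    labeled_fragment: str
    labeled_element: str
    spike_target_permil: float
    delta_bulk_shift: float
    sd: float = 0.0
    molecule: MoleculeDef = SMX

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        # validates fragment/element membership
        self.delta_calc(self.labeled_fragment, self.labeled_element)

    def delta_calc(self, fragment: str, element: str) -> float:
        """Calculated fragment shift; zero away from the labeled position."""
        if (fragment, element) != (self.labeled_fragment, self.labeled_element):
            return 0.0
        return fragment_calc_from_bulk(
            self.delta_bulk_shift, self.molecule, fragment, element
        )


@dataclass(frozen=True)
class CalibrationModel:
    """A linear map measured = intercept + slope * true for one fragment/element."""

    fragment: str
    element: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_points: int
    kind: str = "regression"

    def __post_init__(self) -> None:
        if self.kind not in ("regression", "two_point"):
            raise ValidationError(f"unknown calibration kind {self.kind!r}")
        if self.kind == "two_point" and self.n_points != 2:
            raise ValidationError("two_point calibration requires exactly 2 points")
        if self.n_points < 2:
            raise ValidationError("calibration requires >= 2 points")


def build_regression(
    points: Sequence[tuple[float, float, float]],
    fragment: str = "",
    element: str = "",
    weighted: bool = False,
) -> CalibrationModel:
    """Least squares of measured on calculated delta shifts.

    ``points`` holds (delta_calc, delta_measured, sigma_measured) triples.
    Unweighted OLS by default; ``weighted=True`` uses 1/sigma^2 weights.
    """
    if len(points) < 2:
        raise ValidationError("regression requires >= 2 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("degenerate abscissa: all calculated shifts equal")
    if weighted:
        sigma = np.array([p[2] for p in points], dtype=float)
        if np.any(sigma <= 0):
            raise ValidationError("weighted regression requires sigma > 0")
        w = 1.0 / sigma**2
        wx, wy = np.average(x, weights=w), np.average(y, weights=w)
        sxx = np.sum(w * (x - wx) ** 2)
        slope = float(np.sum(w * (x - wx) * (y - wy)) / sxx)
        intercept = float(wy - slope * wx)
        dof = len(points) - 2
        if dof > 0:
            resid = y - (intercept + slope * x)
            s2 = float(np.sum(w * resid**2) / dof)
            slope_se = float(np.sqrt(s2 / sxx))
            intercept_se = float(np.sqrt(s2 * (1.0 / np.sum(w) + wx**2 / sxx)))
        else:
            slope_se = intercept_se = 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        slope_se = float(fit.stderr) if len(points) > 2 else 0.0
        intercept_se = float(fit.intercept_stderr) if len(points) > 2 else 0.0
    kind = "two_point" if len(points) == 2 else "regression"
    return CalibrationModel(
        fragment, element, slope, intercept, slope_se, intercept_se, len(points), kind
    )


def two_point_calibrate(
    delta_measured_sample: float,
    std_lo: tuple[float, float],
    std_hi: tuple[float, float],
) -> float:
    """Map a measured shift through the line defined by two standards.

    Each standard is a (true, measured) pair; the sample's measured value is
    linearly interpolated (or extrapolated) onto the true scale.
    """
    true_lo, meas_lo = std_lo
    true_hi, meas_hi = std_hi
    if meas_lo == meas_hi:
        raise ValidationError("two-point calibration: measured values coincide")
    return true_lo + (delta_measured_sample - meas_lo) * (true_hi - true_lo) / (
        meas_hi - meas_lo
    )


def apply_calibration(
    model: CalibrationModel, delta_measured: float, sigma_measured: float = 0.0
) -> tuple[float, float]:
    """Invert the calibration line: true = (measured - intercept) / slope.

    The sigma is scaled by 1/|slope| (first order).
    """
    if abs(model.slope) < _MIN_SLOPE:
        raise ProcessingError(
            f"calibration slope {model.slope} too close to zero; uncalibratable"
        )
    if sigma_measured < 0:
        raise ValidationError("sigma_measured must be >= 0")
    calibrated = (delta_measured - model.intercept) / model.slope
    return calibrated, sigma_measured / abs(model.slope)


def principle_of_identical_treatment_check(
    reference_pathway_tag: str | None, sample_pathway_tag: str | None
) -> tuple[bool, str]:
    """Verify sample and bracketing reference shared one processing pathway.

    Returns (passed, message); missing tags raise.
    """
    if not reference_pathway_tag or not sample_pathway_tag:
        raise ValidationError("both pathway tags are required")
    if reference_pathway_tag != sample_pathway_tag:
        return (
            False,
            f"identical-treatment violation: reference processed via "
            f"{reference_pathway_tag!r} but sample via {sample_pathway_tag!r}",
        )
    return True, "identical treatment: ok"


def models_from_standards(
    standards: Sequence[StandardDefinition],
    measured: Mapping[tuple[str, str], Mapping[str, tuple[float, float]]],
    weighted: bool = False,
) -> dict[tuple[str, str], CalibrationModel]:
    """Build one calibration model per labeled (fragment, element).

    ``measured`` maps (fragment, element) -> {standard_id: (delta, sigma)}.
    A natural-abundance anchor at (0, 0) may be included by listing a
    standard whose bulk shift is zero.
    """
    models: dict[tuple[str, str], CalibrationModel] = {}
    by_position: dict[tuple[str, str], list[StandardDefinition]] = {}
    for std in standards:
        by_position.setdefault(
            (std.labeled_fragment, std.labeled_element), []
        ).append(std)
    for key, stds in by_position.items():
        observed = measured.get(key, {})
        points = [
            (std.delta_calc(*key), *observed[std.standard_id])
            for std in stds
            if std.standard_id in observed
        ]
        if len(points) < 2:
            raise ValidationError(
                f"model {key[0]}-{key[1]}: needs >= 2 measured standards, "
                f"got {len(points)}"
            )
        models[key] = build_regression(points, *key, weighted=weighted)
    return models
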