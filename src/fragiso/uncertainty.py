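"""Uncertainty propagation for bracketed delta values.

Two stages: Gaussian propagation of ratio standard errors into the delta
value of one sample/reference bracketing, and aggregation of per-bracketing
sigmas into a 95% confidence interval using the Student t-factor,

    sigma_95%CI = sqrt((1/n) * sum(sigma_i^2)) * t_{alpha, n-1}.

Note the aggregation multiplies the root-mean-square sigma by t (no further
1/sqrt(n)); this conservative form is kept as the default, with a
conventional replicate-SD interval available as an alternative.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "propagate_delta_sigma",
    "t_factor",
    "ci95",
    "replicate_sd_ci",
]


def propagate_delta_sigma(
    sigma_sample: float,
    r_sample: float,
    r_ref_avg: float,
    sigma_ref_avg: float,
) -> float:
    """Gaussian propagation of ratio standard errors into a delta sigma (per mil):

    sqrt((sigma_sample / R_ref)^2 + (R_sample * sigma_ref / R_ref^2)^2) * 1000
    """
    if r_ref_avg <= 0:
        raise ValidationError(f"reference-average ratio must be > 0, got {r_ref_avg}")
    if sigma_sample < 0 or sigma_ref_avg < 0:
        raise ValidationError("sigmas must be >= 0")
    return 1000.0 * math.hypot(
        sigma_sample / r_ref_avg, r_sample * sigma_ref_avg / r_ref_avg**2
    )


def t_factor(n: int, alpha: float = 0.05) -> float:
    """Two-sided Student t critical value at n - 1 degrees of freedom."""
    if n < 2:
        raise ValidationError(f"t_factor requires n >= 2, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))


def ci95(sigmas: Sequence[float], alpha: float = 0.05) -> float:
    """95% CI half-width from per-bracketing sigmas: RMS(sigma) * t(n, alpha)."""
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.size < 2:
        raise ValidationError(f"ci95 requires >= 2 sigmas, got {sigmas.size}")
    if np.any(sigmas < 0):
        raise ValidationError("sigmas must be >= 0")
    rms = float(np.sqrt(np.mean(sigmas**2)))
    return rms * t_factor(int(sigmas.size), alpha)


def replicate_sd_ci(deltas: Sequence[float], alpha: float = 0.05) -> float:
    """Conventional replicate CI half-width: t(n, alpha) * sd / sqrt(n)."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size < 2:
        raise ValidationError(f"replicate CI requires >= 2 values, got {deltas.size}")
    return t_factor(int(deltas.size), alpha) * float(
        np.std(deltas, ddof=1) / np.sqrt(deltas.size)
    )
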