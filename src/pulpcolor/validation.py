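"""Analytical method validation: coefficients of variation and Horwitz limits.

The Horwitz function is the empirical inter-laboratory precision curve
CV% = 2^(1 - 0.5 log10 C), with C the analyte concentration as a
dimensionless mass fraction; it evaluates to 16% at C = 1e-6 (1 ug/g) and
2% at C = 1.  A method passes when both the experimental coefficient of
variation (CV_E, over replicate measurements) and the predicted one (CV_P,
over model predictions on the validated rows) fall at or below the limit.

Two limit modes are provided: ``fixed`` applies the conventional per-regime
thresholds (16% for ug/g-scale analytes such as carotenoids, 8% for
mg/100 g-scale analytes such as anthocyanins and polyphenols); ``horwitz``
evaluates the continuous function at the experimental mean converted to a
mass fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError

__all__ = [
    "ValidationSummary",
    "ComparisonResult",
    "coefficient_of_variation",
    "horwitz_cv_limit",
    "validate_against_horwitz",
    "compare_experimental_predicted",
    "UNIT_REGIMES",
]

#: Fixed CV acceptance limit (%) and mass-fraction conversion per unit regime.
UNIT_REGIMES = {
    "ug_per_g": {"fixed_limit": 16.0, "mass_fraction": 1e-6},
    "mg_per_100g": {"fixed_limit": 8.0, "mass_fraction": 1e-5},
}


@dataclass(frozen=True)
class ValidationSummary:
    """Experimental vs predicted agreement and Horwitz verdict for one analyte."""

    fruit_label: str
    analyte: str
    experimental_mean: float
    experimental_sd: float
    predicted_mean: float
    predicted_sd: float
    cv_e: float
    cv_p: float
    horwitz_limit: float
    passes_horwitz: bool
    relative_error: float


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Relative standard deviation in percent, 100 * sd / |mean|."""
    if mean == 0:
        raise DomainError("coefficient of variation undefined for zero mean")
    if sd < 0:
        raise DomainError("standard deviation must be non-negative")
    return 100.0 * sd / abs(mean)


def horwitz_cv_limit(concentration: float) -> float:
    """Horwitz precision limit CV% = 2^(1 - 0.5 log10 C).

    ``concentration`` is a dimensionless mass fraction in (0, 1]; the limit
    is strictly decreasing in C.
    """
    if not 0.0 < concentration <= 1.0:
        raise DomainError(
            f"concentration must be a mass fraction in (0, 1], got {concentration!r}"
        )
    return 2.0 ** (1.0 - 0.5 * math.log10(concentration))


def validate_against_horwitz(
    fruit_label: str,
    analyte: str,
    experimental_mean: float,
    experimental_sd: float,
    predicted_mean: float,
    predicted_sd: float,
    unit_regime: str,
    mode: str = "fixed",
) -> ValidationSummary:
    """Build a :class:`ValidationSummary` for one fruit x analyte.

    ``unit_regime`` is ``"ug_per_g"`` or ``"mg_per_100g"``; ``mode`` selects
    the fixed per-regime threshold (default) or the continuous Horwitz
    function evaluated at the experimental mean.
    """
    if unit_regime not in UNIT_REGIMES:
        raise ValidationError(
            f"unknown unit regime {unit_regime!r}; expected one of {sorted(UNIT_REGIMES)}"
        )
    if experimental_mean <= 0 or predicted_mean <= 0:
        raise DomainError("means must be positive for CV-based validation")
    regime = UNIT_REGIMES[unit_regime]
    cv_e = coefficient_of_variation(experimental_mean, experimental_sd)
    cv_p = coefficient_of_variation(predicted_mean, predicted_sd)
    if mode == "fixed":
        limit = regime["fixed_limit"]
    elif mode == "horwitz":
        limit = horwitz_cv_limit(experimental_mean * regime["mass_fraction"])
    else:
        raise ValidationError(f"unknown validation mode {mode!r}")
    relative_error = 100.0 * abs(predicted_mean - experimental_mean) / experimental_mean
    return ValidationSummary(
        fruit_label=fruit_label,
        analyte=analyte,
        experimental_mean=experimental_mean,
        experimental_sd=experimental_sd,
        predicted_mean=predicted_mean,
        predicted_sd=predicted_sd,
        cv_e=cv_e,
        cv_p=cv_p,
        horwitz_limit=limit,
        passes_horwitz=max(cv_e, cv_p) <= limit,
        relative_error=relative_error,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Per-item experimental vs predicted relative errors plus their mean."""

    table: pd.DataFrame
    mean_relative_error: float


def compare_experimental_predicted(experimental, predicted) -> ComparisonResult:
    """Per-item relative error 100 |pred - exp| / exp and its mean.

    Items with a zero experimental value are flagged and excluded from the
    mean rather than producing a division failure.
    """
    exp = np.asarray(experimental, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if exp.shape != pred.shape or exp.ndim != 1 or len(exp) == 0:
        raise ValidationError("inputs must be equal-length non-empty vectors")
    flagged = exp == 0.0
    rel = np.full(len(exp), np.nan)
    rel[~flagged] = 100.0 * np.abs(pred[~flagged] - exp[~flagged]) / exp[~flagged]
    table = pd.DataFrame(
        {
            "experimental": exp,
            "predicted": pred,
            "relative_error_pct": rel,
            "flagged_zero": flagged,
        }
    )
    if flagged.all():
        raise DomainError("all experimental values are zero; no mean defined")
    return ComparisonResult(table, float(np.nanmean(rel)))
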