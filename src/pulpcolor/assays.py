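"""Deterministic spectrophotometric assay arithmetic.

Converts raw absorbance readings into the reported analytical quantities:

* total monomeric anthocyanin content (TAC) by the pH-differential method,
  expressed as mg cyanidin-3-glucoside chloride per 100 g dry weight;
* total carotenoid content (TCC) by Beer-Lambert absorbance at 450 nm with
  the beta-carotene-in-hexane extinction coefficient 2592, in ug/g DW;
* total polyphenol content (TPC) by Folin-Ciocalteu with an A/B fraction
  interference correction and a gallic-acid calibration curve, in
  mg GAE/100 g DW;
* Trolox-equivalent antioxidant capacity from ABTS/DPPH calibration curves,
  in umol TE/g;
* the maturity index (total soluble solids / titratable acidity) and the
  chroma/hue transform (see :mod:`pulpcolor.colorimetry`).

All computations run in full floating-point precision; rounding to the two
decimals used in reports is left to the presentation layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AssayWarning, DomainError, SchemaError
from .colorimetry import ColorTriplet, chroma_hue  # noqa: F401  (re-export)

__all__ = [
    "PhDifferentialReading",
    "CarotenoidReading",
    "CalibrationCurve",
    "MaturityInputs",
    "TPC_GALLIC_ACID_CURVE",
    "ABTS_TROLOX_CURVE",
    "DPPH_TROLOX_CURVE",
    "maturity_index",
    "tac_ph_differential",
    "tcc_spectrophotometric",
    "invert_calibration",
    "tpc_folin",
    "trolox_equivalents",
    "apply_assay_table",
]

#: Molecular weight of cyanidin-3-glucoside chloride (C21H21ClO11), g/mol.
CYANIDIN_3_GLUCOSIDE_MW = 484.84
#: Molar absorptivity of cyanidin-3-glucoside chloride, L mol^-1 cm^-1.
CYANIDIN_3_GLUCOSIDE_EPSILON = 34300.0
#: Extinction coefficient of beta-carotene in hexane (1% w/v, 1 cm).
BETA_CAROTENE_E1PCT = 2592.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response curve ``absorbance = slope * concentration + intercept``."""

    slope: float
    intercept: float
    concentration_unit: str = "mg/L"

    def __post_init__(self) -> None:
        if self.slope == 0.0:
            raise DomainError("calibration curve slope must be non-zero")

    def response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


#: Gallic-acid standard curve used for Folin-Ciocalteu quantification.
TPC_GALLIC_ACID_CURVE = CalibrationCurve(0.0011, 0.0529, "mg/L")
#: Trolox standard curve for the ABTS radical assay.
ABTS_TROLOX_CURVE = CalibrationCurve(0.0007, 0.0671, "umol/L")
#: Trolox standard curve for the DPPH radical assay.
DPPH_TROLOX_CURVE = CalibrationCurve(0.0013, 0.007, "umol/L")


@dataclass(frozen=True)
class PhDifferentialReading:
    """Absorbances for the anthocyanin pH-differential method.

    Readings at 510 and 700 nm in pH 1.0 and pH 4.5 buffers.  The combined
    absorbance is A = (A510 - A700)_pH1.0 - (A510 - A700)_pH4.5, the
    standard AOAC form; a pre-combined A can be supplied via
    :meth:`from_combined`.
    """

    abs_510_pH1: float
    abs_700_pH1: float
    abs_510_pH45: float
    abs_700_pH45: float
    dilution_factor: float
    sample_weight: float
    molecular_weight: float = CYANIDIN_3_GLUCOSIDE_MW
    molar_absorptivity: float = CYANIDIN_3_GLUCOSIDE_EPSILON

    def __post_init__(self) -> None:
        if self.sample_weight <= 0:
            raise DomainError("sample_weight must be positive (grams)")
        if self.dilution_factor <= 0:
            raise DomainError("dilution_factor must be positive")
        for name in ("abs_510_pH1", "abs_700_pH1", "abs_510_pH45", "abs_700_pH45"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @classmethod
    def from_combined(
        cls,
        combined_absorbance: float,
        dilution_factor: float,
        sample_weight: float,
        **kwargs: float,
    ) -> "PhDifferentialReading":
        """Build a reading from an already background-corrected absorbance."""
        return cls(
            abs_510_pH1=combined_absorbance,
            abs_700_pH1=0.0,
            abs_510_pH45=0.0,
            abs_700_pH45=0.0,
            dilution_factor=dilution_factor,
            sample_weight=sample_weight,
            **kwargs,
        )

    @property
    def combined_absorbance(self) -> float:
        return (self.abs_510_pH1 - self.abs_700_pH1) - (
            self.abs_510_pH45 - self.abs_700_pH45
        )


@dataclass(frozen=True)
class CarotenoidReading:
    """One 450 nm absorbance reading with extraction parameters."""

    abs_450: float
    total_volume: float
    sample_weight: float
    extinction_coefficient: float = BETA_CAROTENE_E1PCT
    unit_factor: float = 1e4

    def __post_init__(self) -> None:
        if self.total_volume <= 0:
            raise DomainError("total_volume must be positive (mL)")
        if self.sample_weight <= 0:
            raise DomainError("sample_weight must be positive (grams)")


@dataclass(frozen=True)
class MaturityInputs:
    """Total soluble solids (degrees Brix) and titratable acidity (g/100 g)."""

    total_soluble_solids: float
    titratable_acidity: float

    def __post_init__(self) -> None:
        if self.total_soluble_solids < 0:
            raise DomainError("total_soluble_solids must be non-negative")
        if self.titratable_acidity <= 0:
            raise DomainError("titratable_acidity must be positive")


def maturity_index(inputs: MaturityInputs) -> float:
    """Dimensionless ripeness ratio MI = TSS / TA."""
    return inputs.total_soluble_solids / inputs.titratable_acidity


def tac_ph_differential(reading: PhDifferentialReading) -> float:
    """Total anthocyanin content, mg cyanidin-3-glucoside chloride / 100 g DW.

    TAC = A * MW * DF * 100 / (epsilon * W).  A negative combined absorbance
    (signal below the detection limit) yields 0 with an :class:`AssayWarning`.
    """
    a = reading.combined_absorbance
    if a < 0:
        warnings.warn(
            "background-corrected absorbance is negative; "
            "anthocyanin signal below detection limit, reporting 0",
            AssayWarning,
            stacklevel=2,
        )
        return 0.0
    return (
        a
        * reading.molecular_weight
        * reading.dilution_factor
        * 100.0
        / (reading.molar_absorptivity * reading.sample_weight)
    )


def tcc_spectrophotometric(reading: CarotenoidReading) -> float:
    """Total carotenoid content, ug beta-carotene / g DW.

    TCC = A * VT * 10^4 / (2592 * W).
    """
    return (
        reading.abs_450
        * reading.total_volume
        * reading.unit_factor
        / (reading.extinction_coefficient * reading.sample_weight)
    )


def invert_calibration(curve: CalibrationCurve, response: float) -> float:
    """Concentration from an absorbance via the inverse calibration line.

    Responses below the intercept produce a negative concentration which is
    flagged with an :class:`AssayWarning` but not clamped.
    """
    concentration = (response - curve.intercept) / curve.slope
    if concentration < 0:
        warnings.warn(
            "response below calibration intercept; negative concentration",
            AssayWarning,
            stacklevel=2,
        )
    return concentration


def tpc_folin(
    abs_B: float,
    abs_A: float,
    curve: CalibrationCurve = TPC_GALLIC_ACID_CURVE,
    *,
    extract_volume: float,
    dilution_factor: float,
    sample_weight: float,
) -> float:
    """Total polyphenol content, mg gallic acid equivalents / 100 g DW.

    The soluble-fraction absorbance ``abs_B`` is corrected by the
    interference fraction ``abs_A`` (net response abs_B - abs_A), converted
    to a gallic-acid concentration in mg/L through the calibration curve,
    then scaled by extract volume (L), dilution factor and sample weight (g).
    """
    if sample_weight <= 0:
        raise DomainError("sample_weight must be positive (grams)")
    net = abs_B - abs_A
    concentration = invert_calibration(curve, net)
    if concentration < 0:
        # invert_calibration already warned; below detection limit -> 0.
        return 0.0
    return concentration * extract_volume * dilution_factor * 100.0 / sample_weight


def trolox_equivalents(
    curve: CalibrationCurve,
    response: float,
    *,
    extract_volume: float,
    sample_weight: float,
) -> float:
    """Antioxidant capacity in umol Trolox equivalents per g of sample."""
    if sample_weight <= 0:
        raise DomainError("sample_weight must be positive (grams)")
    concentration = invert_calibration(curve, response)
    if concentration < 0:
        return 0.0
    return concentration * extract_volume / sample_weight


# ---------------------------------------------------------------------------
# Tabular interface

_ASSAY_COLUMNS = {
    "TAC": ["abs_510_pH1", "abs_700_pH1", "abs_510_pH45", "abs_700_pH45", "DF", "W"],
    "TCC": ["abs_450", "VT", "W"],
    "TPC": ["abs_B", "abs_A", "slope", "intercept", "V", "DF", "W"],
}


def apply_assay_table(records: pd.DataFrame) -> pd.Series:
    """Convert a table of absorbance records into contents, row by row.

    ``records`` must carry an ``assay`` column (TAC/TCC/TPC) plus the
    per-assay parameter columns: absorbances, dilution factor ``DF``,
    sample weight ``W``, total/extract volume ``VT``/``V`` and, for TPC,
    the calibration ``slope``/``intercept``.
    """
    if "assay" not in records.columns:
        raise SchemaError("records must have an 'assay' column")
    out = np.empty(len(records), dtype=float)
    for pos, (_, row) in enumerate(records.iterrows()):
        assay = row["assay"]
        if assay == "TAC":
            reading = PhDifferentialReading(
                abs_510_pH1=row["abs_510_pH1"],
                abs_700_pH1=row["abs_700_pH1"],
                abs_510_pH45=row["abs_510_pH45"],
                abs_700_pH45=row["abs_700_pH45"],
                dilution_factor=row["DF"],
                sample_weight=row["W"],
            )
            out[pos] = tac_ph_differential(reading)
        elif assay == "TCC":
            out[pos] = tcc_spectrophotometric(
                CarotenoidReading(
                    abs_450=row["abs_450"],
                    total_volume=row["VT"],
                    sample_weight=row["W"],
                )
            )
        elif assay == "TPC":
            out[pos] = tpc_folin(
                row["abs_B"],
                row["abs_A"],
                CalibrationCurve(row["slope"], row["intercept"]),
                extract_volume=row["V"],
                dilution_factor=row["DF"],
                sample_weight=row["W"],
            )
        else:
            raise SchemaError(f"unknown assay {assay!r}; expected TAC, TCC or TPC")
    return pd.Series(out, index=records.index, name="content")
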