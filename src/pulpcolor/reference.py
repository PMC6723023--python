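"""Bundled study measurements for six Ecuadorian tropical and Andean fruits.

The package ships the published summary tables for araza, blackberry,
Andean blueberry, naranjilla, tamarillo and goldenberry: mean pulp color
coordinates (with SDs), maturity inputs, the fitted color-model
coefficients per analyte, and the experimental vs predicted content
summary.  These tables drive the worked examples, the synthetic-data
defaults and the acceptance checks; anthocyanins are non-detectable in the
four yellow-orange fruits and carotenoids in the two red-purple ones, so
those (fruit, analyte) pairs are simply absent from the coefficient table.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .colorimetry import ColorTriplet
from .exceptions import ValidationError

__all__ = [
    "FRUITS",
    "load_color_summary",
    "load_maturity",
    "load_model_coefficients",
    "load_content_summary",
    "mean_color",
    "coefficients_for",
    "available_analytes",
]

FRUITS = (
    "Araza",
    "Blackberry",
    "Andean blueberry",
    "Naranjilla",
    "Tamarillo",
    "Goldenberry",
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("pulpcolor.data").joinpath(name).open("r") as handle:
        return pd.read_csv(handle)


def load_color_summary() -> pd.DataFrame:
    """Mean and SD of (L*, a*, b*) per fruit pulp."""
    return _load("fruit_colors.csv")


def load_maturity() -> pd.DataFrame:
    """Titratable acidity (g/100 g), total soluble solids (Brix), maturity index."""
    return _load("fruit_maturity.csv")


def load_model_coefficients() -> pd.DataFrame:
    """Fitted color-model coefficients (b0..b3) and R^2 per fruit x analyte."""
    return _load("model_coefficients.csv")


def load_content_summary() -> pd.DataFrame:
    """Experimental and predicted content means with their CVs (%)."""
    return _load("content_summary.csv")


def mean_color(fruit: str) -> ColorTriplet:
    """Mean pulp color of one of the six bundled fruits."""
    table = load_color_summary()
    row = table[table["fruit"] == fruit]
    if row.empty:
        raise ValidationError(f"unknown fruit {fruit!r}; expected one of {FRUITS}")
    row = row.iloc[0]
    return ColorTriplet(row["L_mean"], row["a_mean"], row["b_mean"])


def coefficients_for(fruit: str, analyte: str) -> np.ndarray:
    """Bundled (b0, b1, b2, b3) for one fruit x analyte combination."""
    table = load_model_coefficients()
    row = table[(table["fruit"] == fruit) & (table["analyte"] == analyte)]
    if row.empty:
        raise ValidationError(
            f"no bundled model for {fruit!r}/{analyte!r} (non-detectable analyte?)"
        )
    return row.iloc[0][["b0", "b1", "b2", "b3"]].to_numpy(dtype=float)


def available_analytes(fruit: str) -> list[str]:
    """Analytes with a bundled model for the given fruit."""
    table = load_model_coefficients()
    return table.loc[table["fruit"] == fruit, "analyte"].tolist()
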