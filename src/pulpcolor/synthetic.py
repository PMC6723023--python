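"""Synthetic fruit-pulp datasets with the structure the calibration assumes.

The generator emulates the study design the calibration pipeline expects:
15 pulp samples per fruit measured in triplicate (45 rows), pulp color
drawn per sample from independent Gaussians on (L*, a*, b*) (replicates
share the sample draw plus optional replicate-level measurement noise),
and contents generated from the linear model

    Y_i = b0 + b1 L*_i + b2 a*_i + b3 b*_i + e_i,   e_i ~ N(0, noise_sd^2),

with an optional outlier fraction: floor(outlier_fraction * n) rows, chosen
uniformly without replacement, are additionally shifted by
+/- outlier_shift * noise_sd with alternating sign.  L* is clipped to
[0, 100]; the chromatic axes are unbounded.

Matching raw-absorbance records can be produced by analytically inverting
the assay formulas, so the assay arithmetic round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assays
from .dataset import ANALYTES, FruitDataset
from .exceptions import ValidationError

__all__ = [
    "SyntheticSpec",
    "spec_from_reference",
    "TacAssayParameters",
    "TccAssayParameters",
    "TpcAssayParameters",
    "generate_color_samples",
    "generate_biocompound_values",
    "generate_fruit_dataset",
    "generate_absorbance_records",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and sampling design for one synthetic fruit dataset.

    ``true_coefficients`` are (b0, b1, b2, b3) in analyte units;
    ``color_means``/``color_sds`` parameterize the per-sample Gaussian color
    draw; ``replicate_sd`` adds replicate-level color measurement noise on
    top of the shared sample draw (0 by default); ``noise_sd`` is the
    additive content noise; outliers are controlled by ``outlier_fraction``
    (in [0, 0.5)) and ``outlier_shift`` (a multiple of ``noise_sd``).
    """

    fruit_label: str
    true_coefficients: tuple[float, float, float, float]
    color_means: tuple[float, float, float]
    color_sds: tuple[float, float, float]
    noise_sd: float
    n_samples: int = 15
    n_replicates: int = 3
    outlier_fraction: float = 0.0
    outlier_shift: float = 5.0
    replicate_sd: float = 0.0
    analyte: str = "TAC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_replicates < 1:
            raise ValidationError("n_samples and n_replicates must be positive")
        if len(self.true_coefficients) != 4:
            raise ValidationError("true_coefficients must have 4 entries")
        if len(self.color_means) != 3 or len(self.color_sds) != 3:
            raise ValidationError("color_means and color_sds must have 3 entries")
        if any(s < 0 for s in self.color_sds) or self.noise_sd < 0:
            raise ValidationError("color_sds and noise_sd must be non-negative")
        if self.replicate_sd < 0:
            raise ValidationError("replicate_sd must be non-negative")
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ValidationError("outlier_fraction must lie in [0, 0.5)")
        if self.analyte not in ANALYTES:
            raise ValidationError(f"analyte must be one of {ANALYTES}")

    @property
    def n_rows(self) -> int:
        return self.n_samples * self.n_replicates


def generate_color_samples(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw the replicate-level color table for one fruit.

    Returns a frame with columns ``sample_id, replicate, L, a, b`` and
    exactly ``n_samples * n_replicates`` rows, deterministic in
    ``spec.seed``.  Each sample gets one Gaussian color draw shared by its
    replicates; ``replicate_sd`` adds independent replicate noise.  L* is
    clipped to [0, 100].
    """
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.color_means, dtype=float)
    sds = np.asarray(spec.color_sds, dtype=float)
    sample_colors = means + sds * rng.standard_normal((spec.n_samples, 3))
    colors = np.repeat(sample_colors, spec.n_replicates, axis=0)
    if spec.replicate_sd > 0:
        colors = colors + spec.replicate_sd * rng.standard_normal(colors.shape)
    colors[:, 0] = np.clip(colors[:, 0], 0.0, 100.0)
    return pd.DataFrame(
        {
            "sample_id": np.repeat(np.arange(1, spec.n_samples + 1), spec.n_replicates),
            "replicate": np.tile(np.arange(1, spec.n_replicates + 1), spec.n_samples),
            "L": colors[:, 0],
            "a": colors[:, 1],
            "b": colors[:, 2],
        }
    )


def generate_biocompound_values(
    colors: pd.DataFrame,
    coefficients,
    noise_sd: float,
    outlier_fraction: float = 0.0,
    outlier_shift: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Contents from the linear color model plus noise and planted outliers.

    Returns ``(values, outlier_indices)``.  The outlier count is
    floor(outlier_fraction * n); indices are drawn uniformly without
    replacement and shifted by outlier_shift * noise_sd with alternating
    sign (+, -, +, ... in sorted index order).
    """
    if len(colors) == 0:
        raise ValidationError("colors table must be non-empty")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if not 0.0 <= outlier_fraction < 0.5:
        raise ValidationError("outlier_fraction must lie in [0, 0.5)")
    b = np.asarray(coefficients, dtype=float)
    if b.shape != (4,):
        raise ValidationError("coefficients must be a 4-vector")
    rng = np.random.default_rng(seed)
    X = colors[["L", "a", "b"]].to_numpy(dtype=float)
    values = b[0] + X @ b[1:]
    n = len(values)
    values = values + noise_sd * rng.standard_normal(n)
    n_outliers = math.floor(outlier_fraction * n)
    outlier_indices = np.sort(rng.choice(n, size=n_outliers, replace=False))
    signs = np.where(np.arange(n_outliers) % 2 == 0, 1.0, -1.0)
    values[outlier_indices] += signs * outlier_shift * noise_sd
    return values, outlier_indices


def generate_fruit_dataset(spec: SyntheticSpec) -> FruitDataset:
    """Compose colors and contents into a :class:`FruitDataset`.

    Deterministic in ``spec.seed``; content noise uses a seed derived from
    the color seed so the two stages stay independent.
    """
    colors = generate_color_samples(spec)
    values, outlier_indices = generate_biocompound_values(
        colors,
        spec.true_coefficients,
        spec.noise_sd,
        outlier_fraction=spec.outlier_fraction,
        outlier_shift=spec.outlier_shift,
        seed=spec.seed + 1,
    )
    frame = colors.copy()
    frame["content"] = values
    flags = np.zeros(len(frame), dtype=bool)
    flags[outlier_indices] = True
    frame["is_outlier"] = flags
    return FruitDataset(spec.fruit_label, spec.analyte, frame)


def spec_from_reference(
    fruit: str,
    analyte: str,
    seed: int = 0,
    outlier_fraction: float = 0.0,
    outlier_shift: float = 5.0,
) -> SyntheticSpec:
    """Study-condition spec for one of the six bundled fruits.

    Ground-truth coefficients and the color distribution come from the
    bundled summary tables; the content noise SD is set to the reported
    prediction CV times the predicted mean, i.e. the residual scatter the
    published calibrations exhibit, so refitting the synthetic data
    reproduces determination coefficients in the published 0.75-0.98 range.
    """
    from . import reference

    colors = reference.load_color_summary()
    row = colors[colors["fruit"] == fruit]
    if row.empty:
        raise ValidationError(f"unknown fruit {fruit!r}")
    row = row.iloc[0]
    summary = reference.load_content_summary()
    cell = summary[(summary["fruit"] == fruit) & (summary["analyte"] == analyte)]
    if cell.empty:
        raise ValidationError(f"no bundled summary for {fruit!r}/{analyte!r}")
    cell = cell.iloc[0]
    noise_sd = cell["cv_p"] / 100.0 * cell["predicted_mean"]
    return SyntheticSpec(
        fruit_label=fruit,
        analyte=analyte,
        true_coefficients=tuple(reference.coefficients_for(fruit, analyte)),
        color_means=(row["L_mean"], row["a_mean"], row["b_mean"]),
        color_sds=(row["L_sd"], row["a_sd"], row["b_sd"]),
        noise_sd=float(noise_sd),
        outlier_fraction=outlier_fraction,
        outlier_shift=outlier_shift,
        seed=seed,
    )


@dataclass(frozen=True)
class TacAssayParameters:
    """pH-differential assay settings used to invert contents to absorbances."""

    dilution_factor: float = 1000.0
    sample_weight: float = 0.25
    molecular_weight: float = assays.CYANIDIN_3_GLUCOSIDE_MW
    molar_absorptivity: float = assays.CYANIDIN_3_GLUCOSIDE_EPSILON


@dataclass(frozen=True)
class TccAssayParameters:
    total_volume: float = 50.0
    sample_weight: float = 1.0


@dataclass(frozen=True)
class TpcAssayParameters:
    curve: assays.CalibrationCurve = assays.TPC_GALLIC_ACID_CURVE
    extract_volume: float = 0.025
    dilution_factor: float = 1.0
    sample_weight: float = 0.5
    #: interference-fraction absorbance added to both channels
    background_abs: float = 0.05


AssayParameters = TacAssayParameters | TccAssayParameters | TpcAssayParameters


def generate_absorbance_records(
    dataset: FruitDataset, assay_params: AssayParameters
) -> pd.DataFrame:
    """Raw absorbance records whose forward assay reproduces the contents.

    Each assay formula is inverted analytically, so
    :func:`pulpcolor.assays.apply_assay_table` applied to the output
    reproduces ``dataset.frame['content']`` to floating-point accuracy.
    Requires non-negative contents.
    """
    contents = dataset.response
    if np.any(contents < 0):
        raise ValidationError("contents must be non-negative to invert an assay")
    base = pd.DataFrame(
        {
            "fruit": dataset.fruit_label,
            "sample_id": dataset.frame["sample_id"],
            "replicate": dataset.frame["replicate"],
            "assay": dataset.analyte,
        }
    )
    if isinstance(assay_params, TacAssayParameters):
        a = (
            contents
            * assay_params.molar_absorptivity
            * assay_params.sample_weight
            / (assay_params.molecular_weight * assay_params.dilution_factor * 100.0)
        )
        base["abs_510_pH1"] = a
        base["abs_700_pH1"] = 0.0
        base["abs_510_pH45"] = 0.0
        base["abs_700_pH45"] = 0.0
        base["DF"] = assay_params.dilution_factor
        base["W"] = assay_params.sample_weight
    elif isinstance(assay_params, TccAssayParameters):
        base["abs_450"] = (
            contents
            * assays.BETA_CAROTENE_E1PCT
            * assay_params.sample_weight
            / (assay_params.total_volume * 1e4)
        )
        base["VT"] = assay_params.total_volume
        base["W"] = assay_params.sample_weight
    elif isinstance(assay_params, TpcAssayParameters):
        concentration = (
            contents
            * assay_params.sample_weight
            / (100.0 * assay_params.extract_volume * assay_params.dilution_factor)
        )
        net = assay_params.curve.response(concentration)
        base["abs_B"] = net + assay_params.background_abs
        base["abs_A"] = assay_params.background_abs
        base["slope"] = assay_params.curve.slope
        base["intercept"] = assay_params.curve.intercept
        base["V"] = assay_params.extract_volume
        base["DF"] = assay_params.dilution_factor
        base["W"] = assay_params.sample_weight
    else:  # pragma: no cover - guarded by the union type
        raise ValidationError(f"unsupported assay parameters {type(assay_params)!r}")
    return base
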