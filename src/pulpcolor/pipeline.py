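"""End-to-end orchestration: assay -> fit -> filter -> refit -> validate.

For every (fruit, analyte) dataset the pipeline runs the full calibration
sequence: initial normal-equations fit, residual-based homogeneity
filtering with refit, coefficient significance tests, prediction at the
mean color of the retained rows, and a Horwitz-style validation summary
comparing experimental and predicted contents.  Failures are isolated per
fruit x analyte; analytes declared non-detectable for a fruit are reported
as "N.D" without fitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import FruitDataset, read_samples_csv
from .exceptions import ValidationError
from .regression import (
    coefficient_t_statistics,
    fit_linear_model,
    fit_with_filtering,
    predict_content,
)
from .validation import validate_against_horwitz

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)

#: Reporting unit regime per analyte (carotenoids in ug/g, the rest mg/100 g).
ANALYTE_UNIT_REGIME = {"TAC": "mg_per_100g", "TCC": "ug_per_g", "TPC": "mg_per_100g"}


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one pipeline run."""

    input_path: str | None = None
    output_dir: str = "pulpcolor_out"
    #: fruit -> analytes declared non-detectable (no fit attempted)
    non_detectable: dict[str, list[str]] = field(default_factory=dict)
    filter_k: float = 2.0
    filter_passes: int = 1
    alpha: float = 0.05
    validation_mode: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_k <= 0:
            raise ValidationError("filter_k must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.filter_passes < 0:
            raise ValidationError("filter_passes must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _analyze_dataset(dataset: FruitDataset, config: PipelineConfig) -> dict:
    initial = fit_linear_model(dataset)
    final, reports = fit_with_filtering(
        dataset, k=config.filter_k, passes=config.filter_passes
    )
    t, p = coefficient_t_statistics(final)
    # Map per-pass kept indices (positions in each pass's working subset)
    # back to positions in the full dataset.
    kept = np.arange(dataset.n_rows)
    for report in reports:
        kept = kept[np.asarray(report.kept_indices, dtype=int)]
    kept_mask = np.zeros(dataset.n_rows, dtype=bool)
    kept_mask[kept] = True
    retained = dataset.subset(kept)
    mean_color = retained.mean_color()
    X = dataset.design_matrix
    # Model predictions are summarized over the validated (retained) rows;
    # the experimental summary keeps all replicates, so the relative error
    # reflects what filtering changed rather than vanishing by the OLS
    # mean identity.
    predictions = X[kept_mask] @ final.coefficients
    experimental = dataset.response
    prediction_at_mean = predict_content(final.coefficients, mean_color)
    summary = validate_against_horwitz(
        dataset.fruit_label,
        dataset.analyte,
        float(experimental.mean()),
        float(experimental.std(ddof=1)),
        float(predictions.mean()),
        float(predictions.std(ddof=1)),
        unit_regime=ANALYTE_UNIT_REGIME[dataset.analyte],
        mode=config.validation_mode,
    )
    logger.info(
        "%s/%s: %d rows -> %d after filtering, R2 %.3f",
        dataset.fruit_label,
        dataset.analyte,
        dataset.n_rows,
        final.n_used,
        final.r_squared,
    )
    return {
        "status": "ok",
        "n_initial": dataset.n_rows,
        "n_final": final.n_used,
        "initial": {
            "coefficients": initial.coefficients.tolist(),
            "r_squared": initial.r_squared,
        },
        "filter": [
            {
                "pass": report.passes,
                "sigma": report.sigma,
                "k": report.threshold_multiplier,
                "n_dropped": int(len(report.dropped_indices)),
                "dropped_indices": np.asarray(report.dropped_indices).tolist(),
            }
            for report in reports
        ],
        "final": {
            "coefficients": final.coefficients.tolist(),
            "r_squared": final.r_squared,
            "t_statistics": t.tolist(),
            "p_values": p.tolist(),
            "significant": (p < config.alpha).tolist(),
            "dof": final.dof,
        },
        "prediction_at_mean_color": prediction_at_mean,
        "validation": {
            "experimental_mean": summary.experimental_mean,
            "experimental_sd": summary.experimental_sd,
            "predicted_mean": summary.predicted_mean,
            "predicted_sd": summary.predicted_sd,
            "cv_e": summary.cv_e,
            "cv_p": summary.cv_p,
            "horwitz_limit": summary.horwitz_limit,
            "passes_horwitz": summary.passes_horwitz,
            "relative_error": summary.relative_error,
        },
    }


def run_pipeline(
    config: PipelineConfig, datasets: list[FruitDataset] | None = None
) -> dict:
    """Run the calibration pipeline over all (fruit, analyte) datasets.

    ``datasets`` may be supplied directly; otherwise they are read from
    ``config.input_path``.  The report maps fruit -> analyte -> result cell;
    a failure in one combination is recorded in its cell and never aborts
    the others.
    """
    if datasets is None:
        if config.input_path is None:
            raise ValidationError("either datasets or config.input_path is required")
        datasets = read_samples_csv(config.input_path)
    cells: dict[str, dict[str, dict]] = {}
    for dataset in datasets:
        fruit_cells = cells.setdefault(dataset.fruit_label, {})
        if dataset.analyte in config.non_detectable.get(dataset.fruit_label, []):
            fruit_cells[dataset.analyte] = {"status": "N.D"}
            logger.info("%s/%s marked N.D; no fit", dataset.fruit_label, dataset.analyte)
            continue
        try:
            fruit_cells[dataset.analyte] = _analyze_dataset(dataset, config)
        except Exception as exc:  # fail-isolation per fruit x analyte
            logger.warning(
                "%s/%s failed: %s", dataset.fruit_label, dataset.analyte, exc
            )
            fruit_cells[dataset.analyte] = {
                "status": "error",
                "error_type": type(exc).__name__,
                "message": str(exc),
            }
    return {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "fruits": cells,
    }


def write_report(
    report: dict, output_dir: str | Path, formats: tuple[str, ...] = ("csv", "json")
) -> list[Path]:
    """Write the run report as coefficient/validation CSVs and/or JSON.

    The coefficient CSV uses the layout ``fruit,analyte,b0,b1,b2,b3,r2``
    with "N.D" rows for non-detectable analytes; the validation CSV mirrors
    the experimental/predicted summary columns plus pass/fail flags.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "csv" in formats:
        coeff_rows, valid_rows = [], []
        for fruit, analytes in sorted(report["fruits"].items()):
            for analyte, cell in sorted(analytes.items()):
                if cell["status"] == "ok":
                    b = cell["final"]["coefficients"]
                    coeff_rows.append(
                        {
                            "fruit": fruit,
                            "analyte": analyte,
                            "b0": b[0],
                            "b1": b[1],
                            "b2": b[2],
                            "b3": b[3],
                            "r2": cell["final"]["r_squared"],
                        }
                    )
                    v = cell["validation"]
                    valid_rows.append(
                        {
                            "fruit": fruit,
                            "analyte": analyte,
                            "experimental_mean": v["experimental_mean"],
                            "cv_e": v["cv_e"],
                            "predicted_mean": v["predicted_mean"],
                            "cv_p": v["cv_p"],
                            "horwitz_limit": v["horwitz_limit"],
                            "passes_horwitz": v["passes_horwitz"],
                            "relative_error": v["relative_error"],
                        }
                    )
                elif cell["status"] == "N.D":
                    coeff_rows.append(
                        {
                            "fruit": fruit,
                            "analyte": analyte,
                            "b0": "N.D",
                            "b1": "N.D",
                            "b2": "N.D",
                            "b3": "N.D",
                            "r2": "N.D",
                        }
                    )
        coeff_path = output_dir / "coefficients.csv"
        pd.DataFrame(
            coeff_rows, columns=["fruit", "analyte", "b0", "b1", "b2", "b3", "r2"]
        ).to_csv(coeff_path, index=False)
        written.append(coeff_path)
        valid_path = output_dir / "validation.csv"
        pd.DataFrame(
            valid_rows,
            columns=[
                "fruit",
                "analyte",
                "experimental_mean",
                "cv_e",
                "predicted_mean",
                "cv_p",
                "horwitz_limit",
                "passes_horwitz",
                "relative_error",
            ],
        ).to_csv(valid_path, index=False)
        written.append(valid_path)
    if "json" in formats:
        json_path = output_dir / "report.json"
        json_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        written.append(json_path)
    return written
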