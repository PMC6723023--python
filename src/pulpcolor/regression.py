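"""Least-squares color calibration: normal equations, filtering, inference.

The calibration model is linear in the pulp color coordinates,

    Y = b0 + b1 L* + b2 a* + b3 b* + e,

fit by solving the normal equations (X'X) b = X'Y directly.  The solver is
general (any full-rank n x p design), so the univariate-polynomial layout of
classical curve fitting is a special case of the same system.  Inference on
the partial coefficients uses t_i = b_i / sqrt(P_ii * S^2) with P the
inverse cross-product matrix (X'X)^-1 and S^2 the residual variance at
n - p degrees of freedom.  Data homogeneity is enforced by a residual
filter: rows whose absolute residual exceeds k standard deviations
(default k = 2) of the initial fit are dropped and the model is refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .colorimetry import ColorTriplet
from .dataset import FruitDataset
from .exceptions import (
    InsufficientDataError,
    NegativePredictionWarning,
    SingularSystemError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "NormalEquationsSolution",
    "RegressionFit",
    "FilterReport",
    "solve_normal_equations",
    "fit_linear_model",
    "coefficient_t_statistics",
    "correlation_matrix",
    "filter_by_residuals",
    "refit_filtered",
    "fit_with_filtering",
    "predict_content",
]

#: Number of parameters in the color model (intercept + L*, a*, b*).
N_PARAMS = 4


class NormalEquationsSolution(NamedTuple):
    coefficients: np.ndarray
    xtx_inverse: np.ndarray


def solve_normal_equations(design, response) -> NormalEquationsSolution:
    """Solve (X'X) b = X'Y for a full-rank design.

    Returns the coefficient vector together with (X'X)^-1, whose diagonal
    feeds the coefficient t-statistics.  A rank-deficient design raises
    :class:`SingularSystemError`; no silent pseudo-inverse is taken.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2:
        raise ValidationError("design must be a 2-D matrix")
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError("response length must match design rows")
    if n < p:
        raise InsufficientDataError(f"need at least {p} rows, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise SingularSystemError(
            "design matrix is rank-deficient; normal equations are singular"
        )
    xtx = X.T @ X
    xtx_inverse = np.linalg.inv(xtx)
    coefficients = np.linalg.solve(xtx, X.T @ y)
    return NormalEquationsSolution(coefficients, xtx_inverse)


@dataclass
class RegressionFit:
    """Result of one least-squares fit of the linear color model."""

    fruit_label: str
    analyte: str
    coefficients: np.ndarray
    residuals: np.ndarray
    residual_variance: float
    xtx_inverse_diagonal: np.ndarray
    t_statistics: np.ndarray
    r_squared: float
    n_used: int
    dof: int
    #: positional indices of the dataset rows used in this fit
    row_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    provenance: dict | None = None


def fit_linear_model(dataset: FruitDataset) -> RegressionFit:
    """Fit content = b0 + b1 L* + b2 a* + b3 b* by normal equations.

    Computes residuals, the dof-corrected residual variance
    S^2 = SSE / (n - 4), R^2 = 1 - SSE/SST, and per-coefficient t-statistics.
    Requires at least 5 rows and a full-rank color design.
    """
    n = dataset.n_rows
    if n < N_PARAMS + 1:
        raise InsufficientDataError(
            f"{dataset.fruit_label}/{dataset.analyte}: need >= {N_PARAMS + 1} rows "
            f"for a {N_PARAMS}-parameter fit, got {n}"
        )
    X = dataset.design_matrix
    y = dataset.response
    solution = solve_normal_equations(X, y)
    b = solution.coefficients
    residuals = y - X @ b
    sse = float(residuals @ residuals)
    dof = n - N_PARAMS
    s2 = sse / dof
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        r_squared = 1.0 if np.isclose(sse, 0.0) else 0.0
    else:
        r_squared = min(max(1.0 - sse / sst, 0.0), 1.0)
    diag = np.diag(solution.xtx_inverse).copy()
    t = _t_statistics(b, diag, s2)
    return RegressionFit(
        fruit_label=dataset.fruit_label,
        analyte=dataset.analyte,
        coefficients=b,
        residuals=residuals,
        residual_variance=s2,
        xtx_inverse_diagonal=diag,
        t_statistics=t,
        r_squared=r_squared,
        n_used=n,
        dof=dof,
        row_indices=np.arange(n),
    )


def _t_statistics(b: np.ndarray, diag: np.ndarray, s2: float) -> np.ndarray:
    if s2 == 0.0:
        # Perfect fit: coefficients are known exactly; report infinite t
        # (0 for coefficients that are exactly zero) instead of failing.
        t = np.zeros_like(b)
        t[b != 0.0] = np.sign(b[b != 0.0]) * np.inf
        return t
    return b / np.sqrt(diag * s2)


def coefficient_t_statistics(
    fit: RegressionFit,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient t-statistics and two-sided p-values at dof = n - 4."""
    if fit.dof < 1:
        raise InsufficientDataError("t-test needs at least 1 residual dof")
    t = _t_statistics(fit.coefficients, fit.xtx_inverse_diagonal, fit.residual_variance)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df=fit.dof)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


_CORR_LABELS = ["content", "L", "a", "b"]


def correlation_matrix(dataset: FruitDataset) -> pd.DataFrame:
    """4x4 Pearson correlation matrix over (content, L*, a*, b*)."""
    if dataset.n_rows < 3:
        raise InsufficientDataError("correlation needs at least 3 rows")
    columns = np.column_stack(
        [dataset.response, dataset.frame["L"], dataset.frame["a"], dataset.frame["b"]]
    )
    for j, label in enumerate(_CORR_LABELS):
        if np.ptp(columns[:, j]) == 0.0:
            raise UndefinedCorrelationError(
                f"column {label!r} is constant; correlation undefined"
            )
    corr = np.corrcoef(columns, rowvar=False)
    return pd.DataFrame(corr, index=_CORR_LABELS, columns=_CORR_LABELS)


@dataclass
class FilterReport:
    """Outcome of one residual-based homogeneity filter pass."""

    kept_indices: np.ndarray
    dropped_indices: np.ndarray
    sigma: float
    threshold_multiplier: float = 2.0
    passes: int = 1

    @property
    def kept_fraction(self) -> float:
        total = len(self.kept_indices) + len(self.dropped_indices)
        return len(self.kept_indices) / total


def filter_by_residuals(
    fit: RegressionFit, dataset: FruitDataset, k: float = 2.0
) -> FilterReport:
    """Flag rows whose |residual| exceeds k residual standard deviations.

    sigma is the dof-corrected residual SD of ``fit``; ties at exactly
    k * sigma are kept.  The report partitions the dataset's positional
    indices into kept and dropped sets.
    """
    if k <= 0:
        raise ValidationError("threshold multiplier k must be positive")
    if len(fit.residuals) != dataset.n_rows:
        raise ValidationError("fit does not correspond to this dataset")
    sigma = float(np.sqrt(fit.residual_variance))
    keep = np.abs(fit.residuals) <= k * sigma
    indices = np.arange(dataset.n_rows)
    return FilterReport(
        kept_indices=indices[keep],
        dropped_indices=indices[~keep],
        sigma=sigma,
        threshold_multiplier=k,
        passes=1,
    )


def refit_filtered(dataset: FruitDataset, report: FilterReport) -> RegressionFit:
    """Refit the model on the rows the filter kept.

    The returned fit records provenance: the filter report and the original
    row count, with ``row_indices`` mapping back into the full dataset.
    """
    kept = np.asarray(report.kept_indices, dtype=int)
    if len(kept) < N_PARAMS + 1:
        raise InsufficientDataError(
            f"only {len(kept)} rows kept; need >= {N_PARAMS + 1} to refit"
        )
    fit = fit_linear_model(dataset.subset(kept))
    fit.row_indices = kept
    fit.provenance = {
        "filter_report": report,
        "initial_n": dataset.n_rows,
    }
    return fit


def fit_with_filtering(
    dataset: FruitDataset, k: float = 2.0, passes: int = 1
) -> tuple[RegressionFit, list[FilterReport]]:
    """Initial fit followed by ``passes`` rounds of 2-sigma filter + refit.

    Returns the final fit and the per-pass filter reports (kept/dropped
    indices are positions in the *current* working subset of each pass).
    """
    if passes < 0:
        raise ValidationError("passes must be >= 0")
    working = dataset
    fit = fit_linear_model(working)
    reports: list[FilterReport] = []
    for pass_number in range(1, passes + 1):
        report = filter_by_residuals(fit, working, k=k)
        report.passes = pass_number
        reports.append(report)
        if len(report.dropped_indices) == 0:
            break
        working = working.subset(report.kept_indices)
        fit = fit_linear_model(working)
        fit.provenance = {"filter_report": report, "initial_n": dataset.n_rows}
    return fit, reports


def predict_content(coefficients, color: ColorTriplet | tuple) -> float:
    """Evaluate b0 + b1 L* + b2 a* + b3 b* at one color.

    Negative predictions (extrapolation outside the calibrated color range)
    are returned as-is with a :class:`NegativePredictionWarning`.
    """
    b = np.asarray(coefficients, dtype=float)
    if b.shape != (N_PARAMS,):
        raise ValidationError(f"expected {N_PARAMS} coefficients, got shape {b.shape}")
    if isinstance(color, ColorTriplet):
        L, a, bb = color.as_tuple()
    else:
        L, a, bb = color
    value = float(b[0] + b[1] * L + b[2] * a + b[3] * bb)
    if value < 0:
        warnings.warn(
            f"predicted content is negative ({value:.4g})",
            NegativePredictionWarning,
            stacklevel=2,
        )
    return value
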