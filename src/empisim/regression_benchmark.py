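"""Ordinary linear regression benchmark with closed-form prediction variance.

The benchmark fits ŵ = (XᵀX)⁻¹XᵀY and predicts ŷ_t = x_tᵀŵ with variance
σ̂² x_tᵀ(XᵀX)⁻¹x_t.  Design coding for the demo table: intercept, indicator
columns for each non-reference dose level (reference 0.5 mg) and the
supplement indicator — 4 parameters, the same count as the one-hot similarity
model it is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr

from .data_model import CovariateSchema, Dataset, ValidationError


@dataclass(frozen=True)
class LinearFit:
    """Closed-form least-squares fit: ŵ, σ̂², (XᵀX)⁻¹ and the design coding."""

    coefficients: np.ndarray
    design_labels: tuple[str, ...]
    sigma2: float
    xtx_inverse: np.ndarray
    schema: CovariateSchema

    @property
    def p(self) -> int:
        return len(self.design_labels)


def design_matrix(data: Dataset) -> tuple[np.ndarray, tuple[str, ...]]:
    """Factor-coded design: intercept; k−1 level indicators per multi-level
    covariate (first declared level is the reference); binary columns as-is."""
    return _design_rows(data.covariates, data.schema)


def _design_rows(
    rows: np.ndarray, schema: CovariateSchema
) -> tuple[np.ndarray, tuple[str, ...]]:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    cols = [np.ones(rows.shape[0])]
    labels = ["intercept"]
    for j, name in enumerate(schema.names):
        kind = schema.kind_of(name)
        col = rows[:, j]
        if kind == "binary":
            cols.append(col)
            labels.append(name)
            continue
        numeric = schema.numeric_levels_of(name)
        if numeric is None:
            cols.append(col)
            labels.append(name)
            continue
        raw = schema.levels_of(name)
        for lev, lab in list(zip(numeric, raw))[1:]:
            cols.append(np.isclose(col, lev).astype(float))
            labels.append(f"{name}={lab}")
    return np.column_stack(cols), tuple(labels)


def fit_lm(data: Dataset) -> LinearFit:
    """Closed-form OLS fit (which coincides with ML under Gaussian errors).

    Raises on a rank-deficient design, naming the dependent columns.
    """
    X, labels = design_matrix(data)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # pivoted QR: columns beyond the numerical rank are the dependent ones
        _, _, piv = qr(X, pivoting=True)
        bad = sorted(labels[i] for i in piv[rank:])
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")
    if n <= p:
        raise ValidationError(f"need n > p={p} observations for a variance estimate")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ data.response)
    resid = data.response - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    return LinearFit(coef, labels, sigma2, xtx_inv, data.schema)


def predict_lm(fit: LinearFit, target) -> tuple[float, float]:
    """Point prediction x_tᵀŵ and its variance σ̂² x_tᵀ(XᵀX)⁻¹x_t."""
    x, labels = _design_rows(np.atleast_2d(target), fit.schema)
    if labels != fit.design_labels:
        raise ValidationError("target row does not match the fitted design coding")
    x = x[0]
    value = float(x @ fit.coefficients)
    variance = float(fit.sigma2 * (x @ fit.xtx_inverse @ x))
    return value, variance


def predict_lm_many(fit: LinearFit, targets: Dataset | np.ndarray) -> np.ndarray:
    """Vectorized point predictions for a test table."""
    rows = targets.covariates if isinstance(targets, Dataset) else np.atleast_2d(targets)
    X, labels = _design_rows(rows, fit.schema)
    if labels != fit.design_labels:
        raise ValidationError("target rows do not match the fitted design coding")
    return X @ fit.coefficients
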