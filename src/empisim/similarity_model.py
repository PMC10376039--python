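"""The empirical-similarity predictor and its residual structures.

The model forecasts a response as a similarity-weighted average of other
observed responses,

    Ŷ_t = Σ_{i≠t} s(x_i, x_t) y_i / Σ_{i≠t} s(x_i, x_t),

with s a decreasing kernel of a weighted covariate distance.  Two residual
constructions feed estimation:

* leave-one-out (``residuals_loo``): every other row is the prediction pool —
  this is the objective the least-squares weight fit minimizes;
* sequential (``residuals_sequential``): row t is predicted from rows 1..t−1
  in a fixed ordering — the construction underlying the Gaussian likelihood,
  whose first observation is anchored at the sample mean.

Both are evaluated through :class:`SimilarityEngine`, which caches the
per-covariate pairwise difference tensor of a fixed dataset so that repeated
evaluations at new weights (the inner loop of estimation) cost one tensor
contraction each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import Dataset
from .metrics import (
    DistanceSpec,
    SimilaritySpec,
    base_terms,
    check_weights,
    finish,
    kernel_of_distance,
)

logger = logging.getLogger(__name__)

#: Below this total similarity mass a prediction falls back to the pool mean
#: (the EX kernel underflows for huge δ-inflated distances).
MASS_FLOOR = 1e-300


@dataclass(frozen=True)
class ModelSpec:
    """Model strategy (M1 or M2) plus its distance and kernel choices.

    M1 keeps covariates in original form and admits WBD/WED/WMD; M2 operates
    on a one-hot encoded dataset and admits WED only.
    """

    approach: str
    distance: DistanceSpec
    similarity: SimilaritySpec

    def __post_init__(self):
        approach = str(self.approach).lower()
        object.__setattr__(self, "approach", approach)
        if approach not in ("m1", "m2"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if approach == "m2" and self.distance.kind != "wed":
            raise ValueError("M2 admits the weighted Euclidean distance only")


@dataclass(frozen=True)
class PredictionResult:
    """One prediction: value, total similarity mass, and the fallback flag."""

    value: float
    weight_mass: float
    fallback_used: bool


class SimilarityEngine:
    """Fast repeated similarity computations against a fixed pool.

    Precomputes the (m, n, n) per-covariate base-term tensor once; each call
    at a new weight vector is then a single ``tensordot`` plus the kernel.
    """

    def __init__(self, pool: Dataset, spec: ModelSpec):
        if pool.n == 0:
            raise ValueError("empty pool")
        self.pool = pool
        self.spec = spec
        self.y = pool.response
        # A[l, i, j] = a_l(x_il, x_jl)
        self.A = np.ascontiguousarray(
            np.moveaxis(
                base_terms(
                    pool.covariates[:, None, :], pool.covariates[None, :, :], spec.distance
                ),
                2,
                0,
            )
        )

    def similarity_matrix(self, w) -> np.ndarray:
        """S[i, j] = s(x_i, x_j) at weights w (diagonal = 1)."""
        w = check_weights(w, self.pool.m)
        with np.errstate(over="ignore"):
            d = finish(np.tensordot(w, self.A, axes=1), self.spec.distance)
        return kernel_of_distance(d, self.spec.similarity)

    def cross_similarity(self, targets: np.ndarray, w) -> np.ndarray:
        """S[t, i] = s(x_i, target_t) for target rows against the pool."""
        w = check_weights(w, self.pool.m)
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        a = base_terms(
            targets[:, None, :], self.pool.covariates[None, :, :], self.spec.distance
        )
        with np.errstate(over="ignore"):
            d = finish(np.tensordot(a, w, axes=1), self.spec.distance)
        return kernel_of_distance(d, self.spec.similarity)

    def predict(self, targets: np.ndarray, w) -> tuple[np.ndarray, np.ndarray]:
        """Predicted values and fallback flags for target rows (pool = all rows)."""
        s = self.cross_similarity(targets, w)
        return _weighted_average(s, self.y)

    def residuals_loo(self, w) -> np.ndarray:
        s = self.similarity_matrix(w).copy()
        np.fill_diagonal(s, 0.0)
        values, fallback = _weighted_average(s, self.y)
        if fallback.any():
            # pool mean excluding the held-out row
            n = self.pool.n
            values[fallback] = (self.y.sum() - self.y[fallback]) / (n - 1)
        return self.y - values

    def residuals_sequential(self, w) -> np.ndarray:
        s = self.similarity_matrix(w)
        s = np.tril(s, k=-1)  # row t sees rows 0..t-1 only
        values, fallback = _weighted_average(s[1:], self.y)
        if fallback.any():
            cum = np.cumsum(self.y)[:-1] / np.arange(1, self.pool.n)
            values[fallback] = cum[fallback]
        return self.y[1:] - values


def _weighted_average(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mass = s.sum(axis=1)
    fallback = mass < MASS_FLOOR
    safe = np.where(fallback, 1.0, mass)
    values = (s @ y) / safe
    if fallback.any():
        values = np.where(fallback, y.mean(), values)
    return values, fallback


def predict_one(target, pool: Dataset, w, spec: ModelSpec) -> PredictionResult:
    """Similarity-weighted mean of pool responses for one target row.

    If the total similarity mass underflows below ``MASS_FLOOR`` the pool mean
    is returned and ``fallback_used`` is set.
    """
    if pool.n == 0:
        raise ValueError("empty pool")
    engine = SimilarityEngine(pool, spec)
    s = engine.cross_similarity(np.atleast_2d(target), w)[0]
    mass = float(s.sum())
    if mass < MASS_FLOOR:
        logger.debug("similarity mass underflow; falling back to pool mean")
        return PredictionResult(float(pool.response.mean()), mass, True)
    return PredictionResult(float(s @ pool.response) / mass, mass, False)


def predict_many(
    targets: Dataset | np.ndarray, pool: Dataset, w, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`predict_one`: returns (values, fallback_flags)."""
    if pool.n == 0:
        raise ValueError("empty pool")
    rows = targets.covariates if isinstance(targets, Dataset) else np.atleast_2d(targets)
    return SimilarityEngine(pool, spec).predict(rows, w)


def residuals_loo(data: Dataset, w, spec: ModelSpec) -> np.ndarray:
    """e_t = y_t − prediction of row t from all other rows; length n."""
    if data.n < 2:
        raise ValueError("need n >= 2 for leave-one-out residuals")
    return SimilarityEngine(data, spec).residuals_loo(w)


def residuals_sequential(data: Dataset, w, spec: ModelSpec) -> np.ndarray:
    """e_t = y_t − prediction of row t from rows 1..t−1, for t = 2..n.

    Returns n−1 values; the first observation enters estimation only through
    the likelihood's sample-mean anchor, not here.  The ordering is the
    dataset row order as supplied.
    """
    if data.n < 2:
        raise ValueError("need n >= 2 for sequential residuals")
    return SimilarityEngine(data, spec).residuals_sequential(w)
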