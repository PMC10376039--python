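"""Synthetic data generators.

Two generators make every stage testable without external data:

* :func:`generate_toothlike` draws a balanced 3 (dose) × 2 (supplement)
  factorial with cell-mean response plus Gaussian noise — the structure of
  the guinea-pig tooth-growth study.  The default cell means are synthetic
  package constants mimicking the qualitative pattern of the real data
  (tooth length increasing in dose under both supplements); they are not
  measured values.
* :func:`generate_similarity_process` simulates the sequential similarity
  process with known weights (y₁ = α + ε₁; y_t = similarity-weighted mean of
  y₁..y_{t−1} + ε_t), the sampling scheme used for parameter-recovery
  experiments.  The leave-one-out form of the model defines a simultaneous
  system with no direct sampling scheme, hence the sequential construction.

Both are pure functions of their configs: the same seed yields bitwise
identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_model import TOOTH_SCHEMA, Dataset, ValidationError
from .metrics import check_weights
from .similarity_model import ModelSpec, SimilarityEngine

#: Synthetic default cell means (dose mg, supplement label) → mean response.
#: Chosen to rise in dose for both supplements, with orange juice ahead at
#: low dose and the two supplements converging at 2.0 mg.
DEFAULT_CELL_MEANS: dict[tuple[float, str], float] = {
    (0.5, "VC"): 8.0,
    (1.0, "VC"): 17.0,
    (2.0, "VC"): 26.0,
    (0.5, "OJ"): 13.0,
    (1.0, "OJ"): 23.0,
    (2.0, "OJ"): 26.0,
}

#: Synthetic default within-cell noise sd, of the order seen in small-animal
#: growth assays relative to the 8–26 cell-mean range.
DEFAULT_SIGMA = 4.0


@dataclass(frozen=True)
class ToothlikeConfig:
    """Balanced 3×2 factorial generator settings."""

    cell_means: Mapping[tuple[float, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_MEANS)
    )
    sigma: float = DEFAULT_SIGMA
    reps_per_cell: int = 10
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cell_means", dict(self.cell_means))
        expected = {
            (d, s) for d in TOOTH_SCHEMA.levels["dose"] for s in TOOTH_SCHEMA.levels["supp"]
        }
        if set(self.cell_means) != expected:
            raise ValidationError(f"cell_means must cover exactly the 6 cells {sorted(expected)}")
        if self.reps_per_cell < 1:
            raise ValidationError("reps_per_cell must be >= 1")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


@dataclass(frozen=True)
class SimProcessConfig:
    """Sequential similarity-process generator settings."""

    true_weights: tuple[float, ...]
    model: ModelSpec
    sigma: float = 1.0
    alpha: float = 0.0
    n: int = 100
    seed: int = 0
    covariates: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "true_weights", tuple(check_weights(self.true_weights).tolist())
        )
        if self.n < 2:
            raise ValidationError("n must be >= 2")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.covariates is not None:
            cov = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if cov.shape != (self.n, len(self.true_weights)):
                raise ValidationError("covariates must be an (n, m) table matching the weights")
            object.__setattr__(self, "covariates", cov)


def generate_toothlike(config: ToothlikeConfig | None = None) -> Dataset:
    """Draw the balanced factorial: reps_per_cell rows per (dose, supplement)
    cell, response = cell mean + N(0, σ²) noise.  Defaults give n = 60."""
    config = config or ToothlikeConfig()
    rng = np.random.default_rng(config.seed)
    doses = TOOTH_SCHEMA.levels["dose"]
    supps = TOOTH_SCHEMA.levels["supp"]
    rows, ys = [], []
    for dose in doses:
        for code, supp in enumerate(supps):
            mu = config.cell_means[(dose, supp)]
            for _ in range(config.reps_per_cell):
                rows.append((dose, code))
                ys.append(mu)
    y = np.asarray(ys) + rng.normal(0.0, config.sigma, size=len(ys))
    return Dataset(TOOTH_SCHEMA, np.asarray(rows, dtype=float), y)


def generate_similarity_process(config: SimProcessConfig) -> Dataset:
    """Simulate the sequential similarity chain under known weights.

    Covariate rows are taken from the config or drawn uniformly from the six
    demo-schema cells.  y₁ = α + ε₁; for t ≥ 2, y_t is the similarity-weighted
    mean of the earlier responses (at the true weights) plus N(0, σ²) noise.
    """
    rng = np.random.default_rng(config.seed)
    w = np.asarray(config.true_weights)
    if config.covariates is not None:
        cov = config.covariates
        schema = _generic_schema(cov)
    else:
        doses = np.asarray(TOOTH_SCHEMA.levels["dose"])
        cov = np.column_stack(
            [rng.choice(doses, size=config.n), rng.integers(0, 2, size=config.n).astype(float)]
        )
        schema = TOOTH_SCHEMA
        if w.size != 2:
            raise ValidationError("demo-schema covariates need exactly 2 weights")
    noise = rng.normal(0.0, config.sigma, size=config.n)
    y = np.empty(config.n)
    y[0] = config.alpha + noise[0]
    # one engine over the full table; predictions only ever look backwards
    probe = Dataset(schema, cov, np.zeros(config.n))
    engine = SimilarityEngine(probe, config.model)
    S = engine.similarity_matrix(w)
    for t in range(1, config.n):
        s = S[t, :t]
        mass = s.sum()
        mean = float(s @ y[:t]) / mass if mass > 0 else float(y[:t].mean())
        y[t] = mean + noise[t]
    return Dataset(schema, cov, y)


def _generic_schema(cov: np.ndarray):
    from .data_model import CovariateSchema

    m = cov.shape[1]
    return CovariateSchema(
        names=tuple(f"x{j + 1}" for j in range(m)), kinds=("ordinal",) * m
    )
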