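"""Monte Carlo sensitivity protocol: scenario grid, repeated splits, CV and MSE.

The protocol repeatedly splits the data 70/30, fits every scenario's model on
the training part with the five-start rule, scores it on the test part, and
summarizes, per scenario, the coefficient of variation of each weight
estimator and the mean/sd of the per-split test MSE across iterations.  The
default grid crosses:

* M1 with WBD and WED at δ ∈ {1, 2, 4} and WMD at γ ∈ {1/4, 1/2, 1, 2, 4},
  each with {OLS, ML} × {EX, FR}  → 44 scenarios;
* M2 (one-hot) with WED at δ ∈ {1, 2, 4} × {OLS, ML} × {EX, FR} → 12;
* the linear-regression benchmark → 1;

57 scenarios in total.  Iteration i of every scenario uses split seed
base_seed + i, so splits are shared across scenarios within an iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Dataset, ValidationError, cell_means, encode_m2, split_train_test
from .estimation import fit_multistart, initial_starts
from .metrics import DistanceSpec, SimilaritySpec
from .regression_benchmark import fit_lm, predict_lm_many
from .similarity_model import ModelSpec, SimilarityEngine

logger = logging.getLogger(__name__)

DEFAULT_DELTAS = (1.0, 2.0, 4.0)
DEFAULT_GAMMAS = (0.25, 0.5, 1.0, 2.0, 4.0)

#: CV convention: values with |mean| and sd both below this floor count as
#: exactly zero (CV 0); |mean| alone below it yields an infinite CV.
CV_FLOOR = 1e-12

#: A redraw after a degenerate split offsets the seed by this co-prime stride
#: so redraw seeds never collide with other iterations' consecutive seeds.
REDRAW_STRIDE = 1009
MAX_REDRAWS = 100


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the model × method × similarity × distance grid."""

    model: str
    method: str | None = None
    similarity: SimilaritySpec | None = None
    distance: DistanceSpec | None = None

    def __post_init__(self):
        model = str(self.model).lower()
        object.__setattr__(self, "model", model)
        if model == "lm":
            if self.method or self.similarity or self.distance:
                raise ValidationError("the LM benchmark takes no method/kernel/distance")
            return
        if model not in ("m1", "m2"):
            raise ValidationError(f"unknown model {self.model!r}")
        method = str(self.method).lower() if self.method else None
        object.__setattr__(self, "method", method)
        if method not in ("ols", "ml"):
            raise ValidationError(f"similarity scenarios need method ols|ml, got {method!r}")
        if self.similarity is None or self.distance is None:
            raise ValidationError("similarity scenarios need a kernel and a distance")
        if model == "m2" and self.distance.kind != "wed":
            raise ValidationError("M2 admits WED only")

    @property
    def label(self) -> str:
        if self.model == "lm":
            return "lm"
        return (
            f"{self.model}-{self.method}-{self.similarity.kind}-"
            f"{self.distance.kind}-{self.distance.exponent_label}"
        )

    def model_spec(self) -> ModelSpec:
        return ModelSpec(self.model, self.distance, self.similarity)


@dataclass(frozen=True)
class IterationRecord:
    """One Monte Carlo iteration of one scenario."""

    iteration: int
    seed: int
    weights: np.ndarray
    test_mse: float
    start_index: int | None
    fallback_count: int

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.test_mse < 0:
            raise ValidationError("test MSE cannot be negative")


@dataclass(frozen=True)
class SensitivitySummary:
    """Per-scenario dispersion summary over Monte Carlo iterations."""

    scenario: ScenarioSpec
    cv_per_weight: np.ndarray
    mean_mse: float
    sd_mse: float
    n_iterations: int


def coefficient_of_variation(values) -> float:
    """Sample sd (n−1 denominator) over |sample mean|.

    Degenerate conventions: all-(near-)zero values give 0; a zero mean with
    non-zero spread gives +inf.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValidationError("coefficient of variation needs >= 2 values")
    sd = float(v.std(ddof=1))
    mean = abs(float(v.mean()))
    if sd < CV_FLOOR and mean < CV_FLOOR:
        return 0.0
    if mean < CV_FLOOR:
        return float("inf")
    return sd / mean


def mean_squared_error(predicted, truth) -> float:
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.size != t.size:
        raise ValidationError(f"length mismatch: {p.size} vs {t.size}")
    if p.size == 0:
        raise ValidationError("need at least one prediction")
    return float(np.mean((p - t) ** 2))


def scenario_grid(config: dict | None = None) -> list[ScenarioSpec]:
    """The full default 57-scenario grid, optionally subset by config.

    Recognized subset keys: ``models``, ``methods``, ``similarities``,
    ``distances``, ``deltas``, ``gammas``.
    """
    config = dict(config or {})
    known = {"models", "methods", "similarities", "distances", "deltas", "gammas"}
    unknown = set(config) - known
    if unknown:
        raise ValidationError(f"unknown scenario config field(s): {sorted(unknown)}")

    def wanted(key, value, default):
        sel = config.get(key)
        if sel is None:
            return True
        sel = [str(s).lower() if isinstance(s, str) else float(s) for s in sel]
        if not sel:
            raise ValidationError(f"scenario config field {key!r} is empty")
        return (str(value).lower() if isinstance(value, str) else float(value)) in sel

    if config.get("models") is not None and not config["models"]:
        raise ValidationError("scenario config field 'models' is empty")

    methods = ("ols", "ml")
    kernels = ("ex", "fr")
    grid: list[ScenarioSpec] = []
    for method in methods:
        if not wanted("methods", method, methods):
            continue
        for kern in kernels:
            if not wanted("similarities", kern, kernels):
                continue
            sim = SimilaritySpec(kern)
            if wanted("models", "m1", None):
                for dkind in ("wbd", "wed"):
                    if not wanted("distances", dkind, None):
                        continue
                    for delta in DEFAULT_DELTAS:
                        if wanted("deltas", delta, None):
                            grid.append(
                                ScenarioSpec("m1", method, sim, DistanceSpec(dkind, delta=delta))
                            )
                if wanted("distances", "wmd", None):
                    for gamma in DEFAULT_GAMMAS:
                        if wanted("gammas", gamma, None):
                            grid.append(
                                ScenarioSpec("m1", method, sim, DistanceSpec("wmd", gamma=gamma))
                            )
            if wanted("models", "m2", None):
                if wanted("distances", "wed", None):
                    for delta in DEFAULT_DELTAS:
                        if wanted("deltas", delta, None):
                            grid.append(
                                ScenarioSpec("m2", method, sim, DistanceSpec("wed", delta=delta))
                            )
    if wanted("models", "lm", None):
        grid.append(ScenarioSpec("lm"))
    if not grid:
        raise ValidationError("scenario configuration selects no scenarios")
    return grid


def _draw_valid_split(data: Dataset, fraction: float, seed: int):
    """Split, redrawing (with a logged offset seed) until every declared
    level appears in the training part — starts and one-hot encoding are
    undefined otherwise."""
    for attempt in range(MAX_REDRAWS):
        seed_used = seed + attempt * REDRAW_STRIDE
        split = split_train_test(data.n, fraction, seed_used)
        train = data.subset(split.train)
        try:
            cell_means(train)
        except ValidationError as err:
            logger.info("seed %d: degenerate split (%s); redrawing", seed_used, err)
            continue
        return split, train, data.subset(split.test)
    raise ValidationError(f"no valid split found after {MAX_REDRAWS} redraws from seed {seed}")


def run_iteration(
    data: Dataset,
    scenario: ScenarioSpec,
    seed: int,
    fraction: float = 0.7,
    iteration: int = 0,
) -> IterationRecord:
    """One split-fit-score pass: split with ``seed``, starts from the training
    cell means, five-start fit (or the closed-form benchmark), test MSE with
    the training set as prediction pool."""
    split, train, test = _draw_valid_split(data, fraction, seed)
    if scenario.model == "lm":
        fit = fit_lm(train)
        pred = predict_lm_many(fit, test)
        return IterationRecord(
            iteration, split.seed, fit.coefficients,
            mean_squared_error(pred, test.response), None, 0,
        )
    starts = initial_starts(train, scenario.model)
    if scenario.model == "m2":
        train, test = encode_m2(train), encode_m2(test)
    spec = scenario.model_spec()
    fit = fit_multistart(train, test, spec, scenario.method, starts)
    _, fallback = SimilarityEngine(train, spec).predict(test.covariates, fit.weights)
    return IterationRecord(
        iteration, split.seed, fit.weights, fit.test_mse, fit.start_index,
        int(fallback.sum()),
    )


def run_sensitivity(
    data: Dataset,
    scenarios: list[ScenarioSpec],
    R: int = 30,
    base_seed: int = 0,
    fraction: float = 0.7,
) -> tuple[list[SensitivitySummary], list[IterationRecord]]:
    """Run every scenario for R iterations (split seeds base_seed+1..+R).

    Returns the per-scenario summaries plus the flat list of iteration
    records (ordered scenario-major, iteration-minor).
    """
    if R < 2:
        raise ValidationError("need R >= 2 iterations")
    summaries: list[SensitivitySummary] = []
    records: list[IterationRecord] = []
    for scenario in scenarios:
        logger.info("scenario %s: %d iterations", scenario.label, R)
        recs = [
            run_iteration(data, scenario, base_seed + i, fraction, iteration=i)
            for i in range(1, R + 1)
        ]
        W = np.vstack([r.weights for r in recs])
        cv = np.array([coefficient_of_variation(W[:, j]) for j in range(W.shape[1])])
        mses = np.array([r.test_mse for r in recs])
        summaries.append(
            SensitivitySummary(scenario, cv, float(mses.mean()), float(mses.std(ddof=1)), R)
        )
        records.extend(recs)
    return summaries, records


def cv_frame(summaries: list[SensitivitySummary]) -> pd.DataFrame:
    """Tidy CV table: one row per scenario × parameter."""
    rows = [
        {"scenario": s.scenario.label, "parameter": f"w{j + 1}", "cv": s.cv_per_weight[j]}
        for s in summaries
        for j in range(len(s.cv_per_weight))
    ]
    return pd.DataFrame(rows, columns=["scenario", "parameter", "cv"])


def mse_frame(summaries: list[SensitivitySummary]) -> pd.DataFrame:
    """Tidy MSE table: one row per scenario."""
    rows = [
        {
            "scenario": s.scenario.label,
            "mean_mse": s.mean_mse,
            "sd_mse": s.sd_mse,
            "n_iterations": s.n_iterations,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["scenario", "mean_mse", "sd_mse", "n_iterations"])


def iterations_frame(
    records: list[IterationRecord], labels: list[str] | None = None
) -> pd.DataFrame:
    """Tidy per-iteration table (weights as w1..wk columns, ragged-safe).

    ``labels`` is an optional scenario-label list parallel to ``records``
    (the scenario-major ordering produced by :func:`run_sensitivity`).
    """
    rows = []
    for k, rec in enumerate(records):
        row = {
            "scenario": labels[k] if labels is not None else "",
            "iteration": rec.iteration,
            "seed": rec.seed,
            "test_mse": rec.test_mse,
            "start_index": rec.start_index,
            "fallback_count": rec.fallback_count,
        }
        for j, wv in enumerate(rec.weights):
            row[f"w{j + 1}"] = wv
        rows.append(row)
    return pd.DataFrame(rows)
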