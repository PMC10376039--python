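"""Mixed categorical/ordinal datasets: schemas, validation, encoding, CSV I/O, splits.

The canonical in-memory layout keeps covariates numeric: ordinal covariates on
their native scale, binary and categorical covariates as integer level codes
(the index of the observed value in the schema's declared level list).  The
schema retains the original labels so CSV round trips are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("categorical", "ordinal", "binary")


class ValidationError(ValueError):
    """A dataset value or schema violates its declared contract."""


class InputError(ValueError):
    """A file or configuration input is malformed."""


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate declaration.

    Parameters
    ----------
    names : covariate identifiers, unique and non-empty.
    kinds : per-covariate tag, one of ``categorical``, ``ordinal``, ``binary``.
    levels : per-covariate ordered tuple of admissible values.  Required for
        categorical and binary covariates; optional for ordinal ones, where it
        restricts the admissible numeric values.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    levels: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "levels", dict(self.levels))
        if len(self.names) != len(set(self.names)) or any(not n for n in self.names):
            raise ValidationError("covariate names must be unique and non-empty")
        if len(self.kinds) != len(self.names):
            raise ValidationError("kinds must match names in length")
        for k in self.kinds:
            if k not in KINDS:
                raise ValidationError(f"unknown covariate kind {k!r}")
        for name, kind in zip(self.names, self.kinds):
            levs = self.levels.get(name)
            if kind == "categorical" and (levs is None or len(levs) < 2):
                raise ValidationError(
                    f"categorical covariate {name!r} needs >= 2 declared levels"
                )
            if kind == "binary" and levs is not None and len(levs) != 2:
                raise ValidationError(f"binary covariate {name!r} must declare 2 levels")

    @property
    def m(self) -> int:
        return len(self.names)

    def kind_of(self, name: str) -> str:
        return self.kinds[self.names.index(name)]

    def levels_of(self, name: str) -> tuple | None:
        levs = self.levels.get(name)
        if levs is None and self.kind_of(name) == "binary":
            return (0, 1)
        return tuple(levs) if levs is not None else None

    def numeric_levels_of(self, name: str) -> tuple | None:
        """Levels on the internal numeric scale (codes for coded covariates)."""
        levs = self.levels_of(name)
        if levs is None:
            return None
        if self.kind_of(name) == "ordinal":
            return tuple(float(v) for v in levs)
        return tuple(range(len(levs)))


#: Schema of the demo guinea-pig tooth-growth table: vitamin C dose in mg
#: (ordinal, three levels) and food supplement type (VC coded 0, OJ coded 1).
TOOTH_SCHEMA = CovariateSchema(
    names=("dose", "supp"),
    kinds=("ordinal", "binary"),
    levels={"dose": (0.5, 1.0, 2.0), "supp": ("VC", "OJ")},
)


def _encode_value(value, kind: str, levels: tuple | None, name: str, row: int):
    """Map one raw CSV value to the internal numeric representation."""
    if kind == "ordinal":
        try:
            v = float(value)
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {row}: covariate {name!r} value {value!r} is not numeric"
            ) from None
        if levels is not None and not any(np.isclose(v, float(l)) for l in levels):
            raise ValidationError(
                f"row {row}: covariate {name!r} value {value!r} outside declared "
                f"levels {levels}"
            )
        return v
    # categorical / binary: match by label, falling back to the numeric code
    assert levels is not None
    for code, lev in enumerate(levels):
        if value == lev or str(value) == str(lev):
            return float(code)
    try:
        code = int(float(value))
        if 0 <= code < len(levels):
            return float(code)
    except (TypeError, ValueError):
        pass
    raise ValidationError(
        f"row {row}: covariate {name!r} value {value!r} outside declared levels {levels}"
    )


@dataclass(frozen=True)
class Dataset:
    """A validated covariate table plus numeric response.

    ``covariates`` is an (n, m) float array in schema column order; categorical
    and binary columns hold level codes.  ``response`` is length n.
    """

    schema: CovariateSchema
    covariates: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        cov = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if cov.size == 0:
            cov = cov.reshape(0, self.schema.m)
        y = np.asarray(self.response, dtype=float).ravel()
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "response", y)
        if cov.shape[1] != self.schema.m:
            raise ValidationError(
                f"covariate table has {cov.shape[1]} columns, schema declares {self.schema.m}"
            )
        if cov.shape[0] != y.size:
            raise ValidationError("covariate row count must equal response length")
        for j, name in enumerate(self.schema.names):
            levs = self.schema.numeric_levels_of(name)
            if levs is None:
                continue
            col = cov[:, j]
            ok = np.isclose(col[:, None], np.asarray(levs)[None, :]).any(axis=1)
            if not ok.all():
                bad = int(np.flatnonzero(~ok)[0])
                raise ValidationError(
                    f"row {bad}: covariate {name!r} value {col[bad]!r} outside "
                    f"declared levels"
                )

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def m(self) -> int:
        return self.covariates.shape[1]

    def subset(self, indices: Sequence[int]) -> "Dataset":
        idx = np.asarray(indices, dtype=int)
        return Dataset(self.schema, self.covariates[idx], self.response[idx])

    def to_frame(self, response_column: str = "len") -> pd.DataFrame:
        """Export with original labels restored (inverse of :func:`load_csv`)."""
        cols = {response_column: self.response}
        for j, name in enumerate(self.schema.names):
            col = self.covariates[:, j]
            if self.schema.kind_of(name) in ("categorical", "binary"):
                levs = self.schema.levels_of(name)
                cols[name] = np.asarray([levs[int(c)] for c in col], dtype=object)
            else:
                cols[name] = col
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class SplitIndices:
    """One train/test partition of row indices 0..n-1."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "train", tuple(int(i) for i in self.train))
        object.__setattr__(self, "test", tuple(int(i) for i in self.test))
        if set(self.train) & set(self.test):
            raise ValidationError("train and test indices overlap")


def load_csv(path, schema: CovariateSchema, response_column: str = "len") -> Dataset:
    """Read a CSV into a validated :class:`Dataset`.

    The header must contain ``response_column`` and every schema covariate.
    Categorical/binary text labels are mapped to level codes via the schema
    (e.g. supplement VC -> 0, OJ -> 1 for the demo table).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in (response_column, *schema.names) if c not in frame.columns]
    if missing:
        raise InputError(f"missing column(s) {missing} in {path}")
    return from_frame(frame, schema, response_column)


def from_frame(
    frame: pd.DataFrame, schema: CovariateSchema, response_column: str = "len"
) -> Dataset:
    """Build a Dataset from a raw (label-valued) DataFrame."""
    n = len(frame)
    cov = np.empty((n, schema.m), dtype=float)
    for j, name in enumerate(schema.names):
        kind = schema.kind_of(name)
        levs = schema.levels_of(name)
        vals = frame[name].tolist()
        cov[:, j] = [_encode_value(v, kind, levs, name, i) for i, v in enumerate(vals)]
    y = pd.to_numeric(frame[response_column], errors="raise").to_numpy(dtype=float)
    return Dataset(schema, cov, y)


def save_csv(data: Dataset, path, response_column: str = "len") -> None:
    """Write a Dataset with original labels; inverse of :func:`load_csv`."""
    data.to_frame(response_column).to_csv(path, index=False)


def load_tooth_growth() -> Dataset:
    """The bundled 60-row guinea-pig tooth-growth table (response in μm)."""
    from importlib.resources import files

    path = files("empisim").joinpath("data/toothgrowth.csv")
    return load_csv(str(path), TOOTH_SCHEMA, response_column="len")


def encode_m2(data: Dataset) -> Dataset:
    """One-hot expansion: every multi-level covariate becomes per-level indicators.

    Each covariate with k declared levels becomes k binary indicator covariates
    named ``name=level`` (1 iff that level was observed); already-binary
    covariates pass through unchanged.  Column order follows the original
    covariate order with levels in schema order, so the demo table (3-level
    dose + binary supplement) yields 4 binary covariates.
    """
    if not any(k != "binary" for k in data.schema.kinds):
        return data
    names: list[str] = []
    kinds: list[str] = []
    levels: dict[str, tuple] = {}
    cols: list[np.ndarray] = []
    for j, name in enumerate(data.schema.names):
        kind = data.schema.kind_of(name)
        col = data.covariates[:, j]
        if kind == "binary":
            names.append(name)
            kinds.append("binary")
            levs = data.schema.levels_of(name)
            if levs is not None:
                levels[name] = tuple(levs)
            cols.append(col)
            continue
        levs = data.schema.numeric_levels_of(name)
        if levs is None:
            raise ValidationError(
                f"covariate {name!r} has no declared levels; cannot binarize"
            )
        raw = data.schema.levels_of(name)
        for code, (lev, lab) in enumerate(zip(levs, raw)):
            names.append(f"{name}={lab}")
            kinds.append("binary")
            levels[names[-1]] = (0, 1)
            cols.append(np.isclose(col, lev).astype(float))
    schema = CovariateSchema(tuple(names), tuple(kinds), levels)
    return Dataset(schema, np.column_stack(cols), data.response)


def split_train_test(n: int, fraction: float, seed: int) -> SplitIndices:
    """Simple random split: round(fraction*n) train rows, the rest test.

    Deterministic given ``seed``.  For the 60-row demo table at fraction 0.7
    this gives |train| = 42, |test| = 18.
    """
    if not 0 < fraction < 1:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    if n < 2:
        raise ValidationError(f"need n >= 2 to split, got {n}")
    n_train = int(np.floor(fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ValidationError(
            f"split of n={n} at fraction={fraction} leaves an empty train or test set"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:])
    return SplitIndices(tuple(train), tuple(test), seed)


def cell_means(data: Dataset) -> dict[tuple[str, object], float]:
    """Mean response per (covariate, level) cell.

    Returns {(name, level_label): mean of y over rows where the covariate takes
    that level}.  Every declared level must occur at least once: downstream
    initial weight values are undefined otherwise.
    """
    out: dict[tuple[str, object], float] = {}
    for j, name in enumerate(data.schema.names):
        labels = data.schema.levels_of(name)
        numeric = data.schema.numeric_levels_of(name)
        if numeric is None:
            numeric = tuple(np.unique(data.covariates[:, j]))
            labels = numeric
        for lab, lev in zip(labels, numeric):
            mask = np.isclose(data.covariates[:, j], lev)
            if not mask.any():
                raise ValidationError(
                    f"level {lab!r} of covariate {name!r} absent from data"
                )
            out[(name, lab)] = float(data.response[mask].mean())
    return out
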