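"""Risk-factor taxonomy, binary incidence data, and the counting primitives.

The empirical input to every downstream stage is a binary incidence matrix:
one row per accident report, one column per risk factor, cell 1 if the
investigation attributed that factor to the accident.  The outcome node
(``FFHA``, the fall-from-height accident itself) is deliberately *not* a
column: every collected report is an accident, so the outcome enters only
through the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, LookupError_, ValidationError

__all__ = [
    "Factor",
    "FactorCatalog",
    "IncidenceMatrix",
    "default_catalog",
    "load_incidence_excerpt",
    "read_incidence",
    "write_incidence",
    "marginal_count",
    "joint_count",
    "parent_combination_counts",
    "split_samples",
]

_ID_COLUMN = "ID"


@dataclass(frozen=True)
class Factor:
    id: str
    label: str
    core_category: str


@dataclass(frozen=True)
class FactorCatalog:
    """The factor taxonomy: 20 coded risk factors in 5 core categories plus the outcome."""

    factors: tuple[Factor, ...]
    outcome_id: str = "FFHA"

    def __post_init__(self):
        ids = [f.id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise ValidationError("factor ids must be unique")
        if self.outcome_id in ids:
            raise ValidationError("outcome id must not also be a factor id")

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.factors)

    @property
    def node_ids(self) -> tuple[str, ...]:
        """All model nodes in canonical order: factors, then the outcome."""
        return self.factor_ids + (self.outcome_id,)

    def label_of(self, factor_id: str) -> str:
        for f in self.factors:
            if f.id == factor_id:
                return f.label
        raise LookupError_(f"unknown factor id {factor_id!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorCatalog":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            factors=tuple(Factor(**f) for f in payload["factors"]),
            outcome_id=payload.get("outcome_id", "FFHA"),
        )


def default_catalog() -> FactorCatalog:
    """The bundled 20-factor taxonomy (A1–A3, B1–B8, C1–C3, D1–D3, E1–E3) + FFHA."""
    with resources.files("ffhrisk.data").joinpath("factor_catalog.json").open(
        "r", encoding="utf-8"
    ) as fh:
        payload = json.load(fh)
    return FactorCatalog(
        factors=tuple(Factor(**f) for f in payload["factors"]),
        outcome_id=payload["outcome_id"],
    )


@dataclass
class IncidenceMatrix:
    """N accident reports × K binary factor indicators, with row order preserved."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate report ids: {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            row, col = self.data.index[bad[0]], self.data.columns[bad[1]]
            raise FormatError(
                f"non-binary cell at report {row!r}, factor {col!r}: "
                f"{self.data.iat[bad[0], bad[1]]!r}"
            )
        self.data = self.data.astype(np.int8)

    @property
    def report_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def factor_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_reports(self) -> int:
        return len(self.data)

    def column(self, factor: str) -> np.ndarray:
        if factor not in self.data.columns:
            raise LookupError_(f"unknown factor id {factor!r}")
        return self.data[factor].to_numpy()

    def drop_column(self, factor: str) -> "IncidenceMatrix":
        if factor not in self.data.columns:
            raise LookupError_(f"unknown factor id {factor!r}")
        return IncidenceMatrix(self.data.drop(columns=[factor]))


def read_incidence(
    path: str | Path, catalog: FactorCatalog | None = None
) -> IncidenceMatrix:
    """Read an incidence CSV (first column ``ID``, then one 0/1 column per factor).

    Any column order is accepted; when a catalog is supplied every column must
    be a catalog factor id (the outcome column, if present, is also allowed so
    synthetic matrices that retain it can round-trip).
    """
    raw = pd.read_csv(path, dtype={0: str})
    if raw.columns[0] != _ID_COLUMN:
        raise FormatError(f"first column must be {_ID_COLUMN!r}, got {raw.columns[0]!r}")
    raw = raw.set_index(_ID_COLUMN)
    if catalog is not None:
        allowed = set(catalog.factor_ids) | {catalog.outcome_id}
        unknown = [c for c in raw.columns if c not in allowed]
        if unknown:
            raise ValidationError(f"columns not in catalog: {unknown}")
    for col in raw.columns:
        if raw[col].isna().any() or not raw[col].isin((0, 1)).all():
            bad = raw.index[~raw[col].isin((0, 1))][0]
            raise FormatError(
                f"non-binary cell at report {bad!r}, factor {col!r}: "
                f"{raw.loc[bad, col]!r}"
            )
    return IncidenceMatrix(raw)


def write_incidence(matrix: IncidenceMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = _ID_COLUMN
    out.to_csv(path)


def load_incidence_excerpt() -> IncidenceMatrix:
    """The bundled 16-report excerpt of the 368-report incidence table."""
    with resources.files("ffhrisk.data").joinpath("incidence_excerpt.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return read_incidence(fh)  # type: ignore[arg-type]


def marginal_count(matrix: IncidenceMatrix, factor: str, state: int = 1) -> int:
    """Number of reports in which ``factor`` takes ``state`` (X_A for state=1)."""
    if state not in (0, 1):
        raise ValueError(f"state must be 0 or 1, got {state!r}")
    return int((matrix.column(factor) == state).sum())


def joint_count(matrix: IncidenceMatrix, assignment: Mapping[str, int]) -> int:
    """Number of reports matching every (factor, state) pair in ``assignment``."""
    if not assignment:
        raise ValueError("assignment must be non-empty")
    mask = np.ones(matrix.n_reports, dtype=bool)
    for factor, state in assignment.items():
        if state not in (0, 1):
            raise ValueError(f"state must be 0 or 1, got {state!r} for {factor!r}")
        mask &= matrix.column(factor) == state
    return int(mask.sum())


def parent_combination_counts(
    matrix: IncidenceMatrix, child: str, parents: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Counts (N_C, X_child|C) over all parent-state combinations.

    Combinations are indexed with the leftmost parent most significant and
    TRUE before FALSE, i.e. index 0 is the all-TRUE combination — the row
    layout used throughout the conditional probability tables.
    """
    parents = list(parents)
    k = len(parents)
    if k == 0:
        raise ValueError("parent_combination_counts requires at least one parent")
    cols = np.stack([matrix.column(p) for p in parents], axis=1)  # (N, k), 1=TRUE
    # bit: TRUE contributes 0, FALSE contributes 1
    idx = ((1 - cols) * (2 ** np.arange(k - 1, -1, -1))).sum(axis=1)
    n_c = np.bincount(idx, minlength=2**k)
    child_col = matrix.column(child)
    x_given_c = np.bincount(idx, weights=child_col, minlength=2**k).astype(int)
    return n_c, x_given_c


def split_samples(
    matrix: IncidenceMatrix, n_first: int
) -> tuple[IncidenceMatrix, IncidenceMatrix]:
    """Deterministic order-preserving split, e.g. 368 → (258 preliminary, 110 saturation)."""
    if not 0 <= n_first <= matrix.n_reports:
        raise ValueError(
            f"n_first must be in [0, {matrix.n_reports}], got {n_first}"
        )
    return (
        IncidenceMatrix(matrix.data.iloc[:n_first].copy()),
        IncidenceMatrix(matrix.data.iloc[n_first:].copy()),
    )
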