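"""Core domain types and I/O for cervical screening histories.

A screening history is an irregular time series of exam records
``(age, exam_type, state)`` for one subject, with states encoded
1 = normal, 2 = low-grade, 3 = high-grade and exam type either
``cytology`` (smear screen) or ``histology`` (confirmatory tissue exam).
Histories are gridded onto a discrete age axis to form the partially
observed state matrix consumed by the latent-profile estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

STATES = (1, 2, 3)
STATE_NAMES = {1: "normal", 2: "low-grade", 3: "high-grade"}
EXAM_TYPES = ("cytology", "histology")

MIN_AGE = 16.0
MAX_AGE = 100.0


class ValidationError(ValueError):
    """A record or history violates the domain invariants."""


class FormatError(ValueError):
    """An input file does not conform to the expected CSV dialect."""


@dataclass(frozen=True)
class ExamRecord:
    """One screening exam: subject age (decimal years), modality and result."""

    time: float
    exam_type: str
    state: int

    def __post_init__(self) -> None:
        if self.exam_type not in EXAM_TYPES:
            raise ValidationError(
                f"exam_type must be one of {EXAM_TYPES}, got {self.exam_type!r}"
            )
        if self.state not in STATES:
            raise ValidationError(f"state must be in {STATES}, got {self.state!r}")
        if not (MIN_AGE <= self.time <= MAX_AGE):
            raise ValidationError(
                f"exam age must lie in [{MIN_AGE}, {MAX_AGE}] years, got {self.time}"
            )


@dataclass(frozen=True)
class ScreeningHistory:
    """Time-ordered exam records for one subject."""

    subject_id: str
    records: tuple[ExamRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValidationError(
                f"history {self.subject_id!r} must contain at least one record"
            )
        times = [r.time for r in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"history {self.subject_id!r} has non-increasing or duplicate exam times"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def states(self) -> np.ndarray:
        return np.array([r.state for r in self.records], dtype=int)


@dataclass
class Cohort:
    """A collection of screening histories with unique subject ids."""

    histories: list[ScreeningHistory]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [h.subject_id for h in self.histories]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.histories)

    def __iter__(self) -> Iterator[ScreeningHistory]:
        return iter(self.histories)

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        wanted = set(subject_ids)
        return Cohort(
            histories=[h for h in self.histories if h.subject_id in wanted],
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class AgeGrid:
    """Discrete age axis: ``resolution`` bins per year on [t_min, t_max)."""

    t_min: float = 16.0
    t_max: float = 80.0
    resolution: int = 4

    def __post_init__(self) -> None:
        if self.t_min >= self.t_max:
            raise ValidationError("t_min must be < t_max")
        if self.resolution < 1 or int(self.resolution) != self.resolution:
            raise ValidationError("resolution must be a positive integer")
        span = (self.t_max - self.t_min) * self.resolution
        if abs(span - round(span)) > 1e-9:
            raise ValidationError("grid span times resolution must be an integer")

    @property
    def n_bins(self) -> int:
        return int(round((self.t_max - self.t_min) * self.resolution))

    def column(self, age: float) -> int:
        """Map an age to its 0-based half-open bin; raises if outside the span."""
        if not (self.t_min <= age < self.t_max):
            raise ValidationError(
                f"age {age} outside grid span [{self.t_min}, {self.t_max})"
            )
        return int(np.floor((age - self.t_min) * self.resolution))

    def bin_center(self, column: int) -> float:
        return self.t_min + (column + 0.5) / self.resolution


@dataclass
class StateMatrix:
    """Partially observed N x T matrix of discrete states on an age grid."""

    values: np.ndarray
    mask: np.ndarray
    grid: AgeGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")
        observed = self.values[self.mask]
        if observed.size and not np.isin(observed, STATES).all():
            raise ValidationError("observed entries must be in {1, 2, 3}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def most_severe_state(history: ScreeningHistory) -> int:
    """Worst (maximum) state ever recorded in a history."""
    return int(max(r.state for r in history.records))


def read_histories(path, dialect: dict | None = None) -> Cohort:
    """Read a cohort from CSV with columns subject_id, age, exam_type, state.

    Rows are grouped by subject and sorted by age; any invariant violation
    (unknown state or exam type, duplicate/non-monotone exam times, age out
    of range) raises with the offending subject named.
    """
    opts = {"sep": ",", "encoding": "utf-8"}
    if dialect:
        opts.update(dialect)
    df = pd.read_csv(path, **opts)
    required = {"subject_id", "age", "exam_type", "state"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")
    return cohort_from_frame(df)


def cohort_from_frame(df: pd.DataFrame) -> Cohort:
    """Build a validated cohort from a long-format records frame."""
    histories = []
    for sid, group in df.groupby("subject_id", sort=True):
        group = group.sort_values("age", kind="stable")
        try:
            records = tuple(
                ExamRecord(
                    time=float(row.age),
                    exam_type=str(row.exam_type),
                    state=int(row.state),
                )
                for row in group.itertuples()
            )
            histories.append(ScreeningHistory(subject_id=str(sid), records=records))
        except ValidationError as err:
            raise ValidationError(f"subject {sid!r}: {err}") from err
    return Cohort(histories=histories)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [
        (h.subject_id, r.time, r.exam_type, r.state)
        for h in cohort
        for r in h.records
    ]
    return pd.DataFrame(rows, columns=["subject_id", "age", "exam_type", "state"])


def write_histories(cohort: Cohort, path) -> None:
    """Write a cohort as CSV (comma separated, UTF-8, dot decimal)."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def to_state_matrix(cohort: Cohort, grid: AgeGrid | None = None) -> StateMatrix:
    """Grid a cohort onto the discrete age axis.

    Each record lands in the bin ``floor((age - t_min) * resolution)``.  When
    two records of one subject collide in a bin, the more severe state is
    kept: downstream use is risk stratification, where missing an abnormality
    is costlier than flagging one.
    """
    grid = grid or AgeGrid()
    n, t = len(cohort), grid.n_bins
    values = np.zeros((n, t), dtype=float)
    mask = np.zeros((n, t), dtype=bool)
    for i, history in enumerate(cohort):
        for rec in history.records:
            try:
                col = grid.column(rec.time)
            except ValidationError as err:
                raise ValidationError(
                    f"subject {history.subject_id!r}: {err}"
                ) from err
            if mask[i, col]:
                values[i, col] = max(values[i, col], rec.state)
            else:
                values[i, col] = rec.state
                mask[i, col] = True
    return StateMatrix(values=values, mask=mask, grid=grid)


def history_prefix(history: ScreeningHistory, n_records: int) -> ScreeningHistory:
    """First ``n_records`` exams of a history as a new history."""
    if n_records < 1 or n_records > len(history):
        raise ValidationError("prefix length out of range")
    return ScreeningHistory(
        subject_id=history.subject_id, records=history.records[:n_records]
    )
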