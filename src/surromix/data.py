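"""Aggregate randomized-trial data for trial-level surrogacy analysis.

One record per study: the estimated treatment effect on the surrogate
endpoint (``y1``, e.g. logHR on progression-free survival or logOR on tumor
response), the estimated effect on the final outcome (``y2``, e.g. logHR on
overall survival), their standard errors, the within-study correlation
between the two estimates, and a treatment-class label.  The exchange
format is a plain CSV with the seven columns below.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = ("study_id", "class_id", "y1", "y2", "se1", "se2", "rho_w")


class DataFormatError(ValueError):
    """The file does not conform to the CSV exchange format."""


class DataValidationError(ValueError):
    """The file parses but a record violates an invariant."""


@dataclass(frozen=True)
class TrialRecord:
    """Aggregate treatment effects of one randomized trial on two outcomes.

    Parameters
    ----------
    study_id, class_id
        Study label and treatment-class label.
    y1, y2
        Estimated treatment effects on the surrogate and the final outcome,
        on a log scale (logHR or logOR); dimensionless.
    se1, se2
        Standard errors of ``y1`` and ``y2``; strictly positive.
    rho_w
        Within-study correlation between the two estimates, in (-1, 1).
    """

    study_id: str
    class_id: str
    y1: float
    y2: float
    se1: float
    se2: float
    rho_w: float

    def __post_init__(self) -> None:
        for name in ("y1", "y2", "se1", "se2", "rho_w"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise DataValidationError(
                    f"study {self.study_id!r}: non-finite value for {name}"
                )
        if self.se1 <= 0 or self.se2 <= 0:
            raise DataValidationError(
                f"study {self.study_id!r}: standard errors must be > 0 "
                f"(got se1={self.se1}, se2={self.se2})"
            )
        if not -1.0 < self.rho_w < 1.0:
            raise DataValidationError(
                f"study {self.study_id!r}: within-study correlation must lie "
                f"strictly inside (-1, 1), got rho_w={self.rho_w}"
            )

    def within_study_covariance(self) -> np.ndarray:
        return within_study_covariance(self)


def within_study_covariance(record: TrialRecord) -> np.ndarray:
    """2x2 within-study covariance matrix of ``(y1, y2)``.

    ``[[se1^2, se1*se2*rho_w], [se1*se2*rho_w, se2^2]]`` — symmetric positive
    definite for any valid record.
    """
    off = record.se1 * record.se2 * record.rho_w
    return np.array([[record.se1**2, off], [off, record.se2**2]])


class SurrogacyDataset:
    """An ordered collection of :class:`TrialRecord` grouped into classes.

    Classes are indexed by order of first appearance; studies keep file
    order.  ``(class_id, study_id)`` pairs must be unique.
    """

    def __init__(self, records: Sequence[TrialRecord] | Iterable[TrialRecord]):
        records = tuple(records)
        if not records:
            raise DataValidationError("no records")
        seen: set[tuple[str, str]] = set()
        class_ids: list[str] = []
        for rec in records:
            key = (rec.class_id, rec.study_id)
            if key in seen:
                raise DataValidationError(
                    f"duplicate (class_id, study_id) pair {key!r}"
                )
            seen.add(key)
            if rec.class_id not in class_ids:
                class_ids.append(rec.class_id)
        self.records: tuple[TrialRecord, ...] = records
        self.class_ids: tuple[str, ...] = tuple(class_ids)
        self.class_index: dict[str, int] = {c: j for j, c in enumerate(class_ids)}

    # -- basic shape ----------------------------------------------------
    @property
    def n_studies(self) -> int:
        return len(self.records)

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    @property
    def n_per_class(self) -> np.ndarray:
        return np.bincount(self.class_codes, minlength=self.n_classes)

    # -- column views ---------------------------------------------------
    def _column(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    @property
    def y1(self) -> np.ndarray:
        return self._column("y1")

    @property
    def y2(self) -> np.ndarray:
        return self._column("y2")

    @property
    def se1(self) -> np.ndarray:
        return self._column("se1")

    @property
    def se2(self) -> np.ndarray:
        return self._column("se2")

    @property
    def rho_w(self) -> np.ndarray:
        return self._column("rho_w")

    @property
    def class_codes(self) -> np.ndarray:
        return np.array(
            [self.class_index[r.class_id] for r in self.records], dtype=int
        )

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(r.study_id for r in self.records)

    # -- manipulation ---------------------------------------------------
    def restrict(self, class_id: str) -> "SurrogacyDataset":
        """Subset containing a single treatment class (order preserved)."""
        if class_id not in self.class_index:
            raise KeyError(f"unknown class_id {class_id!r}")
        return SurrogacyDataset(
            [r for r in self.records if r.class_id == class_id]
        )

    def replace_record(self, index: int, record: TrialRecord) -> "SurrogacyDataset":
        recs = list(self.records)
        recs[index] = record
        return SurrogacyDataset(recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurrogacyDataset":
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise DataFormatError(f"missing required column(s): {missing}")
        records = []
        for row in frame.itertuples(index=False):
            records.append(
                TrialRecord(
                    study_id=str(row.study_id),
                    class_id=str(row.class_id),
                    y1=float(row.y1),
                    y2=float(row.y2),
                    se1=float(row.se1),
                    se2=float(row.se2),
                    rho_w=float(row.rho_w),
                )
            )
        return cls(records)


def read_dataset(path: str | Path, format: str = "csv") -> SurrogacyDataset:
    """Read a dataset from the CSV exchange format.

    Raises :class:`DataFormatError` for structural problems (missing
    columns) and :class:`DataValidationError` for invariant violations,
    naming the offending column or study.
    """
    if format != "csv":
        raise DataFormatError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file, header required") from exc
    if frame.empty:
        raise DataValidationError("no records")
    return SurrogacyDataset.from_frame(frame)


def write_dataset(dataset: SurrogacyDataset, path: str | Path) -> None:
    """Write a dataset back to CSV (12 significant digits)."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.12g")
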