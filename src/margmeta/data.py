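"""Study-level data containers, CSV input/output and MCAR augmentation.

A bivariate meta-analysis dataset is a collection of studies, each reporting
an effect estimate and its within-study standard error for one or both of two
outcomes, optionally a within-study correlation (needed only by the
likelihood/moment comparators), and optionally study-level covariates for
meta-regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "StudyRecord",
    "BivariateDataset",
    "read_dataset",
    "write_dataset",
    "augment_mcar",
]

#: Default within-study variance assigned to missing outcomes (MCAR trick).
DEFAULT_LARGE_VARIANCE = 1e6


class ValidationError(ValueError):
    """Raised when input data violate the model's structural requirements."""


@dataclass(frozen=True)
class StudyRecord:
    """One study's contribution: per-outcome estimates and standard errors.

    ``y1``/``s1`` and ``y2``/``s2`` must be present or absent as pairs;
    ``rho_w`` (the within-study correlation of the two estimates) is only
    meaningful when both outcomes are reported.  ``x1``/``x2`` hold optional
    covariate vectors for meta-regression.
    """

    study_id: str
    y1: float | None = None
    s1: float | None = None
    y2: float | None = None
    s2: float | None = None
    rho_w: float | None = None
    x1: tuple[float, ...] | None = None
    x2: tuple[float, ...] | None = None
    #: set by :func:`augment_mcar` on filled-in outcomes; pseudo-observations
    #: enter weighted sums (with vanishing weight) but are excluded from the
    #: degrees-of-freedom bookkeeping of the moment equations.
    pseudo1: bool = False
    pseudo2: bool = False

    def __post_init__(self) -> None:
        if (self.y1 is None) != (self.s1 is None):
            raise ValidationError(
                f"study {self.study_id!r}: y1 and s1 must be present together"
            )
        if (self.y2 is None) != (self.s2 is None):
            raise ValidationError(
                f"study {self.study_id!r}: y2 and s2 must be present together"
            )
        for name, s in (("s1", self.s1), ("s2", self.s2)):
            if s is not None and not s > 0:
                raise ValidationError(
                    f"study {self.study_id!r}: {name} must be strictly positive, got {s}"
                )
        if self.rho_w is not None:
            if not (self.has_outcome1 and self.has_outcome2):
                raise ValidationError(
                    f"study {self.study_id!r}: rho_w given but both outcomes not reported"
                )
            if not -1.0 <= self.rho_w <= 1.0:
                raise ValidationError(
                    f"study {self.study_id!r}: rho_w must lie in [-1, 1], got {self.rho_w}"
                )

    @property
    def has_outcome1(self) -> bool:
        return self.y1 is not None

    @property
    def has_outcome2(self) -> bool:
        return self.y2 is not None

    @property
    def complete(self) -> bool:
        return self.has_outcome1 and self.has_outcome2


@dataclass(frozen=True)
class BivariateDataset:
    """An ordered collection of :class:`StudyRecord` with reporting-set indices.

    ``R1``, ``R2`` and ``R12`` are the (0-based) index sets of studies
    reporting outcome 1, outcome 2 and both; row order is the stable default
    ordering for every matrix assembly downstream.
    """

    records: tuple[StudyRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("dataset contains no studies")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @cached_property
    def R1(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.records) if r.has_outcome1)

    @cached_property
    def R2(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.records) if r.has_outcome2)

    @cached_property
    def R12(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.records) if r.complete)

    def reporting_set(self, outcome: int) -> tuple[int, ...]:
        if outcome == 1:
            return self.R1
        if outcome == 2:
            return self.R2
        raise ValueError(f"outcome must be 1 or 2, got {outcome}")

    def outcome_arrays(self, outcome: int) -> tuple[np.ndarray, np.ndarray]:
        """Effect estimates and within-study variances over the reporting set."""
        idx = self.reporting_set(outcome)
        if outcome == 1:
            y = np.array([self.records[i].y1 for i in idx], dtype=float)
            s = np.array([self.records[i].s1 for i in idx], dtype=float)
        else:
            y = np.array([self.records[i].y2 for i in idx], dtype=float)
            s = np.array([self.records[i].s2 for i in idx], dtype=float)
        return y, s**2

    @property
    def is_complete(self) -> bool:
        return len(self.R12) == len(self.records)

    def observed_count(self, outcome: int) -> int:
        """Studies genuinely reporting the outcome (pseudo-observations excluded)."""
        if outcome == 1:
            return sum(1 for r in self.records if r.has_outcome1 and not r.pseudo1)
        return sum(1 for r in self.records if r.has_outcome2 and not r.pseudo2)

    def require_rho_w(self) -> None:
        """Raise unless every study reporting both outcomes carries rho_w."""
        missing = [
            self.records[i].study_id
            for i in self.R12
            if self.records[i].rho_w is None
        ]
        if missing:
            raise ValidationError(
                "within-study correlation rho_w required but absent for studies: "
                + ", ".join(map(str, missing))
                + " (the marginal method of moments does not need rho_w)"
            )


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_CANONICAL = ("study", "y1", "s1", "y2", "s2", "rho_w")


def _cell(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        v = value.strip()
        if v == "" or v.upper() in {"NA", "NAN"}:
            return None
        return float(v)
    return float(value)


def read_dataset(path, dialect: Mapping[str, str] | None = None) -> BivariateDataset:
    """Read a study-level CSV into a validated :class:`BivariateDataset`.

    Expected columns: ``study, y1, s1, y2, s2, rho_w`` (``rho_w`` and either
    outcome pair optional), plus covariate columns prefixed ``x1_`` / ``x2_``.
    Missing cells may be blank or ``NA``.  ``dialect`` maps canonical column
    names to the names actually used in the file.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {name: dialect.get(name, name) for name in _CANONICAL}
    have = {k: v for k, v in colmap.items() if v in frame.columns}
    if not ({"y1", "s1"} <= have.keys() or {"y2", "s2"} <= have.keys()):
        raise ValidationError(
            f"{path}: need at least one outcome's (y, s) column pair; "
            f"found columns {list(frame.columns)}"
        )
    x1_cols = sorted(c for c in frame.columns if c.startswith("x1_"))
    x2_cols = sorted(c for c in frame.columns if c.startswith("x2_"))

    records: list[StudyRecord] = []
    for pos, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()

        def get(name: str):
            col = have.get(name)
            return _cell(row[col]) if col is not None else None

        study = row[have["study"]] if "study" in have else str(pos)

        def vec(cols: Sequence[str]):
            if not cols:
                return None
            vals = [_cell(row[c]) for c in cols]
            if all(v is None for v in vals):
                return None
            if any(v is None for v in vals):
                raise ValidationError(f"covariate columns {cols} partially missing")
            return tuple(vals)

        try:
            x1 = vec(x1_cols)
            x2 = vec(x2_cols)
            records.append(
                StudyRecord(
                    study_id=str(study),
                    y1=get("y1"),
                    s1=get("s1"),
                    y2=get("y2"),
                    s2=get("s2"),
                    rho_w=get("rho_w"),
                    x1=x1,
                    x2=x2,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {pos}: {exc}") from exc
    if not records:
        raise ValidationError(f"{path}: no parsable data rows")
    return BivariateDataset(tuple(records))


def write_dataset(ds: BivariateDataset, path) -> None:
    """Write a dataset back to CSV; absent cells become empty strings."""
    p1 = max((len(r.x1) for r in ds if r.x1 is not None), default=0)
    p2 = max((len(r.x2) for r in ds if r.x2 is not None), default=0)
    rows = []
    for r in ds:
        row: dict[str, object] = {
            "study": r.study_id,
            "y1": r.y1,
            "s1": r.s1,
            "y2": r.y2,
            "s2": r.s2,
            "rho_w": r.rho_w,
        }
        for k in range(p1):
            row[f"x1_{k}"] = r.x1[k] if r.x1 is not None and k < len(r.x1) else None
        for k in range(p2):
            row[f"x2_{k}"] = r.x2[k] if r.x2 is not None and k < len(r.x2) else None
        rows.append(row)
    frame = pd.DataFrame(rows)
    # repr-based float formatting round-trips exactly for finite inputs
    frame = frame.map(lambda v: "" if v is None else (repr(v) if isinstance(v, float) else v))
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MCAR augmentation
# ---------------------------------------------------------------------------


def augment_mcar(
    ds: BivariateDataset, large_variance: float = DEFAULT_LARGE_VARIANCE
) -> BivariateDataset:
    """Replace missing outcomes by zero estimates with huge variances.

    Under missing-completely-at-random, complete-data formulas applied to the
    augmented dataset converge (as ``large_variance`` grows) to the direct
    incomplete-data estimates, because the augmented observations receive
    vanishing weight.  The missing estimate is set to 0, its standard error to
    ``sqrt(large_variance)`` and, for any study where either outcome was
    absent, the within-study correlation is set to 0.
    """
    if not large_variance > 0:
        raise ValidationError(f"large_variance must be positive, got {large_variance}")
    big_se = math.sqrt(large_variance)
    out = []
    for r in ds:
        if r.complete:
            out.append(r)
            continue
        out.append(
            replace(
                r,
                y1=r.y1 if r.has_outcome1 else 0.0,
                s1=r.s1 if r.has_outcome1 else big_se,
                y2=r.y2 if r.has_outcome2 else 0.0,
                s2=r.s2 if r.has_outcome2 else big_se,
                rho_w=0.0,
                pseudo1=not r.has_outcome1,
                pseudo2=not r.has_outcome2,
            )
        )
    return BivariateDataset(tuple(out))
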