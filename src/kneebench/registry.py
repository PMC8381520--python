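"""Domain types for knee-replacement registry extracts and their CSV interchange format.

A registry extract is one row per primary procedure: which construct was
implanted, optional patient strata (gender, age at primary), follow-up time
in years, and the terminal status of that follow-up (first revision, death,
or censoring at the data-lock date).  Constructs are identified by the full
brand/fixation/bearing/constraint combination, since each of those features
is known to shift revision risk and each combination is benchmarked as a
separate entity.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ConstructKey",
    "ProcedureRecord",
    "Registry",
    "RegistrySchemaError",
    "RegistryValidationError",
    "REGISTRY_COLUMNS",
    "read_registry",
    "write_registry",
    "group_by_construct",
]

REGISTRY_COLUMNS = (
    "procedure_id",
    "brand",
    "fixation",
    "bearing",
    "constraint",
    "gender",
    "age_at_primary",
    "time_years",
    "status",
)

FIXATIONS = ("cemented", "uncemented")
BEARINGS = ("fixed", "mobile")
CONSTRAINTS = ("CR", "PS")
STATUSES = ("revision", "death", "censored")
GENDERS = ("F", "M", "unknown")


class RegistrySchemaError(ValueError):
    """The CSV header does not match the documented registry schema."""


class RegistryValidationError(ValueError):
    """One or more rows violate field-level constraints.

    Carries ``(row_number, message)`` pairs in :attr:`errors`; row numbers
    are 1-based data-row positions (header excluded).
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        detail = "; ".join(f"row {i}: {m}" for i, m in self.errors[:20])
        extra = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid registry row(s): {detail}{extra}")


@dataclass(frozen=True, order=True)
class ConstructKey:
    """Identity of a knee-replacement construct.

    The unit of comparison: a brand subdivided by fixation (cemented /
    uncemented), bearing mobility (fixed / mobile) and constraint
    (cruciate-retaining CR / posterior-stabilised PS).
    """

    brand: str
    fixation: str
    bearing: str
    constraint: str

    def __post_init__(self) -> None:
        if not self.brand:
            raise ValueError("brand must be non-empty")
        if self.fixation not in FIXATIONS:
            raise ValueError(f"fixation must be one of {FIXATIONS}, got {self.fixation!r}")
        if self.bearing not in BEARINGS:
            raise ValueError(f"bearing must be one of {BEARINGS}, got {self.bearing!r}")
        if self.constraint not in CONSTRAINTS:
            raise ValueError(f"constraint must be one of {CONSTRAINTS}, got {self.constraint!r}")

    @property
    def label(self) -> str:
        """Deterministic display label, e.g. ``"Duracon/fixed/cemented/CR"``."""
        return f"{self.brand}/{self.bearing}/{self.fixation}/{self.constraint}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class ProcedureRecord:
    """One primary knee replacement and its observed follow-up.

    ``status`` marks how follow-up ended: ``revision`` is the *first* linked
    revision only (no repeat events per procedure), ``death`` removes the
    patient from observation, ``censored`` is administrative truncation at
    the data-lock date.  ``time_years`` is the duration from primary to that
    terminal status.
    """

    procedure_id: str
    construct: ConstructKey
    time_years: float
    status: str
    gender: str = "unknown"
    age_at_primary: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time_years < 0:
            raise ValueError(f"time_years must be >= 0, got {self.time_years}")
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.age_at_primary is not None and self.age_at_primary < 0:
            raise ValueError("age_at_primary must be >= 0 when present")


@dataclass
class Registry:
    """A collection of procedure records with unique identifiers."""

    records: list[ProcedureRecord] = field(default_factory=list)
    lock_time: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [r.procedure_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate procedure_id values: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _canon(value: str) -> str:
    return value.strip().lower()


def _parse_row(i: int, row: Mapping[str, object], errors: list[tuple[int, str]]) -> Optional[ProcedureRecord]:
    def _text(col: str) -> str:
        v = row[col]
        return "" if v is None or (isinstance(v, float) and pd.isna(v)) else str(v).strip()

    problems: list[str] = []
    status = _canon(_text("status"))
    if status not in STATUSES:
        problems.append(f"unknown status {_text('status')!r}")
    fixation = _canon(_text("fixation"))
    if fixation not in FIXATIONS:
        problems.append(f"unknown fixation {_text('fixation')!r}")
    bearing = _canon(_text("bearing"))
    if bearing not in BEARINGS:
        problems.append(f"unknown bearing {_text('bearing')!r}")
    constraint = _text("constraint").upper()
    if constraint not in CONSTRAINTS:
        problems.append(f"unknown constraint {_text('constraint')!r}")
    gender = _text("gender") or "unknown"
    if gender not in GENDERS:
        g = gender.upper()
        gender = g if g in GENDERS else gender
        if gender not in GENDERS:
            problems.append(f"unknown gender {_text('gender')!r}")
    try:
        time_years = float(_text("time_years"))
        if time_years < 0:
            problems.append(f"time_years must be >= 0, got {time_years}")
    except ValueError:
        problems.append(f"unparsable time_years {_text('time_years')!r}")
        time_years = float("nan")
    age_text = _text("age_at_primary")
    age: Optional[float] = None
    if age_text:
        try:
            age = float(age_text)
        except ValueError:
            problems.append(f"unparsable age_at_primary {age_text!r}")
    if not _text("procedure_id"):
        problems.append("empty procedure_id")
    if not _text("brand"):
        problems.append("empty brand")

    if problems:
        errors.extend((i, p) for p in problems)
        return None
    return ProcedureRecord(
        procedure_id=_text("procedure_id"),
        construct=ConstructKey(_text("brand"), fixation, bearing, constraint),
        gender=gender,
        age_at_primary=age,
        time_years=time_years,
        status=status,
    )


def read_registry(path: str | Path) -> Registry:
    """Read a registry CSV, validating schema and every row.

    Raises :class:`RegistrySchemaError` if the header is wrong and
    :class:`RegistryValidationError` listing 1-based data-row numbers for any
    malformed rows.  Enum fields are canonicalised (case and surrounding
    whitespace) before validation.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise RegistrySchemaError(
            f"{path}: missing required column(s) {missing}; expected header "
            f"{','.join(REGISTRY_COLUMNS)}"
        )
    errors: list[tuple[int, str]] = []
    records: list[ProcedureRecord] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        rec = _parse_row(i, row, errors)
        if rec is not None:
            records.append(rec)
    if errors:
        raise RegistryValidationError(errors)
    return Registry(records=records)


def write_registry(registry: Registry, path: str | Path) -> None:
    """Write a registry to the documented CSV schema (round-trip safe)."""
    rows = []
    for r in registry:
        rows.append(
            {
                "procedure_id": r.procedure_id,
                "brand": r.construct.brand,
                "fixation": r.construct.fixation,
                "bearing": r.construct.bearing,
                "constraint": r.construct.constraint,
                "gender": r.gender,
                "age_at_primary": "" if r.age_at_primary is None else repr(r.age_at_primary),
                "time_years": repr(r.time_years),
                "status": r.status,
            }
        )
    frame = pd.DataFrame(rows, columns=list(REGISTRY_COLUMNS))
    frame.to_csv(path, index=False)


def group_by_construct(registry: Registry | Iterable[ProcedureRecord]) -> "OrderedDict[ConstructKey, list[ProcedureRecord]]":
    """Partition records by their full four-field construct key.

    Every record lands in exactly one group; group order follows the sorted
    construct label so downstream reports are deterministic.
    """
    groups: dict[ConstructKey, list[ProcedureRecord]] = {}
    for rec in registry:
        groups.setdefault(rec.construct, []).append(rec)
    return OrderedDict(sorted(groups.items(), key=lambda kv: kv[0].label))


def registry_to_frame(registry: Registry) -> pd.DataFrame:
    """Tidy DataFrame view of a registry (one row per procedure)."""
    return pd.DataFrame(
        {
            "procedure_id": [r.procedure_id for r in registry],
            "construct": [r.construct.label for r in registry],
            "gender": [r.gender for r in registry],
            "age_at_primary": [r.age_at_primary for r in registry],
            "time_years": [r.time_years for r in registry],
            "status": [r.status for r in registry],
        }
    )
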