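"""Test-day milk records and 210-day standardized lactation yields.

A *test-day record* is one periodic milk control for one animal: daily milk
yield (kg) plus component measurements (fat, protein, dry matter, lactose as
percent; somatic cell count as x10^3 cells/mL).  Records are grouped into
lactations and each lactation's total milk yield is standardized to a
210-days-in-milk horizon with the interval-weighted (Fleischmann) rule used
by ICAR milk recording.
"""

from __future__ import annotations

import csv
import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ValidationError

#: Documented CSV header for test-day record files (ISO-8601 dates).
RECORD_COLUMNS = (
    "animal_id",
    "farm_id",
    "lactation_no",
    "kidding_date",
    "control_date",
    "milk_kg",
    "fat_pct",
    "protein_pct",
    "dry_matter_pct",
    "lactose_pct",
    "scc",
)

#: Default standardization horizon, days in milk.
HORIZON_DIM = 210


@dataclass(frozen=True)
class TestDayRecord:
    """One milk control for one animal on one date."""

    animal_id: str
    farm_id: str
    lactation_no: int
    kidding_date: _dt.date
    control_date: _dt.date
    milk_kg: float
    fat_pct: float
    protein_pct: float
    dry_matter_pct: float
    lactose_pct: float
    scc: float

    @property
    def dim(self) -> int:
        """Days in milk at the control (1-based: first day after kidding)."""
        return (self.control_date - self.kidding_date).days

    def problems(self) -> list[str]:
        """Return invariant violations, empty when the record is valid."""
        out = []
        if self.lactation_no < 1:
            out.append(f"lactation_no must be >= 1, got {self.lactation_no}")
        if self.dim < 1:
            out.append(
                f"control_date {self.control_date} must be at least one day "
                f"after kidding_date {self.kidding_date}"
            )
        if self.milk_kg < 0:
            out.append(f"negative milk_kg {self.milk_kg}")
        for name in ("fat_pct", "protein_pct", "dry_matter_pct", "lactose_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                out.append(f"{name}={v} outside [0, 100]")
        if self.scc < 0:
            out.append(f"negative scc {self.scc}")
        return out


@dataclass(frozen=True)
class LactationSeries:
    """Time-ordered controls of one lactation plus its standardized yield.

    ``d1`` is the interval from kidding to first control and ``d2`` the
    interval from the penultimate to the last control; ``total_yield_210``
    is the Fleischmann-standardized 210-day milk yield in kg.
    """

    animal_id: str
    lactation_no: int
    kidding_date: _dt.date
    records: tuple[TestDayRecord, ...]
    d1: int = field(init=False)
    d2: int = field(init=False)
    total_yield_210: float = field(init=False)

    def __post_init__(self):
        dims = [r.dim for r in self.records]
        object.__setattr__(self, "d1", dims[0])
        object.__setattr__(self, "d2", dims[-1] - dims[-2] if len(dims) > 1 else 0)
        object.__setattr__(
            self,
            "total_yield_210",
            fleischmann_210(dims, [r.milk_kg for r in self.records]),
        )

    @property
    def dims(self) -> np.ndarray:
        return np.array([r.dim for r in self.records], dtype=float)

    def values(self, trait: str) -> np.ndarray:
        return np.array([getattr(r, trait) for r in self.records], dtype=float)


def _parse_row(row: dict, line_no: int) -> TestDayRecord:
    try:
        return TestDayRecord(
            animal_id=row["animal_id"].strip(),
            farm_id=row["farm_id"].strip(),
            lactation_no=int(row["lactation_no"]),
            kidding_date=_dt.date.fromisoformat(row["kidding_date"].strip()),
            control_date=_dt.date.fromisoformat(row["control_date"].strip()),
            milk_kg=float(row["milk_kg"]),
            fat_pct=float(row["fat_pct"]),
            protein_pct=float(row["protein_pct"]),
            dry_matter_pct=float(row["dry_matter_pct"]),
            lactose_pct=float(row["lactose_pct"]),
            scc=float(row["scc"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"line {line_no}: unparseable field ({exc})") from exc


def read_records(path, *, skip_invalid: bool = False) -> list[TestDayRecord]:
    """Read and validate a test-day record CSV.

    Invalid rows raise :class:`ValidationError` listing every offending line
    and reason; with ``skip_invalid=True`` they are dropped with a warning
    instead.  A missing required column raises :class:`FormatError`.
    """
    records, rejects = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in RECORD_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for line_no, row in enumerate(reader, start=2):
            try:
                rec = _parse_row(row, line_no)
            except ValidationError as exc:
                rejects.append(str(exc))
                continue
            probs = rec.problems()
            if probs:
                rejects.append(f"line {line_no}: " + "; ".join(probs))
            else:
                records.append(rec)
    if rejects:
        msg = f"{path}: {len(rejects)} invalid row(s):\n" + "\n".join(rejects)
        if skip_invalid:
            warnings.warn(msg, stacklevel=2)
        else:
            raise ValidationError(msg)
    return records


def write_records(records, path) -> None:
    """Write records to CSV with the documented header, ISO-8601 dates."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.animal_id,
                    r.farm_id,
                    r.lactation_no,
                    r.kidding_date.isoformat(),
                    r.control_date.isoformat(),
                    repr(r.milk_kg),
                    repr(r.fat_pct),
                    repr(r.protein_pct),
                    repr(r.dry_matter_pct),
                    repr(r.lactose_pct),
                    repr(r.scc),
                ]
            )


def build_lactations(records) -> list[LactationSeries]:
    """Group validated records into time-sorted lactation series.

    Raises :class:`ValidationError` listing any duplicated
    (animal, lactation, control date) triple.
    """
    groups: dict[tuple, list[TestDayRecord]] = {}
    for r in records:
        groups.setdefault((r.animal_id, r.lactation_no), []).append(r)
    dupes = []
    series = []
    for (animal, lact), recs in sorted(groups.items()):
        recs = sorted(recs, key=lambda r: r.control_date)
        seen = set()
        for r in recs:
            key = (animal, lact, r.control_date)
            if key in seen:
                dupes.append(key)
            seen.add(key)
        series.append(
            LactationSeries(
                animal_id=animal,
                lactation_no=lact,
                kidding_date=recs[0].kidding_date,
                records=tuple(recs),
            )
        )
    if dupes:
        raise ValidationError(f"duplicate (animal, lactation, date) controls: {dupes}")
    return series


def fleischmann_210(dims, yields, horizon: int = HORIZON_DIM) -> float:
    """Interval-weighted (Fleischmann) total yield, truncated at ``horizon``.

    total = M1*d1 + sum((Mi + Mi+1)/2 * (di+1 - di)) + (horizon - dlast)*Mlast

    Controls recorded after the horizon are ignored, so the result depends
    only on in-horizon controls; the last in-horizon control extends at its
    own daily yield to the horizon.
    """
    pairs = [(d, m) for d, m in zip(dims, yields) if d <= horizon]
    if not pairs:
        raise ValidationError("no controls at or before the horizon")
    total = pairs[0][1] * pairs[0][0]
    for (d0, m0), (d1, m1) in zip(pairs, pairs[1:]):
        total += 0.5 * (m0 + m1) * (d1 - d0)
    total += (horizon - pairs[-1][0]) * pairs[-1][1]
    return float(total)


def standardize_210(series: LactationSeries, horizon: int = HORIZON_DIM) -> float:
    """Standardized total milk yield (kg) of one lactation."""
    return fleischmann_210(
        [r.dim for r in series.records],
        [r.milk_kg for r in series.records],
        horizon,
    )
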