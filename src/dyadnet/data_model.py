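"""Domain types and I/O for focal-sampling association data.

A *focal sample* follows one individual for a fixed interval and records
every group member within 10 m, within 1 m, and every grooming partner.
This module defines the core types (:class:`Individual`,
:class:`FocalRecord`, :class:`Dyad`), delimited-text readers and writers
for rosters and focal-record streams, and dyad enumeration with maternal
kinship and age-difference covariates.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from datetime import date as Date
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger("dyadnet")

SEX_CODES = ("F", "M")
SEX_TYPES = ("FF", "MF", "MM")

#: Subjects younger than this (years) are flagged as excluded on load:
#: their location is contingent on their mother's, so they carry no
#: independent association signal.
DEFAULT_MIN_AGE = 4.0


@dataclass(frozen=True, order=True)
class Individual:
    """One study subject."""

    id: str
    sex: str  # "F" or "M"
    age_years: float  # age at the study midpoint, decimal years
    group_id: str
    maternal_line: str
    mother_id: Optional[str] = None
    excluded: bool = False  # under minimum age; kept in roster, never analysed

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ValueError(f"unknown sex code {self.sex!r} for individual {self.id!r}")
        if self.age_years < 0:
            raise ValueError(f"negative age for individual {self.id!r}")


@dataclass(frozen=True)
class FocalRecord:
    """One focal sample: the focal's social surroundings at one time point."""

    date: Date
    focal_id: str
    within10m: frozenset
    within1m: frozenset
    grooming: frozenset

    def __post_init__(self) -> None:
        if self.focal_id in self.within10m or self.focal_id in self.within1m or self.focal_id in self.grooming:
            raise ValueError(f"focal {self.focal_id!r} appears in its own associate set on {self.date}")
        if not self.within1m <= self.within10m:
            raise ValueError(f"within1m not nested in within10m for focal {self.focal_id!r} on {self.date}")


@dataclass(frozen=True, order=True)
class Dyad:
    """An unordered within-group pair, canonically ordered lexicographically."""

    member_a: str
    member_b: str
    sex_type: str  # FF, MF, MM
    kin: bool
    age_diff: float
    group_id: str

    def __post_init__(self) -> None:
        if not self.member_a < self.member_b:
            raise ValueError(f"dyad members not in canonical order: {self.member_a!r}, {self.member_b!r}")
        if self.sex_type not in SEX_TYPES:
            raise ValueError(f"invalid sex_type {self.sex_type!r}")
        if self.age_diff < 0:
            raise ValueError("age_diff must be non-negative")


def maternal_kin(a: Individual, b: Individual) -> bool:
    """Maternal relatedness: mother-offspring or maternal siblings.

    When declared mother ids are available for either member the precise
    closure is used (so grandmother/aunt/uncle links along the same line
    do not count as kin); when neither member carries a mother id, shared
    maternal line is used as the fallback.
    """
    if a.mother_id is None and b.mother_id is None:
        return a.maternal_line == b.maternal_line
    if a.mother_id == b.id or b.mother_id == a.id:
        return True
    return a.mother_id is not None and a.mother_id == b.mother_id


def dyad_sex_type(sex_a: str, sex_b: str) -> str:
    """FF / MF / MM label for a pair; mixed pairs are always labelled MF."""
    pair = "".join(sorted((sex_a, sex_b)))
    return "MF" if pair == "FM" else pair


def make_dyad(a: Individual, b: Individual) -> Dyad:
    if a.id == b.id:
        raise ValueError(f"self-dyad for {a.id!r}")
    if a.group_id != b.group_id:
        raise ValueError(f"cross-group dyad {a.id!r}/{b.id!r}")
    if a.id > b.id:
        a, b = b, a
    return Dyad(
        member_a=a.id,
        member_b=b.id,
        sex_type=dyad_sex_type(a.sex, b.sex),
        kin=maternal_kin(a, b),
        age_diff=abs(a.age_years - b.age_years),
        group_id=a.group_id,
    )


# ---------------------------------------------------------------------------
# Roster I/O

_ROSTER_REQUIRED = ("id", "sex", "group", "maternal_line")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_roster(
    path,
    group_filter: Optional[str] = None,
    min_age: float = DEFAULT_MIN_AGE,
    reference_date: Optional[Date] = None,
) -> list:
    """Load and validate a roster from delimited text.

    Required columns: ``id``, ``sex``, ``group``, ``maternal_line``, and one
    of ``age_years`` or ``birthdate`` (the latter needs *reference_date* to
    convert to decimal years). Optional: ``mother_id``.

    Individuals younger than *min_age* are returned with ``excluded=True``
    rather than dropped, so exclusions stay visible in the run log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)
    individuals: list = []
    seen: set = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip() for c in (reader.fieldnames or [])]
        missing = [c for c in _ROSTER_REQUIRED if c not in cols]
        if "age_years" not in cols and "birthdate" not in cols:
            missing.append("age_years|birthdate")
        if missing:
            raise ValueError(f"roster {path} missing required columns: {', '.join(missing)}")
        for row in reader:
            iid = row["id"].strip()
            if not iid:
                continue
            if iid in seen:
                raise ValueError(f"duplicate individual id {iid!r} in roster {path}")
            seen.add(iid)
            if row.get("age_years") not in (None, ""):
                age = float(row["age_years"])
            else:
                if reference_date is None:
                    raise ValueError("roster uses birthdate column but no reference_date was given")
                born = datetime.strptime(row["birthdate"].strip(), "%Y-%m-%d").date()
                age = (reference_date - born).days / 365.25
            mother = row.get("mother_id") or None
            if mother is not None:
                mother = mother.strip() or None
            ind = Individual(
                id=iid,
                sex=row["sex"].strip(),
                age_years=age,
                group_id=row["group"].strip(),
                maternal_line=row["maternal_line"].strip(),
                mother_id=mother,
                excluded=age < min_age,
            )
            if ind.excluded:
                logger.warning("roster: individual %s aged %.2f flagged excluded (min age %.1f)", iid, age, min_age)
            if group_filter is None or ind.group_id == group_filter:
                individuals.append(ind)
    if not individuals:
        logger.warning("roster %s yielded no individuals", path)
    return individuals


def write_roster(individuals: Iterable[Individual], path, delimiter: str = ",") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id", "sex", "age_years", "group", "maternal_line", "mother_id"])
        for ind in sorted(individuals):
            writer.writerow(
                [ind.id, ind.sex, f"{ind.age_years:.6g}", ind.group_id, ind.maternal_line, ind.mother_id or ""]
            )


# ---------------------------------------------------------------------------
# Focal record I/O

_FOCAL_REQUIRED = ("date", "focal_id", "within10m", "within1m", "grooming")
SET_DELIMITER = ";"


def _parse_idset(field: str) -> frozenset:
    field = field.strip()
    if not field:
        return frozenset()
    return frozenset(s.strip() for s in field.split(SET_DELIMITER) if s.strip())


def load_focal_records(
    path,
    roster: Sequence[Individual],
    study_window: Optional[tuple] = None,
) -> list:
    """Load focal records, validating every id against the roster.

    Within-1 m associates missing from the 10 m set are promoted into it
    (closeness implies co-residence), as are grooming partners missing from
    the 1 m set (grooming requires contact); both promotions are logged.
    Records dated outside *study_window* (inclusive ``(start, end)`` dates)
    are excluded with a warning.
    """
    path = Path(path)
    known = {ind.id for ind in roster}
    delim = _sniff_delimiter(path)
    records: list = []
    n_outside = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip() for c in (reader.fieldnames or [])]
        missing = [c for c in _FOCAL_REQUIRED if c not in cols]
        if missing:
            raise ValueError(f"focal file {path} missing required columns: {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            day = datetime.strptime(row["date"].strip(), "%Y-%m-%d").date()
            focal = row["focal_id"].strip()
            w10 = _parse_idset(row["within10m"])
            w1 = _parse_idset(row["within1m"])
            grm = _parse_idset(row["grooming"])
            for iid in {focal} | w10 | w1 | grm:
                if iid not in known:
                    raise ValueError(f"unknown individual id {iid!r} at {path}:{lineno}")
            if focal in w10 | w1 | grm:
                raise ValueError(f"focal {focal!r} listed in its own associate set at {path}:{lineno}")
            if study_window is not None and not (study_window[0] <= day <= study_window[1]):
                n_outside += 1
                logger.warning("focal record at %s:%d dated %s outside study window; excluded", path, lineno, day)
                continue
            if not grm <= w1:
                logger.warning("grooming partners %s promoted into within1m at %s:%d", sorted(grm - w1), path, lineno)
                w1 = w1 | grm
            if not w1 <= w10:
                logger.warning("within1m ids %s promoted into within10m at %s:%d", sorted(w1 - w10), path, lineno)
                w10 = w10 | w1
            records.append(FocalRecord(date=day, focal_id=focal, within10m=w10, within1m=w1, grooming=grm))
    if n_outside:
        logger.warning("%d focal records excluded as outside the study window", n_outside)
    return records


def write_focal_records(records: Iterable[FocalRecord], path, delimiter: str = ",") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(_FOCAL_REQUIRED))
        for rec in records:
            writer.writerow(
                [
                    rec.date.isoformat(),
                    rec.focal_id,
                    SET_DELIMITER.join(sorted(rec.within10m)),
                    SET_DELIMITER.join(sorted(rec.within1m)),
                    SET_DELIMITER.join(sorted(rec.grooming)),
                ]
            )


# ---------------------------------------------------------------------------
# Dyad enumeration


def active_roster(roster: Sequence[Individual]) -> list:
    """Roster members that enter the analysis (excluded flags removed)."""
    return [ind for ind in roster if not ind.excluded]


def enumerate_dyads(roster: Sequence[Individual]) -> list:
    """All n(n-1)/2 unordered pairs of one group's active members.

    Raises if the roster mixes groups or has fewer than two active members.
    """
    active = sorted(active_roster(roster))
    if len(active) < 2:
        raise ValueError(f"need at least 2 active individuals to form dyads, got {len(active)}")
    groups = {ind.group_id for ind in active}
    if len(groups) > 1:
        raise ValueError(f"enumerate_dyads requires a single group, got {sorted(groups)}")
    out = []
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            out.append(make_dyad(a, b))
    return out


def enumerate_dyads_by_group(roster: Sequence[Individual]) -> list:
    """Within-group dyads across every group in the roster, concatenated."""
    by_group: dict = {}
    for ind in active_roster(roster):
        by_group.setdefault(ind.group_id, []).append(ind)
    dyads: list = []
    for gid in sorted(by_group):
        if len(by_group[gid]) >= 2:
            dyads.extend(enumerate_dyads(by_group[gid]))
    return dyads


def dyad_sex_counts(dyads: Iterable[Dyad]) -> dict:
    counts = {st: 0 for st in SEX_TYPES}
    for d in dyads:
        counts[d.sex_type] += 1
    return counts
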