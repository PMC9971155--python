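"""Daily 1/0 binarization and simple-ratio association indices.

The sampling period is the calendar date: a dyad scores 1 on a day if it was
observed associating at least once that day on the chosen stream (from either
member's focal samples), else 0. The simple-ratio index for a dyad is

    SRI = x / (x + Y_AB + Y_A + Y_B)

with x the number of days the pair was observed associated, Y_A / Y_B the
days only one member was identified, and Y_AB the days both were identified
but not associated. "Identified" on a day means focal at least once that day
or recorded in any focal's 10 m set — the most inclusive reading of
gambit-of-the-group focal data — and is measure-independent, so the three
streams (10 m party, 1 m direct, grooming) share their denominators.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .data_model import Dyad, FocalRecord, Individual, active_roster, enumerate_dyads_by_group

logger = logging.getLogger("dyadnet")

MEASURES = ("party10m", "direct1m", "grooming")

__all__ = [
    "MEASURES",
    "SamplingCounts",
    "AssociationMatrix",
    "DailyStream",
    "build_daily_stream",
    "binarize_daily",
    "tally_counts",
    "simple_ratio",
    "build_matrix",
    "dyad_table",
    "hurdle_split",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class SamplingCounts:
    """Per-dyad day tallies feeding the simple-ratio index."""

    x: int
    y_a: int
    y_b: int
    y_ab: int

    def __post_init__(self) -> None:
        if min(self.x, self.y_a, self.y_b, self.y_ab) < 0:
            raise ValueError("sampling counts must be non-negative")

    @property
    def denominator(self) -> int:
        return self.x + self.y_a + self.y_b + self.y_ab


@dataclass
class AssociationMatrix:
    """Symmetric dyad-indexed SRI matrix for one measure."""

    measure: str
    ids: List[str]  # canonical (sorted) roster order
    values: np.ndarray  # (n, n) float, diagonal NaN
    denominators: np.ndarray  # (n, n) int, days with >= 1 member identified

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def _record_sets(rec: FocalRecord, measure: str) -> frozenset:
    if measure == "party10m":
        return rec.within10m
    if measure == "direct1m":
        return rec.within1m
    if measure == "grooming":
        return rec.grooming
    raise ValueError(f"unknown measure {measure!r}")


@dataclass
class DailyStream:
    """Binarized per-day event and identification arrays for all measures.

    ``events[measure]`` is (n_days, n_dyads) boolean; ``identified`` is
    (n_days, n_individuals) boolean; ``eligible`` marks dyad-days with at
    least one member identified (the SRI denominator pattern, shared across
    measures and invariant under datastream permutation).
    """

    ids: List[str]
    dates: List
    dyads: List[Dyad]
    identified: np.ndarray
    events: Dict[str, np.ndarray]

    _idx: Dict[str, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self._idx = {iid: k for k, iid in enumerate(self.ids)}
        self.dyad_a = np.array([self._idx[d.member_a] for d in self.dyads], dtype=np.int64)
        self.dyad_b = np.array([self._idx[d.member_b] for d in self.dyads], dtype=np.int64)

    @property
    def eligible(self) -> np.ndarray:
        return self.identified[:, self.dyad_a] | self.identified[:, self.dyad_b]

    def sri(self, measure: str, events: np.ndarray = None) -> np.ndarray:
        """SRI per dyad; zero-denominator dyads score 0 (flagged in the log)."""
        ev = self.events[measure] if events is None else events
        elig = self.eligible
        x = (ev & elig).sum(axis=0).astype(float)
        denom = elig.sum(axis=0).astype(float)
        never = denom == 0
        if never.any():
            logger.warning("%d dyads never had an identified member; SRI set to 0", int(never.sum()))
        out = np.zeros(len(self.dyads))
        np.divide(x, denom, out=out, where=~never)
        return out


def build_daily_stream(records: Sequence[FocalRecord], roster: Sequence[Individual]) -> DailyStream:
    """Binarize a validated record sequence into day-level arrays."""
    if not records:
        raise ValueError("empty focal record sequence")
    active = active_roster(roster)
    ids = sorted(ind.id for ind in active)
    idx = {iid: k for k, iid in enumerate(ids)}
    dyads = enumerate_dyads_by_group(roster)
    dyad_idx = {(d.member_a, d.member_b): k for k, d in enumerate(dyads)}
    dates = sorted({rec.date for rec in records})
    date_idx = {d: k for k, d in enumerate(dates)}
    n_days, n_ids, n_dyads = len(dates), len(ids), len(dyads)

    identified = np.zeros((n_days, n_ids), dtype=bool)
    events = {m: np.zeros((n_days, n_dyads), dtype=bool) for m in MEASURES}
    for rec in records:
        t = date_idx[rec.date]
        if rec.focal_id in idx:
            identified[t, idx[rec.focal_id]] = True
        for iid in rec.within10m:
            if iid in idx:
                identified[t, idx[iid]] = True
        for measure in MEASURES:
            for iid in _record_sets(rec, measure):
                pair = (rec.focal_id, iid) if rec.focal_id < iid else (iid, rec.focal_id)
                k = dyad_idx.get(pair)
                if k is not None:
                    events[measure][t, k] = True
    return DailyStream(ids=ids, dates=dates, dyads=dyads, identified=identified, events=events)


def binarize_daily(
    records: Sequence[FocalRecord], roster: Sequence[Individual], measure: str
) -> Tuple[Dict, Dict]:
    """Spec-level view: per-date associated dyad sets and identified id sets."""
    stream = build_daily_stream(records, roster)
    ev = stream.events[measure]
    events_by_day: Dict = {}
    identified_by_day: Dict = {}
    for t, day in enumerate(stream.dates):
        events_by_day[day] = {
            (stream.dyads[k].member_a, stream.dyads[k].member_b) for k in np.flatnonzero(ev[t])
        }
        identified_by_day[day] = {stream.ids[i] for i in np.flatnonzero(stream.identified[t])}
    return events_by_day, identified_by_day


def tally_counts(events_by_day: Dict, identified_by_day: Dict, dyad: Dyad) -> SamplingCounts:
    """Day tallies for one dyad; days with neither member identified count nowhere."""
    x = y_a = y_b = y_ab = 0
    pair = (dyad.member_a, dyad.member_b)
    for day, ident in identified_by_day.items():
        a_seen = dyad.member_a in ident
        b_seen = dyad.member_b in ident
        if not (a_seen or b_seen):
            continue
        if pair in events_by_day.get(day, ()):  # associated that day
            x += 1
        elif a_seen and b_seen:
            y_ab += 1
        elif a_seen:
            y_a += 1
        else:
            y_b += 1
    return SamplingCounts(x=x, y_a=y_a, y_b=y_b, y_ab=y_ab)


def simple_ratio(counts: SamplingCounts) -> float:
    """x / (x + Y_AB + Y_A + Y_B); 0 (flagged) when the dyad was never observable."""
    denom = counts.denominator
    if denom == 0:
        logger.warning("simple_ratio: zero denominator (dyad never identified); returning 0")
        return 0.0
    return counts.x / denom


def build_matrix(
    records: Sequence[FocalRecord], roster: Sequence[Individual], measure: str
) -> AssociationMatrix:
    stream = build_daily_stream(records, roster)
    return matrix_from_stream(stream, measure)


def matrix_from_stream(stream: DailyStream, measure: str) -> AssociationMatrix:
    n = len(stream.ids)
    values = np.full((n, n), np.nan)
    denom_m = np.zeros((n, n), dtype=int)
    sri = stream.sri(measure)
    denom = stream.eligible.sum(axis=0)
    for k in range(len(stream.dyads)):
        i, j = stream.dyad_a[k], stream.dyad_b[k]
        values[i, j] = values[j, i] = sri[k]
        denom_m[i, j] = denom_m[j, i] = denom[k]
    return AssociationMatrix(measure=measure, ids=list(stream.ids), values=values, denominators=denom_m)


def dyad_table(records: Sequence[FocalRecord], roster: Sequence[Individual]) -> pd.DataFrame:
    """Long-format dyad table: covariates plus SRI per measure.

    One row per unordered dyad (canonical member order); columns
    ``sri_party``, ``sri_direct``, ``sri_groom`` and the shared denominator.
    """
    stream = build_daily_stream(records, roster)
    return table_from_stream(stream)


def table_from_stream(stream: DailyStream) -> pd.DataFrame:
    rows = {
        "member_a": [d.member_a for d in stream.dyads],
        "member_b": [d.member_b for d in stream.dyads],
        "sex_type": [d.sex_type for d in stream.dyads],
        "kin": [d.kin for d in stream.dyads],
        "age_diff": [d.age_diff for d in stream.dyads],
        "group_id": [d.group_id for d in stream.dyads],
        "sri_party": stream.sri("party10m"),
        "sri_direct": stream.sri("direct1m"),
        "sri_groom": stream.sri("grooming"),
        "denominator": stream.eligible.sum(axis=0),
    }
    return pd.DataFrame(rows)


def hurdle_split(matrix: AssociationMatrix, dyads: Sequence[Dyad]) -> Tuple[Dict, Dict]:
    """Split a matrix into hurdle parts: occurrence (0/1) and nonzero magnitudes."""
    occurrence: Dict = {}
    magnitude: Dict = {}
    for d in dyads:
        v = matrix.value(d.member_a, d.member_b)
        occurrence[(d.member_a, d.member_b)] = int(v > 0)
        if v > 0:
            magnitude[(d.member_a, d.member_b)] = v
    if not magnitude:
        logger.warning("hurdle_split: all SRI values are zero; magnitude stage is empty")
    return occurrence, magnitude


# ---------------------------------------------------------------------------
# Matrix I/O (delimited square matrix with id header row/column)


def write_matrix(matrix: AssociationMatrix, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep=delimiter)


def read_matrix(path, measure: str, delimiter: str = ",") -> AssociationMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    ids = [str(c) for c in df.columns]
    return AssociationMatrix(
        measure=measure, ids=ids, values=df.to_numpy(dtype=float), denominators=np.zeros((len(ids), len(ids)), int)
    )
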