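"""Reproductive-state segmentation and per-sample state labeling.

Female baboons move through three externally observable reproductive
states — ovarian cycling, pregnancy, and postpartum amenorrhea (PPA) —
and a "reproductive event" is one cycling → pregnancy → PPA sequence,
from a cycling resumption to the next one.  This module segments a
female's milestone calendar into state intervals, assigns each fecal
sample a state, phase, and day-within-state, and applies the study's
inclusion/exclusion rules with an auditable reason vocabulary.

Conventions
-----------
* Dates are integer study days (``datetime.date`` inputs are converted to
  proleptic ordinals on ingestion, so calendar CSVs work transparently).
* State intervals are half-open ``[start, end)``; a censored trailing
  interval has ``end=None``.
* A "month" is 30 days everywhere.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .config import LifeHistoryConfig

__all__ = [
    "Milestone", "State", "ExclusionReason", "CycleAnchors",
    "FemaleTimeline", "StateInterval", "TimelineError", "FilterReport",
    "segment_timeline", "assign_cycle_phase", "assign_trimester",
    "assign_ppa_period", "assign_labels", "apply_exclusions",
    "reproductive_day", "read_milestones",
]


class Milestone(str, Enum):
    CYCLE_ONSET = "CYCLE_ONSET"          # onset of menses / anestrus
    SWELLING_ONSET = "SWELLING_ONSET"    # start of follicular swelling
    DETURGESCENCE = "DETURGESCENCE"      # swelling deflation (ovulation end)
    CONCEPTION = "CONCEPTION"
    LIVE_BIRTH = "LIVE_BIRTH"
    MISCARRIAGE = "MISCARRIAGE"
    INFANT_DEATH = "INFANT_DEATH"
    RESUMPTION = "RESUMPTION"            # cycling resumption (event start)
    WEANING = "WEANING"


class State(str, Enum):
    CYCLING = "CYCLING"
    PREGNANT = "PREGNANT"
    PPA = "PPA"


class ExclusionReason(str, Enum):
    FIRST_WEEK_POSTPARTUM = "first_week_postpartum"
    POST_INFANT_DEATH = "post_infant_death_window"
    ABERRANT_CYCLE_LENGTH = "aberrant_cycle_length"
    LONG_PPA = "long_ppa"
    MISCARRIAGE_PREGNANCY = "miscarriage_pregnancy"
    POST_MISCARRIAGE_PPA = "post_miscarriage_ppa"
    OUT_OF_RANGE = "outside_timeline"


class TimelineError(ValueError):
    """A milestone calendar violates an ordering or plausibility rule."""


def _day(x) -> int:
    """Coerce a date-like to an integer study day."""
    if isinstance(x, _dt.datetime):
        return x.date().toordinal()
    if isinstance(x, _dt.date):
        return x.toordinal()
    if isinstance(x, pd.Timestamp):
        return x.date().toordinal()
    return int(x)


@dataclass(frozen=True)
class CycleAnchors:
    """Milestone anchors of one ovarian cycle.

    ``anestrus_onset`` (the next menses) and ``cycle_end`` (the next
    swelling onset, or the end of the cycling interval) may be missing
    for a censored final cycle.
    """

    swelling_onset: int
    deturgescence: int
    anestrus_onset: int | None = None
    cycle_end: int | None = None

    @property
    def swelling_len(self) -> int:
        return self.deturgescence - self.swelling_onset


@dataclass
class FemaleTimeline:
    """Per-female calendar of reproductive milestones."""

    female_id: str
    milestones: list[tuple[int, Milestone]]
    birth_date: int | None = None

    def __post_init__(self) -> None:
        self.milestones = [(_day(d), Milestone(k)) for d, k in self.milestones]
        if self.birth_date is not None:
            self.birth_date = _day(self.birth_date)
        for (d0, k0), (d1, k1) in zip(self.milestones, self.milestones[1:]):
            if d1 < d0:
                raise TimelineError(
                    f"{self.female_id}: milestones out of order: "
                    f"({k0.value} on day {d0}) before ({k1.value} on day {d1})"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.milestones[0][0], self.milestones[-1][0]


@dataclass
class StateInterval:
    """One reproductive-state interval ``[start, end)`` of one female."""

    female_id: str
    event_id: str
    state: State
    start: int
    end: int | None                      # None = censored
    cycles: list[CycleAnchors] = field(default_factory=list)
    conception: int | None = None
    birth: int | None = None
    resumption: int | None = None
    weaning: int | None = None
    infant_death: int | None = None
    miscarriage: bool = False
    after_miscarriage: bool = False

    def contains(self, day: int) -> bool:
        return day >= self.start and (self.end is None or day < self.end)

    @property
    def length(self) -> int | None:
        return None if self.end is None else self.end - self.start


def read_milestones(path) -> list[FemaleTimeline]:
    """Read a tidy milestone CSV (female_id, date, kind), one per row."""
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for fid, grp in df.groupby("female_id", sort=True):
        grp = grp.sort_values("date")
        ms = [(d, Milestone(k)) for d, k in zip(grp["date"], grp["kind"])]
        out.append(FemaleTimeline(str(fid), ms))
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

_STATE_STARTERS = {
    Milestone.RESUMPTION: State.CYCLING,
    Milestone.CONCEPTION: State.PREGNANT,
    Milestone.LIVE_BIRTH: State.PPA,
    Milestone.MISCARRIAGE: State.PPA,
}


def segment_timeline(timeline: FemaleTimeline) -> list[StateInterval]:
    """Segment a milestone calendar into non-overlapping state intervals.

    An event id groups the cycling → pregnancy → PPA triplet of one
    reproductive event; the trailing interval is left open (censored).

    Raises
    ------
    TimelineError
        If milestones are out of order, or a LIVE_BIRTH/MISCARRIAGE has
        no preceding CONCEPTION in the same event.
    """
    ms = timeline.milestones
    if not ms:
        raise TimelineError(f"{timeline.female_id}: empty timeline")

    intervals: list[StateInterval] = []
    event_no = 0
    cur: StateInterval | None = None
    pending_miscarriage = False
    # cycle anchor accumulation inside a CYCLING interval
    open_cycle: dict | None = None

    def close(day: int) -> None:
        nonlocal cur, open_cycle
        if cur is not None:
            _flush_cycle(cur, open_cycle, day)
            open_cycle = None
            cur.end = day
            intervals.append(cur)
            cur = None

    def event_id() -> str:
        return f"{timeline.female_id}:E{event_no}"

    for day, kind in ms:
        if kind == Milestone.RESUMPTION:
            close(day)
            event_no += 1
            pending_miscarriage = False
            cur = StateInterval(timeline.female_id, event_id(),
                                State.CYCLING, day, None, resumption=day)
        elif kind == Milestone.CONCEPTION:
            if cur is None:  # timeline starting mid-event
                event_no += 1
            close(day)
            cur = StateInterval(timeline.female_id, event_id(),
                                State.PREGNANT, day, None, conception=day)
        elif kind in (Milestone.LIVE_BIRTH, Milestone.MISCARRIAGE):
            if cur is None or cur.state != State.PREGNANT:
                raise TimelineError(
                    f"{timeline.female_id}: {kind.value} on day {day} "
                    "without a preceding CONCEPTION"
                )
            conception = cur.conception
            if kind == Milestone.MISCARRIAGE:
                cur.miscarriage = True
                pending_miscarriage = True
            close(day)
            cur = StateInterval(
                timeline.female_id, event_id(), State.PPA, day, None,
                conception=conception, birth=day,
                after_miscarriage=pending_miscarriage,
            )
        elif kind == Milestone.INFANT_DEATH:
            if cur is not None and cur.state == State.PPA:
                cur.infant_death = day
        elif kind == Milestone.WEANING:
            if cur is not None and cur.state == State.PPA:
                cur.weaning = day
        elif kind in (Milestone.SWELLING_ONSET, Milestone.CYCLE_ONSET,
                      Milestone.DETURGESCENCE):
            if cur is None:
                event_no += 1
                cur = StateInterval(timeline.female_id, event_id(),
                                    State.CYCLING, day, None)
            if cur.state != State.CYCLING:
                raise TimelineError(
                    f"{timeline.female_id}: cycle milestone {kind.value} on "
                    f"day {day} inside a {cur.state.value} interval"
                )
            open_cycle = _feed_cycle(cur, open_cycle, day, kind,
                                     timeline.female_id)

    if cur is not None:
        _flush_cycle(cur, open_cycle, None)
        intervals.append(cur)  # censored

    # PPA intervals of an event end at the next event's resumption
    for iv, nxt in zip(intervals, intervals[1:]):
        if iv.state == State.PPA and nxt.state == State.CYCLING:
            iv.resumption = nxt.start
    return intervals


def _feed_cycle(interval, open_cycle, day, kind, fid):
    """Accumulate cycle anchors inside a cycling interval."""
    if kind == Milestone.SWELLING_ONSET:
        if open_cycle is not None:
            _flush_cycle(interval, open_cycle, day)
        return {"swelling_onset": day}
    if open_cycle is None:
        # cycle milestone before the first swelling onset: tolerated as a
        # partial leading cycle (deturgescence without onset is an error)
        if kind == Milestone.DETURGESCENCE:
            raise TimelineError(
                f"{fid}: DETURGESCENCE on day {day} without SWELLING_ONSET")
        return None
    if kind == Milestone.DETURGESCENCE:
        open_cycle["deturgescence"] = day
    elif kind == Milestone.CYCLE_ONSET:
        open_cycle["anestrus_onset"] = day
    return open_cycle


def _flush_cycle(interval, open_cycle, end_day):
    if open_cycle is None:
        return
    if "deturgescence" in open_cycle:
        interval.cycles.append(CycleAnchors(
            swelling_onset=open_cycle["swelling_onset"],
            deturgescence=open_cycle["deturgescence"],
            anestrus_onset=open_cycle.get("anestrus_onset"),
            cycle_end=end_day,
        ))
    # a swelling onset with no deturgescence (censored cycle) is dropped


# ---------------------------------------------------------------------------
# phase assignment
# ---------------------------------------------------------------------------

def assign_cycle_phase(sample_day: int, cycle: CycleAnchors,
                       config: LifeHistoryConfig | None = None) -> str:
    """Assign an ovarian-cycle phase.

    The periovulatory phase is the five days immediately preceding
    deturgescence; the day of deturgescence itself opens the luteal
    phase.  Anestrus runs from the next menses to the cycle's end.
    """
    config = config or LifeHistoryConfig()
    d = _day(sample_day)
    peri_start = max(cycle.swelling_onset,
                     cycle.deturgescence - config.periovulatory_days)
    if cycle.cycle_end is not None and d >= cycle.cycle_end:
        raise ValueError(f"day {d} outside cycle ending {cycle.cycle_end}")
    if d < cycle.swelling_onset:
        raise ValueError(f"day {d} precedes swelling onset "
                         f"{cycle.swelling_onset}")
    if d < peri_start:
        return "follicular"
    if d < cycle.deturgescence:
        return "periovulatory"
    anestrus = cycle.anestrus_onset
    if anestrus is None or d < anestrus:
        return "luteal"
    return "anestrus"


def assign_trimester(days_since_conception: int,
                     config: LifeHistoryConfig | None = None) -> str:
    """Trimester from days since conception: [0,60) T1, [60,120) T2, rest T3."""
    config = config or LifeHistoryConfig()
    d = int(days_since_conception)
    if d < 0:
        raise ValueError(f"negative days since conception: {d}")
    t = config.trimester_len
    if d < t:
        return "T1"
    if d < 2 * t:
        return "T2"
    return "T3"


def assign_ppa_period(days_since_birth: int,
                      resumption_day: int | None = None,
                      weaning_day: int | None = None,
                      infant_death_day: int | None = None,
                      config: LifeHistoryConfig | None = None,
                      ) -> tuple[str | None, ExclusionReason | None]:
    """Assign a postpartum-amenorrhea period PPA1..PPA5 or an exclusion.

    All day arguments are relative to the live birth.  The pre-resumption
    window (PPA5, 30 days before cycling resumption) overrides the
    month-based periods and also rescues post-infant-death samples; the
    first postpartum week is excluded outright.

    Returns ``(period, None)`` or ``(None, reason)``.
    """
    config = config or LifeHistoryConfig()
    d = int(days_since_birth)
    if d < 0:
        raise ValueError(f"negative days since birth: {d}")
    if resumption_day is not None and resumption_day < 0:
        raise TimelineError(
            f"cycling resumption {resumption_day} precedes the birth")
    if d < config.postpartum_excl_days:
        return None, ExclusionReason.FIRST_WEEK_POSTPARTUM
    in_ppa5 = (resumption_day is not None
               and d >= resumption_day - config.preresumption_days)
    if in_ppa5:
        return "PPA5", None
    if infant_death_day is not None and d > infant_death_day:
        return None, ExclusionReason.POST_INFANT_DEATH
    month = d // config.month_days
    if month < 3:
        return "PPA1", None
    if month < 6:
        return "PPA2", None
    if month < 9:
        return "PPA3", None
    # 9 months to weaning (~70 weeks); samples after weaning but before the
    # pre-resumption window stay in PPA4 (documented design choice)
    return "PPA4", None


# ---------------------------------------------------------------------------
# sample labeling
# ---------------------------------------------------------------------------

_LABEL_COLS = ["sample_id", "female_id", "date", "state", "phase", "event_id",
               "day_in_state", "excluded", "exclusion_reason",
               "swelling_len", "interval_len"]


def assign_labels(samples: pd.DataFrame,
                  timelines: Iterable[FemaleTimeline] | dict,
                  config: LifeHistoryConfig | None = None) -> pd.DataFrame:
    """Assign every sample a state label.

    Parameters
    ----------
    samples : DataFrame with columns ``sample_id``, ``female_id``, ``date``.
    timelines : iterable of FemaleTimeline (or mapping female_id → timeline).

    Returns a tidy label frame with one row per sample.  Rule-level
    exclusions found at assignment time (first postpartum week,
    post-infant-death window, out-of-timeline dates) are flagged here;
    interval-level filters are applied by :func:`apply_exclusions`.
    """
    config = config or LifeHistoryConfig()
    if not isinstance(timelines, dict):
        timelines = {t.female_id: t for t in timelines}
    seg = {fid: segment_timeline(t) for fid, t in timelines.items()}

    rows = []
    for rec in samples.itertuples(index=False):
        fid = str(rec.female_id)
        day = _day(rec.date)
        row = dict.fromkeys(_LABEL_COLS)
        row.update(sample_id=rec.sample_id, female_id=fid, date=day,
                   excluded=False)
        iv = next((iv for iv in seg.get(fid, []) if iv.contains(day)), None)
        if iv is None:
            row.update(excluded=True,
                       exclusion_reason=ExclusionReason.OUT_OF_RANGE.value)
            rows.append(row)
            continue
        row.update(state=iv.state.value, event_id=iv.event_id,
                   day_in_state=day - iv.start,
                   interval_len=iv.length)
        if iv.state == State.CYCLING:
            cyc = next((c for c in iv.cycles
                        if c.swelling_onset <= day
                        and (c.cycle_end is None or day < c.cycle_end)), None)
            if cyc is None:
                # before the first recorded swelling onset of the interval:
                # treated as anestrus of an unobserved leading cycle
                row["phase"] = "anestrus"
            else:
                row["phase"] = assign_cycle_phase(day, cyc, config)
                row["swelling_len"] = cyc.swelling_len
        elif iv.state == State.PREGNANT:
            row["phase"] = assign_trimester(day - iv.start, config)
            if iv.miscarriage:
                row.update(excluded=True, exclusion_reason=(
                    ExclusionReason.MISCARRIAGE_PREGNANCY.value))
        else:  # PPA
            res = (None if iv.resumption is None or iv.end is None
                   else iv.resumption - iv.start)
            death = (None if iv.infant_death is None
                     else iv.infant_death - iv.start)
            wean = None if iv.weaning is None else iv.weaning - iv.start
            if iv.after_miscarriage:
                row.update(excluded=True, exclusion_reason=(
                    ExclusionReason.POST_MISCARRIAGE_PPA.value))
            else:
                period, reason = assign_ppa_period(
                    day - iv.start, res, wean, death, config)
                if reason is not None:
                    row.update(excluded=True, exclusion_reason=reason.value)
                else:
                    row["phase"] = period
        rows.append(row)
    return pd.DataFrame(rows, columns=_LABEL_COLS)


@dataclass
class FilterReport:
    """Accounting of the label filters.

    Enforces the bookkeeping identity: retained samples per state sum to
    the retained total, and retained + excluded equals the input count.
    """

    n_input: int
    retained_by_state: dict
    excluded_by_reason: dict

    @property
    def n_retained(self) -> int:
        return sum(self.retained_by_state.values())

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded_by_reason.values())

    def validate(self) -> None:
        if self.n_retained + self.n_excluded != self.n_input:
            raise AssertionError(
                f"filter accounting broken: {self.n_retained} retained + "
                f"{self.n_excluded} excluded != {self.n_input} input")

    @classmethod
    def from_labels(cls, labels: pd.DataFrame) -> "FilterReport":
        kept = labels[~labels["excluded"]]
        rep = cls(
            n_input=len(labels),
            retained_by_state=kept["state"].value_counts().to_dict(),
            excluded_by_reason=(labels.loc[labels["excluded"],
                                           "exclusion_reason"]
                                .value_counts().to_dict()),
        )
        rep.validate()
        return rep


def apply_exclusions(labels: pd.DataFrame,
                     config: LifeHistoryConfig | None = None,
                     ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply interval-level exclusion filters to assigned labels.

    Rules: cycles whose swelling length falls outside the configured
    window are removed; PPA intervals longer than ``ppa_max`` are
    removed; miscarriage pregnancies and their PPAs are already flagged
    at assignment.  Idempotent: re-running changes nothing.
    """
    config = config or LifeHistoryConfig()
    out = labels.copy()
    lo, hi = config.swelling_len_range
    bad_cycle = (
        (out["state"] == State.CYCLING.value)
        & ~out["excluded"]
        & out["swelling_len"].notna()
        & ~out["swelling_len"].between(lo, hi)
    )
    out.loc[bad_cycle, ["excluded", "exclusion_reason"]] = [
        True, ExclusionReason.ABERRANT_CYCLE_LENGTH.value]
    long_ppa = (
        (out["state"] == State.PPA.value)
        & ~out["excluded"]
        & out["interval_len"].notna()
        & (out["interval_len"] > config.ppa_max)
    )
    out.loc[long_ppa, ["excluded", "exclusion_reason"]] = [
        True, ExclusionReason.LONG_PPA.value]
    return out, FilterReport.from_labels(out)


def reproductive_day(label: pd.Series | dict) -> int:
    """Day within the reproductive state (conception-, birth-, or
    resumption-anchored); errors on excluded labels."""
    if label["excluded"]:
        raise ValueError(f"sample {label['sample_id']} is excluded "
                         f"({label['exclusion_reason']})")
    return int(label["day_in_state"])
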