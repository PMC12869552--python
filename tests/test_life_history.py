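"""Reproductive-state segmentation, phase assignment, and exclusions."""

import pandas as pd
import pytest

from reprobiome.config import LifeHistoryConfig
from reprobiome.life_history import (CycleAnchors, ExclusionReason,
                                     FemaleTimeline, FilterReport, Milestone,
                                     State, TimelineError, apply_exclusions,
                                     assign_cycle_phase, assign_labels,
                                     assign_ppa_period, assign_trimester,
                                     reproductive_day, segment_timeline)
from reprobiome.synthetic import CohortParams, generate_timelines

M = Milestone


def tl(*milestones, fid="F1"):
    return FemaleTimeline(fid, list(milestones))


class TestSegmentTimeline:
    def test_full_event_produces_three_intervals_under_one_event(self):
        t = tl((0, M.RESUMPTION), (138, M.CONCEPTION), (316, M.LIVE_BIRTH),
               (638, M.RESUMPTION))
        ivs = segment_timeline(t)
        states = [(iv.state, iv.start, iv.end) for iv in ivs[:3]]
        assert states == [(State.CYCLING, 0, 138),
                          (State.PREGNANT, 138, 316),
                          (State.PPA, 316, 638)]
        assert len({iv.event_id for iv in ivs[:3]}) == 1

    def test_single_resumption_yields_open_cycling_interval(self):
        ivs = segment_timeline(tl((0, M.RESUMPTION)))
        assert len(ivs) == 1
        assert ivs[0].state is State.CYCLING and ivs[0].end is None

    def test_miscarriage_flags_pregnancy_and_following_ppa(self):
        t = tl((0, M.RESUMPTION), (100, M.CONCEPTION), (160, M.MISCARRIAGE),
               (200, M.RESUMPTION))
        ivs = segment_timeline(t)
        preg = next(iv for iv in ivs if iv.state is State.PREGNANT)
        ppa = next(iv for iv in ivs if iv.state is State.PPA)
        assert preg.miscarriage and ppa.after_miscarriage

    def test_out_of_order_milestones_name_the_pair(self):
        with pytest.raises(TimelineError, match="CONCEPTION.*RESUMPTION"):
            tl((138, M.CONCEPTION), (0, M.RESUMPTION))

    def test_birth_without_conception_is_an_error(self):
        with pytest.raises(TimelineError, match="LIVE_BIRTH"):
            segment_timeline(tl((0, M.RESUMPTION), (50, M.LIVE_BIRTH)))

    def test_every_in_span_day_lies_in_exactly_one_interval(self):
        for t in generate_timelines(CohortParams(n_females=8, seed=21)):
            ivs = segment_timeline(t)
            lo, hi = t.span
            for day in range(lo, hi, 7):
                assert sum(iv.contains(day) for iv in ivs) == 1


class TestCyclePhase:
    cycle = CycleAnchors(swelling_onset=5, deturgescence=20,
                         anestrus_onset=34, cycle_end=40)

    @pytest.mark.parametrize("day,phase", [
        (16, "periovulatory"),   # within the 5-day ovulation window
        (5, "follicular"),       # swelling-onset day itself
        (14, "follicular"),
        (15, "periovulatory"),
        (20, "luteal"),          # deturgescence day opens the luteal phase
        (21, "luteal"),
        (34, "anestrus"),
        (39, "anestrus"),
    ])
    def test_phase_boundaries(self, day, phase):
        assert assign_cycle_phase(day, self.cycle) == phase

    def test_outside_cycle_span_raises(self):
        with pytest.raises(ValueError):
            assign_cycle_phase(40, self.cycle)
        with pytest.raises(ValueError):
            assign_cycle_phase(4, self.cycle)


class TestTrimester:
    @pytest.mark.parametrize("day,tri", [
        (0, "T1"), (59, "T1"), (60, "T2"), (119, "T2"), (120, "T3"),
        (178, "T3"),
    ])
    def test_sixty_day_bins(self, day, tri):
        assert assign_trimester(day) == tri

    def test_negative_day_raises(self):
        with pytest.raises(ValueError):
            assign_trimester(-1)


class TestPpaPeriod:
    def test_first_week_postpartum_excluded(self):
        period, reason = assign_ppa_period(5, resumption_day=400)
        assert period is None
        assert reason is ExclusionReason.FIRST_WEEK_POSTPARTUM

    def test_preresumption_window_overrides_month_periods(self):
        # sample in month 8, resumption in month 8.5
        period, reason = assign_ppa_period(245, resumption_day=255)
        assert (period, reason) == ("PPA5", None)

    @pytest.mark.parametrize("day,period", [
        (7, "PPA1"), (89, "PPA1"), (100, "PPA2"), (180, "PPA3"),
        (280, "PPA4"),
    ])
    def test_month_periods(self, day, period):
        assert assign_ppa_period(day, resumption_day=400)[0] == period

    def test_post_infant_death_window_excluded(self):
        period, reason = assign_ppa_period(
            220, resumption_day=300, infant_death_day=200)
        assert reason is ExclusionReason.POST_INFANT_DEATH
        # but within 30 days of resumption the sample is rescued as PPA5
        period, reason = assign_ppa_period(
            280, resumption_day=300, infant_death_day=200)
        assert (period, reason) == ("PPA5", None)

    def test_resumption_before_birth_raises(self):
        with pytest.raises(TimelineError):
            assign_ppa_period(10, resumption_day=-5)

    def test_after_weaning_still_ppa4(self):
        assert assign_ppa_period(500, resumption_day=600)[0] == "PPA4"


def _labels_for(timeline, dates):
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(dates))],
        "female_id": timeline.female_id, "date": dates})
    return assign_labels(samples, [timeline])


class TestExclusions:
    def _cycle_timeline(self, swelling_len):
        return tl((0, M.RESUMPTION), (10, M.SWELLING_ONSET),
                  (10 + swelling_len, M.DETURGESCENCE),
                  (10 + swelling_len + 14, M.CYCLE_ONSET),
                  (80, M.CONCEPTION), (258, M.LIVE_BIRTH),
                  (500, M.RESUMPTION))

    def test_nine_day_swelling_cycle_excluded(self):
        labels = _labels_for(self._cycle_timeline(9), [12, 15])
        out, rep = apply_exclusions(labels)
        assert out["excluded"].all()
        assert set(out["exclusion_reason"]) == {
            ExclusionReason.ABERRANT_CYCLE_LENGTH.value}

    def test_ten_day_swelling_cycle_retained(self):
        labels = _labels_for(self._cycle_timeline(10), [12, 15])
        out, _ = apply_exclusions(labels)
        assert not out["excluded"].any()

    def test_long_ppa_excluded(self):
        t = tl((0, M.RESUMPTION), (100, M.CONCEPTION), (278, M.LIVE_BIRTH),
               (778, M.RESUMPTION))  # 500-day PPA
        out, rep = apply_exclusions(_labels_for(t, [400]))
        assert out.loc[0, "exclusion_reason"] == ExclusionReason.LONG_PPA.value

    def test_filter_is_idempotent(self):
        t = self._cycle_timeline(9)
        once, _ = apply_exclusions(_labels_for(t, [12, 15, 100]))
        twice, _ = apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_no_retained_ppa5_window_sample_has_other_period(self, labeled):
        lab = labeled["labels"]
        kept_ppa = lab[(~lab["excluded"]) & (lab["state"] == "PPA")
                       & lab["interval_len"].notna()]
        in_window = kept_ppa[kept_ppa["day_in_state"]
                             >= kept_ppa["interval_len"] - 30]
        assert (in_window["phase"] == "PPA5").all()

    def test_report_identity_holds(self, labeled):
        rep = labeled["report"]
        rep.validate()
        assert rep.n_retained + rep.n_excluded == rep.n_input

    def test_report_validate_catches_broken_accounting(self):
        rep = FilterReport(n_input=10, retained_by_state={"CYCLING": 5},
                           excluded_by_reason={"long_ppa": 2})
        with pytest.raises(AssertionError):
            rep.validate()


class TestReproductiveDay:
    def test_day_in_state_anchored_at_state_onset(self):
        t = tl((0, M.RESUMPTION), (100, M.CONCEPTION), (278, M.LIVE_BIRTH),
               (600, M.RESUMPTION))
        labels = _labels_for(t, [100, 140, 378])
        assert reproductive_day(labels.iloc[0]) == 0     # conception day
        assert reproductive_day(labels.iloc[1]) == 40    # pregnancy day 40
        assert reproductive_day(labels.iloc[2]) == 100   # PPA day 100

    def test_excluded_sample_raises(self):
        t = tl((0, M.RESUMPTION), (100, M.CONCEPTION), (278, M.LIVE_BIRTH),
               (600, M.RESUMPTION))
        labels = _labels_for(t, [280])  # first week postpartum
        with pytest.raises(ValueError, match="excluded"):
            reproductive_day(labels.iloc[0])


def test_assignment_is_idempotent(cohort):
    first = assign_labels(cohort.samples, cohort.timelines)
    first, _ = apply_exclusions(first)
    again, _ = apply_exclusions(first)
    pd.testing.assert_frame_equal(first, again)
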