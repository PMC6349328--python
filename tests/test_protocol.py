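"""Unit and property tests for classification and the decision engines."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glytrial as gt
from glytrial import (
    ActionNote,
    BGCategory,
    Frailty,
    InfusionState,
    classify_bg,
    dynamic_rate,
    hypo_management,
    initial_rate,
    mgdl_to_mmol,
    next_check_interval,
    resume_rate,
    static_rate,
)
from glytrial.protocol import default_thresholds
from glytrial.util import round_half_up


class TestClassification:
    @pytest.mark.parametrize(
        "bg,profile,expected",
        [
            (80, Frailty.FRAIL, BGCategory.MILD_HYPO),
            (45, Frailty.VIGOROUS, BGCategory.MARKED_HYPO),
            (150, Frailty.FRAIL, BGCategory.IN_TARGET),
            (70, Frailty.FRAIL, BGCategory.MILD_HYPO),  # lower-closed mild band
            (69.9, Frailty.FRAIL, BGCategory.MARKED_HYPO),
            (100, Frailty.FRAIL, BGCategory.BELOW_TARGET),
            (140, Frailty.FRAIL, BGCategory.IN_TARGET),
            (220, Frailty.FRAIL, BGCategory.IN_TARGET),  # target closed above
            (220.1, Frailty.FRAIL, BGCategory.ABOVE_TARGET),
            (250, Frailty.FRAIL, BGCategory.ABOVE_TARGET),  # severe strictly >250
            (250.1, Frailty.FRAIL, BGCategory.SEVERE_HYPER),
            (50, Frailty.VIGOROUS, BGCategory.MILD_HYPO),
            (70, Frailty.VIGOROUS, BGCategory.BELOW_TARGET),
            (100, Frailty.VIGOROUS, BGCategory.IN_TARGET),
            (180, Frailty.VIGOROUS, BGCategory.IN_TARGET),
            (181, Frailty.VIGOROUS, BGCategory.ABOVE_TARGET),
        ],
    )
    def test_band_boundaries(self, bg, profile, expected):
        assert classify_bg(bg, profile) is expected

    def test_rejects_nonpositive_bg(self):
        with pytest.raises(ValueError):
            classify_bg(0, Frailty.VIGOROUS)
        with pytest.raises(ValueError):
            classify_bg(-5, Frailty.FRAIL)

    @given(bg=st.floats(min_value=0.1, max_value=1000), frail=st.booleans())
    @settings(max_examples=200, derandomize=True)
    def test_total_partition(self, bg, frail):
        """Every positive BG maps to exactly one of the six categories."""
        profile = Frailty.FRAIL if frail else Frailty.VIGOROUS
        cat = classify_bg(bg, profile)
        assert cat in BGCategory
        t = default_thresholds(profile)
        # membership is consistent with the declared half-open conventions
        in_target = t.target_low <= bg <= t.target_high
        assert (cat is BGCategory.IN_TARGET) == in_target

    def test_mmol_conversion(self):
        assert round_half_up(mgdl_to_mmol(247), 1) == 13.7
        assert round_half_up(mgdl_to_mmol(258), 1) == 14.3
        assert mgdl_to_mmol(0) == 0.0
        with pytest.raises(ValueError):
            mgdl_to_mmol(-1)


class TestScheduling:
    def test_intervals(self, dynamic_cfg):
        pre = InfusionState(target_reached=False)
        post = InfusionState(target_reached=True)
        assert next_check_interval(pre, BGCategory.IN_TARGET, dynamic_cfg) == 2
        assert next_check_interval(post, BGCategory.ABOVE_TARGET, dynamic_cfg) == 4
        assert next_check_interval(post, BGCategory.MILD_HYPO, dynamic_cfg) == 0.5
        assert next_check_interval(pre, BGCategory.MARKED_HYPO, dynamic_cfg) == 0.5


class TestStaticEngine:
    @pytest.mark.parametrize("bg,rate", [(45, 0.0), (250, 3.0), (400, 5.0),
                                         (80, 0.5), (140, 1.0), (180, 2.0)])
    def test_table_lookup(self, static_cfg, bg, rate):
        assert static_rate(bg, static_cfg) == rate

    @given(
        pair=st.tuples(
            st.floats(min_value=1, max_value=900),
            st.floats(min_value=1, max_value=900),
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_bg(self, static_cfg, pair):
        lo, hi = sorted(pair)
        assert static_rate(lo, static_cfg) <= static_rate(hi, static_cfg)


class TestDynamicEngine:
    def test_rising_above_target_steps_up(self, dynamic_cfg):
        a = dynamic_rate(300, 310, 2, InfusionState(rate=2.0), Frailty.VIGOROUS, dynamic_cfg)
        assert (a.note, a.new_rate) == (ActionNote.STEP_UP, 3.0)

    def test_fast_fall_steps_down(self, dynamic_cfg):
        a = dynamic_rate(300, 180, 2, InfusionState(rate=3.0), Frailty.VIGOROUS, dynamic_cfg)
        assert (a.note, a.new_rate) == (ActionNote.STEP_DOWN, 2.0)

    def test_adequate_fall_maintains(self, dynamic_cfg):
        # roc = -30/h: between fall_fast (-50) and fall_min (-10)
        a = dynamic_rate(300, 240, 2, InfusionState(rate=3.0), Frailty.VIGOROUS, dynamic_cfg)
        assert (a.note, a.new_rate) == (ActionNote.MAINTAIN, 3.0)

    def test_hypo_suspends_and_treats(self, dynamic_cfg):
        a = dynamic_rate(160, 60, 2, InfusionState(rate=2.0), Frailty.VIGOROUS, dynamic_cfg)
        assert a.note is ActionNote.HYPO_TREAT
        assert a.new_rate == 0.0
        assert a.glucose_bolus_g == 15.0
        assert a.next_check_in == 0.5

    def test_below_target_steps_down(self, dynamic_cfg):
        a = dynamic_rate(120, 90, 2, InfusionState(rate=1.0), Frailty.VIGOROUS, dynamic_cfg)
        assert (a.note, a.new_rate) == (ActionNote.STEP_DOWN, 0.5)

    def test_tier_saturation(self, dynamic_cfg):
        top = dynamic_cfg.dynamic.rate_tiers[-1]
        a = dynamic_rate(300, 320, 2, InfusionState(rate=top), Frailty.VIGOROUS, dynamic_cfg)
        assert a.new_rate == top  # step up from the top tier is idempotent
        b = dynamic_rate(120, 95, 2, InfusionState(rate=0.0), Frailty.VIGOROUS, dynamic_cfg)
        assert b.new_rate == 0.0  # step down at zero stays zero

    def test_rejects_bad_dt(self, dynamic_cfg):
        with pytest.raises(ValueError):
            dynamic_rate(200, 190, 0, InfusionState(rate=1.0), Frailty.VIGOROUS, dynamic_cfg)

    @given(
        cur=st.tuples(
            st.floats(min_value=71, max_value=600),
            st.floats(min_value=71, max_value=600),
        ),
        tier_idx=st.integers(min_value=0, max_value=7),
    )
    @settings(max_examples=300, derandomize=True)
    def test_monotone_in_current_bg(self, dynamic_cfg, cur, tier_idx):
        """Over the non-hypo region the new rate is non-decreasing in BG."""
        lo, hi = sorted(cur)
        rate = dynamic_cfg.dynamic.rate_tiers[tier_idx]
        a = dynamic_rate(250, lo, 2, InfusionState(rate=rate), Frailty.VIGOROUS, dynamic_cfg)
        b = dynamic_rate(250, hi, 2, InfusionState(rate=rate), Frailty.VIGOROUS, dynamic_cfg)
        assert a.new_rate <= b.new_rate


class TestHypoManagement:
    def test_mild(self, dynamic_cfg):
        a = hypo_management(BGCategory.MILD_HYPO, Frailty.FRAIL, InfusionState(rate=2.0), dynamic_cfg)
        assert (a.new_rate, a.glucose_bolus_g, a.next_check_in) == (0.0, 15.0, 0.5)

    def test_marked(self, dynamic_cfg):
        a = hypo_management(BGCategory.MARKED_HYPO, Frailty.VIGOROUS, InfusionState(rate=2.0), dynamic_cfg)
        assert (a.new_rate, a.glucose_bolus_g) == (0.0, 30.0)

    def test_rejects_non_hypo(self, dynamic_cfg):
        with pytest.raises(ValueError):
            hypo_management(BGCategory.IN_TARGET, Frailty.FRAIL, InfusionState(), dynamic_cfg)

    def test_resume_at_half_prior_rate_floored_to_tier(self, dynamic_cfg):
        assert resume_rate(2.0, dynamic_cfg) == 1.0
        assert resume_rate(3.0, dynamic_cfg) == 1.0  # 1.5 floors to tier 1
        assert resume_rate(8.0, dynamic_cfg) == 4.0
        assert resume_rate(0.5, dynamic_cfg) == 0.0


class TestInitialRate:
    @pytest.mark.parametrize(
        "bg,rate",
        [(250, 3.0), (90, 0.0), (520, 6.0), (130, 1.0), (700, 8.0), (100, 1.0)],
    )
    def test_nearest_tier_rule(self, dynamic_cfg, bg, rate):
        assert initial_rate(bg, dynamic_cfg) == rate

    def test_static_mode_uses_table(self, static_cfg):
        assert initial_rate(250, static_cfg) == 3.0


class TestDeviationDetection:
    def _record(self, t, bg, cat, presc_rate, applied, bolus, presc_gap, gap):
        from glytrial.records import BGRecord

        return BGRecord("p", t, bg, cat, presc_rate, applied, bolus, presc_gap, gap)

    def test_fully_compliant_log_has_zero_deviations(self, dynamic_cfg):
        recs = [
            self._record(2 * i, 150, BGCategory.IN_TARGET, 1.0, 1.0, 0.0, 2.0, 2.0)
            for i in range(10)
        ]
        recs[-1].actual_gap = math.nan
        d = gt.detect_deviations(recs, dynamic_cfg)
        assert (d.monitoring_deviations, d.rate_deviations, d.hypo_total) == (0, 0, 0)
        assert d.monitoring_total == 10

    def test_late_checks_counted(self, dynamic_cfg):
        recs = []
        t = 0.0
        for i in range(10):
            gap = 2.5 if i < 2 else 2.0  # two late checks beyond 20-min slack
            recs.append(
                self._record(t, 150, BGCategory.IN_TARGET, 1.0, 1.0, 0.0, 2.0, gap)
            )
            t += gap
        d = gt.detect_deviations(recs, dynamic_cfg)
        assert (d.monitoring_deviations, d.monitoring_total) == (2, 10)

    def test_counts_match_injected_flags(self, dynamic_cfg, rng):
        """Counts equal the sums of independently injected deviation flags."""
        recs = []
        t = 0.0
        inj_mon = inj_rate = 0
        for i in range(200):
            late = rng.random() < 0.3
            wrong = rng.random() < 0.2
            gap = 2.0 + (1.0 if late else 0.0)
            applied = 1.5 if wrong else 1.0
            inj_mon += late
            inj_rate += wrong
            recs.append(
                self._record(t, 150, BGCategory.IN_TARGET, 1.0, applied, 0.0, 2.0, gap)
            )
            t += gap
        d = gt.detect_deviations(recs, dynamic_cfg)
        assert d.monitoring_deviations == inj_mon
        assert d.rate_deviations == inj_rate

    def test_misaligned_prescriptions_rejected(self, dynamic_cfg):
        recs = [self._record(0, 150, BGCategory.IN_TARGET, 1.0, 1.0, 0.0, 2.0, 2.0)]
        with pytest.raises(ValueError):
            gt.detect_deviations(recs, dynamic_cfg, prescribed=[])


class TestConfigValidation:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            gt.GlycemicThresholds(
                target_low=100, target_high=90, mild_hypo_low=50,
                mild_hypo_high=70, marked_hypo_below=50,
            )

    def test_static_table_must_be_contiguous(self):
        from glytrial.protocol import StaticBand

        with pytest.raises(ValueError):
            gt.ProtocolConfig(
                mode="static",
                static_table=[
                    StaticBand(bg_low=0, bg_high=100, rate=0),
                    StaticBand(bg_low=150, bg_high=None, rate=2),
                ],
            )

    def test_tiers_must_start_at_zero(self):
        with pytest.raises(ValueError):
            gt.DynamicParams(rate_tiers=[0.5, 1, 2])
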