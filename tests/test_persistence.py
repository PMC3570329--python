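from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesadhere.claims_model import Product
from mesadhere.persistence import (
    EventType,
    TreatmentEpisode,
    build_episode,
    km_estimate,
    logrank_compare,
    permutation_logrank,
    persistence_summary,
)
from conftest import fills_frame, member
from oracles import episode_oracle, km_survival_oracle, logrank_oracle


def _episode(pid="P", time=365, event=EventType.CENSORED, product=Product.SALOFALK):
    return TreatmentEpisode(
        patient_id=pid, index_product=product, runout_dates=(),
        event_type=event, event_time_days=time,
    )


class TestBuildEpisode:
    def test_gapless_monthly_stream_is_censored(self):
        frame = fills_frame([(30 * k, 30) for k in range(12)])
        ep = build_episode(member(), frame)
        assert ep.event_type is EventType.CENSORED
        assert ep.event_time_days == 365 and ep.persistent_at_365

    def test_sixty_day_silence_after_runout_is_discontinuation(self):
        # fills day 0 and 45, 30 d each: runout day 74, silence through day 134
        ep = build_episode(member(), fills_frame([(0, 30), (45, 30)]))
        assert ep.event_type is EventType.GAP_DISCONTINUATION
        assert ep.event_time_days == 75

    def test_fill_on_last_grace_day_closes_the_gap(self):
        # next fill exactly 60 days after runout (day 74 + 60 = 134): persistent
        ep = build_episode(member(), fills_frame([(0, 30), (45, 30), (134, 300)]))
        assert ep.event_type is EventType.CENSORED

    def test_fill_one_day_past_grace_does_not_close(self):
        ep = build_episode(member(), fills_frame([(0, 30), (45, 30), (135, 300)]))
        assert ep.event_type is EventType.GAP_DISCONTINUATION
        assert ep.event_time_days == 75

    def test_switch_to_other_product_is_non_persistent_at_fill_date(self):
        frame = fills_frame(
            [(0, 30), (30, 30), (60, 30), (90, 30), (120, 30)],
            product=Product.ASACOL_OR_GENERIC,
            other=[(90, 30, Product.MEZAVANT)],
        )
        ep = build_episode(member(product=Product.ASACOL_OR_GENERIC), frame)
        assert ep.event_type is EventType.SWITCH
        assert ep.event_time_days == 90
        assert not ep.persistent_at_365

    def test_other_product_fill_closes_gap_but_counts_as_switch(self):
        # index product stops at day 29; Pentasa fill at day 60 inside the
        # would-be silent window: classified as the earlier switch, not a gap
        frame = fills_frame([(0, 30)], other=[(60, 30, Product.PENTASA)])
        ep = build_episode(member(), frame)
        assert ep.event_type is EventType.SWITCH
        assert ep.event_time_days == 60

    def test_strict_index_gap_reading_flag(self):
        frame = fills_frame([(0, 30)], other=[(60, 30, Product.PENTASA)])
        ep = build_episode(member(), frame, any_asa_closes_gap=False)
        # gap at day 30 precedes the day-60 switch under the strict reading
        assert ep.event_type is EventType.GAP_DISCONTINUATION
        assert ep.event_time_days == 30

    def test_require_abandonment_ignores_transient_switch(self):
        frame = fills_frame(
            [(30 * k, 30) for k in range(12)], other=[(90, 30, Product.MEZAVANT)]
        )
        assert build_episode(member(), frame).event_type is EventType.SWITCH
        ep = build_episode(member(), frame, require_abandonment=True)
        assert ep.event_type is EventType.CENSORED

    def test_early_refills_bank_supply_and_prevent_artificial_gaps(self):
        # two overlapping 60-day fills cover through day 119; refill day 170
        # is within grace of the banked runout (119 + 60 = 179)
        frame = fills_frame([(0, 60), (10, 60), (170, 200)])
        ep = build_episode(member(), frame)
        assert ep.event_type is EventType.CENSORED
        assert ep.runout_dates[1] == 119

    def test_runout_too_close_to_window_end_is_censored_not_discontinued(self):
        # final runout day 364+: the 60-day silent period cannot be observed
        frame = fills_frame([(0, 300), (300, 65)])
        ep = build_episode(member(), frame)
        assert ep.event_type is EventType.CENSORED

    def test_late_runout_with_observable_silence_is_discontinued(self):
        frame = fills_frame([(0, 300)])  # runout day 299, silence observable
        ep = build_episode(member(), frame)
        assert ep.event_type is EventType.GAP_DISCONTINUATION
        assert ep.event_time_days == 300

    def test_missing_index_fill_is_an_error(self):
        with pytest.raises(ValueError, match="index-product fill"):
            build_episode(member(), fills_frame([(10, 30)]))


@st.composite
def random_patient_fills(draw):
    idx = [(0, draw(st.integers(7, 90)))]
    for _ in range(draw(st.integers(0, 10))):
        idx.append((draw(st.integers(1, 424)), draw(st.integers(7, 90))))
    others = draw(st.lists(st.integers(1, 424), max_size=3))
    return sorted(idx), sorted(others)


class TestEpisodeProperties:
    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(random_patient_fills())
    def test_classification_matches_exhaustive_day_scan(self, stream):
        idx_fills, other_days = stream
        frame = fills_frame(idx_fills, other=[(t, 30, Product.MEZAVANT) for t in other_days])
        ep = build_episode(member(), frame)
        expected_type, expected_time = episode_oracle(idx_fills, other_days)
        assert (ep.event_type.value, ep.event_time_days) == (expected_type, expected_time)
        # exclusive classification, consistent persistence flag
        assert ep.persistent_at_365 == (ep.event_type is EventType.CENSORED)
        assert (ep.event_time_days == 365) == (ep.event_type is EventType.CENSORED) or \
            ep.event_type is EventType.SWITCH


class TestKaplanMeier:
    def test_all_censored_gives_unit_survival(self):
        eps = [_episode(pid=f"P{i}") for i in range(5)]
        curve = km_estimate(eps)
        assert curve.at(0) == 1.0 and curve.at(365) == 1.0

    def test_hand_product_limit_example(self):
        eps = [
            _episode("A", 10, EventType.GAP_DISCONTINUATION),
            _episode("B", 20, EventType.SWITCH),
            _episode("C"), _episode("D"),
        ]
        curve = km_estimate(eps)
        assert curve.at(10) == pytest.approx(3 / 4)
        assert curve.at(20) == pytest.approx((3 / 4) * (2 / 3))
        assert curve.at(365) == pytest.approx(0.5)

    def test_survival_non_increasing_and_matches_oracle(self):
        rng = np.random.default_rng(7)
        eps = []
        for i in range(40):
            t = int(rng.integers(1, 366))
            event = EventType.GAP_DISCONTINUATION if rng.random() < 0.6 else EventType.CENSORED
            time = 365 if event is EventType.CENSORED else t
            eps.append(_episode(f"P{i}", time, event))
        curve = km_estimate(eps)
        assert all(a >= b for a, b in zip(curve.survival, curve.survival[1:]))
        pairs = [(e.event_time_days, e.event_type is not EventType.CENSORED) for e in eps]
        for t in (50, 180, 365):
            assert curve.at(t) == pytest.approx(km_survival_oracle(pairs, t))

    def test_km_at_365_equals_empirical_proportion_when_censoring_only_at_end(self):
        rng = np.random.default_rng(8)
        eps = []
        for i in range(200):
            if rng.random() < 0.455:
                eps.append(_episode(f"P{i}"))
            else:
                eps.append(_episode(f"P{i}", int(rng.integers(1, 365)),
                                    EventType.GAP_DISCONTINUATION))
        curve = km_estimate(eps)
        empirical = sum(e.persistent_at_365 for e in eps) / len(eps)
        assert curve.at(365) == pytest.approx(empirical)


class TestLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        eps = [_episode("A", 50, EventType.GAP_DISCONTINUATION), _episode("B")]
        stat, p = logrank_compare({"g1": eps, "g2": list(eps)})
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        g1 = [_episode(f"A{i}", 30 + i, EventType.GAP_DISCONTINUATION) for i in range(5)]
        g2 = [_episode(f"B{i}") for i in range(5)]
        stat_ab, _ = logrank_compare({"a": g1, "b": g2})
        stat_ba, _ = logrank_compare({"b": g2, "a": g1})
        assert stat_ab == pytest.approx(stat_ba)

    def test_disjoint_event_supports_match_hand_computation(self):
        g1 = [
            _episode("A1", 10, EventType.GAP_DISCONTINUATION),
            _episode("A2", 20, EventType.GAP_DISCONTINUATION),
            _episode("A3", 30, EventType.GAP_DISCONTINUATION),
        ]
        g2 = [
            _episode("B1", 200, EventType.GAP_DISCONTINUATION),
            _episode("B2", 250, EventType.GAP_DISCONTINUATION),
            _episode("B3"),
        ]
        stat, _ = logrank_compare({"g1": g1, "g2": g2})
        oracle = logrank_oracle({
            "g1": [(e.event_time_days, True) for e in g1],
            "g2": [(200, True), (250, True), (365, False)],
        })
        assert stat == pytest.approx(oracle, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="zero episodes"):
            logrank_compare({"a": [_episode("A")], "b": []})

    def test_asymptotic_p_within_monte_carlo_error_of_permutation_p(self):
        rng = np.random.default_rng(42)
        groups = {}
        for label, rate in (("fast", 0.7), ("slow", 0.45)):
            eps = []
            for i in range(20):
                if rng.random() < rate:
                    eps.append(_episode(f"{label}{i}", int(rng.integers(20, 330)),
                                        EventType.GAP_DISCONTINUATION))
                else:
                    eps.append(_episode(f"{label}{i}"))
            groups[label] = eps
        stat, p_asym = logrank_compare(groups)
        stat_perm, p_perm = permutation_logrank(groups, n_permutations=999, seed=11)
        assert stat == pytest.approx(stat_perm)
        mc_se = np.sqrt(p_perm * (1 - p_perm) / 1000)
        assert abs(p_asym - p_perm) <= max(3 * mc_se, 0.02)


class TestPersistenceSummary:
    def _episodes_from_counts(self, rows):
        eps = []
        for group, n, n_pers in rows:
            for i in range(n):
                if i < n_pers:
                    eps.append(_episode(f"{group}{i}"))
                else:
                    eps.append(_episode(f"{group}{i}", 100, EventType.GAP_DISCONTINUATION))
        grouping = {group: [f"{group}{i}" for i in range(n)] for group, n, _ in rows}
        return eps, grouping

    def test_published_sex_counts_round_to_printed_percentages(self):
        eps, grouping = self._episodes_from_counts([("male", 729, 365), ("female", 952, 400)])
        table = persistence_summary(eps, grouping).set_index("group")
        assert table.loc["male", "pct_persistent"] == 50.1
        assert table.loc["female", "pct_persistent"] == 42.0

    def test_overall_from_sex_counts_rounds_to_45_5(self):
        eps, _ = self._episodes_from_counts([("all", 1681, 765)])
        assert persistence_summary(eps).loc[0, "pct_persistent"] == 45.5

    def test_one_group_partition_equals_overall(self):
        eps, _ = self._episodes_from_counts([("g", 10, 4)])
        overall = persistence_summary(eps)
        one = persistence_summary(eps, {"g": [e.patient_id for e in eps]})
        assert overall.iloc[0, 1:].tolist() == one.iloc[0, 1:].tolist()
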