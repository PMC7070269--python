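"""FSM safety layer, therapy lookup, pulse dosing and oximetry summaries."""

import numpy as np
import pytest

from oxiflow.control import (
    PROFILE_TABLE,
    FsmState,
    TherapyProfile,
    adherence_rate,
    bolus_volume,
    fsm_step,
    profile_lookup,
    run_closed_loop,
    spo2_summary,
)
from oxiflow.synthetic_data import Intensity

# the seven personalisation rows: intensity -> pulse setting
PROFILE_CELLS = {
    1: (1, 2, 4), 2: (1, 3, 5), 3: (1, 4, 5), 4: (2, 4, 5),
    5: (3, 4, 5), 6: (0, 2, 5), 7: (0, 1, 4),
}

# bolus volumes (mL) by pulse setting at 15/20/25 breaths per minute
BOLUS_CELLS = {
    1: (12.0, 9.0, 7.2),
    2: (24.0, 18.0, 14.4),
    3: (36.0, 27.0, 21.6),
    4: (48.0, 36.0, 28.8),
    5: (60.0, 45.0, 36.0),
}


class TestProfiles:
    def test_all_21_cells(self):
        for pid, row in PROFILE_CELLS.items():
            for intensity in Intensity:
                assert profile_lookup(pid, intensity) == row[int(intensity)]

    def test_monotone_in_intensity(self):
        for pid in PROFILE_TABLE:
            row = [profile_lookup(pid, i) for i in Intensity]
            assert row == sorted(row)

    def test_out_of_range_id(self):
        with pytest.raises(ValueError):
            profile_lookup(8, Intensity.SEDENTARY)
        with pytest.raises(ValueError):
            profile_lookup(0, Intensity.LIGHT)


class TestBolus:
    def test_all_15_cells(self):
        for setting, (v15, v20, v25) in BOLUS_CELLS.items():
            assert bolus_volume(setting, 15) == pytest.approx(v15)
            assert bolus_volume(setting, 20) == pytest.approx(v20)
            assert bolus_volume(setting, 25) == pytest.approx(v25)

    def test_anchors(self):
        assert bolus_volume(1, 15) == pytest.approx(12.0)  # 12 mL per level
        assert bolus_volume(5, 1) == pytest.approx(900.0)  # 900 mL/min max
        assert bolus_volume(0, 20) == 0.0

    def test_monotonicity(self):
        for s in range(1, 6):
            assert bolus_volume(s, 15) > bolus_volume(s, 20) > bolus_volume(s, 25)
        for bpm in (15, 20, 25):
            vols = [bolus_volume(s, bpm) for s in range(6)]
            assert vols == sorted(vols)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bolus_volume(1, 0)
        with pytest.raises(ValueError):
            bolus_volume(6, 15)


class TestFsm:
    def test_no_op_when_observed_equals_current(self):
        profile = TherapyProfile.from_id(2)
        state, setting = fsm_step(FsmState(Intensity.SEDENTARY), Intensity.SEDENTARY, profile)
        assert state.current == Intensity.SEDENTARY and setting == 1

    def test_two_step_climb_sedentary_to_moderate(self):
        profile = TherapyProfile.from_id(2)
        state, setting = fsm_step(FsmState(Intensity.SEDENTARY), Intensity.MODERATE, profile)
        assert state.current == Intensity.LIGHT and setting == 3
        state, setting = fsm_step(state, Intensity.MODERATE, profile)
        assert state.current == Intensity.MODERATE and setting == 5

    def test_never_jumps_two_levels(self, rng):
        profile = TherapyProfile.from_id(1)
        state = FsmState(Intensity.SEDENTARY)
        levels = [int(state.current)]
        for obs in rng.integers(0, 3, size=10_000):
            state, _ = fsm_step(state, Intensity(int(obs)), profile)
            levels.append(int(state.current))
        assert np.max(np.abs(np.diff(levels))) <= 1

    @pytest.mark.parametrize("start", list(Intensity))
    @pytest.mark.parametrize("target", list(Intensity))
    def test_converges_within_two_steps(self, start, target):
        profile = TherapyProfile.from_id(3)
        state = FsmState(start)
        for _ in range(2):
            state, _ = fsm_step(state, target, profile)
        assert state.current == target


class TestClosedLoop:
    def test_constant_stream_no_adjustments(self):
        tl = run_closed_loop([0] * 20, TherapyProfile.from_id(2))
        assert np.all(tl.settings == 1)
        assert tl.adjustments == 0

    def test_up_down_excursion(self):
        stream = [0] * 10 + [1] * 10 + [0] * 10
        tl = run_closed_loop(stream, TherapyProfile.from_id(2))
        assert list(np.unique(tl.settings)) == [1, 3]
        assert tl.settings[0] == 1 and tl.settings[15] == 3 and tl.settings[-1] == 1
        assert tl.adjustments == 2

    def test_ramp_through_intermediate_level(self):
        stream = [0] * 10 + [2] * 10
        tl = run_closed_loop(stream, TherapyProfile.from_id(1))
        assert tl.settings[10] == 2  # passes through the light setting
        assert tl.settings[11] == 4
        assert tl.latencies and tl.latencies[-1]["windows"] == 2

    def test_adjustments_match_diff_oracle(self, rng):
        stream = rng.integers(0, 3, size=500)
        tl = run_closed_loop(stream, TherapyProfile.from_id(4))
        assert tl.adjustments == int(np.sum(np.diff(tl.settings) != 0))
        assert np.max(np.abs(np.diff(tl.states))) <= 1

    def test_debounce_delays_reaction(self):
        stream = [0, 1, 0, 1, 0, 1, 1, 1]
        tl = run_closed_loop(stream, TherapyProfile.from_id(2), debounce=2)
        # single-window blips never move the state; only the final sustained
        # run of 1s does
        assert np.all(tl.states[:6] == 0)
        assert tl.states[-1] == 1

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            run_closed_loop([], TherapyProfile.from_id(1))


class TestAdherence:
    @pytest.mark.parametrize(
        "performed,needed,expected", [(17, 96, 17.7), (96, 96, 100.0), (0, 96, 0.0)]
    )
    def test_rates(self, performed, needed, expected):
        assert adherence_rate(performed, needed) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            adherence_rate(1, 0)
        with pytest.raises(ValueError):
            adherence_rate(97, 96)


class TestSpo2:
    def test_constant_healthy(self):
        rep = spo2_summary([95.0] * 100)
        assert rep.ct90 == 0.0 and rep.ct85 == 0.0 and rep.events == 0
        assert rep.mean == 95.0 and rep.min == 95.0

    def test_half_below_90(self):
        rep = spo2_summary([88.0] * 50 + [92.0] * 50)
        assert rep.ct90 == 50.0
        assert rep.ct85 == 0.0

    def test_ct_matches_sample_counting(self, rng):
        series = rng.uniform(80, 100, size=400)
        rep = spo2_summary(series)
        assert rep.ct90 == pytest.approx(100.0 * np.mean(series < 90))
        assert rep.ct85 == pytest.approx(100.0 * np.mean(series < 85))
        assert rep.ct85 <= rep.ct90

    def test_event_counting_with_merge(self):
        # two 15-s dips separated by 5 s of recovery merge into one event;
        # a separate 15-s dip after 30 s of recovery is a second event
        series = (
            [88] * 15 + [95] * 5 + [88] * 15 + [95] * 30 + [88] * 15 + [95] * 20
        )
        rep = spo2_summary(series)
        assert rep.events == 2

    def test_short_dips_not_events(self):
        series = [95] * 20 + [88] * 5 + [95] * 50  # 5 s dip < 10 s minimum
        assert spo2_summary(series).events == 0

    def test_invalid_series(self):
        with pytest.raises(ValueError):
            spo2_summary([])
        with pytest.raises(ValueError):
            spo2_summary([105.0])
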