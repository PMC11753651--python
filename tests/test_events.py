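"""Zero-crossing detection, event detection and cycle assembly."""

import numpy as np
import pytest

import gaitrel as g
from gaitrel.errors import MissingSegmentError, ValidationError


def nearest_errors(detected, truth):
    """Absolute error of each detected event vs its nearest truth event."""
    return np.array([np.min(np.abs(truth - t)) for t in detected])


class TestZeroCrossings:
    def test_two_sample_crossing_interpolated(self):
        times = g.zero_crossings(np.array([-1.0, 1.0]), 100.0, "positive")
        assert np.allclose(times, [0.005])

    def test_constant_series_has_no_events(self):
        for direction in ("positive", "negative"):
            assert g.zero_crossings(np.full(3, 2.0), 100.0, direction).size == 0

    def test_sine_roots_recovered(self):
        # phase-shifted so every crossing is an interior sign change
        delta = 3e-4
        t = np.arange(0, 3.0, 0.01)
        series = np.sin(2 * np.pi * (t - delta))
        times = g.zero_crossings(series, 100.0, "positive")
        assert np.allclose(times, [delta, 1 + delta, 2 + delta], atol=1e-4)
        neg = g.zero_crossings(series, 100.0, "negative")
        assert np.allclose(neg, [0.5 + delta, 1.5 + delta, 2.5 + delta], atol=1e-4)

    def test_exact_zero_assigned_to_its_frame(self):
        times = g.zero_crossings(np.array([-1.0, 0.0, 0.5]), 100.0, "positive")
        assert np.allclose(times, [0.01])

    def test_time_reversal_swaps_directions(self):
        rng = np.random.default_rng(3)
        series = np.cumsum(rng.normal(size=200))
        pos = g.zero_crossings(series, 100.0, "positive")
        neg_rev = g.zero_crossings(series[::-1], 100.0, "negative")
        t_end = (len(series) - 1) / 100.0
        assert len(pos) == len(neg_rev)
        assert np.allclose(np.sort(t_end - neg_rev), pos, atol=1e-9)

    def test_t0_offset_shifts_event_times_exactly(self):
        series = np.sin(2 * np.pi * (np.arange(300) / 100.0 - 3e-4))
        base = g.zero_crossings(series, 100.0, "positive")
        shifted = g.zero_crossings(series, 100.0, "positive", t0=2.5)
        assert np.allclose(shifted, base + 2.5, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            g.zero_crossings(np.array([1.0]), 100.0)


class TestDetectEvents:
    def test_noiseless_trial_recovers_truth_within_one_frame(self, noiseless_trial):
        segs, truth_ev, _, _ = noiseless_trial
        for side in ("L", "R"):
            ev = g.detect_events(segs, side)
            assert nearest_errors(ev.heel_strikes, truth_ev[side].heel_strikes).max() < 0.01
            assert nearest_errors(ev.toe_offs, truth_ev[side].toe_offs).max() < 0.01

    def test_noisy_trials_keep_event_counts(self, template):
        """2 mm position noise, filter on: no doubled or dropped events over
        50 Monte-Carlo trials."""
        design = g.StudyDesign(seed=11)
        config = g.EventConfig()
        margin = config.edge_margin_s
        for k in range(50):
            segs, truth_ev, _, _ = g.synthesize_trial(
                template, design, (0, 0, k), sd_frame_noise=0.002)
            t_max = segs["pelvis"].times[-1]
            # interior window with slack so noise jitter near the edge margin
            # cannot move an event across the counting boundary
            lo, hi = margin + 0.06, t_max - margin - 0.06
            for side in ("L", "R"):
                ev = g.detect_events(segs, side, config)
                for det, tru in ((ev.heel_strikes, truth_ev[side].heel_strikes),
                                 (ev.toe_offs, truth_ev[side].toe_offs)):
                    expected = tru[(tru >= lo) & (tru <= hi)]
                    got = det[(det >= lo) & (det <= hi)]
                    assert len(got) == len(expected)

    def test_missing_segment_rejected(self, noiseless_trial):
        segs = dict(noiseless_trial[0])
        del segs["foot_L"]
        with pytest.raises(MissingSegmentError):
            g.detect_events(segs, "L")

    def test_refinement_stability(self, template):
        """Doubling the frame rate moves noiseless event times < 0.005 s."""
        evs = {}
        for fs in (100.0, 200.0):
            design = g.StudyDesign(frame_rate=fs, seed=1)
            segs, _, _, _ = g.synthesize_trial(template, design)
            evs[fs] = g.detect_events(segs, "R")
        assert np.abs(evs[100.0].heel_strikes - evs[200.0].heel_strikes).max() < 0.005
        assert np.abs(evs[100.0].toe_offs[0] - evs[200.0].toe_offs[0]) < 0.005

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            g.EventConfig(filter_order=3)
        with pytest.raises(ValidationError):
            g.EventConfig(hs_crossing="sideways")


class TestAssembleCycles:
    def test_worked_example(self):
        left = g.GaitEventSet("L", [0.00, 1.10], [0.65])
        right = g.GaitEventSet("R", [0.55], [0.10])
        cycles, notes = g.assemble_cycles(left, right)
        lc = next(c for c in cycles if c.side == "L")
        assert (lc.t_hs_start, lc.t_to, lc.t_hs_contra, lc.t_hs_end) == \
               (0.00, 0.65, 0.55, 1.10)
        assert "side R" in " ".join(notes)  # right has a single HS: no cycle

    def test_missing_toe_off_omits_side(self):
        left = g.GaitEventSet("L", [0.00, 1.10], [1.50])
        right = g.GaitEventSet("R", [0.55], [0.10])
        cycles, notes = g.assemble_cycles(left, right)
        assert not any(c.side == "L" for c in cycles)
        assert any("side L" in n for n in notes)

    def test_full_study_yields_cycle_per_side(self, recovery_study):
        n_cycles = {"L": 0, "R": 0}
        for label in recovery_study.labels():
            trial = recovery_study.trials[label]
            ev = {s: g.detect_events(trial, s) for s in ("L", "R")}
            cycles, _ = g.assemble_cycles(ev["L"], ev["R"])
            for c in cycles:
                n_cycles[c.side] += 1
        assert n_cycles == {"L": 135, "R": 135}

    def test_event_alternation_invariant(self, noiseless_trial):
        segs = noiseless_trial[0]
        ev = {s: g.detect_events(segs, s) for s in ("L", "R")}
        cycles, _ = g.assemble_cycles(ev["L"], ev["R"])
        assert len(cycles) == 2
        for c in cycles:
            assert c.t_hs_start < c.t_to < c.t_hs_end
            assert c.t_hs_start < c.t_hs_contra < c.t_hs_end

    def test_shifted_events_shift_cycles_exactly(self):
        left = g.GaitEventSet("L", [0.00, 1.10], [0.65])
        right = g.GaitEventSet("R", [0.55, 1.65], [0.10, 1.20])
        base, _ = g.assemble_cycles(left, right)
        moved, _ = g.assemble_cycles(left.shifted(2.0), right.shifted(2.0))
        for b, m in zip(base, moved):
            assert m.t_hs_start == pytest.approx(b.t_hs_start + 2.0, abs=1e-12)
            assert m.t_hs_end == pytest.approx(b.t_hs_end + 2.0, abs=1e-12)

    def test_unordered_event_times_rejected(self):
        with pytest.raises(ValidationError):
            g.GaitEventSet("L", [1.0, 0.5], [0.2])
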