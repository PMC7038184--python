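import numpy as np
import pytest

from alphastrand import (
    ConformationState,
    DihedralRecord,
    StrandPattern,
    detect_flips,
    plant_flip_series,
    state_matrix,
    transition_trace,
    window_summary,
)
from alphastrand.trajectory_analysis import StateMatrix, circular_difference

R, L, O, U = (
    ConformationState.ALPHA_R,
    ConformationState.ALPHA_L,
    ConformationState.OTHER,
    ConformationState.UNDEFINED,
)


def rec(res, phi, psi, chain="A", name="ALA"):
    return DihedralRecord(residue_ref=(chain, res, name), phi_deg=phi, psi_deg=psi)


def frames_from_phipsi(per_frame):
    """per_frame: list of lists of (phi, psi) for residues 1..n."""
    return [
        [rec(i + 1, phi, psi) for i, (phi, psi) in enumerate(frame)]
        for frame in per_frame
    ]


class TestStateMatrix:
    def test_constant_alpha_r_frames(self):
        frames = frames_from_phipsi([[(-60, -45)] * 3] * 4)
        m = state_matrix(frames, stride_ps=2.0)
        assert m.states.shape == (4, 3)
        assert all(m.state(t, i) is R for t in range(4) for i in range(3))
        assert list(m.frame_times_ps) == [0.0, 2.0, 4.0, 6.0]

    def test_ragged_frames_error_names_frame(self):
        frames = frames_from_phipsi([[(-60, -45)] * 3, [(-60, -45)] * 2])
        with pytest.raises(ValueError, match="frame 1"):
            state_matrix(frames)

    def test_from_codes_identity(self):
        m = StateMatrix.from_codes([1, 2, 3], ["RLR", "ROL"], stride_ps=2.0)
        assert m.state(0, 0) is R and m.state(1, 1) is O
        assert m.frame_states(0) == {1: R, 2: L, 3: R}


class TestWindowSummary:
    def test_counts_events_and_first_appearance(self):
        codes = ["OOO"] * 100
        for f in (10, 11, 12, 40):
            codes[f] = "RLR"
        m = StateMatrix.from_codes([24, 25, 26], codes, stride_ps=2.0)
        ws = window_summary(m, StrandPattern("RLR", anchored_window=(24, 25, 26)))
        assert ws.frame_count == 4
        assert ws.event_count == 2
        assert ws.first_appearance_ps == 20.0
        assert ws.first_appearance_ns == pytest.approx(0.020)
        assert ws.occupancy_fraction == pytest.approx(0.04)

    def test_absent_pattern(self):
        m = StateMatrix.from_codes([24, 25, 26], ["OOO"] * 10, stride_ps=2.0)
        ws = window_summary(m, StrandPattern("RLR", anchored_window=(24, 25, 26)))
        assert ws.frame_count == 0
        assert ws.first_appearance_ps is None

    def test_conservation_and_event_consistency(self):
        rng = np.random.default_rng(5)
        codes = ["".join(rng.choice(list("RLO"), size=3)) for _ in range(500)]
        m = StateMatrix.from_codes([24, 25, 26], codes, stride_ps=2.0)
        ws = window_summary(m, StrandPattern("RLR", anchored_window=(24, 25, 26)))
        assert ws.frame_count + int(np.sum(~ws.match_mask)) == 500
        assert 0.0 <= ws.occupancy_fraction <= 1.0
        mask = ws.match_mask.astype(int)
        transitions = int(mask[0]) + int(np.sum((mask[1:] == 1) & (mask[:-1] == 0)))
        assert ws.event_count == transitions
        assert ws.event_count <= ws.frame_count

    def test_missing_window_is_lookup_error(self):
        m = StateMatrix.from_codes([1, 2, 3], ["RLR"], stride_ps=2.0)
        with pytest.raises(KeyError):
            window_summary(m, StrandPattern("RLR", anchored_window=(24, 25, 26)))

    def test_window_count_semantics_match_planted_total(self):
        # 1671 matching frames out of 25,000 at 2 ps: frame-count semantics
        n_frames, n_match = 25_000, 1671
        rng = np.random.default_rng(11)
        match_frames = np.sort(rng.choice(n_frames, size=n_match, replace=False))
        codes = ["OOO"] * n_frames
        for f in match_frames:
            codes[f] = "RLR"
        m = StateMatrix.from_codes([24, 25, 26], codes, stride_ps=2.0)
        ws = window_summary(m, StrandPattern("RLR", anchored_window=(24, 25, 26)))
        assert ws.frame_count == 1671
        assert ws.first_appearance_ps == match_frames[0] * 2.0

    def test_nested_windows_monotone(self):
        # matches for 24-28 nest inside 24-27 inside 24-26
        codes = []
        for t in range(100):
            if 30 <= t < 40:
                codes.append("RLRLR")
            elif 20 <= t < 40:
                codes.append("RLRLO")
            elif 10 <= t < 40:
                codes.append("RLROO")
            else:
                codes.append("OOOOO")
        m = StateMatrix.from_codes(list(range(24, 29)), codes, stride_ps=2.0)
        summaries = [
            window_summary(m, StrandPattern(p, anchored_window=tuple(range(24, 24 + len(p)))))
            for p in ("RLR", "RLRL", "RLRLR")
        ]
        counts = [s.frame_count for s in summaries]
        firsts = [s.first_appearance_ps for s in summaries]
        assert counts == [30, 20, 10]
        assert counts[0] >= counts[1] >= counts[2]
        assert firsts[0] <= firsts[1] <= firsts[2]


class TestTransitionTrace:
    def test_state_change_recorded_at_transition_frame(self):
        per_frame = [[(-120, 130)]] * 7 + [[(-60, -45)]] * 3
        frames = frames_from_phipsi(per_frame)
        trace = transition_trace(frames, 1, times_ps=np.arange(10) * 2.0)
        assert trace.changes == [(14.0, O, R)]
        assert trace.initial[3] is O
        assert trace.first_in_state(R)[0] == 14.0

    def test_constant_series_no_changes(self):
        frames = frames_from_phipsi([[(-60, -45)]] * 5)
        assert transition_trace(frames, 1).changes == []

    def test_absent_residue_is_lookup_error(self):
        frames = frames_from_phipsi([[(-60, -45)]] * 3)
        with pytest.raises(KeyError):
            transition_trace(frames, 99)


class TestDetectFlips:
    def test_hand_computed_circular_deltas(self):
        # psi_1: -45 -> 150 (|delta| = 165), phi_2: -60 -> 120 (|delta| = 180)
        f0 = [rec(1, -100, -45), rec(2, -60, -40)]
        f1 = [rec(1, -100, 150), rec(2, 120, -40)]
        events = detect_flips([f0, f1])
        assert len(events) == 1
        ev = events[0]
        assert ev.plane == (1, 2)
        assert abs(ev.delta_psi_i) == pytest.approx(165.0)
        assert abs(ev.delta_phi_ip1) == pytest.approx(180.0)

    def test_small_drift_below_threshold(self):
        f0 = [rec(1, -100, -45), rec(2, -60, -40)]
        f1 = [rec(1, -90, -35), rec(2, -50, -30)]
        assert detect_flips([f0, f1]) == []

    def test_concerted_requirement_rejects_lone_psi_jump(self):
        f0 = [rec(1, -100, -45), rec(2, -60, -40)]
        f1 = [rec(1, -100, 150), rec(2, -60, -40)]  # phi_2 unchanged
        assert detect_flips([f0, f1]) == []

    def test_neighbor_motion_vetoes_event(self):
        # both plane torsions jump but so does the flanking phi_1
        f0 = [rec(1, -100, -45), rec(2, -60, -40)]
        f1 = [rec(1, 100, 150), rec(2, 120, -40)]
        assert detect_flips([f0, f1]) == []

    def test_flip_and_reversal(self):
        frames, truth = plant_flip_series(
            n_residues=4, n_frames=30, flips=[(1, 10), (1, 20)], jitter_deg=3.0, seed=2
        )
        consec = detect_flips(frames, compare="consecutive")
        assert [(e.plane, e.frame_to) for e in consec] == [((2, 3), 10), ((2, 3), 20)]
        # after flipping back, the final frame shows no net change vs frame 0
        vs0 = detect_flips(frames, compare="vs_initial")
        assert all(ev.frame_to < 20 for ev in vs0)

    def test_time_reversal_symmetry(self):
        frames, _ = plant_flip_series(
            n_residues=5, n_frames=25, flips=[(2, 7), (1, 15)], jitter_deg=3.0, seed=4
        )
        fwd = detect_flips(frames)
        rev = detect_flips(frames[::-1])
        assert len(fwd) == len(rev)
        n = len(frames)
        assert sorted((e.plane, n - 1 - e.frame_to, n - 1 - e.frame_from) for e in fwd) == \
            sorted((e.plane, e.frame_from, e.frame_to) for e in rev)

    def test_threshold_validation(self):
        frames = frames_from_phipsi([[(-60, -45)] * 2] * 2)
        with pytest.raises(ValueError):
            detect_flips(frames, theta_deg=0.0)
        with pytest.raises(ValueError):
            detect_flips(frames[:1])


def test_circular_difference_wraps_through_180():
    assert circular_difference(-45.0, 150.0) == pytest.approx(-165.0)
    assert circular_difference(170.0, -170.0) == pytest.approx(20.0)
    assert abs(circular_difference(-60.0, 120.0)) == pytest.approx(180.0)
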