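"""Frame-wise analysis of conformational-state trajectories.

Turns per-frame dihedral records into a frames x residues state matrix and
computes the quantities used to characterise alpha-strand formation along a
trajectory: per-window match counts ("number of alpha-strands" = number of
recorded frames in which an anchored window spells its alternating pattern),
distinct formation events (maximal runs of consecutive matching frames),
first-appearance times, per-residue dihedral transition traces, and
peptide-plane flip events.

A peptide-plane flip is the concerted rotation of the rigid CO-NH unit
between residues i and i+1: psi_i and phi_{i+1} change together by a large
circular difference while the flanking torsions (phi_i, psi_{i+1}) stay put.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .dihedral_core import ConformationState, DihedralRecord, classify
from .strand_scan import StrandPattern

__all__ = [
    "StateMatrix",
    "WindowSummary",
    "FlipEvent",
    "TransitionTrace",
    "state_matrix",
    "window_summary",
    "transition_trace",
    "detect_flips",
    "circular_difference",
]

_CODE_OF = {s: i for i, s in enumerate(ConformationState)}
_STATE_OF = {i: s for s, i in _CODE_OF.items()}


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Signed circular difference b - a wrapped into [-180, 180)."""
    return ((b_deg - a_deg + 180.0) % 360.0) - 180.0


@dataclass
class StateMatrix:
    """Frames x residues grid of conformational states with frame times."""

    residue_ids: list[int]            # author residue numbers, column order
    residue_labels: list[str]
    frame_times_ps: np.ndarray        # strictly increasing
    states: np.ndarray                # int8 codes, shape (n_frames, n_residues)
    stride_ps: Optional[float] = None

    def __post_init__(self):
        self.frame_times_ps = np.asarray(self.frame_times_ps, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        nf, nr = self.states.shape
        if len(self.frame_times_ps) != nf:
            raise ValueError("frame_times_ps length must equal the number of frames")
        if len(self.residue_ids) != nr or len(self.residue_labels) != nr:
            raise ValueError("residue id/label lists must match the number of columns")
        if nf > 1 and not np.all(np.diff(self.frame_times_ps) > 0):
            raise ValueError("frame_times_ps must be strictly increasing")
        if self.stride_ps is not None and self.stride_ps <= 0:
            raise ValueError("stride_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_residues(self) -> int:
        return self.states.shape[1]

    def state(self, frame: int, residue_idx: int) -> ConformationState:
        return _STATE_OF[int(self.states[frame, residue_idx])]

    def column(self, res_id: int) -> int:
        try:
            return self.residue_ids.index(res_id)
        except ValueError:
            raise KeyError(f"residue {res_id} not in matrix") from None

    def frame_states(self, frame: int) -> dict[int, ConformationState]:
        """Author-number -> state mapping for one frame."""
        return {
            rid: _STATE_OF[int(code)]
            for rid, code in zip(self.residue_ids, self.states[frame])
        }

    @classmethod
    def from_codes(cls, residue_ids, codes: Sequence[str] | np.ndarray, times_ps=None,
                   stride_ps: Optional[float] = None, residue_labels=None) -> "StateMatrix":
        """Build from per-frame state-code strings (e.g. ["ROL", "RLR", ...])."""
        grid = np.array(
            [[_CODE_OF[ConformationState(c)] for c in row] for row in codes], dtype=np.int8
        )
        if times_ps is None:
            step = stride_ps if stride_ps else 1.0
            times_ps = np.arange(grid.shape[0]) * step
        if residue_labels is None:
            residue_labels = [str(r) for r in residue_ids]
        return cls(list(residue_ids), list(residue_labels), times_ps, grid, stride_ps)


@dataclass
class WindowSummary:
    """Per-window alpha-strand census over a trajectory."""

    window: tuple[int, ...]
    pattern_string: str
    match_mask: np.ndarray           # per-frame booleans
    frame_count: int
    event_count: int
    first_appearance_ps: Optional[float]   # None = ABSENT
    occupancy_fraction: float

    @property
    def first_appearance_ns(self) -> Optional[float]:
        return None if self.first_appearance_ps is None else self.first_appearance_ps / 1000.0

    def to_table(self):
        header = [
            "window", "pattern", "frame_count", "event_count",
            "first_appearance_ps", "occupancy_fraction", "match_mask",
        ]
        row = [
            "-".join(str(w) for w in self.window),
            self.pattern_string,
            self.frame_count,
            self.event_count,
            "ABSENT" if self.first_appearance_ps is None else repr(self.first_appearance_ps),
            repr(self.occupancy_fraction),
            "".join("1" if m else "0" for m in self.match_mask),
        ]
        return header, [row]

    @classmethod
    def from_table(cls, header, rows) -> "WindowSummary":
        d = dict(zip(header, rows[0]))
        first = None if d["first_appearance_ps"] == "ABSENT" else float(d["first_appearance_ps"])
        return cls(
            window=tuple(int(x) for x in d["window"].split("-")),
            pattern_string=d["pattern"],
            match_mask=np.array([c == "1" for c in d["match_mask"]]),
            frame_count=int(d["frame_count"]),
            event_count=int(d["event_count"]),
            first_appearance_ps=first,
            occupancy_fraction=float(d["occupancy_fraction"]),
        )

    def to_json_dict(self) -> dict:
        return {
            "window": list(self.window),
            "pattern": self.pattern_string,
            "frame_count": self.frame_count,
            "event_count": self.event_count,
            "first_appearance_ps": self.first_appearance_ps,
            "occupancy_fraction": self.occupancy_fraction,
            "match_mask": "".join("1" if m else "0" for m in self.match_mask),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "WindowSummary":
        return cls(
            window=tuple(d["window"]),
            pattern_string=d["pattern"],
            match_mask=np.array([c == "1" for c in d["match_mask"]]),
            frame_count=d["frame_count"],
            event_count=d["event_count"],
            first_appearance_ps=d["first_appearance_ps"],
            occupancy_fraction=d["occupancy_fraction"],
        )

    def __eq__(self, other):
        if not isinstance(other, WindowSummary):
            return NotImplemented
        return (
            self.window == other.window
            and self.pattern_string == other.pattern_string
            and np.array_equal(self.match_mask, other.match_mask)
            and self.frame_count == other.frame_count
            and self.event_count == other.event_count
            and self.first_appearance_ps == other.first_appearance_ps
            and abs(self.occupancy_fraction - other.occupancy_fraction) < 1e-12
        )


@dataclass(frozen=True)
class FlipEvent:
    """A concerted peptide-plane rotation between two compared frames."""

    plane: tuple[int, int]           # author numbers (res_i, res_i+1)
    frame_from: int
    frame_to: int
    delta_psi_i: float
    delta_phi_ip1: float
    neighbor_deltas: tuple[Optional[float], Optional[float]]  # (dphi_i, dpsi_ip1)

    @staticmethod
    def table_header() -> list[str]:
        return ["res_i", "res_ip1", "frame_from", "frame_to",
                "delta_psi_i", "delta_phi_ip1", "delta_phi_i", "delta_psi_ip1"]

    def to_row(self) -> list:
        nd = ["NA" if v is None else round(v, 3) for v in self.neighbor_deltas]
        return [self.plane[0], self.plane[1], self.frame_from, self.frame_to,
                round(self.delta_psi_i, 3), round(self.delta_phi_ip1, 3), nd[0], nd[1]]


@dataclass
class TransitionTrace:
    """Full (time, phi, psi, state) series for one residue plus its state changes."""

    residue: int
    series: list[tuple[float, Optional[float], Optional[float], ConformationState]]
    changes: list[tuple[float, ConformationState, ConformationState]]  # (time, old, new)

    @property
    def initial(self):
        return self.series[0]

    def first_in_state(self, state: ConformationState):
        """Earliest series point in the given state, or None."""
        for point in self.series:
            if point[3] is state:
                return point
        return None


def _check_frames(frames: Sequence[Sequence[DihedralRecord]]) -> list[tuple[str, int, str]]:
    if not frames:
        raise ValueError("no frames")
    ref = [rec.residue_ref for rec in frames[0]]
    for t, frame in enumerate(frames):
        refs = [rec.residue_ref for rec in frame]
        if refs != ref:
            raise ValueError(f"frame {t} residue set/order differs from frame 0")
    return ref


def state_matrix(
    frames: Sequence[Sequence[DihedralRecord]],
    times_ps: Optional[Sequence[float]] = None,
    stride_ps: Optional[float] = None,
) -> StateMatrix:
    """Classify every residue of every frame into a StateMatrix.

    Frames must cover the same residues in the same order (ragged input is a
    shape error naming the offending frame).  Times default to
    ``frame_index * stride_ps`` (stride 1 ps when unspecified).
    """
    ref = _check_frames(frames)
    grid = np.array(
        [[_CODE_OF[rec.state()] for rec in frame] for frame in frames], dtype=np.int8
    )
    if times_ps is None:
        step = stride_ps if stride_ps else 1.0
        times_ps = np.arange(len(frames)) * step
    ids = [r[1] for r in ref]
    labels = [f"{r[2]}-{r[1]}" for r in ref]
    return StateMatrix(ids, labels, np.asarray(times_ps, float), grid, stride_ps)


def _event_count(mask: np.ndarray) -> int:
    if mask.size == 0:
        return 0
    m = mask.astype(np.int8)
    return int(m[0]) + int(np.sum((m[1:] == 1) & (m[:-1] == 0)))


def window_summary(matrix: StateMatrix, pattern: StrandPattern) -> WindowSummary:
    """Census of an anchored alternating pattern over all frames.

    ``frame_count`` is the number of frames in which the window spells the
    pattern (the per-frame reading of "number of alpha-strands");
    ``event_count`` is the number of maximal runs of consecutive matching
    frames (the distinct-event reading).  ``first_appearance_ps`` is None
    when the pattern never appears.
    """
    if pattern.anchored_window is None:
        raise ValueError("window_summary requires an anchored pattern")
    cols = [matrix.column(r) for r in pattern.anchored_window]  # KeyError if absent
    want = np.array(
        [_CODE_OF[ConformationState(c)] for c in pattern.pattern_string], dtype=np.int8
    )
    mask = np.all(matrix.states[:, cols] == want[None, :], axis=1)
    frame_count = int(np.sum(mask))
    first = None
    if frame_count:
        first = float(matrix.frame_times_ps[int(np.argmax(mask))])
    return WindowSummary(
        window=tuple(pattern.anchored_window),
        pattern_string=pattern.pattern_string,
        match_mask=mask,
        frame_count=frame_count,
        event_count=_event_count(mask),
        first_appearance_ps=first,
        occupancy_fraction=frame_count / matrix.n_frames,
    )


def transition_trace(
    frames: Sequence[Sequence[DihedralRecord]],
    residue: int,
    times_ps: Optional[Sequence[float]] = None,
) -> TransitionTrace:
    """Time series of (phi, psi, state) for one residue, plus state changes.

    Supports the initial-vs-first-strand comparison: ``trace.initial`` is the
    starting conformation and ``trace.first_in_state(ALPHA_R)`` the first
    frame in a given quadrant.
    """
    ref = _check_frames(frames)
    ids = [r[1] for r in ref]
    try:
        col = ids.index(residue)
    except ValueError:
        raise KeyError(f"residue {residue} not present in frames") from None
    if times_ps is None:
        times_ps = np.arange(len(frames), dtype=float)
    series = []
    changes = []
    prev_state = None
    for t, frame in zip(times_ps, frames):
        rec = frame[col]
        st = rec.state()
        series.append((float(t), rec.phi_deg, rec.psi_deg, st))
        if prev_state is not None and st is not prev_state:
            changes.append((float(t), prev_state, st))
        prev_state = st
    return TransitionTrace(residue=residue, series=series, changes=changes)


def detect_flips(
    frames: Sequence[Sequence[DihedralRecord]],
    theta_deg: float = 90.0,
    neighbor_theta_deg: float = 90.0,
    compare: Literal["consecutive", "vs_initial"] = "consecutive",
) -> list[FlipEvent]:
    """Peptide-plane flips between compared frame pairs.

    For each plane (i, i+1) a flip is emitted when circular |delta psi_i| and
    |delta phi_{i+1}| both reach ``theta_deg`` while the flanking torsions
    move less than ``neighbor_theta_deg`` (an undefined flanking torsion
    imposes no constraint).  ``consecutive`` compares frame t-1 with t;
    ``vs_initial`` compares frame 0 with every later frame.
    """
    if not (0.0 < theta_deg <= 180.0) or not (0.0 < neighbor_theta_deg <= 180.0):
        raise ValueError("thresholds must lie in (0, 180]")
    ref = _check_frames(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    ids = [r[1] for r in ref]
    events: list[FlipEvent] = []
    if compare == "consecutive":
        pairs = [(t - 1, t) for t in range(1, len(frames))]
    elif compare == "vs_initial":
        pairs = [(0, t) for t in range(1, len(frames))]
    else:
        raise ValueError(f"unknown compare mode {compare!r}")
    for a, b in pairs:
        fa, fb = frames[a], frames[b]
        for i in range(len(ids) - 1):
            ra, rb = fa[i], fb[i]
            sa, sb = fa[i + 1], fb[i + 1]
            if ra.psi_deg is None or rb.psi_deg is None:
                continue
            if sa.phi_deg is None or sb.phi_deg is None:
                continue
            dpsi = circular_difference(ra.psi_deg, rb.psi_deg)
            dphi1 = circular_difference(sa.phi_deg, sb.phi_deg)
            if abs(dpsi) < theta_deg or abs(dphi1) < theta_deg:
                continue
            dphi0 = (
                None
                if ra.phi_deg is None or rb.phi_deg is None
                else circular_difference(ra.phi_deg, rb.phi_deg)
            )
            dpsi1 = (
                None
                if sa.psi_deg is None or sb.psi_deg is None
                else circular_difference(sa.psi_deg, sb.psi_deg)
            )
            if dphi0 is not None and abs(dphi0) >= neighbor_theta_deg:
                continue
            if dpsi1 is not None and abs(dpsi1) >= neighbor_theta_deg:
                continue
            events.append(
                FlipEvent(
                    plane=(ids[i], ids[i + 1]),
                    frame_from=a,
                    frame_to=b,
                    delta_psi_i=dpsi,
                    delta_phi_ip1=dphi1,
                    neighbor_deltas=(dphi0, dpsi1),
                )
            )
    return events
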