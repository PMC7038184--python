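"""Detection of alpha-strand motifs: alternating ALPHA_R/ALPHA_L runs.

A strand hit is a run of >= ``min_len`` successive residues whose
conformational states strictly alternate between the two helical quadrants
(either start state).  Runs never extend across OTHER or UNDEFINED residues
or chain breaks — the definition requires every residue of the run to *be*
in one of the two quadrants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .dihedral_core import ConformationState, states_for_model
from .structure_io import StructureModel

__all__ = ["StrandPattern", "StrandHit", "find_alternating_runs", "match_anchored", "scan_structure"]

_RL = (ConformationState.ALPHA_R, ConformationState.ALPHA_L)


def _alternates(pattern: str) -> bool:
    return len(pattern) >= 2 and all(
        a != b for a, b in zip(pattern, pattern[1:])
    ) and set(pattern) <= {"R", "L"}


def alternating_pattern(start: str, length: int) -> str:
    """The alternating R/L pattern string of given length and start state."""
    other = "L" if start == "R" else "R"
    return "".join(start if i % 2 == 0 else other for i in range(length))


@dataclass(frozen=True)
class StrandPattern:
    """An alternating R/L pattern, optionally anchored to author residue numbers."""

    pattern_string: str
    anchored_window: Optional[tuple[int, ...]] = None
    min_len: int = 3

    def __post_init__(self):
        if not _alternates(self.pattern_string):
            raise ValueError(
                f"pattern {self.pattern_string!r} must strictly alternate over R/L, length >= 2"
            )
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.anchored_window is not None:
            win = tuple(self.anchored_window)
            if len(win) != len(self.pattern_string):
                raise ValueError("anchored_window length must equal pattern length")
            if any(b - a != 1 for a, b in zip(win, win[1:])):
                raise ValueError("anchored_window must be consecutive author residue numbers")
            object.__setattr__(self, "anchored_window", win)


@dataclass(frozen=True)
class StrandHit:
    """A detected alternating run in one (entry, model, chain)."""

    entry_id: str
    model_index: int
    chain_id: str
    start_res: int
    length: int
    pattern_string: str
    window_sequence: str

    @staticmethod
    def table_header() -> list[str]:
        return ["entry_id", "model_index", "chain_id", "start_res", "length", "pattern", "sequence"]

    def to_row(self) -> list:
        return [
            self.entry_id,
            self.model_index,
            self.chain_id,
            self.start_res,
            self.length,
            self.pattern_string,
            self.window_sequence,
        ]

    def to_json_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "model_index": self.model_index,
            "chain_id": self.chain_id,
            "start_res": self.start_res,
            "length": self.length,
            "pattern": self.pattern_string,
            "sequence": self.window_sequence,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "StrandHit":
        return cls(
            d["entry_id"], int(d["model_index"]), d["chain_id"], int(d["start_res"]),
            int(d["length"]), d["pattern"], d["sequence"],
        )


class HitList(list):
    """A list of StrandHits that round-trips through TSV/JSON reports."""

    @staticmethod
    def table_header() -> list[str]:
        return StrandHit.table_header()

    def to_table(self):
        return self.table_header(), [h.to_row() for h in self]

    def to_json_dict(self):
        return [h.to_json_dict() for h in self]

    @classmethod
    def from_table(cls, header, rows) -> "HitList":
        out = cls()
        for r in rows:
            d = dict(zip(header, r))
            out.append(
                StrandHit(
                    d["entry_id"], int(d["model_index"]), d["chain_id"],
                    int(d["start_res"]), int(d["length"]), d["pattern"], d["sequence"],
                )
            )
        return out

    @classmethod
    def from_json_dict(cls, items) -> "HitList":
        return cls(StrandHit.from_json_dict(d) for d in items)


def find_alternating_runs(
    states: Sequence[ConformationState],
    min_len: int = 3,
    *,
    breaks: frozenset[int] | set[int] = frozenset(),
    required_start: Optional[ConformationState] = None,
    residue_numbers: Optional[Sequence[int]] = None,
    sequence: Optional[str] = None,
    entry_id: str = "",
    model_index: int = 1,
    chain_id: str = "",
) -> list[StrandHit]:
    """All maximal alternating runs of length >= min_len, sorted by start.

    ``breaks`` holds indices i with a chain break between positions i and
    i+1.  When ``required_start`` is set, a maximal run beginning with the
    other state is trimmed by one residue so that every reported run starts
    in the required state.  Positions are reported as author residue numbers
    when ``residue_numbers`` is given, else as 0-based indices.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    hits: list[StrandHit] = []
    n = len(states)
    i = 0
    while i < n:
        if states[i] not in _RL:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and states[j + 1] in _RL
            and states[j + 1] != states[j]
            and j not in breaks
        ):
            j += 1
        start, end = i, j  # inclusive maximal run
        if required_start is not None and states[start] != required_start:
            start += 1
        length = end - start + 1
        if length >= min_len and (required_start is None or start <= end):
            pattern = "".join(states[k].code for k in range(start, end + 1))
            hits.append(
                StrandHit(
                    entry_id=entry_id,
                    model_index=model_index,
                    chain_id=chain_id,
                    start_res=residue_numbers[start] if residue_numbers is not None else start,
                    length=length,
                    pattern_string=pattern,
                    window_sequence=sequence[start : end + 1] if sequence is not None else "",
                )
            )
        i = j + 1
    return hits


def match_anchored(
    states: Mapping[int, ConformationState], pattern: StrandPattern
) -> bool:
    """True iff the residues at exactly the anchored window spell the pattern.

    ``states`` maps author residue numbers to states.  A window residue
    absent from the mapping raises ``KeyError`` (distinct from a non-match).
    """
    if pattern.anchored_window is None:
        raise ValueError("pattern has no anchored_window")
    for resnum, want in zip(pattern.anchored_window, pattern.pattern_string):
        state = states[resnum]  # KeyError if the residue is missing
        if state.code != want:
            return False
    return True


def scan_structure(
    model: StructureModel,
    min_len: int = 3,
    motif: Optional[str] = None,
    required_start: Optional[ConformationState] = None,
) -> list[StrandHit]:
    """Scan every chain of one model for alpha-strand hits.

    Without a motif, reports maximal alternating runs of length >= min_len.
    With a one-letter ``motif`` (plain subsequence, no wildcards), reports
    every window of length len(motif) whose sequence equals the motif and
    whose states alternate over R/L (starting with ``required_start`` when
    set); overlapping windows are all reported.
    """
    hits = HitList()
    for chain_id, residues in model.chains.items():
        states = [s for _, s in states_for_model(model, chain_id)]
        numbers = [r.res_seq for r in residues]
        seq = model.sequence(chain_id)
        breaks = model.breaks(chain_id)
        if motif is None:
            hits.extend(
                find_alternating_runs(
                    states,
                    min_len,
                    breaks=breaks,
                    required_start=required_start,
                    residue_numbers=numbers,
                    sequence=seq,
                    entry_id=model.entry_id,
                    model_index=model.model_index,
                    chain_id=chain_id,
                )
            )
            continue
        w = len(motif)
        if w < 2:
            raise ValueError("motif must have length >= 2")
        for i in range(len(states) - w + 1):
            if seq[i : i + w] != motif:
                continue
            window = states[i : i + w]
            if any(s not in _RL for s in window):
                continue
            if any(a == b for a, b in zip(window, window[1:])):
                continue
            if any(k in breaks for k in range(i, i + w - 1)):
                continue
            if required_start is not None and window[0] != required_start:
                continue
            hits.append(
                StrandHit(
                    entry_id=model.entry_id,
                    model_index=model.model_index,
                    chain_id=chain_id,
                    start_res=numbers[i],
                    length=w,
                    pattern_string="".join(s.code for s in window),
                    window_sequence=motif,
                )
            )
    hits.sort(key=lambda h: (h.chain_id, h.start_res))
    return hits
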