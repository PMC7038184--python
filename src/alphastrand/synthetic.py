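"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here at desk
scale: peptide backbones with prescribed (phi, psi, omega) built by
sequential internal-coordinate placement, ideal alpha-strand peptides,
stochastic frames x residues state trajectories with two-state flip kinetics
and planted alternating windows, planted mini structure collections, and
dihedral time series with planted peptide-plane flips.  Each generator
returns (or writes alongside its output) a ground-truth manifest so that
pipeline results can be checked exactly.

The simulator is a statistical stand-in for molecular-dynamics ensembles:
it reproduces the *counting* structure of trajectory analyses (how often a
window matches, when it first appears, how flips cluster) but none of the
physics — no solvent, side chains or energetics.

Representative quadrant-interior dihedrals (-60, -45) for ALPHA_R and
(60, 45) for ALPHA_L are used throughout; (-120, 130) serves as an
extended/beta-like OTHER conformation.  Only the signs matter downstream,
so any interior values would do; these sit well away from the quadrant
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dihedral_core import ConformationState, DihedralRecord
from .structure_io import (
    BackboneResidue,
    ExperimentMethod,
    StructureModel,
    wrap_angle,
    write_structure_pdb,
)
from .trajectory_analysis import StateMatrix

__all__ = [
    "GeometryConstants",
    "BackboneSpec",
    "SimulationSpec",
    "GroundTruthManifest",
    "REP_ALPHA_R",
    "REP_ALPHA_L",
    "REP_OTHER",
    "build_backbone",
    "ideal_alpha_strand",
    "simulate_states",
    "plant_collection",
    "plant_flip_series",
]

REP_ALPHA_R = (-60.0, -45.0)
REP_ALPHA_L = (60.0, 45.0)
REP_OTHER = (-120.0, 130.0)

_REP_OF = {
    ConformationState.ALPHA_R: REP_ALPHA_R,
    ConformationState.ALPHA_L: REP_ALPHA_L,
    ConformationState.OTHER: REP_OTHER,
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class GeometryConstants:
    """Standard peptide backbone bond lengths (Angstrom) and angles (degrees)."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.8

    def __post_init__(self):
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o",
                     "angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca", "angle_ca_c_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BackboneSpec:
    """Sequence plus per-residue (phi, psi, omega) for the builder."""

    sequence: str
    per_residue_dihedrals: Sequence[tuple[float, float, float]]
    geometry: GeometryConstants = field(default_factory=GeometryConstants)
    chain_id: str = "A"
    first_res_seq: int = 1
    entry_id: str = "SYNTH"

    def __post_init__(self):
        if len(self.sequence) != len(self.per_residue_dihedrals):
            raise ValueError("sequence and dihedral list lengths must match")
        if not self.sequence:
            raise ValueError("empty sequence")


class BackboneConstructionError(ValueError):
    """Raised when requested internal coordinates produce overlapping atoms."""


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """Next-atom placement from three predecessors (natural-extension frame)."""
    ang = np.radians(angle_deg)
    tors = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise BackboneConstructionError("collinear reference atoms")
    n = n / nn
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tors),
        bond * np.sin(ang) * np.sin(tors),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(spec: BackboneSpec) -> StructureModel:
    """Construct N/CA/C/O coordinates realising the requested dihedrals.

    Atoms are placed sequentially: psi_i orients N(i+1), omega_{i+1} orients
    CA(i+1), phi_{i+1} orients C(i+1).  Carbonyl O(i) is placed in the C(i)
    plane trans to N(i+1) (torsion psi_i + 180).  Re-measuring the built
    model recovers the requested interior phi/psi to well under 0.5 degrees.
    """
    g = spec.geometry
    n_res = len(spec.sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g.bond_n_ca, 0.0, 0.0)
    theta = np.radians(180.0 - g.angle_n_ca_c)
    C[0] = CA[0] + g.bond_ca_c * np.array([np.cos(theta), np.sin(theta), 0.0])

    for i in range(n_res - 1):
        psi_i = spec.per_residue_dihedrals[i][1]
        omega_next = spec.per_residue_dihedrals[i + 1][2]
        phi_next = spec.per_residue_dihedrals[i + 1][0]
        N[i + 1] = _place(N[i], CA[i], C[i], g.bond_c_n, g.angle_ca_c_n, psi_i)
        CA[i + 1] = _place(CA[i], C[i], N[i + 1], g.bond_n_ca, g.angle_c_n_ca, omega_next)
        C[i + 1] = _place(C[i], N[i + 1], CA[i + 1], g.bond_ca_c, g.angle_n_ca_c, phi_next)

    for i in range(n_res):
        psi_i = spec.per_residue_dihedrals[i][1]
        O[i] = _place(N[i], CA[i], C[i], g.bond_c_o, g.angle_ca_c_o, psi_i + 180.0)

    coords = np.vstack([N, CA, C, O])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if np.min(d) < 0.5:
        raise BackboneConstructionError(
            f"requested geometry places atoms {np.min(d):.3f} A apart (< 0.5 A)"
        )

    residues = []
    for i, aa in enumerate(spec.sequence):
        residues.append(
            BackboneResidue(
                chain_id=spec.chain_id,
                res_seq=spec.first_res_seq + i,
                icode="",
                name3=_ONE_TO_THREE.get(aa, "UNK"),
                one_letter=aa if aa in _ONE_TO_THREE else "X",
                coords_N=N[i],
                coords_CA=CA[i],
                coords_C=C[i],
                coords_O=O[i],
            )
        )
    return StructureModel(
        entry_id=spec.entry_id,
        model_index=1,
        method=ExperimentMethod.UNKNOWN,
        chains={spec.chain_id: residues},
        chain_breaks={spec.chain_id: frozenset()},
        provenance="synthetic:build_backbone",
    )


def ideal_alpha_strand(
    sequence: str,
    start_state: ConformationState = ConformationState.ALPHA_R,
    first_res_seq: int = 1,
    **spec_kwargs,
) -> StructureModel:
    """A peptide whose given residues alternate ALPHA_R/ALPHA_L.

    The requested sequence is flanked by one glycine cap on each side
    (continuing the alternation) so that every requested residue has both
    dihedrals defined — a free peptide's termini always classify UNDEFINED.
    The caps become the new termini, so scanning finds exactly one maximal
    run spanning the requested residues, starting in ``start_state``.
    Representative quadrant dihedrals with omega = 180 are used throughout.
    ``first_res_seq`` numbers the first *requested* residue; caps take the
    adjacent numbers.
    """
    if len(sequence) < 3:
        raise ValueError("sequence must have length >= 3")
    if start_state not in (ConformationState.ALPHA_R, ConformationState.ALPHA_L):
        raise ValueError("start_state must be ALPHA_R or ALPHA_L")
    other = (
        ConformationState.ALPHA_L
        if start_state is ConformationState.ALPHA_R
        else ConformationState.ALPHA_R
    )
    capped = "G" + sequence + "G"
    # index 1 (first requested residue) carries start_state
    states = [start_state if (i - 1) % 2 == 0 else other for i in range(len(capped))]
    dihedrals = [(*_REP_OF[s], 180.0) for s in states]
    return build_backbone(
        BackboneSpec(capped, dihedrals, first_res_seq=first_res_seq - 1, **spec_kwargs)
    )


# ---------------------------------------------------------------------------
# stochastic state trajectories

@dataclass
class SimulationSpec:
    """Two-state flip-kinetics trajectory specification.

    Residues whose baseline state is ALPHA_R or ALPHA_L are flip-able: each
    follows an independent two-state Markov chain between its baseline and
    the opposite quadrant, entering the flipped state with per-frame
    probability ``flip_on_prob`` and reverting with ``flip_off_prob``.
    OTHER-baseline residues are static.  ``planted_window`` =
    (author-number window, pattern string, frame indices) overrides sampled
    states in the listed frames.
    """

    n_residues: int
    n_frames: int
    stride_ps: float = 2.0
    baseline_states: Optional[Sequence[ConformationState]] = None
    flip_on_prob: float = 0.0
    flip_off_prob: float = 0.0
    planted_window: Optional[tuple[Sequence[int], str, Sequence[int]]] = None
    seed: int = 0
    first_res_seq: int = 1

    def __post_init__(self):
        if self.n_residues < 1 or self.n_frames < 1:
            raise ValueError("n_residues and n_frames must be positive")
        if not (0.0 <= self.flip_on_prob <= 1.0 and 0.0 <= self.flip_off_prob <= 1.0):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.stride_ps <= 0:
            raise ValueError("stride_ps must be positive")
        if self.baseline_states is None:
            self.baseline_states = [ConformationState.OTHER] * self.n_residues
        if len(self.baseline_states) != self.n_residues:
            raise ValueError("baseline_states length must equal n_residues")
        if self.planted_window is not None:
            window, pattern, frames = self.planted_window
            if len(window) != len(pattern):
                raise ValueError("planted window and pattern lengths differ")
            lo = self.first_res_seq
            hi = self.first_res_seq + self.n_residues - 1
            if any(not (lo <= w <= hi) for w in window):
                raise ValueError("planted window outside residue range")
            if any(not (0 <= f < self.n_frames) for f in frames):
                raise ValueError("planted frames outside trajectory range")


@dataclass
class GroundTruthManifest:
    """What a generator planted, in pipeline-comparable terms."""

    kind: str
    entries: list[dict] = field(default_factory=list)
    totals: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"kind": self.kind, "entries": self.entries, "totals": self.totals}


_FLIPPED = {
    ConformationState.ALPHA_R: ConformationState.ALPHA_L,
    ConformationState.ALPHA_L: ConformationState.ALPHA_R,
}


def simulate_states(spec: SimulationSpec) -> tuple[StateMatrix, GroundTruthManifest]:
    """Sample a state trajectory and report exact ground truth.

    The manifest records, for the planted window (when present), every frame
    in which the window spells its pattern in the final matrix — planted
    frames by construction, plus any frames where the Markov sampling
    produced the pattern spontaneously — together with per-residue
    transition tallies for kinetics recovery.
    """
    rng = np.random.default_rng(spec.seed)
    base = list(spec.baseline_states)
    codes = np.empty((spec.n_frames, spec.n_residues), dtype="U1")
    on_transitions = np.zeros(spec.n_residues, dtype=int)
    baseline_frames = np.zeros(spec.n_residues, dtype=int)
    flipped = np.zeros(spec.n_residues, dtype=bool)
    for t in range(spec.n_frames):
        for i, b in enumerate(base):
            if b in _FLIPPED:
                if flipped[i]:
                    if rng.random() < spec.flip_off_prob:
                        flipped[i] = False
                else:
                    baseline_frames[i] += 1
                    if rng.random() < spec.flip_on_prob:
                        flipped[i] = True
                        on_transitions[i] += 1
                state = _FLIPPED[b] if flipped[i] else b
            else:
                state = b
            codes[t, i] = state.code
    planted_frames: list[int] = []
    if spec.planted_window is not None:
        window, pattern, frames = spec.planted_window
        cols = [w - spec.first_res_seq for w in window]
        for f in sorted(set(frames)):
            for c, p in zip(cols, pattern):
                codes[f, c] = p
            planted_frames.append(int(f))
    ids = list(range(spec.first_res_seq, spec.first_res_seq + spec.n_residues))
    matrix = StateMatrix.from_codes(
        ids, ["".join(row) for row in codes],
        times_ps=np.arange(spec.n_frames) * spec.stride_ps,
        stride_ps=spec.stride_ps,
    )
    totals: dict = {
        "n_frames": spec.n_frames,
        "flip_on_prob": spec.flip_on_prob,
        "flip_off_prob": spec.flip_off_prob,
        "on_transitions": on_transitions.tolist(),
        "baseline_frames": baseline_frames.tolist(),
    }
    entries: list[dict] = []
    if spec.planted_window is not None:
        window, pattern, _ = spec.planted_window
        cols = [w - spec.first_res_seq for w in window]
        match_frames = [
            int(t)
            for t in range(spec.n_frames)
            if all(codes[t, c] == p for c, p in zip(cols, pattern))
        ]
        entries.append(
            {
                "window": [int(w) for w in window],
                "pattern": pattern,
                "planted_frames": planted_frames,
                "match_frames": match_frames,
                "frame_count": len(match_frames),
                "event_count": _runs(match_frames),
                "first_appearance_ps": (
                    match_frames[0] * spec.stride_ps if match_frames else None
                ),
            }
        )
        totals["frame_count"] = len(match_frames)
    return matrix, GroundTruthManifest(kind="state_trajectory", entries=entries, totals=totals)


def _runs(sorted_frames: list[int]) -> int:
    if not sorted_frames:
        return 0
    return 1 + sum(1 for a, b in zip(sorted_frames, sorted_frames[1:]) if b - a > 1)


# ---------------------------------------------------------------------------
# planted structure collections

_DECOY_ALPHABET = "ADEFKLNQTY"  # avoids V/G/S so motifs appear only where planted


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_DECOY_ALPHABET), size=n))


def _entry_with_occurrences(
    entry_id: str, motif: str, n_occ: int, rng: np.random.Generator,
    method: ExperimentMethod,
) -> list[StructureModel]:
    """One multi-model entry carrying exactly n_occ planted occurrences.

    Each model holds one occurrence: the motif embedded mid-chain with
    alternating quadrant dihedrals, flanked by extended (OTHER) context and
    the termini, so the alternating run is exactly the motif window.
    """
    models = []
    for m in range(1, n_occ + 1):
        left = _random_sequence(rng, int(rng.integers(2, 5)))
        right = _random_sequence(rng, int(rng.integers(2, 5)))
        seq = left + motif + right
        dihedrals = []
        for i in range(len(seq)):
            k = i - len(left)
            if 0 <= k < len(motif):
                rep = REP_ALPHA_R if k % 2 == 0 else REP_ALPHA_L
            else:
                rep = REP_OTHER
            dihedrals.append((*rep, 180.0))
        model = build_backbone(
            BackboneSpec(seq, dihedrals, entry_id=entry_id, chain_id="A")
        )
        model.model_index = m
        model.method = method
        models.append(model)
    return models


def _decoy_entry(entry_id: str, motif: str, rng: np.random.Generator,
                 method: ExperimentMethod) -> list[StructureModel]:
    """A decoy: contains the motif sequence but with non-alternating states."""
    left = _random_sequence(rng, int(rng.integers(2, 5)))
    right = _random_sequence(rng, int(rng.integers(2, 5)))
    seq = left + motif + right
    dihedrals = [(*REP_ALPHA_R, 180.0)] * len(seq)  # all (-,-): no alternation
    model = build_backbone(BackboneSpec(seq, dihedrals, entry_id=entry_id, chain_id="A"))
    model.method = method
    return [model]


def plant_collection(
    n_entries: int,
    n_with_hits: int,
    occurrences_per_hit_entry: Sequence[int],
    motif: str = "VGS",
    seed: int = 0,
    out_dir: str | Path = ".",
) -> GroundTruthManifest:
    """Write a mini structure collection with a known occurrence census.

    ``occurrences_per_hit_entry`` gives, per hit entry, how many occurrences
    to plant (one model each).  Experimental methods alternate X-ray / NMR
    across entries so the census can be method-stratified.  Files and the
    manifest are bit-reproducible for a fixed seed.
    """
    if n_with_hits > n_entries:
        raise ValueError("n_with_hits cannot exceed n_entries")
    if len(occurrences_per_hit_entry) != n_with_hits:
        raise ValueError("need one occurrence count per hit entry")
    if any(k < 1 for k in occurrences_per_hit_entry):
        raise ValueError("occurrence counts must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    hit_positions = sorted(rng.choice(n_entries, size=n_with_hits, replace=False).tolist())
    hit_iter = iter(occurrences_per_hit_entry)
    entries = []
    total_occ = 0
    for idx in range(n_entries):
        entry_id = f"SYN{idx:04d}"
        method = ExperimentMethod.XRAY if idx % 2 == 0 else ExperimentMethod.NMR
        if idx in hit_positions:
            n_occ = next(hit_iter)
            models = _entry_with_occurrences(entry_id, motif, n_occ, rng, method)
        else:
            n_occ = 0
            models = _decoy_entry(entry_id, motif, rng, method)
        write_structure_pdb(models, out_dir / f"{entry_id}.pdb")
        total_occ += n_occ
        entries.append(
            {"entry_id": entry_id, "method": method.value, "occurrences": n_occ}
        )
    by_method: dict[str, dict[str, int]] = {}
    for e in entries:
        if e["occurrences"] < 1:
            continue
        d = by_method.setdefault(e["method"], {"structures_with_hits": 0, "occurrences": 0})
        d["structures_with_hits"] += 1
        d["occurrences"] += e["occurrences"]
    return GroundTruthManifest(
        kind="collection",
        entries=entries,
        totals={
            "n_entries": n_entries,
            "structures_with_hits": n_with_hits,
            "total_occurrences": total_occ,
            "motif": motif,
            "by_method": by_method,
        },
    )


# ---------------------------------------------------------------------------
# planted peptide-plane flips

def plant_flip_series(
    n_residues: int = 5,
    n_frames: int = 40,
    flips: Sequence[tuple[int, int]] = ((2, 10),),
    jitter_deg: float = 5.0,
    seed: int = 0,
    first_res_seq: int = 1,
) -> tuple[list[list[DihedralRecord]], list[tuple[int, int, int]]]:
    """Dihedral frames with planted peptide-plane flips and small jitter.

    ``flips`` lists (plane_index i, frame t) pairs: between frames t-1 and t
    the CO-NH plane of residues (i, i+1) toggles, moving psi_i and phi_{i+1}
    by 180 degrees while everything else only jitters by < ``jitter_deg``.
    Returns the frames plus ground truth [(res_i, res_i+1, frame_to), ...]
    in author numbering.  A plane flipped twice returns to its original
    orientation (flip-back).
    """
    if any(not (0 <= i < n_residues - 1) for i, _ in flips):
        raise ValueError("flip plane index out of range")
    if any(not (1 <= t < n_frames) for _, t in flips):
        raise ValueError("flip frame out of range (must be >= 1)")
    by_frame: dict[int, list[int]] = {}
    for i, t in flips:
        by_frame.setdefault(t, []).append(i)
    for t, planes in by_frame.items():
        planes = sorted(planes)
        if any(b - a < 2 for a, b in zip(planes, planes[1:])):
            raise ValueError(
                f"frame {t}: simultaneous flips on adjacent/equal planes share a torsion "
                "and are not separable events"
            )
    rng = np.random.default_rng(seed)
    base_phi = np.full(n_residues, REP_ALPHA_R[0])
    base_psi = np.full(n_residues, REP_ALPHA_R[1])
    offset_psi = np.zeros(n_residues)
    offset_phi = np.zeros(n_residues)
    flips_by_frame: dict[int, list[int]] = {}
    for i, t in flips:
        flips_by_frame.setdefault(t, []).append(i)
    frames: list[list[DihedralRecord]] = []
    truth: list[tuple[int, int, int]] = []
    for t in range(n_frames):
        for i in flips_by_frame.get(t, ()):
            offset_psi[i] = (offset_psi[i] + 180.0) % 360.0
            offset_phi[i + 1] = (offset_phi[i + 1] + 180.0) % 360.0
            truth.append((first_res_seq + i, first_res_seq + i + 1, t))
        frame = []
        for i in range(n_residues):
            phi = base_phi[i] + offset_phi[i] + rng.uniform(-jitter_deg, jitter_deg)
            psi = base_psi[i] + offset_psi[i] + rng.uniform(-jitter_deg, jitter_deg)
            frame.append(
                DihedralRecord(
                    residue_ref=("A", first_res_seq + i, "ALA"),
                    phi_deg=wrap_angle(phi),
                    psi_deg=wrap_angle(psi),
                )
            )
        frames.append(frame)
    return frames, truth
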