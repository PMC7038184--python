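"""Experiment manifest and amyloid-beta sequence variants.

Ships a transcription of the study's simulation manifest — 39 systems over
three NMR starting structures (1IYT, 1Z0Q, 2NAO), wild type and six point
mutants, 310 K and 498 K, neutral and low pH, 50 ns each — plus the
wild-type human Abeta 1-42 sequence and the mutation labels.  The sequence
is validated at load time against its central-region anchors
(V24-G25-S26-N27-K28), the tripeptide VGS at 24-26 being the motif the rest
of the package hunts for.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "SystemManifestEntry",
    "SequenceVariant",
    "ManifestError",
    "AB42_WT",
    "load_manifest",
    "aggregate_run_time",
    "load_variants",
    "apply_variant",
]

_ANCHORS = {24: "V", 25: "G", 26: "S", 27: "N", 28: "K"}
_ANIONS = {"Cl-", "Br-", "I-", "F-"}
_VALID_TEMPERATURES = {310.0, 498.0}


class ManifestError(ValueError):
    """Raised when a manifest row violates its invariants."""


@dataclass(frozen=True)
class SystemManifestEntry:
    system_id: int
    pdb_id: str
    variant: str              # "WT" or a mutation label such as "E22G"
    ion_species: str          # e.g. "Na+", "Cl-"
    ion_count: int
    temperature_K: float
    ph_class: str             # "NpH" or "LpH"
    run_ns: float


def _data_text(name: str) -> str:
    return resources.files("alphastrand.data").joinpath(name).read_text()


def load_manifest(table_path: Optional[str | Path] = None) -> list[SystemManifestEntry]:
    """Load and validate the simulation manifest (the shipped copy by default).

    Invariants checked per row: temperature in {310, 498} K; low-pH systems
    neutralised with anionic counter ions; positive run length; unique
    system ids.  A violation raises :class:`ManifestError` naming the row.
    """
    if table_path is None:
        text = _data_text("table1.tsv")
    else:
        text = Path(table_path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    expected = ["system_id", "pdb_id", "variant", "counter_ion", "temperature_K", "ph", "run_ns"]
    if header != expected:
        raise ManifestError(f"unexpected columns {header}; want {expected}")
    entries: list[SystemManifestEntry] = []
    seen_ids: set[int] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        d = dict(zip(header, line.split("\t")))
        try:
            sid = int(d["system_id"])
            count_str, species = d["counter_ion"].split()
            ion_count = int(count_str)
            temp = float(d["temperature_K"])
            run = float(d["run_ns"])
        except (KeyError, ValueError) as exc:
            raise ManifestError(f"row {lineno}: malformed fields ({exc})") from exc
        if temp not in _VALID_TEMPERATURES:
            raise ManifestError(f"row {lineno}: temperature {temp} K not in {{310, 498}}")
        ph = d["ph"]
        if ph not in ("NpH", "LpH"):
            raise ManifestError(f"row {lineno}: pH class {ph!r} must be NpH or LpH")
        if ph == "LpH" and species not in _ANIONS:
            raise ManifestError(
                f"row {lineno}: low-pH system must carry anionic counter ions, got {species}"
            )
        if run <= 0:
            raise ManifestError(f"row {lineno}: run length must be positive")
        if sid in seen_ids:
            raise ManifestError(f"row {lineno}: duplicate system id {sid}")
        seen_ids.add(sid)
        entries.append(
            SystemManifestEntry(
                system_id=sid,
                pdb_id=d["pdb_id"],
                variant=d["variant"],
                ion_species=species,
                ion_count=ion_count,
                temperature_K=temp,
                ph_class=ph,
                run_ns=run,
            )
        )
    return entries


def aggregate_run_time(entries: Sequence[SystemManifestEntry]) -> float:
    """Total simulated time in ns across all manifest entries."""
    return float(sum(e.run_ns for e in entries))


# ---------------------------------------------------------------------------
# sequences

def _load_wt() -> str:
    data = json.loads(_data_text("ab42_variants.json"))
    seq = data["wt"]
    if len(seq) != 42:
        raise ManifestError(f"wild-type sequence length {len(seq)} != 42")
    for pos, aa in _ANCHORS.items():
        if seq[pos - 1] != aa:
            raise ManifestError(
                f"wild-type sequence fails anchor {aa}{pos}: found {seq[pos - 1]}"
            )
    return seq


AB42_WT: str = _load_wt()

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class SequenceVariant:
    label: str
    sequence: str
    mutated_positions: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != 42:
            raise ValueError("variant sequence must have length 42")


def load_variants() -> list[str]:
    """Mutation labels shipped with the package."""
    return list(json.loads(_data_text("ab42_variants.json"))["variants"])


def apply_variant(wt_sequence: str, label: str) -> SequenceVariant:
    """Apply one point-mutation label (e.g. "G25P") to a 42-residue sequence.

    The label's wild-type letter must match the sequence at that (1-based)
    position; re-applying a mutation to an already-mutated sequence
    therefore raises.
    """
    if label == "WT":
        return SequenceVariant("WT", wt_sequence, ())
    m = _MUTATION_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse mutation label {label!r}")
    wt_aa, pos_s, new_aa = m.groups()
    pos = int(pos_s)
    if not (1 <= pos <= len(wt_sequence)):
        raise ValueError(f"position {pos} outside sequence of length {len(wt_sequence)}")
    if wt_sequence[pos - 1] != wt_aa:
        raise ValueError(
            f"label {label}: sequence has {wt_sequence[pos - 1]} at position {pos}, not {wt_aa}"
        )
    mutated = wt_sequence[: pos - 1] + new_aa + wt_sequence[pos:]
    return SequenceVariant(label, mutated, (pos,))
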