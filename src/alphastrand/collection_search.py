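"""Batch mining of structure collections for alpha-strand occurrences.

Scans a directory (or explicit list) of coordinate files, excludes entries
with no protein chains, scans every model and chain independently, and
aggregates occurrence counts per entry and per experimental method (X-ray
vs NMR vs other).  One *occurrence* is one matching window in one
(model, chain); a *structure with hits* is an entry with at least one
occurrence.  Unreadable entries are logged and skipped, never fatal to the
batch, keeping the census auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .dihedral_core import ConformationState
from .strand_scan import HitList, StrandHit, scan_structure
from .structure_io import (
    ExperimentMethod,
    StructureParseError,
    method_from_header,
    read_structures,
)

__all__ = ["EntryResult", "CollectionReport", "classify_method", "mine_collection", "merge_reports"]

_STRUCTURE_SUFFIXES = {".pdb", ".ent", ".cif", ".mmcif"}


def classify_method(model_header: Optional[str]) -> ExperimentMethod:
    """Map an experiment-type header record to XRAY/NMR/OTHER/UNKNOWN."""
    return method_from_header(model_header)


@dataclass
class EntryResult:
    entry_id: str
    method: ExperimentMethod
    occurrence_count: int
    hits: list[StrandHit] = field(default_factory=list)


@dataclass
class CollectionReport:
    """Per-entry and method-stratified occurrence census."""

    per_entry: dict[str, EntryResult] = field(default_factory=dict)
    structures_scanned: int = 0
    structures_excluded_non_protein: int = 0
    skipped: dict[str, str] = field(default_factory=dict)  # entry_id -> reason

    @property
    def structures_with_hits(self) -> int:
        return sum(1 for e in self.per_entry.values() if e.occurrence_count >= 1)

    @property
    def total_occurrences(self) -> int:
        return sum(e.occurrence_count for e in self.per_entry.values())

    @property
    def by_method(self) -> dict[ExperimentMethod, tuple[int, int]]:
        """method -> (structures_with_hits, occurrences), with-hits entries only."""
        out: dict[ExperimentMethod, tuple[int, int]] = {}
        for e in self.per_entry.values():
            if e.occurrence_count < 1:
                continue
            s, o = out.get(e.method, (0, 0))
            out[e.method] = (s + 1, o + e.occurrence_count)
        return out

    def to_table(self):
        header = ["entry_id", "method", "occurrence_count"]
        rows = [
            [eid, e.method.value, e.occurrence_count]
            for eid, e in sorted(self.per_entry.items())
        ]
        return header, rows

    @classmethod
    def from_table(cls, header, rows) -> "CollectionReport":
        rep = cls()
        for r in rows:
            d = dict(zip(header, r))
            rep.per_entry[d["entry_id"]] = EntryResult(
                d["entry_id"], ExperimentMethod(d["method"]), int(d["occurrence_count"])
            )
        rep.structures_scanned = len(rep.per_entry)
        return rep

    def to_json_dict(self) -> dict:
        return {
            "per_entry": {
                eid: {
                    "method": e.method.value,
                    "occurrence_count": e.occurrence_count,
                    "hits": [h.to_json_dict() for h in e.hits],
                }
                for eid, e in sorted(self.per_entry.items())
            },
            "totals": {
                "structures_scanned": self.structures_scanned,
                "structures_excluded_non_protein": self.structures_excluded_non_protein,
                "structures_with_hits": self.structures_with_hits,
                "total_occurrences": self.total_occurrences,
            },
            "by_method": {
                m.value: {"structures_with_hits": s, "occurrences": o}
                for m, (s, o) in sorted(self.by_method.items(), key=lambda kv: kv[0].value)
            },
            "skipped": dict(sorted(self.skipped.items())),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CollectionReport":
        rep = cls()
        for eid, e in d["per_entry"].items():
            rep.per_entry[eid] = EntryResult(
                eid,
                ExperimentMethod(e["method"]),
                e["occurrence_count"],
                [StrandHit.from_json_dict(h) for h in e.get("hits", [])],
            )
        rep.structures_scanned = d["totals"]["structures_scanned"]
        rep.structures_excluded_non_protein = d["totals"]["structures_excluded_non_protein"]
        rep.skipped = dict(d.get("skipped", {}))
        return rep


def _resolve_paths(paths: str | Path | Iterable[str | Path]) -> list[Path]:
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        if root.is_dir():
            return sorted(
                p for p in root.iterdir() if p.suffix.lower() in _STRUCTURE_SUFFIXES
            )
        return [root]
    return sorted(Path(p) for p in paths)


def mine_collection(
    paths: str | Path | Iterable[str | Path],
    motif: Optional[str] = None,
    pattern: Optional[str] = None,
    required_start: Optional[ConformationState] = None,
    min_len: int = 3,
    keep_hits: bool = True,
    log_path: Optional[str | Path] = None,
) -> CollectionReport:
    """Mine a collection of structure files for alpha-strand occurrences.

    ``pattern`` (e.g. "RLR") fixes the required start state and, with a
    motif, must have the motif's length.  Entries are processed in sorted
    entry-id order, so the same collection always yields an identical report.
    When ``log_path`` is given, skipped entries and their reasons are written
    there as TSV.
    """
    if pattern is not None:
        if motif is not None and len(pattern) != len(motif):
            raise ValueError("pattern length must equal motif length")
        start = ConformationState(pattern[0])
        if required_start is not None and required_start is not start:
            raise ValueError("required_start conflicts with pattern's first state")
        required_start = start
        min_len = max(min_len, len(pattern)) if motif is None else min_len
    report = CollectionReport()
    for path in _resolve_paths(paths):
        entry_id = path.stem
        try:
            models = read_structures(path)
        except (StructureParseError, FileNotFoundError, OSError) as exc:
            report.skipped[entry_id] = str(exc)
            continue
        report.structures_scanned += 1
        if not models:
            report.structures_excluded_non_protein += 1
            continue
        hits = HitList()
        for model in models:
            hits.extend(
                scan_structure(
                    model, min_len=min_len, motif=motif, required_start=required_start
                )
            )
        report.per_entry[entry_id] = EntryResult(
            entry_id=entry_id,
            method=models[0].method,
            occurrence_count=len(hits),
            hits=list(hits) if keep_hits else [],
        )
    if log_path is not None:
        lines = ["entry_id\treason"]
        lines += [f"{eid}\t{reason}" for eid, reason in sorted(report.skipped.items())]
        Path(log_path).write_text("\n".join(lines) + "\n")
    return report


def merge_reports(a: CollectionReport, b: CollectionReport) -> CollectionReport:
    """Merge censuses of two disjoint collections."""
    overlap = set(a.per_entry) & set(b.per_entry)
    if overlap:
        raise ValueError(f"collections share entries: {sorted(overlap)[:5]}")
    out = CollectionReport()
    out.per_entry = {**a.per_entry, **b.per_entry}
    out.structures_scanned = a.structures_scanned + b.structures_scanned
    out.structures_excluded_non_protein = (
        a.structures_excluded_non_protein + b.structures_excluded_non_protein
    )
    out.skipped = {**a.skipped, **b.skipped}
    return out
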