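"""Reading and writing protein structures and tabular trajectory data.

Structures are read with gemmi (PDB and mmCIF, including multi-model NMR
ensembles) and reduced to ordered backbone residues per chain — the minimal
substrate needed for backbone dihedral analysis.  The module also reads the
whitespace-delimited per-frame ``phi psi label`` tables produced by trajectory
dihedral extractors (the ``gmx rama`` dialect, with ``#``/``@`` comment
lines), and round-trips the package's TSV/JSON report objects.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "BackboneResidue",
    "StructureModel",
    "DihedralTableRow",
    "ExperimentMethod",
    "StructureParseError",
    "DihedralTableError",
    "CHAIN_BREAK_CN_CUTOFF",
    "read_structures",
    "read_dihedral_table",
    "wrap_angle",
    "write_structure_pdb",
    "write_report",
    "read_report",
]

#: Maximum C(i)-N(i+1) distance (Angstrom) for a continuous peptide bond.
#: Larger distances (or author-numbering jumps > 1) mark a chain break, across
#: which phi/psi are left undefined.
CHAIN_BREAK_CN_CUTOFF = 2.5


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class DihedralTableError(ValueError):
    """Raised for malformed dihedral-table rows (message carries the row number)."""


class ExperimentMethod(enum.Enum):
    XRAY = "XRAY"
    NMR = "NMR"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into the interval (-180, 180]."""
    w = ((deg + 180.0) % 360.0) - 180.0
    if w == -180.0:
        return 180.0
    return w


@dataclass
class BackboneResidue:
    """One residue's backbone atoms and identity.

    A residue is *dihedral-eligible* only when N, CA and C are all present;
    O and H are optional and unused by the dihedral machinery.
    """

    chain_id: str
    res_seq: int
    icode: str
    name3: str
    one_letter: str
    coords_N: Optional[np.ndarray] = None
    coords_CA: Optional[np.ndarray] = None
    coords_C: Optional[np.ndarray] = None
    coords_O: Optional[np.ndarray] = None
    coords_H: Optional[np.ndarray] = None

    @property
    def dihedral_eligible(self) -> bool:
        return (
            self.coords_N is not None
            and self.coords_CA is not None
            and self.coords_C is not None
        )

    def __post_init__(self) -> None:
        for name in ("coords_N", "coords_CA", "coords_C", "coords_O", "coords_H"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} of {self.name3} {self.res_seq} must be a finite 3-vector")
            setattr(self, name, v)


@dataclass
class StructureModel:
    """A single conformation: ordered backbone residues grouped by chain.

    ``chain_breaks[chain_id]`` holds the indices *i* such that the peptide
    bond between residues i and i+1 of that chain is broken (author-number
    jump > 1 or C-N distance above :data:`CHAIN_BREAK_CN_CUTOFF`).
    """

    entry_id: str
    model_index: int
    method: ExperimentMethod = ExperimentMethod.UNKNOWN
    chains: dict[str, list[BackboneResidue]] = field(default_factory=dict)
    chain_breaks: dict[str, frozenset[int]] = field(default_factory=dict)
    provenance: str = ""

    def chain(self, chain_id: str) -> list[BackboneResidue]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not present in {self.entry_id} model {self.model_index}")
        return self.chains[chain_id]

    def breaks(self, chain_id: str) -> frozenset[int]:
        return self.chain_breaks.get(chain_id, frozenset())

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain(chain_id))


@dataclass(frozen=True)
class DihedralTableRow:
    frame_index: int
    time_ps: float
    residue_label: str
    phi_deg: float
    psi_deg: float


# ---------------------------------------------------------------------------
# structure reading

_BACKBONE_NAMES = {"N", "CA", "C", "O", "H"}


def method_from_header(text: Optional[str]) -> ExperimentMethod:
    """Map an experiment-type header string (EXPDTA / _exptl.method) to the enum."""
    if not text:
        return ExperimentMethod.UNKNOWN
    t = text.upper()
    if "X-RAY" in t or "XRAY" in t:
        return ExperimentMethod.XRAY
    if "NMR" in t:
        return ExperimentMethod.NMR
    return ExperimentMethod.OTHER


def _one_letter(name3: str) -> str:
    info = gemmi.find_tabulated_residue(name3)
    if info is not None and info.is_amino_acid() and info.is_standard():
        return info.one_letter_code.upper()
    return "X"


def _is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None:
        return info.is_amino_acid()
    # untabulated residues with a complete backbone are treated as
    # nonstandard amino acids
    names = {a.name for a in res}
    return {"N", "CA", "C"} <= names


def _pick_backbone(res: gemmi.Residue) -> dict[str, np.ndarray]:
    """Highest-occupancy altloc per backbone atom name; ties keep the first."""
    best: dict[str, tuple[float, np.ndarray]] = {}
    for atom in res:
        if atom.name not in _BACKBONE_NAMES:
            continue
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        occ = atom.occ
        if atom.name not in best or occ > best[atom.name][0]:
            best[atom.name] = (occ, pos)
    return {name: pos for name, (occ, pos) in best.items()}


def _find_breaks(residues: Sequence[BackboneResidue]) -> frozenset[int]:
    breaks = set()
    for i in range(len(residues) - 1):
        a, b = residues[i], residues[i + 1]
        if b.res_seq - a.res_seq > 1:
            breaks.add(i)
            continue
        if a.coords_C is None or b.coords_N is None:
            breaks.add(i)
            continue
        if float(np.linalg.norm(b.coords_N - a.coords_C)) > CHAIN_BREAK_CN_CUTOFF:
            breaks.add(i)
    return frozenset(breaks)


def read_structures(path: str | Path, format_hint: Optional[str] = None) -> list[StructureModel]:
    """Read a coordinate file into one :class:`StructureModel` per model.

    Returns an empty list when the file contains no amino-acid residues
    (a non-protein entry); raises :class:`StructureParseError` when the file
    cannot be parsed at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format_hint == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    try:
        expt = st.info["_exptl.method"]
    except KeyError:
        expt = None
    method = method_from_header(expt)
    entry_id = (st.name or path.stem).strip() or path.stem

    models: list[StructureModel] = []
    for mi, model in enumerate(st, start=1):
        per_chain: dict[str, list[BackboneResidue]] = {}
        for chain in model:
            for res in chain:
                if not _is_amino_acid(res):
                    continue
                coords = _pick_backbone(res)
                br = BackboneResidue(
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name3=res.name,
                    one_letter=_one_letter(res.name),
                    coords_N=coords.get("N"),
                    coords_CA=coords.get("CA"),
                    coords_C=coords.get("C"),
                    coords_O=coords.get("O"),
                    coords_H=coords.get("H"),
                )
                per_chain.setdefault(chain.name, []).append(br)
        if not per_chain:
            continue
        chains: dict[str, list[BackboneResidue]] = {}
        breaks: dict[str, frozenset[int]] = {}
        for cid, residues in per_chain.items():
            residues.sort(key=lambda r: (r.res_seq, r.icode))
            seen = set()
            for r in residues:
                key = (r.res_seq, r.icode)
                if key in seen:
                    raise StructureParseError(
                        f"{path}: duplicate residue {r.res_seq}{r.icode} in chain {cid}"
                    )
                seen.add(key)
            chains[cid] = residues
            breaks[cid] = _find_breaks(residues)
        models.append(
            StructureModel(
                entry_id=entry_id,
                model_index=getattr(model, "num", mi) or mi,
                method=method,
                chains=chains,
                chain_breaks=breaks,
                provenance=str(path),
            )
        )
    return models


# ---------------------------------------------------------------------------
# structure writing (synthetic-builder output)

def write_structure_pdb(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one or more models as multi-model PDB text.

    Only backbone atoms are written.  The experiment method, when not
    UNKNOWN, is recorded in an EXPDTA header so that re-reading preserves it.
    """
    if isinstance(models, StructureModel):
        models = [models]
    if not models:
        raise ValueError("nothing to write")
    st = gemmi.Structure()
    st.name = models[0].entry_id
    header = {
        ExperimentMethod.XRAY: "X-RAY DIFFRACTION",
        ExperimentMethod.NMR: "SOLUTION NMR",
        ExperimentMethod.OTHER: "OTHER",
    }.get(models[0].method)
    if header:
        st.info["_exptl.method"] = header
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "H": "H"}
    for sm in models:
        model = gemmi.Model(sm.model_index)
        for cid, residues in sm.chains.items():
            chain = gemmi.Chain(cid)
            for r in residues:
                res = gemmi.Residue()
                res.name = r.name3
                res.seqid = gemmi.SeqId(r.res_seq, r.icode or " ")
                for name in ("N", "CA", "C", "O", "H"):
                    pos = getattr(r, f"coords_{name}")
                    if pos is None:
                        continue
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.element = gemmi.Element(elements[name])
                    atom.pos = gemmi.Position(*pos)
                    atom.occ = 1.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


# ---------------------------------------------------------------------------
# dihedral tables

def read_dihedral_table(path: str | Path, stride_ps: float = 2.0) -> list[DihedralTableRow]:
    """Read a whitespace-delimited ``phi psi label`` dihedral table.

    Lines starting with ``#`` or ``@`` are comments.  Rows may carry an
    explicit leading integer frame column (``frame phi psi label``);
    otherwise frame boundaries are inferred from residue-label recurrence:
    a label seen again starts the next frame.  Frame times are
    ``frame_index * stride_ps``.
    """
    path = Path(path)
    rows: list[DihedralTableRow] = []
    frame = 0
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line[0] in "#@":
                continue
            parts = line.split()
            explicit = None
            if len(parts) == 4:
                try:
                    explicit = int(parts[0])
                except ValueError as exc:
                    raise DihedralTableError(f"row {lineno}: bad frame index {parts[0]!r}") from exc
                parts = parts[1:]
            if len(parts) != 3:
                raise DihedralTableError(f"row {lineno}: expected 'phi psi label', got {line!r}")
            try:
                phi = float(parts[0].replace("−", "-"))
                psi = float(parts[1].replace("−", "-"))
            except ValueError as exc:
                raise DihedralTableError(f"row {lineno}: non-numeric angle in {line!r}") from exc
            for val in (phi, psi):
                if not (-360.0 <= val <= 360.0) or not math.isfinite(val):
                    raise DihedralTableError(f"row {lineno}: angle {val} outside [-360, 360]")
            label = parts[2]
            if explicit is not None:
                frame = explicit
            else:
                if label in seen:
                    frame += 1
                    seen = set()
                seen.add(label)
            rows.append(
                DihedralTableRow(
                    frame_index=frame,
                    time_ps=frame * stride_ps,
                    residue_label=label,
                    phi_deg=wrap_angle(phi),
                    psi_deg=wrap_angle(psi),
                )
            )
    return rows


def group_table_frames(rows: Iterable[DihedralTableRow]) -> list[list[DihedralTableRow]]:
    """Group table rows into per-frame lists, ordered by frame index."""
    frames: dict[int, list[DihedralTableRow]] = {}
    for row in rows:
        frames.setdefault(row.frame_index, []).append(row)
    return [frames[k] for k in sorted(frames)]


# ---------------------------------------------------------------------------
# report serialization
#
# Report objects implement ``to_table() -> (header, rows)`` and
# ``to_json_dict()``; their classes implement the matching ``from_table`` /
# ``from_json_dict``.  write_report/read_report dispatch on those hooks so a
# written report re-reads as an equal object.

def write_report(report, path: str | Path, format: str = "tsv") -> None:
    fmt = format.lower()
    path = Path(path)
    if fmt == "tsv":
        header, rows = _to_table(report)
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        path.write_text(json.dumps(_to_json(report), indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unsupported report format {format!r}")


def read_report(cls, path: str | Path, format: str = "tsv"):
    fmt = format.lower()
    text = Path(path).read_text()
    if fmt == "tsv":
        lines = [ln for ln in text.splitlines() if ln]
        header = lines[0].split("\t")
        rows = [ln.split("\t") for ln in lines[1:]]
        return cls.from_table(header, rows)
    if fmt == "json":
        return cls.from_json_dict(json.loads(text))
    raise ValueError(f"unsupported report format {format!r}")


def _to_table(report):
    if hasattr(report, "to_table"):
        return report.to_table()
    if isinstance(report, (list, tuple)):
        if not report:
            raise ValueError("cannot infer columns of an empty untyped list; use a typed report")
        head = report[0]
        if hasattr(head, "to_row"):
            return head.table_header(), [item.to_row() for item in report]
    raise TypeError(f"object of type {type(report).__name__} is not table-serializable")


def _to_json(report):
    if hasattr(report, "to_json_dict"):
        return report.to_json_dict()
    if isinstance(report, (list, tuple)):
        return [_to_json(item) for item in report]
    raise TypeError(f"object of type {type(report).__name__} is not json-serializable")
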