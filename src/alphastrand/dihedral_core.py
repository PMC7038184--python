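"""Backbone torsion angles and Ramachandran-sign classification.

The two conformational states at the heart of the package are defined purely
by the signs of the backbone dihedrals:

* ``ALPHA_R`` — right-handed helical quadrant, -180 < phi < 0 and
  -180 < psi < 0, i.e. (-, -);
* ``ALPHA_L`` — left-handed helical quadrant, 0 < phi < 180 and
  0 < psi < 180, i.e. (+, +).

Everything else with defined dihedrals is ``OTHER`` (including the
measure-zero boundaries phi or psi in {0, +-180}, because the inequalities
are strict), and residues lacking a dihedral (termini, chain breaks) are
``UNDEFINED``.  An alpha-strand is a run of successive residues alternating
between ALPHA_R and ALPHA_L; detection of such runs lives in
:mod:`alphastrand.strand_scan`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structure_io import StructureModel, wrap_angle

__all__ = [
    "ConformationState",
    "DihedralRecord",
    "dihedral_angle",
    "classify",
    "compute_phi_psi",
    "states_for_model",
]

#: Cross-product norm below which three points are treated as collinear and
#: the torsion is undefined.
COLLINEARITY_EPS = 1e-9


class ConformationState(enum.Enum):
    """Ramachandran-sign state of one residue."""

    ALPHA_R = "R"
    ALPHA_L = "L"
    OTHER = "O"
    UNDEFINED = "U"

    @property
    def code(self) -> str:
        return self.value

    @classmethod
    def from_code(cls, code: str) -> "ConformationState":
        return cls(code)


@dataclass(frozen=True)
class DihedralRecord:
    """Per-residue backbone dihedrals in degrees, range (-180, 180]."""

    residue_ref: tuple[str, int, str]  # (chain_id, author res_seq, name3)
    phi_deg: Optional[float]
    psi_deg: Optional[float]
    omega_deg: Optional[float] = None

    @property
    def defined_phi(self) -> bool:
        return self.phi_deg is not None

    @property
    def defined_psi(self) -> bool:
        return self.psi_deg is not None

    @property
    def res_seq(self) -> int:
        return self.residue_ref[1]

    def state(self) -> ConformationState:
        return classify(self.phi_deg, self.psi_deg)


def dihedral_angle(p1, p2, p3, p4) -> Optional[float]:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    cis = 0, trans = 180; positive torsions correspond to a clockwise
    rotation of the far bond when sighting from p2 toward p3.  The result is
    wrapped into (-180, 180].  Returns ``None`` when either atom triple is
    collinear (torsion undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < COLLINEARITY_EPS or np.linalg.norm(n2) < COLLINEARITY_EPS:
        return None
    nb2 = np.linalg.norm(b2)
    if nb2 < COLLINEARITY_EPS:
        return None
    u2 = b2 / nb2
    ang = float(np.degrees(np.arctan2(np.dot(np.cross(n1, n2), u2), np.dot(n1, n2))))
    return wrap_angle(ang)


def classify(phi_deg: Optional[float], psi_deg: Optional[float]) -> ConformationState:
    """Assign the Ramachandran-sign state for one (phi, psi) pair.

    Total function: any input maps to exactly one state.  Boundary values
    (phi or psi exactly 0 or +-180) fall to OTHER because the quadrant rule
    uses strict inequalities; a missing dihedral gives UNDEFINED.
    """
    if phi_deg is None or psi_deg is None:
        return ConformationState.UNDEFINED
    if not (np.isfinite(phi_deg) and np.isfinite(psi_deg)):
        return ConformationState.UNDEFINED
    if -180.0 < phi_deg < 0.0 and -180.0 < psi_deg < 0.0:
        return ConformationState.ALPHA_R
    if 0.0 < phi_deg < 180.0 and 0.0 < psi_deg < 180.0:
        return ConformationState.ALPHA_L
    return ConformationState.OTHER


def compute_phi_psi(
    model: StructureModel, chain_id: str, include_omega: bool = False
) -> list[DihedralRecord]:
    """Backbone dihedrals for every residue of one chain, in chain order.

    phi_i is the C(i-1)-N(i)-CA(i)-C(i) torsion, psi_i the
    N(i)-CA(i)-C(i)-N(i+1) torsion and omega_i the
    CA(i-1)-C(i-1)-N(i)-CA(i) torsion.  phi (and omega) are undefined at the
    chain's first residue and immediately after a break; psi is undefined at
    the last residue and immediately before a break.  Residues missing any
    of N/CA/C get both dihedrals undefined.
    """
    residues = model.chain(chain_id)
    breaks = model.breaks(chain_id)
    records: list[DihedralRecord] = []
    n = len(residues)
    for i, res in enumerate(residues):
        phi = psi = omega = None
        prev_ok = i > 0 and (i - 1) not in breaks
        next_ok = i < n - 1 and i not in breaks
        if res.dihedral_eligible:
            if prev_ok and residues[i - 1].coords_C is not None:
                phi = dihedral_angle(
                    residues[i - 1].coords_C, res.coords_N, res.coords_CA, res.coords_C
                )
            if next_ok and residues[i + 1].coords_N is not None:
                psi = dihedral_angle(
                    res.coords_N, res.coords_CA, res.coords_C, residues[i + 1].coords_N
                )
            if (
                include_omega
                and prev_ok
                and residues[i - 1].coords_CA is not None
                and residues[i - 1].coords_C is not None
            ):
                omega = dihedral_angle(
                    residues[i - 1].coords_CA, residues[i - 1].coords_C, res.coords_N, res.coords_CA
                )
        records.append(
            DihedralRecord(
                residue_ref=(chain_id, res.res_seq, res.name3),
                phi_deg=phi,
                psi_deg=psi,
                omega_deg=omega,
            )
        )
    return records


def states_for_model(
    model: StructureModel, chain_id: str
) -> list[tuple[tuple[str, int, str], ConformationState]]:
    """Composition of :func:`compute_phi_psi` and :func:`classify`, order preserved."""
    return [(rec.residue_ref, rec.state()) for rec in compute_phi_psi(model, chain_id)]
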