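"""Inter-domain opening angles from C-alpha centers of mass.

Two angles describe the arrangement of the mobile substrate-binding
domains of an adenylate-kinase-like protein relative to its CORE
(Beckstein-style definitions):

theta_AMPbd
    vertex at the COM of a CORE residue window; rays to the COM of the
    CORE-LID hinge window and to the COM of an AMPbd window.
theta_LID
    vertex at the COM of the CORE-LID hinge window; rays to the COM of
    a second CORE window and to the COM of a LID window.

Centers of mass are over C-alpha atoms with equal weights.  The E. coli
enzyme's residue windows are provided as the "ake" preset; synthetic
structures carry their own windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure

__all__ = ["AngleDefinition", "theta_ampbd", "theta_lid", "domain_angles", "AKE_ANGLES"]


def _window(lo: int, hi: int) -> tuple[int, ...]:
    return tuple(range(lo, hi + 1))


@dataclass(frozen=True)
class AngleDefinition:
    """Residue windows (1-based inclusive tuples) defining both angles.

    theta_AMPbd uses (core_a, hinge, ampbd) with vertex at core_a;
    theta_LID uses (hinge, core_b, lid) with vertex at hinge.
    """

    core_a: tuple[int, ...]
    hinge: tuple[int, ...]
    ampbd: tuple[int, ...]
    core_b: tuple[int, ...]
    lid: tuple[int, ...]

    @classmethod
    def from_ranges(cls, core_a, hinge, ampbd, core_b, lid) -> "AngleDefinition":
        return cls(*(_window(*r) for r in (core_a, hinge, ampbd, core_b, lid)))


#: E. coli adenylate kinase windows.  Note the hinge window (115-125)
#: and the LID window (125-153) share residue 125 by definition.
AKE_ANGLES = AngleDefinition.from_ranges(
    core_a=(90, 100), hinge=(115, 125), ampbd=(35, 55),
    core_b=(179, 185), lid=(125, 153),
)


def _com(structure: Structure, residues) -> np.ndarray:
    missing = [r for r in residues if not structure.has_atom(r, "CA")]
    if missing:
        raise ValueError(f"residues missing CA atoms: {missing}")
    return structure.ca_coords(list(residues)).mean(axis=0)


def _angle_deg(vertex: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    u, v = p - vertex, q - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("coincident centers of mass; angle undefined")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def theta_ampbd(structure: Structure, defn: AngleDefinition = AKE_ANGLES) -> float:
    """AMPbd-CORE opening angle in degrees, in [0, 180]."""
    vertex = _com(structure, defn.core_a)
    return _angle_deg(vertex, _com(structure, defn.hinge), _com(structure, defn.ampbd))


def theta_lid(structure: Structure, defn: AngleDefinition = AKE_ANGLES) -> float:
    """LID-CORE opening angle in degrees, in [0, 180]."""
    vertex = _com(structure, defn.hinge)
    return _angle_deg(vertex, _com(structure, defn.core_b), _com(structure, defn.lid))


def domain_angles(structure: Structure, defn: AngleDefinition = AKE_ANGLES):
    """(theta_AMPbd, theta_LID) in degrees."""
    return theta_ampbd(structure, defn), theta_lid(structure, defn)
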