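"""Lightweight coordinate container for protein conformers.

A :class:`Structure` holds per-atom residue ids, atom names and
Cartesian coordinates (Angstrom) for a single chain, with fast numpy
lookup paths used throughout the geometry, alignment and selection
code.  PDB reading/writing lives in :mod:`rdcsel.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MissingAtomError(KeyError):
    """An atom required by an operation is absent from the structure."""

    def __init__(self, residue_id: int, atom_name: str):
        self.residue_id = residue_id
        self.atom_name = atom_name
        super().__init__(f"atom {atom_name!r} of residue {residue_id} not found")


@dataclass
class Structure:
    """Atoms of one conformer of one chain.

    Attributes
    ----------
    resids : (n,) int array, author residue numbering (1-based).
    atom_names : (n,) str array, PDB atom names ("N", "CA", "H", ...).
    coords : (n, 3) float array, Angstrom.
    resnames : (n,) str array, residue names; defaults to "ALA".
    """

    resids: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray
    resnames: np.ndarray | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.resids = np.asarray(self.resids, dtype=int)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.resids), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if len(self.atom_names) != len(self.resids):
            raise ValueError("atom_names and resids length mismatch")
        if self.resnames is None:
            self.resnames = np.array(["ALA"] * len(self.resids), dtype=object)
        else:
            self.resnames = np.asarray(self.resnames, dtype=object)
        self._rebuild_index()

    def _rebuild_index(self):
        self._index = {
            (int(r), str(a)): i
            for i, (r, a) in enumerate(zip(self.resids, self.atom_names))
        }

    # -- lookups ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.resids)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.resids))

    def residue_ids(self) -> np.ndarray:
        return np.unique(self.resids)

    def has_atom(self, residue_id: int, atom_name: str) -> bool:
        return (int(residue_id), atom_name) in self._index

    def atom_index(self, residue_id: int, atom_name: str) -> int:
        try:
            return self._index[(int(residue_id), atom_name)]
        except KeyError:
            raise MissingAtomError(residue_id, atom_name) from None

    def coord(self, residue_id: int, atom_name: str) -> np.ndarray:
        return self.coords[self.atom_index(residue_id, atom_name)]

    def atom_mask(self, atom_name: str) -> np.ndarray:
        return np.array([a == atom_name for a in self.atom_names], dtype=bool)

    def ca_coords(self, residue_ids=None) -> np.ndarray:
        """C-alpha coordinates for the given residues (default: all),
        in ascending residue order."""
        if residue_ids is None:
            residue_ids = self.residue_ids()
        return np.array([self.coord(r, "CA") for r in residue_ids])

    def bond_vectors(self, keys) -> np.ndarray:
        """Unit inter-nuclear vectors for (residue_id, atom1, atom2) keys."""
        vecs = np.empty((len(keys), 3))
        for i, (resid, a1, a2) in enumerate(keys):
            v = self.coord(resid, a2) - self.coord(resid, a1)
            n = np.linalg.norm(v)
            if n == 0.0:
                raise ValueError(f"zero-length bond vector at residue {resid}")
            vecs[i] = v / n
        return vecs

    # -- transforms ------------------------------------------------------

    def copy(self) -> "Structure":
        return Structure(
            self.resids.copy(), self.atom_names.copy(), self.coords.copy(),
            self.resnames.copy(),
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Rigidly transformed copy: x -> R x + t."""
        out = self.copy()
        if rotation is not None:
            out.coords = out.coords @ np.asarray(rotation).T
        if translation is not None:
            out.coords = out.coords + np.asarray(translation)
        return out

    def content_hash(self) -> str:
        """Hash of rounded coordinates and atom identity, for caching."""
        import hashlib

        h = hashlib.sha1()
        h.update(np.round(self.coords, 6).tobytes())
        h.update(self.resids.tobytes())
        h.update("|".join(map(str, self.atom_names)).encode())
        return h.hexdigest()


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, Rodrigues form."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)
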