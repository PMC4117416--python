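"""Shape-based (steric) alignment tensor prediction.

Weak alignment in a stretched gel or liquid-crystal medium is modelled
by an obstruction of two parallel planes a distance L apart.  For each
orientation of the plane normal u in the molecular frame, the fraction
of positions at which the molecule fits between the planes is

    f(u) = max(0, L - h(u)) / L

with h(u) the molecular extent along u including bead radii.  The
Saupe order matrix is the f-weighted orientational average

    S_ij = < (3 u_i u_j - delta_ij) / 2 >_f

expressed in the molecular frame, which is symmetric and traceless by
construction.  Elongated molecules are depleted of orientations with
the long axis along the normal, producing shape-dependent alignment;
a sphere produces none.  The absolute tensor magnitude depends on the
(unknown) barrier spacing and is re-fit downstream against experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rdc import AlignmentTensor
from .structure import Structure

__all__ = ["BeadModel", "StericConfig", "coarse_grain", "predict_tensor"]

#: effective residue bead radius (A), ~ one C-alpha virtual bond
RESIDUE_BEAD_RADIUS = 3.8
#: heavy-atom bead radius (A)
ATOM_BEAD_RADIUS = 1.7


@dataclass
class BeadModel:
    """Hard-sphere coarse representation of one conformer."""

    centers: np.ndarray  # (n, 3) A
    radii: np.ndarray  # (n,) A
    provenance: str = ""

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.broadcast_to(
            np.asarray(self.radii, dtype=float), (len(self.centers),)
        ).copy()
        if len(self.centers) == 0:
            raise ValueError("bead model needs at least one bead")
        if (self.radii <= 0).any():
            raise ValueError("bead radii must be positive")

    @property
    def max_radius(self) -> float:
        """Largest distance from the geometric center to a bead surface."""
        c = self.centers.mean(axis=0)
        return float(np.max(np.linalg.norm(self.centers - c, axis=1) + self.radii))

    def extent_along(self, directions: np.ndarray) -> np.ndarray:
        """Molecular span (A) along each unit direction, bead radii included."""
        U = np.asarray(directions, dtype=float)
        Z = self.centers @ U.T  # (n_beads, n_dir)
        return (Z + self.radii[:, None]).max(axis=0) - (Z - self.radii[:, None]).min(axis=0)


@dataclass
class StericConfig:
    """Parameters of the planar-barrier obstruction model.

    grid_deg : angular resolution of the orientation average, degrees
        in (0, 30].
    spacing : barrier separation L in A, or "auto" for 4x the maximal
        molecular radius.
    bead_scheme : "residue" (one bead per C-alpha, r=3.8 A) or "atom"
        (one bead per heavy atom, r=1.7 A).
    """

    grid_deg: float = 10.0
    spacing: float | str = "auto"
    bead_scheme: str = "residue"

    def __post_init__(self):
        if not (0.0 < self.grid_deg <= 30.0):
            raise ValueError("grid_deg must be in (0, 30]")
        if self.bead_scheme not in ("residue", "atom"):
            raise ValueError("bead_scheme must be 'residue' or 'atom'")
        if self.spacing != "auto" and float(self.spacing) <= 0:
            raise ValueError("spacing must be positive or 'auto'")

    def resolve_spacing(self, model: BeadModel) -> float:
        if self.spacing == "auto":
            return 4.0 * model.max_radius
        return float(self.spacing)


def coarse_grain(structure: Structure, scheme: str = "residue") -> BeadModel:
    """Bead model of a structure.

    residue scheme: one bead per residue at its C-alpha; atom scheme:
    one bead per heavy (non-hydrogen) atom.
    """
    if scheme == "residue":
        centers = structure.ca_coords()
        if len(centers) != structure.n_residues:
            raise ValueError("residue-level scheme requires a CA per residue")
        return BeadModel(centers, RESIDUE_BEAD_RADIUS, provenance="residue CA beads")
    if scheme == "atom":
        heavy = np.array(
            [not str(a).strip().upper().startswith("H") for a in structure.atom_names],
            dtype=bool,
        )
        if not heavy.any():
            raise ValueError("no heavy atoms in structure")
        return BeadModel(structure.coords[heavy], ATOM_BEAD_RADIUS,
                         provenance="heavy-atom beads")
    raise ValueError(f"unknown bead scheme {scheme!r}")


def orientation_grid(grid_deg: float):
    """Unit directions and quadrature weights covering the sphere.

    Regular grid in polar angle theta (cell midpoints, sin-theta
    weights) and azimuth phi; antipodal pairs are redundant for the
    even-order average but kept for simplicity.
    """
    step = np.deg2rad(grid_deg)
    n_theta = max(2, int(round(np.pi / step)))
    n_phi = max(4, int(round(2 * np.pi / step)))
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = np.arange(n_phi) * 2 * np.pi / n_phi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    st, ct = np.sin(T).ravel(), np.cos(T).ravel()
    sp, cp = np.sin(P).ravel(), np.cos(P).ravel()
    U = np.column_stack([st * cp, st * sp, ct])
    w = np.sin(T).ravel()
    return U, w / w.sum()


def predict_tensor(model: BeadModel, config: StericConfig | None = None) -> AlignmentTensor:
    """Alignment tensor of a bead model under the planar-barrier model.

    Raises if the molecule fits between the barriers in no orientation
    (degenerate spacing).
    """
    if config is None:
        config = StericConfig()
    L = config.resolve_spacing(model)
    U, w = orientation_grid(config.grid_deg)
    # centers relative to geometric mean: extent is translation invariant
    h = model.extent_along(U)
    allowed = np.clip(L - h, 0.0, None) / L
    weight = w * allowed
    total = weight.sum()
    if total <= 0.0:
        raise ValueError(
            f"degenerate barrier spacing {L:.2f} A: molecule fits in no orientation"
        )
    weight = weight / total
    # S_ij = < (3 u_i u_j - delta_ij)/2 >
    M = (U * weight[:, None]).T @ U  # <u_i u_j>
    S = 1.5 * M - 0.5 * np.eye(3)
    S = 0.5 * (S + S.T)
    S -= np.eye(3) * (np.trace(S) / 3.0)  # kill residual quadrature trace error
    return AlignmentTensor(S)


# ---------------------------------------------------------------------------
# per-conformer tensor cache

_TENSOR_CACHE: dict[tuple, AlignmentTensor] = {}


def predict_tensor_for_structure(
    structure: Structure, config: StericConfig | None = None, cache: bool = True
) -> AlignmentTensor:
    """Coarse-grain then predict; results are cached by conformer
    content hash because selection re-uses per-conformer tensors many
    times."""
    if config is None:
        config = StericConfig()
    key = None
    if cache:
        key = (structure.content_hash(), config.grid_deg,
               str(config.spacing), config.bead_scheme)
        hit = _TENSOR_CACHE.get(key)
        if hit is not None:
            return hit
    tensor = predict_tensor(coarse_grain(structure, config.bead_scheme), config)
    if cache:
        _TENSOR_CACHE[key] = tensor
    return tensor
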