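"""RDC back-calculation, ensemble averaging, scoring and tensor fitting.

The residual dipolar coupling of a bonded pair P-Q in a weakly aligned
molecule is

    D = D_max(P,Q) * sum_ij S_ij cos(phi_i) cos(phi_j)

where S is the Saupe order matrix (3x3, symmetric, traceless) and
phi_i the angle between the inter-nuclear unit vector and axis i of
the frame in which S is expressed.  Agreement between calculated and
experimental couplings is scored with the quality factor

    Q = rms(D_calc - D_exp) / rms(D_exp)

(Cornilescu convention).  Calculated couplings may be rescaled by a
single factor chosen to minimise Q, which absorbs the unknown absolute
degree of alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import d_max
from .structure import Structure

__all__ = [
    "AlignmentTensor",
    "RDCSet",
    "back_calculate",
    "ensemble_average",
    "q_factor",
    "optimal_scale",
    "fit_tensor_svd",
]

#: default uncertainty (Hz) when a table omits one
DEFAULT_SIGMA = 0.3


class AlignmentTensor:
    """Saupe order matrix: 3x3 symmetric traceless, dimensionless.

    Eigenvalues are ordered by magnitude |S_zz| >= |S_yy| >= |S_xx| and
    the matching eigenvectors define the principal alignment frame.
    """

    __slots__ = ("elements",)

    def __init__(self, elements, *, tol: float = 1e-9):
        S = np.asarray(elements, dtype=float)
        if S.shape != (3, 3):
            raise ValueError("alignment tensor must be 3x3")
        if not np.allclose(S, S.T, atol=1e-12, rtol=0.0):
            raise ValueError("alignment tensor must be symmetric")
        if abs(np.trace(S)) >= max(tol, 1e-10):
            raise ValueError(f"alignment tensor must be traceless, trace={np.trace(S):g}")
        self.elements = 0.5 * (S + S.T)

    @classmethod
    def zero(cls) -> "AlignmentTensor":
        return cls(np.zeros((3, 3)))

    @classmethod
    def axial(cls, s: float, axis: int = 2) -> "AlignmentTensor":
        """Axially symmetric tensor diag(-s/2, -s/2, s) with the unique
        axis along the given coordinate axis."""
        d = np.full(3, -0.5 * s)
        d[axis] = s
        return cls(np.diag(d))

    @classmethod
    def from_independent(cls, syy: float, szz: float, sxy: float,
                         sxz: float, syz: float) -> "AlignmentTensor":
        """Build from the 5 independent components (S_xx = -S_yy - S_zz)."""
        sxx = -syy - szz
        return cls(np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]))

    def eigensystem(self):
        """(eigenvalues, eigenvectors) ordered x, y, z by increasing
        magnitude, eigenvectors as columns."""
        w, v = np.linalg.eigh(self.elements)
        order = np.argsort(np.abs(w))
        return w[order], v[:, order]

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.eigensystem()[0]

    @property
    def principal_axis(self) -> np.ndarray:
        """Eigenvector of the largest-magnitude eigenvalue (S_zz)."""
        return self.eigensystem()[1][:, 2]

    def rotated(self, R: np.ndarray) -> "AlignmentTensor":
        R = np.asarray(R)
        return AlignmentTensor(R @ self.elements @ R.T)

    def __add__(self, other):
        return AlignmentTensor(self.elements + other.elements)

    def __mul__(self, a: float):
        return AlignmentTensor(self.elements * a)

    __rmul__ = __mul__

    def __neg__(self):
        return AlignmentTensor(-self.elements)

    def __repr__(self):
        return f"AlignmentTensor(eigenvalues={np.round(self.eigenvalues, 6)})"


@dataclass
class RDCSet:
    """A keyed set of residual dipolar couplings.

    ``table`` has columns residue_id, atom1, atom2, value (Hz),
    sigma (Hz); keys (residue_id, atom1, atom2) are unique.
    """

    table: pd.DataFrame
    origin: str = "experimental"  # experimental | calculated | synthetic

    COLUMNS = ("residue_id", "atom1", "atom2", "value", "sigma")

    def __post_init__(self):
        df = pd.DataFrame(self.table)
        missing = [c for c in ("residue_id", "atom1", "atom2", "value") if c not in df]
        if missing:
            raise ValueError(f"RDC table missing columns {missing}")
        if "sigma" not in df:
            df["sigma"] = DEFAULT_SIGMA
        df = df[list(self.COLUMNS)].copy()
        df["residue_id"] = df["residue_id"].astype(int)
        df["sigma"] = df["sigma"].fillna(DEFAULT_SIGMA).astype(float)
        if (df["sigma"] < 0).any():
            raise ValueError("negative RDC uncertainty")
        if (df["atom1"].astype(str).str.len() == 0).any() or \
           (df["atom2"].astype(str).str.len() == 0).any():
            raise ValueError("empty atom name in RDC table")
        dup = df.duplicated(subset=["residue_id", "atom1", "atom2"])
        if dup.any():
            raise ValueError(
                f"duplicate RDC keys: {df.loc[dup, ['residue_id', 'atom1', 'atom2']].values.tolist()}"
            )
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, keys, values, sigmas=None, origin="calculated") -> "RDCSet":
        keys = list(keys)
        df = pd.DataFrame(
            {
                "residue_id": [k[0] for k in keys],
                "atom1": [k[1] for k in keys],
                "atom2": [k[2] for k in keys],
                "value": np.asarray(values, dtype=float),
                "sigma": DEFAULT_SIGMA if sigmas is None else np.asarray(sigmas, float),
            }
        )
        return cls(df, origin=origin)

    @property
    def keys(self) -> list[tuple[int, str, str]]:
        return list(
            zip(self.table["residue_id"], self.table["atom1"], self.table["atom2"])
        )

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy()

    @property
    def sigmas(self) -> np.ndarray:
        return self.table["sigma"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, keys) -> "RDCSet":
        idx = {k: i for i, k in enumerate(self.keys)}
        rows = [idx[k] for k in keys]
        return RDCSet(self.table.iloc[rows], origin=self.origin)

    def with_values(self, values, origin=None) -> "RDCSet":
        df = self.table.copy()
        df["value"] = np.asarray(values, dtype=float)
        return RDCSet(df, origin=origin or self.origin)

    def align_with(self, other: "RDCSet"):
        """Shared keys (in this set's order) and the two value vectors."""
        other_idx = {k: i for i, k in enumerate(other.keys)}
        shared = [k for k in self.keys if k in other_idx]
        if not shared:
            raise ValueError("RDC sets share no keys")
        self_idx = {k: i for i, k in enumerate(self.keys)}
        a = self.values[[self_idx[k] for k in shared]]
        b = other.values[[other_idx[k] for k in shared]]
        return shared, a, b


# ---------------------------------------------------------------------------
# operations


def _dmax_vector(keys) -> np.ndarray:
    return np.array([d_max(a1, a2) for _, a1, a2 in keys])


def back_calculate(structure: Structure, tensor: AlignmentTensor, keys) -> RDCSet:
    """Couplings D = D_max * v.S.v for each key's unit bond vector v.

    ``keys`` is an iterable of (residue_id, atom1, atom2); both atoms
    must exist in the structure.
    """
    keys = list(keys)
    V = structure.bond_vectors(keys)
    S = tensor.elements
    D = _dmax_vector(keys) * np.einsum("ni,ij,nj->n", V, S, V)
    return RDCSet.from_arrays(keys, D, origin="calculated")


def ensemble_average(members, keys) -> RDCSet:
    """Unweighted mean of back-calculated couplings over
    (structure, tensor) members; equal populations within an ensemble."""
    members = list(members)
    if not members:
        raise ValueError("ensemble_average needs at least one member")
    keys = list(keys)
    acc = np.zeros(len(keys))
    for structure, tensor in members:
        acc += back_calculate(structure, tensor, keys).values
    return RDCSet.from_arrays(keys, acc / len(members), origin="calculated")


def q_factor(calc: RDCSet, exp: RDCSet) -> float:
    """Q = rms(D_calc - D_exp) / rms(D_exp) over the shared keys."""
    _, dc, de = calc.align_with(exp)
    denom = float(np.sqrt(np.mean(de**2)))
    if denom == 0.0:
        raise ZeroDivisionError("experimental RDCs are all zero")
    return float(np.sqrt(np.mean((dc - de) ** 2)) / denom)


def optimal_scale(calc: RDCSet, exp: RDCSet) -> tuple[float, float]:
    """Least-squares scale s* = sum(Dc*De)/sum(Dc^2) and Q at s*.

    Minimises Q over a single multiplicative factor applied to the
    calculated couplings, absorbing the unknown alignment magnitude.
    """
    _, dc, de = calc.align_with(exp)
    denom = float(np.dot(dc, dc))
    if denom == 0.0:
        raise ZeroDivisionError("calculated RDCs are all zero; cannot scale")
    s = float(np.dot(dc, de) / denom)
    return s, q_factor(calc.with_values(calc.values * s), exp)


def _design_matrix(V: np.ndarray) -> np.ndarray:
    """n x 5 matrix mapping (Syy, Szz, Sxy, Sxz, Syz) to v.S.v with
    S_xx = -S_yy - S_zz."""
    x, y, z = V[:, 0], V[:, 1], V[:, 2]
    return np.column_stack([y * y - x * x, z * z - x * x, 2 * x * y, 2 * x * z, 2 * y * z])


def fit_tensor_svd(structure: Structure, exp: RDCSet) -> tuple[AlignmentTensor, float]:
    """Least-squares (SVD) Saupe tensor for one structure against a set
    of couplings; returns the tensor and the resulting Q.

    Requires >= 5 couplings with non-degenerate bond directions.
    """
    keys = exp.keys
    if len(keys) < 5:
        raise ValueError(f"tensor fit needs >=5 RDCs, got {len(keys)}")
    V = structure.bond_vectors(keys)
    A = _design_matrix(V) * _dmax_vector(keys)[:, None]
    rank = np.linalg.matrix_rank(A)
    if rank < 5:
        raise ValueError(
            f"degenerate bond directions: design matrix rank {rank} < 5"
        )
    params, *_ = np.linalg.lstsq(A, exp.values, rcond=None)
    tensor = AlignmentTensor.from_independent(*params)
    return tensor, q_factor(back_calculate(structure, tensor, keys), exp)
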