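"""Physical constants for dipolar-coupling calculations.

The static dipolar coupling constant for a bonded pair P-Q at fixed
distance r is

    D_max = - mu0 * h * gamma_P * gamma_Q / (16 * pi**3 * r**3)   [Hz]

so that the residual coupling observed under weak alignment is
D = D_max * sum_ij S_ij cos(phi_i) cos(phi_j) with S the Saupe order
matrix.  Sign convention: gamma(15N) is negative, hence D_max(N-H) is
positive (~+11.4 kHz at r = 1.02 A).  Conventions in the literature
differ by a factor of 2 depending on where the order-parameter 3/2 is
absorbed; the choice is irrelevant downstream because calculated RDCs
are rescaled against experiment after ensemble averaging.
"""

from __future__ import annotations

import math

#: vacuum permeability, T^2 m^3 / J
MU0 = 4.0e-7 * math.pi
#: Planck constant, J s
H_PLANCK = 6.62607015e-34

#: gyromagnetic ratios, rad s^-1 T^-1
GAMMA = {
    "H": 2.6752218744e8,
    "N": -2.7126180436e7,
    "C": 6.728284e7,
}

#: effective bond lengths per bonded pair, Angstrom
BOND_LENGTHS = {
    ("N", "H"): 1.02,
    ("C", "N"): 1.329,
    ("C", "H"): 1.09,
}


def _element(atom_name: str) -> str:
    """First letter of a PDB atom name gives the element for backbone
    N/H/C atoms (H, HN, CA, C, N...)."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    return name[0].upper()


def bond_length(atom1: str, atom2: str) -> float:
    """Fixed effective bond length (A) for a bonded atom pair."""
    e1, e2 = _element(atom1), _element(atom2)
    for key in ((e1, e2), (e2, e1)):
        if key in BOND_LENGTHS:
            return BOND_LENGTHS[key]
    raise KeyError(f"no default bond length for pair {atom1}-{atom2}")


def d_max(atom1: str, atom2: str, r: float | None = None) -> float:
    """Static dipolar coupling constant in Hz for a bonded pair.

    Parameters
    ----------
    atom1, atom2 : PDB atom names (element inferred from first letter).
    r : bond length in Angstrom; defaults to the tabulated value.
    """
    e1, e2 = _element(atom1), _element(atom2)
    if e1 not in GAMMA or e2 not in GAMMA:
        raise KeyError(f"no gyromagnetic ratio for pair {atom1}-{atom2}")
    if r is None:
        r = bond_length(atom1, atom2)
    r_m = r * 1e-10
    return -MU0 * H_PLANCK * GAMMA[e1] * GAMMA[e2] / (16.0 * math.pi**3 * r_m**3)
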