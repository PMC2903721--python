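"""Idealized ribonucleotide templates.

Each template is built in a base-fixed reference frame: the planar base
(standard heavy-atom geometry, z = 0 plane, minor-groove side at negative
x, Watson-Crick face toward negative y) plus a ribose and reduced
phosphate grown from internal coordinates (bond lengths, bond angles,
torsions) by natural-extension placement.  Sugars are built C3'-endo with
an anti glycosidic torsion, the conformation of A-form RNA.

A Watson-Crick partner is obtained by the frame flip (x, -y, -z): in this
frame the flip brings the complementary base's donor/acceptor atoms to
canonical hydrogen-bond distance (~2.8-3.0 Å).
"""

from __future__ import annotations

import numpy as np

from .geometry import torsion_angle

__all__ = ["base_atoms", "nucleotide_template", "wc_flip", "COMPLEMENT"]

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Planar base heavy atoms (x, y, 0) in the base-fixed frame.  With the
# partner base mapped through (x,-y,-z) the Watson-Crick hydrogen-bonded
# heavy-atom distances come out at 2.87-3.02 Å.
_BASES: dict[str, list[tuple[str, float, float]]] = {
    "A": [
        ("N9", -1.291, 4.498), ("C8", 0.024, 4.897), ("N7", 0.877, 3.902),
        ("C5", 0.071, 2.771), ("C6", 0.369, 1.398), ("N6", 1.611, 0.909),
        ("N1", -0.668, 0.532), ("C2", -1.912, 1.023), ("N3", -2.320, 2.290),
        ("C4", -1.267, 3.124),
    ],
    "G": [
        ("N9", -1.289, 4.551), ("C8", 0.023, 4.962), ("N7", 0.870, 3.969),
        ("C5", 0.071, 2.833), ("C6", 0.424, 1.460), ("O6", 1.554, 0.955),
        ("N1", -0.700, 0.641), ("C2", -1.999, 1.087), ("N2", -2.949, 0.139),
        ("N3", -2.342, 2.364), ("C4", -1.265, 3.177),
    ],
    "C": [
        ("N1", -1.285, 4.542), ("C2", -1.472, 3.158), ("O2", -2.628, 2.709),
        ("N3", -0.391, 2.344), ("C4", 0.837, 2.868), ("N4", 1.875, 2.027),
        ("C5", 1.056, 4.275), ("C6", -0.023, 5.068),
    ],
    "U": [
        ("N1", -1.284, 4.500), ("C2", -1.462, 3.131), ("O2", -2.563, 2.608),
        ("N3", -0.302, 2.397), ("C4", 0.989, 2.884), ("O4", 1.935, 2.094),
        ("C5", 1.089, 4.311), ("C6", -0.024, 5.053),
    ],
}

_PURINES = {"A", "G"}

#: Glycosidic torsion chi (O4'-C1'-N-C) used for all templates: anti, the
#: A-form value.
CHI_ANTI = -158.0

# Ribose endocyclic torsions for C3'-endo (deg):
#   nu0 = C4'-O4'-C1'-C2', nu1 = O4'-C1'-C2'-C3', nu2 = C1'-C2'-C3'-C4'
_NU1 = -25.3
_NU2 = 37.7


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def base_atoms(base: str) -> dict[str, np.ndarray]:
    """Planar base heavy atoms of A/C/G/U in the base-fixed frame."""
    if base not in _BASES:
        raise ValueError(f"unknown base {base!r}; expected one of A, C, G, U")
    return {name: np.array([x, y, 0.0]) for name, x, y in _BASES[base]}


def nucleotide_template(base: str, chi: float = CHI_ANTI) -> dict[str, np.ndarray]:
    """Full heavy-atom ribonucleotide template (base + ribose + P, O5', O3').

    The sugar is C3'-endo; ``chi`` is the glycosidic torsion
    O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines).
    """
    atoms = base_atoms(base)
    if base in _PURINES:
        n_gly, c_chi, c_far = atoms["N9"], atoms["C4"], atoms["C8"]
    else:
        n_gly, c_chi, c_far = atoms["N1"], atoms["C2"], atoms["C6"]

    # glycosidic attachment: C1' in the base plane on the external bisector
    c1 = _place(c_far, c_chi, n_gly, 1.48, 126.3, 180.0)
    atoms["C1'"] = c1
    o4 = _place(c_chi, n_gly, c1, 1.45, 108.2, chi)
    atoms["O4'"] = o4
    # C2' is the other ring substituent on C1' (tetrahedral offset from O4')
    c2 = _place(c_chi, n_gly, c1, 1.53, 114.0, chi + 119.0)
    atoms["C2'"] = c2
    c3 = _place(o4, c1, c2, 1.525, 101.3, _NU1)
    atoms["C3'"] = c3
    c4 = _place(c1, c2, c3, 1.52, 102.7, _NU2)
    atoms["C4'"] = c4
    atoms["O2'"] = _place(o4, c1, c2, 1.41, 110.5, _NU1 - 120.0)
    atoms["O3'"] = _place(c1, c2, c3, 1.42, 110.6, _NU2 + 122.0)
    c5 = _place(c2, c3, c4, 1.51, 115.5, -157.0)
    atoms["C5'"] = c5
    o5 = _place(c3, c4, c5, 1.44, 110.2, 54.0)
    atoms["O5'"] = o5
    atoms["P"] = _place(c4, c5, o5, 1.59, 120.9, 180.0)
    return atoms


def wc_flip(coords: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Map a template onto the Watson-Crick partner position: (x,-y,-z)."""
    flip = np.array([1.0, -1.0, -1.0])
    return {name: pos * flip for name, pos in coords.items()}


def template_chi(base: str) -> float:
    """Glycosidic torsion of the built template (consistency check helper)."""
    t = nucleotide_template(base)
    if base in _PURINES:
        return torsion_angle(t["O4'"], t["C1'"], t["N9"], t["C4"])
    return torsion_angle(t["O4'"], t["C1'"], t["N1"], t["C2"])
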