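"""Vector primitives for nucleic-acid geometry.

Torsion angles, least-squares planes, signed out-of-plane distances and
nucleobase reference frames.  All inputs are Cartesian coordinates in
Ångström; all angles are in degrees.  Every operation here is invariant
under rigid motion of its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "Plane",
    "BaseFrame",
    "torsion_angle",
    "fit_plane",
    "signed_side",
    "base_frame",
    "PURINE_RING_ATOMS",
    "PYRIMIDINE_RING_ATOMS",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear points, missing atoms)."""


@dataclass(frozen=True)
class Plane:
    """Least-squares plane through a point cloud.

    Attributes
    ----------
    normal : unit 3-vector.
    centroid : centroid of the fitted points, Å.
    rms_deviation : root-mean-square point-to-plane distance of the fitted
        points, Å.
    """

    normal: np.ndarray
    centroid: np.ndarray
    rms_deviation: float


@dataclass(frozen=True)
class BaseFrame:
    """Centroid and normal of a nucleobase ring.

    The normal's handedness is fixed by the canonical ring-atom ordering
    (right-hand rule over the tabulated traversal), so it does not depend
    on the order atoms happen to appear in a coordinate file.
    """

    centroid: np.ndarray
    normal: np.ndarray


# Canonical ring traversals used to fix the normal's handedness.
PURINE_RING_ATOMS = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {v.shape}")
    return v


def torsion_angle(p1, p2, p3, p4) -> float:
    """Dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p2 towards p3, a clockwise rotation
    carrying the projection of p2->p1 onto that of p3->p4 is positive.
    A cis (eclipsed) arrangement gives 0, trans gives 180.
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("undefined torsion: collinear or coincident points")
    # atan2 formulation is numerically stable near 0 and 180 degrees
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def fit_plane(points) -> Plane:
    """Least-squares plane through >= 3 points (smallest singular direction)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("fit_plane needs at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centered cloud: the left-singular vector with the smallest
    # singular value is the least-squares normal.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:  # rank < 2: all points collinear
        raise GeometryError("degenerate plane: points are collinear")
    normal = vt[2]
    dists = centered @ normal
    rms = float(np.sqrt(np.mean(dists**2)))
    return Plane(normal=normal, centroid=centroid, rms_deviation=rms)


def signed_side(plane: Plane, p) -> float:
    """Signed distance of p from the plane: dot(normal, p - centroid), Å."""
    return float(np.dot(plane.normal, _as_vec(p) - plane.centroid))


def base_frame(residue) -> BaseFrame:
    """Reference frame (centroid + normal) of a residue's nucleobase ring.

    The least-squares normal is oriented so that traversing the canonical
    ring order counter-clockwise yields it by the right-hand rule; the
    result therefore does not depend on atom order in the file.

    Parameters
    ----------
    residue : structure_io.Residue
        Must carry the tabulated ring atoms (purines: N9..C4, pyrimidines:
        N1..C6).

    Raises
    ------
    GeometryError
        If the ring atoms are incomplete.
    """
    coords = _ring_coords(residue)
    plane = fit_plane(coords)
    # Orient against the polygon's signed-area normal for the tabulated order.
    centered = coords - plane.centroid
    area_vec = np.zeros(3)
    n = len(centered)
    for i in range(n):
        area_vec += np.cross(centered[i], centered[(i + 1) % n])
    normal = plane.normal if np.dot(plane.normal, area_vec) >= 0 else -plane.normal
    return BaseFrame(centroid=plane.centroid, normal=normal)


def _ring_coords(residue) -> np.ndarray:
    atoms = {a.name: a.position for a in residue.atoms}
    # a glycosidic N9 marks a purine: its full 9-ring is then required
    table = PURINE_RING_ATOMS if "N9" in atoms else PYRIMIDINE_RING_ATOMS
    missing = [n for n in table if n not in atoms]
    if missing:
        raise GeometryError(
            f"incomplete base: residue {residue.res_name} lacks ring atoms {missing}"
        )
    return np.array([atoms[name] for name in table], dtype=float)
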