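"""Structural feature annotation: hydrogen bonds, base pairs, stacks, puckers.

Detection is purely geometric over heavy atoms:

* **Hydrogen bonds** — donor/acceptor pairs from per-base tables, with a
  donor-acceptor distance window and a linearity test on the implied
  hydrogen direction (the external bisector of the donor's bonded
  neighbours).  No explicit hydrogens are required.
* **Base pairs** — residue pairs joined by at least one hydrogen bond
  between *face* atoms, grouped into sub-edge interactions
  (Lemieux-Major LW+ faces), then agglomerated to Leontis-Westhof edges
  (Watson-Crick / Hoogsteen / Sugar).  A cis/trans orientation is derived
  from the glycosidic-bond vectors.
* **Base stacks** — centroid distance, normal-vector angle and vertical
  separation thresholds; the relative normal orientation is classified as
  upward/downward/inward/outward from the signs of the normal-times-offset
  projections, and stacks are marked sequence-adjacent or not.
* **Sugar pucker** — envelope (one apex atom out of the plane of the other
  four) or twist (two apexes on opposite sides of the plane of the other
  three), each apex endo (displaced toward the C5' side) or exo.
* **Glycosidic conformation** — syn iff chi = O4'-C1'-N9-C4 (purines) /
  O4'-C1'-N1-C2 (pyrimidines) lies in [-90, +90] degrees.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .geometry import (
    GeometryError,
    base_frame,
    fit_plane,
    signed_side,
    torsion_angle,
)
from .structure_io import Residue, StructureModel, classify_residue

__all__ = [
    "AnnotationParams",
    "HBond",
    "SubEdgeKind",
    "EdgeKind",
    "SubEdgeInteraction",
    "BasePair",
    "BaseStack",
    "PuckerAnnotation",
    "GlycosidicAnnotation",
    "ModelAnnotation",
    "ResidueRef",
    "detect_hydrogen_bonds",
    "subedge_of_atom",
    "detect_base_pairs",
    "detect_base_stacks",
    "classify_pucker",
    "classify_glycosidic",
    "annotate_model",
    "SUBEDGE_TO_EDGE",
]


class SubEdgeKind(str, Enum):
    """Lemieux-Major sub-edges (faces), including the O2'/C8 atom faces."""

    Ww = "Ww"
    Wh = "Wh"
    Ws = "Ws"
    Bw = "Bw"
    Hh = "Hh"
    Hw = "Hw"
    Bh = "Bh"
    C8 = "C8"
    Ss = "Ss"
    Sw = "Sw"
    Bs = "Bs"
    O2p = "O2p"


class EdgeKind(str, Enum):
    WatsonCrick = "WatsonCrick"
    Hoogsteen = "Hoogsteen"
    Sugar = "Sugar"


#: Agglomeration of sub-edges into Leontis-Westhof edges.  Total: every
#: sub-edge maps to exactly one edge.
SUBEDGE_TO_EDGE: dict[SubEdgeKind, EdgeKind] = {
    SubEdgeKind.Ww: EdgeKind.WatsonCrick,
    SubEdgeKind.Wh: EdgeKind.WatsonCrick,
    SubEdgeKind.Ws: EdgeKind.WatsonCrick,
    SubEdgeKind.Bw: EdgeKind.WatsonCrick,
    SubEdgeKind.C8: EdgeKind.Hoogsteen,
    SubEdgeKind.Hh: EdgeKind.Hoogsteen,
    SubEdgeKind.Hw: EdgeKind.Hoogsteen,
    SubEdgeKind.Bh: EdgeKind.Hoogsteen,
    SubEdgeKind.Ss: EdgeKind.Sugar,
    SubEdgeKind.Sw: EdgeKind.Sugar,
    SubEdgeKind.Bs: EdgeKind.Sugar,
    SubEdgeKind.O2p: EdgeKind.Sugar,
}


@dataclass(frozen=True)
class AnnotationParams:
    """Geometric thresholds for feature detection (Å / degrees)."""

    hbond_max_da: float = 3.5
    hbond_min_da: float = 2.4
    hbond_max_angle_dev: float = 45.0
    stack_max_centroid_dist: float = 5.5
    stack_max_normal_angle: float = 35.0
    stack_min_vertical: float = 2.0
    pucker_tol: float = 0.10
    pair_min_interactions: int = 1

    def __post_init__(self):
        if self.hbond_min_da >= self.hbond_max_da:
            raise ValueError("hbond_min_da must be < hbond_max_da")
        for name in ("hbond_max_da", "hbond_min_da", "hbond_max_angle_dev",
                     "stack_max_centroid_dist", "stack_max_normal_angle",
                     "stack_min_vertical", "pucker_tol", "pair_min_interactions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


ResidueRef = tuple[str, int, str]  # (chain_id, seq_num, icode)


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    seq_num: int
    icode: str
    atom_name: str


@dataclass(frozen=True)
class HBond:
    donor_atom: AtomRef
    acceptor_atom: AtomRef
    da_distance: float


@dataclass(frozen=True)
class SubEdgeInteraction:
    """Symmetric n-ary interaction between two faces: (i,j) == (j,i)."""

    subedge_i: SubEdgeKind
    subedge_j: SubEdgeKind
    hbonds: tuple[HBond, ...]


@dataclass(frozen=True)
class BasePair:
    res_i: ResidueRef
    res_j: ResidueRef
    interactions: tuple[SubEdgeInteraction, ...]
    lw_edge_i: EdgeKind
    lw_edge_j: EdgeKind
    orientation: str  # "cis" | "trans"


@dataclass(frozen=True)
class BaseStack:
    res_i: ResidueRef
    res_j: ResidueRef
    adjacency: str  # "adjacent" | "non_adjacent"
    normal_orientation: str  # "upward" | "downward" | "inward" | "outward"


@dataclass(frozen=True)
class PuckerAnnotation:
    mode: str  # "envelope" | "twist" | "planar"
    apex_atoms: tuple[str, ...]
    apex_sides: tuple[str, ...]  # "endo" | "exo" per apex


@dataclass(frozen=True)
class GlycosidicAnnotation:
    chi: float
    conformation: str  # "syn" | "anti"


@dataclass
class ModelAnnotation:
    model_num: int
    pairs: list[BasePair] = field(default_factory=list)
    stacks: list[BaseStack] = field(default_factory=list)
    puckers: dict[ResidueRef, PuckerAnnotation] = field(default_factory=dict)
    glycosidics: dict[ResidueRef, GlycosidicAnnotation] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# hydrogen-bond donor/acceptor chemistry (heavy atoms only)
# ---------------------------------------------------------------------------

# donor atom -> (bonded heavy antecedents, geometry class).  Ring N-H
# donors put the implied hydrogen on the external bisector of the two
# antecedents; exocyclic amino groups have two hydrogens at +-60 degrees
# from the C->N extension within the base plane; the 2'-hydroxyl is
# rotatable, so only the distance and antecedent-angle tests apply.
_BASE_DONORS: dict[str, dict[str, tuple[tuple[str, ...], str]]] = {
    "A": {"N6": (("C6",), "amino")},
    "G": {"N1": (("C2", "C6"), "bisector"), "N2": (("C2",), "amino")},
    "C": {"N4": (("C4",), "amino")},
    "U": {"N3": (("C2", "C4"), "bisector")},
}
_BASE_ACCEPTORS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N1": ("C2", "C6"), "N3": ("C2", "C4"), "N7": ("C5", "C8")},
    "G": {"O6": ("C6",), "N3": ("C2", "C4"), "N7": ("C5", "C8")},
    "C": {"O2": ("C2",), "N3": ("C2", "C4")},
    "U": {"O2": ("C2",), "O4": ("C4",)},
}
# ribose/backbone oxygens shared by every nucleotide
_SUGAR_DONORS = {"O2'": (("C2'",), "rotatable")}
_SUGAR_ACCEPTORS = {
    "O2'": ("C2'",), "O4'": ("C1'", "C4'"), "O3'": ("C3'",),
    "O5'": ("C5'",), "OP1": ("P",), "OP2": ("P",),
}


def _donor_acceptor_tables(res: Residue) -> tuple[dict, dict]:
    cls = classify_residue(res)
    names = {a.name for a in res.atoms}
    donors = dict(_SUGAR_DONORS)
    acceptors = dict(_SUGAR_ACCEPTORS)
    if cls in _BASE_DONORS:
        donors.update(_BASE_DONORS[cls])
        acceptors.update(_BASE_ACCEPTORS[cls])
    elif cls == "modified":
        # merge every standard table entry whose atoms exist in the residue
        source = ("A", "G") if "N9" in names else ("C", "U")
        for s in source:
            donors.update(_BASE_DONORS[s])
            acceptors.update(_BASE_ACCEPTORS[s])
    donors = {k: v for k, v in donors.items() if k in names}
    acceptors = {k: v for k, v in acceptors.items() if k in names}
    return donors, acceptors


def _implied_h_directions(res: Residue, donor: str, antecedents: tuple[str, ...],
                          geometry: str) -> list[np.ndarray]:
    """Candidate N-H/O-H directions for a donor; empty list = no constraint."""
    if geometry == "rotatable":
        return []
    d = res.atom(donor)
    if d is None:
        return []
    vecs = []
    for name in antecedents:
        a = res.atom(name)
        if a is not None:
            v = d.position - a.position
            n = np.linalg.norm(v)
            if n > 0:
                vecs.append(v / n)
    if not vecs:
        return []
    ext = np.sum(vecs, axis=0)
    n = np.linalg.norm(ext)
    if n < 1e-9:
        return []
    ext /= n
    if geometry == "bisector":
        return [ext]
    # amino: two hydrogens at +-60 degrees from the extension, in the base plane
    try:
        normal = base_frame(res).normal
    except GeometryError:
        return [ext]
    perp = np.cross(normal, ext)
    pn = np.linalg.norm(perp)
    if pn < 1e-9:
        return [ext]
    perp /= pn
    c, s = np.cos(np.radians(60.0)), np.sin(np.radians(60.0))
    return [c * ext + s * perp, c * ext - s * perp]


def detect_hydrogen_bonds(r1: Residue, r2: Residue, params: AnnotationParams | None = None) -> list[HBond]:
    """Heavy-atom hydrogen bonds between two (different) residues.

    A donor D (with implied hydrogen along the external bisector of its
    bonded neighbours) and acceptor A form a bond when
    ``hbond_min_da <= |D-A| <= hbond_max_da``, the implied-H direction
    deviates from D->A by at most ``hbond_max_angle_dev`` degrees, and
    every antecedent-donor-acceptor angle is >= 90 degrees.  The scan is
    symmetric: both residues are tried in both roles.
    """
    params = params or AnnotationParams()
    bonds: list[HBond] = []
    for donor_res, acc_res in ((r1, r2), (r2, r1)):
        donors, _ = _donor_acceptor_tables(donor_res)
        _, acceptors = _donor_acceptor_tables(acc_res)
        for dname, (antecedents, geometry) in sorted(donors.items()):
            datom = donor_res.atom(dname)
            hdirs = _implied_h_directions(donor_res, dname, antecedents, geometry)
            for aname in sorted(acceptors):
                aatom = acc_res.atom(aname)
                d = float(np.linalg.norm(aatom.position - datom.position))
                if not (params.hbond_min_da <= d <= params.hbond_max_da):
                    continue
                da = (aatom.position - datom.position) / d
                if hdirs:
                    dev = min(
                        np.degrees(np.arccos(np.clip(np.dot(h, da), -1.0, 1.0)))
                        for h in hdirs
                    )
                    if dev > params.hbond_max_angle_dev:
                        continue
                ok = True
                for ante in antecedents:
                    a = donor_res.atom(ante)
                    if a is None:
                        continue
                    v1 = a.position - datom.position
                    ang = np.degrees(np.arccos(np.clip(
                        np.dot(v1, da) / np.linalg.norm(v1), -1.0, 1.0)))
                    if ang < 90.0:
                        ok = False
                        break
                if not ok:
                    continue
                bonds.append(HBond(
                    donor_atom=AtomRef(donor_res.chain_id, donor_res.seq_num, donor_res.icode, dname),
                    acceptor_atom=AtomRef(acc_res.chain_id, acc_res.seq_num, acc_res.icode, aname),
                    da_distance=d,
                ))
    return bonds


# ---------------------------------------------------------------------------
# LW+ face table
# ---------------------------------------------------------------------------

_PURINE_FACES_COMMON = {
    "O2'": SubEdgeKind.O2p, "C8": SubEdgeKind.C8, "N9": SubEdgeKind.Ss,
    "N7": SubEdgeKind.Hh, "N3": SubEdgeKind.Ss,
}
_PYRIMIDINE_FACES_COMMON = {
    "O2'": SubEdgeKind.O2p, "N1": SubEdgeKind.Ss,
    "O2": SubEdgeKind.Ws, "C5": SubEdgeKind.Hh, "C6": SubEdgeKind.Hw,
}
_FACES: dict[str, dict[str, SubEdgeKind]] = {
    "A": {**_PURINE_FACES_COMMON, "N1": SubEdgeKind.Ww, "N6": SubEdgeKind.Wh,
          "C2": SubEdgeKind.Ws},
    "G": {**_PURINE_FACES_COMMON, "N1": SubEdgeKind.Ww, "O6": SubEdgeKind.Wh,
          "N2": SubEdgeKind.Ws},
    "C": {**_PYRIMIDINE_FACES_COMMON, "N3": SubEdgeKind.Ww, "N4": SubEdgeKind.Wh},
    "U": {**_PYRIMIDINE_FACES_COMMON, "N3": SubEdgeKind.Ww, "O4": SubEdgeKind.Wh},
}
# nonstandard nucleotides: purine naming wins where names collide
_FACES["modified_purine"] = {**_FACES["A"], **{k: v for k, v in _FACES["G"].items()}}
_FACES["modified_pyrimidine"] = {**_FACES["C"], **{k: v for k, v in _FACES["U"].items()}}


def subedge_of_atom(residue_class: str, atom_name: str) -> SubEdgeKind | None:
    """Face (sub-edge) of a base/ribose atom, or None for non-face atoms.

    ``residue_class`` is A/C/G/U or ``modified``; for modified residues the
    purine table is used (documented approximation; for content-aware
    lookup use :func:`subedge_of_residue_atom`).
    """
    if residue_class in _FACES:
        return _FACES[residue_class].get(atom_name)
    if residue_class == "modified":
        return _FACES["modified_purine"].get(atom_name)
    raise ValueError(f"unknown residue class {residue_class!r}")


def subedge_of_residue_atom(res: Residue, atom_name: str) -> SubEdgeKind | None:
    """Like :func:`subedge_of_atom` but resolves modified residues by content."""
    cls = classify_residue(res)
    if cls == "modified":
        names = {a.name for a in res.atoms}
        key = "modified_purine" if "N9" in names else "modified_pyrimidine"
        return _FACES[key].get(atom_name)
    if cls == "non_nucleic":
        return None
    return _FACES[cls].get(atom_name)


# ---------------------------------------------------------------------------
# base pairs
# ---------------------------------------------------------------------------

def _residue_order_key(r: Residue) -> tuple:
    return (r.chain_id, r.seq_num, r.icode)


def _glycosidic_atoms(res: Residue) -> tuple[str, str] | None:
    names = {a.name for a in res.atoms}
    if "N9" in names:
        return ("N9", "C4") if "C4" in names else None
    if {"N1", "C2"} <= names:
        return ("N1", "C2")
    return None


def _pair_orientation(r1: Residue, r2: Residue) -> str:
    """cis/trans from the glycosidic-bond vectors relative to the pair axis.

    The axis runs between the two glycosidic nitrogens; each C1'->N vector
    is projected via a triple product with the first base's normal.  Equal
    signs mean both glycosidic bonds leave the axis on the same side: cis.
    """
    g1 = _glycosidic_atoms(r1)
    g2 = _glycosidic_atoms(r2)
    if g1 is None or g2 is None:
        return "cis"
    try:
        n1 = r1.coord(g1[0])
        n2 = r2.coord(g2[0])
        c1 = r1.coord("C1'")
        c2 = r2.coord("C1'")
        normal = base_frame(r1).normal
    except (KeyError, GeometryError):
        return "cis"
    axis = n2 - n1
    s1 = np.dot(np.cross(axis, c1 - n1), normal)
    s2 = np.dot(np.cross(axis, c2 - n2), normal)
    return "cis" if s1 * s2 >= 0 else "trans"


def _classify_sides(
    r1: Residue, r2: Residue, bonds: list[HBond], params: AnnotationParams
) -> tuple[SubEdgeInteraction, ...] | None:
    """Group face-atom hydrogen bonds into sub-edge interactions."""
    key1 = _residue_order_key(r1)
    groups: dict[tuple[SubEdgeKind, SubEdgeKind], list[HBond]] = {}
    for hb in bonds:
        if (hb.donor_atom.chain_id, hb.donor_atom.seq_num, hb.donor_atom.icode) == key1:
            a1, a2 = hb.donor_atom.atom_name, hb.acceptor_atom.atom_name
        else:
            a1, a2 = hb.acceptor_atom.atom_name, hb.donor_atom.atom_name
        se1 = subedge_of_residue_atom(r1, a1)
        se2 = subedge_of_residue_atom(r2, a2)
        if se1 is None or se2 is None:
            continue
        groups.setdefault((se1, se2), []).append(hb)
    if len(groups) < params.pair_min_interactions:
        return None
    interactions = tuple(
        SubEdgeInteraction(subedge_i=k[0], subedge_j=k[1], hbonds=tuple(v))
        for k, v in sorted(groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value))
    )
    return interactions if interactions else None


def _lw_edge(interactions: tuple[SubEdgeInteraction, ...], side: int) -> EdgeKind:
    counts: dict[SubEdgeKind, int] = {}
    for it in interactions:
        se = it.subedge_i if side == 0 else it.subedge_j
        counts[se] = counts.get(se, 0) + len(it.hbonds)
    best = max(counts.values())
    winners = [se for se, c in counts.items() if c == best]
    if len(winners) == 1:
        return SUBEDGE_TO_EDGE[winners[0]]
    first = interactions[0]
    return SUBEDGE_TO_EDGE[first.subedge_i if side == 0 else first.subedge_j]


def detect_base_pairs(m: StructureModel, params: AnnotationParams | None = None) -> list[BasePair]:
    """All base pairs in one model (at least one face-face hydrogen bond)."""
    params = params or AnnotationParams()
    residues = sorted(
        (r for r in m.residues() if classify_residue(r) != "non_nucleic"),
        key=_residue_order_key,
    )
    pairs: list[BasePair] = []
    for r1, r2 in itertools.combinations(residues, 2):
        if not _close_enough(r1, r2, params.hbond_max_da):
            continue
        bonds = detect_hydrogen_bonds(r1, r2, params)
        if not bonds:
            continue
        interactions = _classify_sides(r1, r2, bonds, params)
        if interactions is None:
            continue
        pairs.append(BasePair(
            res_i=_residue_order_key(r1),
            res_j=_residue_order_key(r2),
            interactions=interactions,
            lw_edge_i=_lw_edge(interactions, 0),
            lw_edge_j=_lw_edge(interactions, 1),
            orientation=_pair_orientation(r1, r2),
        ))
    return pairs


def _close_enough(r1: Residue, r2: Residue, cutoff: float) -> bool:
    # cheap prefilter on C1'/first-atom separation
    a1 = r1.atom("C1'") or (r1.atoms[0] if r1.atoms else None)
    a2 = r2.atom("C1'") or (r2.atoms[0] if r2.atoms else None)
    if a1 is None or a2 is None:
        return False
    return float(np.linalg.norm(a1.position - a2.position)) <= cutoff + 18.0


# ---------------------------------------------------------------------------
# base stacks
# ---------------------------------------------------------------------------

_ORIENTATION = {(1, 1): "upward", (-1, -1): "downward",
                (1, -1): "inward", (-1, 1): "outward"}


def detect_base_stacks(m: StructureModel, params: AnnotationParams | None = None) -> list[BaseStack]:
    """Base stacks: close, near-parallel bases with real vertical overlap."""
    params = params or AnnotationParams()
    residues = sorted(
        (r for r in m.residues() if classify_residue(r) != "non_nucleic"),
        key=_residue_order_key,
    )
    frames = {}
    for r in residues:
        try:
            frames[_residue_order_key(r)] = base_frame(r)
        except GeometryError:
            continue
    chain_index: dict[tuple[str, ResidueRef], int] = {}
    for cid, chain in m.chains.items():
        for idx, r in enumerate(chain):
            chain_index[(cid, _residue_order_key(r))] = idx

    stacks: list[BaseStack] = []
    for r1, r2 in itertools.combinations(residues, 2):
        k1, k2 = _residue_order_key(r1), _residue_order_key(r2)
        if k1 not in frames or k2 not in frames:
            continue
        f1, f2 = frames[k1], frames[k2]
        cij = f2.centroid - f1.centroid
        dist = float(np.linalg.norm(cij))
        if dist > params.stack_max_centroid_dist or dist == 0.0:
            continue
        ang = np.degrees(np.arccos(np.clip(abs(np.dot(f1.normal, f2.normal)), 0.0, 1.0)))
        if ang > params.stack_max_normal_angle:
            continue
        mean_normal = f1.normal + (f2.normal if np.dot(f1.normal, f2.normal) >= 0 else -f2.normal)
        mean_normal /= np.linalg.norm(mean_normal)
        if abs(float(np.dot(cij, mean_normal))) < params.stack_min_vertical:
            continue
        s1 = 1 if np.dot(f1.normal, cij) >= 0 else -1
        s2 = 1 if np.dot(f2.normal, cij) >= 0 else -1
        adjacent = (
            r1.chain_id == r2.chain_id
            and abs(chain_index[(r1.chain_id, k1)] - chain_index[(r2.chain_id, k2)]) == 1
        )
        stacks.append(BaseStack(
            res_i=k1, res_j=k2,
            adjacency="adjacent" if adjacent else "non_adjacent",
            normal_orientation=_ORIENTATION[(s1, s2)],
        ))
    return stacks


# ---------------------------------------------------------------------------
# pucker and glycosidic
# ---------------------------------------------------------------------------

_RING = ("C1'", "C2'", "C3'", "C4'", "O4'")


def classify_pucker(r: Residue, params: AnnotationParams | None = None) -> PuckerAnnotation:
    """Envelope/twist/planar classification of the ribose ring.

    Envelope: some apex atom lies > pucker_tol off the plane of the other
    four (which are coplanar within pucker_tol RMS).  Twist: two atoms lie
    on opposite sides of the plane of the other three.  Endo means the
    apex is displaced toward the C5' side of the reference plane.
    """
    params = params or AnnotationParams()
    tol = params.pucker_tol
    coords = {}
    for name in _RING + ("C5'",):
        a = r.atom(name)
        if a is None:
            raise GeometryError(f"classify_pucker: residue lacks atom {name}")
        coords[name] = a.position
    c5 = coords["C5'"]

    envelopes = []
    for apex in _RING:
        others = [coords[n] for n in _RING if n != apex]
        plane = fit_plane(others)
        dev = signed_side(plane, coords[apex])
        if plane.rms_deviation <= tol and abs(dev) > tol:
            side = "endo" if dev * signed_side(plane, c5) > 0 else "exo"
            envelopes.append((abs(dev), apex, side))
    if envelopes:
        _, apex, side = max(envelopes)
        return PuckerAnnotation(mode="envelope", apex_atoms=(apex,), apex_sides=(side,))

    twists = []
    # twist apexes are adjacent ring atoms; non-adjacent exclusions leave a
    # near-collinear atom triple whose plane is ill-conditioned
    ring_pairs = [(_RING[i], _RING[(i + 1) % 5]) for i in range(5)]
    for a1, a2 in ring_pairs:
        others = [coords[n] for n in _RING if n not in (a1, a2)]
        plane = fit_plane(others)
        d1 = signed_side(plane, coords[a1])
        d2 = signed_side(plane, coords[a2])
        if abs(d1) > tol and abs(d2) > tol and d1 * d2 < 0:
            c5d = signed_side(plane, c5)
            sides = tuple("endo" if d * c5d > 0 else "exo" for d in (d1, d2))
            twists.append((min(abs(d1), abs(d2)), (a1, a2), sides))
    if twists:
        _, apexes, sides = max(twists)
        return PuckerAnnotation(mode="twist", apex_atoms=apexes, apex_sides=sides)
    return PuckerAnnotation(mode="planar", apex_atoms=(), apex_sides=())


def classify_glycosidic(r: Residue) -> GlycosidicAnnotation:
    """Glycosidic torsion chi and its syn/anti classification."""
    gly = _glycosidic_atoms(r)
    if gly is None:
        raise GeometryError("classify_glycosidic: no glycosidic nitrogen found")
    chi = torsion_angle(r.coord("O4'"), r.coord("C1'"), r.coord(gly[0]), r.coord(gly[1]))
    return GlycosidicAnnotation(chi=chi, conformation="syn" if -90.0 <= chi <= 90.0 else "anti")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def annotate_model(m: StructureModel, params: AnnotationParams | None = None) -> ModelAnnotation:
    """Run every detector over one model; per-residue failures warn, not fail."""
    params = params or AnnotationParams()
    ann = ModelAnnotation(model_num=m.model_num)
    ann.pairs = detect_base_pairs(m, params)
    ann.stacks = detect_base_stacks(m, params)
    for res in sorted(m.residues(), key=_residue_order_key):
        if classify_residue(res) == "non_nucleic":
            if res.atom("C1'") is not None:  # looks like a degraded nucleotide
                warnings.warn(
                    f"residue {_residue_order_key(res)} has ribose atoms but no "
                    "complete base ring; excluded from annotation", stacklevel=2)
            continue
        key = _residue_order_key(res)
        try:
            ann.puckers[key] = classify_pucker(res, params)
        except GeometryError as exc:
            warnings.warn(f"pucker skipped for {key}: {exc}", stacklevel=2)
        try:
            ann.glycosidics[key] = classify_glycosidic(res)
        except (GeometryError, KeyError) as exc:
            warnings.warn(f"glycosidic skipped for {key}: {exc}", stacklevel=2)
    return ann
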