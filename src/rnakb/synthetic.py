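"""Synthetic test-input generators with exact ground truth.

Three families:

* :func:`make_duplex` — an idealized double helix built from the bundled
  ribonucleotide templates: each Watson-Crick pair sits in a common base
  frame (partner flipped through the pair's pseudo-dyad), pairs are
  stacked with the canonical A-form rise and twist, and optional Gaussian
  coordinate noise is applied with a seeded generator.  Ground truth is
  returned for every complementary pair, intra-strand neighbour stack and
  glycosidic state.
* :func:`make_pucker_ring` — a five-membered ribose ring constructed with
  a prescribed envelope pucker (apex atom, endo/exo side, amplitude).
* :func:`make_kb_fixture` — a knowledge graph built directly from a pair
  and stack plan (bypassing geometry), with exact expected answer sets for
  the bundled query templates computed combinatorially from the plan.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, MolecularStructureFile, Residue, StructureModel
from .templates import COMPLEMENT, nucleotide_template, wc_flip

__all__ = [
    "DuplexSpec",
    "DuplexGroundTruth",
    "make_duplex",
    "make_pucker_ring",
    "KBFixtureSpec",
    "KBFixtureGroundTruth",
    "make_kb_fixture",
]


# ---------------------------------------------------------------------------
# A-form duplex
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplexSpec:
    """Recipe for a synthetic double helix.

    ``helical_rise``/``helical_twist`` default to the canonical A-form
    values (2.81 Å, 32.7 degrees).  ``noise_sigma`` is the per-coordinate
    Gaussian displacement in Å.
    """

    sequence: str
    n_models: int = 1
    helical_rise: float = 2.81
    helical_twist: float = 32.7
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) < 2:
            raise ValueError("sequence must have length >= 2")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(f"sequence contains non-ACGU characters: {sorted(bad)}")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


@dataclass(frozen=True)
class DuplexGroundTruth:
    """Expected annotations, identical for every model of the file."""

    pairs: tuple[tuple[tuple[str, int, str], tuple[str, int, str]], ...]
    stacks: tuple[tuple[tuple[str, int, str], tuple[str, int, str]], ...]
    glycosidic: dict[tuple[str, int, str], str]


def _rz(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_duplex(spec: DuplexSpec) -> tuple[MolecularStructureFile, DuplexGroundTruth]:
    """Build the duplex coordinate file and its exact ground truth.

    Chain A carries ``spec.sequence`` 5'->3'; chain B the reverse
    complement.  Residue i of chain A pairs residue n+1-i of chain B.
    """
    n = len(spec.sequence)
    rng = np.random.default_rng(spec.seed)
    models = []
    for im in range(spec.n_models):
        chains: dict[str, list[Residue]] = {"A": [], "B": []}
        for i, base in enumerate(spec.sequence):  # chain A, level i
            coords = _placed(nucleotide_template(base), i, spec)
            chains["A"].append(_make_residue("A", i + 1, base, coords, rng, spec))
        for j in range(1, n + 1):  # chain B residue j at level n - j
            level = n - j
            base = COMPLEMENT[spec.sequence[level]]
            coords = _placed(wc_flip(nucleotide_template(base)), level, spec)
            chains["B"].append(_make_residue("B", j, base, coords, rng, spec))
        models.append(StructureModel(model_num=im + 1, chains=chains))
    msf = MolecularStructureFile(pdb_id="SYNT", models=models, source_path="<synthetic>")

    pairs = tuple((("A", i, ""), ("B", n + 1 - i, "")) for i in range(1, n + 1))
    stacks = tuple(
        ((c, i, ""), (c, i + 1, "")) for c in ("A", "B") for i in range(1, n)
    )
    glyco = {(c, i, ""): "anti" for c in ("A", "B") for i in range(1, n + 1)}
    return msf, DuplexGroundTruth(pairs=pairs, stacks=stacks, glycosidic=glyco)


def _placed(coords: dict[str, np.ndarray], level: int, spec: DuplexSpec) -> dict[str, np.ndarray]:
    rot = _rz(spec.helical_twist * level)
    shift = np.array([0.0, 0.0, spec.helical_rise * level])
    return {k: rot @ v + shift for k, v in coords.items()}


def _make_residue(chain: str, seq: int, base: str, coords: dict[str, np.ndarray],
                  rng: np.random.Generator, spec: DuplexSpec) -> Residue:
    atoms = []
    for name, pos in coords.items():
        if spec.noise_sigma > 0:
            pos = pos + rng.normal(0.0, spec.noise_sigma, size=3)
        atoms.append(Atom(name=name, element=name.strip("'0123456789")[0], position=pos))
    return Residue(chain_id=chain, seq_num=seq, icode="", res_name=base, atoms=atoms)


# ---------------------------------------------------------------------------
# pucker ring
# ---------------------------------------------------------------------------

_RING_ORDER = ("C1'", "C2'", "C3'", "C4'", "O4'")


def make_pucker_ring(apex: str, side: str, amplitude: float) -> Residue:
    """Ribose ring with a constructed envelope pucker.

    The four non-apex ring atoms are placed exactly coplanar on a circle
    of ribose-like radius (z = 0); the apex is displaced by ``amplitude``
    toward (endo) or away from (exo) a C5' fixed at positive z.  Ground
    truth is (envelope, apex, side).
    """
    if apex not in _RING_ORDER:
        raise ValueError(f"invalid apex {apex!r}; must be one of {_RING_ORDER}")
    if side not in ("endo", "exo"):
        raise ValueError("side must be 'endo' or 'exo'")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    radius = 1.53 / (2.0 * np.sin(np.pi / 5.0))  # pentagon edge ~ C-C bond
    coords: dict[str, np.ndarray] = {}
    for k, name in enumerate(_RING_ORDER):
        ang = 2.0 * np.pi * k / 5.0
        coords[name] = np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0])
    # C5' above the ring plane (+z): endo = displaced toward it
    c4 = coords["C4'"]
    coords["C5'"] = c4 + np.array([0.6, 0.0, 1.35])
    z = amplitude if side == "endo" else -amplitude
    coords[apex] = coords[apex] + np.array([0.0, 0.0, z])
    atoms = [Atom(name=n, element=n[0], position=p) for n, p in coords.items()]
    return Residue(chain_id="A", seq_num=1, icode="", res_name="G", atoms=atoms)


# ---------------------------------------------------------------------------
# planned knowledge-graph fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KBFixtureSpec:
    """Plan for a directly-built knowledge graph with known ground truth.

    ``pair_plan`` entries: (model_num, res_i, res_j, interactions) where
    res_* are (chain_id, seq_num) tuples and interactions is a list of
    (subedge_i, subedge_j) face-name pairs (e.g. ("Ww", "Hh")).
    ``stack_plan`` entries: (model_num, res_i, res_j, adjacency,
    orientation).
    """

    pdb_id: str = "TEST"
    n_models: int = 1
    n_chains: int = 1
    residues_per_chain: int = 4
    pair_plan: tuple = ()
    stack_plan: tuple = ()
    residue_bases: tuple = ()  # optional explicit base per (chain, seq); else cycled ACGU
    seed: int = 0


@dataclass(frozen=True)
class KBFixtureGroundTruth:
    """Expected answer sets (as URI sets) for the bundled query templates."""

    models: frozenset
    pairs_with_hoogsteen: frozenset          # query template B
    pairs_hoogsteen_on_g: frozenset          # query template C
    pairs_ww_ect_hh: frozenset               # query template D
    pairs_hoogsteen_in_file: frozenset       # query template E
    all_pairs: frozenset


def make_kb_fixture(spec: KBFixtureSpec):
    """Build (KBGraph, ground truth) directly from a plan.

    The graph is emitted through the same knowledge-graph builder used for
    real structures; expected query answers are enumerated combinatorially
    from the plan, independently of the query engine.
    """
    # local import: the builder imports annotator types, not this module
    from .annotator import SubEdgeInteraction, SubEdgeKind
    from . import kb_builder

    chains = [chr(ord("A") + c) for c in range(spec.n_chains)]
    bases = dict(spec.residue_bases)
    letters = "ACGU"
    residues = {}
    for ci, ch in enumerate(chains):
        for s in range(1, spec.residues_per_chain + 1):
            residues[(ch, s)] = bases.get((ch, s), letters[(ci + s) % 4])

    for (mnum, ri, rj, _ints) in spec.pair_plan:
        _check_ref(spec, residues, mnum, ri, rj, "pair")
    for (mnum, ri, rj, _adj, _ori) in spec.stack_plan:
        _check_ref(spec, residues, mnum, ri, rj, "stack")

    graph = kb_builder.build_planned_graph(
        pdb_id=spec.pdb_id,
        n_models=spec.n_models,
        residues=residues,
        pair_plan=spec.pair_plan,
        stack_plan=spec.stack_plan,
    )

    ns = kb_builder.NAMESPACE
    pid = spec.pdb_id.upper()
    hoogsteen = {"C8", "Hh", "Hw", "Bh"}

    def pair_uri(mnum, ri, rj):
        (c1, s1), (c2, s2) = sorted([tuple(ri), tuple(rj)])
        return f"{ns}{pid}_m{mnum}_c{c1}_r{s1}_c{c2}_r{s2}_bp"

    def part_uri(mnum, ref, face):
        c, s = tuple(ref)
        return f"{ns}{pid}_m{mnum}_c{c}_r{s}_se{face}"

    # participant-level bookkeeping: a (model, residue, face) participant is
    # ONE individual even when it appears in several pairs, so externally-
    # connected-to links may reach across pairs of the same model.
    part_face: dict[str, str] = {}
    part_res: dict[str, tuple] = {}
    ect: dict[str, set[str]] = {}
    pair_parts: dict[str, set[str]] = {}
    all_pairs = set()
    for (mnum, ri, rj, ints) in spec.pair_plan:
        uri = pair_uri(mnum, ri, rj)
        all_pairs.add(uri)
        parts = pair_parts.setdefault(uri, set())
        for (sei, sej) in ints:
            ui, uj = part_uri(mnum, ri, sei), part_uri(mnum, rj, sej)
            part_face[ui], part_face[uj] = sei, sej
            part_res[ui], part_res[uj] = tuple(ri), tuple(rj)
            parts |= {ui, uj}
            ect.setdefault(ui, set()).add(uj)
            ect.setdefault(uj, set()).add(ui)

    # Parthood entails more than the directly asserted participants: a pair
    # has its residues as parts, residues are model-independent, and every
    # participant (from any model's pairs) is part of its residue — so by
    # transitivity those participants are parts of the pair as well.
    by_residue: dict[tuple, set[str]] = {}
    for p, ref in part_res.items():
        by_residue.setdefault(ref, set()).add(p)
    pair_residues = {
        pair_uri(m, ri, rj): {tuple(ri), tuple(rj)}
        for (m, ri, rj, _ints) in spec.pair_plan
    }
    entailed_parts = {
        uri: parts | set().union(*(by_residue.get(r, set()) for r in pair_residues[uri]))
        for uri, parts in pair_parts.items()
    }

    b_set, c_set, d_set = set(), set(), set()
    for uri, parts in entailed_parts.items():
        for p in parts:
            connected = ect.get(p, set())
            if not connected:
                continue
            if part_face[p] in hoogsteen:
                b_set.add(uri)
                if residues[part_res[p]] == "G":
                    c_set.add(uri)
            if part_face[p] == "Ww" and any(part_face[q] == "Hh" for q in connected):
                d_set.add(uri)

    models = frozenset(f"{ns}{pid}_m{i}" for i in range(1, spec.n_models + 1))
    return graph, KBFixtureGroundTruth(
        models=models,
        pairs_with_hoogsteen=frozenset(b_set),
        pairs_hoogsteen_on_g=frozenset(c_set),
        pairs_ww_ect_hh=frozenset(d_set),
        pairs_hoogsteen_in_file=frozenset(b_set),
        all_pairs=frozenset(all_pairs),
    )


def _check_ref(spec, residues, mnum, ri, rj, what):
    if not (1 <= mnum <= spec.n_models):
        raise ValueError(f"{what} plan references model {mnum} outside 1..{spec.n_models}")
    for ref in (ri, rj):
        if tuple(ref) not in residues:
            raise ValueError(f"{what} plan references unknown residue {ref}")
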