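"""Knowledge-graph population: URI minting and triple emission.

Entity naming follows one scheme throughout (prime characters become "p",
all local names are URI-safe):

==================  =============================================
entity              local name
==================  =============================================
file                ``PDBID``
structure model     ``PDBID_mMODEL``
molecule (chain)    ``PDBID_cCHAIN``
residue             ``PDBID_cCHAIN_rRESIDUE``
atom                ``PDBID_cCHAIN_rRESIDUE_aATOM``
nucleoside/ribose/  residue name + ``_ns`` / ``_rib`` / ``_nb``
nucleobase
base pair           ``PDBID_mMODEL_cC1_rR1_cC2_rR2_bp``
base stack          ``PDBID_mMODEL_cC1_rR1_cC2_rR2_stk``
sub-edge participant ``PDBID_mMODEL_cCHAIN_rRESIDUE_seFACE``
quality             ``PDBID_mMODEL_cCHAIN_rRESIDUE_QUALITY``
==================  =============================================

Structure models, features (pairs, stacks) and qualities are model-scoped;
molecules, residues and atoms are model-independent material entities.
Serialization to Turtle/N-Triples goes through rdflib.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .annotator import ModelAnnotation, SubEdgeKind
from .schema import RESIDUE_CLASS_ID, SUBEDGE_CLASS, SchemaCatalog, load_schema
from .structure_io import MolecularStructureFile, classify_residue

__all__ = [
    "NAMESPACE",
    "VOCAB",
    "KBGraph",
    "EntityDescriptor",
    "KBBuildError",
    "mint_uri",
    "build_graph",
    "build_planned_graph",
    "serialize_graph",
    "parse_graph",
]

NAMESPACE = "http://rnakb.example.org/kb/"
VOCAB = "http://rnakb.example.org/vocab#"

_SAFE = re.compile(r"[^A-Za-z0-9_.\-]")


class KBBuildError(ValueError):
    pass


@dataclass
class KBGraph:
    """Triple container with label and type indices.

    ``triples`` hold object-property statements ``(subject_uri,
    property_id, object_uri)``; rdf:type and rdfs:label statements live in
    the dedicated indices and are emitted as triples on serialization.
    """

    triples: set[tuple[str, str, str]] = field(default_factory=set)
    types: dict[str, set[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)  # uri -> label
    label_index: dict[str, str] = field(default_factory=dict)  # label -> uri

    def add(self, s: str, p: str, o: str) -> None:
        self.triples.add((s, p, o))

    def add_type(self, uri: str, class_id: str) -> None:
        self.types.setdefault(uri, set()).add(class_id)

    def set_label(self, uri: str, label: str) -> None:
        self.labels[uri] = label
        self.label_index[label] = uri

    def individuals(self):
        return self.types.keys()

    def objects(self, s: str, p: str) -> set[str]:
        return {o for (s2, p2, o) in self.triples if s2 == s and p2 == p}

    def copy(self) -> "KBGraph":
        return KBGraph(
            triples=set(self.triples),
            types={k: set(v) for k, v in self.types.items()},
            labels=dict(self.labels),
            label_index=dict(self.label_index),
        )

    def __len__(self) -> int:
        return len(self.triples) + len(self.labels) + sum(len(v) for v in self.types.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, KBGraph):
            return NotImplemented
        return (self.triples == other.triples and self.types == other.types
                and self.labels == other.labels)


@dataclass(frozen=True)
class EntityDescriptor:
    """Field bundle from which a URI is minted; unused fields stay None."""

    kind: str  # file | structure_model | molecule | residue | atom |
    #            nucleoside | ribose | nucleobase | base_pair | base_stack |
    #            subedge | quality
    pdb_id: str
    model_num: int | None = None
    chain: str | None = None
    seq_num: int | None = None
    icode: str = ""
    atom_name: str | None = None
    quality_token: str | None = None
    face: str | None = None
    partner_chain: str | None = None
    partner_seq: int | None = None
    partner_icode: str = ""


def _san(text: str) -> str:
    return _SAFE.sub("_", text.replace("'", "p"))


def _res_token(seq_num: int, icode: str) -> str:
    return f"{seq_num}{icode}"


def mint_uri(d: EntityDescriptor) -> str:
    """Mint the URI for an entity descriptor (raises on missing fields)."""
    pid = d.pdb_id.upper()

    def need(*fields):
        for f in fields:
            if getattr(d, f) is None:
                raise KBBuildError(f"descriptor kind {d.kind!r} requires field {f!r}")

    if d.kind == "file":
        local = pid
    elif d.kind == "structure_model":
        need("model_num")
        local = f"{pid}_m{d.model_num}"
    elif d.kind == "molecule":
        need("chain")
        local = f"{pid}_c{d.chain}"
    elif d.kind in ("residue", "nucleoside", "ribose", "nucleobase"):
        need("chain", "seq_num")
        local = f"{pid}_c{d.chain}_r{_res_token(d.seq_num, d.icode)}"
        suffix = {"residue": "", "nucleoside": "_ns", "ribose": "_rib", "nucleobase": "_nb"}
        local += suffix[d.kind]
    elif d.kind == "atom":
        need("chain", "seq_num", "atom_name")
        local = f"{pid}_c{d.chain}_r{_res_token(d.seq_num, d.icode)}_a{d.atom_name}"
    elif d.kind in ("base_pair", "base_stack"):
        need("model_num", "chain", "seq_num", "partner_chain", "partner_seq")
        tag = "bp" if d.kind == "base_pair" else "stk"
        local = (f"{pid}_m{d.model_num}_c{d.chain}_r{_res_token(d.seq_num, d.icode)}"
                 f"_c{d.partner_chain}_r{_res_token(d.partner_seq, d.partner_icode)}_{tag}")
    elif d.kind == "subedge":
        need("model_num", "chain", "seq_num", "face")
        local = f"{pid}_m{d.model_num}_c{d.chain}_r{_res_token(d.seq_num, d.icode)}_se{d.face}"
    elif d.kind == "quality":
        need("model_num", "chain", "seq_num", "quality_token")
        local = f"{pid}_m{d.model_num}_c{d.chain}_r{_res_token(d.seq_num, d.icode)}_{d.quality_token}"
    else:
        raise KBBuildError(f"unknown descriptor kind {d.kind!r}")
    return NAMESPACE + _san(local)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(
    f: MolecularStructureFile,
    anns: list[ModelAnnotation],
    schema: SchemaCatalog | None = None,
    emit_orientation: bool = False,
    about_atoms: bool = False,
) -> KBGraph:
    """Emit the knowledge graph for a structure file and its annotations.

    One annotation per model is required.  Feature and quality individuals
    are model-scoped; molecules, residues and atoms are shared by models.
    """
    schema = schema or load_schema()
    if len(anns) != len(f.models):
        raise KBBuildError(f"{len(f.models)} models but {len(anns)} annotations")
    g = KBGraph()
    pid = f.pdb_id.upper()
    file_uri = mint_uri(EntityDescriptor(kind="file", pdb_id=pid))
    g.add_type(file_uri, "MolecularStructureFile")
    g.set_label(file_uri, f"Molecular Structure File PDB:{pid.lower()}")

    # model-independent matter from the first model's skeleton
    skeleton_model = f.models[0]
    residue_uri: dict[tuple[str, int, str], str] = {}
    residue_part: dict[tuple[str, int, str], dict[str, str]] = {}
    molecule_uris = []
    for chain_id, chain in skeleton_model.chains.items():
        mol = mint_uri(EntityDescriptor(kind="molecule", pdb_id=pid, chain=chain_id))
        g.add_type(mol, "Molecule")
        molecule_uris.append(mol)
        prev_uri = None
        for res in chain:
            cls = classify_residue(res)
            uri = mint_uri(EntityDescriptor(kind="residue", pdb_id=pid, chain=chain_id,
                                            seq_num=res.seq_num, icode=res.icode))
            residue_uri[res.key] = uri
            g.add_type(uri, RESIDUE_CLASS_ID[cls])
            g.add(mol, "hasProperPart", uri)
            if prev_uri is not None:
                g.add(prev_uri, "isImmediatelyBefore", uri)
            prev_uri = uri
            if cls == "non_nucleic":
                continue
            parts = {}
            for kind, class_id in (("nucleoside", "Nucleoside"), ("ribose", "Ribose"),
                                   ("nucleobase", "Nucleobase")):
                puri = mint_uri(EntityDescriptor(kind=kind, pdb_id=pid, chain=chain_id,
                                                 seq_num=res.seq_num, icode=res.icode))
                g.add_type(puri, class_id)
                g.add(uri, "hasProperPart", puri)
                parts[kind] = puri
            residue_part[res.key] = parts
            for a in res.atoms:
                auri = mint_uri(EntityDescriptor(kind="atom", pdb_id=pid, chain=chain_id,
                                                 seq_num=res.seq_num, icode=res.icode,
                                                 atom_name=a.name))
                g.add_type(auri, "Atom")
                g.add(uri, "hasProperPart", auri)

    for model, ann in zip(f.models, anns):
        _emit_model(g, pid, model.model_num, ann, file_uri, molecule_uris,
                    residue_uri, residue_part, emit_orientation, about_atoms)
    return g


def _emit_model(g, pid, model_num, ann, file_uri, molecule_uris, residue_uri,
                residue_part, emit_orientation, about_atoms):
    model_uri = mint_uri(EntityDescriptor(kind="structure_model", pdb_id=pid, model_num=model_num))
    g.add_type(model_uri, "StructureModel")
    g.add(model_uri, "isRepresentedBy", file_uri)
    for mol in molecule_uris:
        g.add(model_uri, "isAbout", mol)
    if about_atoms:
        for (s, p, o) in list(g.triples):
            if p == "hasProperPart" and "Atom" in g.types.get(o, ()):
                g.add(model_uri, "isAbout", o)

    def resolve_res(key):
        uri = residue_uri.get(tuple(key))
        if uri is None:
            raise KBBuildError(f"annotation references residue {key} absent from the model")
        return uri

    for pair in ann.pairs:
        ri, rj = pair.res_i, pair.res_j
        pair_uri = mint_uri(EntityDescriptor(
            kind="base_pair", pdb_id=pid, model_num=model_num,
            chain=ri[0], seq_num=ri[1], icode=ri[2],
            partner_chain=rj[0], partner_seq=rj[1], partner_icode=rj[2]))
        g.add_type(pair_uri, "NucleotideBasePair")
        g.add(model_uri, "isAbout", pair_uri)
        g.add(pair_uri, "hasProperPart", resolve_res(ri))
        g.add(pair_uri, "hasProperPart", resolve_res(rj))
        for inter in pair.interactions:
            u_i = _participant(g, pid, model_num, ri, inter.subedge_i, resolve_res(ri))
            u_j = _participant(g, pid, model_num, rj, inter.subedge_j, resolve_res(rj))
            g.add(pair_uri, "hasPart", u_i)
            g.add(pair_uri, "hasPart", u_j)
            g.add(u_i, "externallyConnectedTo", u_j)
        if emit_orientation:
            q = mint_uri(EntityDescriptor(
                kind="quality", pdb_id=pid, model_num=model_num, chain=ri[0],
                seq_num=ri[1], icode=ri[2],
                quality_token=f"c{rj[0]}_r{_res_token(rj[1], rj[2])}_{pair.orientation}"))
            g.add_type(q, "CisOrientation" if pair.orientation == "cis" else "TransOrientation")
            g.add(pair_uri, "hasQuality", q)

    for stack in ann.stacks:
        ri, rj = stack.res_i, stack.res_j
        stack_uri = mint_uri(EntityDescriptor(
            kind="base_stack", pdb_id=pid, model_num=model_num,
            chain=ri[0], seq_num=ri[1], icode=ri[2],
            partner_chain=rj[0], partner_seq=rj[1], partner_icode=rj[2]))
        g.add_type(stack_uri, "NucleotideBaseStack")
        g.add(model_uri, "isAbout", stack_uri)
        g.add(stack_uri, "hasProperPart", resolve_res(ri))
        g.add(stack_uri, "hasProperPart", resolve_res(rj))
        adj_cls = ("AdjacentStackQuality" if stack.adjacency == "adjacent"
                   else "NonAdjacentStackQuality")
        ori_cls = stack.normal_orientation.capitalize()
        for token, cls in (("adj", adj_cls), ("ori", ori_cls)):
            q = NAMESPACE + _san(stack_uri[len(NAMESPACE):] + "_" + token)
            g.add_type(q, cls)
            g.add(stack_uri, "hasQuality", q)

    for key, glyco in ann.glycosidics.items():
        if tuple(key) not in residue_part:
            continue
        q = mint_uri(EntityDescriptor(kind="quality", pdb_id=pid, model_num=model_num,
                                      chain=key[0], seq_num=key[1], icode=key[2],
                                      quality_token=glyco.conformation))
        g.add_type(q, "SynConformation" if glyco.conformation == "syn" else "AntiConformation")
        g.add(q, "qualityOf", residue_part[tuple(key)]["nucleoside"])

    for key, pucker in ann.puckers.items():
        if tuple(key) not in residue_part or pucker.mode == "planar":
            continue
        q = mint_uri(EntityDescriptor(kind="quality", pdb_id=pid, model_num=model_num,
                                      chain=key[0], seq_num=key[1], icode=key[2],
                                      quality_token=pucker.mode))
        g.add_type(q, "EnvelopeConformation" if pucker.mode == "envelope" else "TwistConformation")
        g.add(q, "qualityOf", residue_part[tuple(key)]["ribose"])
        for apex, side in zip(pucker.apex_atoms, pucker.apex_sides):
            atom_uri = mint_uri(EntityDescriptor(kind="atom", pdb_id=pid, chain=key[0],
                                                 seq_num=key[1], icode=key[2], atom_name=apex))
            qa = mint_uri(EntityDescriptor(kind="quality", pdb_id=pid, model_num=model_num,
                                           chain=key[0], seq_num=key[1], icode=key[2],
                                           quality_token=f"a{apex}_{side}"))
            g.add_type(qa, "Endo" if side == "endo" else "Exo")
            g.add(qa, "qualityOf", atom_uri)


def _participant(g: KBGraph, pid: str, model_num: int, res_key, face: SubEdgeKind,
                 res_uri: str) -> str:
    uri = mint_uri(EntityDescriptor(kind="subedge", pdb_id=pid, model_num=model_num,
                                    chain=res_key[0], seq_num=res_key[1], icode=res_key[2],
                                    face=face.value))
    g.add_type(uri, SUBEDGE_CLASS[face])
    g.add(uri, "partOf", res_uri)
    return uri


def build_planned_graph(pdb_id: str, n_models: int, residues: dict,
                        pair_plan=(), stack_plan=()) -> KBGraph:
    """Emit a graph directly from a synthetic plan (no coordinates).

    ``residues`` maps (chain_id, seq_num) -> base letter.  Pair-plan
    entries carry explicit face names per interaction; the same emission
    rules as :func:`build_graph` apply.
    """
    g = KBGraph()
    pid = pdb_id.upper()
    file_uri = mint_uri(EntityDescriptor(kind="file", pdb_id=pid))
    g.add_type(file_uri, "MolecularStructureFile")
    g.set_label(file_uri, f"Molecular Structure File PDB:{pid.lower()}")

    residue_uri = {}
    chains: dict[str, list[int]] = {}
    for (chain, seq) in sorted(residues):
        chains.setdefault(chain, []).append(seq)
    molecule_uris = []
    for chain, seqs in chains.items():
        mol = mint_uri(EntityDescriptor(kind="molecule", pdb_id=pid, chain=chain))
        g.add_type(mol, "Molecule")
        molecule_uris.append(mol)
        prev = None
        for seq in seqs:
            uri = mint_uri(EntityDescriptor(kind="residue", pdb_id=pid, chain=chain, seq_num=seq))
            residue_uri[(chain, seq)] = uri
            g.add_type(uri, RESIDUE_CLASS_ID[residues[(chain, seq)]])
            g.add(mol, "hasProperPart", uri)
            if prev is not None:
                g.add(prev, "isImmediatelyBefore", uri)
            prev = uri

    for m in range(1, n_models + 1):
        model_uri = mint_uri(EntityDescriptor(kind="structure_model", pdb_id=pid, model_num=m))
        g.add_type(model_uri, "StructureModel")
        g.add(model_uri, "isRepresentedBy", file_uri)
        for mol in molecule_uris:
            g.add(model_uri, "isAbout", mol)

    for (m, ri, rj, interactions) in pair_plan:
        ri, rj = tuple(ri), tuple(rj)
        if rj < ri:  # canonical order; faces stay with their residues
            ri, rj = rj, ri
            interactions = [(fj, fi) for (fi, fj) in interactions]
        model_uri = mint_uri(EntityDescriptor(kind="structure_model", pdb_id=pid, model_num=m))
        pair_uri = mint_uri(EntityDescriptor(
            kind="base_pair", pdb_id=pid, model_num=m, chain=ri[0], seq_num=ri[1],
            partner_chain=rj[0], partner_seq=rj[1]))
        g.add_type(pair_uri, "NucleotideBasePair")
        g.add(model_uri, "isAbout", pair_uri)
        g.add(pair_uri, "hasProperPart", residue_uri[ri])
        g.add(pair_uri, "hasProperPart", residue_uri[rj])
        for (face_i, face_j) in interactions:
            u_i = _participant(g, pid, m, (ri[0], ri[1], ""), SubEdgeKind(face_i), residue_uri[ri])
            u_j = _participant(g, pid, m, (rj[0], rj[1], ""), SubEdgeKind(face_j), residue_uri[rj])
            g.add(pair_uri, "hasPart", u_i)
            g.add(pair_uri, "hasPart", u_j)
            g.add(u_i, "externallyConnectedTo", u_j)

    for (m, ri, rj, adjacency, orientation) in stack_plan:
        ri, rj = sorted([tuple(ri), tuple(rj)])
        model_uri = mint_uri(EntityDescriptor(kind="structure_model", pdb_id=pid, model_num=m))
        stack_uri = mint_uri(EntityDescriptor(
            kind="base_stack", pdb_id=pid, model_num=m, chain=ri[0], seq_num=ri[1],
            partner_chain=rj[0], partner_seq=rj[1]))
        g.add_type(stack_uri, "NucleotideBaseStack")
        g.add(model_uri, "isAbout", stack_uri)
        g.add(stack_uri, "hasProperPart", residue_uri[ri])
        g.add(stack_uri, "hasProperPart", residue_uri[rj])
        adj_cls = "AdjacentStackQuality" if adjacency == "adjacent" else "NonAdjacentStackQuality"
        ori_cls = orientation.capitalize()
        for token, cls in (("adj", adj_cls), ("ori", ori_cls)):
            q = NAMESPACE + _san(stack_uri[len(NAMESPACE):] + "_" + token)
            g.add_type(q, cls)
            g.add(stack_uri, "hasQuality", q)
    return g


# ---------------------------------------------------------------------------
# serialization (rdflib-backed)
# ---------------------------------------------------------------------------

def serialize_graph(g: KBGraph, format: str = "turtle") -> str:
    """Serialize to Turtle or N-Triples (deterministic, sorted output)."""
    import rdflib
    from rdflib import RDF, RDFS, Literal, URIRef

    if format not in ("turtle", "ntriples"):
        raise ValueError(f"unknown format {format!r}; use 'turtle' or 'ntriples'")
    rg = rdflib.Graph()
    rg.bind("kb", NAMESPACE)
    rg.bind("v", VOCAB)
    for (s, p, o) in sorted(g.triples):
        rg.add((URIRef(s), URIRef(VOCAB + p), URIRef(o)))
    for uri, classes in sorted(g.types.items()):
        for c in sorted(classes):
            rg.add((URIRef(uri), RDF.type, URIRef(VOCAB + c)))
    for uri, label in sorted(g.labels.items()):
        rg.add((URIRef(uri), RDFS.label, Literal(label)))
    fmt = "turtle" if format == "turtle" else "nt"
    text = rg.serialize(format=fmt)
    if format == "ntriples":
        # rdflib's nt output is unsorted; sort lines for determinism
        lines = sorted(line for line in text.splitlines() if line.strip())
        text = "\n".join(lines) + ("\n" if lines else "")
    return text


def parse_graph(text: str, format: str = "turtle") -> KBGraph:
    """Parse a Turtle/N-Triples document back into a :class:`KBGraph`."""
    import rdflib
    from rdflib import RDF, RDFS

    if format not in ("turtle", "ntriples"):
        raise ValueError(f"unknown format {format!r}; use 'turtle' or 'ntriples'")
    rg = rdflib.Graph()
    rg.parse(data=text, format="turtle" if format == "turtle" else "nt")
    g = KBGraph()
    for (s, p, o) in rg:
        s, p, o = str(s), str(p), str(o)
        if p == str(RDF.type):
            g.add_type(s, o[len(VOCAB):] if o.startswith(VOCAB) else o)
        elif p == str(RDFS.label):
            g.set_label(s, o)
        else:
            pid = p[len(VOCAB):] if p.startswith(VOCAB) else p
            g.add(s, pid, o)
    return g
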