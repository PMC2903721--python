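"""Schema catalog: classes, properties, labels and axioms.

The catalog is a static bundled data file (YAML) loaded at import of the
knowledge-base machinery.  It provides the class hierarchy (including the
agglomerating sub-edge unions), the object-property axioms (inverses,
symmetry, transitivity, sub-properties) and the existential axioms that
let queries over edges reach individuals asserted at sub-edge level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from .annotator import SubEdgeKind

__all__ = [
    "ClassDef",
    "PropertyDef",
    "SchemaCatalog",
    "SchemaError",
    "UnresolvedLabelError",
    "load_schema",
    "SUBEDGE_CLASS",
]


class SchemaError(ValueError):
    """Catalog inconsistency (duplicate label, unknown id, parent cycle)."""


class UnresolvedLabelError(KeyError):
    """A label used in a query or lookup does not resolve to any entity."""

    def __init__(self, label: str, near_misses: list[str]):
        self.label = label
        self.near_misses = near_misses
        hint = f"; similar labels: {near_misses}" if near_misses else ""
        super().__init__(f"unresolved label {label!r}{hint}")


@dataclass(frozen=True)
class ClassDef:
    id: str
    label: str
    parents: frozenset[str]
    equivalent_union: frozenset[str] | None = None
    xref: str | None = None


@dataclass(frozen=True)
class PropertyDef:
    id: str
    label: str
    inverse: str | None = None
    transitive: bool = False
    symmetric: bool = False
    parents: frozenset[str] = field(default_factory=frozenset)


#: Face enumeration -> schema class id.
SUBEDGE_CLASS: dict[SubEdgeKind, str] = {
    SubEdgeKind.Ww: "WatsonWatsonSubEdge",
    SubEdgeKind.Wh: "WatsonHoogsteenSubEdge",
    SubEdgeKind.Ws: "WatsonSugarSubEdge",
    SubEdgeKind.Bw: "BifurcatedWatsonSubEdge",
    SubEdgeKind.Hh: "HoogsteenHoogsteenSubEdge",
    SubEdgeKind.Hw: "HoogsteenWatsonSubEdge",
    SubEdgeKind.Bh: "BifurcatedHoogsteenSubEdge",
    SubEdgeKind.C8: "C8SubEdge",
    SubEdgeKind.Ss: "SugarSugarSubEdge",
    SubEdgeKind.Sw: "SugarWatsonSubEdge",
    SubEdgeKind.Bs: "BifurcatedSugarSubEdge",
    SubEdgeKind.O2p: "O2PrimeSubEdge",
}

#: residue_class -> species class id used when typing residue individuals.
RESIDUE_CLASS_ID = {
    "A": "AMPResidue",
    "C": "CMPResidue",
    "G": "GMPResidue",
    "U": "UMPResidue",
    "modified": "ModifiedNucleotideResidue",
    "non_nucleic": "ChemicalEntity",
}


class SchemaCatalog:
    """Immutable catalog with label resolution and subsumption closure."""

    def __init__(self, classes: dict[str, ClassDef], properties: dict[str, PropertyDef],
                 existential_axioms: list[tuple[str, str, str]]):
        self.classes = classes
        self.properties = properties
        self.existential_axioms = existential_axioms
        self._label_to_id: dict[str, str] = {}
        for cid, c in classes.items():
            if c.label in self._label_to_id:
                raise SchemaError(f"duplicate label {c.label!r}")
            self._label_to_id[c.label] = cid
        for pid, p in properties.items():
            if p.label in self._label_to_id:
                raise SchemaError(f"duplicate label {p.label!r}")
            self._label_to_id[p.label] = pid
        # bare-token synonyms: property labels with underscores for spaces
        # (queries may write e.g. externally_connected_to unquoted)
        for pid, p in properties.items():
            alt = p.label.replace(" ", "_")
            self._label_to_id.setdefault(alt, pid)
        self._validate()
        # membership in agglomerating unions: member class id -> union ids
        self._member_of_union: dict[str, set[str]] = {}
        for cid, c in classes.items():
            if c.equivalent_union:
                for m in c.equivalent_union:
                    self._member_of_union.setdefault(m, set()).add(cid)
        self._super_cache: dict[str, frozenset[str]] = {}

    def _validate(self) -> None:
        for cid, c in self.classes.items():
            for p in c.parents:
                if p not in self.classes:
                    raise SchemaError(f"class {cid}: unknown parent {p}")
            if c.equivalent_union:
                for m in c.equivalent_union:
                    if m not in self.classes:
                        raise SchemaError(f"class {cid}: unknown union member {m}")
        for pid, p in self.properties.items():
            if p.inverse is not None:
                inv = self.properties.get(p.inverse)
                if inv is None:
                    raise SchemaError(f"property {pid}: unknown inverse {p.inverse}")
                if inv.inverse != pid:
                    raise SchemaError(f"inverse of {pid} is not involutive")
            for q in p.parents:
                if q not in self.properties:
                    raise SchemaError(f"property {pid}: unknown parent {q}")
        for (sub, prop, filler) in self.existential_axioms:
            if sub not in self.classes or filler not in self.classes:
                raise SchemaError(f"existential axiom references unknown class: {sub}/{filler}")
            if prop not in self.properties:
                raise SchemaError(f"existential axiom references unknown property: {prop}")
        # cycle check over parents
        seen_done: dict[str, int] = {}

        def visit(cid: str, stack: set[str]) -> None:
            if cid in stack:
                raise SchemaError(f"cycle in class parents at {cid}")
            if seen_done.get(cid):
                return
            stack.add(cid)
            for p in self.classes[cid].parents:
                visit(p, stack)
            stack.discard(cid)
            seen_done[cid] = 1

        for cid in self.classes:
            visit(cid, set())

    # -- lookups ----------------------------------------------------------

    def superclasses_of(self, cid: str) -> frozenset[str]:
        """Reflexive-transitive parent closure, plus agglomerate classes
        reachable through equivalent-union membership."""
        if cid not in self.classes:
            raise SchemaError(f"unknown class id {cid!r}")
        cached = self._super_cache.get(cid)
        if cached is not None:
            return cached
        result: set[str] = set()
        frontier = [cid]
        while frontier:
            c = frontier.pop()
            if c in result:
                continue
            result.add(c)
            frontier.extend(self.classes[c].parents)
            frontier.extend(self._member_of_union.get(c, ()))
        out = frozenset(result)
        self._super_cache[cid] = out
        return out

    def subclasses_of(self, cid: str) -> frozenset[str]:
        return frozenset(c for c in self.classes if cid in self.superclasses_of(c))

    def property_ancestors(self, pid: str) -> frozenset[str]:
        """Reflexive-transitive sub-property closure."""
        result: set[str] = set()
        frontier = [pid]
        while frontier:
            p = frontier.pop()
            if p in result:
                continue
            result.add(p)
            frontier.extend(self.properties[p].parents)
        return frozenset(result)

    def resolve_label(self, label: str, graph=None) -> str:
        """Exact, case-sensitive label lookup over the catalog and,
        optionally, a knowledge graph's individuals."""
        if label in self._label_to_id:
            return self._label_to_id[label]
        if graph is not None and label in graph.label_index:
            return graph.label_index[label]
        candidates = list(self._label_to_id)
        if graph is not None:
            candidates.extend(graph.label_index)
        low = label.lower()
        near = [c for c in candidates
                if low in c.lower() or c.lower() in low or _close(low, c.lower())][:5]
        raise UnresolvedLabelError(label, near)

    def label_of(self, entity_id: str) -> str:
        if entity_id in self.classes:
            return self.classes[entity_id].label
        if entity_id in self.properties:
            return self.properties[entity_id].label
        raise SchemaError(f"unknown entity id {entity_id!r}")


def _close(a: str, b: str) -> bool:
    if abs(len(a) - len(b)) > 2:
        return False
    return sum(1 for x, y in zip(a, b) if x != y) <= 2


@lru_cache(maxsize=1)
def load_schema() -> SchemaCatalog:
    """Load the bundled catalog (cached)."""
    with resources.files("rnakb.data").joinpath("schema.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    classes = {
        cid: ClassDef(
            id=cid,
            label=spec["label"],
            parents=frozenset(spec.get("parents") or ()),
            equivalent_union=(frozenset(spec["equivalent_union"])
                              if spec.get("equivalent_union") else None),
            xref=spec.get("xref"),
        )
        for cid, spec in raw["classes"].items()
    }
    properties = {
        pid: PropertyDef(
            id=pid,
            label=spec["label"],
            inverse=spec.get("inverse"),
            transitive=bool(spec.get("transitive", False)),
            symmetric=bool(spec.get("symmetric", False)),
            parents=frozenset(spec.get("parents") or ()),
        )
        for pid, spec in raw["properties"].items()
    }
    axioms = [tuple(ax) for ax in raw["existential_axioms"]]
    return SchemaCatalog(classes, properties, axioms)
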