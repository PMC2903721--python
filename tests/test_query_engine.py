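import random

import pytest

from rnakb import query_engine as qe
from rnakb.kb_builder import KBGraph
from rnakb.query_engine import (
    And,
    Exactly,
    NamedClass,
    Nominal,
    Or,
    QueryParseError,
    Some,
    UnsupportedExpressionError,
    evaluate,
    parse_class_expression,
    run_template_query,
    saturate,
)
from rnakb.synthetic import KBFixtureSpec, make_kb_fixture


# --------------------------------------------------------------------------
# independent brute-force interpreter (the oracle)
# --------------------------------------------------------------------------

def naive_eval(e, g, schema):
    universe = set(g.types)

    def resolve(label):
        return schema.resolve_label(label, g)

    def rel(pid, inverse):
        out = {}
        for (s, p, o) in g.triples:
            if p != pid:
                continue
            a, b = (o, s) if inverse else (s, o)
            out.setdefault(a, set()).add(b)
        return out

    def ev(node):
        if isinstance(node, NamedClass):
            cid = resolve(node.label)
            if cid in schema.classes:
                return {u for u in universe if cid in g.types[u]}
            return {cid}
        if isinstance(node, And):
            sets = [ev(x) for x in node.operands]
            out = sets[0]
            for s in sets[1:]:
                out = {u for u in out if u in s}
            return out
        if isinstance(node, Or):
            out = set()
            for x in node.operands:
                out |= ev(x)
            return out
        if isinstance(node, Nominal):
            return {resolve(lab) for lab in node.labels}
        if isinstance(node, Some):
            pid = resolve(node.prop)
            fillers = ev(node.filler)
            links = rel(pid, node.inverse)
            out = {u for u in universe if links.get(u, set()) & fillers}
            axioms = [] if node.inverse else [a for a in schema.existential_axioms if a[1] == pid]
            if axioms:
                named = _named_ids(node.filler, schema, g)
                if named is None and not isinstance(node.filler, Nominal):
                    raise UnsupportedExpressionError("complex filler with axioms")
                for (sub, _p, ax_filler) in axioms:
                    if named and set(schema.superclasses_of(ax_filler)) & set(named):
                        out |= {u for u in universe if sub in g.types[u]}
            return out
        if isinstance(node, Exactly):
            pid = resolve(node.prop)
            fillers = ev(node.filler)
            links = rel(pid, node.inverse)
            return {u for u in universe
                    if len(links.get(u, set()) & fillers) == node.n}
        raise AssertionError(type(node))

    def _named_ids(node, schema, g):
        if isinstance(node, NamedClass):
            cid = resolve(node.label)
            return [cid] if cid in schema.classes else None
        if isinstance(node, Or):
            ids = []
            for part in node.operands:
                sub = _named_ids(part, schema, g)
                if sub:
                    ids.extend(sub)
            return ids or None
        return None

    return ev(e)


def random_expression(rng, class_labels, prop_labels, indiv_labels, depth):
    if depth == 0 or rng.random() < 0.3:
        if indiv_labels and rng.random() < 0.2:
            return Nominal((rng.choice(indiv_labels),))
        return NamedClass(rng.choice(class_labels))
    kind = rng.choice(["and", "or", "some", "some_inv", "exactly"])
    if kind in ("and", "or"):
        ops = tuple(random_expression(rng, class_labels, prop_labels, indiv_labels, depth - 1)
                    for _ in range(2))
        return And(ops) if kind == "and" else Or(ops)
    prop = rng.choice(prop_labels)
    filler = random_expression(rng, class_labels, prop_labels, indiv_labels, depth - 1)
    if kind == "exactly":
        return Exactly(n=rng.randint(0, 2), prop=prop, filler=filler)
    return Some(prop=prop, filler=filler, inverse=(kind == "some_inv"))


def fixture_graph(seed, schema):
    rng = random.Random(seed)
    faces = [k.value for k in __import__("rnakb.annotator", fromlist=["SubEdgeKind"]).SubEdgeKind]
    n_models = rng.randint(1, 3)
    rpc = rng.randint(3, 5)
    residues = [("A", s) for s in range(1, rpc + 1)]
    plan, seen = [], set()
    for _ in range(rng.randint(0, 4)):
        m = rng.randint(1, n_models)
        ri, rj = rng.sample(residues, 2)
        key = (m, frozenset((ri, rj)))
        if key in seen:
            continue
        seen.add(key)
        plan.append((m, ri, rj, [(rng.choice(faces), rng.choice(faces))]))
    spec = KBFixtureSpec(pdb_id=f"Q{seed}", n_models=n_models, n_chains=1,
                         residues_per_chain=rpc, pair_plan=tuple(plan), seed=seed)
    g, gt = make_kb_fixture(spec)
    return saturate(g, schema), gt, spec


# --------------------------------------------------------------------------
# parser
# --------------------------------------------------------------------------

class TestParser:
    def test_model_file_query_shape(self):
        e = parse_class_expression(
            "'structure model' that 'is represented by' some "
            "{'Molecular Structure File PDB:1am0'}")
        assert isinstance(e, And)
        named, some = e.operands
        assert named == NamedClass("structure model")
        assert isinstance(some, Some) and some.prop == "is represented by"
        assert some.filler == Nominal(("Molecular Structure File PDB:1am0",))

    def test_precedence_and_binds_tighter_than_or(self):
        e = parse_class_expression("'A' or 'B' and 'C'")
        assert e == Or((NamedClass("A"), And((NamedClass("B"), NamedClass("C")))))

    def test_exactly_node(self):
        e = parse_class_expression(
            "'nucleotide base pair' that 'has proper part' exactly 2 'AMP residue'")
        assert isinstance(e, And)
        ex = e.operands[1]
        assert isinstance(ex, Exactly)
        assert (ex.n, ex.prop) == (2, "has proper part")

    def test_inv_restriction(self):
        e = parse_class_expression("inv('is about') some 'structure model'")
        assert isinstance(e, Some) and e.inverse and e.prop == "is about"

    def test_bare_token_property(self):
        e = parse_class_expression("externally_connected_to some 'nucleotide edge'")
        assert isinstance(e, Some) and e.prop == "externally_connected_to"

    @pytest.mark.parametrize("text", [
        "'unbalanced", "('A'", "'A' that", "'A' some", "", "'A' exactly x 'B'",
        "'A' and and 'B'", "{'x'",
    ])
    def test_malformed_expressions_raise(self, text):
        with pytest.raises(QueryParseError):
            parse_class_expression(text)

    def test_that_and_and_are_the_same_connective(self):
        assert parse_class_expression("'A' that 'B'") == parse_class_expression("'A' and 'B'")


# --------------------------------------------------------------------------
# saturation
# --------------------------------------------------------------------------

class TestSaturation:
    def test_member_face_gains_agglomerate_type(self, schema):
        g = KBGraph()
        g.add_type("http://x/i", "HoogsteenWatsonSubEdge")
        sat = saturate(g, schema)
        assert "HoogsteenSubEdge" in sat.types["http://x/i"]
        assert "NucleotideSubEdge" in sat.types["http://x/i"]

    def test_symmetric_closure_of_ect(self, schema):
        g = KBGraph()
        g.add_type("http://x/a", "Atom")
        g.add_type("http://x/b", "Atom")
        g.add("http://x/a", "externallyConnectedTo", "http://x/b")
        sat = saturate(g, schema)
        assert ("http://x/b", "externallyConnectedTo", "http://x/a") in sat.triples

    def test_transitive_and_inverse_closure_of_parthood(self, schema):
        g = KBGraph()
        for u in "abc":
            g.add_type(f"http://x/{u}", "Atom")
        g.add("http://x/a", "partOf", "http://x/b")
        g.add("http://x/b", "partOf", "http://x/c")
        sat = saturate(g, schema)
        assert ("http://x/a", "partOf", "http://x/c") in sat.triples
        assert ("http://x/c", "hasPart", "http://x/a") in sat.triples

    def test_proper_parthood_promotes_but_does_not_become_transitive(self, schema):
        g = KBGraph()
        for u in "abc":
            g.add_type(f"http://x/{u}", "Atom")
        g.add("http://x/c", "hasProperPart", "http://x/b")
        g.add("http://x/b", "hasProperPart", "http://x/a")
        sat = saturate(g, schema)
        assert ("http://x/c", "hasPart", "http://x/b") in sat.triples
        assert ("http://x/c", "hasPart", "http://x/a") in sat.triples  # via transitive hasPart
        assert ("http://x/c", "hasProperPart", "http://x/a") not in sat.triples

    def test_saturation_is_idempotent(self, schema):
        sat, _, _ = fixture_graph(5, schema)
        again = saturate(sat, schema)
        assert again.triples == sat.triples
        assert again.types == sat.types


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

class TestEvaluate:
    def test_model_count_query(self, schema):
        sat, gt, spec = fixture_graph(1, schema)
        r = run_template_query("A", sat, schema, pdb_id=spec.pdb_id)
        assert set(r.individuals) == set(gt.models)

    def test_some_with_empty_filler_is_empty(self, schema):
        sat, _, _ = fixture_graph(2, schema)
        r = evaluate(parse_class_expression("'has quality' some 'endo'"), sat, schema)
        assert r.cardinality == 0

    def test_template_b_empty_on_watson_only_pair(self, schema):
        spec = KBFixtureSpec(pdb_id="WWONLY", n_models=1, residues_per_chain=2,
                             pair_plan=((1, ("A", 1), ("A", 2), [("Ww", "Ww")]),))
        g, gt = make_kb_fixture(spec)
        sat = saturate(g, schema)
        assert run_template_query("B", sat, schema, pdb_id="wwonly").cardinality == 0
        assert gt.pairs_with_hoogsteen == frozenset()

    def test_template_b_finds_hoogsteen_pair(self, schema):
        spec = KBFixtureSpec(pdb_id="HHWW", n_models=1, residues_per_chain=2,
                             pair_plan=((1, ("A", 1), ("A", 2), [("Hh", "Ww")]),))
        g, gt = make_kb_fixture(spec)
        sat = saturate(g, schema)
        r = run_template_query("B", sat, schema, pdb_id="hhww")
        assert set(r.individuals) == set(gt.pairs_with_hoogsteen)
        assert r.cardinality == 1

    def test_template_d_on_planned_interaction(self, schema):
        spec = KBFixtureSpec(pdb_id="DFIX", n_models=1, residues_per_chain=2,
                             pair_plan=((1, ("A", 1), ("A", 2), [("Ww", "Hh")]),))
        g, gt = make_kb_fixture(spec)
        sat = saturate(g, schema)
        r = run_template_query("D", sat, schema, pdb_id="dfix")
        assert set(r.individuals) == set(gt.pairs_ww_ect_hh)
        assert r.cardinality == 1

    def test_templates_a_and_f_agree(self, schema):
        for seed in range(5):
            sat, _, spec = fixture_graph(seed, schema)
            a = run_template_query("A", sat, schema, pdb_id=spec.pdb_id)
            f = run_template_query("F", sat, schema, pdb_id=spec.pdb_id)
            assert a == f

    def test_template_matches_inline_text(self, schema):
        sat, _, spec = fixture_graph(3, schema)
        text = qe.TEMPLATES["B"]
        direct = evaluate(parse_class_expression(text), sat, schema)
        assert run_template_query("B", sat, schema, pdb_id=spec.pdb_id) == direct

    def test_cardinality_counts_proper_parts_only(self, schema):
        sat, gt, _ = fixture_graph(7, schema)
        expr = parse_class_expression(
            "'nucleotide base pair' that 'has proper part' exactly 2 'nucleotide residue'")
        r = evaluate(expr, sat, schema)
        assert set(r.individuals) == set(gt.all_pairs)

    def test_complex_filler_with_axiom_property_raises(self, schema):
        sat, _, _ = fixture_graph(4, schema)
        expr = parse_class_expression(
            "'part of' some ('hoogsteen edge' and 'nucleotide edge')")
        with pytest.raises(UnsupportedExpressionError):
            evaluate(expr, sat, schema)

    def test_unresolved_label_raises(self, schema):
        sat, _, _ = fixture_graph(4, schema)
        from rnakb.schema import UnresolvedLabelError
        with pytest.raises(UnresolvedLabelError):
            evaluate(parse_class_expression("'no such class at all'"), sat, schema)


class TestOracleEquivalence:
    def test_random_expressions_match_brute_force(self, schema):
        """200 random class expressions over random graphs: the evaluator
        agrees set-for-set with a naive recursive interpreter."""
        rng = random.Random(20240)
        class_labels = ["nucleotide base pair", "structure model", "nucleotide residue",
                        "GMP residue [chebi:50324]", "hoogsteen sub-edge", "watson sub-edge",
                        "hoogsteen edge", "nucleotide edge", "watson watson sub edge",
                        "molecule", "material entity"]
        prop_labels = ["has part", "part of", "has proper part", "is about",
                       "is represented by", "externally connected to",
                       "isImmediatelyBefore"]
        checked = mismatches = 0
        graphs = [fixture_graph(seed, schema) for seed in range(8)]
        while checked < 200:
            sat, _, spec = graphs[rng.randrange(len(graphs))]
            indiv = [f"Molecular Structure File PDB:{spec.pdb_id.lower()}"]
            expr = random_expression(rng, class_labels, prop_labels, indiv,
                                     depth=rng.randint(1, 3))
            try:
                mine = set(evaluate(expr, sat, schema).individuals)
                failed = None
            except UnsupportedExpressionError:
                failed = UnsupportedExpressionError
            try:
                ref = naive_eval(expr, sat, schema)
                ref_failed = None
            except UnsupportedExpressionError:
                ref_failed = UnsupportedExpressionError
            if failed or ref_failed:
                assert failed == ref_failed
            else:
                if mine != ref:
                    mismatches += 1
            checked += 1
        assert checked == 200
        assert mismatches == 0

    def test_monotonicity_of_positive_expressions(self, schema):
        """Adding triples never shrinks an axiom-free positive expression."""
        sat, _, spec = fixture_graph(6, schema)
        expr = parse_class_expression(
            "'nucleotide base pair' that 'has proper part' some 'nucleotide residue'")
        before = set(evaluate(expr, sat, schema).individuals)
        bigger = sat.copy()
        extra_pair = "http://rnakb.example.org/kb/EXTRA_bp"
        some_res = next(u for u, t in sat.types.items() if "NucleotideResidue" in t)
        bigger.add_type(extra_pair, "NucleotideBasePair")
        bigger.add(extra_pair, "hasProperPart", some_res)
        bigger = saturate(bigger, schema)
        after = set(evaluate(expr, bigger, schema).individuals)
        assert before <= after
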