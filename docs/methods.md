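# Methods

## Scope and data flow

The package turns RNA coordinate files into a queryable knowledge graph
in four stages: (1) `structure_io` parses PDB text into a
file → models → chains → residues → atoms hierarchy; (2) `annotator`
computes hydrogen bonds, base pairs, base stacks, ribose puckers and
glycosidic conformations per model from heavy-atom geometry; (3)
`kb_builder` mints URIs and emits triples typed against the bundled
`schema` catalog; (4) `query_engine` saturates the graph and evaluates
Manchester-subset class expressions closed-world. `synthetic` generates
all test inputs (duplexes, pucker rings, planned graphs) with exact
ground truth, so the test suite needs no downloads.

## Structure parsing

Only ATOM/HETATM/MODEL/ENDMDL/TER records are interpreted; a file with
no MODEL records yields one model numbered 1. Alternate locations are
resolved at parse time (highest occupancy wins, file order breaks ties).
Residue classification is by chemical content, not record type: a
residue is a standard ribonucleotide iff it has a standard name (A/C/G/U
or the legacy ADE/CYT/GUA/URA), an O2' atom and a complete base ring;
ring content without a standard name is `modified`; anything else is
`non_nucleic`. HETATM nucleotides (ligands such as AMP) therefore
annotate like chain nucleotides. Hydrogens are kept when present but
never required. Author residue numbering (seq number + insertion code)
is authoritative and is what appears in URIs.

## Hydrogen-bond model

Donors and acceptors are heavy atoms from fixed per-base tables (ring
N–H: G N1, U N3; amino: A N6, G N2, C N4; acceptors: ring N and
exocyclic O atoms; O2' in both roles; backbone O4'/O3'/O5'/OP acceptors
are detected but are not pair-forming faces). A bond requires

* donor–acceptor distance within `[hbond_min_da, hbond_max_da]`
  (defaults 2.4–3.5 Å),
* implied-hydrogen deviation ≤ `hbond_max_angle_dev` (default 45°), and
* every antecedent–donor–acceptor angle ≥ 90°.

The implied hydrogen direction depends on the donor's chemistry: for
ring N–H it is the external bisector of the two ring neighbours; for
exocyclic amino groups the two hydrogens sit at ±60° from the C→N
extension within the base plane, and the deviation is taken against the
nearer one; the 2'-hydroxyl is rotatable, so only the distance and
antecedent-angle tests apply. The angular test is what separates true
in-plane pairing contacts from the many 2.9–3.5 Å vertical contacts
between stacked bases (those approach the acceptor perpendicular to the
donor's base plane and fail by a wide margin).

## Faces, edges and pair typing

The face table maps base atoms to Lemieux–Major sub-edges one-to-one.
Only the membership of O2' (its own face), C8 (purines) and the
glycosidic N9/N1 (sugar side), plus the agglomeration of sub-edges into
the three Leontis–Westhof edges, are fixed by the underlying
classification scheme; the remaining atom assignments (e.g. G: N1→Ww,
O6→Wh, N2→Ws, N7→Hh, N3→Ss) are this package's documented approximation
of the face geometry and are editable in `annotator._FACES`. Pyrimidine
C5/C6 are tabulated on the C–H (Hoogsteen-analog) side but never donate
in the hydrogen-bond model. For modified residues the purine or
pyrimidine table is chosen by ring content.

A pair's per-side LW edge is the edge of the face carrying the most
hydrogen bonds on that side (ties fall to the first interaction in the
deterministic face ordering). Orientation is cis when the two
glycosidic-bond vectors leave the axis through the two glycosidic
nitrogens on the same side (triple product with the first base's
normal); it is computed because LW classification requires it, but it is
not emitted as triples unless `emit_orientation` is set.

## Stacks

Candidates need a computable base frame (least-squares ring plane with
handedness fixed by the canonical ring-atom traversal, so file atom
order is irrelevant). Thresholds: centroid distance ≤ 5.5 Å, normal
angle min(θ, 180°−θ) ≤ 35°, |projection of the centroid offset on the
mean normal| ≥ 2.0 Å. The orientation quality derives from the sign
pair (n_i·c_ij, n_j·c_ij): (+,+) upward, (−,−) downward, (+,−) inward,
(−,+) outward. Adjacency means same chain and neighbouring positions in
the chain's residue order.

## Pucker and glycosidic conformation

For each candidate apex the other four ring atoms are fitted by a
least-squares plane; an envelope needs that quad coplanar within
`pucker_tol` (0.10 Å RMS) and the apex more than `pucker_tol` off the
plane. Failing that, twist is sought over the five *adjacent* ring-atom
pairs — non-adjacent exclusions leave a near-collinear triple whose
plane is numerically meaningless — requiring both excluded atoms beyond
tolerance on opposite sides. Among qualifying candidates the largest
apex deviation wins; a ring with no candidate is planar. Endo/exo
compares the sign of the apex displacement with that of C5' against the
same reference plane. χ and the syn/anti rule are as stated in the
README; the dihedral uses the IUPAC sign convention (verified against
biopython in the tests).

## Knowledge-graph modelling

Molecules, residues, sugars, bases and atoms are model-independent
material entities; structure models, pairs, stacks and qualities are
model-scoped (one individual per feature per model). The structure-model
URI pattern is `PDBID_mMODEL`: a per-chain pattern would collide with
the per-chain molecule individuals and cannot distinguish the models
that the per-model qualities refer to. Pair individuals link their two
residues with `has proper part` and their sub-edge participants with
`has part`; participants are typed by their face class, linked `part of`
to their residue, and the two participants of each interaction are
`externally connected to` each other. No individual is ever asserted to
be an instance of an edge class: edge-level queries are answered through
the agglomerating union classes and their existential `part of` axioms
at saturation/evaluation time.

One consequence of this mereology is worth stating: because residues
are shared across models and `has part` is transitive, a pair acquires
as parts *all* sub-edge participants of its residues, from every model
and every pair they engage in — exactly what an OWL reasoner would
entail from the same assertions. The synthetic fixture's combinatorial
ground truth enumerates this full entailment, and the randomized
fixture-vs-engine tests hold set-for-set under it.

## Query evaluation

Saturation materializes sub-property, inverse, symmetric and transitive
closures plus type subsumption (including union-class membership) to a
fixed point; it is idempotent. Existential restrictions add a TBox
shortcut: for an axiom `C ⊑ p some D`, every instance of `C` satisfies
`p some E` whenever `E` is a named class (or union of named classes)
subsuming `D`. A complex filler on an axiom-bearing property raises an
unsupported-expression error rather than returning silently incomplete
answers. Cardinality restrictions count asserted+saturated fillers of
exactly the named property — in practice the non-transitive
`has proper part`, since transitive roles may not carry cardinality.
For the positive existential fragment exercised here this closed-world
materialization returns the same answer sets a description-logic
reasoner certifies; negation, universal and datatype restrictions are
out of scope.

## Synthetic data

`make_duplex` places idealized ribonucleotide templates — planar bases
with standard heavy-atom geometry in a base-fixed frame, C3'-endo
sugars grown from internal coordinates, χ = −158° (anti) — along a
twisted ladder with the canonical A-form rise (2.81 Å) and twist
(32.7°); the complementary strand is the frame flip (x,−y,−z), which
lands Watson–Crick donor/acceptor distances at 2.87–3.02 Å. The helix
axis passes through the base-pair centers (no displacement or
inclination), so the backbone phosphodiester linkage is schematic —
O3'(i)–P(i+1) is not at bonding distance — which is invisible to every
detector because none uses covalent connectivity. What the duplex does
reproduce faithfully: pairing chemistry and counts, stacking geometry,
sugar pucker and glycosidic state, multi-model files, seeded Gaussian
coordinate noise. What it does not: loops, non-canonical pairs from
real tertiary structure, NMR ensemble variability; passing on it shows
detector correctness under controlled geometry, not field performance
on distorted experimental structures. Noise robustness is measured, not
assumed: at σ = 0.1 Å mean feature agreement over 20 seeds stays above
95 %.

`make_pucker_ring` builds four exactly coplanar ring atoms on a circle
of ribose-like radius and displaces a chosen apex toward or away from an
off-plane C5'. `make_kb_fixture` emits a graph directly from a pair/
stack plan through the same builder used for real structures and
computes expected answer sets for all bundled templates combinatorially
(participant-level, including the cross-pair parthood entailment above).

## Problem sizes and determinism

The default test run uses duplexes of 2–12 base pairs, 50 random graph
plans and 200 random class expressions (depth ≤ 3); the acceptance
script mirrors these sizes and finishes in well under a minute. All
randomness is seeded; property-based tests run derandomized. Structural
feature detection is deterministic with lexicographic tie-breaking by
(chain, residue number, insertion code, atom name).

## Known limitations

* The face table is a single-face-per-atom approximation; atoms shared
  between edges (G O6, A N6) are assigned to their Watson-side face, so
  a pure Hoogsteen pair read through those atoms classifies via its N7/
  C8 contacts.
* Pair detection is pairwise only; base triples appear as multiple
  pairs, not as one n-ary object.
* The writer emits single-character chain ids only (PDB columns).
* Queries support the positive existential fragment plus qualified
  exact cardinality; there is no negation and no SPARQL endpoint.
* Benchmarking against experimentally determined NMR entries requires
  the user to supply the PDB files; no network access is attempted.
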