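# rnakb

Structure-based RNA annotation and knowledge-graph question answering.

`rnakb` parses RNA 3D coordinate files (PDB format, including multi-model
NMR entries), computes the classical structural annotations — base pairs
with Leontis–Westhof edge and Lemieux–Major sub-edge (face)
classification, base stacks with sequence-adjacency and base-normal
orientation qualities, ribose pucker (envelope/twist, endo/exo) and
glycosidic syn/anti conformation — and populates an RDF/OWL-style
knowledge graph in which *information content entities* (the PDB file,
its structure models) are `is about` / `is represented by`-related to
*material entities* (molecules, residues, atoms, base pairs, base stacks)
and their *qualities*. Description-logic-style class-expression queries
(a Manchester-syntax subset with `that`/`and`, `or`, `some`,
`exactly n`, `inv(p)` and nominals) are answered over the saturated graph
under closed-world semantics.

It is aimed at structural bioinformaticians who want RNA structural
features as queryable linked data rather than as flat annotation tables.

## The annotations

* **Hydrogen bonds** are detected between heavy atoms from per-base
  donor/acceptor tables: donor–acceptor distance in [2.4, 3.5] Å and the
  implied hydrogen (external bisector for ring N–H, the two ±60°
  in-plane directions for exocyclic amino groups, unconstrained for the
  rotatable 2'-OH) within 45° of the donor→acceptor direction.
* **Base pairs** require at least one hydrogen bond between *face* atoms.
  Faces follow the Lemieux–Major sub-edge scheme extended with the O2'
  and the glycosidic N9/N1 atoms; each face agglomerates into one
  Leontis–Westhof edge (Watson–Crick ← {Ww, Wh, Ws, Bw}, Hoogsteen ←
  {C8, Hh, Hw, Bh}, Sugar ← {Ss, Sw, Bs, O2'}).
* **Base stacks** require base-ring centroid distance ≤ 5.5 Å, normal
  angle (or its supplement) ≤ 35° and vertical separation ≥ 2.0 Å; the
  orientation quality (upward/downward/inward/outward) comes from the
  signs of each normal projected on the centroid offset.
* **Pucker**: envelope when one ring atom lies > 0.1 Å off the
  least-squares plane of the coplanar other four, twist when two
  adjacent ring atoms lie on opposite sides of the plane of the other
  three; an apex is *endo* when displaced toward the C5' side.
* **Glycosidic**: χ = O4'–C1'–N9–C4 (purines) / O4'–C1'–N1–C2
  (pyrimidines); syn iff χ ∈ [−90°, +90°].

Every entity gets a deterministic URI (`1AJU_cA_r34`,
`1AM0_m7_cA_r5_anti`, `..._cA_r36_aO2p`, …); the bundled schema catalog
supplies the class hierarchy, the agglomerating sub-edge union classes
and the existential axioms ("a hoogsteen sub-edge is part of some
hoogsteen edge") that let edge-level queries reach individuals asserted
only at sub-edge level.

## Worked example

```bash
rnakb fixtures duplex --seq GGCGCC --models 2 --out toy.pdb
rnakb build-kb toy.pdb --out toy.ttl
rnakb query toy.ttl --template A --pdb-id toy
```

prints

```
http://rnakb.example.org/kb/TOY_m1
http://rnakb.example.org/kb/TOY_m2
# 2 individual(s)
```

— the two structure-model individuals represented by the file. Counting
the pair individuals:

```bash
rnakb query toy.ttl --expr "'nucleotide base pair'"
```

ends with `# 12 individual(s)`: six Watson–Crick pairs per model, one
individual per model because features are model-scoped while residues
and atoms are shared. The same library calls are available in Python
(`rnakb.synthetic.make_duplex`, `rnakb.annotator.annotate_model`,
`rnakb.kb_builder.build_graph`, `rnakb.query_engine.run_template_query`).

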