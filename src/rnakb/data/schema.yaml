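# Static schema catalog: classes, properties and axioms used for typing,
# saturation and class-expression query answering.  A minimal-import style
# subset of community ontology terms (RNAO / ChEBI / IAO-like) plus local
# classes; external accession ids are kept as annotation cross-references.
#
# classes: id -> {label, parents, equivalent_union?, xref?}
# properties: id -> {label, inverse?, transitive?, symmetric?, parents?}
# existential_axioms: [subclass_id, property_id, filler_class_id]
#   meaning: subclass_id SubClassOf property_id some filler_class_id

classes:
  Entity:            {label: "entity", parents: []}
  MaterialEntity:    {label: "material entity", parents: [Entity]}
  Quality:           {label: "quality", parents: [Entity]}
  InformationContentEntity: {label: "information content entity", parents: [Entity]}

  # information content entities
  MolecularStructureFile: {label: "molecular structure file", parents: [InformationContentEntity]}
  StructureModel:         {label: "structure model", parents: [InformationContentEntity]}

  # material entities
  Molecule:          {label: "molecule", parents: [MaterialEntity]}
  ChemicalEntity:    {label: "chemical entity", parents: [MaterialEntity]}
  Atom:              {label: "atom", parents: [MaterialEntity]}
  NucleotideResidue: {label: "nucleotide residue", parents: [MaterialEntity], xref: "CHEBI:50319"}
  AMPResidue:        {label: "AMP residue", parents: [NucleotideResidue], xref: "CHEBI:50318"}
  CMPResidue:        {label: "CMP residue", parents: [NucleotideResidue], xref: "CHEBI:50320"}
  GMPResidue:        {label: "GMP residue [chebi:50324]", parents: [NucleotideResidue], xref: "CHEBI:50324"}
  UMPResidue:        {label: "UMP residue", parents: [NucleotideResidue], xref: "CHEBI:50327"}
  ModifiedNucleotideResidue: {label: "modified nucleotide residue", parents: [NucleotideResidue]}
  Nucleoside:        {label: "nucleoside", parents: [MaterialEntity], xref: "RKB:000027"}
  Ribose:            {label: "ribose", parents: [MaterialEntity], xref: "CHEBI:27476"}
  Nucleobase:        {label: "nucleobase", parents: [MaterialEntity]}

  NucleotideBasePair:  {label: "nucleotide base pair", parents: [MaterialEntity]}
  NucleotideBaseStack: {label: "nucleotide base stack", parents: [MaterialEntity]}

  # Leontis-Westhof edges
  NucleotideEdge:   {label: "nucleotide edge", parents: [MaterialEntity]}
  HoogsteenEdge:    {label: "hoogsteen edge", parents: [NucleotideEdge]}
  WatsonCrickEdge:  {label: "watson-crick edge", parents: [NucleotideEdge]}
  SugarEdge:        {label: "sugar edge", parents: [NucleotideEdge]}

  # agglomerating sub-edge classes (each equivalent to the union of its
  # member faces; each known to be part of its edge)
  NucleotideSubEdge: {label: "nucleotide sub-edge", parents: [MaterialEntity]}
  HoogsteenSubEdge:
    label: "hoogsteen sub-edge"
    parents: [NucleotideSubEdge]
    xref: "RKB:000092"
    equivalent_union: [C8SubEdge, HoogsteenHoogsteenSubEdge, HoogsteenWatsonSubEdge, BifurcatedHoogsteenSubEdge]
  WatsonSubEdge:
    label: "watson sub-edge"
    parents: [NucleotideSubEdge]
    equivalent_union: [WatsonWatsonSubEdge, WatsonHoogsteenSubEdge, WatsonSugarSubEdge, BifurcatedWatsonSubEdge]
  SugarSubEdge:
    label: "sugar sub-edge"
    parents: [NucleotideSubEdge]
    equivalent_union: [SugarSugarSubEdge, SugarWatsonSubEdge, BifurcatedSugarSubEdge, O2PrimeSubEdge]

  # member sub-edge (face) classes
  C8SubEdge:                  {label: "C8 sub edge", parents: [HoogsteenSubEdge]}
  HoogsteenHoogsteenSubEdge:  {label: "hoogsteen hoogsteen sub edge", parents: [HoogsteenSubEdge]}
  HoogsteenWatsonSubEdge:     {label: "hoogsteen watson sub edge", parents: [HoogsteenSubEdge]}
  BifurcatedHoogsteenSubEdge: {label: "bifurcated hoogsteen sub edge", parents: [HoogsteenSubEdge]}
  WatsonWatsonSubEdge:        {label: "watson watson sub edge", parents: [WatsonSubEdge]}
  WatsonHoogsteenSubEdge:     {label: "watson hoogsteen sub edge", parents: [WatsonSubEdge]}
  WatsonSugarSubEdge:         {label: "watson sugar sub edge", parents: [WatsonSubEdge]}
  BifurcatedWatsonSubEdge:    {label: "bifurcated watson sub edge", parents: [WatsonSubEdge]}
  SugarSugarSubEdge:          {label: "sugar sugar sub edge", parents: [SugarSubEdge]}
  SugarWatsonSubEdge:         {label: "sugar watson sub edge", parents: [SugarSubEdge]}
  BifurcatedSugarSubEdge:     {label: "bifurcated sugar sub edge", parents: [SugarSubEdge]}
  O2PrimeSubEdge:             {label: "O2' sub edge", parents: [SugarSubEdge]}

  # qualities
  Conformation:          {label: "conformation", parents: [Quality], xref: "RNAO:0000123"}
  SynConformation:       {label: "syn conformation", parents: [Conformation]}
  AntiConformation:      {label: "anti conformation", parents: [Conformation]}
  EnvelopeConformation:  {label: "envelope conformation", parents: [Conformation]}
  TwistConformation:     {label: "twist conformation", parents: [Conformation]}
  Endo:                  {label: "endo", parents: [Quality]}
  Exo:                   {label: "exo", parents: [Quality]}
  StackAdjacencyQuality: {label: "base stack sequence adjacency", parents: [Quality]}
  AdjacentStackQuality:  {label: "adjacent stack quality", parents: [StackAdjacencyQuality]}
  NonAdjacentStackQuality: {label: "non-adjacent stack quality", parents: [StackAdjacencyQuality]}
  StackNormalOrientation: {label: "base stack base-normal orientation", parents: [Quality]}
  Upward:   {label: "upward", parents: [StackNormalOrientation]}
  Downward: {label: "downward", parents: [StackNormalOrientation]}
  Inward:   {label: "inward", parents: [StackNormalOrientation]}
  Outward:  {label: "outward", parents: [StackNormalOrientation]}
  CisOrientation:   {label: "cis orientation", parents: [Quality]}
  TransOrientation: {label: "trans orientation", parents: [Quality]}

properties:
  hasPart:    {label: "has part", inverse: partOf, transitive: true}
  partOf:     {label: "part of", inverse: hasPart, transitive: true}
  hasProperPart: {label: "has proper part", inverse: properPartOf, parents: [hasPart]}
  properPartOf:  {label: "proper part of", inverse: hasProperPart, parents: [partOf]}
  externallyConnectedTo: {label: "externally connected to", symmetric: true}
  isAbout:       {label: "is about", inverse: isSubjectOf}
  isSubjectOf:   {label: "is subject of", inverse: isAbout}
  isRepresentedBy: {label: "is represented by", inverse: represents}
  represents:      {label: "represents", inverse: isRepresentedBy}
  hasQuality: {label: "has quality", inverse: qualityOf}
  qualityOf:  {label: "quality of", inverse: hasQuality}
  isImmediatelyBefore: {label: "isImmediatelyBefore", inverse: isImmediatelyAfter}
  isImmediatelyAfter:  {label: "isImmediatelyAfter", inverse: isImmediatelyBefore}

existential_axioms:
  - [HoogsteenSubEdge, partOf, HoogsteenEdge]
  - [WatsonSubEdge, partOf, WatsonCrickEdge]
  - [SugarSubEdge, partOf, SugarEdge]
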