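# Default network schema: the Chem2Bio2RDF semantic network enriched with
# PubChem compound 2D-similarity and protein sequence-similarity links.
# 9 node types, 12 edge types (A1-A12). Every edge type is traversable in
# both directions; the reverse adjacency is the transpose of the forward one.
#
# self_loops_on_similarity: similarity/interaction links between nodes of the
# same type carry a zero diagonal (a compound is not its own neighbor); flip
# to true only if your source data asserts self-similarity.
name: chem2bio2rdf-enriched
self_loops_on_similarity: false
node_types:
  - compound
  - protein
  - side_effect
  - go_annotation
  - chebi_type
  - substructure
  - tissue
  - pathway
  - disease
edge_types:
  - id: A1
    predicate: has ChEBI type
    source: compound
    target: chebi_type
  - id: A2
    predicate: binds to
    source: compound
    target: protein
  - id: A3
    predicate: has part
    source: compound
    target: substructure
  - id: A4
    predicate: induced by
    source: side_effect
    target: compound
  - id: A5
    predicate: treated by
    source: disease
    target: compound
  - id: A6
    predicate: interacts with
    source: protein
    target: protein
    symmetric: true
  - id: A7
    predicate: has GO annotation
    source: protein
    target: go_annotation
  - id: A8
    predicate: caused by
    source: disease
    target: protein
  - id: A9
    predicate: has participants
    source: pathway
    target: protein
  - id: A10
    predicate: expresses
    source: tissue
    target: protein
  - id: A11
    predicate: similar to
    source: compound
    target: compound
    symmetric: true
    is_similarity: true
  - id: A12
    predicate: similar to
    source: protein
    target: protein
    symmetric: true
    is_similarity: true
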