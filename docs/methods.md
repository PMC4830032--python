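# Methods

## Network model

The network is typed: a schema declares node types and edge types, each edge
type connecting one source to one target node type. Every relation is
treated as reversible; the reverse adjacency is the transpose of the forward
one, so a single sparse 0/1 matrix per edge type suffices. Same-type
relations (protein–protein interaction A6, compound similarity A11, protein
similarity A12) are stored symmetric with a **zero diagonal**: the sources
do not assert self-similarity, and a self-loop on A11 would let every
compound "reach" its own targets through the similar-then-binds meta-path,
trivializing it. The flag `self_loops_on_similarity` in the schema config
re-enables self-loops for data sources that do assert them. Duplicate input
edges collapse to a single link (adjacency entries are 0/1, not
multiplicities), and self-loops on symmetric types are dropped with a
warning.

`remove_links` is copy-on-write: it returns a modified network and leaves
the original untouched, so one base network can serve several
leakage-controlled experiments side by side.

## Meta-paths and features

A meta-path is identified by its oriented step sequence, not by its id
string; ids (C1–C51) are labels. Catalog entries are validated by type
chaining, and each entry's human-readable arrow label is regenerated from
the schema and compared against the label declared in the config, so the
packaged catalog cannot silently drift from the schema.

The 51-entry default catalog is generated by a small grammar rather than
hard-coded: an optional compound-side neighborhood detour (shared ChEBI
type, substructure, side effect, treated disease, or shared protein target),
an optional compound-similarity hop, the central binds step (or the
treats → caused-by disease bridge), an optional protein-side hop
(interaction or similarity), and an optional protein-side neighborhood
detour (shared GO annotation, pathway, tissue, or caused disease), truncated
to lengths 2–4. Length-1 (the bare binds link) is excluded — it is the
prediction target, not a feature. Users can register alternative presets;
the packaged preset is frozen by a set-equality test against the catalog
config. The catalog's provenance note records one known discrepancy in the
source material the catalog transcribes: its worked example applies the id
C15 to the shape listed as C6; the tabulated row ordering is followed here.

**Walk semantics.** Commuting matrices are ordered sparse integer matrix
products, and matrix products count *walks*, which may revisit nodes and
links (e.g. compound → p → same compound → p contributes to the shared-target
path count when the compound–p link is present). The explicit enumeration
oracle (`brute_force_walk_count` / `brute_force_commuting`) implements
exactly these semantics by frontier expansion, and tests assert entry-wise
equality on random networks; its cost grows with the number of walks, so it
is restricted to ≤ 40 nodes per type and density ≤ 0.3. Accumulation is
64-bit integer — real networks reach path counts of ~10⁷, far beyond 32-bit
float precision but comfortably exact in int64.

**Measures.** PC is the raw count; RW divides each row by its sum with the
0/0 → 0 convention (an isolated compound has no walk mass to distribute).
NPC (count over row-plus-column mass) and SRW (row normalization plus the
reverse path's) are implemented but off by default; the standard feature
sets use PC and RW only. Feature columns are ordered catalog-first
(C1_PC, C1_RW, C2_PC, …), and each commuting matrix is computed once per
catalog entry regardless of how many pairs are featurized.

## Labeling, splits, leakage control

Bioassay-derived labels use two thresholds with units of μM: activity above
10 μM is a negative; an "active" call with activity below 1 μM is a
positive. Records firing neither rule are dropped, as are pairs with
conflicting evidence across records (conservative; the count is logged).
Non-positive activity values are rejected as data errors.

Train/test splits are stratified per label with a 2:1 default ratio and
floor rounding of the training share: 5,387 positives and 26,682 negatives
split into exactly 3,591/17,788 train and 1,796/8,894 test. The split
permutation is driven entirely by the stated seed. The evolving-network
split is deterministic: pairs tagged `in_network` train, `post_network`
test.

Leakage control removes **all** positively labeled binds links globally
before feature computation (not per fold), matching the evaluation protocol
the feature design assumes; a per-pair leave-one-out variant can be built
from `remove_links` but is not the default. A negatively labeled pair found
present in the binds adjacency is a hard error — negatives are by definition
unobserved links, so this indicates corrupted inputs.

## Classifiers and metrics

The random forest uses 500 trees; `mtry` (features tried per split) is
chosen from a small grid around √p by minimal out-of-bag error, the forest's
internal generalization estimate. RF features are used raw (tree splits are
scale-invariant). The RBF SVM z-scores features with training statistics and
grid-searches cost C ∈ 2⁻²…2⁶ and kernel width λ ∈ 2⁻⁸…2² (log grids;
sources typically print only the optima) by mean F1 over stratified 10-fold
CV; probabilities come from a sigmoid (Platt-style) calibration of decision
values. The F1 threshold on predicted probability is 0.5; both the
threshold and the SVM probability method are config-exposed choices.

AUCs default to trapezoidal integration (deterministic and
dependency-free); a natural cubic-spline mode is available and every report
names the mode used. BEDROC follows the RIE closed form with Ra = n/N and
1-based ranks after a descending sort; **ties are broken by a seeded
shuffle**, documented because path-count features leave many scores tied at
zero. The value is clipped to [0, 1] to absorb floating-point wobble at the
extremes. Tests cross-check BEDROC against an independently coded direct
sum, its rank monotonicity, and its small-α convergence to the pairwise
(Mann–Whitney) AUC; the ROC area is checked against the brute-force
pairwise statistic with ties counting one half.

Permutation importance: MDA permutes one feature across all pairs and
measures the accuracy drop. For a forest evaluated on its own training
pairs the drop is measured **per tree on out-of-bag pairs** and averaged —
on memorized training data the in-sample drop is near zero for every
feature and the ranking is noise; the OOB variant restores the standard
randomForest semantics. One repeat usually suffices because the estimate is
already an average over 500 trees. MDG is read from the forest's impurity
bookkeeping (normalized mean decrease in impurity); an SVM has none. The
stability experiment refits many forests on randomly drawn 100+100
training pairs with disjoint 50+50 test draws and reports per-feature
importance means/SDs and the F1 range.

## Synthetic networks

The generator emulates the structure of the real network, not its content:
latent groups over compounds and proteins; binds links with probability
`p_in` within a group and `p_out` across (the planted signal); similarity
and interaction edges landing in-group with probability `coherence`;
annotation nodes with group-correlated attachment. Defaults — 200
compounds, 100 proteins, 8 groups, p_in = 0.30, p_out = 0.005,
compound similarity degree 8 at coherence 0.98, protein similarity and
interaction degree 2, annotation attachment 0.08 in-group vs 0.02 out —
were chosen so that the signal is carried primarily by the compound
similarity neighboring links: binding alone is sparse (≈ 3 in-group targets
per compound), while a compound's ~8 coherent similar neighbors jointly
cover its group's targets. This makes similarity-mediated meta-paths the
informative ones and the full catalog strictly more useful than the
similarity-free subset, mirroring the network-enrichment claim under test.

A `holdout_fraction` of true links becomes labeled positives and is removed
from the emitted network before it leaves the generator. Negatives are
never-linked pairs built by crossing the compound of one random positive
with the protein of another. This endpoint-matched sampling is deliberate:
restricting negatives to cross-group pairs would make latent group
membership itself predictive (similarity and annotation links reveal it),
and uniform pair sampling would make raw node degree predictive — under
either shortcut even a null network (p_in = p_out) classifies above chance.
With endpoint matching the negative class has the same marginal endpoint
distribution (including removed-link history) as the positives, and only
the joint link structure distinguishes the classes; measured null AUCROC is
chance level within its sampling noise.

All randomness flows from one seed through a fixed `SeedSequence` spawn
order (groups, binds, similarity, annotations, holdout, negatives), so any
stage can be regenerated independently and identical configs give
byte-identical edge lists.

**What the generator does not emulate:** real chemistry (no fingerprints or
Tanimoto similarity), protein families, the heavy-tailed degree
distributions and edge counts of curated databases, or assay noise
structure beyond uniform label flips. Passing tests therefore demonstrate
that the machinery recovers a planted topological signal under controlled
conditions — not that the learned models transfer to any particular real
network.

## Problem sizes used in checks

The walk-count oracle equivalence runs on 100 random networks of 6–14
nodes per type at densities 0.08–0.25 (all entries, all 51 meta-paths);
signal-recovery checks use the default 200×100 generator and 500-tree
forests; the null check averages three seeds at p_in = p_out = 0.1; the
metric oracles use 1,000 random instances of up to 40 scores. These sizes
are the package's standard verification configuration.

## Known limitations

* The enumeration grammar reproduces the packaged 51-path catalog exactly,
  but whether the original catalog was generated by these constraints or
  curated by hand is not documented; only set-equality is guaranteed.
* OOB-based MDA requires the importance call to receive the same pairs the
  forest was trained on; with foreign pairs, pass `use_oob=False`.
* The evolving-network protocol is implemented as a deterministic era split;
  assembling genuinely time-stamped label sets is the caller's
  responsibility.
* Features for the ~billions of unobserved pairs of a real network are
  never materialized; extraction is lazy over requested pair lists.
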