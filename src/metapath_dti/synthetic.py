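"""Seeded synthetic heterogeneous networks with a planted drug-target signal.

The generator emits a network over the full default schema (9 node types, 12
edge types) whose binds links follow a latent block model: compounds and
proteins carry hidden group assignments, a compound binds an in-group protein
with probability ``p_in`` and an out-group protein with ``p_out``.
Similarity neighboring links (compound-compound, protein-protein) and
protein-protein interactions are drawn edge-by-edge, each landing within a
group with probability ``coherence``; peripheral annotation nodes (ChEBI
types, substructures, side effects, diseases, GO annotations, pathways,
tissues) are themselves assigned groups and attached preferentially in-group.
With coherent similarity and block-structured binding, similarity-mediated
meta-paths (similar-then-binds) and shared-target meta-paths
(binds/binds-back/binds) become informative for exactly the held-out links —
the planted signal every downstream stage is tested against.

A fraction of true binds links is held out as labeled positives and removed
from the emitted network (the leakage-control protocol applied at the
source); an equal number of never-linked pairs, built by crossing positive
endpoints so the class marginals match, serves as negatives.  All randomness flows from one seed through a fixed
``SeedSequence`` spawn order, so identical configs produce byte-identical
edge lists.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import ActivityRecord, LabeledPair
from .hetnet import HetNet, read_edge_list
from .schema import NetworkSchema, default_schema

__all__ = ["SynthConfig", "SynthTruth", "generate_hetnet", "generate_activity_table"]

ANNOTATION_PLAN = (
    # (edge_id, annotation_node_type, prefix, attaches_to, annotation_is_source)
    ("A1", "chebi_type", "chebi", "compound", False),
    ("A3", "substructure", "sub", "compound", False),
    ("A4", "side_effect", "se", "compound", True),
    ("A5", "disease", "dis", "compound", True),
    ("A7", "go_annotation", "go", "protein", False),
    ("A8", "disease", "dis", "protein", True),
    ("A9", "pathway", "pw", "protein", True),
    ("A10", "tissue", "ts", "protein", True),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the package's standard test fixture.

    ``p_in``/``p_out`` control the planted signal strength (set them equal
    for a null network); ``coherence`` is the probability that a similarity
    or interaction edge joins two nodes of the same latent group.
    """

    seed: int
    n_compounds: int = 200
    n_proteins: int = 100
    n_groups: int = 8
    p_in: float = 0.30
    p_out: float = 0.005
    coherence: float = 0.98
    compound_sim_degree: float = 8.0
    protein_sim_degree: float = 2.0
    ppi_degree: float = 2.0
    holdout_fraction: float = 0.3
    annot_p_in: float = 0.08
    annot_p_out: float = 0.02
    n_chebi: int = 30
    n_substructure: int = 40
    n_side_effect: int = 25
    n_disease: int = 20
    n_go: int = 40
    n_pathway: int = 15
    n_tissue: int = 10

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "coherence", "holdout_fraction",
                     "annot_p_in", "annot_p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_compounds", "n_proteins", "n_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SynthTruth:
    """Ground truth accompanying a generated network."""

    compound_groups: dict[str, int]
    protein_groups: dict[str, int]
    positives: list[tuple[str, str]] = field(default_factory=list)
    negatives: list[tuple[str, str]] = field(default_factory=list)

    def labeled_pairs(self) -> list[LabeledPair]:
        return [LabeledPair(c, p, "positive", source="synthetic") for c, p in self.positives] + [
            LabeledPair(c, p, "negative", source="synthetic") for c, p in self.negatives
        ]


def _pair_edges_blockwise(
    rng: np.random.Generator,
    groups: np.ndarray,
    n_edges: int,
    coherence: float,
    prefix: str,
) -> set[tuple[str, str]]:
    """Sample undirected same-type edges, in-group with prob ``coherence``."""
    n = len(groups)
    by_group = [np.flatnonzero(groups == g) for g in range(groups.max() + 1)]
    edges: set[tuple[str, str]] = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        if rng.random() < coherence:
            members = by_group[rng.integers(len(by_group))]
            if len(members) < 2:
                continue
            i, j = rng.choice(members, size=2, replace=False)
        else:
            i, j = rng.choice(n, size=2, replace=False)
        a, b = sorted((int(i), int(j)))
        edges.add((f"{prefix}{a}", f"{prefix}{b}"))
    return edges


def generate_hetnet(
    config: SynthConfig, schema: NetworkSchema | None = None
) -> tuple[HetNet, SynthTruth]:
    """Generate a schema-conforming network plus its ground truth.

    The returned network already excludes the held-out positive links (they
    are the prediction targets); ``SynthTruth`` carries them alongside the
    endpoint-matched negatives and the latent group assignments.
    """
    schema = schema if schema is not None else default_schema()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_groups = np.random.default_rng(streams[0])
    rng_binds = np.random.default_rng(streams[1])
    rng_sim = np.random.default_rng(streams[2])
    rng_annot = np.random.default_rng(streams[3])
    rng_holdout = np.random.default_rng(streams[4])
    rng_neg = np.random.default_rng(streams[5])

    comp_groups = rng_groups.integers(config.n_groups, size=config.n_compounds)
    prot_groups = rng_groups.integers(config.n_groups, size=config.n_proteins)
    compounds = [f"c{i}" for i in range(config.n_compounds)]
    proteins = [f"p{i}" for i in range(config.n_proteins)]

    # binds links from the block model
    same = comp_groups[:, None] == prot_groups[None, :]
    probs = np.where(same, config.p_in, config.p_out)
    binds = rng_binds.random(probs.shape) < probs
    true_links = [(compounds[i], proteins[j]) for i, j in zip(*np.nonzero(binds))]

    # hold out a fraction as labeled positives, removed at the source
    n_hold = int(round(config.holdout_fraction * len(true_links)))
    hold_idx = set(
        rng_holdout.choice(len(true_links), size=n_hold, replace=False).tolist()
    ) if n_hold else set()
    positives = [true_links[k] for k in sorted(hold_idx)]
    emitted_binds = [pair for k, pair in enumerate(true_links) if k not in hold_idx]

    # negatives: never-linked pairs, as many as positives, built by crossing
    # the compound of one random held-out positive with the protein of
    # another (endpoint-matched sampling).  This keeps the negative
    # endpoints' marginal distributions identical to the positives' — the
    # same compounds with the same removed-link history — so neither latent
    # group membership, raw node degree, nor the leakage removal itself can
    # separate the classes; only the joint link structure can.  Cross-group
    # or uniform sampling would each leave such a shortcut open and lift
    # even a null network (p_in == p_out) above chance.
    linked = set(true_links)
    negatives: list[tuple[str, str]] = []
    seen_neg: set[tuple[str, str]] = set()
    guard = 0
    while (
        positives
        and len(negatives) < len(positives)
        and guard < 500 * max(1, len(positives))
    ):
        guard += 1
        c = positives[int(rng_neg.integers(len(positives)))][0]
        p = positives[int(rng_neg.integers(len(positives)))][1]
        pair = (c, p)
        if pair in linked or pair in seen_neg:
            continue
        seen_neg.add(pair)
        negatives.append(pair)

    rows: list[tuple[str, str, str]] = [("A2", c, p) for c, p in emitted_binds]

    # similarity neighboring links and protein interactions
    n_sim_c = int(round(config.compound_sim_degree * config.n_compounds / 2))
    n_sim_p = int(round(config.protein_sim_degree * config.n_proteins / 2))
    n_ppi = int(round(config.ppi_degree * config.n_proteins / 2))
    for a, b in sorted(_pair_edges_blockwise(rng_sim, comp_groups, n_sim_c,
                                             config.coherence, "c")):
        rows.append(("A11", a, b))
    for a, b in sorted(_pair_edges_blockwise(rng_sim, prot_groups, n_sim_p,
                                             config.coherence, "p")):
        rows.append(("A12", a, b))
    for a, b in sorted(_pair_edges_blockwise(rng_sim, prot_groups, n_ppi,
                                             config.coherence, "p")):
        rows.append(("A6", a, b))

    # group-correlated peripheral annotations
    annot_counts = {
        "chebi": config.n_chebi, "sub": config.n_substructure,
        "se": config.n_side_effect, "dis": config.n_disease,
        "go": config.n_go, "pw": config.n_pathway, "ts": config.n_tissue,
    }
    annot_groups = {
        prefix: rng_annot.integers(config.n_groups, size=count)
        for prefix, count in annot_counts.items()
    }
    entity_groups = {"compound": comp_groups, "protein": prot_groups}
    entity_ids = {"compound": compounds, "protein": proteins}
    for edge_id, _node_type, prefix, attaches_to, annot_is_source in ANNOTATION_PLAN:
        e_groups = entity_groups[attaches_to]
        e_ids = entity_ids[attaches_to]
        a_groups = annot_groups[prefix]
        same = a_groups[:, None] == e_groups[None, :]
        p = np.where(same, config.annot_p_in, config.annot_p_out)
        hits = rng_annot.random(p.shape) < p
        for a, e in zip(*np.nonzero(hits)):
            annot_id = f"{prefix}{a}"
            if annot_is_source:
                rows.append((edge_id, annot_id, e_ids[e]))
            else:
                rows.append((edge_id, e_ids[e], annot_id))

    tsv = "".join(f"{e}\t{s}\t{t}\n" for e, s, t in rows)
    preregister = {
        "compound": compounds,
        "protein": proteins,
        "chebi_type": [f"chebi{i}" for i in range(config.n_chebi)],
        "substructure": [f"sub{i}" for i in range(config.n_substructure)],
        "side_effect": [f"se{i}" for i in range(config.n_side_effect)],
        "disease": [f"dis{i}" for i in range(config.n_disease)],
        "go_annotation": [f"go{i}" for i in range(config.n_go)],
        "pathway": [f"pw{i}" for i in range(config.n_pathway)],
        "tissue": [f"ts{i}" for i in range(config.n_tissue)],
    }
    net = read_edge_list(io.StringIO(tsv), schema, preregister=preregister)
    truth = SynthTruth(
        compound_groups={compounds[i]: int(g) for i, g in enumerate(comp_groups)},
        protein_groups={proteins[i]: int(g) for i, g in enumerate(prot_groups)},
        positives=positives,
        negatives=negatives,
    )
    return net, truth


def generate_activity_table(
    truth: SynthTruth, noise_rate: float = 0.0, seed: int = 0
) -> list[ActivityRecord]:
    """Emit bioassay-style activity records consistent with the truth labels.

    Positives become "active" records with sub-μM activity; negatives get
    activities above the 10 μM cutoff.  With probability ``noise_rate`` a
    record is flipped across the thresholds (label noise).
    """
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    records: list[ActivityRecord] = []
    for c, p in truth.positives:
        flip = rng.random() < noise_rate
        if flip:
            records.append(ActivityRecord(c, p, float(rng.uniform(11.0, 100.0)), "inactive"))
        else:
            records.append(ActivityRecord(c, p, float(rng.uniform(0.05, 0.95)), "active"))
    for c, p in truth.negatives:
        flip = rng.random() < noise_rate
        if flip:
            records.append(ActivityRecord(c, p, float(rng.uniform(0.05, 0.95)), "active"))
        else:
            records.append(ActivityRecord(c, p, float(rng.uniform(11.0, 100.0)), "inactive"))
    return records


def config_to_dict(config: SynthConfig) -> dict:
    return asdict(config)


def random_hetnet(
    seed: int,
    n_per_type: dict[str, int] | int = 10,
    density: float = 0.15,
    schema: NetworkSchema | None = None,
) -> HetNet:
    """Unstructured random network: every adjacency entry Bernoulli(density).

    No planted signal and no group structure — used to exercise the
    commuting-matrix machinery against the walk-enumeration oracle on small
    instances (keep node counts <= 40 per type and density <= 0.3).
    """
    schema = schema if schema is not None else default_schema()
    if not 0.0 <= density <= 0.3:
        raise ValueError("density must lie in [0, 0.3] for oracle-scale networks")
    rng = np.random.default_rng(seed)
    counts = (
        {nt: int(n_per_type) for nt in schema.node_types}
        if isinstance(n_per_type, int)
        else dict(n_per_type)
    )
    for nt, n in counts.items():
        if not 1 <= n <= 40:
            raise ValueError(f"{nt}: node count {n} outside [1, 40]")
    prefix = {nt: nt[:2] for nt in schema.node_types}
    ids = {nt: [f"{prefix[nt]}{i}" for i in range(counts[nt])] for nt in schema.node_types}
    rows: list[tuple[str, str, str]] = []
    for spec in schema.edge_specs:
        n_src, n_tgt = counts[spec.source_type], counts[spec.target_type]
        hits = rng.random((n_src, n_tgt)) < density
        for i, j in zip(*np.nonzero(hits)):
            if spec.symmetric and i == j:
                continue
            rows.append((spec.id, ids[spec.source_type][i], ids[spec.target_type][j]))
    tsv = "".join(f"{e}\t{s}\t{t}\n" for e, s, t in rows)
    return read_edge_list(io.StringIO(tsv), schema, preregister=ids)
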