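"""End-to-end run: leakage guard -> features -> split -> train -> evaluate.

``run_pipeline`` composes the stages with one seed, derives per-stage seeds
from it, and writes a manifest (config hash, derived seeds, catalog/schema
fingerprints, feature columns) plus metrics and importance tables into a run
directory, so a rerun with the same config reproduces identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import LabeledPair, leakage_guard, read_labels_tsv, split
from .features import MetaPathFeaturizer
from .hetnet import HetNet, read_edge_list
from .metapaths import Catalog, default_catalog, parse_catalog, similarity_free
from .models import DTIClassifier, evaluate, permutation_importance
from .schema import NetworkSchema, default_schema, load_schema
from .synthetic import SynthConfig, generate_hetnet

__all__ = ["RunConfig", "run_pipeline", "FEATURE_SET_PRESETS", "resolve_feature_set"]

logger = logging.getLogger(__name__)

# Named feature-set presets: I = similarity-free path counts, II = all path
# counts, III = all path counts plus random-walk normalization.
FEATURE_SET_PRESETS = {
    "I": {"similarity_free": True, "measures": ("PC",)},
    "II": {"similarity_free": False, "measures": ("PC",)},
    "III": {"similarity_free": False, "measures": ("PC", "RW")},
}


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    seed: int
    out_dir: str
    network_path: str | None = None     # None -> synthetic
    schema_path: str | None = None      # None -> packaged default
    catalog_path: str | None = None     # None -> packaged default
    labels_path: str | None = None      # None -> synthetic truth labels
    feature_set: str = "III"            # I | II | III
    algorithm: str = "rf"               # rf | svm
    ntree: int = 500
    threshold: float = 0.5
    bedroc_alpha: float = 20.0
    split_ratio: tuple[int, int] = (2, 1)
    importance_repeats: int = 1  # OOB MDA already averages over all trees
    synth: dict = field(default_factory=dict)  # SynthConfig overrides

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def resolve_feature_set(
    name: str, catalog: Catalog, schema: NetworkSchema
) -> tuple[Catalog, tuple[str, ...]]:
    """Map a feature-set preset name to (catalog subset, measures)."""
    try:
        preset = FEATURE_SET_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown feature set {name!r}; choose from {sorted(FEATURE_SET_PRESETS)}"
        ) from None
    cat = similarity_free(catalog, schema) if preset["similarity_free"] else catalog
    return cat, tuple(preset["measures"])


def _derive_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("synth", "split", "train", "eval")
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)
    logger.info("derived stage seeds: %s", seeds)

    stage = "load"
    try:
        schema = load_schema(config.schema_path) if config.schema_path else default_schema()
        catalog = (
            parse_catalog(config.catalog_path, schema)
            if config.catalog_path
            else default_catalog(schema)
        )
        if config.network_path:
            net: HetNet = read_edge_list(config.network_path, schema)
            if not config.labels_path:
                raise ValueError("labels_path is required with an explicit network")
            pairs = read_labels_tsv(config.labels_path)
        else:
            synth_cfg = SynthConfig(seed=seeds["synth"], **config.synth)
            net, truth = generate_hetnet(synth_cfg, schema)
            pairs = (
                read_labels_tsv(config.labels_path)
                if config.labels_path
                else truth.labeled_pairs()
            )

        stage = "guard"
        guarded = leakage_guard(net, pairs)

        stage = "features"
        cat, measures = resolve_feature_set(config.feature_set, catalog, schema)
        featurizer = MetaPathFeaturizer(guarded, cat, measures=measures).fit()
        keys = [p.key for p in pairs]
        X = featurizer.transform(keys)
        y = np.array([1 if p.label == "positive" else 0 for p in pairs])

        stage = "split"
        ds = split(pairs, ratio=config.split_ratio, seed=seeds["split"])
        index = {p.key: i for i, p in enumerate(pairs)}
        tr = np.array([index[p.key] for p in ds.train])
        te = np.array([index[p.key] for p in ds.test])

        stage = "train"
        model = DTIClassifier(
            algorithm=config.algorithm, ntree=config.ntree, random_state=seeds["train"]
        ).fit(X[tr], y[tr])

        stage = "evaluate"
        report_train = evaluate(model, X[tr], y[tr], threshold=config.threshold,
                                alpha=config.bedroc_alpha, seed=seeds["eval"])
        report_test = evaluate(model, X[te], y[te], threshold=config.threshold,
                               alpha=config.bedroc_alpha, seed=seeds["eval"])

        stage = "importance"
        imp = permutation_importance(
            model, X[tr], y[tr], n_repeats=config.importance_repeats,
            seed=seeds["eval"], feature_names=featurizer.feature_names_out_,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    metrics = {
        "train": report_train.to_dict(),
        "test": report_test.to_dict(),
        "best_params": model.best_params_,
        "split_counts": ds.counts(),
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    imp_df = pd.DataFrame({
        "feature": imp.feature_names,
        "mda": imp.mda,
        "mda_sd": imp.mda_sd,
    })
    if imp.mdg is not None:
        imp_df["mdg"] = imp.mdg
    imp_df.sort_values("mda", ascending=False).to_csv(
        out / "importance.tsv", sep="\t", index=False
    )
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "derived_seeds": seeds,
        "schema_name": schema.name,
        "n_metapaths": len(cat),
        "feature_columns": featurizer.feature_names_out_,
        "n_feature_columns": len(featurizer.feature_names_out_),
        "n_pairs": len(pairs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: test AUCROC=%.3f F1=%.3f",
                metrics["test"]["auc_roc"], metrics["test"]["f1"])
    return out
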