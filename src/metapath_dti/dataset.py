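"""Labeled compound-protein pairs: activity labeling, splits, leakage control.

Labeling follows the bioassay-evidence convention: a pair is *negative* when
its measured activity is weaker than 10 μM, and *positive* when the assay
outcome is "active" with activity stronger than 1 μM.  Pairs meeting neither
rule are dropped, as are pairs with conflicting evidence.

Leakage control removes every positively labeled link from the binds
adjacency before topological features are computed, so no feature encodes
direct knowledge of the labels being predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hetnet import HetNet

__all__ = [
    "ActivityRecord",
    "LabeledPair",
    "SplitDataset",
    "label_from_activity",
    "split",
    "leakage_guard",
    "evolving_split",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_activity_tsv",
]

logger = logging.getLogger(__name__)

BINDS_EDGE = "A2"
NEGATIVE_THRESHOLD_UM = 10.0
POSITIVE_THRESHOLD_UM = 1.0


class DataConsistencyError(ValueError):
    """Raised when labels contradict the network (e.g. a 'negative' observed link)."""


@dataclass(frozen=True)
class ActivityRecord:
    """One bioassay observation for a compound-protein pair.

    ``activity_um`` is the reported activity in μM (lower = more potent);
    ``outcome`` is the assay call: active, inactive, or unspecified.
    """

    compound_id: str
    protein_id: str
    activity_um: float | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if self.activity_um is None and self.outcome is None:
            raise ValueError("record needs an activity value or an outcome")
        if self.activity_um is not None and self.activity_um <= 0:
            raise ValueError(
                f"non-positive activity {self.activity_um} μM for "
                f"({self.compound_id}, {self.protein_id})"
            )


@dataclass(frozen=True)
class LabeledPair:
    compound_id: str
    protein_id: str
    label: str  # "positive" | "negative"
    source: str = ""
    era: str | None = None  # "in_network" | "post_network" for evolving splits

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_id, self.protein_id)


@dataclass(frozen=True)
class SplitDataset:
    train: tuple[LabeledPair, ...]
    test: tuple[LabeledPair, ...]
    seed: int | None
    ratio: tuple[int, int]

    def counts(self) -> dict[str, int]:
        out = {}
        for name, part in (("train", self.train), ("test", self.test)):
            for lab in ("positive", "negative"):
                out[f"{name}_{lab}"] = sum(1 for p in part if p.label == lab)
        return out


def label_from_activity(
    records: Iterable[ActivityRecord],
    negative_threshold_um: float = NEGATIVE_THRESHOLD_UM,
    positive_threshold_um: float = POSITIVE_THRESHOLD_UM,
) -> list[LabeledPair]:
    """Derive labeled pairs from activity evidence.

    negative  iff activity > ``negative_threshold_um`` (10 μM default);
    positive  iff outcome == "active" and activity < ``positive_threshold_um``
    (1 μM default).  Records firing neither rule are dropped; pairs collecting
    both labels across records are dropped with a logged conflict count.
    """
    if not (0 < positive_threshold_um <= negative_threshold_um):
        raise ValueError("need 0 < positive_threshold <= negative_threshold")
    labels: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        label = None
        if rec.activity_um is not None and rec.activity_um > negative_threshold_um:
            label = "negative"
        elif (
            rec.outcome == "active"
            and rec.activity_um is not None
            and rec.activity_um < positive_threshold_um
        ):
            label = "positive"
        if label is not None:
            labels.setdefault((rec.compound_id, rec.protein_id), set()).add(label)
    conflicts = sum(1 for v in labels.values() if len(v) > 1)
    if conflicts:
        logger.warning("dropping %d pair(s) with conflicting labels", conflicts)
    return [
        LabeledPair(c, p, next(iter(v)), source="activity")
        for (c, p), v in labels.items()
        if len(v) == 1
    ]


def split(
    pairs: Sequence[LabeledPair],
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
    stratified: bool = True,
) -> SplitDataset:
    """Random train/test split, stratified per label by default.

    Per label, the training share is ``floor(n * ratio_train / ratio_total)``
    and the remainder goes to test; the permutation is seeded and
    reproducible.
    """
    pairs = list(pairs)
    rng = np.random.default_rng(seed)
    groups: dict[str, list[LabeledPair]]
    if stratified:
        groups = {"positive": [], "negative": []}
        for p in pairs:
            groups[p.label].append(p)
        for lab, members in groups.items():
            if not members:
                raise ValueError(f"stratified split with no {lab} pairs")
    else:
        groups = {"all": pairs}
    train: list[LabeledPair] = []
    test: list[LabeledPair] = []
    for members in groups.values():
        perm = rng.permutation(len(members))
        n_train = (len(members) * ratio[0]) // (ratio[0] + ratio[1])
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return SplitDataset(tuple(train), tuple(test), seed=seed, ratio=tuple(ratio))


def leakage_guard(net: HetNet, pairs: Iterable[LabeledPair]) -> HetNet:
    """Remove all positively labeled binds links from the network.

    Returns a copy of ``net`` with A2 zeroed at every positive pair.  A
    negative pair found *present* in A2 contradicts its label (negatives are
    by construction unobserved links) and raises
    :class:`DataConsistencyError`.
    """
    pairs = list(pairs)
    offenders = [
        p.key for p in pairs if p.label == "negative" and net.has_link(BINDS_EDGE, *p.key)
    ]
    if offenders:
        raise DataConsistencyError(
            f"negatively labeled pair(s) present in the binds adjacency: {offenders[:10]}"
        )
    positives = [p.key for p in pairs if p.label == "positive"]
    return net.remove_links(BINDS_EDGE, positives)


def evolving_split(net: HetNet, pairs: Sequence[LabeledPair]) -> SplitDataset:
    """Deterministic era split: train on in-network pairs, test on later ones.

    Every pair must carry an ``era`` tag ("in_network" or "post_network");
    pairs discovered after the network snapshot form the test set.
    """
    untagged = [p.key for p in pairs if p.era not in ("in_network", "post_network")]
    if untagged:
        raise ValueError(f"pairs without a valid era tag: {untagged[:10]}")
    train = tuple(p for p in pairs if p.era == "in_network")
    test = tuple(p for p in pairs if p.era == "post_network")
    if not test:
        logger.warning("evolving split has an empty test set (no post-network pairs)")
    return SplitDataset(train, test, seed=None, ratio=(0, 0))


# -- TSV I/O ----------------------------------------------------------------


def read_labels_tsv(path) -> list[LabeledPair]:
    """Read labels TSV: compound_id, protein_id, label[, era]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = ["compound_id", "protein_id", "label"]
    if not set(cols) <= set(df.columns):
        raise ValueError(f"labels file must have columns {cols}")
    has_era = "era" in df.columns
    return [
        LabeledPair(
            r.compound_id, r.protein_id, r.label,
            era=(r.era if has_era and isinstance(r.era, str) else None),
        )
        for r in df.itertuples()
    ]


def write_labels_tsv(pairs: Iterable[LabeledPair], path) -> None:
    rows = [
        {"compound_id": p.compound_id, "protein_id": p.protein_id,
         "label": p.label, **({"era": p.era} if p.era else {})}
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_activity_tsv(path) -> list[ActivityRecord]:
    """Read activity TSV: compound_id, protein_id, activity_um[, outcome]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for r in df.itertuples():
        value = getattr(r, "activity_um", None)
        records.append(
            ActivityRecord(
                str(r.compound_id), str(r.protein_id),
                activity_um=None if value is None or pd.isna(value) else float(value),
                outcome=getattr(r, "outcome", None),
            )
        )
    return records
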