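"""Commuting matrices and per-pair topological features.

The commuting matrix of a meta-path is the ordered product of the oriented
adjacency matrices along its steps; entry (i, j) counts the walk instances of
that meta-path from compound i to protein j (walks may revisit nodes and
links, matching the matrix-product semantics).  Two per-pair measures are
derived from it:

``PC``
    path count — the raw commuting-matrix entry, a non-negative integer.
``RW``
    random walk — PC normalized by the compound's row sum ``PC_{i,.}``, i.e.
    the probability that a walker leaving compound i along this meta-path ends
    at protein j.  All-zero rows stay zero (0/0 -> 0).

Optional extensions ``NPC`` (path count normalized by row plus column mass)
and ``SRW`` (symmetric random walk, adding the reverse-path row normalization)
are available but disabled by default.

:class:`MetaPathFeaturizer` wraps the extraction as a scikit-learn style
transformer: ``fit`` computes one commuting matrix per catalog entry,
``transform`` maps an array of (compound_id, protein_id) pairs to the feature
matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .hetnet import HetNet
from .metapaths import Catalog, MetaPath, validate_metapath

__all__ = [
    "compute_commuting",
    "brute_force_walk_count",
    "brute_force_commuting",
    "rw_normalize",
    "extract_features",
    "MetaPathFeaturizer",
    "MEASURES",
]

MEASURES = ("PC", "RW", "NPC", "SRW")
DEFAULT_MEASURES = ("PC", "RW")


def compute_commuting(net: HetNet, mp: MetaPath) -> sp.csr_matrix:
    """Ordered sparse product of the oriented adjacencies along ``mp``.

    Rows index the meta-path's start type (compounds for catalog paths),
    columns its end type.  Accumulation is 64-bit integer; entries are exact
    walk counts.
    """
    validate_metapath(mp, net.schema)
    out = None
    for step in mp.steps:
        adj = net.adjacency(step.edge_id, step.orientation).astype(np.int64)
        out = adj if out is None else out @ adj
    return out.tocsr()


def brute_force_walk_count(
    net: HetNet, mp: MetaPath, compound_id: str, protein_id: str
) -> int:
    """Count walk instances by explicit traversal (test oracle; exponential).

    Enumerates every oriented walk step by step — node revisits allowed — and
    counts those ending at ``protein_id``.  Use only on small networks.
    """
    start_reg = net.registries[mp.start_type(net.schema)]
    end_reg = net.registries[mp.end_type(net.schema)]
    counts = _walk_counts_from(_step_neighbor_lists(net, mp), start_reg.index(compound_id))
    return int(counts.get(end_reg.index(protein_id), 0))


def brute_force_commuting(net: HetNet, mp: MetaPath) -> sp.csr_matrix:
    """Full commuting matrix by explicit walk enumeration from every source."""
    n_src = len(net.registries[mp.start_type(net.schema)])
    n_tgt = len(net.registries[mp.end_type(net.schema)])
    neighbor_lists = _step_neighbor_lists(net, mp)
    mat = sp.lil_matrix((n_src, n_tgt), dtype=np.int64)
    for i in range(n_src):
        for j, c in _walk_counts_from(neighbor_lists, i).items():
            mat[i, j] = c
    return mat.tocsr()


def _step_neighbor_lists(net: HetNet, mp: MetaPath) -> list:
    return [
        net.adjacency(step.edge_id, step.orientation).tolil().rows
        for step in mp.steps
    ]


def _walk_counts_from(neighbor_lists, start: int) -> dict[int, int]:
    """Endpoint -> number of walks, by explicit expansion of frontiers."""
    frontier = [start]
    for rows in neighbor_lists:
        frontier = [nbr for node in frontier for nbr in rows[node]]
        if not frontier:
            return {}
    counts: dict[int, int] = {}
    for node in frontier:
        counts[node] = counts.get(node, 0) + 1
    return counts


def rw_normalize(pc: sp.spmatrix) -> sp.csr_matrix:
    """Row-normalize a path-count matrix; all-zero rows stay zero."""
    pc = pc.tocsr().astype(np.float64)
    row_sums = np.asarray(pc.sum(axis=1)).ravel()
    inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    return sp.diags(inv) @ pc


def _npc_normalize(pc: sp.spmatrix) -> sp.csr_matrix:
    pc = pc.tocsr().astype(np.float64)
    rows = np.asarray(pc.sum(axis=1)).ravel()
    cols = np.asarray(pc.sum(axis=0)).ravel()
    coo = pc.tocoo()
    denom = rows[coo.row] + cols[coo.col]
    data = np.divide(coo.data, denom, out=np.zeros_like(coo.data), where=denom > 0)
    return sp.csr_matrix((data, (coo.row, coo.col)), shape=pc.shape)


def extract_features(
    net: HetNet,
    catalog: Catalog,
    pairs,
    measures=DEFAULT_MEASURES,
) -> pd.DataFrame:
    """Feature table for a list of (compound_id, protein_id) pairs.

    One commuting matrix is computed per catalog meta-path (not per pair);
    columns are named ``<metapath id>_<measure>`` in catalog order with the
    requested measure order nested per meta-path.  Any leakage control
    (removal of positively labeled links) must be applied to ``net`` first.
    """
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}; choose from {MEASURES}")
    pairs = list(pairs)
    if not pairs:
        cols = [f"{mp.id}_{m}" for mp in catalog for m in measures]
        return pd.DataFrame(
            columns=cols,
            index=pd.MultiIndex.from_arrays([[], []], names=["compound_id", "protein_id"]),
        )
    comp_reg = net.registries["compound"]
    prot_reg = net.registries["protein"]
    missing = [
        (c, p) for c, p in pairs if c not in comp_reg or p not in prot_reg
    ]
    if missing:
        raise KeyError(f"unregistered pair id(s): {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    rows = np.array([comp_reg.index(c) for c, _ in pairs], dtype=np.intp)
    cols = np.array([prot_reg.index(p) for _, p in pairs], dtype=np.intp)

    data: dict[str, np.ndarray] = {}
    for mp in catalog:
        pc = compute_commuting(net, mp)
        per_measure = {}
        if "PC" in measures:
            per_measure["PC"] = pc
        if "RW" in measures or "SRW" in measures:
            rw = rw_normalize(pc)
            if "RW" in measures:
                per_measure["RW"] = rw
        if "NPC" in measures:
            per_measure["NPC"] = _npc_normalize(pc)
        if "SRW" in measures:
            rw_rev = rw_normalize(pc.T)
            per_measure["SRW"] = rw + rw_rev.T
        for m in measures:
            mat = per_measure[m].tocsr()
            data[f"{mp.id}_{m}"] = np.asarray(mat[rows, cols]).ravel()

    index = pd.MultiIndex.from_tuples(pairs, names=["compound_id", "protein_id"])
    return pd.DataFrame(data, index=index)


class MetaPathFeaturizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer from compound-protein pairs to features.

    Parameters
    ----------
    net : HetNet
        The network the walks are counted on.  Apply leakage control (remove
        positively labeled binds links) before fitting.
    catalog : Catalog
        Meta-paths to featurize, e.g. the packaged 51-entry default.
    measures : tuple of str
        Subset of ``("PC", "RW", "NPC", "SRW")``; the standard feature
        sets use PC only (I/II) or PC+RW (III).

    After ``fit``, ``commuting_`` holds one sparse matrix per meta-path and
    ``feature_names_out_`` the column order.  ``transform`` accepts an
    (n, 2) array-like of string pairs and returns an (n, k) float array.
    """

    def __init__(self, net: HetNet, catalog: Catalog, measures=DEFAULT_MEASURES):
        self.net = net
        self.catalog = catalog
        self.measures = tuple(measures)

    def fit(self, X=None, y=None) -> "MetaPathFeaturizer":
        for m in self.measures:
            if m not in MEASURES:
                raise ValueError(f"unknown measure {m!r}")
        self.commuting_ = {mp.id: compute_commuting(self.net, mp) for mp in self.catalog}
        self.feature_names_out_ = [
            f"{mp.id}_{m}" for mp in self.catalog for m in self.measures
        ]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "commuting_"):
            raise RuntimeError("MetaPathFeaturizer is not fitted")
        pairs = [(str(c), str(p)) for c, p in np.asarray(X, dtype=object)]
        comp_reg = self.net.registries["compound"]
        prot_reg = self.net.registries["protein"]
        rows = np.array([comp_reg.index(c) for c, _ in pairs], dtype=np.intp)
        cols = np.array([prot_reg.index(p) for _, p in pairs], dtype=np.intp)
        blocks = []
        for mp in self.catalog:
            pc = self.commuting_[mp.id]
            mats = {}
            if "PC" in self.measures:
                mats["PC"] = pc
            if "RW" in self.measures or "SRW" in self.measures:
                rw = rw_normalize(pc)
                mats["RW"] = rw
            if "NPC" in self.measures:
                mats["NPC"] = _npc_normalize(pc)
            if "SRW" in self.measures:
                mats["SRW"] = mats["RW"] + rw_normalize(pc.T).T
            for m in self.measures:
                blocks.append(np.asarray(mats[m].tocsr()[rows, cols]).ravel())
        return np.column_stack(blocks) if blocks else np.empty((len(pairs), 0))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)

    def transform_frame(self, pairs) -> pd.DataFrame:
        """Like :meth:`transform` but returns a labeled DataFrame."""
        arr = self.transform(list(pairs))
        index = pd.MultiIndex.from_tuples(
            [(str(c), str(p)) for c, p in pairs], names=["compound_id", "protein_id"]
        )
        return pd.DataFrame(arr, index=index, columns=self.feature_names_out_)
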