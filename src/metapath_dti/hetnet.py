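"""Typed heterogeneous network with one sparse boolean adjacency per edge type.

Nodes of each type are registered in a :class:`NodeRegistry` mapping opaque
external identifiers to dense 0-based matrix positions.  Each edge type A_k is
stored as a sparse 0/1 matrix of shape (|source type|, |target type|); the
reverse relation is the transpose.  Symmetric edge types (protein interaction,
similarity neighboring links) are stored symmetrized with a zero diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
import scipy.io
import scipy.sparse as sp

from .schema import NetworkSchema

__all__ = [
    "NodeRegistry",
    "HetNet",
    "EdgeListError",
    "read_edge_list",
    "write_edge_list",
    "export_matrix",
    "import_matrix",
]

logger = logging.getLogger(__name__)


class EdgeListError(ValueError):
    """Raised on malformed edge-list input."""


class MatrixIOError(ValueError):
    """Raised when an exported matrix and its id-map sidecar disagree."""


@dataclass
class NodeRegistry:
    """Bijection between external node ids of one type and 0..n-1."""

    node_type: str
    ids: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def add(self, node_id: str) -> int:
        """Register ``node_id`` if new; return its dense position."""
        pos = self._index.get(node_id)
        if pos is None:
            pos = len(self.ids)
            self.ids.append(node_id)
            self._index[node_id] = pos
        return pos

    def index(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(
                f"unknown {self.node_type} id {node_id!r}"
            ) from None

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def copy(self) -> "NodeRegistry":
        reg = NodeRegistry(self.node_type)
        reg.ids = list(self.ids)
        reg._index = dict(self._index)
        return reg


class HetNet:
    """A typed network: schema + node registries + per-edge-type adjacencies.

    Adjacency matrices are CSR, dtype int8, entries in {0, 1}.  Use
    :meth:`adjacency` to obtain oriented matrices; mutate only through
    :func:`read_edge_list` / :meth:`remove_links`.
    """

    def __init__(self, schema: NetworkSchema):
        self.schema = schema
        self.registries: dict[str, NodeRegistry] = {
            nt: NodeRegistry(nt) for nt in schema.node_types
        }
        self._adjacency: dict[str, sp.csr_matrix] = {}

    # -- construction ------------------------------------------------------

    def _materialize(self, edges: dict[str, set[tuple[int, int]]]) -> None:
        """Build all adjacency matrices from dense-index edge sets."""
        for spec in self.schema.edge_specs:
            n_src = len(self.registries[spec.source_type])
            n_tgt = len(self.registries[spec.target_type])
            pairs = edges.get(spec.id, set())
            if pairs:
                rows, cols = zip(*pairs)
                mat = sp.csr_matrix(
                    (np.ones(len(pairs), dtype=np.int8), (rows, cols)),
                    shape=(n_src, n_tgt),
                )
            else:
                mat = sp.csr_matrix((n_src, n_tgt), dtype=np.int8)
            mat.data[:] = 1  # collapse duplicates summed by construction
            self._adjacency[spec.id] = mat

    # -- queries -----------------------------------------------------------

    def adjacency(self, edge_id: str, direction: str = "forward") -> sp.csr_matrix:
        """Oriented adjacency of one edge type; reverse is the transpose.

        The returned matrix is shared, not copied; treat it as read-only.
        """
        spec = self.schema.edge_spec(edge_id)
        mat = self._adjacency[spec.id]
        if direction == "forward":
            return mat
        if direction == "reverse":
            return mat.T.tocsr()
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")

    def nnz(self, edge_id: str) -> int:
        """Number of observed links of one edge type (Table-style 'Count')."""
        return int(self._adjacency[self.schema.edge_spec(edge_id).id].nnz)

    def shape(self, edge_id: str) -> tuple[int, int]:
        return self._adjacency[self.schema.edge_spec(edge_id).id].shape

    # -- mutation (copy-on-write) ------------------------------------------

    def remove_links(
        self, edge_id: str, pairs: Iterable[tuple[str, str]]
    ) -> "HetNet":
        """Return a copy of the network with the listed links zeroed out.

        For symmetric edge types the mirrored entry is zeroed too.  Pairs with
        unregistered ids or already-absent links are skipped with a log
        message; the original network is left untouched.
        """
        spec = self.schema.edge_spec(edge_id)
        src_reg = self.registries[spec.source_type]
        tgt_reg = self.registries[spec.target_type]

        new = HetNet(self.schema)
        new.registries = {nt: reg.copy() for nt, reg in self.registries.items()}
        new._adjacency = dict(self._adjacency)

        mat = self._adjacency[spec.id].tolil(copy=True)
        removed = 0
        for src_id, tgt_id in pairs:
            if src_id not in src_reg or tgt_id not in tgt_reg:
                logger.info(
                    "remove_links(%s): pair (%s, %s) not registered; skipped",
                    edge_id, src_id, tgt_id,
                )
                continue
            i, j = src_reg.index(src_id), tgt_reg.index(tgt_id)
            if mat[i, j] != 0:
                mat[i, j] = 0
                removed += 1
            else:
                logger.info(
                    "remove_links(%s): pair (%s, %s) already absent", edge_id, src_id, tgt_id
                )
            if spec.symmetric and mat[j, i] != 0:
                mat[j, i] = 0
        new._adjacency[spec.id] = mat.tocsr()
        new._adjacency[spec.id].eliminate_zeros()
        logger.info("remove_links(%s): removed %d link(s)", edge_id, removed)
        return new

    def has_link(self, edge_id: str, src_id: str, tgt_id: str) -> bool:
        spec = self.schema.edge_spec(edge_id)
        src_reg = self.registries[spec.source_type]
        tgt_reg = self.registries[spec.target_type]
        if src_id not in src_reg or tgt_id not in tgt_reg:
            return False
        return bool(
            self._adjacency[spec.id][src_reg.index(src_id), tgt_reg.index(tgt_id)]
        )


# -- edge-list I/O ---------------------------------------------------------


def _iter_rows(stream: TextIO) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def read_edge_list(
    source,
    schema: NetworkSchema,
    preregister: dict[str, Sequence[str]] | None = None,
) -> HetNet:
    """Build a :class:`HetNet` from TSV rows ``(edge_type_id, source, target)``.

    Duplicate rows collapse to a single link; symmetric edge types are
    symmetrized; self-loops on symmetric types are dropped with a warning.
    ``preregister`` may supply per-node-type id lists to fix matrix dimensions
    beyond the ids observed in the stream (e.g. isolated nodes).
    """
    net = HetNet(schema)
    if preregister:
        for node_type, ids in preregister.items():
            reg = net.registries[node_type]
            for node_id in ids:
                reg.add(node_id)

    edges: dict[str, set[tuple[int, int]]] = {}

    def consume(stream: TextIO) -> None:
        for lineno, fields in _iter_rows(stream):
            if len(fields) != 3:
                raise EdgeListError(
                    f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            edge_id, src_id, tgt_id = fields
            if edge_id not in schema:
                raise EdgeListError(
                    f"line {lineno}: unknown edge type id {edge_id!r}"
                )
            spec = schema.edge_spec(edge_id)
            if spec.symmetric and src_id == tgt_id and not schema.self_loops_on_similarity:
                logger.warning(
                    "line %d: self-loop (%s, %s) on symmetric edge type %s dropped",
                    lineno, src_id, tgt_id, edge_id,
                )
                continue
            i = net.registries[spec.source_type].add(src_id)
            j = net.registries[spec.target_type].add(tgt_id)
            bucket = edges.setdefault(edge_id, set())
            bucket.add((i, j))
            if spec.symmetric:
                bucket.add((j, i))

    if hasattr(source, "read"):
        consume(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            consume(fh)
    net._materialize(edges)
    return net


def write_edge_list(net: HetNet, path) -> None:
    """Write a network back to 3-column TSV (symmetric links once, i < j)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# edge_type_id\tsource_id\ttarget_id\n")
        for spec in net.schema.edge_specs:
            mat = net.adjacency(spec.id).tocoo()
            src_ids = net.registries[spec.source_type].ids
            tgt_ids = net.registries[spec.target_type].ids
            for i, j in zip(mat.row, mat.col):
                if spec.symmetric and i > j:
                    continue
                fh.write(f"{spec.id}\t{src_ids[i]}\t{tgt_ids[j]}\n")


# -- Matrix Market round-trip ----------------------------------------------


def export_matrix(net: HetNet, edge_id: str, path) -> None:
    """Export one adjacency to Matrix Market plus an id-map sidecar.

    The sidecar ``<path>.ids.tsv`` lists row ids then column ids so the matrix
    can be re-attached to external identifiers on import.
    """
    path = Path(path)
    spec = net.schema.edge_spec(edge_id)
    scipy.io.mmwrite(str(path), net.adjacency(edge_id).tocoo())
    with open(path.with_suffix(path.suffix + ".ids.tsv"), "w", encoding="utf-8") as fh:
        fh.write(f"#edge_type\t{spec.id}\n")
        for node_id in net.registries[spec.source_type].ids:
            fh.write(f"row\t{node_id}\n")
        for node_id in net.registries[spec.target_type].ids:
            fh.write(f"col\t{node_id}\n")


def import_matrix(path) -> tuple[str, sp.csr_matrix, list[str], list[str]]:
    """Read back an exported adjacency; returns (edge_id, matrix, row_ids, col_ids)."""
    path = Path(path)
    mat = sp.csr_matrix(scipy.io.mmread(str(path)))
    sidecar = path.with_suffix(path.suffix + ".ids.tsv")
    if not sidecar.exists():
        raise MatrixIOError(f"missing id-map sidecar {sidecar}")
    edge_id = None
    row_ids: list[str] = []
    col_ids: list[str] = []
    with open(sidecar, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, value = line.partition("\t")
            if key == "#edge_type":
                edge_id = value
            elif key == "row":
                row_ids.append(value)
            elif key == "col":
                col_ids.append(value)
            else:
                raise MatrixIOError(f"malformed sidecar line {line!r}")
    if edge_id is None:
        raise MatrixIOError("sidecar does not declare an edge type")
    if mat.shape != (len(row_ids), len(col_ids)):
        raise MatrixIOError(
            f"matrix shape {mat.shape} does not match sidecar "
            f"({len(row_ids)} rows, {len(col_ids)} cols)"
        )
    return edge_id, mat, row_ids, col_ids
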