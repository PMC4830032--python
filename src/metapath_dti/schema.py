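"""Network schema: typed node and edge declarations.

A heterogeneous (semantic) network is described by a schema listing its node
types and its edge types.  Each edge type connects one source node type to one
target node type and is traversable in both directions: the adjacency matrix
of the reverse relation is the transpose of the forward one.  The packaged
default schema describes an enriched chemical-biological network with 9 node
types (compounds, proteins, side effects, GO annotations, ChEBI types,
substructures, tissues, pathways, diseases) and 12 edge types A1-A12, where
A11/A12 are structure/sequence similarity "neighboring" links.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

import yaml

__all__ = [
    "EdgeTypeSpec",
    "NetworkSchema",
    "SchemaError",
    "load_schema",
    "default_schema",
]

DEFAULT_SCHEMA_RESOURCE = "schema_chem2bio2rdf.yaml"


class SchemaError(ValueError):
    """Raised when a schema config is internally inconsistent."""


@dataclass(frozen=True)
class EdgeTypeSpec:
    """One typed relation (e.g. A2 'binds to': compound -> protein).

    ``symmetric`` marks same-type relations stored symmetrically with a zero
    diagonal (protein-protein interaction, similarity links); ``is_similarity``
    marks the similarity neighboring links (A11, A12) so that feature sets can
    exclude them.
    """

    id: str
    predicate: str
    source_type: str
    target_type: str
    symmetric: bool = False
    is_similarity: bool = False

    def __post_init__(self) -> None:
        if self.symmetric and self.source_type != self.target_type:
            raise SchemaError(
                f"edge type {self.id!r} marked symmetric but connects "
                f"{self.source_type!r} to {self.target_type!r}"
            )


@dataclass(frozen=True)
class NetworkSchema:
    """An ordered collection of node types and edge type specs."""

    name: str
    node_types: tuple[str, ...]
    edge_specs: tuple[EdgeTypeSpec, ...]
    self_loops_on_similarity: bool = False
    _by_id: dict[str, EdgeTypeSpec] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        declared = set(self.node_types)
        if len(declared) != len(self.node_types):
            raise SchemaError("duplicate node type names")
        by_id: dict[str, EdgeTypeSpec] = {}
        for spec in self.edge_specs:
            if spec.id in by_id:
                raise SchemaError(f"duplicate edge type id {spec.id!r}")
            for role, nt in (("source", spec.source_type), ("target", spec.target_type)):
                if nt not in declared:
                    raise SchemaError(
                        f"edge type {spec.id!r} references undeclared "
                        f"{role} node type {nt!r}"
                    )
            by_id[spec.id] = spec
        object.__setattr__(self, "_by_id", by_id)

    def edge_spec(self, edge_id: str) -> EdgeTypeSpec:
        try:
            return self._by_id[edge_id]
        except KeyError:
            raise KeyError(f"unknown edge type id {edge_id!r}") from None

    @property
    def edge_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.edge_specs)

    def __contains__(self, edge_id: str) -> bool:
        return edge_id in self._by_id


def _parse_schema_dict(cfg: dict) -> NetworkSchema:
    try:
        node_types = tuple(str(nt) for nt in cfg["node_types"])
    except KeyError:
        raise SchemaError("schema config missing 'node_types'") from None
    raw_edges: Iterable[dict] = cfg.get("edge_types", [])
    specs = []
    for entry in raw_edges:
        try:
            specs.append(
                EdgeTypeSpec(
                    id=str(entry["id"]),
                    predicate=str(entry.get("predicate", entry["id"])),
                    source_type=str(entry["source"]),
                    target_type=str(entry["target"]),
                    symmetric=bool(entry.get("symmetric", False)),
                    is_similarity=bool(entry.get("is_similarity", False)),
                )
            )
        except KeyError as exc:
            raise SchemaError(
                f"edge type entry {entry!r} missing required key {exc}"
            ) from None
    return NetworkSchema(
        name=str(cfg.get("name", "unnamed")),
        node_types=node_types,
        edge_specs=tuple(specs),
        self_loops_on_similarity=bool(cfg.get("self_loops_on_similarity", False)),
    )


def load_schema(source) -> NetworkSchema:
    """Load a :class:`NetworkSchema` from a YAML path, stream, or dict."""
    if isinstance(source, dict):
        return _parse_schema_dict(source)
    if hasattr(source, "read"):
        return _parse_schema_dict(yaml.safe_load(source.read()))
    with open(source, "r", encoding="utf-8") as fh:
        return _parse_schema_dict(yaml.safe_load(fh))


def default_schema() -> NetworkSchema:
    """The packaged 9-node-type / 12-edge-type (A1-A12) schema."""
    ref = importlib.resources.files("metapath_dti.data") / DEFAULT_SCHEMA_RESOURCE
    return _parse_schema_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
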