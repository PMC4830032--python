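"""Meta-paths: typed, oriented walks from compounds to proteins.

A meta-path is an ordered sequence of oriented edge-type steps whose node
types chain: the oriented target type of step k equals the oriented source
type of step k+1.  The packaged default catalog holds the 51 compound-to-
protein meta-paths of length 2-4 over the default A1-A12 schema; the same set
is reproducible with the ``slap51`` grammar preset of
:func:`enumerate_metapaths`, which composes an optional compound-neighborhood
detour, an optional compound-similarity hop, the central binds link (or the
treats/caused-by disease bridge), an optional protein-side hop, and an
optional protein-neighborhood detour.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from itertools import product
from typing import Iterable

import yaml

from .schema import NetworkSchema

__all__ = [
    "MetaPathStep",
    "MetaPath",
    "Catalog",
    "CatalogError",
    "MetaPathValidationError",
    "validate_metapath",
    "parse_catalog",
    "default_catalog",
    "enumerate_metapaths",
    "similarity_free",
]

DEFAULT_CATALOG_RESOURCE = "catalog_slap51.yaml"

_REV_SUFFIX = "_rev"


class CatalogError(ValueError):
    """Raised when a catalog config fails validation."""


class MetaPathValidationError(ValueError):
    """Raised when a meta-path's steps do not chain over the schema."""


@dataclass(frozen=True)
class MetaPathStep:
    """One oriented edge-type traversal."""

    edge_id: str
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def source_type(self, schema: NetworkSchema) -> str:
        spec = schema.edge_spec(self.edge_id)
        return spec.source_type if self.orientation == "forward" else spec.target_type

    def target_type(self, schema: NetworkSchema) -> str:
        spec = schema.edge_spec(self.edge_id)
        return spec.target_type if self.orientation == "forward" else spec.source_type

    def reversed(self) -> "MetaPathStep":
        flip = "reverse" if self.orientation == "forward" else "forward"
        return MetaPathStep(self.edge_id, flip)

    @classmethod
    def parse(cls, token: str) -> "MetaPathStep":
        """Parse 'A2' (forward) or 'A2_rev' (reverse)."""
        token = token.strip()
        if token.endswith(_REV_SUFFIX):
            return cls(token[: -len(_REV_SUFFIX)], "reverse")
        return cls(token)

    def token(self) -> str:
        return self.edge_id + (_REV_SUFFIX if self.orientation == "reverse" else "")


@dataclass(frozen=True)
class MetaPath:
    """An identified sequence of steps; identity is the step sequence."""

    id: str
    steps: tuple[MetaPathStep, ...]

    @property
    def length(self) -> int:
        return len(self.steps)

    def start_type(self, schema: NetworkSchema) -> str:
        return self.steps[0].source_type(schema)

    def end_type(self, schema: NetworkSchema) -> str:
        return self.steps[-1].target_type(schema)

    def reversed(self, new_id: str | None = None) -> "MetaPath":
        return MetaPath(
            new_id or f"{self.id}_rev",
            tuple(s.reversed() for s in reversed(self.steps)),
        )

    def uses_similarity(self, schema: NetworkSchema) -> bool:
        return any(schema.edge_spec(s.edge_id).is_similarity for s in self.steps)

    def label(self, schema: NetworkSchema) -> str:
        """Mechanical arrow label, e.g. 'compound -similar to-> compound'."""
        parts = [self.steps[0].source_type(schema)]
        for step in self.steps:
            pred = schema.edge_spec(step.edge_id).predicate
            arrow = f" -{pred}-> " if step.orientation == "forward" else f" <-{pred}- "
            parts.append(arrow)
            parts.append(step.target_type(schema))
        return "".join(parts)

    def step_tokens(self) -> tuple[str, ...]:
        return tuple(s.token() for s in self.steps)


def validate_metapath(mp: MetaPath, schema: NetworkSchema) -> None:
    """Check that adjacent steps chain type-compatibly; raise otherwise."""
    if not mp.steps:
        raise MetaPathValidationError(f"meta-path {mp.id!r} has no steps")
    for step in mp.steps:
        if step.edge_id not in schema:
            raise MetaPathValidationError(
                f"meta-path {mp.id!r}: unknown edge type {step.edge_id!r}"
            )
    for k in range(len(mp.steps) - 1):
        here, there = mp.steps[k], mp.steps[k + 1]
        if here.target_type(schema) != there.source_type(schema):
            raise MetaPathValidationError(
                f"meta-path {mp.id!r}: step {k + 1} ends at "
                f"{here.target_type(schema)!r} but step {k + 2} starts at "
                f"{there.source_type(schema)!r}"
            )


@dataclass(frozen=True)
class Catalog:
    """Ordered collection of meta-paths with unique ids."""

    metapaths: tuple[MetaPath, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [mp.id for mp in self.metapaths]
        if len(set(ids)) != len(ids):
            raise CatalogError("duplicate meta-path ids in catalog")

    def __len__(self) -> int:
        return len(self.metapaths)

    def __iter__(self):
        return iter(self.metapaths)

    def __getitem__(self, mp_id: str) -> MetaPath:
        for mp in self.metapaths:
            if mp.id == mp_id:
                return mp
        raise KeyError(f"no meta-path {mp_id!r} in catalog")

    def length_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for mp in self.metapaths:
            hist[mp.length] = hist.get(mp.length, 0) + 1
        return hist

    def step_sequences(self) -> set[tuple[str, ...]]:
        return {mp.step_tokens() for mp in self.metapaths}


def parse_catalog(source, schema: NetworkSchema) -> Catalog:
    """Load a catalog config (YAML path, stream, or dict) and validate it.

    Every entry is validated against the schema; if an entry declares an
    expected ``label``, it is compared against the label regenerated from the
    schema and a mismatch is a :class:`CatalogError`.
    """
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)

    metapaths = []
    for entry in cfg.get("metapaths", []):
        mp = MetaPath(
            id=str(entry["id"]),
            steps=tuple(MetaPathStep.parse(tok) for tok in entry["steps"]),
        )
        try:
            validate_metapath(mp, schema)
        except MetaPathValidationError as exc:
            raise CatalogError(str(exc)) from None
        declared = entry.get("label")
        if declared is not None and declared != mp.label(schema):
            raise CatalogError(
                f"meta-path {mp.id!r}: declared label {declared!r} does not "
                f"match regenerated label {mp.label(schema)!r}"
            )
        metapaths.append(mp)
    return Catalog(tuple(metapaths), provenance=str(cfg.get("provenance", "")))


def default_catalog(schema: NetworkSchema | None = None) -> Catalog:
    """The packaged 51-meta-path compound-to-protein catalog (C1-C51)."""
    from .schema import default_schema

    ref = importlib.resources.files("metapath_dti.data") / DEFAULT_CATALOG_RESOURCE
    return parse_catalog(
        yaml.safe_load(ref.read_text(encoding="utf-8")),
        schema if schema is not None else default_schema(),
    )


# -- grammar-preset enumeration --------------------------------------------

# A preset is a list of grammar forms; each form is a list of slots; each slot
# is a list of alternative step-token sequences (the empty tuple is epsilon).
# The enumerator takes the cross product of slots within each form, chains the
# segments, and keeps type-valid compound-to-protein paths of length within
# [2, max_len], deduplicated on the step sequence.

def _slap51_preset() -> list[list[list[tuple[str, ...]]]]:
    compound_detours = [
        (),
        ("A1", "A1_rev"),       # shared ChEBI type
        ("A3", "A3_rev"),       # shared substructure
        ("A4_rev", "A4"),       # shared side effect
        ("A5_rev", "A5"),       # shared treated disease
        ("A2", "A2_rev"),       # shared protein target
    ]
    compound_similarity = [(), ("A11",)]
    protein_hop = [(), ("A6",), ("A12",)]
    protein_detours = [
        (),
        ("A7", "A7_rev"),       # shared GO annotation
        ("A9_rev", "A9"),       # shared pathway
        ("A10_rev", "A10"),     # shared expressing tissue
        ("A8_rev", "A8"),       # shared caused disease
    ]
    binds_form = [compound_detours, compound_similarity, [("A2",)], protein_hop,
                  protein_detours]
    disease_bridge_form = [compound_detours, [("A5_rev", "A8")], protein_detours]
    return [binds_form, disease_bridge_form]


PRESETS = {"slap51": _slap51_preset}


def enumerate_metapaths(
    schema: NetworkSchema,
    preset: str = "slap51",
    max_len: int = 4,
    min_len: int = 2,
) -> set[MetaPath]:
    """Enumerate compound-to-protein meta-paths from a grammar preset.

    Length-1 paths (the bare binds link — the prediction target itself) are
    excluded by the default ``min_len`` of 2.  Results are deduplicated on the
    oriented step sequence and assigned ids ``M1..Mn`` in a deterministic
    (length, steps) order; use :func:`parse_catalog` for the canonically
    numbered packaged catalog.
    """
    try:
        forms = PRESETS[preset]()
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        ) from None
    for form in forms:
        for slot in form:
            for alt in slot:
                for tok in alt:
                    step = MetaPathStep.parse(tok)
                    if step.edge_id not in schema:
                        raise ValueError(
                            f"preset references unknown edge type {step.edge_id!r}"
                        )

    seen: set[tuple[str, ...]] = set()
    for form in forms:
        for combo in product(*form):
            tokens = tuple(tok for segment in combo for tok in segment)
            if not (min_len <= len(tokens) <= max_len):
                continue
            seen.add(tokens)

    ordered = sorted(seen, key=lambda toks: (len(toks), toks))
    out: set[MetaPath] = set()
    for k, tokens in enumerate(ordered, start=1):
        mp = MetaPath(f"M{k}", tuple(MetaPathStep.parse(t) for t in tokens))
        validate_metapath(mp, schema)
        if mp.start_type(schema) != "compound" or mp.end_type(schema) != "protein":
            raise ValueError(f"preset produced non compound-to-protein path {tokens}")
        out.add(mp)
    return out


def similarity_free(catalog: Catalog, schema: NetworkSchema) -> Catalog:
    """Filter out every meta-path that traverses a similarity neighboring link."""
    kept = tuple(mp for mp in catalog if not mp.uses_similarity(schema))
    note = (catalog.provenance + " | " if catalog.provenance else "") + "similarity-free subset"
    return Catalog(kept, provenance=note)
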