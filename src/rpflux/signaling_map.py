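"""Molecular signaling map: pathways, reactions, crosstalk.

The map is the network model into which expression profiles are projected.
Each pathway is a set of reactions; a reaction carries the genes whose
products participate in it and a regulatory role (activator / inhibitor /
neutral) that fixes the sign of its influence on pathway flux.  Directed,
weighted crosstalk edges encode how flux in one pathway discounts the flux
of another.  Reactions tagged ``radiation_responsive`` (with a non-negative
``sensitivity``) are the ones perturbed when a post-irradiation expression
state is simulated.

Serialization is a small bespoke JSON schema::

    {"pathways": [{"id": ..., "name": ..., "rp_relevant": ...,
                   "reactions": [{"id": ..., "genes": [...], "role": ...,
                                  "radiation_responsive": ..., "sensitivity": ...}]}],
     "crosstalk": [{"source": ..., "target": ..., "weight": ...}]}
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import MapValidationError, UnknownPathwayError

__all__ = [
    "Role",
    "Reaction",
    "Pathway",
    "CrosstalkEdge",
    "SignalingMap",
    "load_map",
    "write_map",
    "map_from_dict",
    "map_to_dict",
    "crosstalk_sources",
    "pathway_gene_set",
]


class Role(enum.Enum):
    """Regulatory role of a reaction within its pathway."""

    ACTIVATOR = "activator"
    INHIBITOR = "inhibitor"
    NEUTRAL = "neutral"

    @property
    def sign(self) -> int:
        return {Role.ACTIVATOR: 1, Role.INHIBITOR: -1, Role.NEUTRAL: 0}[self]


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    genes: tuple[str, ...]
    role: Role
    radiation_responsive: bool = False
    sensitivity: float = 0.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise MapValidationError(
                f"reaction {self.reaction_id!r}: gene list is empty"
            )
        if len(set(self.genes)) != len(self.genes):
            raise MapValidationError(
                f"reaction {self.reaction_id!r}: duplicate gene symbols"
            )
        if self.sensitivity < 0:
            raise MapValidationError(
                f"reaction {self.reaction_id!r}: negative sensitivity "
                f"{self.sensitivity}"
            )


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    reactions: tuple[Reaction, ...]
    rp_relevant: bool = False

    def __post_init__(self) -> None:
        if not self.reactions:
            raise MapValidationError(
                f"pathway {self.pathway_id!r}: no reactions"
            )
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise MapValidationError(
                f"pathway {self.pathway_id!r}: duplicate reaction ids"
            )

    @property
    def n_reactions(self) -> int:
        """Reaction count N(P), the flux normalizer."""
        return len(self.reactions)


@dataclass(frozen=True)
class CrosstalkEdge:
    """Directed edge: flux of ``source_pathway`` discounts ``target_pathway``."""

    source_pathway: str
    target_pathway: str
    weight: float

    def __post_init__(self) -> None:
        if self.source_pathway == self.target_pathway:
            raise MapValidationError(
                f"crosstalk self-loop on {self.source_pathway!r}"
            )
        if not 0.0 <= self.weight <= 1.0:
            raise MapValidationError(
                f"crosstalk {self.source_pathway!r}->{self.target_pathway!r}: "
                f"weight {self.weight} outside [0, 1]"
            )


@dataclass(frozen=True)
class SignalingMap:
    pathways: tuple[Pathway, ...]
    crosstalk: tuple[CrosstalkEdge, ...] = ()
    _by_id: dict = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise MapValidationError("duplicate pathway ids")
        known = set(ids)
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.crosstalk:
            for endpoint in (e.source_pathway, e.target_pathway):
                if endpoint not in known:
                    raise MapValidationError(
                        f"crosstalk edge {e.source_pathway!r}->"
                        f"{e.target_pathway!r} references unknown pathway "
                        f"{endpoint!r}"
                    )
            pair = (e.source_pathway, e.target_pathway)
            if pair in seen_pairs:
                raise MapValidationError(
                    f"duplicate crosstalk edge {pair[0]!r}->{pair[1]!r}"
                )
            seen_pairs.add(pair)
        object.__setattr__(self, "_by_id", {p.pathway_id: p for p in self.pathways})

    def pathway(self, pathway_id: str) -> Pathway:
        try:
            return self._by_id[pathway_id]
        except KeyError:
            raise UnknownPathwayError(pathway_id) from None

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    @property
    def gene_universe(self) -> set[str]:
        """Union of gene symbols across every reaction of every pathway."""
        return {g for p in self.pathways for r in p.reactions for g in r.genes}


# ---------------------------------------------------------------------------
# serialization

def map_from_dict(data: dict) -> SignalingMap:
    """Build a validated :class:`SignalingMap` from the JSON-schema dict."""
    if not isinstance(data, dict) or "pathways" not in data:
        raise MapValidationError("top-level object must contain 'pathways'")
    pathways = []
    for p in data["pathways"]:
        reactions = []
        for r in p.get("reactions", []):
            role_raw = r.get("role")
            try:
                role = Role(role_raw)
            except ValueError:
                raise MapValidationError(
                    f"reaction {r.get('id')!r}: unknown role {role_raw!r}"
                ) from None
            reactions.append(
                Reaction(
                    reaction_id=str(r["id"]),
                    genes=tuple(r.get("genes", [])),
                    role=role,
                    radiation_responsive=bool(r.get("radiation_responsive", False)),
                    sensitivity=float(r.get("sensitivity", 0.0)),
                )
            )
        pathways.append(
            Pathway(
                pathway_id=str(p["id"]),
                name=str(p.get("name", p["id"])),
                reactions=tuple(reactions),
                rp_relevant=bool(p.get("rp_relevant", False)),
            )
        )
    edges = tuple(
        CrosstalkEdge(str(e["source"]), str(e["target"]), float(e["weight"]))
        for e in data.get("crosstalk", [])
    )
    return SignalingMap(pathways=tuple(pathways), crosstalk=edges)


def map_to_dict(smap: SignalingMap) -> dict:
    return {
        "pathways": [
            {
                "id": p.pathway_id,
                "name": p.name,
                "rp_relevant": p.rp_relevant,
                "reactions": [
                    {
                        "id": r.reaction_id,
                        "genes": list(r.genes),
                        "role": r.role.value,
                        "radiation_responsive": r.radiation_responsive,
                        "sensitivity": r.sensitivity,
                    }
                    for r in p.reactions
                ],
            }
            for p in smap.pathways
        ],
        "crosstalk": [
            {"source": e.source_pathway, "target": e.target_pathway, "weight": e.weight}
            for e in smap.crosstalk
        ],
    }


def load_map(path: str | Path) -> SignalingMap:
    """Read and validate a signaling map from its JSON file.

    Raises ``OSError`` for a missing file and
    :class:`~rpflux.errors.MapValidationError` for any schema violation,
    naming the offending element.
    """
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MapValidationError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return map_from_dict(data)
    except KeyError as exc:
        raise MapValidationError(f"{path}: missing required key {exc}") from exc


def write_map(smap: SignalingMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(map_to_dict(smap), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# queries

def crosstalk_sources(smap: SignalingMap, pathway_id: str) -> list[tuple[str, float]]:
    """All (source id, weight) pairs feeding crosstalk into ``pathway_id``.

    Sorted by source id so the result is independent of edge order in the
    file.  Empty list when the pathway receives no crosstalk.
    """
    smap.pathway(pathway_id)  # raises UnknownPathwayError
    pairs = [
        (e.source_pathway, e.weight)
        for e in smap.crosstalk
        if e.target_pathway == pathway_id
    ]
    return sorted(pairs)


def pathway_gene_set(smap: SignalingMap, pathway_id: str) -> set[str]:
    """Union of gene symbols over the pathway's reactions."""
    p = smap.pathway(pathway_id)
    return {g for r in p.reactions for g in r.genes}
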