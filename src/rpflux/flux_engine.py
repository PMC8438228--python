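"""Pathway-flux computation from a single expression profile.

The flux of pathway P is

    F(P) = (sum_i I_i(reaction, role)) / N(P)  -  flux(Crosstalk(P))

where N(P) is the pathway's reaction count, the influence of one reaction is

    I(reaction, role) = sign(role) * mean_g log2(abundance_g + 1)

over the reaction's genes, and the crosstalk term is the mean over incoming
crosstalk edges of (edge weight * raw flux of the source pathway).  The
crosstalk term is computed from *raw* fluxes in a single pass — never from
net fluxes — so evaluation is a finite, order-independent computation even
on cyclic crosstalk graphs.

The post-irradiation expression state is a deterministic surrogate: every
gene appearing in at least one radiation-responsive reaction is scaled by
(1 + sensitivity * dose / d0), using the maximum sensitivity over the
reactions that contain the gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import DegenerateInputError, DomainError
from .signaling_map import Pathway, Reaction, SignalingMap, crosstalk_sources

__all__ = [
    "ExpressionProfile",
    "ReactionInfluence",
    "PathwayFluxResult",
    "normalize_expression",
    "reaction_influence",
    "raw_pathway_flux",
    "crosstalk_flux",
    "pathway_flux",
    "all_pathway_fluxes",
    "simulate_irradiation_state",
    "read_expression_tsv",
    "write_expression_tsv",
]

logger = logging.getLogger(__name__)

_MAX_LISTED_MISSING = 20


@dataclass(frozen=True)
class ExpressionProfile:
    """One sample's gene -> abundance mapping (counts or TPM scale)."""

    sample_id: str
    values: dict[str, float]
    normalized: bool = False
    state_label: str = "control"  # "control" (measured) or "treat" (simulated)

    def __post_init__(self) -> None:
        for gene, v in self.values.items():
            if math.isnan(v) or v < 0:
                raise DomainError(
                    f"profile {self.sample_id!r}: gene {gene!r} has invalid "
                    f"abundance {v}"
                )


@dataclass(frozen=True)
class ReactionInfluence:
    reaction_id: str
    value: float  # signed, log2-abundance units


@dataclass(frozen=True)
class PathwayFluxResult:
    pathway_id: str
    raw_flux: float
    crosstalk_component: float
    net_flux: float = field(default=None)

    def __post_init__(self) -> None:
        if self.net_flux is None:
            object.__setattr__(
                self, "net_flux", self.raw_flux - self.crosstalk_component
            )


def normalize_expression(profile: ExpressionProfile, mode: str = "cpm") -> ExpressionProfile:
    """Rescale abundances; ``cpm`` makes them sum to 1e6, ``none`` is identity."""
    if mode == "none":
        return replace(profile, normalized=True)
    if mode != "cpm":
        raise DomainError(f"unknown normalization mode {mode!r}")
    total = sum(profile.values.values())
    if total <= 0:
        raise DegenerateInputError(
            f"profile {profile.sample_id!r}: all-zero profile cannot be "
            "CPM-normalized"
        )
    scale = 1e6 / total
    return replace(
        profile,
        values={g: v * scale for g, v in profile.values.items()},
        normalized=True,
    )


def _log2_abundance(profile: ExpressionProfile, gene: str, missing: set | None) -> float:
    v = profile.values.get(gene)
    if v is None:
        if missing is not None:
            missing.add(gene)
        v = 0.0
    return math.log2(v + 1.0)


def reaction_influence(
    profile: ExpressionProfile,
    reaction: Reaction,
    _missing: set | None = None,
) -> ReactionInfluence:
    """Signed mean log2(abundance+1) over the reaction's genes.

    Genes absent from the profile count with abundance 0; they are recorded
    in ``_missing`` (or logged directly when no collector is supplied).
    """
    local: set = set() if _missing is None else _missing
    mean = sum(_log2_abundance(profile, g, local) for g in reaction.genes) / len(
        reaction.genes
    )
    if _missing is None and local:
        warn_missing_genes(profile.sample_id, local)
    return ReactionInfluence(
        reaction_id=reaction.reaction_id, value=reaction.role.sign * mean
    )


def warn_missing_genes(sample_id: str, missing: set) -> None:
    listed = sorted(missing)[:_MAX_LISTED_MISSING]
    suffix = "" if len(missing) <= _MAX_LISTED_MISSING else (
        f" (+{len(missing) - _MAX_LISTED_MISSING} more)"
    )
    logger.warning(
        "profile %s: %d map gene(s) absent from expression, counted as 0: %s%s",
        sample_id, len(missing), ", ".join(listed), suffix,
    )


def raw_pathway_flux(
    profile: ExpressionProfile,
    pathway: Pathway,
    _missing: set | None = None,
) -> float:
    """(sum of reaction influences) / N(P)."""
    total = sum(
        reaction_influence(profile, r, _missing if _missing is not None else set()).value
        for r in pathway.reactions
    )
    return total / pathway.n_reactions


def crosstalk_flux(
    profile: ExpressionProfile,
    smap: SignalingMap,
    pathway_id: str,
    _missing: set | None = None,
) -> float:
    """Mean over incoming edges of weight * raw flux of the source pathway.

    Single pass over raw fluxes only; 0 when no edge targets the pathway.
    """
    sources = crosstalk_sources(smap, pathway_id)
    if not sources:
        return 0.0
    total = sum(
        w * raw_pathway_flux(profile, smap.pathway(src), _missing)
        for src, w in sources
    )
    return total / len(sources)


def pathway_flux(
    profile: ExpressionProfile,
    smap: SignalingMap,
    pathway_id: str,
    _missing: set | None = None,
) -> PathwayFluxResult:
    """Net pathway flux F(P) = raw - crosstalk, with both components."""
    raw = raw_pathway_flux(profile, smap.pathway(pathway_id), _missing)
    ct = crosstalk_flux(profile, smap, pathway_id, _missing)
    return PathwayFluxResult(pathway_id=pathway_id, raw_flux=raw, crosstalk_component=ct)


def all_pathway_fluxes(
    profile: ExpressionProfile, smap: SignalingMap
) -> dict[str, PathwayFluxResult]:
    """F(P) for every pathway; missing genes logged once per profile."""
    missing: set = set()
    out = {
        p.pathway_id: pathway_flux(profile, smap, p.pathway_id, missing)
        for p in smap.pathways
    }
    if missing:
        warn_missing_genes(profile.sample_id, missing)
    return out


def simulate_irradiation_state(
    profile: ExpressionProfile,
    smap: SignalingMap,
    dose: float,
    d0: float = 50.0,
) -> ExpressionProfile:
    """Deterministic post-irradiation surrogate state.

    Genes of radiation-responsive reactions are scaled by
    (1 + sensitivity * dose / d0); when a gene sits in several responsive
    reactions the maximum sensitivity applies once.  ``d0`` sets the dose
    scale (Gy) at which a sensitivity-1 gene doubles.
    """
    if dose < 0:
        raise DomainError(f"negative dose {dose}")
    if d0 <= 0:
        raise DomainError(f"d0 must be positive, got {d0}")
    sens: dict[str, float] = {}
    for p in smap.pathways:
        for r in p.reactions:
            if r.radiation_responsive:
                for g in r.genes:
                    sens[g] = max(sens.get(g, 0.0), r.sensitivity)
    values = dict(profile.values)
    for g, s in sens.items():
        if g in values:
            values[g] = values[g] * (1.0 + s * dose / d0)
    return replace(profile, values=values, state_label="treat")


# ---------------------------------------------------------------------------
# expression matrix I/O (TSV, first column "gene", one column per sample)

def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples abundance matrix; index 'gene', non-negative reals."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise DomainError(
            f"{path}: first column must be 'gene', got {df.columns[0]!r}"
        )
    df = df.set_index("gene")
    if df.isna().any().any() or (df < 0).any().any():
        raise DomainError(f"{path}: abundances must be non-negative and non-NaN")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def profiles_from_matrix(df: pd.DataFrame) -> list[ExpressionProfile]:
    """Split a genes x samples matrix into per-sample profiles."""
    return [
        ExpressionProfile(sample_id=str(col), values=df[col].to_dict())
        for col in df.columns
    ]
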