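"""Shared fixtures: the two-pathway toy map and a matching profile."""

import numpy as np
import pytest

from rpflux import (
    CrosstalkEdge,
    ExpressionProfile,
    Pathway,
    Reaction,
    Role,
    SignalingMap,
    write_map,
)


def build_toy3() -> SignalingMap:
    """P1 (activator R1 radiation-responsive + inhibitor R2) and P2 (activator R3),
    symmetric crosstalk with weight 0.5."""
    return SignalingMap(
        pathways=(
            Pathway(
                "P1", "toy pathway 1",
                (
                    Reaction("R1", ("G1",), Role.ACTIVATOR,
                             radiation_responsive=True, sensitivity=1.0),
                    Reaction("R2", ("G2", "G3"), Role.INHIBITOR),
                ),
                rp_relevant=True,
            ),
            Pathway(
                "P2", "toy pathway 2",
                (Reaction("R3", ("G4",), Role.ACTIVATOR),),
                rp_relevant=True,
            ),
        ),
        crosstalk=(CrosstalkEdge("P2", "P1", 0.5), CrosstalkEdge("P1", "P2", 0.5)),
    )


@pytest.fixture(scope="session")
def toy3() -> SignalingMap:
    return build_toy3()


@pytest.fixture(scope="session")
def toy3_file(tmp_path_factory, toy3):
    path = tmp_path_factory.mktemp("maps") / "toy3.json"
    write_map(toy3, path)
    return path


@pytest.fixture()
def toy_profile() -> ExpressionProfile:
    """Abundances used throughout the worked flux examples."""
    return ExpressionProfile("s1", {"G1": 7.0, "G2": 3.0, "G3": 1.0, "G4": 15.0})


def random_map(rng: np.random.Generator, max_pathways: int = 5) -> SignalingMap:
    """Arbitrary small valid map: mixed roles, possibly cyclic crosstalk."""
    n_p = int(rng.integers(1, max_pathways + 1))
    pathways = []
    gene_pool = [f"g{i}" for i in range(12)]
    for p in range(n_p):
        n_r = int(rng.integers(1, 4))
        reactions = []
        for r in range(n_r):
            n_g = int(rng.integers(1, 4))
            genes = tuple(rng.choice(gene_pool, size=n_g, replace=False))
            role = Role(list(Role)[int(rng.integers(0, 3))].value)
            responsive = bool(rng.random() < 0.4)
            reactions.append(Reaction(
                f"p{p}r{r}", genes, role,
                radiation_responsive=responsive,
                sensitivity=float(rng.uniform(0, 3)) if responsive else 0.0,
            ))
        pathways.append(Pathway(f"p{p}", f"pathway {p}", tuple(reactions),
                                rp_relevant=bool(rng.random() < 0.5)))
    edges = []
    for s in range(n_p):
        for t in range(n_p):
            if s != t and rng.random() < 0.4:
                edges.append(CrosstalkEdge(f"p{s}", f"p{t}", float(rng.uniform(0, 1))))
    return SignalingMap(tuple(pathways), tuple(edges))


def random_profile(rng: np.random.Generator, smap: SignalingMap,
                   missing_fraction: float = 0.0) -> ExpressionProfile:
    genes = sorted(smap.gene_universe)
    values = {}
    for g in genes:
        if rng.random() >= missing_fraction:
            values[g] = float(rng.lognormal(2.0, 2.0))
    return ExpressionProfile("rnd", values)


def brute_force_net_flux(profile: ExpressionProfile, smap: SignalingMap,
                         pathway_id: str) -> float:
    """Naive independent evaluation of F(P) straight from its definition."""
    import math

    def log2p1(gene):
        return math.log2(profile.values.get(gene, 0.0) + 1.0)

    def raw(pid):
        p = smap.pathway(pid)
        total = 0.0
        for reac in p.reactions:
            m = sum(log2p1(g) for g in reac.genes) / len(reac.genes)
            total += reac.role.sign * m
        return total / len(p.reactions)

    incoming = [(e.source_pathway, e.weight) for e in smap.crosstalk
                if e.target_pathway == pathway_id]
    ct = (sum(w * raw(src) for src, w in incoming) / len(incoming)) if incoming else 0.0
    return raw(pathway_id) - ct
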