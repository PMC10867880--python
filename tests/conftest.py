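"""Shared builders for toy webs used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from webcva.core import FoodWeb, Group, Residency, SpeciesNode


def make_web(
    groups: dict[str, str],
    edges: list[tuple[str, str]],
    residency: dict[str, str] | None = None,
) -> FoodWeb:
    """Build a small web from {id: group} and an edge list."""
    residency = residency or {}
    nodes = [
        SpeciesNode(
            id=i,
            group=Group(g),
            residency=Residency(residency.get(i, "not_applicable")),
        )
        for i, g in groups.items()
    ]
    return FoodWeb(nodes, edges)


def random_layered_web(
    rng: np.random.Generator,
    n_nodes: int = 12,
    n_basal: int = 3,
    max_prey: int = 3,
) -> FoodWeb:
    """A random acyclic group-labeled web where every consumer has prey.

    Basal nodes are plants; consumers are assigned random animal groups and
    eat 1..max_prey uniformly chosen earlier nodes, so the web is always
    valid, fully connected to basal resources, and flux-solvable.
    """
    animal = ["bird", "mammal", "reptile", "invertebrate"]
    groups: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    ids: list[str] = []
    for k in range(n_nodes):
        i = f"n{k:02d}"
        if k < n_basal:
            groups[i] = "plant"
        else:
            groups[i] = animal[int(rng.integers(len(animal)))]
            n_prey = int(rng.integers(1, min(max_prey, k) + 1))
            prey = rng.choice(k, size=n_prey, replace=False)
            edges.extend((i, ids[p]) for p in prey)
        ids.append(i)
    return make_web(groups, edges)


def random_strengths(rng: np.random.Generator, web: FoodWeb) -> pd.DataFrame:
    """Random normalized strength columns (Dirichlet) for every consumer."""
    consumers = [i for i in web.ids if web.resources_of(i)]
    s = pd.DataFrame(0.0, index=web.ids, columns=consumers)
    for j in consumers:
        res = sorted(web.resources_of(j))
        s.loc[res, j] = rng.dirichlet(np.ones(len(res)))
    return s


def random_traits(rng: np.random.Generator, web: FoodWeb) -> pd.DataFrame:
    """Random positive masses/biomasses suitable for the energetics stack."""
    from webcva.energetics import compute_traits

    masses = {
        i: float(10 ** rng.uniform(0, 3))
        for i in web.ids
        if web.nodes[i].group is not Group.plant
    }
    return compute_traits(
        web, masses, plant_biomass_g_per_km2=float(10 ** rng.uniform(6, 8))
    )


@pytest.fixture(scope="session")
def mojave_synth():
    """One mojave-like synthetic web shared across the session."""
    from webcva.synthetic import generate_web, mojave_like_config

    return generate_web(mojave_like_config(seed=42))


@pytest.fixture(scope="session")
def mojave_strengths(mojave_synth):
    from webcva.energetics import (
        diet_preferences,
        interaction_strengths,
        metabolic_demands,
        solve_fluxes,
    )

    w = diet_preferences(mojave_synth.web, mojave_synth.traits)
    flux = solve_fluxes(
        mojave_synth.web, w, metabolic_demands(mojave_synth.web, mojave_synth.traits)
    )
    return interaction_strengths(flux)
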