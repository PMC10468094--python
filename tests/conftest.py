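"""Shared fixtures: hand-built micro-networks and random-network builders."""

from __future__ import annotations

import random

import pytest

from gsmn.netcore import Metabolite, Reaction, Reconstruction
from gsmn.synthetic_data import ToySpec, generate_toy


def make_recon(edges, reversible=(), name="fixture") -> Reconstruction:
    """Reconstruction from (reactants, products) edges over auto-declared
    intracellular metabolites.  ``edges`` maps reaction id -> (dict, dict)."""
    recon = Reconstruction(name=name)
    for rid, (reac, prod) in edges.items():
        for m in list(reac) + list(prod):
            if m not in recon.metabolites:
                compartment = "e" if m.endswith("_e") else "c"
                recon.add_metabolite(Metabolite(m, compartment=compartment))
        lb = -1000.0 if rid in reversible else 0.0
        recon.add_reaction(Reaction(rid, dict(reac), dict(prod), lb, 1000.0,
                                    provenance={"annotation"}))
    return recon


def random_network(rng: random.Random, n_reactions: int,
                   n_metabolites: int | None = None) -> Reconstruction:
    """Random small network for oracle-equivalence property tests."""
    n_metabolites = n_metabolites or max(4, n_reactions)
    mets = [f"m{i}_c" for i in range(n_metabolites)]
    recon = Reconstruction(name="random")
    for m in mets:
        recon.add_metabolite(Metabolite(m))
    for j in range(n_reactions):
        k_in = rng.randint(1, min(3, n_metabolites))
        k_out = rng.randint(1, min(3, n_metabolites))
        reac = {m: 1.0 for m in rng.sample(mets, k_in)}
        prod = {m: 1.0 for m in rng.sample(mets, k_out) if m not in reac}
        if not prod:
            prod = {rng.choice([m for m in mets if m not in reac]): 1.0}
        lb = -1000.0 if rng.random() < 0.3 else 0.0
        recon.add_reaction(Reaction(f"r{j}", reac, prod, lb, 1000.0,
                                    provenance={"annotation"}))
    return recon


@pytest.fixture
def toy():
    recon, truth = generate_toy(ToySpec(rng_seed=11))
    return recon, truth


@pytest.fixture
def defective_toy():
    spec = ToySpec(
        rng_seed=12,
        branch_prob=0.9,
        imbalance_frac=0.6,
        missing_formula_frac=0.4,
        duplicate_frac=0.4,
        leak_count=2,
    )
    recon, truth = generate_toy(spec)
    return recon, truth
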