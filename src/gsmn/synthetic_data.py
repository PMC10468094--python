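"""Toy reconstructions with known ground truth.

The generator emulates the shape of a curated fungal reconstruction at toy
scale: boundary seeds with uptake reactions, transport into the cell,
linear/branched biosynthetic pathways ending in terminal products, and a
biomass pseudo-reaction consuming the terminals - so the flux optimum has a
closed form (the most limiting substrate-rate / stoichiometric-demand
ratio) and the topological scope is known by construction.  Controlled
defects (mass-imbalanced reactions, missing formulas, duplicate reactions,
mass leaks) can be injected with a registry of what was injected, enabling
parameter-recovery tests of the QC stages.

Ground truth is computed during generation by an independent naive closure
(full passes to a fixed point), *not* by the package's scope
implementation, so generator and implementation can check each other.

What the toys do not emulate: genome-scale degree distributions, hub
currency metabolites, compartment-specific chemistry, or GPR complexity
beyond single genes - conclusions about real reconstructions need the real
thing.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .fluxmodel import FluxModel
from .netcore import Gene, Metabolite, Reaction, Reconstruction

__all__ = [
    "GroundTruth",
    "ToySpec",
    "degrade",
    "generate_toy",
    "toy_biomass_model",
]


@dataclass
class ToySpec:
    """Parameters of a generated toy reconstruction.

    Defaults give a clean (defect-free) five-pathway network, roughly the
    smallest shape that still exercises branching, reversibility and
    multi-source provenance.
    """

    n_pathways: int = 5
    pathway_length: int = 4
    branch_prob: float = 0.3
    fraction_reversible: float = 0.2
    n_sources: int = 3
    imbalance_frac: float = 0.0
    missing_formula_frac: float = 0.0
    duplicate_frac: float = 0.0
    leak_count: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        if self.pathway_length < 1:
            raise ValueError("pathway_length must be >= 1")
        for name in ("branch_prob", "fraction_reversible", "imbalance_frac",
                     "missing_formula_frac", "duplicate_frac"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.leak_count < 0:
            raise ValueError("leak_count must be >= 0")


@dataclass
class GroundTruth:
    """What the generated network is known to do, by construction."""

    producible: dict[str, frozenset[str]]  # seed-set name -> producible set
    seed_sets: dict[str, frozenset[str]]
    terminal_products: tuple[str, ...]
    biomass_id: str
    biomass_coefficients: dict[str, float]
    uptake_rates: dict[str, float]          # terminal -> supplying rate
    fba_optimum: float
    imbalanced_reactions: frozenset[str] = frozenset()
    missing_formula_metabolites: frozenset[str] = frozenset()
    duplicate_pairs: tuple[tuple[str, str], ...] = ()
    leak_reactions: frozenset[str] = frozenset()
    leak_metabolites: frozenset[str] = frozenset()
    chain_reactions: tuple[str, ...] = ()


_SOURCE_LABELS = ["annotation", "orthology:template%d", "external:db%d",
                  "manual"]


def _source_pool(n: int) -> list[str]:
    pool = []
    i = 0
    while len(pool) < n:
        template = _SOURCE_LABELS[i % len(_SOURCE_LABELS)]
        pool.append(template % (i // len(_SOURCE_LABELS) + 1)
                    if "%d" in template else template)
        i += 1
    return pool[:n]


def _naive_closure(directions, seeds) -> frozenset[str]:
    """Independent ground-truth closure: full passes to a fixed point."""
    producible = set(seeds)
    changed = True
    while changed:
        changed = False
        for substrates, products in directions:
            if substrates <= producible and not products <= producible:
                producible |= products
                changed = True
    return frozenset(producible)


def generate_toy(spec: ToySpec) -> tuple[Reconstruction, GroundTruth]:
    """Build a toy reconstruction plus its ground truth.

    Deterministic for a fixed ``rng_seed``: repeated calls produce
    identical objects (and byte-identical SBML).  Metabolite formulas are
    assigned compositionally - every designed reaction converts a compound
    into an equal-formula compound - so all non-injected reactions are
    mass and charge balanced by construction.
    """
    spec.validate()
    rng = random.Random(spec.rng_seed)
    sources = _source_pool(spec.n_sources)
    recon = Reconstruction(name=f"toy{spec.rng_seed}")

    terminal: list[str] = []
    chain_rxns: list[str] = []
    branch_rxns: list[str] = []
    branch_mets: list[str] = []
    uptake_rate = 10.0

    for p in range(spec.n_pathways):
        formula = f"C{3 + p}H{6 + 2 * p}O{2 + (p % 3)}"
        seed_e = f"S{p}_e"
        seed_c = f"S{p}_c"
        recon.add_metabolite(Metabolite(seed_e, f"substrate {p}", "e",
                                        formula, 0))
        recon.add_metabolite(Metabolite(seed_c, f"substrate {p}", "c",
                                        formula, 0))
        ug = recon.next_artificial_gene("u")
        recon.add_gene(Gene(ug))
        recon.add_reaction(Reaction(
            f"Uptake_S{p}", {}, {seed_e: 1.0}, 0.0, uptake_rate,
            gpr=ug, provenance={"artificial"}, category="uptake",
        ))
        tg = recon.next_artificial_gene("t")
        recon.add_gene(Gene(tg))
        recon.add_reaction(Reaction(
            f"Transport_S{p}", {seed_e: 1.0}, {seed_c: 1.0}, 0.0, 1000.0,
            gpr=tg, provenance={"artificial"}, category="transport",
        ))
        prev = seed_c
        for j in range(spec.pathway_length):
            met = f"X{p}_{j}_c"
            recon.add_metabolite(Metabolite(met, f"intermediate {p}.{j}",
                                            "c", formula, 0))
            reversible = rng.random() < spec.fraction_reversible
            rid = f"P{p}_R{j}"
            recon.add_reaction(Reaction(
                rid, {prev: 1.0}, {met: 1.0},
                -1000.0 if reversible else 0.0, 1000.0,
                gpr=f"g{p}_{j}",
                provenance={rng.choice(sources)},
            ))
            chain_rxns.append(rid)
            if rng.random() < spec.branch_prob:
                bmet = f"B{p}_{j}_c"
                recon.add_metabolite(Metabolite(
                    bmet, f"byproduct {p}.{j}", "c", formula, 0))
                brid = f"P{p}_B{j}"
                recon.add_reaction(Reaction(
                    brid, {met: 1.0}, {bmet: 1.0}, 0.0, 1000.0,
                    gpr=f"g{p}_{j}b",
                    provenance={rng.choice(sources)},
                ))
                branch_rxns.append(brid)
                branch_mets.append(bmet)
            prev = met
        terminal.append(prev)

    coefficients = {t: float(rng.randint(1, 3)) for t in terminal}
    recon.add_reaction(Reaction(
        "BIOMASS", dict(coefficients), {}, 0.0, 1000.0,
        provenance={"manual"}, category="biomass",
    ))

    # --- injected defects ------------------------------------------------
    imbalanced: list[str] = []
    n_imb = math.ceil(spec.imbalance_frac * len(branch_rxns))
    for rid in branch_rxns[:n_imb]:
        rxn = recon.reactions[rid]
        met = next(iter(rxn.products))
        rxn.products[met] = 2.0  # 1:1 formulas, so x2 breaks the balance
        imbalanced.append(rid)

    missing: list[str] = []
    safe_mets = [
        m for m in branch_mets
        if not any(m in recon.reactions[r].products for r in imbalanced)
    ]
    n_missing = math.ceil(spec.missing_formula_frac * len(safe_mets))
    for met_id in safe_mets[:n_missing]:
        recon.metabolites[met_id].formula = None
        missing.append(met_id)

    duplicates: list[tuple[str, str]] = []
    n_dup = math.ceil(spec.duplicate_frac * len(chain_rxns))
    for rid in chain_rxns[:n_dup]:
        rxn = recon.reactions[rid]
        dup_id = f"{rid}_homemade"
        recon.add_reaction(Reaction(
            dup_id, dict(rxn.reactants), dict(rxn.products),
            rxn.lower_bound, rxn.upper_bound, gpr=rxn.gpr,
            provenance={"external:reconciliation"},
        ))
        duplicates.append((rid, dup_id))

    leak_rxns: list[str] = []
    leak_mets: list[str] = []
    for j in range(spec.leak_count):
        lmet = f"L{j}_c"
        recon.add_metabolite(Metabolite(lmet, f"leaked {j}", "c", "C2H4O2", 0))
        carrier = f"S{j % spec.n_pathways}_c"
        lrid = f"LEAK_{j}"
        # catalytic mass-from-nothing: the carrier passes through unchanged
        recon.add_reaction(Reaction(
            lrid, {carrier: 1.0}, {carrier: 1.0, lmet: 1.0}, 0.0, 1000.0,
            provenance={"manual"},
        ))
        leak_rxns.append(lrid)
        leak_mets.append(lmet)

    # --- ground truth by independent closure -----------------------------
    directions = []
    for rxn in recon.reactions.values():
        if rxn.blocked:
            continue
        if rxn.upper_bound > 0:
            directions.append(
                (frozenset(rxn.reactants), frozenset(rxn.products)))
        if rxn.lower_bound < 0:
            directions.append(
                (frozenset(rxn.products), frozenset(rxn.reactants)))
    boundary = frozenset(f"S{p}_e" for p in range(spec.n_pathways))
    seed_sets = {"boundary": boundary}
    producible = {"boundary": _naive_closure(directions, boundary)}
    for p in range(spec.n_pathways):
        name = f"S{p}_e"
        seed_sets[name] = frozenset({name})
        producible[name] = _naive_closure(directions, {name})

    optimum = min(uptake_rate / coefficients[t] for t in terminal)
    truth = GroundTruth(
        producible=producible,
        seed_sets=seed_sets,
        terminal_products=tuple(terminal),
        biomass_id="BIOMASS",
        biomass_coefficients=coefficients,
        uptake_rates={t: uptake_rate for t in terminal},
        fba_optimum=optimum,
        imbalanced_reactions=frozenset(imbalanced),
        missing_formula_metabolites=frozenset(missing),
        duplicate_pairs=tuple(duplicates),
        leak_reactions=frozenset(leak_rxns),
        leak_metabolites=frozenset(leak_mets),
        chain_reactions=tuple(chain_rxns),
    )
    return recon, truth


# ---------------------------------------------------------------------------
# controlled degradation for gap-filling tests
# ---------------------------------------------------------------------------


def degrade(
    recon: Reconstruction,
    k: int,
    rng_seed: int = 0,
    targets: list[str] | None = None,
) -> tuple[Reconstruction, frozenset[str]]:
    """Remove *k* bridge reactions, each disconnecting >= 1 target.

    The removed set is then *a* minimal completion restoring all targets:
    every member is needed and together they suffice.  Targets default to
    the products of the biomass reaction's reactants (the terminal
    products).  Raises when fewer than *k* bridges exist.
    """
    from .topology import SeedSet, boundary_seeds, compute_scope

    if targets is None:
        biomass = [r for r in recon.reactions.values()
                   if r.category == "biomass"]
        if not biomass:
            raise ValueError("no biomass reaction and no explicit targets")
        targets = sorted(biomass[0].reactants)
    seeds = boundary_seeds(recon)
    exchange = {"uptake", "production", "demand", "sink", "biomass"}

    draft = recon.copy()
    removed: list[str] = []
    rng = random.Random(rng_seed)
    for _ in range(k):
        candidates = []
        base = compute_scope(draft, seeds).producible
        reachable_targets = set(targets) & base
        for rid in sorted(draft.reactions):
            rxn = draft.reactions[rid]
            if rxn.category in exchange or rxn.blocked or rid in removed:
                continue
            trial = draft.copy()
            del trial.reactions[rid]
            lost = reachable_targets - compute_scope(trial, seeds).producible
            if lost:
                candidates.append(rid)
        if not candidates:
            raise ValueError(
                f"only {len(removed)} bridge reactions available, "
                f"requested {k}"
            )
        pick = rng.choice(candidates)
        removed.append(pick)
        del draft.reactions[pick]
    return draft, frozenset(removed)


# ---------------------------------------------------------------------------
# closed-form biomass model
# ---------------------------------------------------------------------------


def toy_biomass_model(
    substrate_rates: list[float],
    demands: list[float],
) -> tuple[FluxModel, float]:
    """A flux model whose unique FBA optimum is
    ``min_i(rate_i / coefficient_i)``.

    One substrate per (rate, coefficient) pair: uptake bounded at the rate,
    1:1 transport into the cell, biomass consuming ``coefficient`` units.
    Returns the model together with the closed-form optimum.
    """
    if len(substrate_rates) != len(demands):
        raise ValueError("rates and demand coefficients must pair up")
    if not substrate_rates:
        raise ValueError("at least one substrate required")
    for rate in substrate_rates:
        if rate < 0:
            raise ValueError("rates must be >= 0")
    for coeff in demands:
        if coeff <= 0:
            raise ValueError("demand coefficients must be > 0")
    recon = Reconstruction(name="toy-biomass")
    biomass_reactants: dict[str, float] = {}
    for i, (rate, coeff) in enumerate(zip(substrate_rates, demands)):
        recon.add_metabolite(Metabolite(f"S{i}_e", compartment="e"))
        recon.add_metabolite(Metabolite(f"S{i}_c", compartment="c"))
        ug = recon.next_artificial_gene("u")
        recon.add_gene(Gene(ug))
        recon.add_reaction(Reaction(
            f"Uptake_S{i}", {}, {f"S{i}_e": 1.0}, 0.0, float(rate),
            gpr=ug, provenance={"artificial"}, category="uptake",
        ))
        recon.add_reaction(Reaction(
            f"Transport_S{i}", {f"S{i}_e": 1.0}, {f"S{i}_c": 1.0},
            0.0, 1e9, provenance={"artificial"}, category="transport",
        ))
        biomass_reactants[f"S{i}_c"] = float(coeff)
    recon.add_reaction(Reaction(
        "BIOMASS", biomass_reactants, {}, 0.0, 1e9,
        provenance={"manual"}, category="biomass",
    ))
    optimum = min(
        rate / coeff for rate, coeff in zip(substrate_rates, demands)
    )
    return FluxModel(recon, "BIOMASS", "default"), optimum
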