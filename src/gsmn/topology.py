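"""Seed-based topological producibility (network expansion / scope).

A metabolite is *topologically producible* from a seed set when some chain
of reactions, each firing only once all of its substrates are available,
eventually produces it.  This is pure hypergraph reachability: stoichiometric
coefficients are ignored and each direction of a reversible reaction fires
independently.  Blocked reactions (both bounds zero) never fire, so scope
counts reflect curation-stage blocking.

The scope is the least fixed point of the expansion operator; it is computed
with a worklist algorithm (O(|reactions| * |metabolites|) worst case).  A
deliberately naive full-pass closure is kept alongside as an independent
oracle for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .netcore import Reaction, Reconstruction

__all__ = [
    "ConnectivityClasses",
    "ProgressRow",
    "ScopeResult",
    "SeedSet",
    "TargetSet",
    "boundary_seeds",
    "classify_metabolites",
    "compute_scope",
    "naive_scope",
    "producibility_report",
]


@dataclass
class SeedSet:
    """Metabolites assumed available from the environment."""

    metabolites: frozenset[str]

    def __init__(self, metabolites) -> None:
        self.metabolites = frozenset(metabolites)

    def validate(self, recon: Reconstruction) -> None:
        missing = self.metabolites - set(recon.metabolites)
        if missing:
            raise ValueError(f"seeds not in reconstruction: {sorted(missing)}")


@dataclass
class TargetSet:
    """Metabolites whose producibility curation monitors."""

    name: str
    metabolites: frozenset[str]
    confidence: str = "high"

    def __init__(self, name, metabolites, confidence="high") -> None:
        self.name = name
        self.metabolites = frozenset(metabolites)
        self.confidence = confidence

    def resolve(self, recon: Reconstruction) -> tuple[frozenset[str], frozenset[str]]:
        """(resolvable, orphan) partition against the reconstruction."""
        present = self.metabolites & set(recon.metabolites)
        return present, self.metabolites - present


@dataclass
class ScopeResult:
    producible: frozenset[str]
    active: frozenset[str]
    iterations: int = 0


def _directions(rxn: Reaction):
    """Firing directions of a reaction: (substrates, products) pairs."""
    if rxn.blocked:
        return
    if rxn.upper_bound > 0:
        yield frozenset(rxn.reactants), frozenset(rxn.products)
    if rxn.lower_bound < 0:
        yield frozenset(rxn.products), frozenset(rxn.reactants)


def compute_scope(recon: Reconstruction, seeds: SeedSet) -> ScopeResult:
    """Least fixed point of network expansion from *seeds* (worklist)."""
    seeds.validate(recon)
    producible = set(seeds.metabolites)
    active: set[str] = set()
    # index: metabolite -> direction entries waiting on it
    entries = []  # (rxn_id, missing_count holder, products)
    waiting: dict[str, list[int]] = {}
    ready: list[int] = []
    for rxn in recon.reactions.values():
        for substrates, products in _directions(rxn):
            idx = len(entries)
            missing = [m for m in substrates if m not in producible]
            entries.append([rxn.id, len(missing), products])
            if missing:
                for m in missing:
                    waiting.setdefault(m, []).append(idx)
            else:
                ready.append(idx)

    iterations = 0
    queue = list(ready)
    while queue:
        iterations += 1
        idx = queue.pop()
        rid, _, products = entries[idx]
        active.add(rid)
        for m in products:
            if m not in producible:
                producible.add(m)
                for widx in waiting.get(m, ()):
                    entries[widx][1] -= 1
                    if entries[widx][1] == 0:
                        queue.append(widx)
    return ScopeResult(frozenset(producible), frozenset(active), iterations)


def naive_scope(recon: Reconstruction, seeds: SeedSet) -> ScopeResult:
    """Independent O(n^2) oracle: repeated full passes until no change."""
    producible = set(seeds.metabolites)
    active: set[str] = set()
    passes = 0
    changed = True
    while changed:
        changed = False
        passes += 1
        for rxn in recon.reactions.values():
            for substrates, products in _directions(rxn):
                if substrates <= producible:
                    if rxn.id not in active:
                        active.add(rxn.id)
                        changed = True
                    if not products <= producible:
                        producible |= products
                        changed = True
    return ScopeResult(frozenset(producible), frozenset(active), passes)


def boundary_seeds(recon: Reconstruction) -> SeedSet:
    """Seeds = metabolites produced by an uptake reaction (system boundary)."""
    seeds: set[str] = set()
    for rxn in recon.reactions.values():
        if rxn.category == "uptake":
            seeds |= set(rxn.products)
    return SeedSet(seeds)


@dataclass
class ConnectivityClasses:
    """Partition of metabolites by consumer/producer membership.

    Both directions of a reversible reaction count, so a metabolite in a
    reversible reaction is both consumed and produced.
    """

    consumed_only: frozenset[str]
    produced_only: frozenset[str]
    both: frozenset[str]
    disconnected: frozenset[str]

    @property
    def dead_ends(self) -> frozenset[str]:
        return self.consumed_only | self.produced_only


def classify_metabolites(recon: Reconstruction) -> ConnectivityClasses:
    consumed: set[str] = set()
    produced: set[str] = set()
    for rxn in recon.reactions.values():
        reac, prod = set(rxn.reactants), set(rxn.products)
        consumed |= reac
        produced |= prod
        if rxn.reversible:
            consumed |= prod
            produced |= reac
    everything = set(recon.metabolites)
    return ConnectivityClasses(
        consumed_only=frozenset((consumed - produced) & everything),
        produced_only=frozenset((produced - consumed) & everything),
        both=frozenset(consumed & produced & everything),
        disconnected=frozenset(everything - consumed - produced),
    )


@dataclass
class ProgressRow:
    """One curation-stage row of a producibility progress table."""

    stage: str
    n_reactions: int
    n_active: int
    n_metabolites: int
    n_producible: int
    consumed_only: int
    produced_only: int
    both: int
    disconnected: int
    targets: dict[str, tuple[int, int]] = field(default_factory=dict)
    absent_targets: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "stage": self.stage,
            "reactions": self.n_reactions,
            "active_reactions": self.n_active,
            "metabolites": self.n_metabolites,
            "producible_metabolites": self.n_producible,
            "consumed_only": self.consumed_only,
            "produced_only": self.produced_only,
            "consumed_and_produced": self.both,
            "disconnected": self.disconnected,
        }
        for name, (k, total) in self.targets.items():
            d[f"producible_{name}"] = f"{k}/{total}"
        return d


def producibility_report(
    recon: Reconstruction,
    seeds: SeedSet,
    targets: list[TargetSet] | None = None,
    stage: str = "",
) -> ProgressRow:
    """Scope + connectivity counts + per-target producibility fractions.

    Targets absent from the reconstruction stay in the denominator and are
    tallied in ``absent_targets``; rows across curation stages rebuild a
    progress table.
    """
    scope = compute_scope(recon, seeds)
    classes = classify_metabolites(recon)
    row = ProgressRow(
        stage=stage,
        n_reactions=len(recon.reactions),
        n_active=len(scope.active),
        n_metabolites=len(recon.metabolites),
        n_producible=len(scope.producible),
        consumed_only=len(classes.consumed_only),
        produced_only=len(classes.produced_only),
        both=len(classes.both),
        disconnected=len(classes.disconnected),
    )
    for tset in targets or []:
        present, orphan = tset.resolve(recon)
        k = len(present & scope.producible)
        row.targets[tset.name] = (k, len(tset.metabolites))
        if orphan:
            row.absent_targets[tset.name] = len(orphan)
    return row
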