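"""Minimal topological completion (gap-filling) of a draft reconstruction.

Given seeds, unproducible targets and a *repair database* of candidate
reactions, gap-filling seeks a smallest set of repair reactions whose
addition makes the targets producible under scope semantics
(:mod:`gsmn.topology`).  Repair databases are tiered by confidence
(e.g. fungal subsets before the full reference database) and queried
iteratively from the most trusted tier, mirroring a reasoned curation
workflow rather than a single global search.

``minimal_completion`` implements an exact branch-and-bound over repair
reactions (branching on frontier reactions, pruning by reachability and by
the incumbent cardinality) plus a greedy subset-minimal mode for large
instances.  ``brute_force_completion`` is the deliberately naive
enumeration oracle used to certify minimality in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .netcore import Gene, Reaction, Reconstruction
from .topology import SeedSet, TargetSet, compute_scope

__all__ = [
    "Completion",
    "GapfillLog",
    "GapfillRun",
    "RepairDB",
    "admit_spontaneous",
    "brute_force_completion",
    "iterative_gapfill",
    "minimal_completion",
]


@dataclass
class RepairDB:
    """A tiered pool of candidate repair reactions.

    Tier 1 is the highest-confidence subset; the label names the pool
    (e.g. ``fungal-subset``, ``spontaneous``, ``no-enzyme``, ``full``).
    """

    reactions: dict[str, Reaction]
    tier: int = 1
    label: str = "repair"
    metabolites: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tier < 1:
            raise ValueError("tier must be >= 1")


@dataclass
class Completion:
    reactions: frozenset[str]
    satisfied: frozenset[str]
    unsatisfiable: frozenset[str]
    minimal: bool = False


def _augmented(draft: Reconstruction, repair: RepairDB,
               chosen) -> Reconstruction:
    ext = draft.copy()
    for rid in chosen:
        rxn = repair.reactions[rid]
        for m in rxn.metabolite_ids():
            if m not in ext.metabolites:
                met = repair.metabolites.get(m)
                ext.add_metabolite(
                    met if met is not None else _stub_metabolite(m)
                )
        if rid not in ext.reactions:
            ext.add_reaction(_copy_reaction(rxn))
    return ext


def _stub_metabolite(met_id: str):
    from .netcore import Metabolite

    return Metabolite(met_id, compartment="c")


def _copy_reaction(rxn: Reaction) -> Reaction:
    return Reaction(
        id=rxn.id,
        reactants=dict(rxn.reactants),
        products=dict(rxn.products),
        lower_bound=rxn.lower_bound,
        upper_bound=rxn.upper_bound,
        gpr=rxn.gpr,
        provenance=set(rxn.provenance) or {"external:repair"},
        category=rxn.category,
        sbo=rxn.sbo,
        name=rxn.name,
    )


class _ScopeEngine:
    """Incremental scope evaluation over draft + chosen repair reactions.

    Directions are precomputed once; evaluating a candidate subset is a
    single worklist closure, cheap enough for branch-and-bound.
    """

    def __init__(self, draft: Reconstruction, repair: RepairDB,
                 seeds: SeedSet):
        from .topology import _directions

        self.seeds = frozenset(seeds.metabolites)
        self.draft_dirs: list[tuple[frozenset, frozenset]] = []
        for rxn in draft.reactions.values():
            self.draft_dirs.extend(_directions(rxn))
        self.repair_dirs: dict[str, list[tuple[frozenset, frozenset]]] = {
            rid: list(_directions(rxn))
            for rid, rxn in repair.reactions.items()
        }

    def producible(self, chosen=()) -> frozenset[str]:
        dirs = list(self.draft_dirs)
        for rid in chosen:
            dirs.extend(self.repair_dirs[rid])
        producible = set(self.seeds)
        changed = True
        while changed:
            changed = False
            rest = []
            for substrates, products in dirs:
                if substrates <= producible:
                    if not products <= producible:
                        producible |= products
                        changed = True
                else:
                    rest.append((substrates, products))
            dirs = rest
        return frozenset(producible)


def _prepare(draft, repair, seeds, targets):
    engine = _ScopeEngine(draft, repair, seeds)
    base = engine.producible()
    wanted = frozenset(targets.metabolites)
    already = wanted & base
    full = engine.producible(sorted(repair.reactions))
    unsat = wanted - full
    goals = wanted - already - unsat
    return engine, base, already, unsat, goals


def minimal_completion(
    draft: Reconstruction,
    repair: RepairDB,
    seeds: SeedSet,
    targets: TargetSet,
    mode: str = "exact",
) -> Completion:
    """Smallest repair set making the targets producible.

    ``exact`` returns a minimum-cardinality completion (ties broken by the
    lexicographically smallest sorted id tuple); ``greedy`` a subset-minimal
    one.  Targets unreachable even with the whole repair database are
    reported in ``unsatisfiable``, never silently dropped.
    """
    if mode not in ("exact", "greedy"):
        raise ValueError(f"unknown mode {mode!r}")
    engine, base, already, unsat, goals = _prepare(
        draft, repair, seeds, targets
    )
    if not goals:
        return Completion(frozenset(), already, unsat, minimal=True)

    if mode == "greedy":
        chosen = _greedy(engine, goals)
    else:
        chosen = _branch_and_bound(engine, goals)
    prod = engine.producible(chosen)
    return Completion(
        frozenset(chosen),
        already | (goals & prod),
        unsat,
        minimal=(mode == "exact"),
    )


def _useful_candidates(engine: _ScopeEngine, goals) -> list[str]:
    """Repair reactions that can ever fire in the full augmentation."""
    full = engine.producible(sorted(engine.repair_dirs))
    base = engine.producible()
    out = []
    for rid, dirs in engine.repair_dirs.items():
        for substrates, products in dirs:
            if substrates <= full and not products <= base:
                out.append(rid)
                break
    return sorted(out)


def _greedy(engine: _ScopeEngine, goals) -> tuple[str, ...]:
    candidates = _useful_candidates(engine, goals)
    chosen: list[str] = []
    prod = engine.producible()
    while not goals <= prod:
        best_rid, best_gain = None, -1
        for rid in candidates:
            if rid in chosen:
                continue
            new = engine.producible(chosen + [rid])
            gain = len(new & goals) * 10_000 + len(new)
            if gain > best_gain:
                best_rid, best_gain = rid, gain
        if best_rid is None:  # pragma: no cover - goals pre-filtered
            break
        chosen.append(best_rid)
        prod = engine.producible(chosen)
    # prune to subset-minimality
    for rid in sorted(chosen, reverse=True):
        trial = [r for r in chosen if r != rid]
        if goals <= engine.producible(trial):
            chosen = trial
    return tuple(sorted(chosen))


def _branch_and_bound(engine: _ScopeEngine, goals) -> tuple[str, ...]:
    candidates = _useful_candidates(engine, goals)
    best: list[tuple[str, ...]] = [tuple(sorted(_greedy(engine, goals)))]

    def better(a: tuple, b: tuple) -> bool:
        return (len(a), a) < (len(b), b)

    def rec(chosen: tuple[str, ...], banned: frozenset[str]) -> None:
        if len(chosen) > len(best[0]):
            return
        prod = engine.producible(chosen)
        if goals <= prod:
            cand = tuple(sorted(chosen))
            if better(cand, best[0]):
                best[0] = cand
            return
        if len(chosen) == len(best[0]):  # cannot extend within the bound
            return
        # frontier: usable repair reactions that extend the current scope
        frontier = []
        for rid in candidates:
            if rid in chosen or rid in banned:
                continue
            for substrates, products in engine.repair_dirs[rid]:
                if substrates <= prod and not products <= prod:
                    frontier.append(rid)
                    break
        if not frontier:
            return
        # branch on the first frontier reaction: include it or ban it
        rid = frontier[0]
        rec(chosen + (rid,), banned)
        rec(chosen, banned | {rid})

    rec((), frozenset())
    return best[0]


def brute_force_completion(
    draft: Reconstruction,
    repair: RepairDB,
    seeds: SeedSet,
    targets: TargetSet,
) -> Completion:
    """Exhaustive oracle: subsets in increasing cardinality, lexicographic
    tie-break; refuses repair databases larger than 20 reactions."""
    if len(repair.reactions) > 20:
        raise ValueError("brute force limited to 20 repair reactions")
    engine, base, already, unsat, goals = _prepare(
        draft, repair, seeds, targets
    )
    if not goals:
        return Completion(frozenset(), already, unsat, minimal=True)
    ids = sorted(repair.reactions)
    for k in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            if goals <= engine.producible(combo):
                return Completion(
                    frozenset(combo), goals | already, unsat, minimal=True
                )
    # goals were filtered to be reachable with the full DB
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# iterative, tiered gap-filling
# ---------------------------------------------------------------------------


@dataclass
class GapfillRun:
    target_tier: str
    repair_label: str
    added: tuple[str, ...]
    newly_producible: int
    unsatisfied_after: int


@dataclass
class GapfillLog:
    runs: list[GapfillRun] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {
                "run": i + 1,
                "targets": r.target_tier,
                "repair": r.repair_label,
                "added_reactions": ";".join(r.added),
                "n_added": len(r.added),
                "newly_producible": r.newly_producible,
                "unsatisfied_after": r.unsatisfied_after,
            }
            for i, r in enumerate(self.runs)
        ]


def _apply_completion(
    recon: Reconstruction, repair: RepairDB, completion: Completion
) -> Reconstruction:
    out = _augmented(recon, repair, sorted(completion.reactions))
    for rid in completion.reactions:
        rxn = out.reactions[rid]
        rxn.provenance.add(f"gapfill:{repair.label}")
        if not rxn.gpr:
            gid = out.next_artificial_gene("gf")
            out.add_gene(Gene(gid))
            rxn.gpr = gid
    return out


def iterative_gapfill(
    draft: Reconstruction,
    repair_tiers: list[RepairDB],
    target_tiers: list[TargetSet],
    seeds: SeedSet | None = None,
    mode: str = "exact",
) -> tuple[Reconstruction, GapfillLog]:
    """Tiered gap-filling: per target tier, query repair tiers in order,
    then the union of the tiers already tried.

    The first repair pool that newly satisfies targets wins the run, so a
    tier-1 route is preferred over a shorter tier-2 route.  Accepted
    reactions gain ``gapfill:<label>`` provenance and, when no gene came
    with them, a fresh artificial gene.  Re-running on the output adds
    nothing (idempotence).
    """
    from .topology import boundary_seeds

    current = draft.copy()
    log = GapfillLog()
    seeds = seeds or boundary_seeds(draft)
    for tset in target_tiers:
        pending_pools: list[RepairDB] = []
        for pool in sorted(repair_tiers, key=lambda p: p.tier):
            remaining = _unproducible(current, seeds, tset)
            if not remaining:
                log.runs.append(
                    GapfillRun(tset.name, pool.label, (), 0, 0)
                )
                continue
            run_targets = TargetSet(tset.name, remaining, tset.confidence)
            completion = minimal_completion(
                current, pool, seeds, run_targets, mode=mode
            )
            current, n_new = _accept(current, pool, completion)
            log.runs.append(
                GapfillRun(
                    tset.name,
                    pool.label,
                    tuple(sorted(completion.reactions)),
                    n_new,
                    len(_unproducible(current, seeds, tset)),
                )
            )
            pending_pools.append(pool)
        remaining = _unproducible(current, seeds, tset)
        if remaining and len(pending_pools) > 1:
            union = RepairDB(
                reactions={
                    rid: rxn
                    for pool in pending_pools
                    for rid, rxn in pool.reactions.items()
                },
                tier=max(p.tier for p in pending_pools),
                label="+".join(p.label for p in pending_pools),
                metabolites={
                    m: met
                    for pool in pending_pools
                    for m, met in pool.metabolites.items()
                },
            )
            completion = minimal_completion(
                current, union, seeds,
                TargetSet(tset.name, remaining, tset.confidence), mode=mode,
            )
            current, n_new = _accept(current, union, completion)
            log.runs.append(
                GapfillRun(
                    tset.name,
                    union.label,
                    tuple(sorted(completion.reactions)),
                    n_new,
                    len(_unproducible(current, seeds, tset)),
                )
            )
    return current, log


def _unproducible(recon, seeds, tset) -> frozenset[str]:
    scope = compute_scope(recon, seeds)
    present, _orphans = tset.resolve(recon)
    in_model_unprod = present - scope.producible
    orphans = tset.metabolites - set(recon.metabolites)
    return in_model_unprod | orphans


def _accept(current, pool, completion):
    if not completion.reactions:
        return current, 0
    before = compute_scope(
        current, SeedSet(_seed_ids(current))
    ).producible
    new = _apply_completion(current, pool, completion)
    after = compute_scope(new, SeedSet(_seed_ids(new))).producible
    return new, len(after - before)


def _seed_ids(recon) -> frozenset[str]:
    from .topology import boundary_seeds

    return boundary_seeds(recon).metabolites


# ---------------------------------------------------------------------------
# spontaneous reactions
# ---------------------------------------------------------------------------


def admit_spontaneous(
    draft: Reconstruction, spontaneous_db: RepairDB
) -> list[Reaction]:
    """Admit enzyme-free (spontaneous) reactions that touch the draft.

    A spontaneous reaction is admitted exactly when at least one of its
    reactants or products is already in the draft; each admitted reaction
    receives a fresh artificial gene in the s-series, assigned in
    deterministic id order.  The draft is modified in place and the admitted
    reactions returned.
    """
    admitted: list[Reaction] = []
    for rid in sorted(spontaneous_db.reactions):
        rxn = spontaneous_db.reactions[rid]
        if rxn.gpr:
            raise ValueError(
                f"spontaneous reaction {rid} carries a GPR; expected none"
            )
        if not (rxn.metabolite_ids() & set(draft.metabolites)):
            continue
        copy = _copy_reaction(rxn)
        copy.provenance.add(f"external:{spontaneous_db.label}")
        gid = draft.next_artificial_gene("s")
        draft.add_gene(Gene(gid))
        copy.gpr = gid
        for m in copy.metabolite_ids():
            if m not in draft.metabolites:
                met = spontaneous_db.metabolites.get(m)
                draft.add_metabolite(
                    met if met is not None else _stub_metabolite(m)
                )
        draft.add_reaction(copy)
        admitted.append(copy)
    return admitted
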