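"""Merging and reconciling subnetworks from multiple evidence sources.

A reconstruction is assembled from a functional-annotation subnetwork,
orthology subnetworks inferred from template models, and external databases
or earlier published networks.  Reconciliation keeps every piece of
knowledge (nothing is deleted; dubious entries are blocked), records the
source of each reaction as provenance tags, admits external reactions only
under identifier-compatibility + gene-support rules, resolves duplicate
reactions in favour of the better-balanced / reference-identified member,
and compares model versions by exact identifiers or by InChIKey blocks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .netcore import (
    Reaction,
    Reconstruction,
    gpr_or_join,
)

__all__ = [
    "DuplicatePair",
    "IdMap",
    "MergeConflictError",
    "OverlapReport",
    "SourceTag",
    "admit_external_reaction",
    "compare_reconstructions",
    "find_duplicate_pairs",
    "inchikey_tier",
    "merge_networks",
    "resolve_duplicates",
]


@dataclass(frozen=True)
class SourceTag:
    """Provenance of a subnetwork: where its reactions came from."""

    kind: str  # annotation | orthology | external | gapfill | manual | artificial
    label: str = ""

    KINDS = ("annotation", "orthology", "external", "gapfill", "manual",
             "artificial")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")

    def __str__(self) -> str:
        return f"{self.kind}:{self.label}" if self.label else self.kind


class MergeConflictError(ValueError):
    """Same reaction id with different stoichiometry in two sources."""


def merge_networks(
    base: Reconstruction, addition: Reconstruction, tag: SourceTag
) -> Reconstruction:
    """Union of two subnetworks with provenance tracking.

    Reactions present in both keep one entry whose provenance is the union
    plus *tag*, whose GPR is the OR-join of both gene associations and whose
    bounds are widened to the containing interval (the reconstruction stage
    is permissive; restriction happens when deriving a flux model).  A shared
    reaction id with different stoichiometry is a hard conflict.
    """
    out = base.copy()
    for met in addition.metabolites_sorted():
        if met.id not in out.metabolites:
            if met.compartment not in out.compartments:
                out.compartments[met.compartment] = (
                    addition.compartments.get(met.compartment, met.compartment)
                )
            out.add_metabolite(met)
        else:
            ours = out.metabolites[met.id]
            for ns, ids in met.annotations.items():
                known = ours.annotations.setdefault(ns, [])
                known.extend(i for i in ids if i not in known)
            if ours.formula is None and met.formula is not None:
                ours.formula = met.formula
            if ours.charge is None and met.charge is not None:
                ours.charge = met.charge
    for gene in addition.genes.values():
        out.add_gene(gene)
    for rxn in addition.reactions_sorted():
        if rxn.id not in out.reactions:
            new = Reaction(
                id=rxn.id,
                reactants=dict(rxn.reactants),
                products=dict(rxn.products),
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                gpr=rxn.gpr,
                provenance=set(rxn.provenance) | {str(tag)},
                category=rxn.category,
                sbo=rxn.sbo,
                name=rxn.name,
            )
            out.add_reaction(new)
        else:
            ours = out.reactions[rxn.id]
            if ours.stoichiometry_key() != rxn.stoichiometry_key():
                raise MergeConflictError(
                    f"reaction {rxn.id}: conflicting stoichiometry\n"
                    f"  base:     {ours.equation()}\n"
                    f"  addition: {rxn.equation()}"
                )
            ours.provenance |= rxn.provenance | {str(tag)}
            if rxn.genes() - ours.genes():
                ours.gpr = gpr_or_join(ours.gpr, rxn.gpr)
                from .netcore import Gene

                for g in rxn.genes():
                    out.add_gene(addition.genes.get(g) or Gene(g))
            ours.lower_bound = min(ours.lower_bound, rxn.lower_bound)
            ours.upper_bound = max(ours.upper_bound, rxn.upper_bound)
    return out


# ---------------------------------------------------------------------------
# external-source admission
# ---------------------------------------------------------------------------


@dataclass
class IdMap:
    """Identifier mapping into the reference namespace (e.g. a MetaNetX
    dictionary mapping source ids to reference database ids).

    ``entries`` maps source-namespace ids to reference ids (many-to-one
    allowed); ids already in the reference namespace are listed in
    ``reference_ids`` and map to themselves.  Lookups that fail are recorded
    in ``unmapped``.
    """

    entries: dict[str, str] = field(default_factory=dict)
    reference_ids: set[str] = field(default_factory=set)
    unmapped: set[str] = field(default_factory=set)

    def to_reference(self, ident: str) -> str | None:
        if ident in self.reference_ids:
            return ident
        target = self.entries.get(ident)
        if target is None:
            self.unmapped.add(ident)
        return target

    @classmethod
    def from_tsv(cls, path: str, reference_ids=()) -> "IdMap":
        entries = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                src, dst = line.split("\t")[:2]
                entries[src] = dst
        return cls(entries, set(reference_ids))


@dataclass
class AdmissionDecision:
    decision: str  # admit_mapped | admit_original_id | reject
    reason: str = ""
    mapped_id: str | None = None


def admit_external_reaction(
    rxn: Reaction, namespace_check: IdMap, draft: Reconstruction
) -> AdmissionDecision:
    """Admission rule for a reaction from an external source.

    Admit under its (mapped) reference id when the reaction id is known to
    the reference namespace; failing that, admit under its original id when
    every reactant and product maps to the reference namespace.  Both routes
    require support by at least one gene; otherwise reject with a reason.
    """
    if not rxn.gpr:
        return AdmissionDecision("reject", "no_gpr")
    mapped = namespace_check.to_reference(rxn.id)
    if mapped is not None:
        return AdmissionDecision("admit_mapped", mapped_id=mapped)
    unmapped = [
        m for m in sorted(rxn.metabolite_ids())
        if namespace_check.to_reference(m) is None
    ]
    if not unmapped:
        return AdmissionDecision("admit_original_id", mapped_id=rxn.id)
    return AdmissionDecision(
        "reject", f"unmapped_species:{','.join(unmapped)}"
    )


# ---------------------------------------------------------------------------
# duplicate detection and resolution
# ---------------------------------------------------------------------------


@dataclass
class DuplicatePair:
    a: str
    b: str
    relation: str  # same_direction | opposite_direction | reversibility_conflict
    gpr_relation: str  # identical | subset | disjoint | overlap


def _gpr_relation(ga: frozenset[str], gb: frozenset[str]) -> str:
    if ga == gb:
        return "identical"
    if ga <= gb or gb <= ga:
        return "subset"
    if ga & gb:
        return "overlap"
    return "disjoint"


def find_duplicate_pairs(recon: Reconstruction) -> list[DuplicatePair]:
    """All unordered reaction pairs with identical stoichiometric multisets
    (same direction) or with reactant/product sides swapped (opposite
    direction).  Compartments are part of metabolite ids, so copies of a
    reaction in different compartments are not duplicates."""
    by_key: dict[tuple, list[str]] = {}
    for rxn in recon.reactions.values():
        by_key.setdefault(rxn.stoichiometry_key(), []).append(rxn.id)
    pairs: list[DuplicatePair] = []
    seen: set[tuple[str, str]] = set()
    for key, ids in by_key.items():
        ids = sorted(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                pairs.append(_make_pair(recon, a, b, "same_direction"))
                seen.add((a, b))
        swapped = (key[1], key[0])
        if swapped != key and swapped in by_key:
            for a in ids:
                for b in sorted(by_key[swapped]):
                    lo, hi = sorted((a, b))
                    if (lo, hi) not in seen:
                        seen.add((lo, hi))
                        pairs.append(
                            _make_pair(recon, lo, hi, "opposite_direction")
                        )
    pairs.sort(key=lambda p: (p.a, p.b))
    return pairs


def _make_pair(recon, a, b, relation) -> DuplicatePair:
    ra, rb = recon.reactions[a], recon.reactions[b]
    if relation == "same_direction" and ra.reversible != rb.reversible:
        relation = "reversibility_conflict"
    return DuplicatePair(a, b, relation, _gpr_relation(ra.genes(), rb.genes()))


def resolve_duplicates(
    recon: Reconstruction,
    pairs: list[DuplicatePair],
    balance: "BalanceReport",
    reference_id_check=None,
) -> Reconstruction:
    """Block the lesser member of each duplicate pair (never delete).

    Keeps the mass-balanced member when exactly one is balanced; with equal
    balance keeps the member whose id the reference namespace recognises
    (``reference_id_check(id) -> bool``, default: ids without a
    ``homemade`` marker), breaking remaining ties toward the
    lexicographically smaller id.  A pair is only acted on when one GPR
    gene set contains the other; otherwise it is flagged for manual review
    in ``out.review_pairs``.
    """
    out = recon.copy()
    out.review_pairs = []
    if reference_id_check is None:
        reference_id_check = lambda rid: "homemade" not in rid.lower()
    for pair in pairs:
        if pair.gpr_relation not in ("identical", "subset"):
            out.review_pairs.append(pair)
            continue
        ra, rb = out.reactions[pair.a], out.reactions[pair.b]
        if ra.blocked or rb.blocked:
            continue
        bal_a = balance.mass_status.get(pair.a) == "balanced"
        bal_b = balance.mass_status.get(pair.b) == "balanced"
        if bal_a != bal_b:
            loser = rb if bal_a else ra
        else:
            ref_a, ref_b = reference_id_check(pair.a), reference_id_check(pair.b)
            if ref_a != ref_b:
                loser = rb if ref_a else ra
            else:
                loser = out.reactions[max(pair.a, pair.b)]
        loser.block(f"duplicate_of:{pair.a if loser.id == pair.b else pair.b}")
    return out


# ---------------------------------------------------------------------------
# InChIKey comparison
# ---------------------------------------------------------------------------

_INCHIKEY_RE = re.compile(r"^([A-Z]{14})-([A-Z]{8}[A-Z]{2})-([A-Z])$")


def inchikey_tier(a: str, b: str) -> int:
    """Agreement tier of two InChIKeys (14-10-1 hyphenated layout).

    3 = exact match, 2 = first two blocks, 1 = first (planar-structure)
    block only, 0 = none.
    """
    ma, mb = _INCHIKEY_RE.match(a or ""), _INCHIKEY_RE.match(b or "")
    if ma is None:
        raise ValueError(f"malformed InChIKey: {a!r}")
    if mb is None:
        raise ValueError(f"malformed InChIKey: {b!r}")
    if a == b:
        return 3
    if ma.group(1) == mb.group(1):
        return 2 if ma.group(2) == mb.group(2) else 1
    return 0


@dataclass
class OverlapReport:
    key: str
    shared: int
    exclusive_a: int
    exclusive_b: int
    incomparable_a: int
    incomparable_b: int
    shared_keys: frozenset[str] = frozenset()

    @property
    def total_a(self) -> int:
        return self.shared + self.exclusive_a

    @property
    def total_b(self) -> int:
        return self.shared + self.exclusive_b


def _metabolite_keys(recon: Reconstruction, key: str):
    """(comparison-unit set, n incomparable).  Tier-1 key collisions within
    one model collapse to a single comparison unit."""
    if key == "exact_id":
        return {m for m in recon.metabolites}, 0
    if key != "inchikey_tier1":
        raise ValueError(f"unknown comparison key {key!r}")
    units: set[str] = set()
    incomparable = 0
    for met in recon.metabolites.values():
        ik = met.inchikey
        if ik and _INCHIKEY_RE.match(ik):
            units.add(ik.split("-")[0])
        else:
            incomparable += 1
    return units, incomparable


def compare_reconstructions(
    a: Reconstruction, b: Reconstruction, key: str = "exact_id"
) -> OverlapReport:
    """Shared/exclusive metabolite counts under the chosen comparison key.

    Metabolites without the key are reported as incomparable, never counted
    as exclusive.
    """
    ka, inc_a = _metabolite_keys(a, key)
    kb, inc_b = _metabolite_keys(b, key)
    shared = ka & kb
    return OverlapReport(
        key=key,
        shared=len(shared),
        exclusive_a=len(ka - kb),
        exclusive_b=len(kb - ka),
        incomparable_a=inc_a,
        incomparable_b=inc_b,
        shared_keys=frozenset(shared),
    )
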