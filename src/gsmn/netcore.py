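"""Core data model for genome-scale metabolic network (GSMN) reconstructions.

A *reconstruction* is the knowledge network of an organism's metabolism:
metabolites, reactions with stoichiometry and flux bounds, genes, and the
boolean gene-protein-reaction (GPR) associations linking them.  Every entity
carries annotations (MIRIAM-style namespace -> identifier lists), an SBO term,
and per-reaction provenance tags recording which source contributed it
(functional annotation, orthology template, external database, gap-filling
run, manual curation, or an artificial construct such as an exchange
reaction).

The model deliberately separates the permissive *reconstruction* (nothing is
ever deleted, dubious reactions are blocked by zeroing their bounds) from the
numeric *flux model* built on top of it (see :mod:`gsmn.fluxmodel`).

Serialisation is SBML Level 3 Version 1 with the FBC v2 package: species
formulas/charges via FBC attributes, flux bounds as model parameters, GPRs as
FBC gene-product associations.  Provenance, reaction category and gene
localisation - which have no FBC slot - are serialised as ``key: value``
lines in SBML notes so they survive round-trips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ARTIFICIAL_GENE_RE",
    "CATEGORIES",
    "ElementMap",
    "Gene",
    "Metabolite",
    "Reaction",
    "Reconstruction",
    "SummaryReport",
    "parse_formula",
    "summarize",
]

#: Reaction categories.  ``uptake``/``production`` are the artificial exchange
#: reactions across the system boundary; ``demand`` is the irreversible
#: external-to-intracellular transfer convention used here; ``sink`` buffers a
#: metabolite; ``dissipation`` is a temporary energy-dissipating reaction used
#: by the energy-cycle screen.
CATEGORIES = (
    "metabolic",
    "transport",
    "uptake",
    "production",
    "demand",
    "sink",
    "biomass",
    "atpm",
    "dissipation",
)

#: Default SBO term per reaction category.
CATEGORY_SBO = {
    "metabolic": "SBO:0000176",
    "transport": "SBO:0000655",
    "uptake": "SBO:0000627",
    "production": "SBO:0000627",
    "demand": "SBO:0000628",
    "sink": "SBO:0000632",
    "biomass": "SBO:0000629",
    "atpm": "SBO:0000630",
    "dissipation": "SBO:0000628",
}

#: Artificial gene ids: t### transport, d### demand, u### uptake, sk### sink,
#: p### production, s### spontaneous, gf### gap-fill-assigned.
ARTIFICIAL_GENE_RE = re.compile(r"^(t|d|u|p|s|sk|gf)\d{3,}$")


class ReconstructionError(ValueError):
    """An invariant of the reconstruction data model is violated."""


# ---------------------------------------------------------------------------
# chemical formulas
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

#: IUPAC element symbols.  Placeholder tokens such as R (generic residue)
#: or X (halide/unknown) are not elements and make a formula unparseable.
ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe "
    "Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In "
    "Sn Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf "
    "Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am "
    "Cm Bk Cf Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts "
    "Og".split()
)


@dataclass
class ElementMap:
    """Element -> count map for one metabolite formula.

    ``parse_status`` is ``ok`` for a clean Hill-notation formula, ``absent``
    for a missing formula and ``unparseable`` for anything else (polymer
    notation, R-groups, stray characters).  Counts are strictly positive;
    explicit zero counts are dropped.
    """

    counts: dict[str, int] = field(default_factory=dict)
    parse_status: str = "ok"

    def __bool__(self) -> bool:
        return self.parse_status == "ok"


def parse_formula(text: str | None) -> ElementMap:
    """Parse a Hill-notation elemental formula.

    Total on arbitrary input: unrecognisable text yields status
    ``unparseable`` and an empty map, never an exception.  ``None`` or an
    empty string yields status ``absent``.
    """
    if text is None or text == "":
        return ElementMap({}, "absent")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos or m.group(0) == "":
            return ElementMap({}, "unparseable")
        if m.group(1) not in ELEMENTS:
            return ElementMap({}, "unparseable")
        n = int(m.group(2)) if m.group(2) else 1
        if n > 0:
            counts[m.group(1)] = counts.get(m.group(1), 0) + n
        pos = m.end()
        if pos == len(text):
            break
    if pos != len(text):
        return ElementMap({}, "unparseable")
    return ElementMap(counts, "ok")


# ---------------------------------------------------------------------------
# entities
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None
    annotations: dict[str, list[str]] = field(default_factory=dict)
    sbo: str = "SBO:0000247"
    boundary: bool = False

    def element_map(self) -> ElementMap:
        return parse_formula(self.formula)

    @property
    def inchikey(self) -> str | None:
        keys = self.annotations.get("inchikey")
        return keys[0] if keys else None


@dataclass
class Gene:
    id: str
    artificial: bool = False
    localization: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        looks = bool(ARTIFICIAL_GENE_RE.match(self.id))
        if not self.artificial:
            self.artificial = looks
        elif not looks:
            raise ReconstructionError(
                f"gene {self.id!r} flagged artificial but id does not match "
                "the artificial prefixes (t/d/u/p/s/sk/gf + digits)"
            )


_GPR_SPLIT_RE = re.compile(r"[()\s]+")


def gpr_genes(gpr: str) -> frozenset[str]:
    """Gene ids referenced by a GPR string such as ``(g1 and g2) or g3``."""
    if not gpr:
        return frozenset()
    return frozenset(
        tok for tok in _GPR_SPLIT_RE.split(gpr) if tok and tok not in ("and", "or")
    )


def gpr_or_join(a: str, b: str) -> str:
    """OR-join two GPR expressions, keeping both verbatim."""
    if not a:
        return b
    if not b:
        return a
    if a == b:
        return a
    return f"({a}) or ({b})"


@dataclass
class Reaction:
    """One reaction: stoichiometry, bounds, GPR, provenance, category.

    ``reactants`` and ``products`` map metabolite ids to positive
    stoichiometric coefficients.  Flux bounds are in mmol gDW^-1 h^-1.
    Exchange reactions are written one-sided: an uptake has only products
    (boundary -> e), a production only reactants (e -> boundary).
    """

    id: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""
    provenance: set[str] = field(default_factory=set)
    category: str = "metabolic"
    sbo: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ReconstructionError(
                f"reaction {self.id!r}: unknown category {self.category!r}"
            )
        if not self.sbo:
            self.sbo = CATEGORY_SBO[self.category]

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def blocked(self) -> bool:
        return self.lower_bound == 0 and self.upper_bound == 0

    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)

    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.reactants) | frozenset(self.products)

    def stoichiometry_key(self) -> tuple:
        """Canonical (reactants, products) key for duplicate detection."""
        return (
            tuple(sorted((m, round(c, 9)) for m, c in self.reactants.items())),
            tuple(sorted((m, round(c, 9)) for m, c in self.products.items())),
        )

    def equation(self) -> str:
        def side(d: Mapping[str, float]) -> str:
            return " + ".join(
                (f"{c:g} {m}" if c != 1 else m) for m, c in sorted(d.items())
            )

        arrow = "<=>" if self.reversible else "-->"
        return f"{side(self.reactants)} {arrow} {side(self.products)}"

    def block(self, note: str | None = None) -> None:
        """Zero both bounds; knowledge is never deleted, only silenced."""
        self.lower_bound = 0.0
        self.upper_bound = 0.0
        if note:
            self.provenance.add(f"blocked:{note}")


@dataclass
class Reconstruction:
    """A knowledge network: metabolites, reactions, genes, compartments."""

    name: str = ""
    version: str = ""
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    compartments: dict[str, str] = field(
        default_factory=lambda: {"c": "intracellular", "e": "extracellular"}
    )

    # -- construction ------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ReconstructionError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ReconstructionError(
                f"metabolite {met.id!r}: compartment {met.compartment!r} "
                "not declared"
            )
        self.metabolites[met.id] = met
        return met

    def add_gene(self, gene: Gene) -> Gene:
        self.genes.setdefault(gene.id, gene)
        return self.genes[gene.id]

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ReconstructionError(f"duplicate reaction id {rxn.id!r}")
        missing = rxn.metabolite_ids() - set(self.metabolites)
        if missing:
            raise ReconstructionError(
                f"reaction {rxn.id!r} references unknown metabolites "
                f"{sorted(missing)}"
            )
        if rxn.lower_bound > rxn.upper_bound:
            raise ReconstructionError(
                f"reaction {rxn.id!r}: lower bound exceeds upper bound"
            )
        if not rxn.provenance:
            raise ReconstructionError(f"reaction {rxn.id!r}: empty provenance")
        for g in rxn.genes():
            self.add_gene(Gene(g))
        self.reactions[rxn.id] = rxn
        return rxn

    def next_artificial_gene(self, prefix: str) -> str:
        """Next free id in an artificial series, zero-padded to 3 digits."""
        taken = [
            int(g[len(prefix):])
            for g in self.genes
            if g.startswith(prefix) and g[len(prefix):].isdigit()
        ]
        return f"{prefix}{(max(taken) + 1 if taken else 1):03d}"

    # -- checks ------------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when consistent)."""
        problems = []
        for rxn in self.reactions.values():
            for m in rxn.metabolite_ids():
                if m not in self.metabolites:
                    problems.append(f"reaction {rxn.id}: unknown metabolite {m}")
            if rxn.lower_bound > rxn.upper_bound:
                problems.append(f"reaction {rxn.id}: lb > ub")
            if not rxn.provenance:
                problems.append(f"reaction {rxn.id}: empty provenance")
            for g in rxn.genes():
                if g not in self.genes:
                    problems.append(f"reaction {rxn.id}: unknown gene {g}")
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                problems.append(
                    f"metabolite {met.id}: undeclared compartment "
                    f"{met.compartment}"
                )
        return problems

    def copy(self) -> "Reconstruction":
        import copy as _copy

        return _copy.deepcopy(self)

    def reactions_sorted(self) -> list[Reaction]:
        return [self.reactions[r] for r in sorted(self.reactions)]

    def metabolites_sorted(self) -> list[Metabolite]:
        return [self.metabolites[m] for m in sorted(self.metabolites)]


# ---------------------------------------------------------------------------
# summary reporting
# ---------------------------------------------------------------------------


@dataclass
class SummaryReport:
    """Entity counts and metadata coverage of a reconstruction.

    ``n_metabolites_unique`` strips the trailing compartment suffix
    (``_c`` / ``_e``) before counting, the convention used when a network's
    "unique metabolites" are quoted independently of compartmentalisation.
    """

    n_metabolites: int = 0
    n_metabolites_unique: int = 0
    n_reactions: int = 0
    n_genes: int = 0
    n_artificial_genes: int = 0
    sbo_reactions: dict[str, int] = field(default_factory=dict)
    categories: dict[str, int] = field(default_factory=dict)
    annotation_coverage: dict[str, float] = field(default_factory=dict)

    def to_lines(self) -> list[str]:
        lines = [
            f"metabolites\t{self.n_metabolites}",
            f"metabolites (compartment-stripped)\t{self.n_metabolites_unique}",
            f"reactions\t{self.n_reactions}",
            f"genes\t{self.n_genes}",
            f"artificial genes\t{self.n_artificial_genes}",
        ]
        for cat in sorted(self.categories):
            lines.append(f"category {cat}\t{self.categories[cat]}")
        for sbo in sorted(self.sbo_reactions):
            lines.append(f"reaction {sbo}\t{self.sbo_reactions[sbo]}")
        for ns in sorted(self.annotation_coverage):
            lines.append(
                f"metabolite annotation {ns}\t"
                f"{self.annotation_coverage[ns]:.1%}"
            )
        return lines


def strip_compartment(met_id: str, compartments: Iterable[str]) -> str:
    for code in compartments:
        suffix = f"_{code}"
        if met_id.endswith(suffix):
            return met_id[: -len(suffix)]
    return met_id


def summarize(recon: Reconstruction) -> SummaryReport:
    """Tally entities, SBO terms, categories and annotation coverage."""
    rep = SummaryReport(
        n_metabolites=len(recon.metabolites),
        n_reactions=len(recon.reactions),
        n_genes=len(recon.genes),
        n_artificial_genes=sum(g.artificial for g in recon.genes.values()),
    )
    rep.n_metabolites_unique = len(
        {
            strip_compartment(m, recon.compartments)
            for m in recon.metabolites
        }
    )
    for rxn in recon.reactions.values():
        rep.sbo_reactions[rxn.sbo] = rep.sbo_reactions.get(rxn.sbo, 0) + 1
        rep.categories[rxn.category] = rep.categories.get(rxn.category, 0) + 1
    if recon.metabolites:
        ns_counts: dict[str, int] = {}
        for met in recon.metabolites.values():
            for ns, ids in met.annotations.items():
                if ids:
                    ns_counts[ns] = ns_counts.get(ns, 0) + 1
        n = len(recon.metabolites)
        rep.annotation_coverage = {ns: k / n for ns, k in ns_counts.items()}
    return rep
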