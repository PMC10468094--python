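"""From knowledge network to constraint-ready flux model.

Turning a reconstruction into a model that can be simulated requires an
exchange architecture at the system boundary, stoichiometric quality
control (elemental mass and charge balance of every reaction), a
reversibility policy for reactions of unknown direction, and screens for
the classic failure modes of draft models: mass leaks (a species producible
from nothing in a fully closed model), siphons (a species consumable into
nothing), and erroneous energy-generating cycles that charge energy
carriers without any nutrient input.

Three bound parameterisations of the same network are used throughout:

* ``closed``  - every uptake shut; nothing may enter the system.
* ``open``    - every uptake open at 10 mmol gDW^-1 h^-1.
* ``default`` - only the uptakes of a stated growth medium open, at their
  stated rates.

Curation never deletes a reaction: offenders are *blocked* by setting both
bounds to zero, so the knowledge network stays intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .netcore import (
    ElementMap,
    Gene,
    Metabolite,
    Reaction,
    Reconstruction,
    parse_formula,
)

__all__ = [
    "BalanceReport",
    "DirectionTable",
    "DissipationSet",
    "FluxModel",
    "MediumSpec",
    "apply_reversibility_policy",
    "build_exchange_layer",
    "check_balance",
    "derive_model",
    "detect_leaks_siphons",
    "energy_cycle_check",
    "DEFAULT_OPEN_BOUND",
    "UNLIMITED_BOUND",
]

DEFAULT_OPEN_BOUND = 10.0   # mmol gDW^-1 h^-1, the open-model uptake bound
UNLIMITED_BOUND = 1e6       # numeric stand-in for an unlimited uptake
FEASIBILITY_TOL = 1e-6
ZERO_FLUX_TOL = 1e-9

#: Categories evaluated but tagged exempt by the balance check: they cross
#: the system boundary or are lumped pseudo-reactions, so elemental balance
#: is not expected of them.
EXEMPT_CATEGORIES = {"uptake", "production", "demand", "sink", "biomass",
                     "atpm", "dissipation"}


# ---------------------------------------------------------------------------
# exchange architecture
# ---------------------------------------------------------------------------


def build_exchange_layer(
    recon: Reconstruction,
    importables: list[str],
    exportables: list[str],
    demands: list[str] | None = None,
    sinks: list[str] | None = None,
) -> Reconstruction:
    """Add the artificial boundary reactions of the model in place.

    Per importable extracellular metabolite one *uptake* (boundary -> e,
    gene ``u###``); per exportable one *production* (e -> boundary, gene
    ``p###``); per demand an irreversible external-to-intracellular
    transfer (gene ``d###``); per sink a reversible buffer (gene ``sk###``).
    Gene numbering is dense, deterministic and zero-padded.
    """
    for met_id in importables + exportables:
        met = recon.metabolites.get(met_id)
        if met is None:
            raise ValueError(f"unknown metabolite {met_id!r}")
        if met.compartment != "e":
            raise ValueError(
                f"{met_id!r} is not extracellular (compartment "
                f"{met.compartment!r})"
            )
    for met_id in sorted(importables):
        gid = recon.next_artificial_gene("u")
        recon.add_gene(Gene(gid))
        recon.add_reaction(Reaction(
            id=f"Uptake_{met_id}",
            products={met_id: 1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_OPEN_BOUND,
            gpr=gid,
            provenance={"artificial"},
            category="uptake",
        ))
    for met_id in sorted(exportables):
        gid = recon.next_artificial_gene("p")
        recon.add_gene(Gene(gid))
        recon.add_reaction(Reaction(
            id=f"Production_{met_id}",
            reactants={met_id: 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr=gid,
            provenance={"artificial"},
            category="production",
        ))
    for met_id in sorted(demands or []):
        inner = _intracellular_partner(recon, met_id)
        gid = recon.next_artificial_gene("d")
        recon.add_gene(Gene(gid))
        recon.add_reaction(Reaction(
            id=f"Demand_{met_id}",
            reactants={met_id: 1.0},
            products={inner: 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr=gid,
            provenance={"artificial"},
            category="demand",
        ))
    for met_id in sorted(sinks or []):
        gid = recon.next_artificial_gene("sk")
        recon.add_gene(Gene(gid))
        recon.add_reaction(Reaction(
            id=f"Sink_{met_id}",
            reactants={met_id: 1.0},
            lower_bound=-1000.0,
            upper_bound=1000.0,
            gpr=gid,
            provenance={"artificial"},
            category="sink",
        ))
    return recon


def _intracellular_partner(recon: Reconstruction, met_id: str) -> str:
    met = recon.metabolites[met_id]
    base = met_id[:-2] if met_id.endswith(f"_{met.compartment}") else met_id
    inner = f"{base}_c"
    if inner not in recon.metabolites:
        recon.add_metabolite(Metabolite(
            inner, met.name, "c", met.formula, met.charge,
            {ns: list(ids) for ns, ids in met.annotations.items()},
        ))
    return inner


# ---------------------------------------------------------------------------
# mass / charge balance
# ---------------------------------------------------------------------------


@dataclass
class BalanceReport:
    """Per-reaction elemental and charge residuals.

    ``mass_status[rid]`` is ``balanced`` (all element residuals zero),
    ``imbalanced`` or ``undetermined`` (some participant has an absent or
    unparseable formula).  Boundary and pseudo-reactions are evaluated but
    listed in ``exempt`` and excluded from the summary counts.
    """

    mass_status: dict[str, str] = field(default_factory=dict)
    mass_residuals: dict[str, dict[str, float]] = field(default_factory=dict)
    charge_status: dict[str, str] = field(default_factory=dict)
    charge_residuals: dict[str, float] = field(default_factory=dict)
    formula_status: dict[str, str] = field(default_factory=dict)
    exempt: set[str] = field(default_factory=set)

    def _count(self, table: dict[str, str], status: str) -> int:
        return sum(
            1 for rid, st in table.items()
            if st == status and rid not in self.exempt
        )

    @property
    def n_mass_imbalanced(self) -> int:
        return self._count(self.mass_status, "imbalanced")

    @property
    def n_mass_balanced(self) -> int:
        return self._count(self.mass_status, "balanced")

    @property
    def n_mass_undetermined(self) -> int:
        return self._count(self.mass_status, "undetermined")

    @property
    def n_charge_imbalanced(self) -> int:
        return self._count(self.charge_status, "imbalanced")

    @property
    def n_missing_formula(self) -> int:
        return sum(1 for st in self.formula_status.values() if st != "ok")

    def metabolites_in_balanced_only(self, recon: Reconstruction) -> int:
        """Metabolites that never take part in an imbalanced reaction."""
        tainted: set[str] = set()
        touched: set[str] = set()
        for rxn in recon.reactions.values():
            if rxn.id in self.exempt:
                continue
            touched |= rxn.metabolite_ids()
            if self.mass_status.get(rxn.id) == "imbalanced":
                tainted |= rxn.metabolite_ids()
        return len(touched - tainted)


def check_balance(recon: Reconstruction) -> BalanceReport:
    """Coefficient-weighted element and charge residuals per reaction.

    Residual = sum over products - sum over reactants; zero residuals in
    every element mean balanced.  Protons and water are *not* excluded:
    imbalance is reported raw, the policy decision of what to block is the
    caller's.
    """
    report = BalanceReport()
    elems: dict[str, ElementMap] = {}
    for met in recon.metabolites.values():
        em = parse_formula(met.formula)
        elems[met.id] = em
        report.formula_status[met.id] = em.parse_status
    for rxn in recon.reactions.values():
        if rxn.category in EXEMPT_CATEGORIES:
            report.exempt.add(rxn.id)
        residual: dict[str, float] = {}
        undetermined = False
        for side, sign in ((rxn.reactants, -1.0), (rxn.products, 1.0)):
            for met_id, coeff in side.items():
                em = elems[met_id]
                if em.parse_status != "ok":
                    undetermined = True
                    break
                for el, n in em.counts.items():
                    residual[el] = residual.get(el, 0.0) + sign * coeff * n
            if undetermined:
                break
        if undetermined:
            report.mass_status[rxn.id] = "undetermined"
        else:
            residual = {el: v for el, v in residual.items() if abs(v) > 1e-9}
            report.mass_residuals[rxn.id] = residual
            report.mass_status[rxn.id] = (
                "balanced" if not residual else "imbalanced"
            )
        q = 0.0
        q_undet = False
        for side, sign in ((rxn.reactants, -1.0), (rxn.products, 1.0)):
            for met_id, coeff in side.items():
                charge = recon.metabolites[met_id].charge
                if charge is None:
                    q_undet = True
                    break
                q += sign * coeff * charge
            if q_undet:
                break
        if q_undet:
            report.charge_status[rxn.id] = "undetermined"
        else:
            report.charge_residuals[rxn.id] = q
            report.charge_status[rxn.id] = (
                "balanced" if abs(q) <= 1e-9 else "imbalanced"
            )
    return report


# ---------------------------------------------------------------------------
# reversibility policy
# ---------------------------------------------------------------------------


@dataclass
class DirectionTable:
    """Curated direction labels for (a subset of) reversible reactions."""

    directions: dict[str, str] = field(default_factory=dict)

    LABELS = ("left_to_right", "right_to_left", "reversible", "unknown")

    def __post_init__(self) -> None:
        for rid, label in self.directions.items():
            if label not in self.LABELS:
                raise ValueError(f"{rid}: unknown direction label {label!r}")

    @classmethod
    def from_tsv(cls, path: str) -> "DirectionTable":
        directions = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rid, label = line.split("\t")[:2]
                directions[rid] = label
        return cls(directions)


def apply_reversibility_policy(
    recon: Reconstruction, table: DirectionTable
) -> Reconstruction:
    """Constrain reaction directions per the curated table (in place).

    ``left_to_right`` closes the lower bound, ``right_to_left`` the upper,
    ``unknown`` blocks the reaction entirely, ``reversible`` leaves it
    untouched.  Changes are logged on ``recon.direction_log``; table entries
    absent from the model are warnings, not errors.
    """
    log: list[str] = []
    for rid in sorted(table.directions):
        label = table.directions[rid]
        rxn = recon.reactions.get(rid)
        if rxn is None:
            log.append(f"WARNING {rid}: not in model, skipped")
            continue
        before = (rxn.lower_bound, rxn.upper_bound)
        if label == "left_to_right":
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        elif label == "right_to_left":
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
        elif label == "unknown":
            rxn.block("unknown_direction")
        if (rxn.lower_bound, rxn.upper_bound) != before:
            log.append(
                f"{rid}: {label} {before} -> "
                f"({rxn.lower_bound:g}, {rxn.upper_bound:g})"
            )
    recon.direction_log = log
    return recon


# ---------------------------------------------------------------------------
# flux model modes
# ---------------------------------------------------------------------------


@dataclass
class MediumSpec:
    """A growth medium as uptake openings.

    The canonical reference medium for fungal growth simulations: one
    carbon source at 15, one nitrogen source at 5, fixed cofactor uptakes
    (sulphur, riboflavin, thiamine, phosphate, iron) at
    10 mmol gDW^-1 h^-1, unlimited oxygen, everything else closed.
    """

    carbon: tuple[str, float] | None = None
    nitrogen: tuple[str, float] | None = None
    fixed: dict[str, float] = field(default_factory=dict)
    unlimited: list[str] = field(default_factory=list)
    extra_open: dict[str, float] = field(default_factory=dict)
    all_others_closed: bool = True

    def rates(self) -> dict[str, float]:
        rates: dict[str, float] = {}
        if self.carbon:
            rates[self.carbon[0]] = self.carbon[1]
        if self.nitrogen:
            rid, rate = self.nitrogen
            rates[rid] = max(rates.get(rid, 0.0), rate)
        rates.update(self.fixed)
        rates.update(self.extra_open)
        for rid in self.unlimited:
            rates[rid] = UNLIMITED_BOUND
        for rate in rates.values():
            if rate < 0:
                raise ValueError("medium rates must be >= 0")
        return rates


@dataclass
class FluxModel:
    """Reconstruction plus numeric bounds, an objective and a mode."""

    recon: Reconstruction
    objective: str
    mode: str = "default"

    def __post_init__(self) -> None:
        if self.objective not in self.recon.reactions:
            raise ValueError(f"objective {self.objective!r} not in model")

    def uptakes(self) -> list[Reaction]:
        return [
            r for r in self.recon.reactions_sorted() if r.category == "uptake"
        ]


def derive_model(
    recon: Reconstruction,
    mode: str,
    medium: MediumSpec | None = None,
    objective: str | None = None,
) -> FluxModel:
    """Parameterise the reconstruction's uptake bounds for a mode.

    ``closed``: every uptake (0, 0).  ``open``: every uptake
    (0, 10 mmol gDW^-1 h^-1).  ``default``: exactly the medium's uptakes
    open at their stated rates (an explicit medium is required).  The
    non-growth ATP maintenance reaction, if present, keeps its stored
    bounds in every mode.
    """
    if mode not in ("default", "open", "closed"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "default" and medium is None:
        raise ValueError("default mode requires a medium")
    out = recon.copy()
    if objective is None:
        biomass = [r.id for r in out.reactions.values()
                   if r.category == "biomass"]
        if len(biomass) != 1:
            raise ValueError(
                "objective not given and biomass reaction not unique"
            )
        objective = biomass[0]
    rates = medium.rates() if medium is not None else {}
    for rxn in out.reactions.values():
        if rxn.category != "uptake":
            continue
        if mode == "closed":
            rxn.upper_bound = 0.0
        elif mode == "open":
            rxn.upper_bound = DEFAULT_OPEN_BOUND
        else:
            if rxn.id in rates:
                rxn.upper_bound = rates[rxn.id]
            elif medium.all_others_closed:
                rxn.upper_bound = 0.0
        rxn.lower_bound = 0.0
    return FluxModel(out, objective, mode)


# ---------------------------------------------------------------------------
# leak / siphon detection
# ---------------------------------------------------------------------------


@dataclass
class LeakSiphonReport:
    leaks: frozenset[str]
    siphons: frozenset[str]

    @property
    def clean(self) -> bool:
        return not self.leaks and not self.siphons


def detect_leaks_siphons(model: FluxModel,
                         tol: float = FEASIBILITY_TOL) -> LeakSiphonReport:
    """Find species producible from (leak) or consumable into (siphon)
    nothing in the closed model.

    Metabolite *i* leaks when a flux exists with net production of *i*
    strictly positive and every other net zero; formulated as an LP with a
    unit-production relaxation variable (maximise y subject to
    S v - e_i y = 0, 0 <= y <= 1); *i* leaks iff the optimum exceeds the
    feasibility tolerance.  Siphons are symmetric.  Boundary-crossing
    columns (reactions with an empty reactant or product side, i.e.
    exchanges and lumped pseudo-reactions) are closed for the test:
    leaks and siphons are about generation or loss *inside* the network.
    """
    import numpy as np
    from scipy.optimize import linprog

    from .simulate import build_problem

    if model.mode != "closed":
        raise ValueError("leak/siphon detection expects a closed model")
    problem = build_problem(model)
    S = problem.S
    m, n = S.shape
    lbv, ubv = problem.lb.copy(), problem.ub.copy()
    for j, rid in enumerate(problem.reaction_ids):
        rxn = model.recon.reactions[rid]
        if not rxn.reactants or not rxn.products:
            lbv[j] = ubv[j] = 0.0
    leaks: set[str] = set()
    siphons: set[str] = set()
    bounds = list(zip(lbv, ubv)) + [(0.0, 1.0)]
    c = np.zeros(n + 1)
    c[-1] = -1.0  # maximise y
    for i, met_id in enumerate(problem.metabolite_ids):
        for sign, bucket in ((-1.0, leaks), (1.0, siphons)):
            col = np.zeros((m, 1))
            col[i, 0] = sign
            A = np.hstack([S, col])
            res = linprog(c, A_eq=A, b_eq=np.zeros(m), bounds=bounds,
                          method="highs")
            if res.status == 0 and -res.fun > tol:
                bucket.add(met_id)
    return LeakSiphonReport(frozenset(leaks), frozenset(siphons))


# ---------------------------------------------------------------------------
# energy-generating cycle screen
# ---------------------------------------------------------------------------

#: Canonical dissipation chemistry per energy carrier: consumed species ->
#: produced species (1:1 unless noted).  Species are resolved against the
#: model by alias matching on metabolite id stem and name; water, phosphate
#: and protons are attached when resolvable.
CARRIER_ALIASES: dict[str, dict] = {
    "ATP": {"consume": ["ATP", "WATER"], "produce": ["ADP", "Pi", "PROTON"]},
    "CTP": {"consume": ["CTP", "WATER"], "produce": ["CDP", "Pi", "PROTON"]},
    "GTP": {"consume": ["GTP", "WATER"], "produce": ["GDP", "Pi", "PROTON"]},
    "UTP": {"consume": ["UTP", "WATER"], "produce": ["UDP", "Pi", "PROTON"]},
    "ITP": {"consume": ["ITP", "WATER"], "produce": ["IDP", "Pi", "PROTON"]},
    "NADH": {"consume": ["NADH"], "produce": ["NAD", "PROTON"]},
    "NADPH": {"consume": ["NADPH"], "produce": ["NADP", "PROTON"]},
    "FADH2": {"consume": ["FADH2"], "produce": ["FAD", "PROTON"]},
    "FMNH2": {"consume": ["FMNH2"], "produce": ["FMN", "PROTON"]},
    "Ubiquinol-8": {"consume": ["UBIQUINOL-8"],
                    "produce": ["UBIQUINONE-8", "PROTON"]},
    "Acetyl-CoA": {"consume": ["ACETYL-COA", "WATER"],
                   "produce": ["ACETATE", "CO-A", "PROTON"]},
    "Glutamate": {"consume": ["GLT", "WATER"],
                  "produce": ["2-KETOGLUTARATE", "AMMONIUM"]},
    "Proton": {"consume": ["PROTON_E"], "produce": ["PROTON_C"]},
}

#: The 13 energy carriers screened by default.
DEFAULT_CARRIERS = (
    "ATP", "CTP", "GTP", "UTP", "ITP", "NADH", "NADPH", "FADH2", "FMNH2",
    "Ubiquinol-8", "Acetyl-CoA", "Glutamate", "Proton",
)

#: Optional co-species: skipped silently when unresolvable.
_OPTIONAL_SPECIES = {"WATER", "Pi", "PROTON"}


@dataclass
class DissipationSet:
    """Energy carriers to screen plus their resolved dissipation chemistry."""

    carriers: tuple[str, ...] = DEFAULT_CARRIERS
    aliases: dict[str, dict] = field(default_factory=lambda: CARRIER_ALIASES)


@dataclass
class EnergyCycleReport:
    optima: dict[str, float]
    flagged: frozenset[str]
    skipped: frozenset[str]


def _resolve_species(recon: Reconstruction, alias: str) -> str | None:
    alias_low = alias.lower()
    for met in recon.metabolites_sorted():
        stem = met.id.lower()
        for code in recon.compartments:
            if stem.endswith(f"_{code}"):
                stem = stem[: -(len(code) + 1)]
                break
        if stem == alias_low or met.name.lower() == alias_low:
            if alias.endswith("_E") and met.compartment != "e":
                continue
            if alias.endswith("_C") and met.compartment != "c":
                continue
            return met.id
    return None


def energy_cycle_check(
    model: FluxModel,
    dset: DissipationSet | None = None,
    tol: float = ZERO_FLUX_TOL,
) -> EnergyCycleReport:
    """Screen a closed model for erroneous energy-generating cycles.

    For each carrier a canonical dissipation reaction (hydrolysis or
    oxidation to its discharged form) is added, its flux maximised and then
    removed again; any optimum above tolerance flags the carrier, because a
    closed model must not charge an energy carrier from nothing.  Carriers
    whose species cannot be resolved are skipped with a warning entry.
    """
    from .simulate import fba

    if model.mode != "closed":
        raise ValueError("energy-cycle check expects a closed model")
    dset = dset or DissipationSet()
    optima: dict[str, float] = {}
    flagged: set[str] = set()
    skipped: set[str] = set()
    for carrier in dset.carriers:
        spec = dset.aliases.get(carrier)
        if spec is None:
            skipped.add(carrier)
            continue
        consume, produce = {}, {}
        unresolved_core = False
        for alias_list, bucket in ((spec["consume"], consume),
                                   (spec["produce"], produce)):
            for alias in alias_list:
                met_id = _resolve_species(model.recon, alias)
                if met_id is None:
                    if alias.split("_")[0] not in _OPTIONAL_SPECIES:
                        unresolved_core = True
                else:
                    bucket[met_id] = bucket.get(met_id, 0.0) + 1.0
        if unresolved_core or not consume:
            skipped.add(carrier)
            continue
        trial = model.recon.copy()
        rid = f"DISSIPATION_{carrier}"
        trial.add_reaction(Reaction(
            id=rid,
            reactants=consume,
            products=produce,
            lower_bound=0.0,
            upper_bound=1000.0,
            provenance={"artificial"},
            category="dissipation",
        ))
        sol = fba(FluxModel(trial, rid, model.mode))
        opt = sol.objective if sol.status == "optimal" else (
            float("inf") if sol.status == "unbounded" else 0.0
        )
        optima[carrier] = opt
        if opt > tol:
            flagged.add(carrier)
    return EnergyCycleReport(optima, frozenset(flagged), frozenset(skipped))
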