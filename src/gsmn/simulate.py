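"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA maximises an objective (usually the biomass pseudo-reaction, whose flux
is the growth-rate proxy) over steady-state flux vectors::

    max c.v   s.t.   S v = 0,   lb <= v <= ub

FVA reports, per reaction, the attainable flux minimum and maximum subject
to the objective staying at a stated fraction of its optimum; a reaction is
*active* when either end of its range clears the zero-flux tolerance.

On top of these two primitives sit the growth-media experiments: a media
matrix scanning carbon and nitrogen sources (amino acids doubling as both),
and the specialised-metabolite scan reporting the maximum attainable export
flux of each target compound at 80% biomass with pathway-specific
conditional uptakes opened.

All linear programs are assembled here and solved with HiGHS via
:func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .fluxmodel import (
    DEFAULT_OPEN_BOUND,
    FluxModel,
    MediumSpec,
    ZERO_FLUX_TOL,
    derive_model,
)

__all__ = [
    "FluxProblem",
    "FluxSolution",
    "FvaRange",
    "build_problem",
    "fba",
    "fva",
    "media_scan",
    "sm_scan",
]


@dataclass
class FluxProblem:
    """Numeric form of a flux model: S (metabolites x reactions), bounds,
    objective coefficients, and the id orderings tying them back."""

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    metabolite_ids: list[str]
    reaction_ids: list[str]


def build_problem(model: FluxModel) -> FluxProblem:
    recon = model.recon
    met_ids = sorted(recon.metabolites)
    rxn_ids = sorted(recon.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    c = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        rxn = recon.reactions[rid]
        for m, coeff in rxn.reactants.items():
            S[met_index[m], j] -= coeff
        for m, coeff in rxn.products.items():
            S[met_index[m], j] += coeff
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
    c[rxn_ids.index(model.objective)] = 1.0
    return FluxProblem(S, lb, ub, c, met_ids, rxn_ids)


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective: float = 0.0
    fluxes: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible",
           3: "unbounded", 4: "numerical"}


def _solve(problem: FluxProblem, c_extra=None,
           A_ub=None, b_ub=None) -> tuple[str, float, np.ndarray | None]:
    c = problem.c if c_extra is None else c_extra
    res = linprog(
        -c,
        A_eq=problem.S,
        b_eq=np.zeros(problem.S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(problem.lb, problem.ub)),
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return status, 0.0, None
    return "optimal", -res.fun, res.x


def fba(model: FluxModel) -> FluxSolution:
    """Maximise the model objective; infeasibility and unboundedness are
    reported as statuses, never raised."""
    problem = build_problem(model)
    status, obj, x = _solve(problem)
    if status != "optimal":
        return FluxSolution(status)
    return FluxSolution(
        "optimal", obj, dict(zip(problem.reaction_ids, x))
    )


@dataclass
class FvaRange:
    """Per-reaction flux (min, max) at a biomass fraction."""

    fraction: float
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def active(self, tol: float = ZERO_FLUX_TOL) -> frozenset[str]:
        return frozenset(
            rid for rid, (lo, hi) in self.ranges.items()
            if hi > tol or lo < -tol
        )


def fva(
    model: FluxModel,
    fraction: float = 1.0,
    reactions: list[str] | None = None,
) -> FvaRange:
    """Flux variability at ``objective >= fraction * optimum``.

    When the base optimum is zero the fraction constraint is vacuous and
    skipped.  An infeasible base problem is an error with diagnostics.
    """
    problem = build_problem(model)
    status, opt, _ = _solve(problem)
    if status != "optimal":
        raise ValueError(
            f"FVA base FBA is {status}; check bounds and medium "
            f"(objective {model.objective})"
        )
    A_ub = b_ub = None
    if opt > ZERO_FLUX_TOL and fraction > 0:
        A_ub = -problem.c[None, :]
        b_ub = np.array([-fraction * opt])
    targets = reactions if reactions is not None else problem.reaction_ids
    result = FvaRange(fraction)
    for rid in targets:
        j = problem.reaction_ids.index(rid)
        rxn = model.recon.reactions[rid]
        if rxn.blocked:
            result.ranges[rid] = (0.0, 0.0)
            continue
        e = np.zeros_like(problem.c)
        e[j] = 1.0
        _, hi, _ = _solve(problem, c_extra=e, A_ub=A_ub, b_ub=b_ub)
        _, neg_lo, _ = _solve(problem, c_extra=-e, A_ub=A_ub, b_ub=b_ub)
        result.ranges[rid] = (-neg_lo, hi)
    return result


# ---------------------------------------------------------------------------
# growth-media experiments
# ---------------------------------------------------------------------------

C_SOURCE_RATE = 15.0     # mmol gDW^-1 h^-1
N_SOURCE_RATE = 5.0
COFACTOR_RATE = 10.0
AA_DUAL_RATE = 15.0


def media_scan(
    model: FluxModel,
    reference: MediumSpec,
    c_sources: list[str] | None = None,
    n_sources: list[str] | None = None,
    aa_dual: list[str] | None = None,
    tol: float = ZERO_FLUX_TOL,
) -> dict[str, dict]:
    """Growth matrix over media conditions.

    For each candidate carbon source the reference nitrogen source is kept
    (and vice versa); an amino acid serving as both carbon and nitrogen
    source replaces both at 15 mmol gDW^-1 h^-1.  Fixed cofactor uptakes
    and unlimited oxygen come from the reference medium; all other uptakes
    are closed.  Conditions with no optimum above tolerance are recorded
    as no-growth.
    """
    known = {r.id for r in model.uptakes()}
    results: dict[str, dict] = {}

    def run(name: str, medium: MediumSpec) -> None:
        derived = derive_model(
            model.recon, "default", medium, objective=model.objective
        )
        sol = fba(derived)
        growth = sol.status == "optimal" and sol.objective > tol
        results[name] = {
            "status": sol.status,
            "objective": sol.objective if sol.status == "optimal" else 0.0,
            "growth": bool(growth),
        }

    def check(uptake_id: str) -> bool:
        if uptake_id not in known:
            results[uptake_id] = {"status": "skipped_unknown_uptake",
                                  "objective": 0.0, "growth": False}
            return False
        return True

    for src in c_sources or []:
        if check(src):
            run(f"C:{src}", MediumSpec(
                carbon=(src, C_SOURCE_RATE),
                nitrogen=reference.nitrogen,
                fixed=reference.fixed,
                unlimited=reference.unlimited,
            ))
    for src in n_sources or []:
        if check(src):
            run(f"N:{src}", MediumSpec(
                carbon=reference.carbon,
                nitrogen=(src, N_SOURCE_RATE),
                fixed=reference.fixed,
                unlimited=reference.unlimited,
            ))
    for src in aa_dual or []:
        if check(src):
            run(f"CN:{src}", MediumSpec(
                carbon=(src, AA_DUAL_RATE),
                nitrogen=None,
                fixed=reference.fixed,
                unlimited=reference.unlimited,
            ))
    return results


def sm_scan(
    model: FluxModel,
    sm_exchanges: list[str],
    fraction: float = 0.8,
    conditional_uptakes: list[str] | None = None,
    reference: MediumSpec | None = None,
) -> dict[str, dict]:
    """Maximum export flux of specialised-metabolite production reactions
    at a biomass fraction.

    The model runs on the reference medium with the pathway-specific
    conditional uptakes (e.g. decanoate, phenoxyacetate, a flavoprotein)
    additionally opened at 10 mmol gDW^-1 h^-1; a zero maximum means the
    compound is not producible under the condition.  Missing exchanges are
    flagged absent rather than dropped.
    """
    if reference is not None:
        medium = MediumSpec(
            carbon=reference.carbon,
            nitrogen=reference.nitrogen,
            fixed=dict(reference.fixed),
            unlimited=list(reference.unlimited),
            extra_open=dict(reference.extra_open),
        )
        for rid in conditional_uptakes or []:
            medium.extra_open[rid] = DEFAULT_OPEN_BOUND
        run_model = derive_model(
            model.recon, "default", medium, objective=model.objective
        )
    else:
        run_model = FluxModel(model.recon.copy(), model.objective, model.mode)
        for rid in conditional_uptakes or []:
            if rid in run_model.recon.reactions:
                run_model.recon.reactions[rid].upper_bound = (
                    DEFAULT_OPEN_BOUND
                )

    present = [r for r in sm_exchanges if r in run_model.recon.reactions]
    absent = [r for r in sm_exchanges if r not in run_model.recon.reactions]
    table: dict[str, dict] = {
        rid: {"status": "absent", "max_flux": None} for rid in absent
    }
    if present:
        ranges = fva(run_model, fraction=fraction, reactions=present)
        for rid in present:
            lo, hi = ranges[rid]
            table[rid] = {
                "status": "ok",
                "max_flux": hi,
                "producible": hi > ZERO_FLUX_TOL,
            }
    return table
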