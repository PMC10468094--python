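"""FBA/FVA correctness, including an independent cobrapy cross-check, and
the media-matrix / specialised-metabolite protocols."""

import pytest

from gsmn.fluxmodel import FluxModel, MediumSpec, derive_model
from gsmn.netcore import Metabolite, Reaction, Reconstruction
from gsmn.simulate import fba, fva, media_scan, sm_scan
from gsmn.synthetic_data import ToySpec, generate_toy, toy_biomass_model
from gsmn.topology import boundary_seeds, compute_scope
from tests.conftest import make_recon


def _linear_model(rate=10.0):
    recon = Reconstruction()
    recon.add_metabolite(Metabolite("x_e", compartment="e"))
    recon.add_metabolite(Metabolite("x_c"))
    recon.add_reaction(Reaction("Uptake_x", {}, {"x_e": 1.0}, 0, rate,
                                provenance={"a"}, category="uptake"))
    recon.add_reaction(Reaction("T_x", {"x_e": 1.0}, {"x_c": 1.0}, 0, 1000,
                                provenance={"a"}, category="transport"))
    recon.add_reaction(Reaction("BIOMASS", {"x_c": 1.0}, {}, 0, 1000,
                                provenance={"a"}, category="biomass"))
    return FluxModel(recon, "BIOMASS", "default")


class TestFba:
    def test_bound_limited_chain(self):
        sol = fba(_linear_model(10.0))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(10.0, abs=1e-6)
        assert sol["Uptake_x"] == pytest.approx(10.0, abs=1e-6)

    def test_limiting_substrate_sets_optimum(self):
        model, _ = toy_biomass_model([10.0, 10.0], [1.0, 2.0])
        sol = fba(model)
        assert sol.objective == pytest.approx(5.0, abs=1e-6)

    def test_infeasible_reported_as_status(self):
        model = _linear_model()
        model.recon.reactions["T_x"].lower_bound = 20.0  # force > uptake
        model.recon.reactions["T_x"].upper_bound = 30.0
        sol = fba(model)
        assert sol.status == "infeasible"

    def test_optimum_invariant_under_reversible_split(self):
        base = _linear_model()
        base.recon.reactions["T_x"].lower_bound = -1000.0
        split = base.recon.copy()
        rxn = split.reactions.pop("T_x")
        split.add_reaction(Reaction("T_fwd", dict(rxn.reactants),
                                    dict(rxn.products), 0, 1000,
                                    provenance={"a"}))
        split.add_reaction(Reaction("T_rev", dict(rxn.products),
                                    dict(rxn.reactants), 0, 1000,
                                    provenance={"a"}))
        assert fba(FluxModel(split, "BIOMASS", "default")).objective == \
            pytest.approx(fba(base).objective, abs=1e-6)

    def test_agrees_with_cobrapy_on_generated_toys(self):
        """Dual-route check: our LP assembly vs an independent COBRA
        implementation of the same model."""
        cobra = pytest.importorskip("cobra")

        for seed in (1, 2):
            recon, truth = generate_toy(ToySpec(rng_seed=seed))
            ours = fba(derive_model(recon, "open")).objective

            cm = cobra.Model("toy")
            mets = {m.id: cobra.Metabolite(m.id.replace("-", "__"))
                    for m in recon.metabolites.values()}
            for rxn in recon.reactions.values():
                cr = cobra.Reaction(rxn.id)
                cr.lower_bound = rxn.lower_bound
                cr.upper_bound = (10.0 if rxn.category == "uptake"
                                  else rxn.upper_bound)
                cm.add_reactions([cr])
                cr.add_metabolites(
                    {mets[m]: -c for m, c in rxn.reactants.items()})
                cr.add_metabolites(
                    {mets[m]: c for m, c in rxn.products.items()})
            cm.objective = "BIOMASS"
            theirs = cm.optimize().objective_value
            assert ours == pytest.approx(theirs, abs=1e-6)
            assert ours == pytest.approx(truth.fba_optimum, abs=1e-6)


class TestFva:
    def test_blocked_reaction_has_zero_range(self):
        model = _linear_model()
        model.recon.reactions["T_x"].block()
        # unblock growth via a second route so the base FBA stays feasible
        model.recon.add_reaction(Reaction(
            "T_alt", {"x_e": 1.0}, {"x_c": 1.0}, 0, 1000, provenance={"a"}))
        ranges = fva(model, fraction=0.5)
        assert ranges["T_x"] == (0.0, 0.0)

    def test_chain_collapses_to_fba_flux_at_fraction_one(self):
        model = _linear_model()
        sol = fba(model)
        ranges = fva(model, fraction=1.0)
        for rid, (lo, hi) in ranges.ranges.items():
            assert lo == pytest.approx(sol[rid], abs=1e-6)
            assert hi == pytest.approx(sol[rid], abs=1e-6)

    def test_nesting_in_the_fraction(self, toy):
        recon, _ = toy
        model = derive_model(recon, "open")
        loose = fva(model, fraction=0.3)
        tight = fva(model, fraction=0.9)
        for rid in loose.ranges:
            lo1, hi1 = loose[rid]
            lo2, hi2 = tight[rid]
            assert lo2 >= lo1 - 1e-7 and hi2 <= hi1 + 1e-7

    def test_flux_producible_implies_topologically_producible(self, toy):
        recon, _ = toy
        model = derive_model(recon, "open")
        scope = compute_scope(recon, boundary_seeds(recon)).producible
        ranges = fva(model, fraction=0.0)
        for rid in ranges.active():
            rxn = recon.reactions[rid]
            fwd_max = ranges[rid][1]
            produced = rxn.products if fwd_max > 1e-9 else rxn.reactants
            for met in produced:
                assert met in scope

    def test_infeasible_base_is_an_error(self):
        model = _linear_model()
        model.recon.reactions["T_x"].lower_bound = 20.0
        model.recon.reactions["T_x"].upper_bound = 30.0
        with pytest.raises(ValueError, match="infeasible"):
            fva(model)


def _media_toy():
    """Two-substrate toy: S0 is the carbon analogue (required), S1 the
    nitrogen analogue (required), S2 an unusable dead-end nutrient."""
    recon = Reconstruction()
    for i in range(3):
        recon.add_metabolite(Metabolite(f"S{i}_e", compartment="e"))
        recon.add_metabolite(Metabolite(f"S{i}_c"))
        recon.add_reaction(Reaction(f"Uptake_S{i}", {}, {f"S{i}_e": 1.0},
                                    0, 10, provenance={"a"},
                                    category="uptake"))
        recon.add_reaction(Reaction(f"T_S{i}", {f"S{i}_e": 1.0},
                                    {f"S{i}_c": 1.0}, 0, 1000,
                                    provenance={"a"}, category="transport"))
    # an amino-acid-like nutrient usable as C and N at once
    recon.add_metabolite(Metabolite("aa_e", compartment="e"))
    recon.add_metabolite(Metabolite("aa_c"))
    recon.add_reaction(Reaction("Uptake_aa", {}, {"aa_e": 1.0}, 0, 10,
                                provenance={"a"}, category="uptake"))
    recon.add_reaction(Reaction("T_aa", {"aa_e": 1.0}, {"aa_c": 1.0},
                                0, 1000, provenance={"a"},
                                category="transport"))
    recon.add_reaction(Reaction("AA_split", {"aa_c": 1.0},
                                {"S0_c": 1.0, "S1_c": 1.0}, 0, 1000,
                                provenance={"a"}))
    recon.add_reaction(Reaction("BIOMASS", {"S0_c": 1.0, "S1_c": 1.0}, {},
                                0, 1000, provenance={"a"},
                                category="biomass"))
    return recon


REFERENCE = MediumSpec(carbon=("Uptake_S0", 15.0),
                       nitrogen=("Uptake_S1", 5.0))


class TestMediaScan:
    def test_no_nitrogen_means_no_growth(self):
        recon = _media_toy()
        model = derive_model(recon, "default", REFERENCE)
        results = media_scan(model, REFERENCE, n_sources=["Uptake_S2"])
        assert results["N:Uptake_S2"]["growth"] is False

    def test_reference_sources_grow_and_rate_is_n_limited(self):
        recon = _media_toy()
        model = derive_model(recon, "default", REFERENCE)
        results = media_scan(model, REFERENCE,
                             c_sources=["Uptake_S0"],
                             n_sources=["Uptake_S1"])
        assert results["C:Uptake_S0"]["growth"] is True
        # nitrogen at 5 limits a 1:1 biomass
        assert results["C:Uptake_S0"]["objective"] == pytest.approx(5.0,
                                                                    abs=1e-6)

    def test_doubling_limiting_carbon_doubles_growth(self):
        recon = _media_toy()
        model = derive_model(recon, "default", REFERENCE)
        lo = MediumSpec(carbon=("Uptake_S0", 2.0),
                        nitrogen=("Uptake_S1", 50.0))
        hi = MediumSpec(carbon=("Uptake_S0", 4.0),
                        nitrogen=("Uptake_S1", 50.0))
        obj = [fba(derive_model(recon, "default", m,
                                objective="BIOMASS")).objective
               for m in (lo, hi)]
        assert obj[1] == pytest.approx(2 * obj[0], abs=1e-6)

    def test_amino_acid_as_dual_source(self):
        recon = _media_toy()
        model = derive_model(recon, "default", REFERENCE)
        results = media_scan(model, REFERENCE, aa_dual=["Uptake_aa"])
        entry = results["CN:Uptake_aa"]
        assert entry["growth"] is True
        # dual source at 15, 1:1 split feeds both demands
        assert entry["objective"] == pytest.approx(15.0, abs=1e-6)

    def test_unknown_uptake_skipped_and_logged(self):
        recon = _media_toy()
        model = derive_model(recon, "default", REFERENCE)
        results = media_scan(model, REFERENCE, c_sources=["Uptake_ghost"])
        assert results["Uptake_ghost"]["status"] == "skipped_unknown_uptake"


class TestSmScan:
    def _sm_toy(self):
        recon = _media_toy()
        # specialised metabolite needs a conditional precursor uptake
        recon.add_metabolite(Metabolite("prec_e", compartment="e"))
        recon.add_metabolite(Metabolite("prec_c"))
        recon.add_metabolite(Metabolite("sm_e", compartment="e"))
        recon.add_metabolite(Metabolite("sm_c"))
        recon.add_reaction(Reaction("Uptake_prec", {}, {"prec_e": 1.0},
                                    0, 0, provenance={"a"},
                                    category="uptake"))
        recon.add_reaction(Reaction("T_prec", {"prec_e": 1.0},
                                    {"prec_c": 1.0}, 0, 1000,
                                    provenance={"a"}, category="transport"))
        recon.add_reaction(Reaction("SM_SYN", {"prec_c": 1.0, "S0_c": 1.0},
                                    {"sm_c": 1.0}, 0, 1000,
                                    provenance={"a"}))
        recon.add_reaction(Reaction("T_sm", {"sm_c": 1.0}, {"sm_e": 1.0},
                                    0, 1000, provenance={"a"},
                                    category="transport"))
        recon.add_reaction(Reaction("Production_sm", {"sm_e": 1.0}, {},
                                    0, 1000, provenance={"a"},
                                    category="production"))
        return derive_model(recon, "default", REFERENCE)

    def test_conditional_uptake_gates_production(self):
        model = self._sm_toy()
        closed = sm_scan(model, ["Production_sm"], fraction=0.8,
                         conditional_uptakes=[], reference=REFERENCE)
        assert closed["Production_sm"]["max_flux"] == pytest.approx(0.0,
                                                                    abs=1e-9)
        opened = sm_scan(model, ["Production_sm"], fraction=0.8,
                         conditional_uptakes=["Uptake_prec"],
                         reference=REFERENCE)
        assert opened["Production_sm"]["max_flux"] > 0.1
        assert opened["Production_sm"]["producible"]

    def test_missing_exchange_flagged_absent(self):
        model = self._sm_toy()
        table = sm_scan(model, ["Production_ghost"], reference=REFERENCE)
        assert table["Production_ghost"]["status"] == "absent"

    def test_fraction_zero_equals_unconstrained_fva(self):
        model = self._sm_toy()
        at_zero = sm_scan(model, ["Production_sm"], fraction=0.0,
                          conditional_uptakes=["Uptake_prec"],
                          reference=REFERENCE)
        medium = MediumSpec(carbon=REFERENCE.carbon,
                            nitrogen=REFERENCE.nitrogen,
                            extra_open={"Uptake_prec": 10.0})
        unconstrained = fva(
            derive_model(model.recon, "default", medium,
                         objective="BIOMASS"),
            fraction=0.0, reactions=["Production_sm"])
        assert at_zero["Production_sm"]["max_flux"] == pytest.approx(
            unconstrained["Production_sm"][1], abs=1e-6)
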