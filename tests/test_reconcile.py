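"""Subnetwork merging, external admission, duplicates, InChIKey overlap."""

import itertools
import random

import pytest

from gsmn.fluxmodel import check_balance
from gsmn.netcore import Metabolite, Reaction, Reconstruction
from gsmn.reconcile import (
    IdMap,
    MergeConflictError,
    SourceTag,
    admit_external_reaction,
    compare_reconstructions,
    find_duplicate_pairs,
    inchikey_tier,
    merge_networks,
    resolve_duplicates,
)
from tests.conftest import make_recon, random_network


TAG = SourceTag("orthology", "template1")


class TestMerge:
    def test_merge_with_empty_is_identity(self):
        base = make_recon({"r1": ({"a_c": 1}, {"b_c": 1})})
        merged = merge_networks(base, Reconstruction(), TAG)
        assert merged.reactions["r1"].provenance == {"annotation"}
        assert set(merged.reactions) == {"r1"}

    def test_shared_reaction_carries_both_tags_and_or_joined_gpr(self):
        a = make_recon({"r1": ({"a_c": 1}, {"b_c": 1}),
                        "r2": ({"b_c": 1}, {"c_c": 1})})
        b = make_recon({"r2": ({"b_c": 1}, {"c_c": 1}),
                        "r3": ({"c_c": 1}, {"d_c": 1})})
        a.reactions["r2"].gpr = "g1"
        b.reactions["r2"].gpr = "g2"
        merged = merge_networks(a, b, TAG)
        assert set(merged.reactions) == {"r1", "r2", "r3"}
        assert str(TAG) in merged.reactions["r2"].provenance
        assert "annotation" in merged.reactions["r2"].provenance
        assert merged.reactions["r2"].genes() == {"g1", "g2"}
        assert " or " in merged.reactions["r2"].gpr

    def test_self_merge_keeps_structure_and_adds_tag(self):
        a = make_recon({"r1": ({"a_c": 1}, {"b_c": 1})})
        merged = merge_networks(a, a, SourceTag("external", "again"))
        assert set(merged.reactions) == set(a.reactions)
        assert "external:again" in merged.reactions["r1"].provenance

    def test_bounds_conflict_widens(self):
        a = make_recon({"r1": ({"a_c": 1}, {"b_c": 1})})
        b = make_recon({"r1": ({"a_c": 1}, {"b_c": 1})}, reversible={"r1"})
        merged = merge_networks(a, b, TAG)
        assert merged.reactions["r1"].lower_bound == -1000.0
        assert merged.reactions["r1"].upper_bound == 1000.0

    def test_stoichiometry_conflict_raises_with_both_equations(self):
        a = make_recon({"r1": ({"a_c": 1}, {"b_c": 1})})
        b = make_recon({"r1": ({"a_c": 2}, {"b_c": 1})})
        with pytest.raises(MergeConflictError) as err:
            merge_networks(a, b, TAG)
        assert "a_c" in str(err.value) and "2 a_c" in str(err.value)

    def test_merge_associative_on_entity_sets(self):
        nets = [
            make_recon({"r1": ({"a_c": 1}, {"b_c": 1})}),
            make_recon({"r2": ({"b_c": 1}, {"c_c": 1})}),
            make_recon({"r1": ({"a_c": 1}, {"b_c": 1}),
                        "r3": ({"c_c": 1}, {"d_c": 1})}),
        ]
        t = SourceTag("external", "x")
        left = merge_networks(merge_networks(nets[0], nets[1], t), nets[2], t)
        right = merge_networks(nets[0], merge_networks(nets[1], nets[2], t), t)
        assert set(left.reactions) == set(right.reactions)
        assert set(left.metabolites) == set(right.metabolites)
        assert set(left.genes) == set(right.genes)


class TestAdmission:
    @pytest.fixture
    def idmap(self):
        return IdMap(entries={"ext:R9": "RXN-9", "x_c": "X-c", "y_c": "Y-c"},
                     reference_ids={"RXN-1702", "X-c", "Y-c"})

    def _rxn(self, rid, gpr="gene1"):
        return Reaction(rid, {"x_c": 1}, {"y_c": 1}, 0, 1000, gpr=gpr,
                        provenance={"external:src"})

    def test_recognised_id_with_gene_admitted_mapped(self, idmap):
        d = admit_external_reaction(self._rxn("RXN-1702"), idmap,
                                    Reconstruction())
        assert d.decision == "admit_mapped" and d.mapped_id == "RXN-1702"
        d = admit_external_reaction(self._rxn("ext:R9"), idmap,
                                    Reconstruction())
        assert d.decision == "admit_mapped" and d.mapped_id == "RXN-9"

    def test_unrecognised_id_all_species_mapped_keeps_original_id(self, idmap):
        d = admit_external_reaction(self._rxn("homemade:1"), idmap,
                                    Reconstruction())
        assert d.decision == "admit_original_id"
        assert d.mapped_id == "homemade:1"

    def test_unmapped_species_rejected_with_reason(self, idmap):
        rxn = Reaction("homemade:2", {"x_c": 1, "z_c": 1}, {"y_c": 1},
                       0, 1000, gpr="gene1", provenance={"external:src"})
        d = admit_external_reaction(rxn, idmap, Reconstruction())
        assert d.decision == "reject" and "z_c" in d.reason

    def test_missing_gpr_rejected(self, idmap):
        d = admit_external_reaction(self._rxn("RXN-1702", gpr=""), idmap,
                                    Reconstruction())
        assert d.decision == "reject" and d.reason == "no_gpr"


class TestDuplicates:
    def test_identical_equation_two_ids(self):
        recon = make_recon({"r1": ({"a_c": 1}, {"b_c": 1}),
                            "r2": ({"a_c": 1}, {"b_c": 1})})
        recon.reactions["r1"].gpr = recon.reactions["r2"].gpr = "g1"
        (pair,) = find_duplicate_pairs(recon)
        assert (pair.a, pair.b) == ("r1", "r2")
        assert pair.relation == "same_direction"
        assert pair.gpr_relation == "identical"

    def test_swapped_sides_are_opposite_direction(self):
        recon = make_recon({"r1": ({"a_c": 1}, {"b_c": 1}),
                            "r2": ({"b_c": 1}, {"a_c": 1})})
        (pair,) = find_duplicate_pairs(recon)
        assert pair.relation == "opposite_direction"

    def test_different_coefficients_are_not_duplicates(self):
        recon = make_recon({"r1": ({"a_c": 1}, {"b_c": 1}),
                            "r2": ({"a_c": 2}, {"b_c": 1})})
        assert find_duplicate_pairs(recon) == []

    def test_agrees_with_brute_force_on_random_networks(self):
        rng = random.Random(7)
        for _ in range(10):
            recon = random_network(rng, n_reactions=40, n_metabolites=8)
            got = {(p.a, p.b) for p in find_duplicate_pairs(recon)}
            expected = set()
            for ra, rb in itertools.combinations(
                    sorted(recon.reactions.values(), key=lambda r: r.id), 2):
                ka, kb = ra.stoichiometry_key(), rb.stoichiometry_key()
                if ka == kb or ka == (kb[1], kb[0]):
                    expected.add((ra.id, rb.id))
            assert got == expected

    def _balanced_pair(self, make_b_unbalanced=False, gpr_b="g1"):
        recon = Reconstruction()
        recon.add_metabolite(Metabolite("a_c", formula="C2H4"))
        recon.add_metabolite(Metabolite("b_c", formula="C2H4"))
        coeff = 2.0 if make_b_unbalanced else 1.0
        recon.add_reaction(Reaction("RXN-1", {"a_c": 1}, {"b_c": 1}, 0, 1000,
                                    gpr="g1", provenance={"annotation"}))
        recon.add_reaction(Reaction("homemade-1", {"a_c": 1}, {"b_c": coeff},
                                    0, 1000, gpr=gpr_b,
                                    provenance={"external:old"}))
        return recon

    def test_unbalanced_member_blocked(self):
        """The balance rule dominates the reference-id rule: when only one
        member is balanced it is kept even with the 'homemade' id.  Pairs
        from find_duplicate_pairs always share balance status (identical
        stoichiometry), so the pair is supplied externally here."""
        recon = self._balanced_pair()
        pairs = find_duplicate_pairs(recon)
        balance = check_balance(recon)
        balance.mass_status["RXN-1"] = "imbalanced"  # curator's verdict
        out = resolve_duplicates(recon, pairs, balance)
        assert out.reactions["RXN-1"].blocked
        assert not out.reactions["homemade-1"].blocked

    def test_homemade_id_blocked_when_both_balanced(self):
        recon = self._balanced_pair()
        out = resolve_duplicates(recon, find_duplicate_pairs(recon),
                                 check_balance(recon))
        assert out.reactions["homemade-1"].blocked
        assert not out.reactions["RXN-1"].blocked

    def test_disjoint_gprs_not_blocked_but_flagged(self):
        recon = self._balanced_pair(gpr_b="g2")
        out = resolve_duplicates(recon, find_duplicate_pairs(recon),
                                 check_balance(recon))
        assert not out.reactions["homemade-1"].blocked
        assert not out.reactions["RXN-1"].blocked
        assert len(out.review_pairs) == 1

    def test_resolution_never_removes_entities(self, defective_toy):
        recon, truth = defective_toy
        out = resolve_duplicates(recon, find_duplicate_pairs(recon),
                                 check_balance(recon))
        assert set(out.reactions) == set(recon.reactions)
        assert set(out.metabolites) == set(recon.metabolites)
        for orig, dup in truth.duplicate_pairs:
            assert out.reactions[dup].blocked
            assert not out.reactions[orig].blocked


K1 = "WQZGKKKJIJFFOK-GASJEMHNSA-N"
K2 = "WQZGKKKJIJFFOK-GASJEMHNSA-M"   # last char differs
K3 = "WQZGKKKJIJFFOK-AAAAAAAAAA-N"   # only first block shared
K4 = "AAAAAAAAAAAAAA-GASJEMHNSA-N"   # nothing shared (first block)


class TestInchikey:
    @pytest.mark.parametrize("a, b, tier", [
        (K1, K1, 3), (K1, K2, 2), (K1, K3, 1), (K1, K4, 0),
    ])
    def test_tiers(self, a, b, tier):
        assert inchikey_tier(a, b) == tier
        assert inchikey_tier(b, a) == tier

    def test_malformed_key_names_offender(self):
        with pytest.raises(ValueError, match="not-a-key"):
            inchikey_tier("not-a-key", K1)

    def _with_keys(self, keys):
        recon = Reconstruction()
        for i, key in enumerate(keys):
            ann = {"inchikey": [key]} if key else {}
            recon.add_metabolite(Metabolite(f"m{i}_c", annotations=ann))
        return recon

    def test_identical_models_have_no_exclusives(self):
        a = self._with_keys([K1, K3])
        rep = compare_reconstructions(a, a, key="inchikey_tier1")
        assert rep.exclusive_a == rep.exclusive_b == 0

    def test_disjoint_key_sets_share_nothing(self):
        rep = compare_reconstructions(
            self._with_keys([K1]), self._with_keys([K4]),
            key="inchikey_tier1")
        assert rep.shared == 0
        assert rep.exclusive_a == rep.exclusive_b == 1

    def test_symmetry_and_unkeyed_are_incomparable(self):
        a = self._with_keys([K1, K2, None])   # K1/K2 collapse at tier 1
        b = self._with_keys([K1, K4])
        ab = compare_reconstructions(a, b, key="inchikey_tier1")
        ba = compare_reconstructions(b, a, key="inchikey_tier1")
        assert ab.shared == ba.shared == 1
        assert ab.incomparable_a == 1 and ab.exclusive_a == 0
        assert ab.total_a == 1  # two keyed metabolites, one comparison unit
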