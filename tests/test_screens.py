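"""Decomposition, supplementation, knockout, and minimal-set screens."""

from itertools import combinations

import pandas as pd
import pytest

from cometab.core import DietSpec, FluxOutcome, delete_reactions
from cometab.screens import (
    annotate_reactions_with_genes,
    decompose_contributions,
    diet_supplementation_screen,
    find_minimal_deletion_set,
    high_secretion_metabolites,
    single_knockout_screen,
)
from cometab.synth import (
    HOST_KO_CANDIDATES,
    PLANTED_MINIMAL_SET,
    SUPPLEMENT_CANDIDATES,
)
from cometab.wholebody import HostModel, max_urine_secretion


class TestDecompose:
    def test_identity_holds_by_construction(self, male_host, two_species_community, hdiet):
        rec = decompose_contributions(male_host, two_species_community, hdiet, "for")
        assert rec.delta == pytest.approx(
            rec.urine_max_personalised - rec.urine_max_germfree, abs=1e-9
        )
        assert rec.co_metabolism_excess == pytest.approx(
            rec.delta - rec.microbial_secretion, abs=1e-9
        )
        assert rec.delta >= -1e-6

    def test_serine_community_shows_co_metabolism(self, male_host, serine_community, hdiet):
        """The community secretes no formate, yet the personalised urine
        maximum rises: the host turns microbial serine into formate."""
        rec = decompose_contributions(male_host, serine_community, hdiet, "for")
        assert rec.microbial_secretion == pytest.approx(0.0, abs=1e-6)
        assert rec.delta > 1.0
        assert rec.co_metabolism_excess > 1.0
        assert rec.has_co_metabolism

    def test_formate_community_excess_near_zero(self, male_host, two_species_community, hdiet):
        """With a direct formate secreter present, the bridge can carry
        roughly the whole personalised gain."""
        rec = decompose_contributions(male_host, two_species_community, hdiet, "for")
        assert rec.microbial_secretion > 0
        assert rec.co_metabolism_excess < 0.05 * rec.microbial_secretion


class TestHighSecretion:
    def _sol(self, bridges):
        return FluxOutcome(status="optimal", objective_value=0.0,
                           fluxes={f"Bridge_{k}": v for k, v in bridges.items()})

    def test_all_zero_gives_empty(self):
        sols = [self._sol({"ser_L": 0.0, "ac": 0.0})]
        assert high_secretion_metabolites(sols) == []

    def test_threshold_semantics(self):
        sols = [
            self._sol({"ser_L": 50, "gly": 35, "ac": 15, "for": 100}),
            self._sol({"ser_L": 30, "gly": 45, "ac": 5, "for": 100}),
        ]
        out = high_secretion_metabolites(sols, threshold=30.0, exclude="for")
        assert out == ["gly", "ser_L"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            high_secretion_metabolites([])


@pytest.fixture(scope="module")
def records(male_host, hdiet):
    return diet_supplementation_screen(male_host, hdiet, SUPPLEMENT_CANDIDATES, "for")


@pytest.fixture(scope="module")
def screen(male_host, hdiet):
    return single_knockout_screen(male_host, hdiet, HOST_KO_CANDIDATES, "for")


class TestSupplementation:
    def test_monotone_never_negative(self, records):
        for r in records:
            if r.percent_change is not None:
                assert r.percent_change >= -1e-9

    def test_nine_candidates_with_routes_positive(self, records):
        positive = {r.perturbation_id for r in records if r.percent_change and r.percent_change > 0}
        assert positive == {"ser_L", "gly", "trp_L", "cys_L", "tyr_L", "orn", "glc_D", "nh4", "meoh"}

    def test_nitrogen_only_ammonium_positive(self, records):
        nh4 = next(r for r in records if r.perturbation_id == "nh4")
        assert nh4.percent_change > 0

    def test_routeless_candidates_unchanged(self, records):
        for met in ("ac", "lac_D", "his_L", "succ", "etoh"):
            rec = next(r for r in records if r.perturbation_id == met)
            assert rec.percent_change == pytest.approx(0.0, abs=1e-9)

    def test_already_unconstrained_candidate_no_change(self, male_host, hdiet):
        rich = hdiet.with_entry("trp_L", 300.0)
        recs = diet_supplementation_screen(male_host, rich, ["trp_L"], "for")
        assert recs[0].percent_change == pytest.approx(0.0, abs=1e-9)

    def test_candidate_without_exchange_flagged(self, male_host, hdiet):
        recs = diet_supplementation_screen(male_host, hdiet, ["ghost_met"], "for")
        assert recs[0].flag == "not_applicable"

    def test_supplement_values_match_oracle_resolve(self, male_host, hdiet):
        """Independent re-solve: same diet edit applied by hand."""
        for met in ("ser_L", "nh4", "ac"):
            rec = diet_supplementation_screen(male_host, hdiet, [met], "for")[0]
            by_hand = max_urine_secretion(male_host, "for", hdiet.with_entry(met, 300.0))
            assert rec.perturbed == pytest.approx(by_hand, abs=1e-6)


class TestKnockoutScreen:
    def test_reductions_match_oracle_resolves(self, male_host, hdiet, screen):
        records, _ = screen
        baseline = max_urine_secretion(male_host, "for", hdiet)
        for rec in records[::4]:  # spot-check a quarter of them independently
            host_ko = HostModel(delete_reactions(male_host.model, [rec.perturbation_id]), "male")
            val = max_urine_secretion(host_ko, "for", hdiet)
            assert rec.perturbed == pytest.approx(val, abs=1e-6)
            assert rec.percent_change == pytest.approx(100 * (val - baseline) / baseline, abs=1e-6)

    def test_redundant_isoforms_unflagged(self, screen):
        _, flagged = screen
        for dup in ("SHMT", "SHMTm", "MTHFD", "FALDH", "FALDH2", "FKYNH", "FKYNH2"):
            assert dup not in flagged

    def test_endpoints_flagged(self, screen):
        _, flagged = screen
        for rid in PLANTED_MINIMAL_SET:
            assert rid in flagged

    def test_reaction_off_formate_paths_unchanged(self, male_host, hdiet):
        records, _ = single_knockout_screen(male_host, hdiet, ["ABS_ac"], "for")
        assert records[0].percent_change == pytest.approx(0.0, abs=1e-9)

    def test_zero_baseline_is_error(self, male_host):
        with pytest.raises(RuntimeError, match="baseline"):
            single_knockout_screen(male_host, DietSpec({}), ["PSP_L"], "for")

    def test_deletion_monotonicity(self, male_host, hdiet):
        """Reduction of a pair is at least the best of its singletons."""
        baseline = max_urine_secretion(male_host, "for", hdiet)

        def red(subset):
            h = HostModel(delete_reactions(male_host.model, list(subset)), "male")
            return 100 * (baseline - max_urine_secretion(h, "for", hdiet)) / baseline

        picks = ["PSP_L", "SFGTH", "TRPO2", "CHOLOX"]
        singles = {r: red((r,)) for r in picks}
        for a, b in combinations(picks, 2):
            assert red((a, b)) >= max(singles[a], singles[b]) - 1e-6


class TestMinimalSet:
    def test_target_zero_returns_empty(self, male_host, hdiet):
        res = find_minimal_deletion_set(male_host, hdiet, ["PSP_L"], "for", reduction_target_pct=0)
        assert res.found and res.reactions == ()

    def test_single_total_knockout_found_as_singleton(self, male_host, hdiet):
        res = find_minimal_deletion_set(
            male_host, hdiet, ["FORt_u", "PSP_L"], "for", reduction_target_pct=99.0
        )
        assert res.found and res.reactions == ("FORt_u",)

    def test_planted_four_set_recovered(self, male_host, hdiet):
        _, flagged = single_knockout_screen(male_host, hdiet, HOST_KO_CANDIDATES, "for")
        res = find_minimal_deletion_set(male_host, hdiet, flagged, "for",
                                        reduction_target_pct=85.0, max_size=4)
        assert res.found
        assert res.reactions == PLANTED_MINIMAL_SET
        assert res.reduction_pct >= 85.0

    def test_not_found_result_is_explicit(self, male_host, hdiet):
        res = find_minimal_deletion_set(
            male_host, hdiet, ["CYSCAT", "ORNCAT"], "for", reduction_target_pct=85.0, max_size=2
        )
        assert not res.found
        assert res.reactions == ()

    def test_greedy_labelled_heuristic(self, male_host, hdiet):
        res = find_minimal_deletion_set(
            male_host, hdiet, list(PLANTED_MINIMAL_SET), "for",
            reduction_target_pct=85.0, method="greedy",
        )
        assert res.method == "greedy"
        assert res.found
        assert set(res.reactions) == set(PLANTED_MINIMAL_SET)

    def test_empty_candidates_rejected(self, male_host, hdiet):
        with pytest.raises(ValueError):
            find_minimal_deletion_set(male_host, hdiet, [], "for")


class TestGeneAnnotation:
    def _tables(self):
        gene_map = pd.DataFrame(
            {
                "reaction_id": ["R1", "R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8", "R9"],
                "gene": ["g1", "g2", "g3", "g4", "g5", "g6", "g7", "g8", "g9", "g10"],
            }
        )
        assoc = pd.DataFrame(
            {
                "gene": ["g1", "g3", "g5", "g7", "g9", "g11"],
                "association": ["AD"] * 6,
                "direction": ["up", "down", "up", "up", "down", "up"],
            }
        )
        return gene_map, assoc

    def test_counts_match_hand_join(self):
        gene_map, assoc = self._tables()
        reactions = [f"R{i}" for i in range(1, 11)]
        table, counts = annotate_reactions_with_genes(reactions, gene_map, assoc,
                                                      flagged_ids=["R1", "R2", "R10"])
        # hand-joined: R1(g1), R2(g3), R4(g5), R6(g7), R8(g9) associated
        assert counts == {"n_reactions": 10, "n_associated": 5, "n_associated_and_flagged": 2}
        assert table.set_index("reaction_id").loc["R10", "genes"] == "no gene"

    def test_empty_association_table(self):
        gene_map, _ = self._tables()
        assoc = pd.DataFrame({"gene": [], "association": []})
        _, counts = annotate_reactions_with_genes(["R1"], gene_map, assoc)
        assert counts["n_associated"] == 0

    def test_single_hit(self):
        gene_map = pd.DataFrame({"reaction_id": ["R1"], "gene": ["g1"]})
        assoc = pd.DataFrame({"gene": ["g1"], "association": ["AD"]})
        _, counts = annotate_reactions_with_genes(["R1"], gene_map, assoc)
        assert counts["n_associated"] == 1
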