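"""Media application, differential biomass, starvation and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemflux import (
    DifferentialReport,
    MediumSpec,
    ReactionChange,
    UndefinedBaselineError,
    apply_medium,
    assemble_problem,
    carbon_source_comparison,
    differential_biomass,
    make_branched,
    make_chain,
    make_random_model,
    make_starvation_toy,
    medium_from_model,
    preferred_carbon_source,
    rank_differential_reactions,
    read_medium,
    solve_fba,
    starvation_experiment,
    write_medium,
)


class TestApplyMedium:
    def test_single_entry_medium_sets_growth(self):
        model, _ = make_chain(2, 99.0)  # native cap irrelevant once medium applied
        conditioned = apply_medium(model, MediumSpec({"EX_M0": (-10.0, 0.0)}))
        sol = solve_fba(assemble_problem(conditioned))
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_empty_medium_closes_all_uptakes(self):
        model, _ = make_branched()
        conditioned = apply_medium(model, MediumSpec({}, name="empty"))
        sol = solve_fba(assemble_problem(conditioned))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_original_model_untouched(self):
        model, _ = make_chain(2, 10.0)
        before = model.get_reaction("EX_M0").lower_bound
        apply_medium(model, MediumSpec({"EX_M0": (-1.0, 0.0)}))
        assert model.get_reaction("EX_M0").lower_bound == before

    def test_unknown_id_suggests_near_matches(self):
        model, _ = make_chain(2, 10.0)
        with pytest.raises(ValueError, match="EX_M0"):
            apply_medium(model, MediumSpec({"EX_M00": (-1.0, 0.0)}))

    def test_non_exchange_id_rejected(self):
        model, _ = make_chain(2, 10.0)
        with pytest.raises(ValueError, match="not an exchange"):
            apply_medium(model, MediumSpec({"R1": (-1.0, 0.0)}))

    def test_medium_file_round_trip(self, tmp_path):
        spec = MediumSpec({"EX_a": (-10.0, 0.0), "EX_b": (-5.0, 100.0)}, name="m")
        path = tmp_path / "m.tsv"
        write_medium(spec, path)
        assert read_medium(path).entries == spec.entries

    def test_shipped_default_medium_parses(self):
        from importlib import resources

        with resources.as_file(
            resources.files("gemflux") / "data" / "default_medium.tsv"
        ) as path:
            medium = read_medium(path)
        assert medium.entries["EX_glc_e"] == (-10.0, 0.0)
        assert len(medium.entries) == 4


class TestDifferentialBiomass:
    @pytest.mark.parametrize(
        "g_with, g_without, expected",
        [(1.0, 0.679, -32.1), (10.0, 13.0, 30.0), (5.5, 5.5, 0.0)],
    )
    def test_formula(self, g_with, g_without, expected):
        assert differential_biomass(g_with, g_without) == pytest.approx(expected, abs=1e-9)

    def test_tiny_baseline_is_undefined(self):
        with pytest.raises(UndefinedBaselineError):
            differential_biomass(1e-9, 5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        g=st.floats(0.01, 1e3),
        g2=st.floats(0.0, 1e3),
        k=st.floats(0.01, 1e4),
    )
    def test_invariant_under_common_scaling(self, g, g2, k):
        assert differential_biomass(k * g, k * g2) == pytest.approx(
            differential_biomass(g, g2), rel=1e-9, abs=1e-9
        )


class TestStarvationExperiment:
    def test_constructed_reduction_is_recovered(self):
        for prim, alt, cap in [(1.0, 0.679, 10.0), (2.0, 1.0, 5.0), (1.0, 0.25, 8.0)]:
            model, spec = make_starvation_toy(prim, alt, cap)
            report = starvation_experiment(
                model, medium_from_model(model), spec.ground_truth["primary_exchange"]
            )
            assert report.ok
            assert report.biomass_change_pct == pytest.approx(
                -spec.ground_truth["reduction_pct"], abs=1e-6
            )

    def test_removing_unused_nutrient_changes_nothing(self):
        model, spec = make_starvation_toy()
        report = starvation_experiment(
            model, medium_from_model(model), spec.ground_truth["alternative_exchange"]
        )
        assert report.biomass_change_pct == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_condition_reports_status(self):
        model, spec = make_starvation_toy()
        model.get_reaction("BIOMASS").lower_bound = 9.0  # unreachable when starved
        report = starvation_experiment(
            model, medium_from_model(model), spec.ground_truth["primary_exchange"]
        )
        assert report.status_without == "infeasible"
        assert report.biomass_change_pct is None
        assert np.isnan(report.biomass_without)

    def test_unknown_nutrient_suggests_alternatives(self):
        model, _ = make_starvation_toy()
        with pytest.raises(ValueError, match="EX_glc_e"):
            starvation_experiment(model, medium_from_model(model), "EX_glc")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nutrient_removal_never_increases_growth(self, seed):
        model, _ = make_random_model(12, seed=seed)
        medium = medium_from_model(model)
        nutrient = sorted(medium.entries)[seed % len(medium.entries)]
        report = starvation_experiment(model, medium, nutrient)
        if report.ok and report.biomass_change_pct is not None:
            assert report.biomass_change_pct <= 1e-6


class TestCarbonSourceComparison:
    def _single_source_media(self, spec):
        caps = dict(zip(spec.parameters["substrates"], spec.parameters["uptake_caps"]))
        return [
            MediumSpec({f"EX_{s}_e": (-caps[s], 0.0)}, name=s)
            for s in spec.parameters["substrates"]
        ]

    def test_ranking_follows_constructed_yields(self):
        model, spec = make_branched()
        media = self._single_source_media(spec)
        table = carbon_source_comparison(model, media)
        truth = spec.ground_truth["single_source_growth"]
        expected_order = sorted(truth, key=lambda s: -truth[s])
        assert list(table["medium"]) == expected_order
        for _, row in table.iterrows():
            assert row["growth"] == pytest.approx(truth[row["medium"]], abs=1e-6)

    def test_preferred_source_is_highest_yield_substrate(self):
        model, spec = make_branched()
        media = self._single_source_media(spec)
        assert preferred_carbon_source(model, media) == spec.ground_truth["preferred_source"]

    def test_rows_reproducible_independently(self):
        """Each row equals a fresh apply_medium + solve_fba run (no shared state)."""
        model, spec = make_branched()
        media = self._single_source_media(spec)
        table = carbon_source_comparison(model, media)
        for medium in media:
            sol = solve_fba(assemble_problem(apply_medium(model, medium)))
            row = table[table["medium"] == medium.name].iloc[0]
            assert row["growth"] == pytest.approx(sol.objective_value, abs=1e-6)

    def test_substrate_uptakes_are_negative_fluxes(self):
        model, spec = make_branched()
        media = self._single_source_media(spec)
        table = carbon_source_comparison(model, media)
        top = table.iloc[0]
        assert top[f"uptake:EX_{top['medium']}_e"] < 0

    def test_single_row_input(self):
        model, spec = make_branched()
        table = carbon_source_comparison(model, self._single_source_media(spec)[:1])
        assert len(table) == 1

    def test_empty_media_list_rejected(self):
        model, _ = make_branched()
        with pytest.raises(ValueError):
            carbon_source_comparison(model, [])


class TestRankDifferentialReactions:
    def _report(self, entries):
        return DifferentialReport(
            status_with="optimal",
            status_without="optimal",
            per_reaction={
                rid: ReactionChange(pct=p, flags=f) for rid, (p, f) in entries.items()
            },
        )

    def test_five_defined_entries_k2(self):
        report = self._report(
            {
                "a": (10.0, ()),
                "b": (-50.0, ()),
                "c": (5.0, ()),
                "d": (10.0, ()),
                "e": (0.0, ()),
            }
        )
        increased, decreased, excluded = rank_differential_reactions(report, 2)
        assert increased == [("a", 10.0), ("d", 10.0)]  # tie broken by id
        assert decreased == [("b", -50.0), ("e", 0.0)]
        assert excluded == []

    def test_all_undefined_entries_listed_separately(self):
        report = self._report(
            {rid: (None, ("undefined-baseline",)) for rid in "abcde"}
        )
        increased, decreased, excluded = rank_differential_reactions(report, 2)
        assert increased == [] and decreased == []
        assert excluded == list("abcde")

    def test_activated_alternative_pathway_tops_increased_list(self):
        """Starving the preferred substrate must switch on the designated
        alternative pathway, which heads the increased ranking."""
        model, spec = make_starvation_toy()
        report = starvation_experiment(
            model, medium_from_model(model), spec.ground_truth["primary_exchange"]
        )
        alt = set(spec.ground_truth["alternative_pathway"])
        # the alternative exchange activates too, so allow one extra slot
        increased, _, excluded = rank_differential_reactions(report, len(alt) + 1)
        assert alt <= {rid for rid, _ in increased}
        assert all(pct == float("inf") for rid, pct in increased if rid in alt)
        assert not alt & set(excluded)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            rank_differential_reactions(self._report({}), 0)
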