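"""Condition-specific model construction: expression mapping, medium and
measurement bounds, and guarded pruning."""

import numpy as np
import pandas as pd
import pytest

from fluxshift import (ContextConfig, ExpressionProfile, MediumSpec,
                       apply_measurements, apply_medium, build_context_model,
                       fba, prune_condition_specific, prune_globally_silent,
                       reaction_expression, toy_network)


def profile_from(means: dict[str, dict[str, float]]) -> ExpressionProfile:
    """Build a 2-samples-per-condition profile with exact condition means."""
    conditions = list(next(iter(means.values())))
    data, cond_map = {}, {}
    for c in conditions:
        for s in (1, 2):
            name = f"{c}_{s}"
            data[name] = {g: means[g][c] for g in means}
            cond_map[name] = c
    fpkm = pd.DataFrame(data)
    fpkm.index.name = "gene"
    return ExpressionProfile(fpkm, cond_map)


@pytest.fixture
def rich_profile():
    """All toy genes well expressed in both conditions."""
    return profile_from({g: {"control": 10.0, "drug": 10.0}
                         for g in ["g1", "g2", "g3", "g4", "g5"]})


class TestReactionExpression:
    def test_single_gene_pass_through(self, toy):
        prof = profile_from({g: {"control": 0.4} for g in toy.genes})
        assert reaction_expression(toy, prof, "control")["R_upper"] == pytest.approx(0.4)

    def test_empty_gpr_is_absent(self, toy, rich_profile):
        assert reaction_expression(toy, rich_profile, "control")["EX_A"] is None

    def test_and_takes_min(self, toy):
        means = {g: {"control": 10.0} for g in toy.genes}
        means["g2"]["control"] = 3.0
        means["g3"]["control"] = 0.2
        prof = profile_from(means)
        assert reaction_expression(toy, prof, "control")["R_ox"] == pytest.approx(0.2)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            profile_from({"g1": {"control": -1.0}})


class TestMedium:
    def test_unlisted_uptake_closed(self, toy):
        m = apply_medium(toy, MediumSpec({"EX_A": (10.0, 0.0)}))
        assert m.get_reaction("EX_O2").upper_bound == 0.0
        assert m.get_reaction("EX_A").upper_bound == 10.0
        # secretion exchanges (oriented outward) stay open
        assert m.get_reaction("EX_C").upper_bound > 0

    def test_empty_medium_zeroes_the_optimum(self, toy):
        m = apply_medium(toy, MediumSpec({}))
        assert fba(m).objective_value == pytest.approx(0.0, abs=1e-12)

    def test_medium_wider_than_template_is_clipped(self, toy):
        log = []
        m = apply_medium(toy, MediumSpec({"EX_A": (50.0, 0.0)}), log)
        assert m.get_reaction("EX_A").upper_bound == 10.0
        assert any("clipped" in e.get("note", "") for e in log)

    def test_non_exchange_id_rejected(self, toy):
        with pytest.raises(ValueError, match="R_upper"):
            apply_medium(toy, MediumSpec({"R_upper": (1.0, 0.0)}))


class TestMeasurements:
    def meas(self, mean, sd, rid="EX_O2"):
        return [{"parameter": "OCR", "reaction_id": rid, "mean": mean,
                 "sd": sd, "units": "model_flux", "conversion": 1.0}]

    def test_bounds_intersected(self, toy):
        m = apply_measurements(toy, self.meas(4.0, 0.5), k_sd=2.0)
        r = m.get_reaction("EX_O2")
        assert (r.lower_bound, r.upper_bound) == pytest.approx((3.0, 5.0))

    def test_disjoint_interval_raises(self, toy):
        with pytest.raises(ValueError, match="OCR"):
            apply_measurements(toy, self.meas(20.0, 0.5), k_sd=2.0)

    def test_k_zero_pins_the_reaction(self, toy):
        m = apply_measurements(toy, self.meas(4.0, 0.5), k_sd=0.0)
        r = m.get_reaction("EX_O2")
        assert r.lower_bound == r.upper_bound == pytest.approx(4.0)

    def test_unit_conversion_applied(self, toy):
        meas = self.meas(400.0, 50.0)
        meas[0]["conversion"] = 0.01
        m = apply_measurements(toy, meas, k_sd=2.0)
        r = m.get_reaction("EX_O2")
        assert (r.lower_bound, r.upper_bound) == pytest.approx((3.0, 5.0))


class TestGlobalPrune:
    def test_silent_reaction_removed(self, toy):
        means = {g: {"control": 10.0, "drug": 10.0} for g in toy.genes}
        means["g4"] = {"control": 0.5, "drug": 0.5}
        means["g5"] = {"control": 0.3, "drug": 0.2}
        prof = profile_from(means)
        pruned, log = prune_globally_silent(toy, prof, ContextConfig())
        assert "R_ferm" not in pruned.reaction_ids()
        assert any(e["reaction"] == "R_ferm" and e["action"] == "removed" for e in log)

    def test_essential_bottleneck_retained(self, toy):
        means = {g: {"control": 10.0, "drug": 10.0} for g in toy.genes}
        means["g1"] = {"control": 0.5, "drug": 0.5}  # R_upper carries all biomass
        prof = profile_from(means)
        pruned, log = prune_globally_silent(toy, prof, ContextConfig())
        assert "R_upper" in pruned.reaction_ids()
        entry = next(e for e in log if e["reaction"] == "R_upper")
        assert entry["action"] == "retained" and entry["reason"] == "essential"

    def test_threshold_boundary_is_strict(self, toy):
        means = {g: {"control": 10.0, "drug": 10.0} for g in toy.genes}
        means["g4"] = {"control": 1.0, "drug": 1.0}
        means["g5"] = {"control": 0.2, "drug": 0.2}
        prof = profile_from(means)
        pruned, _ = prune_globally_silent(toy, prof, ContextConfig())
        # score is exactly 1.0 (OR/max): "under 1" is strict, so retained
        assert "R_ferm" in pruned.reaction_ids()

    def test_biomass_never_drops_below_fraction(self, toy, rich_profile):
        cfg = ContextConfig()
        base = fba(toy).objective_value
        pruned, _ = prune_globally_silent(toy, rich_profile, cfg)
        assert fba(pruned).objective_value >= cfg.biomass_fraction * base - 1e-9


class TestConditionPrune:
    def de(self, fdr):
        return pd.DataFrame({"gene": ["g4", "g5"], "log2FC": [-3.8, -3.8],
                             "FC": [0.07, 0.07], "pvalue": [fdr / 2] * 2,
                             "FDR": [fdr] * 2})

    def profile(self, treated_low=True):
        means = {g: {"control": 10.0, "drug": 10.0} for g in toy_network().genes}
        if treated_low:
            means["g4"] = {"control": 4.2, "drug": 0.3}
            means["g5"] = {"control": 4.2, "drug": 0.3}
        return profile_from(means)

    def test_significant_low_reaction_removed(self, toy):
        pruned, _ = prune_condition_specific(
            toy, self.de(0.01), self.profile(), "drug", "control", ContextConfig())
        assert "R_ferm" not in pruned.reaction_ids()

    def test_fdr_gate(self, toy):
        pruned, _ = prune_condition_specific(
            toy, self.de(0.2), self.profile(), "drug", "control", ContextConfig())
        assert "R_ferm" in pruned.reaction_ids()

    def test_expression_gate(self, toy):
        pruned, _ = prune_condition_specific(
            toy, self.de(0.01), self.profile(treated_low=False),
            "drug", "control", ContextConfig())
        assert "R_ferm" in pruned.reaction_ids()


class TestBuildContext:
    def test_toy_scenario_keeps_all_reactions(self, scenario):
        prof = ExpressionProfile(scenario.fpkm, scenario.condition_map)
        models, log = build_context_model(
            scenario.model, prof, {"treated": scenario.de_table},
            medium=None, measurements=None, config=ContextConfig())
        assert len(models["control"].reactions) == 8

    def test_isozyme_backup_protects_reaction(self, toy):
        means = {g: {"control": 10.0, "drug": 10.0} for g in toy.genes}
        means["g5"] = {"control": 0.1, "drug": 0.1}  # g4 still expressed
        prof = profile_from(means)
        models, _ = build_context_model(toy, prof, {}, None, None,
                                        ContextConfig())
        assert "R_ferm" in models["control"].reaction_ids()

    def test_determinism(self, toy, rich_profile):
        a = build_context_model(toy, rich_profile, {}, MediumSpec({"EX_A": (10, 0),
                                                                   "EX_O2": (5, 0)}),
                                None, ContextConfig())
        b = build_context_model(toy, rich_profile, {}, MediumSpec({"EX_A": (10, 0),
                                                                   "EX_O2": (5, 0)}),
                                None, ContextConfig())
        assert a[0]["control"].reaction_ids() == b[0]["control"].reaction_ids()
        assert a[1] == b[1]

    def test_medium_exchanges_never_pruned(self, toy):
        means = {g: {"control": 0.5, "drug": 0.5} for g in toy.genes}
        prof = profile_from(means)
        medium = MediumSpec({"EX_A": (10, 0), "EX_O2": (5, 0)})
        models, _ = build_context_model(toy, prof, {}, medium, None,
                                        ContextConfig())
        kept = set(models["control"].reaction_ids())
        assert {"EX_A", "EX_O2"} <= kept
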