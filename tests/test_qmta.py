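"""Quadratic transformation: weights, QP assembly, solution properties and
oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import control_reference, qp_bruteforce
from fluxshift import (FluxDistribution, QMTAConfig, assemble_qp, flux_log2fc,
                       gene_weights, make_scenario, map_genes_to_reactions,
                       pathway_report, solve_qmta, toy_network)
from fluxshift.core import MetabolicModel, Metabolite, Reaction


def de_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "log2FC", "FC", "pvalue", "FDR"])


class TestGeneWeights:
    @pytest.mark.parametrize("fdr,expected", [
        (0.025, 1.0),     # one decade below the threshold
        (0.0025, 2.0),    # two decades
    ])
    def test_decade_weights(self, fdr, expected):
        de = de_frame([("g", 1.0, 2.0, fdr / 2, fdr)])
        (w,) = gene_weights(de, p_th=0.25)
        assert w.weight == pytest.approx(expected, abs=1e-12)

    def test_threshold_boundary_excluded(self):
        de = de_frame([("g", 1.0, 2.0, 0.1, 0.25)])
        assert gene_weights(de, p_th=0.25) == []

    def test_zero_p_rejected(self):
        de = de_frame([("g", 1.0, 2.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="floor"):
            gene_weights(de)

    def test_smaller_fdr_larger_weight(self):
        weights = [gene_weights(de_frame([("g", 1, 2, p, p)]))[0].weight
                   for p in (0.1, 0.01, 0.001)]
        assert weights == sorted(weights)


class TestGeneReactionMap:
    def test_toy_mapping(self, toy):
        mapping, dropped = map_genes_to_reactions(toy, ["g2", "g4", "NOT_A_GENE"])
        assert mapping["g2"] == {"R_ox"}
        assert mapping["g4"] == {"R_ferm"}
        assert dropped == ["NOT_A_GENE"]

    def test_gene_in_two_gprs(self, toy):
        toy.reactions.append(Reaction("R_alt", {"B": -1.0, "C": 1.0},
                                      0, 10, gpr="g4"))
        mapping, _ = map_genes_to_reactions(toy, ["g4"])
        assert mapping["g4"] == {"R_ferm", "R_alt"}


class TestAssembly:
    def test_no_de_no_measurements_is_pure_ru(self, toy, empty_de, scenario):
        vref = control_reference(scenario)
        spec = assemble_qp(toy, vref, empty_de, [], None)
        assert set(spec.term_kind) == {"ru"}
        assert all(v == "ru" for v in spec.categories.values())

    def test_fc_one_contributes_nothing(self, scenario):
        de = de_frame([("g4", 0.0, 1.0, 1e-4, 1e-4)])
        vref = control_reference(scenario)
        spec = assemble_qp(scenario.model, vref, de, gene_weights(de), None)
        assert "de" not in spec.term_kind
        assert any("contributes nothing" in line for line in spec.log)

    def test_measurement_overrides_de(self, scenario):
        de = de_frame([("g2", 1.0, 2.0, 1e-3, 1e-3)])  # g2 -> R_ox
        meas = [{"parameter": "x", "reaction_id": "R_ox", "mean": 1.0,
                 "sd": 0.1, "conversion": 1.0}]
        vref = control_reference(scenario)
        spec = assemble_qp(scenario.model, vref, de, gene_weights(de), meas)
        assert spec.categories["R_ox"] == "measured"
        assert "de" not in spec.term_kind

    def test_de_target_scales_signed_reference(self, scenario):
        de = de_frame([("g4", 1.0, 2.0, 1e-3, 1e-3)])
        vref = control_reference(scenario)
        spec = assemble_qp(scenario.model, vref, de, gene_weights(de), None)
        j = spec.reaction_ids.index("R_ferm")
        (k,) = [i for i, kind in enumerate(spec.term_kind) if kind == "de"]
        assert spec.term_index[k] == j
        assert spec.term_target[k] == pytest.approx(2.0 * vref.values["R_ferm"])


class TestSolve:
    def test_identity_when_nothing_changes(self, scenario, empty_de):
        vref = control_reference(scenario)
        res = solve_qmta(assemble_qp(scenario.model, vref, empty_de, [], None))
        dev = max(abs(res.v_mta.values[r] - vref.values[r])
                  for r in scenario.model.reaction_ids())
        assert dev <= 1e-6
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_chain_couples_and_matches_hand_kkt(self):
        """A 2-reaction chain with one DE gene at FC=2: mass balance forces
        a single degree of freedom, so the optimum is the weighted mean of
        the expression target (2 v_ref) and the unchanged target (v_ref),
        both reactions moving together."""
        m = MetabolicModel(id="chain", metabolites=[Metabolite("A", "A", "c")])
        m.reactions = [Reaction("R1", {"A": 1.0}, 0, 100, gpr="g1"),
                       Reaction("R2", {"A": -1.0}, 0, 100)]
        m.genes = ["g1"]
        m.validate()
        vref = FluxDistribution({"R1": 3.0, "R2": 3.0}, m.id)
        assert vref.check_feasibility(m)
        de = de_frame([("g1", 1.0, 2.0, 1e-3, 1e-3)])
        weights = gene_weights(de)
        spec = assemble_qp(m, vref, de, weights, None)
        res = solve_qmta(spec)
        # hand KKT on min w1 (v-6)^2 + w2 (v-3)^2 with v = v_R1 = v_R2
        w1 = weights[0].weight / (3.0 * (2.0 - 1.0)) ** 2
        w2 = 1.0 / 3.0
        expected = (w1 * 6.0 + w2 * 3.0) / (w1 + w2)
        assert res.v_mta.values["R1"] == pytest.approx(expected, abs=1e-6)
        assert res.v_mta.values["R2"] == pytest.approx(expected, abs=1e-6)
        assert 3.0 < expected < 6.0  # a genuine compromise, shifted upward
        x_oracle, f_oracle = qp_bruteforce(spec)
        assert res.objective == pytest.approx(f_oracle, abs=1e-8)

    def test_solution_is_feasible(self, scenario):
        vref = control_reference(scenario)
        w = gene_weights(scenario.de_table)
        res = solve_qmta(assemble_qp(scenario.model, vref, scenario.de_table,
                                     w, scenario.measurements))
        assert res.v_mta.feasible
        assert res.objective == pytest.approx(sum(res.decomposition.values()))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        sc = make_scenario(seed=seed, noise_cv=0.0)
        vref = control_reference(sc)
        w = gene_weights(sc.de_table)
        spec = assemble_qp(sc.model, vref, sc.de_table, w, sc.measurements)
        res = solve_qmta(spec)
        x_oracle, f_oracle = qp_bruteforce(spec)
        assert res.objective == pytest.approx(f_oracle, abs=1e-6)
        v = res.v_mta.as_array(spec.reaction_ids)
        assert np.abs(v - x_oracle).max() <= 1e-4

    def test_weight_monotonicity(self, scenario):
        """Sweeping one gene's FDR downward pulls its reaction's fitted flux
        weakly closer to the expression target."""
        vref = control_reference(scenario)
        m = scenario.model
        target = 2.0 * vref.values["R_ferm"]
        gaps = []
        for fdr in (0.2, 0.02, 0.002, 2e-5):
            de = de_frame([("g4", 1.0, 2.0, fdr, fdr)])
            res = solve_qmta(assemble_qp(m, vref, de, gene_weights(de), None))
            gaps.append(abs(res.v_mta.values["R_ferm"] - target))
        assert all(b <= a + 1e-9 for a, b in zip(gaps, gaps[1:]))


class TestLog2FC:
    @pytest.mark.parametrize("ref,mta,expected,flip", [
        (1.0, 2.0, 1.0, False),
        (3.0, 3.0, 0.0, False),
        (0.5, -0.5, 0.0, True),
    ])
    def test_cases(self, ref, mta, expected, flip):
        a = FluxDistribution({"r": ref})
        b = FluxDistribution({"r": mta})
        l2, flag, flux = flux_log2fc(a, b, epsilon=0.0)["r"]
        assert l2 == pytest.approx(expected)
        assert flag is flip
        assert flux == mta


class TestPathwayReport:
    def test_groups_and_schema(self, scenario):
        vref = control_reference(scenario)
        w = gene_weights(scenario.de_table)
        res = solve_qmta(assemble_qp(scenario.model, vref, scenario.de_table,
                                     w, scenario.measurements))
        report = pathway_report(res, scenario.model)
        assert list(report.columns) == ["subsystem", "reaction_id", "v_ref",
                                        "v_mta", "log2FC", "sign_flip", "direction"]
        glyc = report[report.subsystem == "Glycolysis-like"]
        assert set(glyc.reaction_id) == {"R_upper", "R_ferm"}
        # deterministic ordering
        assert report.equals(pathway_report(res, scenario.model))
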