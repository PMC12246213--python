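"""The calibrated scenario, ancestral sampling, MCAR injection, oracles,
and the phenotype-code generator."""

import numpy as np
import pytest

from chdnet.cohort import VariableSpec
from chdnet.inference import ConditionalProbabilityTable, FittedNetwork, query
from chdnet.simulate import (
    FylerScenario,
    GroundTruthNetwork,
    ScenarioConfig,
    SimulationError,
    generate_fyler_cohort,
    inject_missingness,
    sample_cohort,
    separable_fyler_scenario,
    true_absolute_rr,
    true_relative_rr,
)
from chdnet.structure import DirectedAcyclicGraph


def two_node_net(pc=0.1, p_t_given_c1=0.2, p_t_given_c0=0.05):
    dag = DirectedAcyclicGraph(("C", "T"), {"T": frozenset(["C"])})
    cpts = {
        "C": ConditionalProbabilityTable("C", (), np.array([pc])),
        "T": ConditionalProbabilityTable(
            "T", ("C",), np.array([p_t_given_c0, p_t_given_c1])),
    }
    fn = FittedNetwork(dag, cpts, N=0, smoothing_policy="none",
                       smoothing_value=0.0)
    specs = (VariableSpec("C", "genotype"), VariableSpec("T", "outcome"))
    return GroundTruthNetwork(specs, fn)


class TestScenarioCalibration:
    def test_damaging_genotype_union_prevalence(self, scenario):
        """Enumerated P(any damaging genotype) hits the cohort's 10.6%."""
        p_none = query(scenario.network, {"CHRMdGV": 0, "CILIAdGV": 0})
        assert 1.0 - p_none == pytest.approx(0.106, abs=0.001)

    def test_planted_relative_risks_match_anchors(self, scenario):
        anchors = {
            ("MORT", "CHRMdGV"): 1.8, ("ARREST", "CHRMdGV"): 1.7,
            ("VENT7", "CHRMdGV"): 1.6, ("MORT", "CILIAdGV"): 1.4,
            ("ARREST", "CILIAdGV"): 1.5, ("VENT7", "CILIAdGV"): 1.4,
        }
        for (target, factor), rr in anchors.items():
            got = true_relative_rr(scenario, {target: 1}, factor)
            assert got == pytest.approx(rr, abs=1e-6), (target, factor)

    def test_planted_absolute_risks_match_anchors(self, scenario):
        assert true_absolute_rr(scenario, ("LVO", 1), ("CHRMdGV", 1)) == \
            pytest.approx(1.6, abs=1e-9)
        assert true_absolute_rr(scenario, ("HTX", 1), ("CILIAdGV", 1)) == \
            pytest.approx(2.6, abs=1e-9)

    def test_hlhs_nested_within_lvo(self, scenario):
        cohort = sample_cohort(scenario, 20_000, seed=4)
        hlhs = cohort.column("HLHS")
        lvo = cohort.column("LVO")
        assert ((hlhs == 1) <= (lvo == 1)).all()
        assert hlhs.sum() > 0


class TestSampling:
    def test_seed_determinism(self, scenario):
        a = sample_cohort(scenario, 500, seed=9)
        b = sample_cohort(scenario, 500, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        c = sample_cohort(scenario, 500, seed=10)
        assert not np.array_equal(a.values, c.values)

    def test_empty_cohort_is_valid(self, scenario):
        m = sample_cohort(scenario, 0, seed=0)
        assert m.n_patients == 0
        assert m.variable_names == list(scenario.variable_names)

    def test_empirical_joint_matches_enumeration(self):
        """Full-joint frequencies of a large sample sit within 3 Monte-Carlo
        SE of the exact CPT-defined joint (small hand-built network, so every
        configuration has appreciable mass)."""
        gtn = two_node_net(pc=0.3, p_t_given_c1=0.6, p_t_given_c0=0.2)
        n = 1_000_000
        cohort = sample_cohort(gtn, n, seed=13)
        packed = (cohort.column("C") + 2 * cohort.column("T")).astype(int)
        emp = np.bincount(packed, minlength=4) / n
        for c in (0, 1):
            for t in (0, 1):
                p = query(gtn.network, {"C": c, "T": t})
                se = np.sqrt(p * (1 - p) / n)
                assert abs(emp[c + 2 * t] - p) < 3 * se


class TestMissingness:
    def test_rate_zero_is_identity(self, scenario):
        m = sample_cohort(scenario, 200, seed=1)
        assert inject_missingness(m, 0.0, seed=2) is m

    def test_rate_matches_binomial_expectation(self, scenario):
        n = 10_000
        m = sample_cohort(scenario, n, seed=1)
        holed = inject_missingness(m, 0.05, seed=2)
        frac = holed.missing_fraction()
        se = np.sqrt(0.05 * 0.95 / n)
        assert (abs(frac - 0.05) < 3 * se).all()

    def test_cap_enforced_without_override(self, scenario):
        m = sample_cohort(scenario, 100, seed=1)
        with pytest.raises(SimulationError, match="cap"):
            inject_missingness(m, 0.2, seed=0)
        holed = inject_missingness(m, 0.2, seed=0, override_cap=True)
        assert holed.missing_fraction().mean() > 0.1

    def test_scenario_config_validates(self):
        with pytest.raises(SimulationError):
            ScenarioConfig(n_patients=-1)
        with pytest.raises(SimulationError):
            ScenarioConfig(missing_rate=0.5)


class TestOracles:
    def test_hand_enumerated_absolute_rr(self):
        gtn = two_node_net()
        # P(T) = 0.1*0.2 + 0.9*0.05 = 0.065
        assert true_absolute_rr(gtn, ("T", 1), ("C", 1)) == \
            pytest.approx(0.2 / 0.065, rel=1e-12)

    def test_d_separated_condition_gives_unity(self):
        dag = DirectedAcyclicGraph(("A", "B"), {})
        cpts = {
            "A": ConditionalProbabilityTable("A", (), np.array([0.3])),
            "B": ConditionalProbabilityTable("B", (), np.array([0.6])),
        }
        gtn = GroundTruthNetwork(
            (VariableSpec("A"), VariableSpec("B")),
            FittedNetwork(dag, cpts, 0, "none", 0.0))
        assert true_absolute_rr(gtn, ("B", 1), ("A", 1)) == pytest.approx(1.0)
        assert true_relative_rr(gtn, {"B": 1}, "A") == pytest.approx(1.0)

    def test_self_conditioning_inverts_marginal(self):
        gtn = two_node_net()
        assert true_absolute_rr(gtn, ("C", 1), ("C", 1)) == \
            pytest.approx(1 / 0.1, rel=1e-12)

    def test_zero_probability_condition_is_undefined(self, scenario):
        # HLHS=1 is impossible without LVO=1, so conditioning on the joint
        # event through a deterministic-zero CPT row fails loudly
        with pytest.raises(SimulationError, match="undefined ratio"):
            true_relative_rr(scenario, {"HLHS": 1, "LVO": 0}, "CHRMdGV")

    def test_joint_target_relative_rr_matches_hand_sum(self, scenario):
        """Relative RR with a joint target equals the ratio of explicitly
        enumerated conditional sums."""
        fn = scenario.network
        num = query(fn, {"MORT": 1, "LVO": 1}, {"CHRMdGV": 1})
        den = query(fn, {"MORT": 1, "LVO": 1}, {"CHRMdGV": 0})
        got = true_relative_rr(scenario, {"MORT": 1, "LVO": 1}, "CHRMdGV")
        assert got == pytest.approx(num / den, rel=1e-12)
        assert 1.0 < got < 4.0  # planted amplification stays in band


class TestFylerGenerator:
    def test_separable_scenario_is_deterministic_mapping(self):
        fs = separable_fyler_scenario()
        frame, labels = generate_fyler_cohort(fs, 300, seed=6)
        for cat in fs.categories:
            col = f"FC_{cat}_0"
            mask = labels == cat
            assert (frame.loc[mask, col] == 1).all()
            assert (frame.loc[~mask, col] == 0).all()

    def test_seed_determinism(self):
        fs = FylerScenario()
        f1, l1 = generate_fyler_cohort(fs, 200, seed=8)
        f2, l2 = generate_fyler_cohort(fs, 200, seed=8)
        assert f1.equals(f2) and l1.equals(l2)

    def test_code_frequencies_match_emission_profile(self):
        fs = FylerScenario()
        n = 100_000
        frame, labels = generate_fyler_cohort(fs, n, seed=12)
        em = fs.emission_matrix()
        for ci, cat in enumerate(fs.categories):
            mask = (labels == cat).to_numpy()
            nc = mask.sum()
            emp = frame.loc[mask].mean(axis=0).to_numpy()
            se = np.sqrt(em[ci] * (1 - em[ci]) / nc)
            assert (np.abs(emp - em[ci]) < 3 * se + 1e-12).all(), cat

    def test_bad_priors_rejected(self):
        with pytest.raises(SimulationError):
            FylerScenario(priors=(0.5, 0.5, 0.0, 0.0, 0.1))
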