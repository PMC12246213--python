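"""Risk ratios, bootstrap intervals, feature screening, enrichment tables."""

import numpy as np
import pandas as pd
import pytest

from chdnet.inference import fit_cpts, query
from chdnet.risk import (
    RiskEstimationError,
    RiskQuery,
    absolute_rr,
    bootstrap_risk,
    estimates_to_frame,
    format_enrichment_table,
    pathway_enrichment_table,
    point_risk,
    read_report,
    relative_rr,
    screen_features,
    write_report,
)
from chdnet.simulate import sample_cohort
from chdnet.structure import DirectedAcyclicGraph, learn_exact

from .conftest import make_matrix, random_fitted_network
from .test_simulate import two_node_net


class TestPointRatios:
    def test_absolute_rr_hand_enumeration(self):
        fn = two_node_net().network
        assert absolute_rr(fn, "T", "C") == pytest.approx(0.2 / 0.065,
                                                          rel=1e-12)

    def test_independent_pair_gives_unity(self):
        m = make_matrix((np.random.default_rng(0).random((500, 2)) < 0.4)
                        .astype(float))
        dag = DirectedAcyclicGraph(("V0", "V1"), {})  # no edge: d-separated
        fitted = fit_cpts(dag, m, smoothing=0)
        assert absolute_rr(fitted, "V0", "V1") == pytest.approx(1.0)
        assert relative_rr(fitted, {"V0": 1}, "V1") == pytest.approx(1.0)

    def test_relative_rr_matches_enumeration_oracle(self, scenario):
        got = relative_rr(scenario.network, {"MORT": 1}, "CHRMdGV")
        assert got == pytest.approx(1.8, abs=1e-6)

    def test_reciprocal_coherence(self, scenario):
        """relative_rr(T|F) * P(T|F=0) == P(T|F=1) exactly."""
        fn = scenario.network
        t = {"VENT7": 1}
        rr = relative_rr(fn, t, "CILIAdGV")
        p0 = query(fn, t, {"CILIAdGV": 0})
        p1 = query(fn, t, {"CILIAdGV": 1})
        assert rr * p0 == pytest.approx(p1, rel=1e-12)

    def test_factor_among_targets_rejected(self, scenario):
        with pytest.raises(RiskEstimationError):
            relative_rr(scenario.network, {"MORT": 1}, "MORT")


@pytest.fixture(scope="module")
def cohort(scenario):
    return sample_cohort(scenario, 2253, seed=42)


class TestBootstrap:

    def test_degenerate_bootstrap_equals_direct_estimate(self, cohort):
        rq = RiskQuery("absolute", {"LVO": 1}, "CHRMdGV")
        names = cohort.variable_names
        est = bootstrap_risk(cohort, names, rq, B=1, seed=0, resample=False,
                             smoothing=0.0)
        direct = point_risk(cohort, names, rq, smoothing=0.0)
        assert est.point == pytest.approx(direct, rel=1e-12)
        assert est.n_undefined == 0

    def test_seed_determinism_end_to_end(self, cohort):
        rq = RiskQuery("relative", {"MORT": 1}, "CHRMdGV")
        names = cohort.variable_names
        a = bootstrap_risk(cohort, names, rq, B=25, seed=5,
                           keep_replicates=True)
        b = bootstrap_risk(cohort, names, rq, B=25, seed=5,
                           keep_replicates=True)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        c = bootstrap_risk(cohort, names, rq, B=25, seed=6,
                           keep_replicates=True)
        assert not np.array_equal(a.replicates, c.replicates)

    def test_t_summary_uses_replicate_spread(self, cohort):
        rq = RiskQuery("absolute", {"LVO": 1}, "CHRMdGV")
        est = bootstrap_risk(cohort, cohort.variable_names, rq, B=40, seed=1,
                             summary="t_mean", keep_replicates=True)
        reps = est.replicates[~np.isnan(est.replicates)]
        from scipy import stats

        half = stats.t.ppf(0.975, len(reps) - 1) * reps.std(ddof=1)
        assert est.point == pytest.approx(reps.mean(), rel=1e-12)
        assert est.ci_high - est.point == pytest.approx(half, rel=1e-9)

    def test_percentile_summary_brackets_median(self, cohort):
        rq = RiskQuery("absolute", {"LVO": 1}, "CHRMdGV")
        est = bootstrap_risk(cohort, cohort.variable_names, rq, B=40, seed=1,
                             keep_replicates=True)
        reps = est.replicates[~np.isnan(est.replicates)]
        assert est.point == pytest.approx(np.median(reps))
        assert est.ci_low <= est.point <= est.ci_high

    def test_undefined_replicates_counted_not_imputed(self, scenario):
        """A near-empty condition variable leaves some resamples with zero
        carriers; those replicates must be excluded and reported."""
        cohort = sample_cohort(scenario, 60, seed=2)
        vals = cohort.values.copy()
        vals[:, 0] = 0.0
        vals[0, 0] = 1.0  # single carrier of V0
        rare = make_matrix(vals, names=cohort.variable_names)
        rq = RiskQuery("relative", {"MORT": 1}, "CHRMdGV")
        est = bootstrap_risk(rare, rare.variable_names, rq, B=30, seed=3,
                             smoothing=0.0, keep_replicates=True)
        assert est.n_undefined > 0
        assert np.isnan(est.replicates).sum() == est.n_undefined

    def test_query_variables_must_be_in_subset(self, cohort):
        rq = RiskQuery("absolute", {"LVO": 1}, "CHRMdGV")
        with pytest.raises(RiskEstimationError, match="query variables"):
            bootstrap_risk(cohort, ["LVO", "HTX"], rq, B=2, seed=0)


class TestScreenFeatures:
    def test_planted_direction_of_selection(self, scenario):
        """A positively dependent pair is selected; an anti-dependent pair
        is excluded by the RR >= 1 rule."""
        rng = np.random.default_rng(8)
        n = 2253
        cand = (rng.random(n) < 0.3).astype(float)
        pos = np.where(cand == 1, rng.random(n) < 0.5,
                       rng.random(n) < 0.2).astype(float)
        neg = np.where(cand == 1, rng.random(n) < 0.1,
                       rng.random(n) < 0.4).astype(float)
        m = make_matrix(np.column_stack([cand, pos, neg]),
                        names=["G", "UP", "DOWN"])
        table = screen_features(m, ["G"], ["UP", "DOWN"], B=60, seed=1)
        sel = dict(zip(table["target"], table["selected"]))
        assert sel["UP"] and not sel["DOWN"]

    def test_disjoint_candidate_target_sets_required(self, scenario):
        cohort = sample_cohort(scenario, 50, seed=1)
        with pytest.raises(RiskEstimationError):
            screen_features(cohort, ["LVO"], ["LVO"], B=2)


class TestEnrichmentTable:
    def test_zero_carrier_pathway_gives_dash_row(self, scenario):
        cohort = sample_cohort(scenario, 300, seed=5)
        vals = cohort.values.copy()
        vals[:, 0] = 0.0  # no CHRMdGV carriers at all
        m = make_matrix(vals, names=cohort.variable_names)
        table = pathway_enrichment_table(m, ["CHRMdGV"], ["LVO", "HTX"],
                                         B=10, seed=0)
        assert (table["n_pathway"] == 0).all()
        assert table["point"].isna().all()
        wide = format_enrichment_table(table)
        assert (wide.loc["CHRMdGV", ["LVO", "HTX"]] == "-").all()

    def test_planted_enrichment_detected(self, scenario):
        cohort = sample_cohort(scenario, 2253, seed=6)
        table = pathway_enrichment_table(
            cohort, ["CHRMdGV", "CILIAdGV"], ["LVO", "HTX"], B=60, seed=1)
        row = table.set_index(["pathway", "phenotype"])
        # strong planted cell (true 2.6-fold) excludes the null
        assert row.loc[("CILIAdGV", "HTX"), "ci_low"] > 1.0
        assert row.loc[("CILIAdGV", "HTX"), "point"] == pytest.approx(
            2.6, abs=0.8)
        # independent cell (true 1.0) keeps the null inside its interval
        assert row.loc[("CILIAdGV", "LVO"), "ci_low"] <= 1.0 <= \
            row.loc[("CILIAdGV", "LVO"), "ci_high"]
        # weaker planted cell (true 1.6) estimated in the right vicinity
        assert row.loc[("CHRMdGV", "LVO"), "point"] == pytest.approx(
            1.6, abs=0.5)


class TestReportIO:
    def test_empty_report_has_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report([], path)
        frame = read_report(path)
        assert len(frame) == 0
        assert "n_undefined_replicates" in frame.columns

    def test_round_trip_and_deterministic_order(self, scenario, tmp_path):
        cohort = sample_cohort(scenario, 400, seed=9)
        names = cohort.variable_names
        ests = [
            bootstrap_risk(cohort, names,
                           RiskQuery("relative", {"MORT": 1}, "CHRMdGV"),
                           B=5, seed=1),
            bootstrap_risk(cohort, names,
                           RiskQuery("absolute", {"LVO": 1}, "CHRMdGV"),
                           B=5, seed=1),
        ]
        path = tmp_path / "r.tsv"
        write_report(ests, path)
        frame = read_report(path)
        assert list(frame["kind"]) == sorted(frame["kind"])
        expected = estimates_to_frame(ests)
        pd.testing.assert_frame_equal(frame, expected, check_dtype=False)
        assert frame["n_undefined_replicates"].notna().all()
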