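import numpy as np
import pandas as pd
import pytest

from methexpr.dataio import ConfigError, LabeledMatrix, ProbeAnnotation
from methexpr.diffexpr import fit_group_model
from methexpr.diffmeth import (
    ContingencyTable2x2,
    aggregate_region,
    beta_to_m,
    call_dmfs,
    chi_square_2x2,
    decile_thresholds,
    delta_beta,
    enhancer_enrichment,
    m_to_beta,
)


def quantile_oracle(values, q):
    """Sort-and-interpolate order statistics with h = (n-1)q, by hand."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def chi2_closed_form(a, b, c, d):
    """n(ad - bc)^2 / (r1 r2 c1 c2) for a 2x2 table."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestBetaMTransforms:
    def test_symmetry_point(self):
        assert beta_to_m(0.5) == 0.0

    def test_log2_four(self):
        assert beta_to_m(0.8) == pytest.approx(2.0, abs=1e-12)
        assert m_to_beta(2.0) == pytest.approx(0.8, abs=1e-12)

    def test_round_trip_grid(self):
        grid = np.linspace(0.001, 0.999, 999)
        assert np.max(np.abs(grid - m_to_beta(beta_to_m(grid)))) < 1e-12

    def test_strictly_increasing(self):
        grid = np.linspace(0.001, 0.999, 500)
        assert np.all(np.diff(beta_to_m(grid)) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(np.array([0.5, np.inf]))

    def test_extreme_beta_clamped_to_finite_m(self):
        assert np.isfinite(beta_to_m(np.array([0.0, 1.0]))).all()


def _meth_fixture():
    """Five probes, two genes, one shared probe; 2 case + 2 control samples."""
    values = pd.DataFrame(
        {
            "c1": [0.2, 0.4, 0.1, 0.3, 0.5],
            "c2": [0.2, 0.4, 0.1, 0.3, 0.5],
            "n1": [0.3, 0.5, 0.2, 0.3, 0.5],
            "n2": [0.3, 0.5, 0.2, 0.3, 0.5],
        },
        index=["p1", "p2", "p3", "p4", "p5"],
    )
    group = pd.Series(
        {"c1": "case", "c2": "case", "n1": "control", "n2": "control"}
    )
    meth = LabeledMatrix(values=values, scale="beta", group=group)
    probes = pd.DataFrame(
        {
            "chr": ["1"] * 5,
            "position": [10, 20, 30, 40, 50],
            "enhancer": [False] * 5,
            "intergenic": [False] * 5,
        },
        index=pd.Index(["p1", "p2", "p3", "p4", "p5"], name="probe_id"),
    )
    assignments = pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "p3", "p4", "p4", "p5"],
            "gene": ["G1", "G1", "G1", "G1", "G2", "G2"],
            "region": ["TSS200", "TSS200", "TSS1500", "Body", "Body", "Body"],
        }
    )
    return meth, ProbeAnnotation(probes=probes, assignments=assignments)


class TestAggregateRegion:
    def test_region_mean(self):
        meth, ann = _meth_fixture()
        level = aggregate_region(meth, ann, "TSS200")
        assert level.beta_means.loc["G1", "c1"] == pytest.approx(0.3)
        assert level.probe_counts["G1"] == 2

    def test_multi_gene_probe_contributes_to_both(self):
        meth, ann = _meth_fixture()
        level = aggregate_region(meth, ann, "Body")
        # p4 feeds both G1 (alone) and G2 (with p5)
        assert level.beta_means.loc["G1", "c1"] == pytest.approx(0.3)
        assert level.beta_means.loc["G2", "c1"] == pytest.approx(0.4)

    def test_all_selector_pools_every_region(self):
        meth, ann = _meth_fixture()
        level = aggregate_region(meth, ann, "ALL")
        # G1 has 4 distinct CpGs: 0.2, 0.4, 0.1, 0.3
        assert level.beta_means.loc["G1", "c1"] == pytest.approx(0.25)
        assert level.probe_counts["G1"] == 4

    def test_probe_order_permutation_invariant(self):
        meth, ann = _meth_fixture()
        base = aggregate_region(meth, ann, "ALL").beta_means
        perm = ann.assignments.sample(frac=1.0, random_state=1).reset_index(drop=True)
        ann2 = ProbeAnnotation(probes=ann.probes, assignments=perm)
        again = aggregate_region(meth, ann2, "ALL").beta_means
        pd.testing.assert_frame_equal(base.sort_index(), again.sort_index())

    def test_empty_selector_warns(self):
        meth, ann = _meth_fixture()
        with pytest.warns(UserWarning):
            level = aggregate_region(meth, ann, "3UTR")
        assert level.beta_means.empty

    def test_unknown_selector_rejected(self):
        meth, ann = _meth_fixture()
        with pytest.raises(ConfigError):
            aggregate_region(meth, ann, "promoter")


class TestDeltaBeta:
    def test_subtraction(self):
        meth, ann = _meth_fixture()
        level = aggregate_region(meth, ann, "TSS1500")
        assert delta_beta(level)["G1"] == pytest.approx(-0.1)

    def test_identical_groups_zero(self):
        meth, ann = _meth_fixture()
        assert delta_beta(aggregate_region(meth, ann, "Body"))["G2"] == pytest.approx(0.0)


class TestDecileThresholds:
    def test_interpolated_oracle_example(self):
        deltas = [-10, -8, -6, -4, -2, 0, 2, 4, 6, 8]
        low, high = decile_thresholds(deltas)
        assert low == pytest.approx(-8.2)
        assert high == pytest.approx(4.4)

    def test_degenerate_distribution(self):
        low, high = decile_thresholds([3.0] * 12)
        assert low == high == 3.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            vals = rng.normal(size=rng.integers(10, 60))
            low, high = decile_thresholds(vals)
            assert low == pytest.approx(quantile_oracle(vals, 0.1), abs=1e-12)
            assert high == pytest.approx(quantile_oracle(vals, 0.8), abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ConfigError):
            decile_thresholds([0.1] * 9)


class TestCallDmfs:
    def _inputs(self, deltas, pvals):
        idx = [f"f{i}" for i in range(len(deltas))]
        m_stats = pd.DataFrame(
            {"effect": deltas, "t_stat": np.zeros(len(deltas)), "p_value": pvals}, index=idx
        )
        return m_stats, pd.Series(deltas, index=idx)

    def test_boundary_delta_is_strict(self):
        m_stats, deltas = self._inputs([-0.05, 0.0, 0.01], [0.001, 0.5, 0.9])
        out = call_dmfs(m_stats, deltas, thresholds=(-0.05, 0.02))
        assert not out.loc["f0", "significant"]  # delta == low exactly

    def test_both_criteria_required(self):
        m_stats, deltas = self._inputs([-0.08, -0.08], [0.2, 0.0001])
        out = call_dmfs(m_stats, deltas, thresholds=(-0.05, 0.02))
        assert not out.loc["f0", "significant"]  # extreme delta, weak p
        assert out.loc["f1", "significant"] and out.loc["f1", "direction"] == "hypo"

    def test_feature_mismatch_rejected(self):
        m_stats, deltas = self._inputs([-0.08], [0.001])
        with pytest.raises(ConfigError):
            call_dmfs(m_stats, deltas.rename({"f0": "other"}), thresholds=(-0.05, 0.02))

    def test_direction_hyper(self):
        m_stats, deltas = self._inputs([0.09], [0.0001])
        out = call_dmfs(m_stats, deltas, thresholds=(-0.05, 0.02))
        assert out.loc["f0", "direction"] == "hyper"

    def test_call_counts_bounded_by_deciles(self, tiny_cohort):
        level = aggregate_region(tiny_cohort.methylation, tiny_cohort.annotation, "ALL")
        stats = fit_group_model(level.m_matrix())
        deltas = delta_beta(level)
        out = call_dmfs(stats, deltas, decile_thresholds(deltas))
        n = len(out)
        assert out["significant"].sum() <= 0.3 * n + 2


class TestChiSquare:
    def test_independence(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(20, 10, 10, 20))
        assert stat == pytest.approx(20 / 3, abs=1e-9)
        assert p == pytest.approx(0.00982, abs=1e-5)

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat, _ = chi_square_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert stat == pytest.approx(chi2_closed_form(a, b, c, d), abs=1e-9)

    def test_degenerate_marginal_rejected(self):
        with pytest.raises(ConfigError, match="degenerate"):
            chi_square_2x2(ContingencyTable2x2(0, 0, 10, 20))

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            ContingencyTable2x2(-1, 1, 1, 1)

    def test_underflow_reported_as_tiny_positive(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(100000, 10, 10, 100000))
        assert p >= np.finfo(float).tiny > 0


class TestEnhancerEnrichment:
    def test_enriched_cohort_detected(self, tiny_cohort):
        meth, ann = tiny_cohort.methylation, tiny_cohort.annotation
        ig = ann.intergenic_ids
        beta = LabeledMatrix(values=meth.values.loc[ig], scale="beta", group=meth.group)
        m = LabeledMatrix(
            values=beta_to_m(beta.values), scale="log2_expression", group=meth.group
        )
        stats = fit_group_model(m)
        deltas = delta_beta(beta)
        calls = call_dmfs(stats, deltas, decile_thresholds(deltas))
        table, stat, p = enhancer_enrichment(calls, ann)
        assert table.a + table.b + table.c + table.d == len(ig)
        assert stat >= 0 and 0 < p <= 1

    def test_genic_probe_rejected(self):
        meth, ann = _meth_fixture()
        calls = pd.DataFrame({"significant": [True]}, index=["p1"])
        with pytest.raises(ConfigError):
            enhancer_enrichment(calls, ann)
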