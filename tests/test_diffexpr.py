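import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from thydex import (
    adjust_bh,
    classify_status,
    collapse_to_genes,
    differential_expression,
    fit_variance_prior,
    local_fdr,
    qpcr_relative_expression,
)
from thydex.diffexpr import ComparisonResult, grenander_density, trigamma_inverse
from thydex.io import ProbeAnnotation, ValidationError
from .conftest import toy_matrix


def two_group_sheet(n_a, n_b, group_a="AT", group_b="ET"):
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = [group_a] * n_a + [group_b] * n_b
    return pd.DataFrame({"group": groups}, index=pd.Index(ids, name="sample_id")), ids


class TestModeratedT:
    def test_logfc_is_difference_of_group_means(self):
        sheet, ids = two_group_sheet(3, 3)
        values = np.vstack([[8, 8, 8, 7, 7, 7], [5, 5, 5, 6, 6, 6]]).astype(float)
        # add a little noise to avoid zero variances on other rows
        rng = np.random.default_rng(0)
        values = np.vstack([values, rng.normal(7, 1, (10, 6))])
        m = toy_matrix(values, sample_ids=ids)
        res = differential_expression(m, sheet, "AT", "ET", compute_lfdr=False)
        np.testing.assert_allclose(res.table["logFC"].iloc[0], 1.0)
        np.testing.assert_allclose(res.table["logFC"].iloc[1], -1.0)

    def test_d0_zero_equals_textbook_pooled_t(self):
        """With moderation off, the statistic is the classical pooled t."""
        sheet, ids = two_group_sheet(3, 3)
        rng = np.random.default_rng(1)
        values = rng.normal(7, 1, (20, 6))
        m = toy_matrix(values, sample_ids=ids)
        res = differential_expression(m, sheet, "AT", "ET", d0_override=0.0,
                                      compute_lfdr=False)
        for i in range(20):
            t_ref, p_ref = stats.ttest_ind(values[i, :3], values[i, 3:],
                                           equal_var=True)
            assert abs(res.table["t"].iloc[i] - t_ref) < 1e-10
            assert abs(res.table["p"].iloc[i] - p_ref) < 1e-10

    def test_d0_infinite_shrinks_to_prior(self):
        sheet, ids = two_group_sheet(4, 4)
        rng = np.random.default_rng(2)
        m = toy_matrix(rng.normal(0, 1, (15, 8)), sample_ids=ids)
        res = differential_expression(m, sheet, "AT", "ET",
                                      d0_override=np.inf, s0sq_override=0.5,
                                      compute_lfdr=False)
        # posterior variance equals s0sq exactly: t = logFC / sqrt(s0sq * (1/4+1/4))
        expected_t = res.table["logFC"] / np.sqrt(0.5 * 0.5)
        np.testing.assert_allclose(res.table["t"], expected_t, atol=1e-10)

    def test_sign_symmetry(self):
        sheet, ids = two_group_sheet(4, 5)
        rng = np.random.default_rng(3)
        m = toy_matrix(rng.normal(7, 1, (30, 9)), sample_ids=ids)
        ab = differential_expression(m, sheet, "AT", "ET", compute_lfdr=False)
        ba = differential_expression(m, sheet, "ET", "AT", compute_lfdr=False)
        np.testing.assert_array_equal(ab.table["logFC"].to_numpy(),
                                      -ba.table["logFC"].to_numpy())
        np.testing.assert_array_equal(ab.table["t"].to_numpy(),
                                      -ba.table["t"].to_numpy())
        np.testing.assert_array_equal(ab.table["p"].to_numpy(),
                                      ba.table["p"].to_numpy())

    def test_absent_group_and_small_groups_rejected(self):
        sheet, ids = two_group_sheet(3, 3)
        m = toy_matrix(np.random.default_rng(4).normal(0, 1, (12, 6)),
                       sample_ids=ids)
        with pytest.raises(ValidationError, match="absent"):
            differential_expression(m, sheet, "AT", "AM")
        sheet1, ids1 = two_group_sheet(1, 5)
        m1 = toy_matrix(np.random.default_rng(5).normal(0, 1, (12, 6)),
                        sample_ids=ids1)
        with pytest.raises(ValidationError, match="2 samples"):
            differential_expression(m1, sheet1, "AT", "ET")

    def test_zero_variance_features_floored(self):
        sheet, ids = two_group_sheet(3, 3)
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, (12, 6))
        values[0] = [1, 1, 1, 1, 1, 1]  # no residual variance
        m = toy_matrix(values, sample_ids=ids)
        res = differential_expression(m, sheet, "AT", "ET", compute_lfdr=False)
        assert bool(res.table["var_floored"].iloc[0])
        assert np.isfinite(res.table["t"].iloc[0])

    def test_prior_fit_recovers_known_parameters(self):
        """Method-of-moments (d0, s0sq) fit on variances drawn from the model."""
        rng = np.random.default_rng(7)
        d0_true, s0sq_true, df = 4.0, 0.25, 12
        sigma2 = d0_true * s0sq_true / rng.chisquare(d0_true, size=10_000)
        s2 = sigma2 * rng.chisquare(df, size=10_000) / df
        d0, s0sq = fit_variance_prior(s2, df)
        assert abs(d0 - d0_true) / d0_true < 0.2
        assert abs(s0sq - s0sq_true) / s0sq_true < 0.2

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for x in (0.1, 1.0, 5.0, 40.0):
            y = float(polygamma(1, x))
            assert abs(trigamma_inverse(y) - x) < 1e-6 * max(1.0, x)


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.03])), [0.03])

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(adjust_bh(p), ref, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_bounds_property(self, p):
        p = np.asarray(p)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.5]))


class TestLocalFdr:
    def test_uniform_grid_pure_null(self):
        n = 1000
        p = (np.arange(1, n + 1) - 0.5) / n
        pi0, lfdr = local_fdr(p)
        assert abs(pi0 - 1.0) <= 1.0 / n + 1e-12
        order = np.argsort(p)
        upper_90 = lfdr[order][n // 10:]
        assert (upper_90 >= 0.95).all()

    def test_spiked_grid(self):
        rng = np.random.default_rng(9)
        n = 2000
        p = np.concatenate([rng.uniform(0, 0.001, n // 2),
                            rng.uniform(0, 1, n // 2)])
        pi0, lfdr = local_fdr(p)
        assert lfdr[p < 0.0005].max() < 0.2
        assert lfdr[p > 0.5].min() > 0.8

    def test_monotone_in_p(self):
        rng = np.random.default_rng(10)
        p = np.concatenate([rng.beta(0.3, 4, 300), rng.uniform(0, 1, 700)])
        _, lfdr = local_fdr(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(lfdr[order]) >= -1e-12).all()

    def test_grenander_matches_isotonic_regression_oracle(self):
        """The PAVA Grenander slopes equal a decreasing isotonic fit of the
        raw ECDF slopes weighted by support width."""
        rng = np.random.default_rng(11)
        p = np.sort(rng.uniform(0, 1, 500))
        uniq = np.unique(p)
        x = np.concatenate([[0.0], uniq, [1.0]])
        F = np.concatenate([[0.0],
                            np.searchsorted(p, uniq, side="right") / p.size,
                            [1.0]])
        dx = np.diff(x)
        raw = np.diff(F) / dx
        iso = IsotonicRegression(increasing=False).fit(
            np.arange(raw.size), raw, sample_weight=dx)
        ref = iso.predict(np.arange(raw.size))
        f_hat = grenander_density(p)
        idx = np.clip(np.searchsorted(np.cumsum(dx), p, side="left"), 0,
                      ref.size - 1)
        np.testing.assert_allclose(f_hat, ref[idx], atol=1e-9)

    def test_small_input_fallback_and_errors(self):
        pi0, lfdr = local_fdr(np.array([0.5, 0.6, 0.7, 0.8]))
        assert (lfdr == min(1.0, pi0)).all()
        with pytest.raises(ValueError):
            local_fdr(np.array([]))


def make_result(rows):
    table = pd.DataFrame(
        rows, columns=["logFC", "p", "adj_p", "lfdr"],
        index=[f"g{i}" for i in range(len(rows))])
    table["mean_a"] = 0.0
    table["mean_b"] = 0.0
    table["s2"] = 1.0
    table["df"] = 10.0
    table["t"] = 0.0
    table["var_floored"] = False
    return ComparisonResult("comp1", "AT", "ET", 5, 9, table, 4.0, 0.25, 0.9)


class TestStatusClassifier:
    def test_strong_upregulation_is_de_up(self):
        # thyroid peroxidase-like record: huge fold change, tiny adjusted p
        res = make_result([[5.091, 1e-9, 5.03e-7, 0.001]])
        status, conflicts = classify_status(res)
        assert status["status"].iloc[0] == "DE_UP"
        assert conflicts == 0

    @pytest.mark.parametrize(
        "row, expected",
        [
            ([-2.0, 1e-5, 1e-4, 0.0], "DE_DOWN"),
            ([0.5, 1e-3, 0.01, 0.1], "SIGNIFICANT"),   # sub-twofold
            ([0.1, 0.5, 0.4, 0.97], "UNCHANGED"),
            ([0.1, 0.5, 0.4, 0.5], "UNCERTAIN"),
            ([1.0, 0.04, 0.049, 0.5], "DE_UP"),        # inclusive twofold bound
        ],
    )
    def test_rule_table(self, row, expected):
        status, _ = classify_status(make_result([row]))
        assert status["status"].iloc[0] == expected

    def test_conflicts_counted_and_resolved_by_precedence(self):
        res = make_result([[2.0, 1e-4, 1e-3, 0.99]])
        status, conflicts = classify_status(res)
        assert status["status"].iloc[0] == "DE_UP"
        assert conflicts == 1

    def test_missing_lfdr_rejected(self):
        res = make_result([[1.0, 0.01, 0.02, np.nan]])
        with pytest.raises(ValidationError):
            classify_status(res)


class TestCollapseToGenes:
    def make_status(self, records):
        df = pd.DataFrame(records,
                          columns=["status", "logFC", "p", "adj_p", "lfdr"])
        df.index = [f"p{i}" for i in range(len(records))]
        return df

    def test_one_probe_per_gene_identity(self):
        status = self.make_status([["DE_UP", 2.0, 1e-4, 1e-3, 0.0]])
        ann = ProbeAnnotation({"p0": "G1"})
        out = collapse_to_genes(status, ann)
        assert out.loc["G1", "probe_id"] == "p0"

    def test_min_adj_p_wins(self):
        status = self.make_status([
            ["SIGNIFICANT", 0.5, 0.1, 0.5, 0.2],
            ["DE_UP", 2.0, 1e-4, 0.001, 0.0],
        ])
        ann = ProbeAnnotation({"p0": "G1", "p1": "G1"})
        out = collapse_to_genes(status, ann)
        assert out.loc["G1", "probe_id"] == "p1"
        assert out.loc["G1", "status"] == "DE_UP"

    def test_tie_broken_by_abs_logfc_then_id(self):
        status = self.make_status([
            ["DE_UP", 1.2, 1e-3, 0.01, 0.0],
            ["DE_UP", -2.0, 1e-3, 0.01, 0.0],
        ])
        ann = ProbeAnnotation({"p0": "G1", "p1": "G1"})
        out = collapse_to_genes(status, ann)
        assert out.loc["G1", "probe_id"] == "p1"
        status2 = self.make_status([
            ["DE_UP", 2.0, 1e-3, 0.01, 0.0],
            ["DE_UP", 2.0, 1e-3, 0.01, 0.0],
        ])
        out2 = collapse_to_genes(status2, ann)
        assert out2.loc["G1", "probe_id"] == "p0"  # lexicographic

    def test_unannotated_probes_dropped(self):
        status = self.make_status([
            ["DE_UP", 2.0, 1e-4, 0.001, 0.0],
            ["UNCHANGED", 0.0, 0.9, 0.95, 0.99],
        ])
        ann = ProbeAnnotation({"p0": "G1", "p1": None})
        out = collapse_to_genes(status, ann)
        assert list(out.index) == ["G1"]


class TestQpcr:
    def make_ct(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "group", "gene",
                                           "replicate", "ct"])

    def test_equal_ct_gives_unit_ratio(self):
        rows = []
        for sid, grp in (("s1", "A"), ("c1", "B")):
            rows += [(sid, grp, "T", 1, 25.0), (sid, grp, "R1", 1, 20.0),
                     (sid, grp, "R2", 1, 22.0)]
        ratios = qpcr_relative_expression(self.make_ct(rows), ["T"],
                                          ("R1", "R2"), calibrator="c1")
        np.testing.assert_allclose(ratios.loc["s1", "T"], 1.0)

    def test_one_cycle_is_one_doubling(self):
        rows = [("s1", "A", "T", 1, 24.0), ("s1", "A", "R1", 1, 20.0),
                ("s1", "A", "R2", 1, 22.0),
                ("c1", "B", "T", 1, 25.0), ("c1", "B", "R1", 1, 20.0),
                ("c1", "B", "R2", 1, 22.0)]
        ratios = qpcr_relative_expression(self.make_ct(rows), ["T"],
                                          ("R1", "R2"), calibrator="c1")
        np.testing.assert_allclose(ratios.loc["s1", "T"], 2.0)

    def test_duplicates_averaged_and_ref_mean_rule(self):
        rows = [("s1", "A", "T", 1, 24.0), ("s1", "A", "T", 2, 26.0),
                ("s1", "A", "R1", 1, 20.0), ("s1", "A", "R2", 1, 22.0),
                ("c1", "B", "T", 1, 25.0), ("c1", "B", "R1", 1, 20.0),
                ("c1", "B", "R2", 1, 22.0)]
        ratios = qpcr_relative_expression(self.make_ct(rows), ["T"],
                                          ("R1", "R2"), calibrator="c1")
        # mean target Ct 25 vs refs mean 21 in both -> ratio 1
        np.testing.assert_allclose(ratios.loc["s1", "T"], 1.0)

    def test_missing_reference_rejected(self):
        rows = [("s1", "A", "T", 1, 24.0), ("s1", "A", "R1", 1, 20.0),
                ("c1", "B", "T", 1, 25.0), ("c1", "B", "R1", 1, 20.0),
                ("c1", "B", "R2", 1, 22.0)]
        with pytest.raises(ValidationError, match="R2"):
            qpcr_relative_expression(self.make_ct(rows), ["T"], ("R1", "R2"),
                                     calibrator="c1")
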