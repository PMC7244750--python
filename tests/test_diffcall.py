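"""Normalization, NB Wald testing, BH correction and significance calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kat3id.diffcall import (
    bh_adjust,
    call_significant,
    nb_test,
    run_diffcall,
    size_factors,
)


def make_counts(array, samples=None):
    array = np.asarray(array)
    samples = samples or [f"s{i}" for i in range(array.shape[1])]
    return pd.DataFrame(array, index=[f"f{i}" for i in range(array.shape[0])],
                        columns=samples)


def two_group_sheet(n_per_group):
    rows = []
    for g in ("control", "KO"):
        for r in range(n_per_group):
            rows.append({"sample": f"{g}{r}", "genotype": g, "replicate": r + 1})
    return pd.DataFrame(rows)


def nb_counts(rng, mu, n_feat, n_samples, disp):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mu), size=(n_feat, n_samples))


class TestSizeFactors:
    def test_identical_samples(self):
        counts = make_counts([[10, 10], [20, 20], [5, 5]])
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        counts = make_counts([[10, 20], [30, 60], [7, 14]])
        assert np.allclose(size_factors(counts), [2**-0.5, 2**0.5])

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(0)
        counts = make_counts(rng.poisson(50, (100, 4)))
        s0 = size_factors(counts)
        scaled = counts.copy()
        scaled["s2"] = scaled["s2"] * 3
        s1 = size_factors(scaled)
        ratio = s1 / s0
        assert np.allclose(ratio["s2"] / ratio["s0"], 3.0)

    def test_no_common_positive_feature(self):
        counts = make_counts([[5, 0], [0, 5]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)
        s = size_factors(counts, pseudo_reference=True)
        assert np.allclose(np.exp(np.mean(np.log(s))), 1.0)


class TestNbTest:
    def test_constant_feature_is_null(self):
        sheet = two_group_sheet(3)
        counts = make_counts(np.full((1, 6), 40), sheet["sample"].tolist())
        res = nb_test(counts, sheet)
        assert res.loc[0, "log2FC"] == 0.0
        assert res.loc[0, "p"] > 0.99

    def test_all_zero_feature(self):
        sheet = two_group_sheet(2)
        arr = np.vstack([np.zeros(4), np.full(4, 30)])
        res = nb_test(make_counts(arr, sheet["sample"].tolist()), sheet)
        assert res.loc[0, "p"] == 1.0 and res.loc[0, "log2FC"] == 0.0

    def test_requires_both_genotypes(self):
        sheet = two_group_sheet(3)
        sheet["genotype"] = "control"
        counts = make_counts(np.full((2, 6), 10), sheet["sample"].tolist())
        with pytest.raises(ValueError, match="genotype"):
            nb_test(counts, sheet)

    def test_type_one_error_calibration(self):
        """Null NB features: rejection rate at p<0.05 stays near nominal."""
        rng = np.random.default_rng(2024)
        sheet = two_group_sheet(5)
        counts = make_counts(nb_counts(rng, 100.0, 2000, 10, 0.1),
                             sheet["sample"].tolist())
        res = nb_test(counts, sheet)
        rate = (res["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_on_large_effect(self):
        """A 4-fold drop at mu=200 is detected nearly always at n=5."""
        rng = np.random.default_rng(7)
        sheet = two_group_sheet(5)
        n_eff, n_null = 500, 4500
        mu = np.full((n_eff + n_null, 10), 200.0)
        is_ko = (sheet["genotype"] == "KO").to_numpy()
        mu[:n_eff, is_ko] *= 2.0**-2
        r = 1 / 0.05
        counts = make_counts(rng.negative_binomial(r, r / (r + mu)),
                             sheet["sample"].tolist())
        res = nb_test(counts, sheet)
        power = ((res["p"][:n_eff] < 0.05) & (res["log2FC"][:n_eff] < 0)).mean()
        assert power > 0.9

    def test_scale_invariance(self):
        """Multiplying one sample's counts leaves log2FC and p essentially
        unchanged. Exact invariance is unattainable for the p-values: scaling
        a sample's counts genuinely shrinks its relative counting noise, so
        only the normalized means (hence log2FC) are invariant up to the
        pseudo-count, while the variance model sees a slightly different
        library."""
        rng = np.random.default_rng(5)
        sheet = two_group_sheet(3)
        counts = make_counts(rng.poisson(80, (50, 6)), sheet["sample"].tolist())
        res0 = nb_test(counts, sheet)
        scaled = counts.copy()
        scaled[scaled.columns[1]] *= 7
        res1 = nb_test(scaled, sheet)
        assert np.allclose(res0["log2FC"], res1["log2FC"], atol=5e-3)
        assert np.allclose(res0["p"], res1["p"], atol=5e-2)
        # calls at the study thresholds are unaffected
        assert (np.abs(res0["log2FC"]) >= 1).equals(np.abs(res1["log2FC"]) >= 1)


class TestBhAdjust:
    def test_closed_form(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_order_independence(self, pvals):
        padj = bh_adjust(pvals)
        assert (padj >= np.asarray(pvals) - 1e-12).all()
        assert (padj <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(pvals))
        assert np.allclose(np.asarray(padj)[perm], bh_adjust(np.asarray(pvals)[perm]))

    def test_independent_step_up_formula(self):
        """Cross-check against a direct step-up computation."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 37)
        order = np.argsort(p)
        m = len(p)
        raw = p[order] * m / np.arange(1, m + 1)
        expected = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
        got = bh_adjust(p)[order]
        assert np.allclose(got, expected)


class TestCallSignificant:
    @pytest.mark.parametrize(
        "padj,lfc,expected",
        [
            (0.04, -1.2, "down"),
            (0.04, 0.5, "ns"),
            (0.2, -3.0, "ns"),
            (0.01, 1.0, "up"),  # boundary |log2FC| == 1 counts
            (0.01, -1.0, "down"),
        ],
    )
    def test_threshold_rules(self, padj, lfc, expected):
        df = pd.DataFrame(
            {"feature": ["x"], "baseMean": [10.0], "log2FC": [lfc],
             "p": [padj], "padj": [padj], "status": ["ns"]}
        )
        assert call_significant(df).loc[0, "status"] == expected

    def test_strict_comparator_excludes_boundary(self):
        df = pd.DataFrame(
            {"feature": ["x"], "baseMean": [10.0], "log2FC": [-1.0],
             "p": [0.01], "padj": [0.01], "status": ["ns"]}
        )
        assert call_significant(df, strict_lfc=True).loc[0, "status"] == "ns"

    def test_alpha_validation(self):
        df = pd.DataFrame(
            {"feature": ["x"], "baseMean": [1.0], "log2FC": [0.0],
             "p": [1.0], "padj": [1.0], "status": ["ns"]}
        )
        with pytest.raises(ValueError):
            call_significant(df, alpha=1.5)

    def test_requires_padj(self):
        df = pd.DataFrame(
            {"feature": ["x"], "baseMean": [1.0], "log2FC": [0.0],
             "p": [1.0], "padj": [np.nan], "status": ["ns"]}
        )
        with pytest.raises(ValueError, match="padj"):
            call_significant(df)


def test_empirical_fdr_control():
    """BH keeps the realized FDR below 1.5x nominal on a null/effect mix."""
    rng = np.random.default_rng(99)
    sheet = two_group_sheet(5)
    n_eff, n_null = 1000, 2000
    mu = np.full((n_eff + n_null, 10), 150.0)
    mu[:n_eff, (sheet["genotype"] == "KO").to_numpy()] *= 2.0**-2
    r = 1 / 0.05
    counts = make_counts(rng.negative_binomial(r, r / (r + mu)),
                         sheet["sample"].tolist())
    res = run_diffcall(counts, sheet, alpha=0.05, min_abs_lfc=1.0)
    called = res["status"] != "ns"
    false = called[n_eff:].sum()
    assert called.sum() > 0
    assert false / called.sum() <= 1.5 * 0.05
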