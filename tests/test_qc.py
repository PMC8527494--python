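"""Marker QC filters, exact HWE test and frequency imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from merinogp.containers import GenotypeMatrix
from merinogp.qc import (
    QCThresholds,
    apply_qc,
    hwe_exact_pvalue,
    impute_sporadic,
    marker_call_rate,
    marker_maf,
)
from tests.conftest import make_markers


def hwe_pvalue_oracle(n_AA, n_Aa, n_aa):
    """Independent enumeration oracle: log-gamma form of the conditional
    probability of each heterozygote count given the allele counts."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa

    def logprob(het):
        hom_a = (n_a - het) // 2
        hom_b = n - het - hom_a
        return (
            gammaln(n + 1)
            - gammaln(hom_a + 1) - gammaln(het + 1) - gammaln(hom_b + 1)
            + het * np.log(2)
            + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1)
        )

    feas = [h for h in range(min(n_a, 2 * n - n_a) + 1) if (n_a - h) % 2 == 0]
    logs = np.array([logprob(h) for h in feas])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[feas.index(n_Aa)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


class TestCallRateAndMaf:
    def test_call_rate_counts_missing(self):
        assert marker_call_rate(np.array([0, 1, 2, np.nan])) == 0.75
        assert marker_call_rate(np.array([0.0, 1.0])) == 1.0
        assert marker_call_rate(np.array([np.nan, np.nan])) == 0.0

    def test_maf_folds_frequency(self):
        assert marker_maf(np.array([0, 0, 0, 1.0])) == pytest.approx(0.125)
        assert marker_maf(np.array([2.0, 2, 2, 2])) == 0.0
        assert marker_maf(np.array([1.0, 1.0])) == 0.5

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError):
            marker_maf(np.array([np.nan]))


class TestHweExact:
    def test_monomorphic_gives_one(self):
        assert hwe_exact_pvalue(20, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 7) == 1.0

    def test_modal_outcome_near_one(self):
        # 50% frequency, observed het count is the null mode
        assert hwe_exact_pvalue(25, 50, 25) >= 0.99

    def test_heterozygote_excess_detected(self):
        assert hwe_exact_pvalue(0, 100, 0) < 1e-20

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(-1, 2, 3)

    @pytest.mark.parametrize("counts", [(0, 4, 0), (0, 10, 0), (3, 4, 3)])
    def test_examples_match_enumeration(self, counts):
        assert hwe_exact_pvalue(*counts) == pytest.approx(hwe_pvalue_oracle(*counts))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=0, max_value=200),
    )
    def test_agrees_with_enumeration_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0 or n_aa + n_ab + n_bb > 200:
            return
        expected = hwe_pvalue_oracle(n_aa, n_ab, n_bb)
        assert hwe_exact_pvalue(n_aa, n_ab, n_bb) == pytest.approx(expected, rel=1e-9)


def build_gm(columns, chroms=None):
    cols = [np.asarray(c, dtype=float) for c in columns]
    d = np.column_stack(cols)
    markers = make_markers(d.shape[1])
    if chroms is not None:
        markers["chrom"] = chroms
    ids = [f"i{k}" for k in range(d.shape[0])]
    return GenotypeMatrix(d, ids, markers)


class TestApplyQc:
    def test_call_rate_boundary_kept_below_removed(self):
        # 40 individuals: 2 missing = 0.95 exactly (kept), 3 missing (removed)
        base = np.ones(40)
        at = base.copy(); at[:2] = np.nan
        below = base.copy(); below[:3] = np.nan
        poly = np.tile([0.0, 1, 2, 1], 10)
        gm = build_gm([np.where(np.isnan(at), np.nan, poly),
                       np.where(np.isnan(below), np.nan, poly),
                       poly])
        out, report = apply_qc(gm, QCThresholds())
        assert out.marker_ids == ["snp1", "snp3"]
        assert report.removed_call_rate == 1

    def test_maf_boundary(self):
        # p = 0.005 -> removed; p = 0.01 -> kept (strict 'below' removal)
        n = 100
        rare = np.zeros(n); rare[0] = 1  # MAF 0.005
        edge = np.zeros(n); edge[0] = 2  # MAF 0.01
        common = np.tile([0.0, 1, 2, 1], 25)
        gm = build_gm([rare, edge, common])
        out, report = apply_qc(gm, QCThresholds(min_hwe_p=0.0))
        assert out.marker_ids == ["snp2", "snp3"]
        assert report.removed_maf == 1

    def test_non_autosomal_removed_first(self):
        col = np.tile([0.0, 1, 2, 1], 5)
        gm = build_gm([col, col, col], chroms=["1", "X", "MT"])
        out, report = apply_qc(gm, QCThresholds())
        assert out.marker_ids == ["snp1"]
        assert report.removed_non_autosomal == 2

    def test_hwe_filter_removes_extreme_deviation(self):
        het_only = np.ones(60)  # p ~ 1e-26
        ok = np.tile([0.0, 1, 2, 1], 15)
        gm = build_gm([het_only, ok])
        out, report = apply_qc(gm, QCThresholds())
        assert out.marker_ids == ["snp2"]
        assert report.removed_hwe == 1

    def test_report_reconciles_and_idempotent(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.3, size=(60, 30)).astype(float)
        d[rng.random((60, 30)) < 0.1] = np.nan
        d[:, 5] = 0.0  # monomorphic -> MAF 0
        gm = GenotypeMatrix(d, [f"i{k}" for k in range(60)], make_markers(30))
        out, report = apply_qc(gm, QCThresholds())
        assert report.n_markers_out == out.n_markers
        assert report.n_markers_in - report.n_markers_out == (
            report.removed_non_autosomal + report.removed_call_rate
            + report.removed_maf + report.removed_hwe
        )
        out2, report2 = apply_qc(out, QCThresholds())
        assert out2.marker_ids == out.marker_ids
        assert report2.n_markers_out == report.n_markers_out

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QCThresholds(min_maf=1.5)


class TestImpute:
    def test_expected_dosage_fill(self):
        gm = build_gm([[0.0, 2.0, np.nan]])
        out, n = impute_sporadic(gm)
        assert out.dosages[2, 0] == pytest.approx(1.0)
        assert n == 1

    def test_complete_matrix_unchanged(self, small_dataset):
        gm, _, _ = small_dataset
        out, n = impute_sporadic(gm)
        assert n == 0
        np.testing.assert_array_equal(out.dosages, gm.dosages)

    def test_sampled_mode_reproducible_and_integer(self):
        gm = build_gm([[0.0, 1.0, 2.0, np.nan, np.nan]])
        a, _ = impute_sporadic(gm, mode="sampled", seed=11)
        b, _ = impute_sporadic(gm, mode="sampled", seed=11)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert set(np.unique(a.dosages)) <= {0.0, 1.0, 2.0}

    def test_never_touches_observed_cells(self):
        gm = build_gm([[0.0, 2.0, np.nan], [1.0, np.nan, 1.0]])
        out, _ = impute_sporadic(gm, mode="sampled", seed=1)
        obs = np.isfinite(gm.dosages)
        np.testing.assert_array_equal(out.dosages[obs], gm.dosages[obs])

    def test_all_missing_marker_rejected(self):
        gm = build_gm([[np.nan, np.nan]])
        with pytest.raises(ValueError, match="entirely missing"):
            impute_sporadic(gm)
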