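"""Matrix gates: variance, validity, imputation, quantifiability, fold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadromics import (
    ExpressionMatrix,
    group_fold_change,
    lfq_impute,
    min_valid_count,
    quantifiability_mask,
    tpm_variance_filter,
    validity_filter,
)
from quadromics.matrices import LayerError
from quadromics.preprocess import ImputationError


def tpm_matrix(design, rows):
    return ExpressionMatrix(
        pd.DataFrame(rows, columns=design.sample_ids), layer="TPM"
    )


class TestVarianceFilter:
    def test_constant_feature_removed_varying_retained(self, design):
        vals = {
            "flat": np.full(36, 7.0),
            "near_flat": np.r_[np.full(35, 7.0), 7.1],
            "noisy": np.linspace(1, 5, 36),
        }
        m = tpm_matrix(design, pd.DataFrame(vals).T.to_numpy())
        m.values.index = list(vals)
        kept = tpm_variance_filter(m)
        assert kept == ["near_flat", "noisy"]

    def test_all_zero_matrix_gives_empty_result(self, design):
        m = tpm_matrix(design, np.zeros((3, 36)))
        assert tpm_variance_filter(m) == []

    def test_lfq_layer_rejected(self, make_lfq):
        with pytest.raises(LayerError):
            tpm_variance_filter(make_lfq())


class TestMinValidCount:
    @pytest.mark.parametrize(
        "n,frac,expected", [(18, 0.70, 13), (10, 0.70, 8), (1, 0.70, 1), (18, 0.0, 1)]
    )
    def test_known_thresholds(self, n, frac, expected):
        assert min_valid_count(n, frac) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 500), st.floats(0.0, 0.999))
    def test_returns_smallest_count_strictly_above_fraction(self, n, frac):
        k = min_valid_count(n, frac)
        assert 1 <= k <= n
        assert k / n > frac
        assert (k - 1) / n <= frac


class TestValidityFilter:
    @pytest.mark.parametrize("n_valid,expected", [(13, True), (12, False), (18, True)])
    def test_70_percent_rule_at_n18(self, design, make_lfq, n_valid, expected):
        female_ids = set(design.stratum_ids("F")[:n_valid])

        def fill(i, srow):
            if srow["sex"] == "M":
                return 2.0 ** 25
            return 2.0 ** 25 if srow["sample_id"] in female_ids else np.nan

        m = make_lfq(n_features=1, fill=fill)
        report = validity_filter(m, design, "F")
        assert report.table.loc["prot0", "n_valid"] == n_valid
        assert bool(report.table.loc["prot0", "validity_pass"]) is expected

    def test_zero_tpm_does_not_count_as_valid(self, design):
        row = np.zeros(36)
        f_ids = design.stratum_ids("F")
        row[[design.sample_ids.index(s) for s in f_ids[:12]]] = 5.0
        m = tpm_matrix(design, row[None, :])
        assert not validity_filter(m, design, "F").table["validity_pass"].iloc[0]

    def test_monotone_in_fraction(self, design, make_lfq, monkeypatch):
        rng = np.random.default_rng(5)

        def fill(i, srow):
            return np.nan if rng.random() < 0.3 else 2.0 ** 24

        m = make_lfq(n_features=30, fill=fill)
        passed = None
        for frac in (0.0, 0.3, 0.6, 0.9):
            now = set(validity_filter(m, design, "M", frac).passing("validity_pass"))
            if passed is not None:
                assert now <= passed
            passed = now


class TestImputation:
    def test_fully_observed_matrix_unchanged(self, design, make_lfq):
        m = make_lfq(n_features=5)
        out = lfq_impute(m, design)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_percentile_of_condition_block_fills_missing(self, design, make_lfq):
        cell = design.cell_ids("F", "GL00")

        def fill(i, srow):
            if srow["sample_id"] == cell[0]:
                return np.nan
            if srow["sample_id"] in cell:
                return {cell[1]: 100.0, cell[2]: 300.0}[srow["sample_id"]]
            return 200.0

        m = make_lfq(n_features=1, fill=fill)
        out = lfq_impute(m, design, percentile=1.0)
        # brute-force oracle: sorted observed {100, 300}, linear
        # interpolation at position 0.01 * (2 - 1)
        expected = 100.0 + 0.01 * (300.0 - 100.0)
        assert out.values.loc["prot0", cell[0]] == pytest.approx(expected)
        # observed entries bit-identical
        untouched = [s for s in design.sample_ids if s != cell[0]]
        pd.testing.assert_frame_equal(out.values[untouched], m.values[untouched])

    def test_idempotent(self, design, make_lfq):
        rng = np.random.default_rng(3)

        def fill(i, srow):
            return np.nan if rng.random() < 0.2 else float(2 ** 24 + i)

        m = make_lfq(n_features=10, fill=fill)
        once = lfq_impute(m, design)
        twice = lfq_impute(once, design)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_condition_with_no_observed_value_raises(self, design, make_lfq):
        dead = set(design.cell_ids("M", "GL05"))

        def fill(i, srow):
            return np.nan if srow["sample_id"] in dead else 2.0 ** 23

        m = make_lfq(n_features=1, fill=fill)
        with pytest.raises(ImputationError, match="prot0.*M/GL05"):
            lfq_impute(m, design)


class TestQuantifiability:
    def test_single_peptide_protein_excluded(self, design, make_lfq):
        m = make_lfq(n_features=2, peptide_counts=[1, 2])
        kept = quantifiability_mask(m, design, ("GL40", "GL00"), stratum="F")
        assert kept == ["prot1"]

    def test_complete_in_one_condition_is_enough(self, design, make_lfq):
        gl00_f = set(design.cell_ids("F", "GL00"))

        def fill(i, srow):
            return np.nan if srow["sample_id"] in gl00_f else 2.0 ** 24

        m = make_lfq(n_features=1, fill=fill, peptide_counts=[3])
        assert quantifiability_mask(m, design, ("GL40", "GL00"), stratum="F") == ["prot0"]

    def test_two_of_three_in_both_conditions_excluded(self, design, make_lfq):
        drop = {design.cell_ids("F", "GL40")[0], design.cell_ids("F", "GL00")[0]}

        def fill(i, srow):
            return np.nan if srow["sample_id"] in drop else 2.0 ** 24

        m = make_lfq(n_features=1, fill=fill, peptide_counts=[2])
        assert quantifiability_mask(m, design, ("GL40", "GL00"), stratum="F") == []

    def test_unknown_group_rejected(self, design, make_lfq):
        with pytest.raises(ValueError, match="GLXX"):
            quantifiability_mask(make_lfq(), design, ("GLXX", "GL00"))


class TestFoldChange:
    def _matrix_with_cell_means(self, design, gl40, gl00, other=100.0):
        def value(srow):
            if srow["sex"] != "F":
                return other
            return {"GL40": gl40, "GL00": gl00}.get(srow["group"], other)

        row = [value(srow) for _, srow in design.samples.iterrows()]
        return ExpressionMatrix(
            pd.DataFrame([row], index=["f"], columns=design.sample_ids), layer="TPM"
        )

    @pytest.mark.parametrize(
        "gl40,gl00,ratio,passes",
        [(200.0, 50.0, 4.0, True), (30.0, 100.0, 0.3, True), (80.0, 80.0, 1.0, False)],
    )
    def test_two_fold_in_either_direction(self, design, gl40, gl00, ratio, passes):
        m = self._matrix_with_cell_means(design, gl40, gl00)
        out = group_fold_change(m, design, "F")
        assert out.loc["f", "ratio"] == pytest.approx(ratio)
        assert bool(out.loc["f", "fold_pass"]) is passes

    def test_zero_denominator_undefined_and_fails(self, design):
        m = self._matrix_with_cell_means(design, 200.0, 0.0)
        out = group_fold_change(m, design, "F")
        assert np.isnan(out.loc["f", "ratio"])
        assert not out.loc["f", "fold_pass"]

    def test_invariant_to_global_rescaling(self, design, make_lfq):
        m = make_lfq(n_features=8)
        scaled = ExpressionMatrix(
            m.values * 37.5, layer="LFQ", peptide_counts=m.peptide_counts
        )
        a = group_fold_change(m, design, "M")
        b = group_fold_change(scaled, design, "M")
        pd.testing.assert_series_equal(a["ratio"], b["ratio"], rtol=1e-12)
        pd.testing.assert_series_equal(a["fold_pass"], b["fold_pass"])
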