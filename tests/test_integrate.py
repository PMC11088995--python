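"""Quadrant assignment, regulation classes, ANOVA and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadromics import (
    assign_quadrant,
    balanced_two_way_anova,
    classify_regulation,
    overrepresentation_test,
    pair_layers,
    read_gmt,
    simulate_cohort,
    two_way_anova,
)
from quadromics.integrate import AmbiguityError, SexTermError
from quadromics.matrices import ExpressionMatrix

T = 0.46876  # representative significance threshold for n=18 screens


def quadrant_oracle(x, y, t):
    """Independent region predicates for the row-major 3x3 grid."""
    preds = {
        1: x <= -t and y >= t,
        2: -t < x < t and y >= t,
        3: x >= t and y >= t,
        4: x <= -t and -t < y < t,
        5: -t < x < t and -t < y < t,
        6: x >= t and -t < y < t,
        7: x <= -t and y <= -t,
        8: -t < x < t and y <= -t,
        9: x >= t and y <= -t,
    }
    fired = [q for q, hit in preds.items() if hit]
    return fired


class TestQuadrants:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (0.7, 0.7, 3),    # positive at both layers
            (0.7, 0.1, 6),    # protein-only positive
            (0.0, 0.0, 5),    # origin: nothing significant
            (-0.5, 0.5, 1),   # protein negative, transcript positive
            (-0.7, -0.7, 7),
            (0.1, -0.7, 8),
            (-0.6, 0.1, 4),
            (0.2, 0.6, 2),
            (0.6, -0.6, 9),
        ],
    )
    def test_reference_placements(self, x, y, expected):
        assert assign_quadrant(x, y, T) == expected

    def test_partition_fires_exactly_one_region(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(-1, 1, size=(10_000, 2))
        quads = assign_quadrant(xy[:, 0], xy[:, 1], T)
        for (x, y), q in zip(xy, quads):
            fired = quadrant_oracle(x, y, T)
            assert fired == [q]

    def test_negation_maps_q_to_10_minus_q(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(-1, 1, size=(2_000, 2))
        q = assign_quadrant(xy[:, 0], xy[:, 1], T)
        q_neg = assign_quadrant(-xy[:, 0], -xy[:, 1], T)
        np.testing.assert_array_equal(q + q_neg, 10)

    def test_boundary_ties_go_to_significant_side(self):
        assert assign_quadrant(T, T, T) == 3
        assert assign_quadrant(-T, 0.0, T) == 4
        assert assign_quadrant(T, T, T) != assign_quadrant(T, T, T, boundary="central")

    def test_rho_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            assign_quadrant(1.2, 0.0, T)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(-1, 1), st.floats(-1, 1),
        st.floats(0.05, 0.99),
    )
    def test_partition_property(self, x, y, t):
        q = assign_quadrant(x, y, t)
        assert 1 <= q <= 9


class TestRegulationClasses:
    @pytest.mark.parametrize(
        "quadrant,fold2,expected",
        [
            (3, True, "transcriptional_pos"),
            (7, True, "transcriptional_neg"),
            (6, True, "post_transcriptional_pos"),
            (9, True, "post_transcriptional_pos"),
            (1, True, "post_transcriptional_neg"),
            (4, True, "post_transcriptional_neg"),
            (2, False, "transcript_only_pos"),
            (8, True, "transcript_only_neg"),
            (5, True, "none"),
            (3, False, "none"),  # not two-fold: not coloured
            (6, False, "none"),
        ],
    )
    def test_mapping(self, quadrant, fold2, expected):
        assert classify_regulation(quadrant, fold2) == expected

    def test_invalid_quadrant_rejected(self):
        with pytest.raises(ValueError):
            classify_regulation(0, True)


class TestPairing:
    def test_disjoint_layers_pair_nothing(self):
        t = pd.DataFrame({"rho": [0.5]}, index=["a"])
        p = pd.DataFrame({"rho": [0.5]}, index=["b"])
        paired, leftover = pair_layers(t, p)
        assert paired.empty
        assert leftover == {"transcript_only": ["a"], "protein_only": ["b"]}

    def test_full_overlap_pairs_everything(self):
        t = pd.DataFrame({"rho": [0.1, 0.2]}, index=["a", "b"])
        paired, leftover = pair_layers(t, t.copy())
        assert len(paired) == 2
        assert leftover == {"transcript_only": [], "protein_only": []}

    def test_duplicate_ids_rejected(self):
        t = pd.DataFrame({"rho": [0.1, 0.2]}, index=["a", "a"])
        with pytest.raises(AmbiguityError):
            pair_layers(t, t)

    def test_transcript_only_features_excluded_exactly(self):
        cohort = simulate_cohort(seed=5, n_transcript_only=25)
        t = pd.DataFrame(index=cohort.tpm.feature_ids)
        p = pd.DataFrame(index=cohort.lfq.feature_ids)
        paired, leftover = pair_layers(t, p)
        assert len(paired) == len(cohort.lfq.feature_ids)
        assert len(leftover["transcript_only"]) == 25
        assert all(g.startswith("transcript_only") for g in leftover["transcript_only"])


def anova_oracle(y, a, b):
    """Independent route: statsmodels OLS + type-I anova table."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "a": a, "b": b})
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    return sm.stats.anova_lm(fit, typ=1)


class TestTwoWayAnova:
    @pytest.mark.parametrize("levels_b", [2, 3])
    def test_matches_statsmodels_on_balanced_toys(self, levels_b):
        rng = np.random.default_rng(levels_b)
        a = np.repeat(["x", "y"], levels_b * 3)
        b = np.tile(np.repeat([f"b{i}" for i in range(levels_b)], 3), 2)
        y = rng.normal(size=a.size) + (a == "x") * 0.8
        rec = balanced_two_way_anova(y, a, b)
        tab = anova_oracle(y, a, b)
        assert rec.f_sex == pytest.approx(tab.loc["C(a)", "F"], abs=1e-10)
        assert rec.f_treatment == pytest.approx(tab.loc["C(b)", "F"], abs=1e-10)
        assert rec.f_interaction == pytest.approx(tab.loc["C(a):C(b)", "F"], abs=1e-10)
        assert rec.p_sex == pytest.approx(tab.loc["C(a)", "PR(>F)"], abs=1e-10)

    def test_pure_sex_effect_detected_only_on_sex_term(self, design):
        rng = np.random.default_rng(0)
        vals = 100.0 + (design.samples["sex"] == "F").to_numpy() * 100.0
        vals = vals + rng.normal(0, 1e-6, size=36)
        m = ExpressionMatrix(
            pd.DataFrame([vals], index=["g"], columns=design.sample_ids),
            layer="TPM",
        )
        rec = two_way_anova(m, design, "g")
        assert rec.p_sex < 1e-10
        assert rec.p_treatment > 0.05
        assert rec.p_interaction > 0.05

    def test_constant_feature_reports_undefined_f(self, design):
        m = ExpressionMatrix(
            pd.DataFrame([[8.0] * 36], index=["g"], columns=design.sample_ids),
            layer="TPM",
        )
        rec = two_way_anova(m, design, "g")
        assert not rec.defined
        assert math.isnan(rec.f_sex)

    def test_single_sex_feature_raises(self, design, make_lfq):
        def fill(i, srow):
            return 2.0 ** 24 if srow["sex"] == "F" else np.nan

        m = make_lfq(n_features=1, fill=fill)
        with pytest.raises(SexTermError, match="only in F"):
            two_way_anova(m, design, "prot0")

    def test_sums_of_squares_partition_total(self, cohort):
        gene = cohort.truth.ids_of("sex_dimorphic")[0]
        rec = two_way_anova(cohort.tpm, cohort.design, gene)
        y = np.log2(cohort.tpm.values.loc[gene] + 1.0)
        # reconstruct SS from F, df and residual MS via the oracle route
        tab = anova_oracle(
            y.to_numpy(), cohort.design.samples["sex"], cohort.design.samples["group"]
        )
        total = ((y - y.mean()) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(total, rel=1e-10)
        assert rec.p_sex == pytest.approx(tab.loc["C(a)", "PR(>F)"], abs=1e-10)


def hypergeom_tail_oracle(N, K, n, k):
    """Exact upper tail by direct combinatorial enumeration."""
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(n, K) + 1)
    ) / math.comb(N, n)


class TestOverrepresentation:
    def test_selection_equal_background_gives_p_one(self):
        bg = {f"g{i}" for i in range(10)}
        ann = {"term": {"g0", "g1", "g2"}}
        out = overrepresentation_test(bg, bg, ann)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_combinatorial_enumeration(self):
        bg = [f"g{i}" for i in range(20)]
        term = set(bg[:5])
        selection = set(bg[:4]) | {bg[10], bg[11]}  # k=4 of K=5, n=6
        out = overrepresentation_test(selection, bg, {"t": term})
        assert out["p"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(20, 5, 6, 4), rel=1e-12
        )

    def test_disjoint_term_gives_p_one(self):
        bg = [f"g{i}" for i in range(12)]
        out = overrepresentation_test(set(bg[:3]), bg, {"t": set(bg[8:])})
        assert out.loc[0, "k"] == 0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_bonferroni_scales_with_terms_tested(self):
        bg = [f"g{i}" for i in range(30)]
        ann = {f"t{j}": set(bg[j: j + 6]) for j in range(5)}
        out = overrepresentation_test(set(bg[:6]), bg, ann)
        for _, row in out.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p"] * 5))

    def test_selection_outside_background_rejected(self):
        with pytest.raises(ValueError, match="not contained"):
            overrepresentation_test({"x"}, {"a", "b"}, {})

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "respiration\tcomplex III\tUqcrb\tUqcrq\tCyc1\n"
            "acute_phase\tinflammation\tC4b\tMbl2\n"
        )
        sets = read_gmt(path)
        assert sets == {
            "respiration": {"Uqcrb", "Uqcrq", "Cyc1"},
            "acute_phase": {"C4b", "Mbl2"},
        }
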