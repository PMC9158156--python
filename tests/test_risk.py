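"""PRS computation, population scaling, APOE risk, family averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famead import (
    ApoeModel, PolygenicScorer, apoe_risk, beta_to_or, compute_prs,
    family_average, load_prs_weights, scale_to_population,
)


def weight_table(weights, r2=None, apoe=None):
    n = len(weights)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "risk_allele": ["A"] * n,
        "weight": weights,
        "imputation_r2": r2 if r2 is not None else [0.9] * n,
        "is_apoe_region": apoe if apoe is not None else [False] * n,
    })


class TestComputePrs:
    def test_zero_dosages_zero_score(self):
        w = weight_table([0.1, 0.2])
        d = pd.DataFrame(0.0, index=["s1"], columns=["v0", "v1"])
        assert compute_prs(d, w).loc["s1"] == 0.0

    def test_linearity_single_variant(self):
        w = weight_table([0.1])
        d = pd.DataFrame({"v0": [2.0]}, index=["s1"])
        assert compute_prs(d, w).loc["s1"] == pytest.approx(0.2)

    def test_loop_oracle_equals_vectorized(self, rng):
        """Brute-force per-term summation matches the vectorized score on a
        random 35-variant panel."""
        w = load_prs_weights()
        d = pd.DataFrame(rng.integers(0, 3, (10, len(w))).astype(float),
                         index=[f"s{i}" for i in range(10)],
                         columns=list(w["variant_id"]))
        scores = compute_prs(d, w)
        lut = dict(zip(w["variant_id"], w["weight"]))
        kept = w.loc[w["imputation_r2"] >= 0.3, "variant_id"]
        for s in d.index:
            manual = sum(d.loc[s, v] * lut[v] for v in kept)
            assert scores.loc[s] == pytest.approx(manual, abs=1e-12)

    def test_low_r2_variants_dropped(self):
        w = weight_table([1.0, 1.0], r2=[0.2, 0.9])
        d = pd.DataFrame([[2.0, 2.0]], index=["s"], columns=["v0", "v1"])
        assert compute_prs(d, w).loc["s"] == pytest.approx(2.0)
        assert compute_prs(d, w, min_r2=0.6).loc["s"] == pytest.approx(2.0)
        with pytest.raises(ValueError, match="no panel variants"):
            compute_prs(d, w, min_r2=0.95)

    def test_apoe_region_excluded(self):
        w = weight_table([1.0, 1.0], apoe=[True, False])
        d = pd.DataFrame([[2.0, 1.0]], index=["s"], columns=["v0", "v1"])
        assert compute_prs(d, w).loc["s"] == pytest.approx(1.0)

    def test_missing_dosage_skipped_per_sample(self):
        w = weight_table([0.5, 0.5])
        d = pd.DataFrame([[np.nan, 2.0], [1.0, 1.0]], index=["s1", "s2"],
                         columns=["v0", "v1"])
        out = compute_prs(d, w)
        assert out.loc["s1"] == pytest.approx(1.0)
        assert out.loc["s2"] == pytest.approx(1.0)

    def test_out_of_range_dosage_rejected(self):
        w = weight_table([0.5])
        d = pd.DataFrame([[2.5]], index=["s"], columns=["v0"])
        with pytest.raises(ValueError, match="dosages"):
            compute_prs(d, w)

    @given(st.lists(st.floats(0, 2), min_size=3, max_size=3),
           st.lists(st.floats(0, 2), min_size=3, max_size=3))
    def test_prs_additivity(self, da, db):
        """Score of summed dosage vectors equals the sum of scores (when the
        sum stays a valid dosage)."""
        if any(a + b > 2 for a, b in zip(da, db)):
            return
        w = weight_table([0.1, -0.2, 0.3])
        cols = ["v0", "v1", "v2"]
        d = pd.DataFrame([da, db, [a + b for a, b in zip(da, db)]],
                         index=["a", "b", "ab"], columns=cols)
        s = compute_prs(d, w)
        assert s.loc["ab"] == pytest.approx(s.loc["a"] + s.loc["b"], abs=1e-9)


class TestScaling:
    def test_control_mean_maps_to_zero(self, rng):
        raw = pd.Series(rng.normal(1.0, 0.3, 50))
        controls = rng.normal(1.0, 0.3, 980)
        scaled = scale_to_population(raw, controls)
        assert scale_to_population(pd.Series([controls.mean()]), controls).iloc[0] == 0

    def test_shift_invariance(self, rng):
        raw = pd.Series(rng.normal(0, 1, 20))
        controls = rng.normal(0, 1, 100)
        c = 0.7
        shifted = scale_to_population(raw, controls + c)
        base = scale_to_population(raw, controls)
        assert np.allclose(shifted, base - c)

    def test_scaled_control_mean_is_zero(self, rng):
        controls = pd.Series(rng.normal(0.5, 0.2, 980))
        scaled = scale_to_population(controls, controls)
        assert abs(scaled.mean()) < 1e-12

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            scale_to_population(pd.Series([1.0]), [])

    def test_transformer_fit_then_transform(self, rng):
        w = load_prs_weights()
        cols = list(w["variant_id"])
        ctrl = pd.DataFrame(rng.integers(0, 3, (200, len(cols))).astype(float),
                            columns=cols)
        cohort = pd.DataFrame(rng.integers(0, 3, (30, len(cols))).astype(float),
                              columns=cols)
        scorer = PolygenicScorer(weights=w).fit(ctrl)
        out = scorer.transform(cohort)
        manual = compute_prs(cohort, w) - compute_prs(ctrl, w).mean()
        assert np.allclose(out, manual)
        # sklearn param plumbing
        assert "min_r2" in scorer.get_params()


class TestApoeRisk:
    @pytest.mark.parametrize("genotype,expected", [
        ("33", -0.36),
        ("34", 0.84),
        ("44", 2.04),
        ("23", -0.83),
        ("24", 0.37),
        ("22", -1.30),
    ])
    def test_closed_form(self, genotype, expected):
        assert apoe_risk(genotype) == pytest.approx(expected)

    def test_e33_is_minus_offset(self):
        model = ApoeModel(population_mean_offset=0.5)
        assert apoe_risk("33", model) == pytest.approx(-0.5)

    def test_missing_propagates(self):
        assert np.isnan(apoe_risk("NA"))
        assert np.isnan(apoe_risk(None))

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="APOE genotype"):
            apoe_risk("45")

    @given(st.sampled_from(["22", "23", "24", "33", "34", "44"]),
           st.sampled_from(["22", "23", "24", "33", "34", "44"]))
    def test_monotone_in_e4_and_e2(self, g1, g2):
        """Risk is non-decreasing in e4 count and non-increasing in e2 count."""
        n4a, n2a = g1.count("4"), g1.count("2")
        n4b, n2b = g2.count("4"), g2.count("2")
        if n4a >= n4b and n2a <= n2b:
            assert apoe_risk(g1) >= apoe_risk(g2)


class TestFamilyAverage:
    def membership(self):
        return pd.DataFrame({
            "sample_id": ["a", "b", "c", "u"],
            "family_id": ["F1", "F1", "F2", "F1"],
            "affected": [True, True, True, False],
        })

    def test_mean_over_affected_only(self):
        vals = {"a": 0.84, "b": 2.04, "c": 1.0, "u": 99.0}
        out = family_average(vals, self.membership())
        assert out["F1"] == pytest.approx(1.44)
        assert out["F2"] == pytest.approx(1.0)

    def test_three_member_mix(self):
        m = pd.DataFrame({"sample_id": ["a", "b", "c"],
                          "family_id": ["F", "F", "F"],
                          "affected": [True] * 3})
        vals = {"a": apoe_risk("44"), "b": apoe_risk("44"), "c": apoe_risk("34")}
        assert family_average(vals, m)["F"] == pytest.approx(1.64)

    def test_single_member(self):
        m = pd.DataFrame({"sample_id": ["a"], "family_id": ["F"],
                          "affected": [True]})
        assert family_average({"a": 0.3}, m)["F"] == pytest.approx(0.3)

    def test_status_column_mci_counts_as_affected(self):
        m = pd.DataFrame({"sample_id": ["a", "b"], "family_id": ["F", "F"],
                          "status": ["MCI", "unaffected"]})
        assert family_average({"a": 1.0, "b": 5.0}, m)["F"] == pytest.approx(1.0)

    def test_family_without_scored_affected_rejected(self):
        m = pd.DataFrame({"sample_id": ["a"], "family_id": ["F"],
                          "affected": [True]})
        with pytest.raises(ValueError, match="without a scored"):
            family_average({"a": np.nan}, m)

    @given(st.lists(st.floats(-2, 2), min_size=1, max_size=6))
    def test_average_within_member_range(self, scores):
        m = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(scores))],
                          "family_id": "F", "affected": True})
        out = family_average(dict(zip(m["sample_id"], scores)), m)["F"]
        assert min(scores) - 1e-9 <= out <= max(scores) + 1e-9


class TestBetaToOr:
    def test_values(self):
        assert beta_to_or(0.0) == pytest.approx(1.0)
        assert round(float(beta_to_or(0.61)), 2) == 1.84
        assert round(float(beta_to_or(1.0)), 2) == 2.72


def test_prs_true_liability_recovered(small_cohort):
    """Recomputing PRS from the emitted dosages reproduces the generator's
    recorded true scores (slope exactly 1)."""
    scores = compute_prs(small_cohort.prs_dosages, small_cohort.weights,
                         min_r2=0.0)
    truth = pd.Series(small_cohort.truth.prs_true)
    aligned = scores.loc[truth.index]
    assert np.allclose(aligned, truth)
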