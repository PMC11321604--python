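"""Random-effects pooling: REML tau2, HKSJ-Jackson interval, SE reconstruction.

Expected values for the four-study per-scanner inputs were computed
independently with R metafor 4.8-0 (rma(yi, sei, method="REML", test="knha"))
and are frozen here.
"""

import numpy as np
import pytest
from scipy import stats

from rpcseg.meta import (
    MetaResult, StudyInput, ci_to_se, forest_data, meta_pool, read_studies_csv,
    reml_tau2,
)

#: per-scanner printed summaries: (effect, lower, upper) per study set
STUDY_SETS = {
    "both": [(0.81, 0.77, 0.84), (0.71, 0.65, 0.78),
             (0.76, 0.72, 0.80), (0.80, 0.78, 0.83)],
    "normalize_only": [(0.80, 0.77, 0.84), (0.70, 0.64, 0.76),
                       (0.74, 0.70, 0.79), (0.81, 0.78, 0.83)],
    "augment_only": [(0.81, 0.77, 0.84), (0.70, 0.64, 0.76),
                     (0.55, 0.47, 0.64), (0.79, 0.77, 0.82)],
    "neither": [(0.80, 0.77, 0.84), (0.69, 0.63, 0.75),
                (0.56, 0.48, 0.65), (0.78, 0.76, 0.81)],
}

# frozen metafor oracle: mu, tau2, ci_lower, ci_upper
METAFOR = {
    "both": (0.776948, 0.00109409, 0.7105, 0.8434),
    "normalize_only": (0.767328, 0.00202737, 0.6866, 0.8480),
    "augment_only": (0.717548, 0.01229159, 0.5324, 0.9027),
    "neither": (0.712974, 0.01029088, 0.5424, 0.8836),
}


def studies_for(name):
    return [StudyInput(f"s{i}", y, ci_to_se(y, lo, hi))
            for i, (y, lo, hi) in enumerate(STUDY_SETS[name])]


class TestCiToSe:
    def test_printed_leica_ci(self):
        assert ci_to_se(0.71, 0.65, 0.78) == pytest.approx(0.13 / 3.919928, rel=1e-4)

    def test_zero_width_ci(self):
        assert ci_to_se(0.5, 0.5, 0.5) == 0.0

    def test_level_90_uses_smaller_quantile(self):
        se = ci_to_se(0.5, 0.4, 0.6, level=0.90)
        assert se == pytest.approx(0.2 / (2 * 1.6448536), rel=1e-5)

    def test_inverted_bounds_raise(self):
        with pytest.raises(ValueError, match="inverted"):
            ci_to_se(0.5, 0.6, 0.4)


class TestAgainstMetafor:
    @pytest.mark.parametrize("name", list(STUDY_SETS))
    def test_pooled_mean_and_tau2_match_reference(self, name):
        result = meta_pool(studies_for(name))
        mu, tau2, lo, hi = METAFOR[name]
        assert result.mu == pytest.approx(mu, abs=2e-4)
        assert result.tau2 == pytest.approx(tau2, abs=2e-5)
        assert result.ci_lower == pytest.approx(lo, abs=2e-3)
        assert result.ci_upper == pytest.approx(hi, abs=2e-3)

    def test_main_analysis_rounds_to_printed_values(self):
        result = meta_pool(studies_for("both"))
        assert round(result.mu, 2) == 0.78
        assert round(result.tau2, 3) == 0.001


class TestPoolingProperties:
    def test_identical_studies_give_common_value_and_zero_tau2(self):
        studies = [StudyInput(f"s{i}", 0.75, 0.02) for i in range(5)]
        r = meta_pool(studies)
        assert r.mu == pytest.approx(0.75)
        assert r.tau2 == pytest.approx(0.0, abs=1e-12)

    def test_equal_se_two_studies_pool_to_unweighted_mean(self):
        r = meta_pool([StudyInput("a", 0.6, 0.05), StudyInput("b", 0.8, 0.05)])
        assert r.mu == pytest.approx(0.7)

    def test_fixed_effect_equivalence_when_tau2_zero(self):
        """With homogeneous studies the pooled mean equals the closed-form FE estimate."""
        studies = [StudyInput("a", 0.70, 0.03), StudyInput("b", 0.70, 0.05),
                   StudyInput("c", 0.70, 0.02)]
        r = meta_pool(studies)
        w = np.array([1 / 0.03**2, 1 / 0.05**2, 1 / 0.02**2])
        fe = (w * 0.70).sum() / w.sum()
        assert r.tau2 == pytest.approx(0.0, abs=1e-12)
        assert r.mu == pytest.approx(fe)

    def test_pooled_mean_within_study_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 8)
            y = rng.uniform(0.2, 0.9, k)
            se = rng.uniform(0.01, 0.1, k)
            r = meta_pool([StudyInput(f"s{i}", yi, si)
                           for i, (yi, si) in enumerate(zip(y, se))])
            assert y.min() - 1e-12 <= r.mu <= y.max() + 1e-12

    def test_weights_sum_to_one(self):
        r = meta_pool(studies_for("both"))
        assert sum(r.weights.values()) == pytest.approx(1.0)

    def test_hksj_interval_at_least_as_wide_as_wald(self):
        """On the small-k four-study input the HKSJ CI dominates the Wald CI."""
        studies = studies_for("both")
        r = meta_pool(studies)
        v = np.array([s.se**2 for s in studies])
        w = 1 / (v + r.tau2)
        wald_half = stats.norm.ppf(0.975) * np.sqrt(1 / w.sum())
        assert (r.ci_upper - r.ci_lower) / 2 >= wald_half - 1e-12

    def test_i2_in_range_and_ci_ordered(self):
        r = meta_pool(studies_for("augment_only"))
        assert 0 <= r.i2 <= 100
        assert r.tau2_ci[0] <= r.tau2 <= r.tau2_ci[1]
        assert r.ci_lower <= r.mu <= r.ci_upper

    def test_single_study_passthrough_warns(self):
        with pytest.warns(UserWarning, match="single study"):
            r = meta_pool([StudyInput("only", 0.8, 0.02)])
        assert r.mu == 0.8 and r.k == 1

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="se must be > 0"):
            StudyInput("bad", 0.5, 0.0)


class TestRemlRecovery:
    @pytest.mark.parametrize("true_tau2", [0.001, 0.01])
    def test_reml_recovers_true_tau2_at_k50(self, true_tau2):
        """Simulated meta-analyses at k=50 recover tau2 with small relative bias."""
        rng = np.random.default_rng(123)
        k, reps = 50, 300
        estimates = []
        for _ in range(reps):
            se = rng.uniform(0.01, 0.05, size=k)
            y = 0.75 + rng.normal(0, np.sqrt(true_tau2 + se**2))
            estimates.append(reml_tau2(y, se**2))
        bias = np.mean(estimates) - true_tau2
        assert abs(bias) < 0.2 * true_tau2

    def test_zero_heterogeneity_floors_at_zero(self):
        rng = np.random.default_rng(5)
        se = np.full(20, 0.05)
        y = 0.7 + rng.normal(0, se)
        assert reml_tau2(y, se**2) >= 0.0


def test_read_studies_csv_accepts_ci_or_se(tmp_path):
    p = tmp_path / "studies.csv"
    p.write_text("label,effect,lower,upper\nphilips,0.81,0.77,0.84\n"
                 "leica,0.71,0.65,0.78\n")
    studies = read_studies_csv(p)
    assert studies[0].se == pytest.approx(ci_to_se(0.81, 0.77, 0.84))
    p2 = tmp_path / "studies_se.csv"
    p2.write_text("label,effect,se\na,0.8,0.02\nb,0.7,0.04\n")
    assert read_studies_csv(p2)[1].se == 0.04


def test_malformed_study_row_names_row(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("label,effect,lower,upper\nphilips,0.81,0.9,0.7\n")
    with pytest.raises(ValueError, match="row 0"):
        read_studies_csv(p)


def test_forest_data_has_diamond_row():
    studies = studies_for("both")
    r = meta_pool(studies)
    df = forest_data(studies, r)
    assert list(df.kind).count("diamond") == 1
    assert len(df) == 5
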