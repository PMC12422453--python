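"""Effect sizes, t-tests, and mixed-model inference."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from skintherm.simulate import GenerativeConfig, simulate_measurements
from skintherm.stats import (ThermalMixedModel, differential_outcome, fit_lmm,
                             one_sample_test, paired_test, skin_tone_report,
                             subject_average)


def vector_with(mean, sd, n, rng=None):
    """Deterministic vector with exactly the requested sample mean and SD."""
    base = np.linspace(-1, 1, n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


class TestSubjectAverage:
    def _records(self, rows):
        return pd.DataFrame(rows)

    def test_single_record_identity_and_two_record_mean(self):
        recs = self._records([
            dict(subject_id="a", phase="baseline", region="roi", median_temp_C=30.0),
            dict(subject_id="a", phase="cooled", region="roi", median_temp_C=30.0),
            dict(subject_id="a", phase="cooled", region="roi", median_temp_C=32.0),
        ])
        out = subject_average(recs)
        cooled = out[(out["phase"] == "cooled")]["median_temp_C"].iloc[0]
        baseline = out[(out["phase"] == "baseline")]["median_temp_C"].iloc[0]
        assert baseline == 30.0 and cooled == 31.0

    def test_matches_groupby_sum_oracle(self, rng):
        n = 1000
        recs = pd.DataFrame({
            "subject_id": rng.choice([f"s{i}" for i in range(12)], n),
            "phase": rng.choice(["baseline", "cooled"], n),
            "region": rng.choice(["roi", "control"], n),
            "median_temp_C": rng.normal(30, 1, n),
        })
        out = subject_average(recs).set_index(["subject_id", "phase", "region"])
        for key, grp in recs.groupby(["subject_id", "phase", "region"]):
            oracle = grp["median_temp_C"].sum() / len(grp)
            assert out.loc[key, "median_temp_C"] == pytest.approx(oracle, rel=1e-12)


class TestOneSampleTest:
    def test_constant_deltas_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            one_sample_test(np.full(10, -3.2))

    def test_table_style_arithmetic(self):
        # mean -3.2, SD 0.6, n 35: t = mean/(SD/sqrt(n)), d = mean/SD
        res = one_sample_test(vector_with(-3.2, 0.6, 35))
        assert res.t == pytest.approx(-3.2 / (0.6 / np.sqrt(35)), rel=1e-10)
        assert res.d == pytest.approx(-3.2 / 0.6, rel=1e-10)
        assert res.df == 34
        assert res.band == "large"

    def test_symmetric_deltas_give_zero_t(self):
        res = one_sample_test(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_equals_paired_against_zeros(self, rng):
        x = rng.normal(-1, 0.5, 20)
        assert one_sample_test(x).t == pytest.approx(
            paired_test(x, np.zeros_like(x)).t, rel=1e-12)


class TestPairedTest:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        res = paired_test(x, x)
        assert res.t == 0.0 and res.d == 0.0 and res.degenerate

    def test_exact_offset_flagged(self):
        control = np.linspace(30, 32, 10)
        res = paired_test(control - 3.7, control)
        assert res.mean_diff == pytest.approx(-3.7)
        assert res.degenerate and np.isnan(res.t)

    def test_matches_formula_oracle(self, rng):
        a, b = rng.normal(28, 1, 25), rng.normal(31, 1, 25)
        res = paired_test(a, b)
        diff = a - b
        t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert res.t == pytest.approx(t_oracle, abs=1e-10)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert res.d_pooled == pytest.approx(diff.mean() / pooled, rel=1e-10)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_test(np.zeros(5), np.zeros(6))


def small_measurements(seed=5, n_subjects=8, **overrides):
    return simulate_measurements(
        GenerativeConfig(n_subjects=n_subjects, rng_seed=seed, **overrides))


class TestMixedModel:
    def test_balanced_two_level_factor_equals_difference_of_means(self):
        # balanced design, single two-level factor: the fixed effect is the
        # plain difference of group means regardless of the intercept fit
        rng = np.random.default_rng(21)
        rows = []
        for i in range(8):
            for phase in ("baseline", "cooled"):
                for rep in range(3):
                    rows.append(dict(
                        subject_id=f"s{i}", phase=phase, camera="E8XT",
                        distance_cm=35, lighting="room", posture="stacked",
                        region="roi", image_id=f"s{i}-{phase}-{rep}",
                        melanin_converted=50.0,
                        median_temp_C=rng.normal(31 - 3 * (phase == "cooled"), 0.4)))
        recs = pd.DataFrame(rows)
        res = fit_lmm(recs, outcome="absolute", fixed_terms=("phase",))
        roi = recs
        expected = (roi[roi.phase == "cooled"].median_temp_C.mean()
                    - roi[roi.phase == "baseline"].median_temp_C.mean())
        assert res.params["phase[cooled]"] == pytest.approx(expected, abs=1e-8)

    def test_no_subject_variance_collapses_to_ols(self):
        rng = np.random.default_rng(22)
        rows = []
        for i in range(10):
            for phase in ("baseline", "cooled"):
                for rep in range(4):
                    rows.append(dict(
                        subject_id=f"s{i}", phase=phase, camera="E8XT",
                        distance_cm=35, lighting="room", posture="stacked",
                        region="roi", image_id=f"{i}-{phase}-{rep}",
                        melanin_converted=50.0,
                        median_temp_C=rng.normal(30 - 2 * (phase == "cooled"), 1.0)))
        recs = pd.DataFrame(rows)
        res = fit_lmm(recs, outcome="absolute", fixed_terms=("phase",))
        y = recs.median_temp_C.to_numpy()
        x = (recs.phase == "cooled").to_numpy().astype(float)
        X = np.column_stack([np.ones_like(x), x])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.params["Intercept"] == pytest.approx(ols[0], abs=1e-4)
        assert res.params["phase[cooled]"] == pytest.approx(ols[1], abs=1e-4)

    def test_outcome_shift_moves_only_intercept(self):
        recs = small_measurements()
        res1 = fit_lmm(recs, outcome="absolute",
                       fixed_terms=("phase", "camera", "phase:camera"))
        shifted = recs.copy()
        shifted["median_temp_C"] = shifted["median_temp_C"] + 5.0
        res2 = fit_lmm(shifted, outcome="absolute",
                       fixed_terms=("phase", "camera", "phase:camera"))
        assert res2.params["Intercept"] == pytest.approx(
            res1.params["Intercept"] + 5.0, abs=1e-8)
        for term in res1.params.index[1:]:
            assert res2.params[term] == pytest.approx(res1.params[term], abs=1e-8)

    def test_matches_lmer_satterthwaite(self, tmp_path):
        """Independent oracle: lme4/lmerTest on the same data."""
        recs = small_measurements(seed=5, n_subjects=8)
        model = ThermalMixedModel.from_measurements(
            recs, outcome="differential",
            fixed_terms=("phase", "camera", "phase:camera"))
        res = model.fit()
        data = model.data.copy()
        data["y"] = model.endog
        csv = tmp_path / "d.csv"
        data[["subject_id", "phase", "camera", "y"]].to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages({{library(lme4); library(lmerTest)}})
            d <- read.csv('{csv}')
            d$phase <- relevel(factor(d$phase), 'baseline')
            d$camera <- relevel(factor(d$camera), 'E8XT')
            m <- lmer(y ~ phase*camera + (1|subject_id), data=d, REML=TRUE)
            write.csv(coef(summary(m)), '{tmp_path / "out.csv"}')
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        ref.index = ["Intercept", "phase[cooled]", "camera[ONEPro]",
                     "phase[cooled]:camera[ONEPro]"]
        for term in res.params.index:
            assert res.params[term] == pytest.approx(
                ref.loc[term, "Estimate"], rel=1e-5, abs=1e-7)
            assert res.bse[term] == pytest.approx(
                ref.loc[term, "Std. Error"], rel=1e-3)
            assert res.df[term] == pytest.approx(ref.loc[term, "df"], rel=0.02)
            assert res.pvalues[term] == pytest.approx(
                ref.loc[term, "Pr(>|t|)"], rel=0.05, abs=1e-12)

    def test_melanin_centering_shifts_phase_effect(self):
        recs = small_measurements(seed=6, n_subjects=10)
        recs = recs[recs["camera"] == "E8XT"]
        uncentered = fit_lmm(recs, outcome="differential",
                             fixed_terms=("phase", "melanin", "phase:melanin"))
        centered = fit_lmm(recs, outcome="differential",
                           fixed_terms=("phase", "melanin", "phase:melanin"),
                           melanin_centered=True)
        # interaction identical; phase main effect differs by beta * mean
        assert centered.params["phase[cooled]:melanin"] == pytest.approx(
            uncentered.params["phase[cooled]:melanin"], rel=1e-6)
        mel_mean = recs.groupby("subject_id")["melanin_converted"].first().mean()
        assert centered.params["phase[cooled]"] == pytest.approx(
            uncentered.params["phase[cooled]"]
            + uncentered.params["phase[cooled]:melanin"] * mel_mean, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        recs = small_measurements()
        recs = recs[recs["camera"] == "E8XT"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(recs, outcome="absolute", fixed_terms=("camera",))

    def test_summary_mentions_df_method(self):
        res = fit_lmm(small_measurements(), outcome="absolute",
                      fixed_terms=("phase",))
        assert "df method" in res.summary()


class TestSkinToneReport:
    def test_translation_of_interaction(self):
        recs = small_measurements(seed=7, n_subjects=10)
        recs = recs[recs["camera"] == "E8XT"]
        res = fit_lmm(recs, outcome="differential",
                      fixed_terms=("phase", "melanin", "phase:melanin"))
        rep = skin_tone_report(res)
        assert rep["per_category_C"] == pytest.approx(rep["per_unit_C"] * 25,
                                                      rel=1e-12)
        assert rep["across_scale_C"] == pytest.approx(rep["per_unit_C"] * 75,
                                                      rel=1e-12)

    def test_missing_term_rejected(self):
        res = fit_lmm(small_measurements(), outcome="differential",
                      fixed_terms=("phase",))
        with pytest.raises(ValueError, match="melanin"):
            skin_tone_report(res)


def test_differential_outcome_requires_both_regions():
    recs = small_measurements()
    with pytest.raises(ValueError):
        differential_outcome(recs[recs["region"] == "roi"])
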