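import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from savrex import SimulationConfig, generate_cohort
from savrex.ancova import batch_adjust, fit_all_genes, fit_gene_ancova, fits_to_frame
from savrex.io import ExpressionMatrix, ValidationError


def statsmodels_oracle(y, sav, pid):
    """Independent route: patsy formula OLS + extra-sum-of-squares anova."""
    df = pd.DataFrame({"y": y, "sav": sav, "pid": pid})
    full = smf.ols("y ~ sav + C(pid, Sum)", df).fit()
    reduced = smf.ols("y ~ sav", df).fit()
    comparison = sm.stats.anova_lm(reduced, full)
    return (
        full.params["sav"],
        full.bse["sav"],
        full.pvalues["sav"],
        comparison["Pr(>F)"].iloc[1],
    )


def _random_design(rng, n_patients=21):
    sav = rng.uniform(100, 300, size=2 * n_patients)
    pid = np.repeat([f"P{i:02d}" for i in range(n_patients)], 2)
    y = (
        np.repeat(rng.normal(0, 0.3, n_patients), 2)
        + rng.uniform(-1e-3, 1e-3) * sav
        + rng.normal(0, 0.2, 2 * n_patients)
    )
    return y, sav, pid


class TestFitGeneAncova:
    def test_noiseless_model_is_interpolated_exactly(self):
        pid = np.array(["p1", "p1", "p2", "p2", "p3", "p3"])
        sav = np.array([110.0, 190.0, 120.0, 230.0, 150.0, 280.0])
        beta = {"p1": -0.5, "p2": 0.5, "p3": 0.0}
        y = 1.0 + np.array([beta[p] for p in pid]) + 0.001 * sav
        fit = fit_gene_ancova(y, sav, pid)
        assert abs(fit.slope - 0.001) < 1e-12
        assert fit.p_slope < 1e-6
        assert abs(fit.intercept - 1.0) < 1e-10
        np.testing.assert_allclose(fit.patient_intercepts, [-0.5, 0.5, 0.0], atol=1e-10)

    def test_per_patient_constant_only_moves_that_intercept(self, rng):
        y, sav, pid = _random_design(rng)
        base = fit_gene_ancova(y, sav, pid)
        shifted = y + np.where(pid == "P03", 10.0, 0.0)
        fit = fit_gene_ancova(shifted, sav, pid)
        assert abs(fit.slope - base.slope) < 1e-10
        assert abs(fit.p_slope - base.p_slope) < 1e-10

    def test_matches_statsmodels_oracle_on_random_designs(self, rng):
        for _ in range(100):
            y, sav, pid = _random_design(rng)
            fit = fit_gene_ancova(y, sav, pid)
            slope, se, p_s, p_p = statsmodels_oracle(y, sav, pid)
            assert abs(fit.slope - slope) <= 1e-8 * abs(slope)
            assert abs(fit.slope_se - se) <= 1e-8 * se
            assert abs(fit.p_slope - p_s) <= 1e-8 * max(p_s, 1e-12)
            assert abs(fit.p_patient - p_p) <= 1e-8 * max(p_p, 1e-12)
            assert abs(fit.patient_intercepts.sum()) < 1e-9
            assert fit.residual_df == 20

    def test_treatment_coding_oracle_gives_same_slope(self, rng):
        # any full-rank patient coding yields the same alpha and p-values
        y, sav, pid = _random_design(rng, n_patients=6)
        fit = fit_gene_ancova(y, sav, pid)
        df = pd.DataFrame({"y": y, "sav": sav, "pid": pid})
        treat = smf.ols("y ~ sav + C(pid)", df).fit()
        assert abs(fit.slope - treat.params["sav"]) < 1e-10
        assert abs(fit.p_slope - treat.pvalues["sav"]) < 1e-10

    def test_missing_values_drop_samples_not_patients(self, rng):
        y, sav, pid = _random_design(rng)
        y = y.copy()
        y[1] = np.nan  # P00 keeps one sample: still contributes an intercept
        fit = fit_gene_ancova(y, sav, pid)
        assert not fit.degenerate
        assert fit.n_used == 41
        assert fit.residual_df == 41 - 21 - 1

    @pytest.mark.parametrize(
        "case",
        ["constant_gene", "constant_sav_within_patients", "too_few_samples"],
    )
    def test_degenerate_designs_flagged_not_crashed(self, case, rng):
        if case == "constant_gene":
            y = np.ones(8)
            sav = np.arange(8, dtype=float)
            pid = np.repeat(["a", "b", "c", "d"], 2)
        elif case == "constant_sav_within_patients":
            y = rng.normal(size=8)
            sav = np.repeat([100.0, 150.0, 200.0, 250.0], 2)
            pid = np.repeat(["a", "b", "c", "d"], 2)
        else:
            y = rng.normal(size=4)
            y[0] = np.nan
            sav = np.array([100.0, 150.0, 200.0, 250.0])
            pid = np.array(["a", "a", "b", "b"])
        fit = fit_gene_ancova(y, sav, pid)
        assert fit.degenerate
        assert np.isnan(fit.p_slope)


class TestFitAllGenes:
    def test_one_fit_per_gene_in_matrix_order(self, small_cohort):
        _, matrix, samples, _ = small_cohort
        disc = samples[samples.cohort == "discovery"].reset_index(drop=True)
        fits = fit_all_genes(matrix, disc)
        assert [f.gene_id for f in fits] == matrix.gene_ids
        assert not any(f.degenerate for f in fits)

    def test_empty_matrix_gives_empty_result(self, small_cohort):
        _, matrix, samples, _ = small_cohort
        disc = samples[samples.cohort == "discovery"].reset_index(drop=True)
        empty = ExpressionMatrix(
            values=matrix.values.iloc[:0], mean_log_intensity=matrix.mean_log_intensity.iloc[:0]
        )
        assert fit_all_genes(empty, disc) == []

    def test_replication_samples_rejected(self, small_cohort):
        _, matrix, samples, _ = small_cohort
        with pytest.raises(ValidationError, match="discovery"):
            fit_all_genes(matrix, samples)

    def test_sample_permutation_leaves_fits_unchanged(self, small_cohort, rng):
        _, matrix, samples, _ = small_cohort
        disc = samples[samples.cohort == "discovery"].reset_index(drop=True)
        base = fits_to_frame(fit_all_genes(matrix, disc))
        permuted = disc.sample(frac=1.0, random_state=8).reset_index(drop=True)
        perm = fits_to_frame(fit_all_genes(matrix, permuted))
        np.testing.assert_allclose(base.slope, perm.slope, atol=1e-12)
        np.testing.assert_allclose(base.p_slope, perm.p_slope, atol=1e-12)

    def test_gene_with_missing_value_matches_single_gene_path(self, small_cohort):
        _, matrix, samples, _ = small_cohort
        disc = samples[samples.cohort == "discovery"].reset_index(drop=True)
        values = matrix.values.copy()
        values.iloc[0, 3] = np.nan
        holey = ExpressionMatrix(values=values, mean_log_intensity=matrix.mean_log_intensity)
        fits = fit_all_genes(holey, disc)
        direct = fit_gene_ancova(
            values.iloc[0][disc.sample_id].to_numpy(),
            disc.sav.to_numpy(),
            disc.patient_id.to_numpy(),
        )
        assert abs(fits[0].slope - direct.slope) < 1e-12
        assert fits[0].n_used == 41


class TestPatientEffectPvalue:
    def test_uniform_when_no_patient_effect(self):
        cfg = SimulationConfig(
            n_genes=2000, frac_affected=0.0, patient_sd=0.0, batch_sd=0.0, seed=13
        )
        matrix, samples, _ = generate_cohort(cfg)
        disc = samples[samples.cohort == "discovery"].reset_index(drop=True)
        fits = fits_to_frame(fit_all_genes(matrix, disc))
        from scipy import stats

        assert stats.kstest(fits.p_patient, "uniform").pvalue > 0.01

    def test_concentrates_near_zero_with_strong_patient_effect(self):
        cfg = SimulationConfig(
            n_genes=500, frac_affected=0.0, patient_sd=0.5, noise_sd=0.05,
            batch_sd=0.0, seed=14,
        )
        matrix, samples, _ = generate_cohort(cfg)
        disc = samples[samples.cohort == "discovery"].reset_index(drop=True)
        fits = fits_to_frame(fit_all_genes(matrix, disc))
        assert fits.p_patient.median() < 0.01


class TestBatchAdjust:
    def test_single_batch_centers_to_grand_mean(self, rng):
        values = pd.DataFrame(
            rng.normal(size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(6)],
        )
        matrix = ExpressionMatrix(values=values, mean_log_intensity=pd.Series(0.0, index=values.index))
        samples = pd.DataFrame(
            {"sample_id": values.columns, "patient_id": "p", "within_patient_index": 1,
             "sav": 150.0, "batch": "batch1", "cohort": "discovery"}
        )
        adj = batch_adjust(matrix, samples)
        expected = values.to_numpy() - values.to_numpy().mean(axis=1, keepdims=True)
        np.testing.assert_allclose(adj.values.to_numpy(), expected, atol=1e-12)

    def test_constructed_offsets_removed_exactly(self):
        flat = np.zeros((4, 6))
        flat[:, :3] += 1.0
        flat[:, 3:] -= 1.0
        values = pd.DataFrame(flat, index=list("abcd"), columns=[f"s{i}" for i in range(6)])
        matrix = ExpressionMatrix(values=values, mean_log_intensity=pd.Series(0.0, index=values.index))
        samples = pd.DataFrame(
            {"sample_id": values.columns, "patient_id": [f"p{i}" for i in range(6)],
             "within_patient_index": 1, "sav": 150.0,
             "batch": ["b1"] * 3 + ["b2"] * 3, "cohort": "replication"}
        )
        adj = batch_adjust(matrix, samples)
        np.testing.assert_allclose(adj.values.to_numpy(), 0.0, atol=1e-15)

    def test_per_batch_means_vanish_and_contrasts_survive(self, rng):
        values = pd.DataFrame(
            rng.normal(size=(50, 20)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(20)],
        )
        matrix = ExpressionMatrix(values=values, mean_log_intensity=pd.Series(0.0, index=values.index))
        batch = np.where(np.arange(20) % 2 == 0, "b1", "b2")
        samples = pd.DataFrame(
            {"sample_id": values.columns, "patient_id": [f"p{i}" for i in range(20)],
             "within_patient_index": 1, "sav": 150.0, "batch": batch, "cohort": "replication"}
        )
        adj = batch_adjust(matrix, samples)
        for level in ("b1", "b2"):
            cols = values.columns[batch == level]
            means = adj.values[cols].mean(axis=1).abs()
            assert (means < 1e-12).all()
            # within-batch differences unchanged
            diff_before = values[cols[0]] - values[cols[1]]
            diff_after = adj.values[cols[0]] - adj.values[cols[1]]
            np.testing.assert_allclose(diff_after, diff_before, atol=1e-12)
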