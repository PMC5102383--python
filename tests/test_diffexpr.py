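"""Per-gene regression, variance moderation, FDR adjustment, and the age /
youthfulness detectors — including a cross-check against R limma."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from skinyouth import (
    SimulationConfig,
    bh_adjust,
    detect_age_genes,
    detect_sy_genes,
    estimate_prior,
    fit_gene_models,
    moderated_test,
    residualize_on_age,
    simulate_study,
)
from skinyouth.diffexpr import GeneFits, InsufficientGroupError, ModerationPrior
from skinyouth.preprocess import preprocess_counts

from conftest import make_matrix


class TestGeneFits:
    def test_hand_ols_on_four_samples(self):
        """Hand oracle: normal equations for y on x with 4 points."""
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.1, 3.9, 6.2, 7.8])
        m = make_matrix(y[None, :])
        fits = fit_gene_models(m, x)
        xc = x - x.mean()
        beta = (y @ xc) / (xc @ xc)
        resid = y - y.mean() - beta * xc
        assert fits.beta[0] == pytest.approx(beta)
        assert fits.v == pytest.approx(1.0 / (xc @ xc))
        assert fits.s2[0] == pytest.approx((resid**2).sum() / 2)
        assert fits.df == 2

    def test_exact_linear_gene_flagged_zero_variance(self):
        ages = np.array([20.0, 35, 50, 65, 80])
        m = make_matrix((0.1 * ages + 5)[None, :])
        fits = fit_gene_models(m, ages)
        assert fits.beta[0] == pytest.approx(0.1)
        assert fits.zero_variance[0]

    def test_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(0, 1, (20, 8))
        x = rng.uniform(0, 1, 8)
        perm = rng.permutation(8)
        f1 = fit_gene_models(make_matrix(Y), x)
        f2 = fit_gene_models(make_matrix(Y[:, perm]), x[perm])
        assert np.allclose(f1.beta, f2.beta)
        assert np.allclose(f1.s2, f2.s2)

    def test_constant_covariate_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_gene_models(make_matrix(np.ones((3, 4))), np.ones(4))


def _fits_from_s2(s2, df=10):
    s2 = np.asarray(s2, dtype=float)
    return GeneFits(
        gene_ids=pd.Index([f"g{i}" for i in range(len(s2))]),
        beta=np.zeros(len(s2)),
        v=1.0,
        s2=s2,
        df=df,
    )


class TestPriorEstimation:
    def test_identical_variances_give_infinite_prior_df(self):
        prior = estimate_prior(_fits_from_s2([0.7] * 50))
        assert np.isinf(prior.d0)
        assert prior.s0_2 == pytest.approx(0.7)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(5, 200) / 5
        p1 = estimate_prior(_fits_from_s2(s2))
        p2 = estimate_prior(_fits_from_s2(2 * s2))
        assert p2.d0 == pytest.approx(p1.d0)
        assert p2.s0_2 == pytest.approx(2 * p1.s0_2)

    def test_recovers_prior_df_from_its_own_model(self):
        """Variances drawn as s0^2 * d0 / chi2_{d0} times chi2_d/d sampling
        noise: the estimated d0 lands within 20% of the true 4."""
        rng = np.random.default_rng(42)
        G, d, d0, s02 = 5000, 10, 4.0, 0.5
        sigma2 = s02 * d0 / rng.chisquare(d0, G)
        s2 = sigma2 * rng.chisquare(d, G) / d
        prior = estimate_prior(_fits_from_s2(s2, df=d))
        assert abs(prior.d0 - d0) / d0 < 0.2
        assert abs(prior.s0_2 - s02) / s02 < 0.2

    def test_too_few_genes_rejected(self):
        from skinyouth.diffexpr import InsufficientGenesError

        with pytest.raises(InsufficientGenesError):
            estimate_prior(_fits_from_s2([1.0] * 5))


class TestModeratedTest:
    def test_vanishing_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, (50, 10))
        x = rng.uniform(0, 1, 10)
        fits = fit_gene_models(make_matrix(Y), x)
        tab = moderated_test(fits, ModerationPrior(d0=1e-9, s0_2=1.0))
        t_ord = fits.beta / np.sqrt(fits.v * fits.s2)
        assert np.allclose(tab["t"], t_ord, rtol=1e-6)
        p_ord = 2 * sps.t.sf(np.abs(t_ord), fits.df)
        assert np.allclose(tab["p"], p_ord, rtol=1e-4)

    def test_zero_coefficient_gives_p_one(self):
        fits = _fits_from_s2([1.0] * 20)
        tab = moderated_test(fits, ModerationPrior(d0=4.0, s0_2=1.0))
        assert (tab["t"] == 0).all()
        assert (tab["p"] == 1.0).all()

    def test_zero_variance_genes_untestable(self):
        fits = _fits_from_s2([1.0] * 19 + [0.0])
        tab = moderated_test(fits, ModerationPrior(d0=4.0, s0_2=1.0))
        assert np.isnan(tab["p"].iloc[-1])

    def test_shrinkage_direction(self):
        """Genes with s2 below the prior get larger posterior variance (less
        significant), genes above get smaller — moderation pulls both ways."""
        fits = _fits_from_s2([0.1, 10.0])
        fits.beta[:] = 1.0
        prior = ModerationPrior(d0=4.0, s0_2=1.0)
        tab = moderated_test(fits, prior)
        t_ord = 1.0 / np.sqrt(fits.s2)
        assert abs(tab["t"].iloc[0]) < t_ord[0]
        assert abs(tab["t"].iloc[1]) > t_ord[1]

    def test_null_pvalues_uniform(self):
        """Calibration: moderated p-values on Gaussian null data pass a KS
        uniformity check (100 genes x 20 reps, scaled down)."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(20):
            Y = rng.normal(0, 1, (100, 12))
            x = rng.uniform(0, 1, 12)
            fits = fit_gene_models(make_matrix(Y), x)
            tab = moderated_test(fits, estimate_prior(fits))
            pvals.append(tab["p"].to_numpy())
        p = np.concatenate(pvals)
        assert sps.kstest(p, "uniform").pvalue > 0.01

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
    def test_matches_reference_limma(self, tmp_path):
        """Independent oracle: limma lmFit + eBayes on a 200x12 fixture
        agrees on the prior, the moderated t and the p-values."""
        rng = np.random.default_rng(3)
        G, n = 200, 12
        sigma2 = 0.5 * 4 / rng.chisquare(4, G)
        Y = rng.normal(6, 1, (G, 1)) + np.sqrt(sigma2)[:, None] * rng.normal(0, 1, (G, n))
        x = rng.uniform(20, 80, n)
        Y[:20] += 0.05 * (x - x.mean())[None, :]
        fits = fit_gene_models(make_matrix(Y), x)
        prior = estimate_prior(fits)
        tab = moderated_test(fits, prior)

        np.savetxt(tmp_path / "Y.tsv", Y, delimiter="\t")
        np.savetxt(tmp_path / "x.tsv", x)
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'Y <- as.matrix(read.table("{tmp_path}/Y.tsv", sep="\\t"))\n'
            f'x <- scan("{tmp_path}/x.tsv", quiet=TRUE)\n'
            "fit <- lmFit(Y, model.matrix(~x))\n"
            "eb <- eBayes(fit)\n"
            "write.table(data.frame(d0=eb$df.prior, s02=eb$s2.prior,\n"
            "            t=eb$t[,2], p=eb$p.value[,2]),\n"
            f'            "{tmp_path}/r.tsv", sep="\\t", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_2 == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        assert np.allclose(tab["t"], ref["t"], rtol=1e-6)
        assert np.allclose(tab["p"], ref["p"], rtol=1e-6)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert (bh_adjust([1.0] * 5) == 1.0).all()

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1, 30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1, 50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestResidualize:
    def test_linear_gene_residuals_vanish(self):
        ages = np.array([20.0, 35, 50, 65])
        m = make_matrix((2.0 * ages + 1)[None, :])
        out = residualize_on_age(m, ages)
        assert np.allclose(out.values.to_numpy(), 0.0, atol=1e-10)

    def test_hand_computed_residuals(self):
        ages = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 5])
        xc = ages - ages.mean()
        beta = (y @ xc) / (xc @ xc)
        expected = y - y.mean() - beta * xc
        out = residualize_on_age(make_matrix(y[None, :]), ages)
        assert np.allclose(out.values.to_numpy()[0], expected)

    def test_residuals_centered_and_uncorrelated_with_age(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(0, 1, (40, 15))
        ages = rng.uniform(18, 89, 15)
        out = residualize_on_age(make_matrix(Y), ages)
        R = out.values.to_numpy()
        assert np.abs(R.sum(axis=1)).max() < 1e-8
        assert np.abs(R @ (ages - ages.mean())).max() < 1e-6


class TestDetectors:
    def test_age_gene_recovery(self):
        """100 planted age genes with a strong slope: >=90% recovered at
        FDR<0.01 with empirical FDR <= 0.05."""
        cfg = SimulationConfig(seed=1, age_effect_log2_per_year=0.03)
        cohort, counts, truth = simulate_study(cfg)
        m = preprocess_counts(counts, batches=cohort["batch"])
        up, down, _ = detect_age_genes(m, cohort["age"].to_numpy(), fdr=0.01)
        detected = set(up) | set(down)
        planted = set(truth.age_gene_signs)
        assert len(detected & planted) >= 0.9 * len(planted)
        assert len(detected - planted) / max(len(detected), 1) <= 0.05

    def test_age_null_detects_almost_nothing(self):
        cfg = SimulationConfig(
            seed=2, n_subjects=45, n_genes=2000, n_age_genes=0, n_sy_genes=0,
            n_batches=1,
        )
        cohort, counts, _ = simulate_study(cfg)
        m = preprocess_counts(counts)
        up, down, _ = detect_age_genes(m, cohort["age"].to_numpy(), fdr=0.01)
        assert len(up) + len(down) <= 2

    def test_up_down_partition(self, default_study):
        cohort, counts, _ = default_study
        m = preprocess_counts(counts, batches=cohort["batch"])
        up, down, table = detect_age_genes(m, cohort["age"].to_numpy())
        detected = table[table["fdr"] < 0.01]
        assert set(up) | set(down) == set(detected.index)
        assert set(up).isdisjoint(down)

    def test_sy_gene_recovery_12_vs_33(self):
        """50 planted youthfulness genes at 2 log2 units, 12 SY vs 33
        non-SY: >=80% recovered at p<0.01 with empirical FDR <= 0.2."""
        cfg = SimulationConfig(
            seed=3, n_subjects=45, age_range=(50.0, 89.0), n_genes=500,
            n_age_genes=0, n_sy_genes=50, sy_effect_log2=2.0,
            sy_top_fraction=12 / 45,
        )
        cohort, counts, truth = simulate_study(cfg)
        is_sy = cohort["subject_id"].isin(truth.true_sy_subjects)
        assert int(is_sy.sum()) == 12
        classes = np.where(is_sy, "SY", "non-SY")
        m = preprocess_counts(counts, batches=cohort["batch"])
        up, down, _ = detect_sy_genes(m, cohort["age"].to_numpy(), classes, p_cut=0.01)
        detected = set(up) | set(down)
        planted = set(truth.sy_gene_signs)
        assert len(detected & planted) >= 0.8 * len(planted)
        assert len(detected - planted) / max(len(detected), 1) <= 0.2

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(5, 1, (100, 20))
        Y[:10, :6] += 1.5
        ages = rng.uniform(50, 89, 20)
        classes = np.array(["SY"] * 6 + ["non-SY"] * 14, dtype=object)
        swapped = np.where(classes == "SY", "non-SY", "SY")
        m = make_matrix(Y)
        _, _, t1 = detect_sy_genes(m, ages, classes)
        _, _, t2 = detect_sy_genes(m, ages, swapped)
        t2 = t2.loc[t1.index]
        assert np.allclose(t1["beta"], -t2["beta"])
        assert np.allclose(t1["p"], t2["p"])

    def test_invariant_to_gene_independent_age_trend(self):
        """Adding the same linear function of age to every gene does not
        change the youthfulness results (residualization removes it)."""
        rng = np.random.default_rng(8)
        Y = rng.normal(5, 1, (80, 18))
        ages = rng.uniform(50, 89, 18)
        classes = np.array(["SY"] * 5 + ["non-SY"] * 13, dtype=object)
        _, _, t1 = detect_sy_genes(make_matrix(Y), ages, classes)
        Y2 = Y + (0.3 * ages - 7.0)[None, :]
        _, _, t2 = detect_sy_genes(make_matrix(Y2), ages, classes)
        assert np.allclose(t1["p"], t2.loc[t1.index, "p"])

    def test_small_group_rejected(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(0, 1, (20, 6)))
        classes = np.array(["SY", "non-SY", "non-SY", "non-SY", "non-SY", "non-SY"])
        with pytest.raises(InsufficientGroupError):
            detect_sy_genes(m, rng.uniform(50, 89, 6), classes)
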