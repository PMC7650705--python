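"""GBLUP and the Bayesian-alphabet samplers against independent oracles."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from gpsel.bayes import BayesHyperparams, fit_bayes, gebv_from_effects
from gpsel.gblup import fit_gblup, predict_masked
from gpsel.kinship import GRM, blend_grm, vanraden_grm
from gpsel.sim import SimConfig, phenotype_vector, simulate_genotypes, simulate_phenotypes
from gpsel.varcomp import VarianceComponents

from conftest import make_matrix


def vc(sa2, se2):
    return VarianceComponents(sa2, se2, sa2 / (sa2 + se2), 0.0, True, 1)


def ridge_gebv(w, y, lam):
    """Closed-form marker-ridge solution with an unpenalized intercept."""
    n, m = w.shape
    a = np.zeros((m + 1, m + 1))
    a[0, 0] = n
    a[0, 1:] = w.sum(axis=0)
    a[1:, 0] = w.sum(axis=0)
    a[1:, 1:] = w.T @ w + lam * np.eye(m)
    sol = np.linalg.solve(a, np.concatenate([[y.sum()], w.T @ y]))
    return w @ sol[1:]


class TestGblup:
    def test_three_animal_mme_oracle(self):
        """Direct inversion of the 4x4 mixed-model equations."""
        g = np.array([[1.2, 0.3, 0.1], [0.3, 1.1, 0.2], [0.1, 0.2, 1.0]])
        y = np.array([1.0, 2.0, 0.5])
        sa2, se2 = 0.4, 0.8
        lam = se2 / sa2
        mme = np.zeros((4, 4))
        mme[0, 0] = 3
        mme[0, 1:] = 1
        mme[1:, 0] = 1
        mme[1:, 1:] = np.eye(3) + lam * np.linalg.inv(g)
        sol = np.linalg.solve(mme, np.concatenate([[y.sum()], y]))
        table = fit_gblup(y, GRM(g, ["a", "b", "c"], np.array([])), vc(sa2, se2))
        assert np.allclose(table["gebv"], sol[1:], atol=1e-10)

    def test_infinite_shrinkage_limit(self, small_herd, small_y):
        genotypes, _, _ = small_herd
        g = vanraden_grm(genotypes)
        table = fit_gblup(small_y, g, vc(1e-10, 100.0))
        assert np.abs(table["gebv"]).max() < 1e-6

    def test_intercept_absorbs_phenotype_shift(self, small_herd, small_y):
        genotypes, _, _ = small_herd
        g = vanraden_grm(genotypes)
        comps = vc(20.0, 60.0)
        base = fit_gblup(small_y, g, comps)["gebv"]
        shifted = fit_gblup(small_y + 42.0, g, comps)["gebv"]
        assert np.allclose(base, shifted, atol=1e-8)

    def test_equals_ridge_marker_regression(self):
        """GBLUP with an observed-frequency GRM equals closed-form ridge
        regression on centered dosages at matched shrinkage."""
        rng = np.random.default_rng(17)
        for _ in range(3):
            n, m = int(rng.integers(30, 100)), int(rng.integers(50, 400))
            gm = make_matrix(rng.integers(0, 3, size=(n, m)))
            p = gm.allele_freq()
            keep = (p > 0) & (p < 1)
            gm = gm.take_snps(np.flatnonzero(keep))
            p = gm.allele_freq()
            w = gm.codes - 2 * p
            y = rng.normal(0, 1, n) + w @ rng.normal(0, 0.1, gm.n_snps)
            sa2, se2 = 0.6, 1.3
            gebv = fit_gblup(y, vanraden_grm(gm), vc(sa2, se2))["gebv"]
            lam = se2 / (sa2 / (2 * np.sum(p * (1 - p))))
            assert np.abs(gebv - ridge_gebv(w, y, lam)).max() < 1e-6


@pytest.fixture(scope="module")
def masked_setup():
    cfg = SimConfig(n_animals=50, n_snps=200, n_chromosomes=2, seed=23)
    geno = simulate_genotypes(cfg)
    pheno, _ = simulate_phenotypes(geno, cfg)
    y = phenotype_vector(pheno, cfg.trait_name, 6, geno.animal_ids)
    grm = blend_grm(vanraden_grm(geno), 0.05)
    comps = vc(30.0, 70.0)
    return y, grm, comps


class TestPredictMasked:
    def test_joint_and_projection_routes_agree(self, masked_setup):
        y, grm, comps = masked_setup
        val = grm.animal_ids[:10]
        a = predict_masked(y, grm, comps, val, route="joint")["gebv"]
        b = predict_masked(y, grm, comps, val, route="project")["gebv"]
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-6

    def test_genotypic_duplicate_interpolates_exactly(self):
        rng = np.random.default_rng(29)
        codes = rng.integers(0, 3, size=(20, 100))
        codes[19] = codes[0]  # validation animal duplicates training animal 0
        gm = make_matrix(codes)
        grm = blend_grm(vanraden_grm(gm), 0.0)  # keep exact duplicate rows
        y = rng.normal(0, 1, 20)
        comps = vc(0.5, 1.0)
        val_id = gm.animal_ids[19]
        masked = predict_masked(y, grm, comps, [val_id])
        full_train = predict_masked(y, grm, comps, [val_id])  # same masked fit
        fitted = fit_gblup(
            y[:19], grm.submatrix(np.arange(19)), comps
        )["gebv"]
        assert masked["gebv"].iloc[0] == pytest.approx(fitted.iloc[0], abs=1e-8)
        assert full_train["gebv"].iloc[0] == masked["gebv"].iloc[0]

    def test_empty_validation_returns_empty_table(self, masked_setup):
        y, grm, comps = masked_setup
        out = predict_masked(y, grm, comps, [])
        assert len(out) == 0

    def test_empty_training_set_is_an_error(self, masked_setup):
        y, grm, comps = masked_setup
        with pytest.raises(ValueError, match="training"):
            predict_masked(y, grm, comps, list(grm.animal_ids))


class TestBayes:
    def test_fixed_seed_chains_are_bit_reproducible(self, small_herd, small_y):
        genotypes, _, _ = small_herd
        hyper = BayesHyperparams(chain_length=500, burn_in=100, thin=1, seed=31)
        a = fit_bayes(small_y, genotypes, "B", hyper)
        b = fit_bayes(small_y, genotypes, "B", hyper)
        assert np.array_equal(a.effects, b.effects)
        assert np.array_equal(a.chains["sigma_e2"], b.chains["sigma_e2"])

    def test_constant_phenotype_gives_null_effects(self, small_herd):
        genotypes, _, _ = small_herd
        hyper = BayesHyperparams(chain_length=400, burn_in=100, thin=1, seed=37)
        post = fit_bayes(np.full(genotypes.n_animals, 5.0), genotypes, "A", hyper)
        assert np.abs(post.effects).max() < 1e-3
        assert post.sigma_e2 < 1e-6  # no-signal boundary

    def test_one_marker_conjugate_ridge_oracle(self):
        """With both variances held fixed and no intercept sampling, the
        posterior mean effect is the conjugate closed form
        (z'y) / (z'z + sigma_e2/sigma_g2)."""
        rng = np.random.default_rng(41)
        gm = make_matrix(rng.integers(0, 3, size=(200, 1)))
        w = (gm.codes - 2 * gm.allele_freq())[:, 0]
        y = 0.8 * w + rng.normal(0, 1, 200)
        sg2, se2 = 0.5, 1.0
        closed = (w @ y) / (w @ w + se2 / sg2)
        means = []
        for s in range(5):
            hyper = BayesHyperparams(
                chain_length=4000, burn_in=1000, thin=1, seed=500 + s,
                sample_mu=False, fixed_marker_var=sg2, fixed_resid_var=se2,
            )
            means.append(fit_bayes(y, gm, "A", hyper).effects[0])
        se = np.std(means, ddof=1) / np.sqrt(5)
        assert abs(np.mean(means) - closed) < 3 * se

    def test_gebv_from_effects_matches_internal_fitted_values(self, small_herd, small_y):
        genotypes, _, _ = small_herd
        hyper = BayesHyperparams(chain_length=800, burn_in=200, thin=1, seed=43)
        post = fit_bayes(small_y, genotypes, "Lasso", hyper)
        accumulated = gebv_from_effects(genotypes, post)["gebv"].to_numpy()
        assert np.abs(accumulated - post.fitted).max() < 1e-8

    def test_zero_effects_give_zero_gebv(self, small_herd, small_y):
        genotypes, _, _ = small_herd
        hyper = BayesHyperparams(chain_length=300, burn_in=100, thin=1, seed=47)
        post = fit_bayes(small_y, genotypes, "A", hyper)
        post.effects[:] = 0.0
        assert np.allclose(gebv_from_effects(genotypes, post)["gebv"], 0.0)

    def test_marker_panel_mismatch_is_an_error(self, small_herd, small_y):
        genotypes, _, _ = small_herd
        hyper = BayesHyperparams(chain_length=300, burn_in=100, thin=1, seed=53)
        post = fit_bayes(small_y, genotypes, "A", hyper)
        with pytest.raises(ValueError, match="marker"):
            gebv_from_effects(genotypes.take_snps(np.arange(10)), post)

    def test_bayesb_enriches_inclusion_at_true_qtl(self):
        """Inclusion probabilities at simulated large-effect loci exceed the
        background in every replicate."""
        wins = 0
        for s in range(3):
            cfg = SimConfig(
                n_animals=250, n_snps=600, n_chromosomes=3, n_qtl=15,
                qtl_variance_share=0.8, h2_target=0.6, seed=600 + s,
            )
            geno = simulate_genotypes(cfg)
            pheno, truth = simulate_phenotypes(geno, cfg)
            y = phenotype_vector(pheno, cfg.trait_name, 6, geno.animal_ids)
            hyper = BayesHyperparams(chain_length=1500, burn_in=500, thin=1, seed=700 + s)
            post = fit_bayes(y, geno, "B", hyper)
            is_qtl = np.zeros(cfg.n_snps, dtype=bool)
            is_qtl[truth.qtl_indices] = True
            wins += post.inclusion[is_qtl].mean() > post.inclusion[~is_qtl].mean()
        assert wins == 3

    def test_bayesc_with_pi_forced_zero_recovers_ridge(self):
        """Common fixed marker variance and pi = 0 turn Bayes C into Bayesian
        ridge; posterior-mean genetic values match the closed form within
        Monte-Carlo error (3 SE over 5 chains, in mean absolute terms)."""
        rng = np.random.default_rng(59)
        n, m = 120, 200
        gm = make_matrix(rng.integers(0, 3, size=(n, m)))
        p = gm.allele_freq()
        w = gm.codes - 2 * p
        y = 10 + w @ rng.normal(0, 0.15, m) + rng.normal(0, 1.5, n)
        sg2, se2 = 0.02, 2.0
        ridge = ridge_gebv(w, y, se2 / sg2)
        fits = []
        for s in range(5):
            hyper = BayesHyperparams(
                chain_length=4000, burn_in=1000, thin=1, seed=800 + s, pi=0.0,
                update_pi=False, fixed_marker_var=sg2, fixed_resid_var=se2,
            )
            fits.append(fit_bayes(y, gm, "C", hyper).fitted)
        fits = np.array(fits)
        dev = np.abs(fits.mean(axis=0) - ridge)
        se = fits.std(axis=0, ddof=1) / np.sqrt(5)
        assert dev.mean() <= 3 * se.mean()

    def test_doubling_chain_length_moves_gebv_within_mc_error(self, small_herd, small_y):
        genotypes, _, _ = small_herd
        h1 = BayesHyperparams(chain_length=3000, burn_in=500, thin=1, seed=61)
        h2 = replace(h1, chain_length=5500)  # doubles the post-burn-in samples
        p1 = fit_bayes(small_y, genotypes, "A", h1)
        p2 = fit_bayes(small_y, genotypes, "A", h2)
        delta = np.abs(p2.fitted - p1.fitted)
        budget = 3 * (p1.mc_se_fitted() + p2.mc_se_fitted()) + 1e-3 * small_y.std()
        assert (delta <= budget).all()

    def test_incomplete_genotypes_rejected(self, small_herd, small_y):
        genotypes, _, _ = small_herd
        codes = genotypes.codes.copy()
        codes[0, 0] = -1
        gm = make_matrix(codes)
        with pytest.raises(ValueError, match="complete"):
            fit_bayes(small_y, gm, "A", BayesHyperparams(chain_length=10, burn_in=1))

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            BayesHyperparams(nu=2.0)
        with pytest.raises(ValueError):
            BayesHyperparams(pi=1.5)
        with pytest.raises(ValueError):
            BayesHyperparams(chain_length=100, burn_in=100)
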