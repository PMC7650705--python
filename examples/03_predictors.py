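"""Fit GBLUP and the four Bayesian marker models on one herd.

All five predictors see the same phenotypes; the printed correlation with
the (simulated) true breeding values shows how well each recovers genetic
merit in-sample.  Bayes B's inclusion probabilities concentrate on the
planted QTL.
"""

import numpy as np

from gpsel import (
    BayesHyperparams,
    SimConfig,
    fit_bayes,
    fit_gblup,
    gebv_from_effects,
    reml_fit,
    simulate_genotypes,
    simulate_phenotypes,
    vanraden_grm,
)
from gpsel.sim import phenotype_vector

cfg = SimConfig(n_animals=300, n_snps=1000, n_chromosomes=5, seed=8, h2_target=0.5, n_qtl=15)
herd = simulate_genotypes(cfg)
pheno, truth = simulate_phenotypes(herd, cfg)
y = phenotype_vector(pheno, cfg.trait_name, 6, herd.animal_ids)

grm = vanraden_grm(herd)
vc = reml_fit(y, grm)
gebv = fit_gblup(y, grm, vc)["gebv"].to_numpy()
print(f"GBLUP      corr(GEBV, true a) = {np.corrcoef(gebv, truth.additive)[0, 1]:.3f}")

hyper = BayesHyperparams(chain_length=4000, burn_in=1000, thin=2, seed=1)
for model in ("A", "B", "C", "Lasso"):
    post = fit_bayes(y, herd, model=model, hyper=hyper, varcomps=vc)
    bayes_gebv = gebv_from_effects(herd, post)["gebv"].to_numpy()
    line = f"Bayes{model:<6}corr(GEBV, true a) = {np.corrcoef(bayes_gebv, truth.additive)[0, 1]:.3f}"
    if model in ("B", "C"):
        qtl = np.zeros(cfg.n_snps, bool)
        qtl[truth.qtl_indices] = True
        line += (f"   mean inclusion: QTL {post.inclusion[qtl].mean():.2f}"
                 f" vs background {post.inclusion[~qtl].mean():.2f}")
    print(line)
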