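"""Repeated k-fold cross-validation and prediction-quality summaries.

Predictive ability is the Pearson correlation between GEBV and observed
phenotype in validation animals; predictive accuracy divides the ability by
the square root of heritability (an estimate of the GEBV-true-breeding-value
correlation).  Results aggregate as the mean over all repeat x fold cells,
with the whole-data REML heritability in the accuracy denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import BayesHyperparams, fit_bayes, gebv_from_effects, reduced_chain
from .gblup import predict_masked
from .genotypes import GenotypeMatrix
from .kinship import GRM, blend_grm, vanraden_grm
from .varcomp import VarianceComponents, reml_fit

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "make_folds",
    "predictive_ability",
    "predictive_accuracy",
    "run_cv",
    "ability_h2_regression",
    "later_age_correlation",
]

BAYES_METHODS = {"bayesA": "A", "bayesB": "B", "bayesC": "C", "bayesLasso": "Lasso"}


@dataclass
class CVResult:
    """Per-cell abilities plus the whole-data heritability used for accuracy."""

    records: pd.DataFrame  # columns: repeat, fold, method, trait, ability, n_validation
    h2: float
    seed: int
    folds: pd.DataFrame = field(repr=False, default=None)

    def mean_ability(self) -> pd.Series:
        return self.records.groupby("method")["ability"].mean()

    def mean_accuracy(self) -> pd.Series:
        return self.mean_ability() / np.sqrt(self.h2)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"ability": self.mean_ability(), "accuracy": self.mean_accuracy()}
        )
        out["h2"] = self.h2
        return out.reset_index()


def make_folds(animal_ids: list[str], k: int = 5, repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Random balanced partitions, one per repeat.

    Returns a frame (repeat, fold, animal_id); per repeat every animal is in
    exactly one fold and fold sizes differ by at most one.
    """
    n = len(animal_ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("more folds than animals")
    rng = np.random.default_rng(seed)
    frames = []
    ids = np.asarray(animal_ids)
    for rep in range(repeats):
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            frames.append(
                pd.DataFrame({"repeat": rep, "fold": fold, "animal_id": ids[chunk]})
            )
    return pd.concat(frames, ignore_index=True)


def predictive_ability(gebv: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between GEBV and phenotype."""
    gebv = np.asarray(gebv, dtype=float)
    y = np.asarray(y, dtype=float)
    if gebv.size != y.size or gebv.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(gebv) == 0 or np.std(y) == 0:
        raise ValueError("predictive ability undefined at zero variance")
    return float(stats.pearsonr(gebv, y).statistic)


def predictive_accuracy(ability: float, h2: float) -> float:
    """ability / sqrt(h2): rescales ability toward the GEBV-TBV correlation."""
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    return float(ability / np.sqrt(h2))


def run_cv(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    methods: list[str] = ("gblup",),
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    trait: str = "trait",
    grm: GRM | None = None,
    varcomps: VarianceComponents | None = None,
    hyper: BayesHyperparams | None = None,
    blend_weight: float = 0.05,
) -> CVResult:
    """Repeated k-fold cross-validation for one trait.

    Animals with a missing phenotype are dropped (and logged) before fold
    assignment.  All methods share the same fold partitions.  GBLUP predicts
    validation animals through the masked mixed-model equations; Bayesian
    methods refit the sampler on each training set and accumulate marker
    effects for the validation animals.  Accuracy uses the whole-data REML
    heritability.
    """
    if not methods:
        raise ValueError("method list is empty")
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    if not keep.all():
        logger.info("dropping %d animals missing trait %s", int((~keep).sum()), trait)
        genotypes = genotypes.take_animals(np.flatnonzero(keep))
        y = y[keep]

    if grm is None:
        grm = blend_grm(vanraden_grm(genotypes), blend_weight)
    if varcomps is None:
        varcomps = reml_fit(y, grm)
    if hyper is None:
        hyper = reduced_chain(BayesHyperparams())

    folds = make_folds(grm.animal_ids, k=k, repeats=repeats, seed=seed)
    id_index = {a: i for i, a in enumerate(grm.animal_ids)}

    rows = []
    for (rep, fold), grp in folds.groupby(["repeat", "fold"]):
        val_ids = list(grp["animal_id"])
        val_idx = np.array([id_index[a] for a in val_ids])
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        for method in methods:
            if method == "gblup":
                pred = predict_masked(y, grm, varcomps, val_ids)
                gebv = pred["gebv"].to_numpy()
            elif method in BAYES_METHODS:
                sub_hyper = replace(
                    hyper, seed=int((hyper.seed + 7919 * rep + 104729 * fold) % (2**31))
                )
                post = fit_bayes(
                    y[train_idx],
                    genotypes.take_animals(train_idx),
                    model=BAYES_METHODS[method],
                    hyper=sub_hyper,
                    varcomps=varcomps,
                )
                val_geno = genotypes.take_animals(val_idx)
                gebv = gebv_from_effects(val_geno, post)["gebv"].to_numpy()
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "method": method,
                    "trait": trait,
                    "ability": predictive_ability(gebv, y[val_idx]),
                    "n_validation": len(val_ids),
                }
            )
    return CVResult(records=pd.DataFrame(rows), h2=varcomps.h2, seed=seed, folds=folds)


def ability_h2_regression(abilities: np.ndarray, h2s: np.ndarray) -> tuple[float, float]:
    """OLS slope and intercept of predictive ability on heritability."""
    abilities = np.asarray(abilities, dtype=float)
    h2s = np.asarray(h2s, dtype=float)
    if abilities.size != h2s.size or abilities.size < 3:
        raise ValueError("need at least 3 traits")
    if np.all(h2s == h2s[0]):
        raise ValueError("zero variance in heritabilities")
    slope, intercept = np.polyfit(h2s, abilities, 1)
    return float(slope), float(intercept)


def later_age_correlation(predictions: np.ndarray, observations: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p-value between early predictions and later
    observations; pairs with a missing later record are dropped."""
    predictions = np.asarray(predictions, dtype=float)
    observations = np.asarray(observations, dtype=float)
    keep = np.isfinite(predictions) & np.isfinite(observations)
    predictions, observations = predictions[keep], observations[keep]
    if predictions.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(predictions) == 0 or np.std(observations) == 0:
        raise ValueError("correlation undefined at zero variance")
    res = stats.pearsonr(predictions, observations)
    return float(res.statistic), float(res.pvalue)
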