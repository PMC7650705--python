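"""Published reference values for early growth traits in a domestic yak herd.

A 354-animal study of body weight (BW), withers height (WH), body length
(BL) and chest girth (CG) at weaning (6 months) and yearling (12 months)
ages reported REML variance components, and five-fold cross-validated
predictive abilities and accuracies for GBLUP and four Bayesian marker
models, plus the correlation between early body-weight predictions and
30-month observations.  These numbers serve as fixed inputs for internal
consistency checks (heritability and accuracy identities, column means,
the ability-on-heritability regression); the study's raw genotypes are not
public, so the values are not recomputed from data here.
"""

from __future__ import annotations

import pandas as pd

TRAITS = ["BW6", "WH6", "BL6", "CG6", "BW12", "WH12", "BL12", "CG12"]
METHODS = ["GBLUP", "BayesA", "BayesB", "BayesC", "BayesLasso"]


def variance_components() -> pd.DataFrame:
    """Per-trait additive and residual variances with the printed h2."""
    data = {
        "BW6": (37.506, 68.848, 0.35),
        "WH6": (15.597, 11.558, 0.57),
        "BL6": (30.752, 24.181, 0.56),
        "CG6": (23.822, 36.526, 0.39),
        "BW12": (26.815, 83.298, 0.24),
        "WH12": (3.941, 13.511, 0.22),
        "BL12": (1.746, 22.812, 0.07),
        "CG12": (6.493, 19.171, 0.25),
    }
    return pd.DataFrame(
        [(t, *data[t]) for t in TRAITS],
        columns=["trait", "sigma_a2", "sigma_e2", "h2"],
    )


def predictive_ability() -> pd.DataFrame:
    """Cross-validated mean correlation r(GEBV, y), traits x methods."""
    rows = {
        "BW6": (0.164, 0.171, 0.194, 0.177, 0.164),
        "WH6": (0.295, 0.255, 0.268, 0.243, 0.286),
        "BL6": (0.198, 0.205, 0.237, 0.246, 0.219),
        "CG6": (0.146, 0.201, 0.207, 0.210, 0.179),
        "BW12": (0.097, 0.094, 0.104, 0.103, 0.161),
        "WH12": (0.112, 0.079, 0.083, 0.097, 0.132),
        "BL12": (0.044, 0.044, 0.041, 0.039, 0.043),
        "CG12": (0.129, 0.110, 0.163, 0.106, 0.110),
    }
    return pd.DataFrame(
        [(t, *rows[t]) for t in TRAITS], columns=["trait", *METHODS]
    ).set_index("trait")


def predictive_accuracy() -> pd.DataFrame:
    """Printed accuracies (ability / sqrt(h2)); the GBLUP-CG12 cell is
    inconsistent with the identity (0.129/sqrt(0.25) = 0.258, printed 0.220)
    and is treated as a typo by the consistency checks."""
    rows = {
        "BW6": (0.277, 0.289, 0.328, 0.299, 0.277),
        "WH6": (0.391, 0.338, 0.355, 0.322, 0.379),
        "BL6": (0.265, 0.274, 0.317, 0.329, 0.293),
        "CG6": (0.234, 0.322, 0.331, 0.336, 0.287),
        "BW12": (0.198, 0.192, 0.212, 0.210, 0.329),
        "WH12": (0.239, 0.168, 0.177, 0.207, 0.281),
        "BL12": (0.166, 0.166, 0.155, 0.147, 0.163),
        "CG12": (0.220, 0.220, 0.326, 0.212, 0.220),
    }
    return pd.DataFrame(
        [(t, *rows[t]) for t in TRAITS], columns=["trait", *METHODS]
    ).set_index("trait")


#: printed mean accuracy per method (all eight traits)
ACCURACY_COLUMN_MEANS = {
    "GBLUP": 0.253,
    "BayesA": 0.246,
    "BayesB": 0.275,
    "BayesC": 0.258,
    "BayesLasso": 0.278,
}

#: printed regression slopes of predictive ability on heritability
ABILITY_ON_H2_SLOPES = {
    "GBLUP": 0.40,
    "BayesA": 0.41,
    "BayesB": 0.44,
    "BayesC": 0.44,
    "BayesLasso": 0.40,
}

#: correlation between early body-weight predictions and 30-month weights
LATER_AGE_CORRELATIONS = {
    "GBLUP": 0.407,
    "BayesA": 0.422,
    "BayesB": 0.403,
    "BayesC": 0.405,
    "BayesLasso": 0.374,
}

#: the one accuracy cell that contradicts the ability/sqrt(h2) identity
ACCURACY_IDENTITY_EXCEPTION = ("CG12", "GBLUP")
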