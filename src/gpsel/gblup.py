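"""GBLUP: breeding values from the mixed-model equations.

y = 1 mu + Z g + e with g ~ N(0, G sigma_a^2), e ~ N(0, I sigma_e^2).  The
equations are solved in their equivalent variance form (GLS intercept, then
g_hat = sigma_a^2 G V^{-1} (y - 1 mu_hat) with V = sigma_a^2 G + sigma_e^2 I),
which is the exact MME solution but also tolerates a positive semi-definite
G: with observed-frequency centering G has a zero row-sum null space, so the
inverse-G form of the equations only exists after blending.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinship import GRM
from .varcomp import VarianceComponents

__all__ = ["fit_gblup", "predict_masked"]


def _blup_components(y: np.ndarray, g: np.ndarray, sa2: float, se2: float):
    n = y.size
    v = sa2 * g + se2 * np.eye(n)
    try:
        c = np.linalg.cholesky(v)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "mixed-model coefficient matrix is singular; blend the GRM "
            "(kinship.blend_grm) or check sigma_e2 > 0"
        ) from exc

    def vsolve(b):
        return np.linalg.solve(c.T, np.linalg.solve(c, b))

    ones = np.ones(n)
    vi1 = vsolve(ones)
    mu = float(ones @ vsolve(y)) / float(ones @ vi1)
    resid = y - mu
    viy = vsolve(resid)
    return mu, viy


def fit_gblup(
    y: np.ndarray,
    grm: GRM,
    varcomps: VarianceComponents,
    method: str = "GBLUP",
) -> pd.DataFrame:
    """Solve the MME for the intercept and the GEBV vector.

    Returns a table (animal_id, gebv, method), one row per animal in the GRM.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size != grm.n:
        raise ValueError("phenotype length does not match GRM order")
    mu, viy = _blup_components(y, grm.values, varcomps.sigma_a2, varcomps.sigma_e2)
    gebv = varcomps.sigma_a2 * (grm.values @ viy)
    return pd.DataFrame({"animal_id": grm.animal_ids, "gebv": gebv, "method": method})


def predict_masked(
    y: np.ndarray,
    grm: GRM,
    varcomps: VarianceComponents,
    validation_ids: list[str],
    route: str = "joint",
    method: str = "GBLUP",
) -> pd.DataFrame:
    """GEBVs for validation animals whose phenotypes are treated as unknown.

    ``y`` is aligned with ``grm.animal_ids``; entries at validation positions
    are ignored (they may be NaN).  Two algebraically equivalent routes are
    implemented: ``"joint"`` solves the training-animal equations and reads
    off the validation GEBVs through the genomic covariances
    (g_all = sigma_a^2 G[:, train] V_tt^{-1} r_t), while ``"project"`` first
    fits the training-only model and then projects
    g_v = G_vt G_tt^{-1} g_t (requiring an invertible G_tt, i.e. a blended
    GRM).  A test holds the two routes to agree to 1e-6.
    """
    validation_ids = list(validation_ids)
    id_index = {a: i for i, a in enumerate(grm.animal_ids)}
    unknown = [a for a in validation_ids if a not in id_index]
    if unknown:
        raise KeyError(f"validation ids not in GRM: {unknown[:5]}")
    if not validation_ids:
        return pd.DataFrame({"animal_id": [], "gebv": [], "method": []})

    val_idx = np.array([id_index[a] for a in validation_ids])
    mask_val = np.zeros(grm.n, dtype=bool)
    mask_val[val_idx] = True
    y = np.asarray(y, dtype=np.float64)
    train_idx = np.flatnonzero(~mask_val & np.isfinite(y))
    if train_idx.size == 0:
        raise ValueError("empty training set")

    g = grm.values
    gtt = g[np.ix_(train_idx, train_idx)]
    y_t = y[train_idx]
    mu, viy = _blup_components(y_t, gtt, varcomps.sigma_a2, varcomps.sigma_e2)

    if route == "joint":
        gebv_val = varcomps.sigma_a2 * (g[np.ix_(val_idx, train_idx)] @ viy)
    elif route == "project":
        gebv_train = varcomps.sigma_a2 * (gtt @ viy)
        coef = np.linalg.solve(gtt, gebv_train)
        gebv_val = g[np.ix_(val_idx, train_idx)] @ coef
    else:
        raise ValueError("route must be 'joint' or 'project'")

    return pd.DataFrame({"animal_id": validation_ids, "gebv": gebv_val, "method": method})
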