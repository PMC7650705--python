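"""REML variance components and heritability under the GBLUP model.

Model: y = 1 mu + g + e with g ~ N(0, G sigma_a^2) and e ~ N(0, I sigma_e^2);
only an intercept is fitted as fixed effect.  The restricted likelihood is
maximized by average-information (AI) updates with EM fallback steps when an
AI step would leave the parameter space.  G is eigen-decomposed once, which
makes every iteration O(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kinship import GRM

logger = logging.getLogger(__name__)

__all__ = ["VarianceComponents", "reml_fit", "heritability"]


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    converged: bool
    n_iterations: int
    boundary: bool = False
    loglik: float = float("nan")


def heritability(sigma_a2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability sigma_a^2 / (sigma_a^2 + sigma_e^2)."""
    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_a2 + sigma_e2
    if total == 0:
        raise ZeroDivisionError("heritability undefined when both variances are zero")
    return float(sigma_a2 / total)


def _profile_quantities(theta, d, yt, xt):
    """Score vector, AI matrix, Py and restricted log-likelihood at theta."""
    sa2, se2 = theta
    v = sa2 * d + se2
    vinv = 1.0 / v
    xvx = float(np.sum(xt * xt * vinv))
    minv = 1.0 / xvx
    beta = minv * float(np.sum(xt * vinv * yt))
    r = yt - xt * beta
    py = vinv * r

    def pdot(w):
        vw = vinv * w
        return vw - vinv * xt * (minv * float(np.sum(xt * vw)))

    # tr(P A) for A = diag(d) and A = I
    tr_a = float(np.sum(d * vinv)) - minv * float(np.sum(xt * xt * d * vinv * vinv))
    tr_e = float(np.sum(vinv)) - minv * float(np.sum(xt * xt * vinv * vinv))
    ypapy_a = float(np.sum(d * py * py))
    ypapy_e = float(np.sum(py * py))
    score = np.array([-0.5 * (tr_a - ypapy_a), -0.5 * (tr_e - ypapy_e)])

    wa = d * py
    we = py
    ai = 0.5 * np.array(
        [
            [float(wa @ pdot(wa)), float(wa @ pdot(we))],
            [float(we @ pdot(wa)), float(we @ pdot(we))],
        ]
    )
    loglik = -0.5 * (
        float(np.sum(np.log(v))) + np.log(xvx) + float(r @ py)
    )
    return score, ai, (tr_a, tr_e, ypapy_a, ypapy_e), loglik


def reml_fit(
    y: np.ndarray,
    grm: GRM,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """AI-REML fit of (sigma_a^2, sigma_e^2) with EM fallback.

    Convergence is declared when the maximum relative parameter change drops
    below ``tol``.  Estimates pinned at the lower boundary (sigma_a^2 -> 0)
    are returned with ``boundary=True`` rather than raised.  The standard
    error of h^2 comes from the inverse AI matrix by the delta method.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n != grm.n:
        raise ValueError("phenotype length does not match GRM order")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be complete (drop missing records first)")

    d, u = np.linalg.eigh(grm.values)
    scale = max(1.0, float(d.max()))
    if d.min() < -1e-8 * scale:
        raise np.linalg.LinAlgError(
            "G has substantially negative eigenvalues; apply kinship.blend_grm "
            "before REML"
        )
    # a PSD G is fine: V = sigma_a2 d + sigma_e2 stays positive, and the
    # zero eigenvalue of an observed-frequency GRM lies along the intercept
    d = np.clip(d, 0.0, None)
    yt = u.T @ y
    xt = u.T @ np.ones(n)

    vary = y.var()
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vary
    theta = np.array([0.5 * vary, 0.5 * vary])

    converged = False
    n_iter = 0
    at_floor = 0
    ll_prev = -np.inf
    score = np.zeros(2)
    ai = np.eye(2)
    for n_iter in range(1, max_iter + 1):
        score, ai, (tr_a, tr_e, ypapy_a, ypapy_e), ll = _profile_quantities(theta, d, yt, xt)
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            step = None
        new = None
        if step is not None and np.all(np.isfinite(step)):
            # damp the AI step by halving until it stays in the parameter
            # space; plain rejection would leave only slow EM crawl steps
            for k in range(13):
                cand = theta + step / 2**k
                if np.all(np.isfinite(cand)) and np.all(cand > 0):
                    new = cand
                    break
        if new is None:
            # EM fallback keeps the iterate inside the parameter space
            new = np.array(
                [
                    theta[0] + theta[0] ** 2 * (ypapy_a - tr_a) / n,
                    theta[1] + theta[1] ** 2 * (ypapy_e - tr_e) / n,
                ]
            )
            new = np.maximum(new, floor)
        rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), floor))
        theta = new
        if rel < tol:
            converged = True
            break
        # EM crawl toward a small-sigma_a2 optimum moves the parameters but
        # not the restricted likelihood; accept once the likelihood is flat
        if n_iter > 5 and abs(ll - ll_prev) < 1e-9 * (1.0 + abs(ll)):
            converged = True
            break
        ll_prev = ll
        # estimates pinned at the lower boundary: accept after three
        # consecutive floor hits instead of grinding out EM crawl steps
        at_floor = at_floor + 1 if theta[0] <= 2 * floor else 0
        if at_floor >= 3:
            converged = True
            break

    score, ai, _, loglik = _profile_quantities(theta, d, yt, xt)
    boundary = bool(theta[0] <= 2 * floor)
    sa2, se2 = float(theta[0]), float(theta[1])
    h2 = heritability(sa2, se2)

    se_h2 = float("nan")
    try:
        cov = np.linalg.inv(ai)
        grad = np.array([se2, -sa2]) / (sa2 + se2) ** 2
        var_h2 = float(grad @ cov @ grad)
        if var_h2 >= 0:
            se_h2 = float(np.sqrt(var_h2))
    except np.linalg.LinAlgError:
        pass

    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)
    return VarianceComponents(
        sigma_a2=sa2,
        sigma_e2=se2,
        h2=h2,
        se_h2=se_h2,
        converged=converged,
        n_iterations=n_iter,
        boundary=boundary,
        loglik=loglik,
    )
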