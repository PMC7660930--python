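"""Independent reference implementations used only to check the package.

Everything here is brute force or closed form and deliberately shares no
code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp


def exact_pip(
    X: np.ndarray, Y: np.ndarray, sigma2: float, sigma_beta2: float, pi0: float
) -> np.ndarray:
    """Posterior inclusion probabilities by enumerating all 2^p models.

    For each inclusion configuration gamma the marginal likelihood of the
    spike-and-slab model is the closed-form Gaussian
    Y ~ N(0, sigma2 (I + sigma_beta2 X_g X_g')), evaluated via the
    Woodbury/determinant-lemma reduction to |gamma|-dimensional algebra.
    """
    n, p = X.shape
    yty = float(Y @ Y)
    logliks = np.empty(2**p)
    configs = []
    for i, gamma in enumerate(itertools.product([0, 1], repeat=p)):
        g = np.array(gamma, dtype=bool)
        configs.append(g)
        k = int(g.sum())
        if k == 0:
            ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + yty / sigma2)
        else:
            Xg = X[:, g]
            M = np.eye(k) + sigma_beta2 * (Xg.T @ Xg)
            _, logdet = np.linalg.slogdet(M)
            XtY = Xg.T @ Y
            quad = (yty - sigma_beta2 * XtY @ np.linalg.solve(M, XtY)) / sigma2
            ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + quad)
        ll += k * np.log(pi0) + (p - k) * np.log(1.0 - pi0)
        logliks[i] = ll
    w = np.exp(logliks - logsumexp(logliks))
    pips = np.zeros(p)
    for wi, g in zip(w, configs):
        pips[g] += wi
    return pips


def two_model_pip(
    x: np.ndarray, Y: np.ndarray, sigma2: float, sigma_beta2: float, pi0: float
) -> float:
    """p = 1 special case: inclusion probability from the exact Bayes factor."""
    return float(exact_pip(x.reshape(-1, 1), Y, sigma2, sigma_beta2, pi0)[0])


def squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Squared correlation from the raw-moment formula (independent route)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    num = n * np.sum(a * b) - a.sum() * b.sum()
    den = np.sqrt(
        (n * np.sum(a**2) - a.sum() ** 2) * (n * np.sum(b**2) - b.sum() ** 2)
    )
    return float((num / den) ** 2)


def bh_keep(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    keep = np.zeros(m, dtype=bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            kmax = rank
    keep[order[:kmax]] = True
    return keep


def regression_z(x: np.ndarray, y: np.ndarray) -> float:
    """t-statistic of the slope in the simple regression y ~ 1 + x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    bhat = (xc @ yc) / (xc @ xc)
    resid = yc - bhat * xc
    se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
    return float(bhat / se)
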