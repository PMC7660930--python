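"""Variational spike-and-slab regression with an annotation-informed prior.

The model for one gene in one tissue:

    Y = X beta + eps,            eps ~ N(0, sigma2 I)
    beta_k | gamma_k = 1  ~  N(0, sigma_beta2 * sigma2)
    beta_k | gamma_k = 0  ~  delta_0
    gamma_k ~ Bernoulli(pi_k),   logit(pi_k) = A_k omega
    omega ~ N(0, eta^{-1} I)

with X the centered cis-SNP dosage matrix and A_k the SNP's epigenetic
annotation row (an explicit intercept column is prepended).  Inference is
coordinate-ascent variational Bayes under the fully factorized family
q(beta, gamma) = prod_k q(beta_k, gamma_k) with a Gaussian q(omega); the
non-conjugate logistic term is handled with the Jaakkola-Jordan quadratic
bound (local parameters xi_k), which keeps every update closed-form and the
(bounded) ELBO monotone.

Per-SNP updates (sufficient-statistic form, residualized against all other
SNPs):

    s2_k  = sigma2 / (x_k'x_k + 1/sigma_beta2)
    mu_k  = s2_k / sigma2 * x_k' r_{-k}
    logit(alpha_k) = A_k E[omega] + 0.5 log(s2_k / (sigma_beta2 sigma2))
                     + mu_k^2 / (2 s2_k)

followed by the Gaussian omega-block update

    Cov(omega)^{-1} = eta I + 2 A' diag(lambda(xi)) A
    E[omega] = Cov(omega) A' (alpha - 1/2),   lambda(xi) = tanh(xi/2)/(4 xi)

and xi_k^2 = A_k (Cov + E E') A_k'.  Hyperparameters theta = (sigma2,
sigma_beta2, eta) are handled on a grid; per-SNP inclusion probabilities
are averaged over the grid with weights proportional to exp(ELBO(theta))
times the prior density of theta (inverse-gamma on the variances, gamma on
eta), giving the posterior probability of selection

    PPS(k) = sum_theta w_theta alpha_k(theta).
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from scipy.special import expit, gammaln, log_expit, logsumexp

from .types import (
    AnnotationMatrix,
    GenotypePanel,
    GridFit,
    ImputationModel,
    PriorConfig,
    SnpRecord,
    VariationalState,
)

__all__ = [
    "logistic_prior",
    "fit_single_theta",
    "fit_grid",
    "fit_vb_baseline",
    "annotation_filter_fit",
    "predict_expression",
]

_INIT_LOGIT = np.log(0.1 / 0.9)  # initial prior inclusion level 0.1
DEFAULT_SEED = 2020


def logistic_prior(a_row: np.ndarray, omega: np.ndarray) -> float:
    """Prior inclusion probability sigmoid(omega_0 + A_row . omega_slopes)."""
    a_row = np.asarray(a_row, dtype=float).ravel()
    omega = np.asarray(omega, dtype=float).ravel()
    if len(omega) != len(a_row) + 1:
        raise ValueError(
            f"omega must have length {len(a_row) + 1} (intercept + slopes)"
        )
    if not (np.all(np.isfinite(a_row)) and np.all(np.isfinite(omega))):
        raise ValueError("non-finite input to logistic_prior")
    return float(expit(omega[0] + a_row @ omega[1:]))


@njit(cache=False)
def _sweep(XtX, XtY, xtx, alpha, mu, w, XtXw, logit_pi, s2, sigma2, slab_var):
    """One cyclic coordinate-ascent pass over all SNPs, in place."""
    p = XtY.shape[0]
    half_log_slab = 0.5 * np.log(slab_var)
    for k in range(p):
        r_k = XtY[k] - XtXw[k] + xtx[k] * w[k]
        mu_k = s2[k] * r_k / sigma2
        u = logit_pi[k] + 0.5 * np.log(s2[k]) - half_log_slab + 0.5 * mu_k * mu_k / s2[k]
        if u > 35.0:
            a_k = 1.0
        elif u < -35.0:
            a_k = 0.0
        else:
            a_k = 1.0 / (1.0 + np.exp(-u))
        mu[k] = mu_k
        alpha[k] = a_k
        w_new = a_k * mu_k
        delta = w_new - w[k]
        if delta != 0.0:
            for j in range(p):
                XtXw[j] += XtX[j, k] * delta
            w[k] = w_new


def _jj_lambda(xi: np.ndarray) -> np.ndarray:
    """lambda(xi) = tanh(xi/2) / (4 xi), with the xi -> 0 limit 1/8."""
    out = np.full_like(xi, 0.125)
    nz = xi > 1e-8
    out[nz] = np.tanh(xi[nz] / 2.0) / (4.0 * xi[nz])
    return out


def _augment(A: AnnotationMatrix | np.ndarray, p: int) -> np.ndarray:
    """Annotation design with a leading intercept column."""
    if isinstance(A, AnnotationMatrix):
        vals = A.values
    else:
        vals = np.atleast_2d(np.asarray(A, dtype=float))
    if vals.shape[0] != p:
        raise ValueError(f"annotation rows ({vals.shape[0]}) != SNPs ({p})")
    return np.column_stack([np.ones(p), vals])


def _xlogx(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a)
    nz = a > 0
    out[nz] = a[nz] * np.log(a[nz])
    return out


def _elbo(
    yty, XtY, xtx, n, alpha, mu, s2, w, XtXw, Aaug, m_w, S_w, xi, sigma2, sigma_beta2, eta
) -> float:
    slab = sigma_beta2 * sigma2
    # E_q || Y - X beta ||^2
    ssr = (
        yty
        - 2.0 * w @ XtY
        + w @ XtXw
        + np.sum(xtx * (alpha * (s2 + mu**2) - w**2))
    )
    e_lik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - ssr / (2.0 * sigma2)
    # slab prior + q(beta|gamma=1) entropy
    e_slab = 0.5 * np.sum(
        alpha * (1.0 + np.log(s2 / slab) - (s2 + mu**2) / slab)
    )
    # gamma prior under the JJ bound, minus gamma entropy
    lam = _jj_lambda(xi)
    Am = Aaug @ m_w
    quad = np.einsum("ij,jk,ik->i", Aaug, S_w + np.outer(m_w, m_w), Aaug)
    e_gamma = np.sum(
        (alpha - 0.5) * Am + log_expit(xi) - xi / 2.0 - lam * (quad - xi**2)
    )
    e_gamma -= np.sum(_xlogx(alpha) + _xlogx(1.0 - alpha))
    # -KL(q(omega) || N(0, eta^{-1} I))
    q = len(m_w)
    sign, logdet = np.linalg.slogdet(S_w)
    e_omega = 0.5 * (
        q * np.log(eta) + logdet + q - eta * (np.trace(S_w) + m_w @ m_w)
    )
    return float(e_lik + e_slab + e_gamma + e_omega)


def fit_single_theta(
    X: np.ndarray,
    Y: np.ndarray,
    A: AnnotationMatrix | np.ndarray,
    theta: tuple[float, float, float],
    init: VariationalState | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    update_omega: bool = True,
    profile_sigma2: bool = False,
    _suff: tuple | None = None,
) -> VariationalState:
    """Coordinate-ascent VB fit at one hyperparameter setting.

    ``X`` must be column-centered; ``Y`` centered.  ``theta`` is (sigma2,
    sigma_beta2, eta).  With ``update_omega=False`` the annotation
    coefficients stay at their initial value (needed when comparing to
    fixed-prior oracles); with ``profile_sigma2=True`` the noise variance is
    re-optimized each outer iteration at its coordinate-wise ELBO maximum.
    Non-convergence is flagged on the returned state, never silent.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in X or Y")
    n, p = X.shape
    if n < 2 or p < 1 or len(Y) != n:
        raise ValueError(f"bad shapes: X {X.shape}, Y {Y.shape}")
    sigma2, sigma_beta2, eta = (float(v) for v in theta)
    if min(sigma2, sigma_beta2, eta) <= 0:
        raise ValueError("theta components must be positive")

    if _suff is None:
        XtX = X.T @ X
        XtY = X.T @ Y
        yty = float(Y @ Y)
    else:
        XtX, XtY, yty = _suff
    xtx = np.ascontiguousarray(np.diag(XtX))
    if np.any(xtx <= 0):
        raise ValueError("X has a constant (zero-variance) column")

    Aaug = _augment(A, p)
    q = Aaug.shape[1]

    if init is not None:
        alpha = init.alpha.copy()
        mu = init.mu.copy()
        m_w = init.omega_mean.copy()
        xi = init.xi.copy()
    else:
        alpha = np.full(p, expit(_INIT_LOGIT))
        mu = np.zeros(p)
        m_w = np.zeros(q)
        m_w[0] = _INIT_LOGIT
        xi = np.ones(p)
    S_w = np.eye(q) / eta

    w = alpha * mu
    XtXw = XtX @ w
    s2 = sigma2 / (xtx + 1.0 / sigma_beta2)

    elbo_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logit_pi = Aaug @ m_w
        _sweep(
            XtX, XtY, xtx, alpha, mu, w, XtXw, logit_pi, s2, sigma2,
            sigma_beta2 * sigma2,
        )

        if update_omega:
            lam = _jj_lambda(xi)
            prec = eta * np.eye(q) + 2.0 * (Aaug.T * lam) @ Aaug
            S_w = np.linalg.inv(prec)
            m_w = S_w @ (Aaug.T @ (alpha - 0.5))
            second = S_w + np.outer(m_w, m_w)
            xi = np.sqrt(np.einsum("ij,jk,ik->i", Aaug, second, Aaug))
        else:
            # omega held fixed; xi still tightens the bound around it
            second = S_w + np.outer(m_w, m_w)
            xi = np.sqrt(np.einsum("ij,jk,ik->i", Aaug, second, Aaug))

        if profile_sigma2:
            ssr = (
                yty
                - 2.0 * w @ XtY
                + w @ XtXw
                + np.sum(xtx * (alpha * (s2 + mu**2) - w**2))
            )
            a_sum = alpha.sum()
            sigma2 = float(
                (ssr + np.sum(alpha * (s2 + mu**2)) / sigma_beta2)
                / (n + a_sum)
            )
            sigma2 = max(sigma2, 1e-10)
            s2 = sigma2 / (xtx + 1.0 / sigma_beta2)

        elbo = _elbo(
            yty, XtY, xtx, n, alpha, mu, s2, w, XtXw, Aaug, m_w, S_w, xi,
            sigma2, sigma_beta2, eta,
        )
        elbo_trace.append(elbo)
        if it > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break

    if not converged:
        last = elbo_trace[-1] - elbo_trace[-2] if len(elbo_trace) > 1 else float("nan")
        warnings.warn(
            f"VB did not converge in {max_iter} iterations "
            f"(last ELBO change {last:.3g})",
            stacklevel=2,
        )
    return VariationalState(
        alpha=alpha,
        mu=mu,
        s2=s2,
        omega_mean=m_w,
        omega_cov=S_w,
        xi=xi,
        elbo_trace=elbo_trace,
        sigma2=sigma2,
        sigma_beta2=sigma_beta2,
        eta=eta,
        converged=converged,
        n_iter=it,
    )


def _log_theta_prior(theta: tuple[float, float, float], cfg: PriorConfig) -> float:
    """Log density of theta under IG(a,b) x IG(c,d) x Gamma(a0,b0)."""
    s2, sb2, eta = theta

    def _log_invgamma(x, shape, scale):
        return (
            shape * np.log(scale) - gammaln(shape) - (shape + 1) * np.log(x) - scale / x
        )

    def _log_gamma(x, shape, rate):
        return shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x

    return float(
        _log_invgamma(s2, cfg.a, cfg.b)
        + _log_invgamma(sb2, cfg.c, cfg.d)
        + _log_gamma(eta, cfg.a0, cfg.b0)
    )


def fit_grid(
    X: np.ndarray,
    Y: np.ndarray,
    A: AnnotationMatrix | np.ndarray,
    config: PriorConfig | None = None,
    seed: int = DEFAULT_SEED,
    gene_id: str = "gene",
    tissue: str = "tissue",
    snps: list[SnpRecord] | None = None,
    train_mean: np.ndarray | None = None,
    method_tag: str = "tgen",
    update_omega: bool = True,
) -> tuple[GridFit, ImputationModel]:
    """Fit the model over the hyperparameter grid and average.

    ``X`` is the raw (uncentered) dosage matrix; it is centered here and
    the column means are stored on the model for prediction-time centering.
    Grid weights are softmax(ELBO(theta) + log p(theta)); PPS and beta_hat
    are the weight-averaged alpha and alpha*mu.
    """
    del seed  # updates are deterministic (cyclic order); kept for interface
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    if config is None:
        config = PriorConfig()
    col_mean = X.mean(axis=0) if train_mean is None else np.asarray(train_mean)
    Xc = X - col_mean
    Yc = Y - Y.mean()
    n, p = Xc.shape

    grid, profile = config.resolve_grid(float(np.var(Yc)))
    XtX = Xc.T @ Xc
    suff = (XtX, Xc.T @ Yc, float(Yc @ Yc))

    states = []
    for theta in grid:
        states.append(
            fit_single_theta(
                Xc, Yc, A, theta,
                tol=config.tol, max_iter=config.max_iter,
                update_omega=update_omega, profile_sigma2=profile,
                _suff=suff,
            )
        )
    if not any(st.converged for st in states):
        diag = ", ".join(
            f"theta={st.sigma2:.3g}/{st.sigma_beta2:.3g}/{st.eta:.3g} "
            f"iters={st.n_iter}" for st in states
        )
        raise RuntimeError(f"no grid point converged: {diag}")

    # weight each theta by its (profiled) ELBO plus the hyper-prior density
    logw = np.array(
        [
            st.elbo + _log_theta_prior((st.sigma2, st.sigma_beta2, st.eta), config)
            for st in states
        ]
    )
    logw = logw - logsumexp(logw)
    fit = GridFit(states=states, log_weights=logw)

    wts = fit.weights
    pps = np.sum([w * st.alpha for w, st in zip(wts, states)], axis=0)
    beta_hat = np.sum([w * st.alpha * st.mu for w, st in zip(wts, states)], axis=0)
    omega_hat = np.sum([w * st.omega_mean for w, st in zip(wts, states)], axis=0)

    if snps is None:
        snps = [
            SnpRecord(f"snp{j}", "1", j + 1, "A", "G", 0.25) for j in range(p)
        ]
    model = ImputationModel(
        gene_id=gene_id,
        tissue=tissue,
        snps=snps,
        beta_hat=beta_hat,
        pps=pps,
        train_mean=col_mean,
        omega_hat=omega_hat,
        method_tag=method_tag,
    )
    return fit, model


def fit_diagnostics(fit: GridFit) -> dict:
    """JSON-serializable per-fit diagnostics: grid, weights, ELBO traces."""
    return {
        "grid": [
            {
                "sigma2": st.sigma2,
                "sigma_beta2": st.sigma_beta2,
                "eta": st.eta,
                "weight": float(w),
                "elbo": st.elbo,
                "n_iter": st.n_iter,
                "converged": st.converged,
                "elbo_trace": [float(v) for v in st.elbo_trace],
            }
            for st, w in zip(fit.states, fit.weights)
        ]
    }


def fit_vb_baseline(
    X: np.ndarray,
    Y: np.ndarray,
    config: PriorConfig | None = None,
    seed: int = DEFAULT_SEED,
    **kwargs,
) -> ImputationModel:
    """Annotation-free spike-and-slab VB (intercept-only prior logit)."""
    p = np.asarray(X).shape[1]
    kwargs.setdefault("method_tag", "vb")
    _, model = fit_grid(
        X, Y, AnnotationMatrix.empty(p), config=config, seed=seed, **kwargs
    )
    return model


def _elnt_fit(Xc: np.ndarray, Yc: np.ndarray, seed: int) -> np.ndarray:
    """Elastic net with mixing parameter 0.5, penalty by internal CV."""
    from sklearn.linear_model import ElasticNetCV

    n = Xc.shape[0]
    cv = min(5, n)
    enet = ElasticNetCV(
        l1_ratio=0.5, cv=cv, random_state=seed, alphas=50, max_iter=5000,
        fit_intercept=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(Xc, Yc)
    return enet.coef_


def fit_elnt(
    X: np.ndarray,
    Y: np.ndarray,
    seed: int = DEFAULT_SEED,
    gene_id: str = "gene",
    tissue: str = "tissue",
    snps: list[SnpRecord] | None = None,
    method_tag: str = "elnt",
) -> ImputationModel:
    """Elastic-net comparator (mixing parameter 0.5, CV-chosen penalty)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    col_mean = X.mean(axis=0)
    beta = _elnt_fit(X - col_mean, Y - Y.mean(), seed)
    p = X.shape[1]
    if snps is None:
        snps = [SnpRecord(f"snp{j}", "1", j + 1, "A", "G", 0.25) for j in range(p)]
    return ImputationModel(
        gene_id=gene_id,
        tissue=tissue,
        snps=snps,
        beta_hat=beta,
        pps=(beta != 0).astype(float),
        train_mean=col_mean,
        omega_hat=np.zeros(1),
        method_tag=method_tag,
    )


def annotation_filter_fit(
    X: np.ndarray,
    Y: np.ndarray,
    A: AnnotationMatrix,
    tracks: list[str] | None = None,
    base: str = "vb",
    config: PriorConfig | None = None,
    seed: int = DEFAULT_SEED,
    gene_id: str = "gene",
    tissue: str = "tissue",
    snps: list[SnpRecord] | None = None,
) -> ImputationModel:
    """Hard annotation filtering then a base fit (the .annot comparators).

    Drops SNPs with no positive value on ANY of the listed tracks, then
    fits either the vb spike-and-slab or the elastic net on the survivors.
    Dropped SNPs are absent from the returned model.
    """
    if base not in ("vb", "elnt"):
        raise ValueError("base must be 'vb' or 'elnt'")
    if tracks is None:
        tracks = list(A.track_names)
    missing = set(tracks) - set(A.track_names)
    if missing:
        raise ValueError(f"unknown tracks: {sorted(missing)}")
    tcols = [A.track_names.index(t) for t in tracks]
    keep = np.any(A.values[:, tcols] > 0, axis=1) if tcols else np.zeros(
        A.n_snps, dtype=bool
    )
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if snps is None:
        snps = [SnpRecord(f"snp{j}", "1", j + 1, "A", "G", 0.25) for j in range(p)]
    tag = "vb.annot" if base == "vb" else "elnt.annot"
    if not keep.any():
        warnings.warn(
            f"{gene_id}: all SNPs removed by annotation filtering", stacklevel=2
        )
        return ImputationModel(
            gene_id=gene_id, tissue=tissue, snps=[],
            beta_hat=np.zeros(0), pps=np.zeros(0), train_mean=np.zeros(0),
            omega_hat=np.zeros(1), method_tag=tag,
        )
    idx = np.flatnonzero(keep)
    Xs = X[:, idx]
    sub_snps = [snps[i] for i in idx]
    if base == "vb":
        model = fit_vb_baseline(
            Xs, Y, config=config, seed=seed, gene_id=gene_id, tissue=tissue,
            snps=sub_snps, method_tag=tag,
        )
    else:
        model = fit_elnt(
            Xs, Y, seed=seed, gene_id=gene_id, tissue=tissue, snps=sub_snps,
            method_tag=tag,
        )
    return model


def predict_expression(model: ImputationModel, panel: GenotypePanel) -> np.ndarray:
    """Impute expression on a panel: centered dosages times beta_hat.

    Dosages are centered with the model's stored training means.  Model
    SNPs absent from the panel contribute 0, with a warning.
    """
    pos = {sid: j for j, sid in enumerate(panel.snp_ids)}
    pred = np.zeros(panel.n_samples)
    missing = []
    for k, snp in enumerate(model.snps):
        j = pos.get(snp.snp_id)
        if j is None:
            missing.append(snp.snp_id)
            continue
        pred += model.beta_hat[k] * (panel.dosages[:, j] - model.train_mean[k])
    if missing:
        warnings.warn(
            f"{model.gene_id}: {len(missing)} model SNPs absent from panel, "
            f"contributing 0 (e.g. {missing[:3]})",
            stacklevel=2,
        )
    return pred
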