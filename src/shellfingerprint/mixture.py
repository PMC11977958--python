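"""Unsupervised Bayesian Gaussian-mixture clustering of settler signatures.

When the brood baseline map does not cover the settler pool, the number of
distinct geochemical sources contributing to a settler cohort can still be
estimated by clustering.  A conjugate Gibbs sampler explores a finite
Gaussian mixture at fixed K (Normal–Inverse-Wishart component priors,
Dirichlet weights), and model selection over K = 1..K_max uses BIC at the
posterior-mean parameters, preferring the smallest K within a small
tolerance of the optimum.

Identifiability: component labels are arbitrary under the likelihood, so
every retained draw is relabelled by sorting components on their mean's
first coordinate before summarizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["NIWPrior", "MixtureFit", "gibbs_gmm", "select_num_sources"]


@dataclass
class NIWPrior:
    """Normal–Inverse-Wishart prior; data-dependent weak defaults."""

    m0: np.ndarray
    kappa0: float
    nu0: float
    psi0: np.ndarray
    alpha: float = 1.0      # symmetric Dirichlet weight prior

    @classmethod
    def default(cls, X: np.ndarray) -> "NIWPrior":
        p = X.shape[1]
        cov = np.cov(X, rowvar=False, ddof=1)
        if cov.ndim == 0:
            cov = cov.reshape(1, 1)
        return cls(m0=X.mean(axis=0), kappa0=0.01, nu0=p + 2, psi0=cov)


@dataclass
class MixtureFit:
    K: int
    weights: np.ndarray
    means: np.ndarray                   # K × p posterior means
    covariances: np.ndarray             # K × p × p posterior means
    membership: np.ndarray              # n × K posterior membership
    log_likelihood: float               # at posterior-mean parameters
    bic: float
    n_iter: int
    burn_in: int
    seed: int
    diagnostics: dict = field(default_factory=dict)
    score_table: dict[int, float] | None = None
    selected_K: int | None = None

    def __post_init__(self) -> None:
        assert np.isclose(self.weights.sum(), 1.0)
        assert np.allclose(self.membership.sum(axis=1), 1.0)


def _mvn_logpdf(X, mean, cov):
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (X - mean).T)
    q = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    p = X.shape[1]
    return -0.5 * (q + logdet + p * np.log(2 * np.pi))


def _loglik(X, weights, means, covs):
    n, K = len(X), len(weights)
    lp = np.empty((n, K))
    for k in range(K):
        lp[:, k] = np.log(weights[k] + 1e-300) + _mvn_logpdf(X, means[k], covs[k])
    m = lp.max(axis=1, keepdims=True)
    return float((m[:, 0] + np.log(np.exp(lp - m).sum(axis=1))).sum())


def _n_params(K: int, p: int) -> int:
    return (K - 1) + K * p + K * p * (p + 1) // 2


def gibbs_gmm(X, K: int, prior: NIWPrior | None = None, n_iter: int = 2000,
              burn_in: int = 500, seed: int = 0) -> MixtureFit:
    """Collapsed-parameter Gibbs sweep at fixed K.

    Alternates categorical membership draws with conjugate Dirichlet /
    Normal–Inverse-Wishart parameter draws.  Post-burn-in draws are
    relabelled (components ordered by first mean coordinate) and averaged.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= K * (p + 1):
        raise ValueError(f"need n > K(p+1) = {K * (p + 1)}; got n = {n}")
    if prior is None:
        prior = NIWPrior.default(X)
    rng = np.random.default_rng(seed)

    z = rng.integers(0, K, size=n)
    means = np.tile(X.mean(axis=0), (K, 1))
    covs = np.tile(prior.psi0, (K, 1, 1))
    weights = np.full(K, 1.0 / K)

    keep = n_iter - burn_in
    sum_w = np.zeros(K)
    sum_mu = np.zeros((K, p))
    sum_cov = np.zeros((K, p, p))
    sum_member = np.zeros((n, K))
    ll_trace = np.empty(n_iter)
    empty_sweeps = 0

    for it in range(n_iter):
        # membership draws
        lp = np.empty((n, K))
        for k in range(K):
            lp[:, k] = np.log(weights[k] + 1e-300) + _mvn_logpdf(X, means[k], covs[k])
        m = lp.max(axis=1, keepdims=True)
        pr = np.exp(lp - m)
        pr /= pr.sum(axis=1, keepdims=True)
        u = rng.random(n)
        z = (pr.cumsum(axis=1) < u[:, None]).sum(axis=1)

        counts = np.bincount(z, minlength=K)
        if (counts == 0).any():
            empty_sweeps += 1
        weights = rng.dirichlet(prior.alpha + counts)

        for k in range(K):
            block = X[z == k]
            nk = len(block)
            if nk:
                xbar = block.mean(axis=0)
                d = block - xbar
                S = d.T @ d
            else:
                xbar = prior.m0
                S = np.zeros((p, p))
            kappa_n = prior.kappa0 + nk
            nu_n = prior.nu0 + nk
            m_n = (prior.kappa0 * prior.m0 + nk * xbar) / kappa_n
            dd = xbar - prior.m0
            psi_n = prior.psi0 + S + (prior.kappa0 * nk / kappa_n) * np.outer(dd, dd)
            covs[k] = stats.invwishart.rvs(df=nu_n, scale=psi_n, random_state=rng)
            covs[k] = np.atleast_2d(covs[k])
            means[k] = rng.multivariate_normal(m_n, covs[k] / kappa_n)

        ll_trace[it] = _loglik(X, weights, means, covs)
        if it >= burn_in:
            order = np.argsort(means[:, 0], kind="mergesort")
            sum_w += weights[order]
            sum_mu += means[order]
            sum_cov += covs[order]
            # relabelled one-hot membership
            relab = np.empty(K, dtype=int)
            relab[order] = np.arange(K)
            onehot = np.zeros((n, K))
            onehot[np.arange(n), relab[z]] = 1.0
            sum_member += onehot

    w_hat = sum_w / keep
    w_hat /= w_hat.sum()
    mu_hat = sum_mu / keep
    cov_hat = sum_cov / keep
    member = sum_member / keep
    member /= member.sum(axis=1, keepdims=True)
    ll = _loglik(X, w_hat, mu_hat, cov_hat)
    bic = -2.0 * ll + _n_params(K, p) * np.log(n)
    diagnostics = {
        "empty_component_sweeps": int(empty_sweeps),
        "empty_component_warning": empty_sweeps > 0.5 * n_iter,
        "loglik_trace_mean_post_burnin": float(ll_trace[burn_in:].mean()),
        "loglik_trace_split_halves": (
            float(ll_trace[burn_in:burn_in + keep // 2].mean()),
            float(ll_trace[burn_in + keep // 2:].mean()),
        ),
    }
    return MixtureFit(K=K, weights=w_hat, means=mu_hat, covariances=cov_hat,
                      membership=member, log_likelihood=ll, bic=bic,
                      n_iter=n_iter, burn_in=burn_in, seed=seed,
                      diagnostics=diagnostics)


def select_num_sources(X, K_max: int = 4, criterion: str = "bic",
                       n_iter: int = 2000, burn_in: int = 500,
                       n_chains: int = 3, seed: int = 0,
                       bic_tol: float = 2.0) -> MixtureFit:
    """Fit K = 1..K_max and select the number of source clusters.

    Each K runs ``n_chains`` seeded chains; the chain with the best
    (lowest) BIC at posterior-mean parameters represents that K.  The
    selected K is the smallest whose score is within ``bic_tol`` of the
    overall optimum — a small-K preference that guards against spurious
    extra components.
    """
    X = np.asarray(X, float)
    if not 1 <= K_max <= 8:
        raise ValueError("K_max must lie in [1, 8]")
    if criterion != "bic":
        raise ValueError("only BIC selection is implemented")
    ss = np.random.SeedSequence(seed)
    fits: dict[int, MixtureFit] = {}
    scores: dict[int, float] = {}
    failed: list[int] = []
    for K in range(1, K_max + 1):
        child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_chains)]
        best = None
        for cs in child_seeds:
            try:
                fit = gibbs_gmm(X, K, n_iter=n_iter, burn_in=burn_in, seed=cs)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best is None or fit.bic < best.bic:
                best = fit
        if best is None:
            failed.append(K)
            continue
        fits[K] = best
        scores[K] = best.bic
    if not fits:
        raise RuntimeError("no K converged")
    best_score = min(scores.values())
    selected = min(K for K, s in scores.items() if s <= best_score + bic_tol)
    out = fits[selected]
    out.score_table = scores
    out.selected_K = selected
    if failed:
        out.diagnostics["failed_K"] = failed
    return out
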