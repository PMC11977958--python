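"""Assigning settlers of unknown origin to brood baseline regions.

Three complementary views, all fitted on broods only (the settler data
never touches baseline fitting):

1. **Projection** into brood LDA canonical space, reporting how many
   settlers fall outside every region's 95% confidence ellipse — a visual
   and quantitative congruence check between baselines and settlers.
2. **Extra-baseline probability**: each region gets a multivariate normal
   fitted to selected log ratios (by default Mn:Ca and Sr:Ca); a settler's
   probability of originating *outside* the sampled baselines is one minus
   the best (largest) chi-square tail probability of its squared
   Mahalanobis distance across regions.  Settlers whose outside-probability
   exceeds the confidence level are flagged; a high flagged fraction warns
   that the baseline map does not cover the settler pool.
3. **Mixed-stock MLE**: settler-cohort mixture proportions over the
   baseline regions by EM with the component densities held fixed at their
   baseline fits; CIs by resampling settlers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import SignatureSet, log_standardize
from .lda import LDAModel, CanonicalScores, canonical_scores, confidence_ellipse, \
    point_in_ellipse, predict_lda

__all__ = [
    "BaselineModel",
    "AssignmentReport",
    "MixtureProportions",
    "fit_baseline",
    "project_settlers",
    "extra_baseline_probability",
    "mle_mixture_proportions",
]


@dataclass
class BaselineModel:
    """Per-region multivariate normals on selected log-scale elements."""

    regions: list[str]
    elements: list[str]
    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]
    n_per_region: dict[str, int]

    def __post_init__(self) -> None:
        for r in self.regions:
            try:
                np.linalg.cholesky(self.covs[r])
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"non-PD baseline covariance for region {r}") from exc

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """n × K log densities under each region's fitted normal."""
        out = np.empty((len(X), len(self.regions)))
        for k, r in enumerate(self.regions):
            out[:, k] = stats.multivariate_normal.logpdf(
                X, mean=self.means[r], cov=self.covs[r])
        return out

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        out = np.empty((len(X), len(self.regions)))
        for k, r in enumerate(self.regions):
            d = X - self.means[r]
            out[:, k] = np.einsum("ij,ij->i", d, np.linalg.solve(self.covs[r], d.T).T)
        return out


def fit_baseline(broods: SignatureSet, elements: list[str],
                 group_by: str = "region", min_n: int = 5) -> BaselineModel:
    """Fit per-region normals to brood log signatures on selected elements."""
    if broods.transform_state == "raw":
        from .io_preprocess import log_transform
        broods = log_transform(broods)
    elif broods.transform_state != "log":
        raise ValueError("baseline is fitted on the log scale, not standardized")
    sub = broods.select_elements(elements)
    groups = sub.meta[group_by]
    regions = list(pd.unique(groups))
    means, covs, ns = {}, {}, {}
    for r in regions:
        block = sub.values[groups == r].to_numpy(float)
        if len(block) < min_n:
            raise ValueError(
                f"region {r} has only {len(block)} broods for elements "
                f"{elements}; need >= {min_n}")
        means[r] = block.mean(axis=0)
        covs[r] = np.cov(block, rowvar=False, ddof=1)
        if covs[r].ndim == 0:
            covs[r] = covs[r].reshape(1, 1)
        ns[r] = len(block)
    return BaselineModel(regions, list(elements), means, covs, ns)


@dataclass
class MixtureProportions:
    proportions: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    log_likelihood: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class AssignmentReport:
    scores: CanonicalScores
    inside_ellipse: pd.DataFrame        # settler × region booleans
    outside_all_fraction: float
    lda_posteriors: pd.DataFrame | None = None
    outside_probability: pd.Series | None = None
    flagged_fraction: float | None = None
    mixture: MixtureProportions | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.to_frame()
        df = df.join(self.inside_ellipse.add_prefix("inside_"))
        if self.lda_posteriors is not None:
            df = df.join(self.lda_posteriors.add_prefix("post_"))
        if self.outside_probability is not None:
            df["outside_probability"] = self.outside_probability
        return df


def _frozen_transform(model: LDAModel, settlers: SignatureSet) -> SignatureSet:
    """Apply the brood-fitted transform; refuse to refit on settlers."""
    if settlers.transform_state == "log_standardized":
        return settlers.select_elements(model.elements)
    if model.transform_params is None:
        raise ValueError(
            "model carries no transform params; supply settlers already in "
            "the model's transformed space")
    full = settlers.select_elements(model.transform_params.elements)
    z, _ = log_standardize(full, params=model.transform_params)
    return z.select_elements(model.elements)


def project_settlers(model: LDAModel, settlers: SignatureSet,
                     level: float = 0.95) -> AssignmentReport:
    """Project settlers into brood LDA space and measure ellipse exclusion.

    Scores use the brood-fitted transform and axes (never refit); region
    ellipses are the ``level`` confidence ellipses of the brood training
    scores, matching the published ordination plots.
    """
    if model.training_scores is None:
        raise ValueError("model lacks stored training scores for ellipses")
    z = _frozen_transform(model, settlers)
    sc = canonical_scores(model, z)
    sc.labels = settlers.meta["site"].to_numpy() if "site" in settlers.meta else None
    pts = sc.scores[:, :2]

    inside = {}
    for c in model.classes:
        grp = model.training_scores[model.training_labels == c][:, :2]
        spec = confidence_ellipse(grp, level=level)
        inside[c] = point_in_ellipse(spec, pts)
    inside_df = pd.DataFrame(inside, index=z.values.index)
    outside_all = float((~inside_df.any(axis=1)).mean())

    labels, post = predict_lda(model, z)
    post_df = pd.DataFrame(post, index=z.values.index, columns=model.classes)
    return AssignmentReport(sc, inside_df, outside_all, lda_posteriors=post_df)


def extra_baseline_probability(
    baseline: BaselineModel, settlers: SignatureSet, level: float = 0.95
) -> tuple[pd.Series, float]:
    """Per-settler probability of extra-baseline origin, plus flagged fraction.

    For each settler the squared Mahalanobis distance to each region's
    fitted normal gives a chi-square tail probability (df = number of
    elements); outside-probability = 1 − max over regions.  A settler is
    flagged when that exceeds ``level``.
    """
    if settlers.transform_state == "raw":
        from .io_preprocess import log_transform
        settlers = log_transform(settlers)
    elif settlers.transform_state != "log":
        raise ValueError("extra-baseline test runs on the log scale")
    sub = settlers.select_elements(baseline.elements)
    X = sub.values.to_numpy(float)
    d2 = baseline.mahalanobis_sq(X)
    tail = stats.chi2.sf(d2, df=len(baseline.elements))
    outside = 1.0 - tail.max(axis=1)
    out = pd.Series(outside, index=sub.values.index, name="outside_probability")
    flagged = float((out > level).mean())
    return out, flagged


def mle_mixture_proportions(
    baseline: BaselineModel, settlers: SignatureSet, max_iter: int = 2000,
    tol: float = 1e-10, n_boot: int = 500, seed: int = 0,
    ci_level: float = 0.95,
) -> MixtureProportions:
    """Mixed-stock EM: cohort mixture proportions over baseline regions.

    Component densities stay fixed at their baseline fits; EM updates only
    the mixing weights, so each iteration is a responsibility average and
    the log-likelihood is non-decreasing.  CIs come from resampling
    settlers with replacement and re-running EM.
    """
    if settlers.transform_state == "raw":
        from .io_preprocess import log_transform
        settlers = log_transform(settlers)
    elif settlers.transform_state != "log":
        raise ValueError("mixed-stock MLE runs on the log scale")
    sub = settlers.select_elements(baseline.elements)
    n = sub.n
    if n < 10:
        raise ValueError("need at least 10 settlers")
    if len(baseline.regions) < 2:
        raise ValueError("need at least 2 baseline regions")
    logL = baseline.log_density(sub.values.to_numpy(float))   # n × K

    def em(logL_mat, record_trace=False):
        K = logL_mat.shape[1]
        pi = np.full(K, 1.0 / K)
        trace = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            a = logL_mat + np.log(pi)
            m = a.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(a - m).sum(axis=1))
            ll = float(lse.sum())
            resp = np.exp(a - lse[:, None])
            pi = resp.mean(axis=0)
            if record_trace:
                trace.append(ll)
            if ll - prev < tol and it > 1:
                converged = True
                break
            prev = ll
        return pi, ll, np.array(trace), converged, it

    pi_hat, ll, trace, converged, n_iter = em(logL, record_trace=True)
    if not converged:
        warnings.warn("mixed-stock EM did not converge within max_iter; "
                      "returning last iterate", stacklevel=2)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(baseline.regions)))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b], _, _, _, _ = em(logL[idx])
    alpha = (1 - ci_level) / 2
    lo = np.percentile(boots, 100 * alpha, axis=0)
    hi = np.percentile(boots, 100 * (1 - alpha), axis=0)
    idx = pd.Index(baseline.regions, name="region")
    return MixtureProportions(
        proportions=pd.Series(pi_hat, index=idx),
        ci_low=pd.Series(lo, index=idx), ci_high=pd.Series(hi, index=idx),
        log_likelihood=ll, loglik_trace=trace, converged=converged, n_iter=n_iter)
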