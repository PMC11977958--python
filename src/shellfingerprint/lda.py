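"""Linear discriminant analysis from first principles.

Discriminant axes solve the generalized eigenproblem of between-group
scatter against pooled within-group covariance, maximizing the ratio of
between- to within-group variance along each axis.  Classification uses the
Gaussian discriminant score with a shared covariance; canonical scores and
95% confidence ellipses support the ordination-style plots used in
elemental-fingerprinting studies.

Conventions (declared, since the math leaves them free):

* pooled covariance uses the unbiased ``n - g`` denominator,
* priors default to group proportions, configurable to uniform,
* each axis is scaled to unit within-class variance (aᵀ S_w a = 1) and
  oriented so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io_preprocess import SignatureSet, TransformParams

__all__ = [
    "LDAModel",
    "CanonicalScores",
    "EllipseSpec",
    "fit_lda",
    "predict_lda",
    "canonical_scores",
    "confidence_ellipse",
    "point_in_ellipse",
]


@dataclass
class LDAModel:
    classes: list[str]
    priors: np.ndarray                  # per class, sums to 1
    class_means: np.ndarray             # g × p
    pooled_cov: np.ndarray              # p × p, denominator n - g
    axes: np.ndarray                    # p × m, aᵀ S_w a = 1
    eigenvalues: np.ndarray             # m, descending
    proportion_of_trace: np.ndarray     # m, sums to 1
    grand_mean: np.ndarray              # p, weighted overall mean
    elements: list[str]
    counts: np.ndarray
    transform_params: TransformParams | None = None
    training_scores: np.ndarray | None = None   # n × m canonical scores
    training_labels: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def to_json(self, path=None) -> str:
        d = {
            "classes": self.classes,
            "priors": self.priors.tolist(),
            "class_means": self.class_means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "axes": self.axes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "proportion_of_trace": self.proportion_of_trace.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "elements": self.elements,
            "counts": self.counts.tolist(),
            "transform_params": (self.transform_params.to_dict()
                                 if self.transform_params else None),
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LDAModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        tp = d.get("transform_params")
        return cls(
            classes=d["classes"],
            priors=np.array(d["priors"]),
            class_means=np.array(d["class_means"]),
            pooled_cov=np.array(d["pooled_cov"]),
            axes=np.array(d["axes"]),
            eigenvalues=np.array(d["eigenvalues"]),
            proportion_of_trace=np.array(d["proportion_of_trace"]),
            grand_mean=np.array(d["grand_mean"]),
            elements=d["elements"],
            counts=np.array(d["counts"]),
            transform_params=TransformParams.from_dict(tp) if tp else None,
        )


@dataclass
class CanonicalScores:
    scores: np.ndarray              # n × m
    labels: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        m = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"LD{i + 1}" for i in range(m)])
        if self.sample_ids is not None:
            df.index = pd.Index(self.sample_ids, name="sample_id")
        if self.labels is not None:
            df.insert(0, "group", np.asarray(self.labels))
        return df


@dataclass
class EllipseSpec:
    """Confidence region {x : (x−c)ᵀ S⁻¹ (x−c) ≤ q}."""

    center: np.ndarray
    shape: np.ndarray
    level: float
    quantile: float = field(init=False)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.shape = np.asarray(self.shape, float)
        if not 0 < self.level < 1:
            raise ValueError("confidence level must lie in (0, 1)")
        try:
            np.linalg.cholesky(self.shape)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate (non-PD) ellipse shape matrix") from exc
        self.quantile = float(stats.chi2.ppf(self.level, df=len(self.center)))


def _resolve_input(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(X, SignatureSet):
        return X.values.to_numpy(float), X.elements, list(X.values.index)
    return np.asarray(X, dtype=float), None, None


def _pooled_scatter(X: np.ndarray, labels: np.ndarray, classes: list):
    g = len(classes)
    n, p = X.shape
    means = np.empty((g, p))
    counts = np.empty(g, dtype=int)
    Sw = np.zeros((p, p))
    for k, c in enumerate(classes):
        block = X[labels == c]
        counts[k] = len(block)
        means[k] = block.mean(axis=0)
        d = block - means[k]
        Sw += d.T @ d
    return means, counts, Sw


def fit_lda(
    X,
    labels=None,
    priors: str | np.ndarray = "proportional",
    transform_params: TransformParams | None = None,
    elements: list[str] | None = None,
) -> LDAModel:
    """Fit an LDA model to signatures with group labels.

    ``X`` may be a :class:`SignatureSet` (labels taken from ``labels`` which
    then names a metadata column, default ``"region"``) or a plain array with
    an explicit label vector.  Classes are ordered by first appearance.
    """
    if isinstance(X, SignatureSet):
        col = labels if isinstance(labels, str) else "region"
        label_vec = X.meta[col].to_numpy()
    else:
        label_vec = np.asarray(labels)
    Xa, els, ids = _resolve_input(X)
    if elements is None:
        elements = els or [f"x{i}" for i in range(Xa.shape[1])]
    n, p = Xa.shape
    classes = list(pd.unique(label_vec))
    g = len(classes)
    if g < 2:
        raise ValueError("need at least 2 groups")
    means, counts, Sw_raw = _pooled_scatter(Xa, label_vec, classes)
    if (counts < 2).any():
        small = [c for c, k in zip(classes, counts) if k < 2]
        raise ValueError(f"each group needs n >= 2; too small: {small}")
    Sw = Sw_raw / (n - g)

    if isinstance(priors, str):
        if priors == "proportional":
            pri = counts / counts.sum()
        elif priors == "uniform":
            pri = np.full(g, 1.0 / g)
        else:
            raise ValueError(f"unknown priors policy {priors!r}")
    else:
        pri = np.asarray(priors, float)
        if len(pri) != g or not np.isclose(pri.sum(), 1.0):
            raise ValueError("explicit priors must match group count and sum to 1")

    grand = (counts[:, None] * means).sum(axis=0) / n
    dm = means - grand
    Sb = (counts[:, None, None] * (dm[:, :, None] * dm[:, None, :])).sum(axis=0) / (n - g)

    try:
        eigvals, eigvecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "singular pooled covariance; reduce the element subset") from exc
    order = np.argsort(eigvals)[::-1]
    m = min(p, g - 1)
    eigvals = np.clip(eigvals[order][:m], 0.0, None)
    axes = eigvecs[:, order][:, :m]          # eigh: vᵀ S_w v = 1 already
    # orient each axis so its largest-|loading| is positive
    for j in range(m):
        i_max = np.argmax(np.abs(axes[:, j]))
        if axes[i_max, j] < 0:
            axes[:, j] = -axes[:, j]
    total = eigvals.sum()
    prop = eigvals / total if total > 0 else np.full(m, 1.0 / m)

    model = LDAModel(
        classes=[str(c) for c in classes], priors=pri, class_means=means,
        pooled_cov=Sw, axes=axes, eigenvalues=eigvals, proportion_of_trace=prop,
        grand_mean=grand, elements=list(elements), counts=counts,
        transform_params=transform_params,
    )
    model.training_scores = (Xa - grand) @ axes
    model.training_labels = np.asarray([str(c) for c in label_vec])
    return model


def _discriminant_scores(model: LDAModel, Xa: np.ndarray) -> np.ndarray:
    """Log posterior up to a row-constant: xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + log π_k."""
    Sinv_mu = np.linalg.solve(model.pooled_cov, model.class_means.T)   # p × g
    lin = Xa @ Sinv_mu
    const = -0.5 * np.einsum("kp,pk->k", model.class_means, Sinv_mu)
    return lin + const + np.log(model.priors)


def predict_lda(model: LDAModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Classify signatures; returns (labels, posterior matrix, rows sum to 1)."""
    Xa, els, _ = _resolve_input(X)
    if els is not None and els != model.elements:
        raise ValueError(f"element panel mismatch: model {model.elements} vs data {els}")
    if Xa.shape[1] != len(model.elements):
        raise ValueError("dimension mismatch with model element subset")
    scores = _discriminant_scores(model, Xa)
    shifted = scores - scores.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    # argmax with deterministic first-in-declared-order tie-break
    pred_idx = np.argmax(scores, axis=1)
    labels = np.asarray(model.classes, dtype=object)[pred_idx]
    return labels, post


def canonical_scores(model: LDAModel, X, labels=None) -> CanonicalScores:
    """Project signatures onto the discriminant axes (centered at fit mean)."""
    Xa, els, ids = _resolve_input(X)
    if els is not None and els != model.elements:
        raise ValueError(f"element panel mismatch: model {model.elements} vs data {els}")
    sc = (Xa - model.grand_mean) @ model.axes
    if labels is None and isinstance(X, SignatureSet) and "region" in X.meta:
        labels = X.meta["region"].to_numpy()
    return CanonicalScores(sc, labels=labels, sample_ids=ids)


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> EllipseSpec:
    """Confidence ellipse for one group's 2-D canonical scores.

    Center = group mean, shape = sample covariance (ddof 1), threshold = the
    chi-square ``level`` quantile with 2 degrees of freedom.
    """
    pts = np.asarray(scores, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected n × 2 score matrix")
    if len(pts) < 3:
        raise ValueError("need at least 3 points for an ellipse")
    center = pts.mean(axis=0)
    shape = np.cov(pts, rowvar=False, ddof=1)
    return EllipseSpec(center=center, shape=shape, level=level)


def point_in_ellipse(spec: EllipseSpec, point) -> bool | np.ndarray:
    """Membership test, boundary inclusive.  Accepts one point or an n × 2 array."""
    pts = np.atleast_2d(np.asarray(point, float))
    d = pts - spec.center
    m2 = np.einsum("ij,ij->i", d, np.linalg.solve(spec.shape, d.T).T)
    inside = m2 <= spec.quantile
    return bool(inside[0]) if np.asarray(point).ndim == 1 else inside
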