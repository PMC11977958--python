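"""Classifier validation and exhaustive element-subset optimization.

Jackknife (leave-one-out) accuracy is the selection criterion: every
non-empty subset of the element panel is scored and the winner chosen by
highest overall accuracy, breaking ties toward fewer elements.  A stratified
90/10 bootstrap then estimates the chosen model's out-of-sample accuracy
with percentile confidence intervals — the jackknife on unbalanced groups
can flatter a classifier, so the two schemes are reported side by side.

The leave-one-out loop uses sufficient-statistic downdates (class sums and
scatters) rather than refitting from scratch, which keeps the 511-subset
exhaustive search fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io_preprocess import SignatureSet
from .lda import fit_lda, predict_lda

__all__ = [
    "ClassificationReport",
    "SubsetSearchResult",
    "jackknife_accuracy",
    "enumerate_subsets",
    "exhaustive_subset_search",
    "bootstrap_accuracy",
]


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame            # actual × predicted counts
    per_group_accuracy: pd.Series
    overall_accuracy: float
    subset: tuple[str, ...]
    scheme: str
    bootstrap_mean: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_replicates: int | None = None
    seed: int | None = None
    per_group_bootstrap: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.overall_accuracy <= 1.0
        total = self.confusion.to_numpy().sum()
        if total:
            trace = np.trace(self.confusion.to_numpy())
            assert np.isclose(self.overall_accuracy, trace / total)

    def to_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "subset": list(self.subset),
            "overall_accuracy": self.overall_accuracy,
            "per_group_accuracy": self.per_group_accuracy.to_dict(),
            "confusion": self.confusion.to_dict(),
        }
        if self.bootstrap_mean is not None:
            d.update(bootstrap_mean=self.bootstrap_mean, ci_low=self.ci_low,
                     ci_high=self.ci_high, n_replicates=self.n_replicates,
                     seed=self.seed)
        return d


@dataclass
class SubsetSearchResult:
    ranking: pd.DataFrame     # subset, size, overall, per-group columns
    winner: tuple[str, ...]
    winner_report: ClassificationReport
    tie_break: str = "max accuracy, then fewer elements, then lexicographic"
    skipped: list[tuple[str, ...]] | None = None


def _extract(X, labels):
    if isinstance(X, SignatureSet):
        col = labels if isinstance(labels, str) else "region"
        return X.values, X.meta[col].to_numpy()
    if isinstance(X, pd.DataFrame):
        vals = X.copy()
        vals.columns = [str(c) for c in vals.columns]
    else:
        arr = np.asarray(X, float)
        vals = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    return vals, np.asarray(labels)


def _confusion(actual, predicted, classes) -> pd.DataFrame:
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        mat[idx[a], idx[p]] += 1
    return pd.DataFrame(mat, index=pd.Index(classes, name="actual"),
                        columns=pd.Index(classes, name="predicted"))


def _report_from_confusion(conf: pd.DataFrame, subset, scheme) -> ClassificationReport:
    mat = conf.to_numpy()
    row = mat.sum(axis=1)
    per = pd.Series(np.diag(mat) / np.where(row > 0, row, 1), index=conf.index)
    overall = np.trace(mat) / mat.sum()
    return ClassificationReport(conf, per, float(overall), tuple(subset), scheme)


def _loo_predictions(Xa: np.ndarray, y: np.ndarray, classes: list,
                     priors: str = "proportional") -> np.ndarray:
    """Leave-one-out predicted labels via sufficient-statistic downdates."""
    n, p = Xa.shape
    g = len(classes)
    cls_idx = {c: k for k, c in enumerate(classes)}
    ki = np.array([cls_idx[c] for c in y])
    counts = np.bincount(ki, minlength=g).astype(float)
    if (counts < 3).any():
        raise ValueError("each group needs n >= 3 for leave-one-out validation")
    sums = np.zeros((g, p))
    scat = np.zeros((g, p, p))
    for k in range(g):
        block = Xa[ki == k]
        sums[k] = block.sum(axis=0)
        mu = sums[k] / counts[k]
        d = block - mu
        scat[k] = d.T @ d
    means_full = sums / counts[:, None]

    preds = np.empty(n, dtype=int)
    log_det_cache = {}
    for i in range(n):
        k = ki[i]
        x = Xa[i]
        nk = counts[k] - 1.0
        mu_k = (sums[k] - x) / nk
        d = x - means_full[k]
        scat_k = scat[k] - np.outer(d, d) * (counts[k] / nk)
        Sw = (scat.sum(axis=0) - scat[k] + scat_k) / (n - 1 - g)
        means = means_full.copy()
        means[k] = mu_k
        cnts = counts.copy()
        cnts[k] = nk
        pri = cnts / cnts.sum() if priors == "proportional" else np.full(g, 1.0 / g)
        try:
            Sinv_mu = np.linalg.solve(Sw, means.T)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular pooled covariance in fold {i} (sample index)") from exc
        score = x @ Sinv_mu - 0.5 * np.einsum("kp,pk->k", means, Sinv_mu) + np.log(pri)
        preds[i] = int(np.argmax(score))
    return preds


def jackknife_accuracy(X, labels=None, subset=None,
                       priors: str = "proportional") -> ClassificationReport:
    """Leave-one-out cross-validated confusion matrix and accuracies.

    Each sample is withheld in turn, the model refit on the remaining n − 1,
    and the withheld sample classified; the confusion matrix aggregates all
    n held-out predictions.
    """
    vals, y = _extract(X, labels)
    if subset is not None:
        vals = vals[list(subset)]
    else:
        subset = tuple(vals.columns.astype(str))
    classes = list(pd.unique(y))
    preds_idx = _loo_predictions(vals.to_numpy(float), y, classes, priors)
    preds = np.asarray(classes, dtype=object)[preds_idx]
    conf = _confusion(y, preds, classes)
    return _report_from_confusion(conf, subset, "jackknife")


def enumerate_subsets(panel: list[str]) -> list[tuple[str, ...]]:
    """All non-empty element subsets, ordered by size then panel order."""
    p = len(panel)
    if not 1 <= p <= 16:
        raise ValueError(
            "panel size must be in [1, 16]; exhaustive enumeration beyond "
            "16 elements is out of scope (use a heuristic search)")
    out: list[tuple[str, ...]] = []
    for size in range(1, p + 1):
        out.extend(combinations(panel, size))
    return out


def exhaustive_subset_search(X, labels=None,
                             priors: str = "proportional") -> SubsetSearchResult:
    """Score every element subset by jackknife accuracy; return the ranking.

    Winner = maximum overall accuracy, ties broken toward fewer elements and
    then lexicographically.  Subsets whose leave-one-out folds hit a singular
    pooled covariance are skipped and reported, never silently scored.
    """
    vals, y = _extract(X, labels)
    panel = list(vals.columns.astype(str))
    classes = list(pd.unique(y))
    Xa_full = vals.to_numpy(float)
    col_idx = {el: j for j, el in enumerate(panel)}

    rows = []
    skipped: list[tuple[str, ...]] = []
    for subset in enumerate_subsets(panel):
        cols = [col_idx[e] for e in subset]
        try:
            preds_idx = _loo_predictions(Xa_full[:, cols], y, classes, priors)
        except np.linalg.LinAlgError:
            skipped.append(subset)
            continue
        preds = np.asarray(classes, dtype=object)[preds_idx]
        conf = _confusion(y, preds, classes)
        mat = conf.to_numpy()
        per = np.diag(mat) / mat.sum(axis=1)
        rows.append({"subset": subset, "size": len(subset),
                     "overall": np.trace(mat) / mat.sum(),
                     **{f"acc_{c}": per[k] for k, c in enumerate(classes)}})
    if not rows:
        raise ValueError("every subset produced singular folds")
    ranking = pd.DataFrame(rows).sort_values(
        by=["overall", "size", "subset"], ascending=[False, True, True],
        kind="mergesort").reset_index(drop=True)
    winner = tuple(ranking.iloc[0]["subset"])
    winner_report = jackknife_accuracy(X, labels, subset=winner, priors=priors)
    return SubsetSearchResult(ranking, winner, winner_report, skipped=skipped or None)


def bootstrap_accuracy(X, labels=None, subset=None, train_fraction: float = 0.9,
                       reps: int = 5000, seed: int = 0,
                       priors: str = "proportional",
                       stratified: bool = True) -> ClassificationReport:
    """Repeated stratified 90/10 split accuracy with percentile 95% CI.

    Each replicate trains on ``train_fraction`` of every group and scores
    the held-out remainder; groups absent from a replicate's test split
    contribute only to the replicates where they appear.
    """
    vals, y = _extract(X, labels)
    if subset is not None:
        vals = vals[list(subset)]
    else:
        subset = tuple(vals.columns.astype(str))
    Xa = vals.to_numpy(float)
    classes = list(pd.unique(y))
    g = len(classes)
    rng = np.random.default_rng(seed)

    group_idx = [np.flatnonzero(y == c) for c in classes]
    n_train = [max(2, int(round(train_fraction * len(ix)))) for ix in group_idx]
    n_train = [min(nt, len(ix) - 1) for nt, ix in zip(n_train, group_idx)]
    if any(nt < 2 or len(ix) - nt < 1 for nt, ix in zip(n_train, group_idx)):
        raise ValueError("stratified split infeasible: a group is too small")

    overall = np.empty(reps)
    per_hits = np.zeros((reps, g))
    per_counts = np.zeros((reps, g))
    conf_total = np.zeros((g, g), dtype=int)
    for r in range(reps):
        tr, te = [], []
        if stratified:
            for ix, nt in zip(group_idx, n_train):
                perm = rng.permutation(ix)
                tr.append(perm[:nt])
                te.append(perm[nt:])
            tr = np.concatenate(tr)
            te = np.concatenate(te)
        else:
            perm = rng.permutation(len(y))
            cut = int(round(train_fraction * len(y)))
            tr, te = perm[:cut], perm[cut:]
        model = fit_lda(Xa[tr], y[tr], priors=priors)
        pred, _ = predict_lda(model, Xa[te])
        actual = y[te]
        hits = pred == actual
        overall[r] = hits.mean()
        for k, c in enumerate(classes):
            mask = actual == c
            per_counts[r, k] = mask.sum()
            per_hits[r, k] = hits[mask].sum()
            for kk, cc in enumerate(classes):
                conf_total[k, kk] += int(((actual == c) & (pred == cc)).sum())

    with np.errstate(invalid="ignore"):
        per_rep = per_hits / per_counts
    per_mean = pd.Series(np.nanmean(per_rep, axis=0), index=pd.Index(classes))
    per_ci = pd.DataFrame({
        "mean": per_mean,
        "ci_low": np.nanpercentile(per_rep, 2.5, axis=0),
        "ci_high": np.nanpercentile(per_rep, 97.5, axis=0),
    })
    conf = pd.DataFrame(conf_total, index=pd.Index(classes, name="actual"),
                        columns=pd.Index(classes, name="predicted"))
    report = _report_from_confusion(conf, subset, "bootstrap-90/10")
    report.bootstrap_mean = float(overall.mean())
    report.ci_low = float(np.percentile(overall, 2.5))
    report.ci_high = float(np.percentile(overall, 97.5))
    report.n_replicates = reps
    report.seed = seed
    report.per_group_bootstrap = per_ci
    return report
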