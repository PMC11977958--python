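"""Gower dissimilarity, ANOSIM, and nonmetric multidimensional scaling.

Used for the two comparisons that don't need a classifier: temporal
stability of signatures within a season (early vs late broods) and the
collection-method contrast (anesthetic vs lethal sampling).

* Gower: range-normalized mean absolute difference, d ∈ [0, 1].
* ANOSIM: rank-based R = (r̄_between − r̄_within) / (M/2) with a label
  permutation test.
* NMDS: Kruskal stress-1 minimized by SMACOF majorization with isotonic
  (monotone) disparities from multiple random starts; a step that fails to
  lower stress ends the start, so each start's stress trajectory is
  non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io_preprocess import SignatureSet

__all__ = ["DissimilarityMatrix", "AnosimResult", "NmdsResult",
           "gower_dissimilarity", "anosim", "nmds"]


@dataclass
class DissimilarityMatrix:
    matrix: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
            raise ValueError("dissimilarity matrix must be square and symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        assert -1.0 - 1e-12 <= self.R <= 1.0 + 1e-12
        assert 0 < self.p_value <= 1


@dataclass
class NmdsResult:
    configuration: np.ndarray
    stress: float
    best_start: int
    n_starts: int
    converged: bool
    stress_history: list[np.ndarray]  # per-start trajectories


def gower_dissimilarity(X) -> DissimilarityMatrix:
    """d(i,j) = mean over elements of |x_ie − x_je| / range_e."""
    if isinstance(X, SignatureSet):
        vals = X.values.to_numpy(float)
        ids = list(X.values.index)
    else:
        vals = np.asarray(X, float)
        ids = [str(i) for i in range(len(vals))]
    rng_ = vals.max(axis=0) - vals.min(axis=0)
    zero = np.flatnonzero(rng_ <= 0)
    if zero.size:
        names = ([X.elements[j] for j in zero] if isinstance(X, SignatureSet)
                 else [f"column {j}" for j in zero])
        raise ValueError(f"zero-range element(s): {names}")
    d = pdist(vals / rng_, metric="cityblock") / vals.shape[1]
    return DissimilarityMatrix(squareform(d), ids)


def anosim(d: DissimilarityMatrix, groups, n_perm: int = 999,
           seed: int = 0) -> AnosimResult:
    """Analysis of similarities: rank contrast of between- vs within-group pairs.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 pairs; the p-value counts permuted R ≥ observed, with the
    +1 correction.
    """
    glab = np.asarray(groups)
    names, counts = np.unique(glab, return_counts=True)
    if len(names) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with n >= 2 each")
    dv = d.condensed()
    if np.allclose(dv, dv[0]):
        raise ValueError("all dissimilarities tied; ANOSIM undefined")
    ranks = rankdata(dv)
    n = d.n
    iu, ju = np.triu_indices(n, k=1)
    M = len(ranks)
    denom = M / 2.0

    def r_stat(lab):
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(glab)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        if r_stat(glab[rng.permutation(n)]) >= observed:
            count_ge += 1
    p = (count_ge + 1) / (n_perm + 1)
    return AnosimResult(float(observed), float(p), n_perm, seed)


def _stress1(disp: np.ndarray, dist: np.ndarray) -> float:
    return float(np.sqrt(np.sum((disp - dist) ** 2) / np.sum(dist ** 2)))


def _isotonic(x: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: nondecreasing fit minimizing squared error."""
    n = len(x)
    level = x.astype(float).copy()
    weight = np.ones(n)
    # blocks as linked list via arrays
    vals: list[float] = []
    wts: list[float] = []
    sizes: list[int] = []
    for v in level:
        vals.append(v)
        wts.append(1.0)
        sizes.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, s2 = vals.pop(), wts.pop(), sizes.pop()
            vals[-1] = (vals[-1] * wts[-1] + v2 * w2) / (wts[-1] + w2)
            wts[-1] += w2
            sizes[-1] += s2
    out = np.empty(n)
    pos = 0
    for v, s in zip(vals, sizes):
        out[pos:pos + s] = v
        pos += s
    return out


def nmds(d: DissimilarityMatrix, k: int = 2, n_starts: int = 100, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-6) -> NmdsResult:
    """Nonmetric MDS by monotone-acceptance SMACOF.

    Each random start alternates (a) isotonic regression of configuration
    distances on the dissimilarity order (disparities) and (b) a Guttman
    transform holding disparities fixed; a step that does not lower Kruskal
    stress-1 terminates the start.  The lowest-stress start wins.
    """
    n = d.n
    if not 1 <= k < n - 1:
        raise ValueError("need 1 <= k < n - 1")
    dv = d.condensed()
    order = np.argsort(dv, kind="mergesort")
    inv_order = np.argsort(order)
    iu, ju = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)

    best_stress = np.inf
    best_conf = None
    best_start = -1
    any_converged = False
    histories: list[np.ndarray] = []

    for s in range(n_starts):
        X = rng.normal(size=(n, k))
        dist = pdist(X)
        disp = _isotonic(dist[order])[inv_order]
        stress = _stress1(disp, dist)
        traj = [stress]
        converged = False
        for _ in range(max_iter):
            # Guttman transform with fixed disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, disp / dist, 0.0)
            B = squareform(-ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X_new = (B @ X) / n
            dist_new = pdist(X_new)
            disp_new = _isotonic(dist_new[order])[inv_order]
            stress_new = _stress1(disp_new, dist_new)
            if stress_new >= stress - 1e-15:
                converged = stress - stress_new < tol or np.isclose(stress_new, stress)
                break
            X, dist, disp, stress = X_new, dist_new, disp_new, stress_new
            traj.append(stress)
            if traj[-2] - traj[-1] < tol:
                converged = True
                break
        histories.append(np.array(traj))
        any_converged = any_converged or converged
        if stress < best_stress:
            best_stress, best_conf, best_start = stress, X, s

    # center the winning configuration (rotation/reflection left free)
    best_conf = best_conf - best_conf.mean(axis=0)
    return NmdsResult(best_conf, best_stress, best_start, n_starts,
                      any_converged, histories)
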