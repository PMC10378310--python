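"""Secondary feature selection (SFS): redundancy removal within F*.

Phase 1 votes features into F* but does not remove redundant ones (e.g.
degree and PageRank are strongly collinear on scale-free graphs).  Phase 2:

1. Pearson-correlate all pairs of F* features (|r| measures redundancy).
2. Agglomerate F* into two clusters, repeatedly merging the cluster pair
   with the largest cross-pair |r| (single linkage on distance 1 − |r|).
3. Weight features by ReliefF, a filter that scores how well a feature
   separates each instance from its nearest misses versus nearest hits.
4. Per cluster, keep the highest-ReliefF "main" feature; if the cluster has
   more than γ = floor(|F*|/2) members, also keep a "supplementary" feature
   — the member least correlated with the main one.  F** is the union.

With |F*| ≤ 2 the two-cluster/γ machinery is vacuous and F** = F*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import TABLE_ORDER, canonical_sort
from .selection_initial import (LabeledDataset, RfeTrace, VoteResult,
                                run_initial_selection)

__all__ = ["FeatureClustering", "FinalSubset", "SelectionConfig", "SelectionResult",
           "pearson_matrix", "cluster_features", "relieff_weights", "select_final",
           "secondary_selection", "two_phase_select"]


@dataclass
class FeatureClustering:
    """Partition of features with the greedy merge history."""

    clusters: list[list[str]]
    merges: list[tuple[list[str], list[str], float]] = field(default_factory=list)
    degenerate: bool = False  # fewer features than requested clusters


@dataclass
class FinalSubset:
    mains: list[str]
    supplementaries: list[str]
    gamma: int
    f_double_star: list[str]


@dataclass
class SelectionConfig:
    """Tunables of the two-phase selection (FFS-SFS).

    ``k`` balanced replicates are voted with threshold ``epsilon`` in phase
    1; ``folds`` and ``C`` parameterise the SVM-RFE-CV wrapper; phase 2 uses
    ``relieff_k`` nearest hits/misses and ``n_clusters`` feature clusters.
    """

    k: int = 10
    epsilon: float = 0.5
    folds: int = 10
    C: float = 1.0
    relieff_k: int = 10
    n_clusters: int = 2
    with_replacement: bool = False


@dataclass
class SelectionResult:
    """F* and F** with every intermediate object retained for inspection."""

    f_star: list[str]
    f_double_star: list[str]
    vote: VoteResult
    traces: list[RfeTrace]
    corr: pd.DataFrame | None = None
    clustering: FeatureClustering | None = None
    relieff: pd.Series | None = None
    final: FinalSubset | None = None


def pearson_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of feature columns (unit diagonal)."""
    if len(X) < 2:
        raise ValueError("need at least two rows")
    arr = X.to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        const = [c for c, s in zip(X.columns, arr.std(axis=0)) if s == 0]
        raise ValueError(f"constant feature(s) {const}: correlation undefined")
    r = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=X.columns, columns=X.columns)


def cluster_features(corr: pd.DataFrame, n_clusters: int = 2) -> FeatureClustering:
    """Greedy agglomeration on |r|: merge the pair of clusters whose closest
    cross-cluster feature pair has the largest |r|, until ``n_clusters``
    remain.  Ties resolve to the pair seen first in canonical column order,
    making the result deterministic.
    """
    names = list(corr.columns)
    if len(names) < n_clusters:
        return FeatureClustering(clusters=[[f] for f in names], degenerate=True)
    absr = corr.abs().to_numpy()
    clusters: list[list[int]] = [[i] for i in range(len(names))]
    merges: list[tuple[list[str], list[str], float]] = []
    while len(clusters) > n_clusters:
        best_sim, best_pair = -np.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                sim = max(absr[i, j] for i in clusters[a] for j in clusters[b])
                if sim > best_sim:
                    best_sim, best_pair = sim, (a, b)
        a, b = best_pair
        merges.append(([names[i] for i in clusters[a]],
                       [names[i] for i in clusters[b]], float(best_sim)))
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
    clusters.sort(key=lambda c: c[0])
    return FeatureClustering(clusters=[[names[i] for i in c] for c in clusters],
                             merges=merges)


def relieff_weights(
    data: LabeledDataset,
    features: list[str] | None = None,
    k_neighbors: int = 10,
    standardize: bool = True,
) -> pd.Series:
    """ReliefF weights on standardised features.

    For every instance the k nearest hits (same class) and k nearest misses
    (other class, weighted by class prior) are found by Euclidean distance;
    each feature's weight accumulates mean |difference| to misses minus mean
    |difference| to hits, averaged over instances.  Discriminative features
    get positive weights, noise stays near zero.  k is reduced per class when
    a class has fewer than k other members.
    """
    feats = list(features) if features is not None else data.feature_names
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    X = data.X[feats].to_numpy(dtype=float)
    y = data.y
    if standardize:
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - X.mean(axis=0)) / std
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    priors = {c: cnt / y.size for c, cnt in zip(classes, counts)}
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    n = y.size
    W = np.zeros(len(feats))
    # pairwise distances; n is at most a few thousand nodes here
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    for i in range(n):
        ci = y[i]
        for c in classes:
            pool = idx_by_class[c]
            pool = pool[pool != i]
            if pool.size == 0:
                continue
            kk = min(k_neighbors, pool.size)
            nearest = pool[np.argsort(d2[i, pool], kind="stable")[:kk]]
            diff = np.abs(X[nearest] - X[i]).mean(axis=0)
            if c == ci:
                W -= diff / n
            else:
                W += (priors[c] / (1.0 - priors[ci])) * diff / n
    return pd.Series(W, index=feats)


def select_final(
    clustering: FeatureClustering,
    weights: pd.Series,
    corr: pd.DataFrame,
    f_star: list[str],
    frequencies: dict[str, float] | None = None,
) -> FinalSubset:
    """Pick main (and possibly supplementary) features per cluster.

    γ = floor(|F*|/2).  Main = maximal ReliefF weight (ties: higher phase-1
    vote frequency, then canonical order).  A cluster strictly larger than γ
    also contributes the member with minimal |r| to its main feature (ties:
    canonical order).
    """
    gamma = len(f_star) // 2
    freq = frequencies or {}
    order = {f: i for i, f in enumerate(TABLE_ORDER)}

    mains, supps = [], []
    for cluster in clustering.clusters:
        if not cluster:
            raise RuntimeError("empty feature cluster")
        main = min(cluster, key=lambda f: (-weights[f], -freq.get(f, 0.0),
                                           order.get(f, len(order)), f))
        mains.append(main)
        if len(cluster) > gamma:
            rest = [f for f in cluster if f != main]
            if rest:
                supp = min(rest, key=lambda f: (abs(corr.loc[main, f]),
                                                order.get(f, len(order)), f))
                supps.append(supp)
    return FinalSubset(mains=mains, supplementaries=supps, gamma=gamma,
                       f_double_star=canonical_sort(set(mains) | set(supps)))


def secondary_selection(
    data: LabeledDataset,
    f_star: list[str],
    cfg: SelectionConfig | None = None,
    frequencies: dict[str, float] | None = None,
) -> tuple[FinalSubset, pd.DataFrame, FeatureClustering, pd.Series]:
    """Phase 2 on a given candidate set (normally F*, or the full set in the
    no-phase-1 ablation): correlate → cluster → ReliefF → pick."""
    cfg = cfg or SelectionConfig()
    corr = pearson_matrix(data.X[list(f_star)])
    clustering = cluster_features(corr, n_clusters=cfg.n_clusters)
    weights = relieff_weights(data, features=list(f_star), k_neighbors=cfg.relieff_k)
    final = select_final(clustering, weights, corr, list(f_star), frequencies)
    return final, corr, clustering, weights


def two_phase_select(
    data: LabeledDataset,
    cfg: SelectionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """The full two-phase selection: FFS (vote into F*) then SFS (F** ⊆ F*).

    When phase 1 leaves at most two features, clustering into two groups is
    vacuous and F** = F*.
    """
    cfg = cfg or SelectionConfig()
    rng = rng or np.random.default_rng()
    vote, traces = run_initial_selection(
        data, k=cfg.k, epsilon=cfg.epsilon, folds=cfg.folds, C=cfg.C, rng=rng,
        with_replacement=cfg.with_replacement,
    )
    f_star = vote.f_star
    if len(f_star) <= 2:
        return SelectionResult(f_star=f_star, f_double_star=list(f_star),
                               vote=vote, traces=traces)
    final, corr, clustering, weights = secondary_selection(
        data, f_star, cfg, frequencies=vote.frequencies)
    return SelectionResult(f_star=f_star, f_double_star=final.f_double_star,
                           vote=vote, traces=traces, corr=corr,
                           clustering=clustering, relieff=weights, final=final)
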