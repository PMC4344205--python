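"""Relief feature weighting and the two clinical/gene integration schemes.

Relief scores each feature by contrasting, for sampled patients, the nearest
neighbour of the same class (the *hit*) with the nearest neighbour of the
other class (the *miss*): a feature that differs between close same-class
patients is penalised, one that differs between close opposite-class
patients is rewarded.  Being neighbourhood-based, it credits features whose
value matters only in context (interactions), which single-feature filters
miss.

All features are categorical here (clinical levels plus discretized
expression), so the per-feature difference is the 0/1 indicator and the
distance between patients is the Hamming distance.  ``relief_rank`` is the
sampled algorithm (m random draws with replacement); ``relief_rank_exhaustive``
is its deterministic counterpart that visits every patient once and serves
as an independent oracle — the sampled weights are unbiased for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReliefWeights",
    "RankedFeatures",
    "diff",
    "relief_rank",
    "relief_rank_exhaustive",
    "method1_select",
    "method2_select",
]


class ReliefError(ValueError):
    pass


def diff(feature_value_a, feature_value_b) -> int:
    """0 if the two items share the feature's value, 1 otherwise."""
    return 0 if feature_value_a == feature_value_b else 1


@dataclass(frozen=True)
class ReliefWeights:
    """Per-feature weights W[F] in [-1, 1] plus the sampling settings used."""

    weights: pd.Series
    m: int
    seed: int | None

    def ranked(self) -> "RankedFeatures":
        w = self.weights
        order = sorted(range(len(w)), key=lambda j: (-w.iloc[j], j))
        return RankedFeatures(features=[w.index[j] for j in order], weights=w)


@dataclass(frozen=True)
class RankedFeatures:
    """Features ordered by descending weight; ties keep column order."""

    features: list[str]
    weights: pd.Series

    def top(self, k: int) -> list[str]:
        if k > len(self.features):
            raise ReliefError(f"k={k} exceeds the {len(self.features)} available features")
        return self.features[:k]


def _encode(items: pd.DataFrame) -> np.ndarray:
    """Integer-code a categorical table; missing values are not allowed."""
    if items.isna().any().any():
        raise ReliefError("Relief requires complete data; impute first")
    cols = []
    for c in items.columns:
        s = items[c]
        if isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(s.cat.codes.to_numpy())
        else:
            cols.append(pd.factorize(s, use_na_sentinel=False)[0])
    return np.column_stack(cols).astype(np.int16)


def _binary_target(target) -> np.ndarray:
    t = np.asarray(target)
    classes = pd.unique(pd.Series(t))
    if len(classes) != 2:
        raise ReliefError(
            "Relief assumes the target variable is binary; got "
            f"{len(classes)} class(es): {list(classes)!r}"
        )
    y = t == classes[0]
    if (y.sum() < 2) or ((~y).sum() < 2):
        raise ReliefError("each target class needs at least 2 items for nearest-hit search")
    return y


def _nearest_hit_miss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per item, the index of the nearest hit and nearest miss.

    Hamming distance over all features; the item itself is excluded; ties
    resolve to the lowest patient index (argmin's first minimum).
    """
    n = X.shape[0]
    hits = np.empty(n, dtype=np.int64)
    misses = np.empty(n, dtype=np.int64)
    big = np.iinfo(np.int32).max
    chunk = max(1, int(2e7) // max(1, n * X.shape[1]))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d = (X[start:stop, None, :] != X[None, :, :]).sum(axis=2).astype(np.int32)
        for i in range(start, stop):
            row = d[i - start]
            same = y == y[i]
            dh = np.where(same, row, big)
            dh[i] = big
            hits[i] = int(np.argmin(dh))
            dm = np.where(same, big, row)
            misses[i] = int(np.argmin(dm))
    return hits, misses


def _weights_from_updates(X, hits, misses, picks, m) -> np.ndarray:
    hit_diff = (X[picks] != X[hits[picks]]).astype(np.float64)
    miss_diff = (X[picks] != X[misses[picks]]).astype(np.float64)
    return (miss_diff.sum(axis=0) - hit_diff.sum(axis=0)) / m


def relief_rank(
    items: pd.DataFrame, target, m: int | None = None, seed: int = 0
) -> ReliefWeights:
    """Sampled Relief: m random items (with replacement) drive the update

        W[F] <- W[F] - Diff(F, D, H)/m + Diff(F, D, M)/m

    where H and M are D's nearest hit and miss.  ``m`` defaults to the
    number of items.  Weights are bounded in [-1, 1] by construction.
    """
    X = _encode(items)
    y = _binary_target(target)
    n = X.shape[0]
    m = n if m is None else int(m)
    if m < 1:
        raise ReliefError("m must be >= 1")
    hits, misses = _nearest_hit_miss(X, y)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n, size=m)
    w = _weights_from_updates(X, hits, misses, picks, m)
    return ReliefWeights(weights=pd.Series(w, index=items.columns), m=m, seed=seed)


def relief_rank_exhaustive(items: pd.DataFrame, target) -> ReliefWeights:
    """Deterministic Relief sweep: every item once, update divided by n."""
    X = _encode(items)
    y = _binary_target(target)
    n = X.shape[0]
    hits, misses = _nearest_hit_miss(X, y)
    w = _weights_from_updates(X, hits, misses, np.arange(n), n)
    return ReliefWeights(weights=pd.Series(w, index=items.columns), m=n, seed=None)


def method1_select(
    features: pd.DataFrame, target, k: int, m: int | None = None, seed: int = 0
) -> list[str]:
    """Rank the pooled clinical + gene table and keep the top k features."""
    if k > features.shape[1]:
        raise ReliefError(f"k={k} exceeds the {features.shape[1]} available features")
    return relief_rank(features, target, m=m, seed=seed).ranked().top(k)


def method2_select(
    genes: pd.DataFrame,
    target,
    k_total: int,
    clinical_names: list[str],
    m: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Rank genes only; keep the top ``k_total - n_clinical`` genes and add
    every clinical feature, so the selected set still has ``k_total`` features."""
    n_clin = len(clinical_names)
    if k_total <= n_clin:
        raise ReliefError(f"k_total={k_total} must exceed the {n_clin} clinical features")
    k_genes = k_total - n_clin
    if k_genes > genes.shape[1]:
        raise ReliefError(f"need {k_genes} genes but only {genes.shape[1]} available")
    top_genes = relief_rank(genes, target, m=m, seed=seed).ranked().top(k_genes)
    return list(clinical_names) + top_genes
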