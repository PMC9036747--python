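"""Cohort-level statistics over trait tables.

Covers the four analyses run on a phenotyped cohort:

* agreement between manually measured and computed traits (R², MAE,
  MAPE);
* per-trait differences between the positive (adaxial) and back
  (abaxial) photographs of the same leaf;
* decision-tree feature importance, to rank colour features by how well
  they separate classes (e.g. positive vs back);
* PCA compression of each feature set to its top 10 components, followed
  by hierarchical (Ward, Euclidean) clustering of the leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.tree import DecisionTreeClassifier

FEATURE_SET_NAMES = ("GEO", "VEN", "CLR", "COM")


@dataclass
class AgreementStats:
    """How well computed values fit manual measurements of one trait."""

    r2: float | None   # coefficient of determination, <= 1
    mae: float         # mean absolute error
    mape: float | None  # mean absolute percentage error, %
    n: int


def agreement_stats(manual: Sequence[float],
                    computed: Sequence[float]) -> AgreementStats:
    """R², MAE and MAPE of computed values against manual measurements.

    R² = 1 - SS_res/SS_tot with the manual values as reference; it is
    undefined (None) when the manual values have zero variance.  MAPE is
    undefined when any manual value is zero.
    """
    m = np.asarray(manual, dtype=float)
    c = np.asarray(computed, dtype=float)
    if m.shape != c.shape or m.ndim != 1:
        raise ValueError("manual and computed must be equal-length vectors")
    if m.size < 2:
        raise ValueError("need at least two paired values")
    resid = c - m
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else None
    mae = float(np.mean(np.abs(resid)))
    mape = (float(np.mean(np.abs(resid / m))) * 100.0
            if not np.any(m == 0) else None)
    return AgreementStats(r2=r2, mae=mae, mape=mape, n=m.size)


def positive_back_difference(pos: Mapping[str, float],
                             back: Mapping[str, float]
                             ) -> dict[str, float | None]:
    """Signed per-trait difference between positive and back leaves, %.

    PB_X = 100 * (X_pos - X_back) / X_pos, so a trait larger on the back
    face comes out negative.  Undefined (None) when the positive value is
    zero or either value is missing.
    """
    out: dict[str, float | None] = {}
    for key in pos:
        if key not in back:
            continue
        p, b = pos[key], back[key]
        if p is None or b is None or p == 0:
            out[key] = None
        else:
            out[key] = 100.0 * (p - b) / p
    return out


def tree_feature_importance(features: pd.DataFrame,
                            labels: Sequence,
                            seed: int = 0) -> pd.Series:
    """Impurity-based importances of a single CART decision tree, percent.

    One classification tree (Gini impurity, unlimited depth) is fit on
    the full table; the returned importances sum to 100 over the nonzero
    entries.  Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")
    tree = DecisionTreeClassifier(criterion="gini", random_state=seed)
    tree.fit(features.to_numpy(), y)
    imp = pd.Series(tree.feature_importances_ * 100.0,
                    index=features.columns)
    return imp.sort_values(ascending=False)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # rows = leaves, columns = PC1..PCk
    explained_variance: np.ndarray  # fractions, non-increasing
    loadings: pd.DataFrame          # columns x PCs
    dropped: list[str]              # constant columns removed


def pca_top10(features: pd.DataFrame, n_components: int = 10,
              prefix: str = "PC") -> PCAResult:
    """Top principal components of a z-scored feature table.

    Columns are standardized before the decomposition (the trait groups
    mix incommensurable units); constant columns are dropped with a
    warning.  Returns scores, explained-variance fractions and loadings.
    """
    X = features.astype(float)
    std = X.std(axis=0, ddof=0)
    dropped = list(X.columns[std == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant column(s) before "
                      "PCA", stacklevel=2)
        X = X.drop(columns=dropped)
        std = std.drop(dropped)
    Z = (X - X.mean(axis=0)) / std
    k = min(n_components, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    cols = [f"{prefix}{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=features.index, columns=cols),
        explained_variance=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=Z.columns,
                              columns=cols),
        dropped=dropped,
    )


def hierarchical_cluster(scores: pd.DataFrame, k: int = 4,
                         linkage: str = "ward") -> np.ndarray:
    """Agglomerative clustering of PC scores, dendrogram cut at k groups.

    Euclidean distance throughout; linkage defaults to Ward and may be
    any of single/complete/average/ward.  Returns integer labels 0..k-1
    in input row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = scores.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of samples")
    if k == X.shape[0]:
        return np.arange(X.shape[0])
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1


def feature_sets(traits: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a trait table into the GEO / VEN / CLR / COM feature sets."""
    from .traits import GEO_TRAITS, VEN_TRAITS, color_trait_names

    geo = [c for c in GEO_TRAITS if c in traits.columns]
    ven = [c for c in VEN_TRAITS if c in traits.columns]
    clr = [c for c in color_trait_names() if c in traits.columns]
    return {"GEO": traits[geo], "VEN": traits[ven], "CLR": traits[clr],
            "COM": traits[geo + ven + clr]}


def pc_correlation(score_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Correlation matrix across the PCs of several feature sets.

    Columns are renamed `<SET>_PC<i>`; with four sets of 10 PCs this is
    the 40x40 matrix.
    """
    parts = []
    for name, t in score_tables.items():
        renamed = t.rename(columns=lambda c: f"{name}_{c}")
        parts.append(renamed.reset_index(drop=True))
    return pd.concat(parts, axis=1).corr()


def cluster_feature_sets(traits: pd.DataFrame, k: int = 4,
                         linkage: str = "ward",
                         n_components: int = 10) -> dict[str, dict]:
    """PCA + hierarchical clustering for every feature set.

    Returns, per feature set, the PCA result, the cluster labels and the
    per-cluster trait means/stds.
    """
    out = {}
    for name, table in feature_sets(traits).items():
        pca = pca_top10(table, n_components=n_components)
        labels = hierarchical_cluster(pca.scores, k=k, linkage=linkage)
        stats = table.groupby(labels).agg(["mean", "std"])
        out[name] = {"pca": pca, "labels": labels, "cluster_stats": stats}
    return out
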