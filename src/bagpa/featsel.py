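"""Data-driven feature selection for brain-age prediction.

Four stages, all fitted inside cross-validation folds:

1. tree-importance screening — gradient-boosted trees rank all IDPs by
   gain-based importance averaged over folds; the top k (default 50) go on;
2. supervised-distance redundancy pruning — d(i, j) = 1 - |rho| of the
   out-of-fold single-feature predictions of age, complete-linkage
   hierarchical clustering cut at a threshold (default 0.75), keeping the
   most important member of each cluster;
3. permutation re-ranking — mean increase in held-out MAE when a feature
   column is permuted;
4. sequential forward selection down the permutation ranking, retaining a
   candidate only when the cross-validated MAE strictly improves, up to a
   feature cap (default 20).

The supervised distance is target-aware: two features that carry the same
information about the prediction task are close even if their raw values
differ in scale or shape.  A raw-correlation variant is available for
sensitivity analysis (``method="raw"``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.tree import DecisionTreeRegressor

from bagpa.brainage import _make_model, DEFAULT_PARAMS

__all__ = [
    "FeatureSelectionReport",
    "rank_tree_importance",
    "supervised_distance",
    "prune_redundant",
    "permutation_rerank",
    "sequential_forward_select",
    "run_feature_selection",
]


def rank_tree_importance(
    table: pd.DataFrame,
    features,
    target: str = "age",
    k: int = 50,
    cv_folds: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Top-``k`` features by gain importance averaged across CV folds."""
    features = list(features)
    if k > len(features):
        raise ValueError(f"k={k} exceeds the {len(features)} available features")
    X = table[features]
    y = table[target].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    total = np.zeros(len(features))
    for tr, _ in kf.split(X):
        model = _make_model(dict(DEFAULT_PARAMS), seed)
        model.fit(X.iloc[tr], y[tr])
        total += model.booster_.feature_importance(importance_type="gain")
    scores = pd.Series(total / cv_folds, index=features)
    # ties broken by column order for determinism
    scores = scores.iloc[np.lexsort((np.arange(len(scores)), -scores.to_numpy()))]
    return scores.iloc[:k]


def supervised_distance(
    table: pd.DataFrame,
    features,
    target: str = "age",
    cv_folds: int = 5,
    seed: int = 0,
    method: str = "supervised",
) -> pd.DataFrame:
    """Pairwise redundancy distances d = 1 - |rho| over a feature subset.

    ``method="supervised"`` (default) correlates out-of-fold predictions of
    the target from shallow single-feature trees (Spearman rho);
    ``method="raw"`` correlates the raw feature columns instead.
    Constant single-feature predictions give undefined correlation; such a
    feature is placed at distance 1 from all others with a warning.
    """
    features = list(features)
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    y = table[target].to_numpy(dtype=float)
    if method == "raw":
        mat = table[features].to_numpy(dtype=float)
    elif method == "supervised":
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cols = []
        for f in features:
            tree = DecisionTreeRegressor(max_depth=4, random_state=seed)
            cols.append(cross_val_predict(tree, table[[f]], y, cv=kf))
        mat = np.column_stack(cols)
    else:
        raise ValueError(f"unknown method: {method!r}")

    col_const = table[features].std(ddof=0).to_numpy() == 0
    constant = (mat.std(axis=0) == 0) | col_const
    if constant.any():
        warnings.warn(
            f"constant single-feature predictions for {list(np.array(features)[constant])}; "
            "distance set to 1 against all other features"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(mat).statistic
    if np.isscalar(rho) or np.ndim(rho) == 0:  # spearmanr collapses for 2 columns
        r = float(rho) if np.isfinite(rho) else 0.0
        rho = np.array([[1.0, r], [r, 1.0]])
    d = 1.0 - np.abs(rho)
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(d, index=features, columns=features)


@dataclass
class PruneResult:
    pruned: list[str]  # cluster representatives, ordered by importance
    clusters: pd.Series  # feature -> cluster label
    linkage: np.ndarray


def prune_redundant(distances: pd.DataFrame, ranking: pd.Series, threshold: float = 0.75) -> PruneResult:
    """Cut the complete-linkage dendrogram at ``threshold`` and keep the
    highest-importance member of each cluster."""
    feats = list(distances.index)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    condensed = squareform(distances.to_numpy(), checks=False)
    Z = linkage(condensed, method="complete")
    labels = fcluster(Z, t=threshold, criterion="distance")
    clusters = pd.Series(labels, index=feats)
    reps = []
    for lab in np.unique(labels):
        members = clusters.index[clusters == lab]
        reps.append(ranking.loc[members].idxmax())
    reps.sort(key=lambda f: -ranking.loc[f])
    return PruneResult(pruned=reps, clusters=clusters, linkage=Z)


def permutation_rerank(
    table: pd.DataFrame,
    features,
    target: str = "age",
    cv_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Features re-ranked by mean increase in held-out MAE under permutation."""
    features = list(features)
    X = table[features]
    y = table[target].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(features))
    for tr, te in kf.split(X):
        model = _make_model(dict(DEFAULT_PARAMS), seed)
        model.fit(X.iloc[tr].to_numpy(dtype=float), y[tr])
        Xte = X.iloc[te].to_numpy(dtype=float)
        base_mae = np.mean(np.abs(model.predict(Xte) - y[te]))
        for j in range(len(features)):
            inc = 0.0
            for _ in range(n_repeats):
                Xp = Xte.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                inc += np.mean(np.abs(model.predict(Xp) - y[te])) - base_mae
            scores[j] += inc / n_repeats
    scores /= cv_folds
    s = pd.Series(scores, index=features)
    return s.iloc[np.lexsort((np.arange(len(s)), -s.to_numpy()))]


def _cv_mae(table, features, y, cv_folds, seed) -> float:
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    preds = np.empty(len(table))
    for tr, te in kf.split(table):
        model = _make_model(dict(DEFAULT_PARAMS), seed)
        model.fit(table[features].iloc[tr], y[tr])
        preds[te] = model.predict(table[features].iloc[te])
    return float(np.mean(np.abs(preds - y)))


def sequential_forward_select(
    table: pd.DataFrame,
    ranking,
    target: str = "age",
    cv_folds: int = 5,
    max_features: int = 20,
    eps: float = 0.0,
    seed: int = 0,
):
    """Greedy forward selection down ``ranking``.

    Starting from the top-ranked feature, each candidate is retained only
    if it strictly decreases the cross-validated MAE (by more than
    ``eps``).  Every trial is recorded.  Returns ``(forward_path,
    final_set)`` where the path is a DataFrame with one row per trial.
    """
    order = list(ranking.index) if isinstance(ranking, pd.Series) else list(ranking)
    if not order:
        raise ValueError("ranking must be non-empty")
    y = table[target].to_numpy(dtype=float)

    selected = [order[0]]
    best = _cv_mae(table, selected, y, cv_folds, seed)
    path = [{"feature": order[0], "cv_mae": best, "retained": True}]
    for cand in order[1:]:
        if len(selected) >= max_features:
            break
        mae = _cv_mae(table, selected + [cand], y, cv_folds, seed)
        keep = mae < best - eps
        path.append({"feature": cand, "cv_mae": mae, "retained": keep})
        if keep:
            selected.append(cand)
            best = mae
    return pd.DataFrame(path), selected


@dataclass
class FeatureSelectionReport:
    importance_ranking: pd.Series
    top_k: list[str]
    distance_matrix: pd.DataFrame
    clusters_at_threshold: pd.Series
    linkage: np.ndarray
    pruned_set: list[str]
    permutation_ranking: pd.Series
    forward_path: pd.DataFrame
    final_set: list[str]
    threshold: float
    seed: int

    def dendrogram_newick(self) -> str:
        """The complete-linkage dendrogram over the top-k features, as a
        Newick string with merge heights as branch lengths."""
        from scipy.cluster.hierarchy import to_tree

        labels = list(self.distance_matrix.index)
        root = to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"

    def to_json(self, path) -> None:
        payload = {
            "importance_ranking": self.importance_ranking.to_dict(),
            "top_k": self.top_k,
            "distance_matrix": self.distance_matrix.to_dict(),
            "clusters_at_threshold": {k: int(v) for k, v in self.clusters_at_threshold.items()},
            "pruned_set": self.pruned_set,
            "permutation_ranking": self.permutation_ranking.to_dict(),
            "forward_path": self.forward_path.to_dict(orient="records"),
            "final_set": self.final_set,
            "threshold": self.threshold,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def run_feature_selection(
    table: pd.DataFrame,
    features,
    target: str = "age",
    top_k: int = 50,
    threshold: float = 0.75,
    max_features: int = 20,
    cv_folds: int = 10,
    distance_cv_folds: int = 5,
    sfs_cv_folds: int = 5,
    n_repeats: int = 5,
    distance_method: str = "supervised",
    seed: int = 0,
) -> FeatureSelectionReport:
    """The full two-step selection pipeline; a pure function of its inputs."""
    importance = rank_tree_importance(table, features, target=target, k=top_k, cv_folds=cv_folds, seed=seed)
    top = list(importance.index)
    dist = supervised_distance(
        table, top, target=target, cv_folds=distance_cv_folds, seed=seed, method=distance_method
    )
    prune = prune_redundant(dist, importance, threshold=threshold)
    perm = permutation_rerank(
        table, prune.pruned, target=target, cv_folds=sfs_cv_folds, n_repeats=n_repeats, seed=seed
    )
    path, final = sequential_forward_select(
        table, perm, target=target, cv_folds=sfs_cv_folds, max_features=max_features, seed=seed
    )
    return FeatureSelectionReport(
        importance_ranking=importance,
        top_k=top,
        distance_matrix=dist,
        clusters_at_threshold=prune.clusters,
        linkage=prune.linkage,
        pruned_set=prune.pruned,
        permutation_ranking=perm,
        forward_path=path,
        final_set=final,
        threshold=threshold,
        seed=seed,
    )
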