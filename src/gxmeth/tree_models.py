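"""Regression-tree and random-forest variable importance.

Both learners are variance-reduction CART models (scikit-learn's
``DecisionTreeRegressor`` / ``RandomForestRegressor``); what this module adds
is the importance bookkeeping used to rank genetic predictors:

* importance = per-feature summed impurity (variance) reduction, reported
  raw and max-normalized (best predictor = 1.0);
* for a tree fit with a training/validation/test partition, out-of-partition
  importances are recomputed by routing the held-out samples through the
  fitted tree and crediting each split with the variance reduction it
  achieves on those samples (normalized by the training maximum, so held-out
  scores of noise features shrink toward 0);
* ranks are dense 1..P by descending score, ties broken by predictor name.

The forest's default predictor set on generator output is Pre, age, sex, the
five causal SNPs and their CpGs, and the 100 background SNPs (113 columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor


@dataclass
class ImportanceResult:
    table: pd.DataFrame  # predictor, score, rank, partition
    model: object
    raw: pd.Series  # unnormalized training importances


def _rank(scores: pd.Series) -> pd.Series:
    order = sorted(scores.index, key=lambda name: (-scores[name], name))
    return pd.Series({name: i + 1 for i, name in enumerate(order)}, name="rank")


def _table(scores: pd.Series, partition: str, norm: float) -> pd.DataFrame:
    normed = scores / norm if norm > 0 else scores * 0.0
    normed = normed.clip(lower=0.0)
    out = pd.DataFrame(
        {"predictor": scores.index, "score": normed.to_numpy(), "partition": partition}
    )
    out["rank"] = _rank(normed).loc[scores.index].to_numpy()
    return out


def _routed_importances(tree: DecisionTreeRegressor, X: np.ndarray, y: np.ndarray, n_features: int):
    """Per-feature squared-error reduction on held-out samples.

    Routes the samples through the fitted tree and credits each split with
    the drop in held-out SSE when predicting with the children's *training*
    means instead of the node's training mean, scaled by 1/N. Overfit splits
    earn negative credit on held-out data, so noise features shrink to ~0.
    """
    t = tree.tree_
    imp = np.zeros(n_features)
    n_total = len(y)
    if n_total == 0:
        return imp
    value = t.value.reshape(-1)  # training mean per node
    stack = [(0, np.arange(n_total))]
    while stack:
        node, idx = stack.pop()
        if t.children_left[node] == -1 or len(idx) == 0:
            continue
        left_node, right_node = t.children_left[node], t.children_right[node]
        mask = X[idx, t.feature[node]] <= t.threshold[node]
        left, right = idx[mask], idx[~mask]
        sse_node = float(np.sum((y[idx] - value[node]) ** 2))
        sse_children = float(np.sum((y[left] - value[left_node]) ** 2)) + float(
            np.sum((y[right] - value[right_node]) ** 2)
        )
        imp[t.feature[node]] += (sse_node - sse_children) / n_total
        stack.append((left_node, left))
        stack.append((right_node, right))
    return imp


def fit_regression_tree(
    features: pd.DataFrame,
    response,
    min_leaf: int = 10,
    partition: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> ImportanceResult:
    """Variance-reduction tree with a minimum leaf size.

    With ``partition=(train, validation, test)`` fractions the individuals
    are split (seeded), the tree is trained on the training part and
    importances are reported per partition; otherwise a single "full" table
    is returned. A constant response yields a single-leaf tree with all
    importances zero.
    """
    if min_leaf < 2:
        raise ValueError("min_leaf must be >= 2")
    X = features.to_numpy(float)
    y = np.asarray(response, float)
    names = list(features.columns)

    if partition is None:
        idx = {"full": np.arange(len(y))}
        train_key = "full"
    else:
        fracs = np.asarray(partition, float)
        if fracs.min() <= 0 or not np.isclose(fracs.sum(), 1.0):
            raise ValueError("partition fractions must be positive and sum to 1")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(y))
        n_train = int(round(fracs[0] * len(y)))
        n_val = int(round(fracs[1] * len(y)))
        idx = {
            "training": perm[:n_train],
            "validation": perm[n_train : n_train + n_val],
            "test": perm[n_train + n_val :],
        }
        train_key = "training"

    model = DecisionTreeRegressor(min_samples_leaf=min_leaf, random_state=seed)
    model.fit(X[idx[train_key]], y[idx[train_key]])
    raw_train = pd.Series(
        model.tree_.compute_feature_importances(normalize=False), index=names
    )
    norm = float(raw_train.max())

    tables = [_table(raw_train, train_key, norm)]
    for key, rows in idx.items():
        if key == train_key:
            continue
        raw = pd.Series(_routed_importances(model, X[rows], y[rows], len(names)), index=names)
        tables.append(_table(raw, key, norm))
    return ImportanceResult(table=pd.concat(tables, ignore_index=True), model=model, raw=raw_train)


def fit_random_forest(
    features: pd.DataFrame,
    response,
    n_trees: int = 500,
    seed: int = 0,
    max_features: float | None = 1.0 / 3.0,
    bootstrap: bool = True,
    min_leaf: int = 1,
) -> ImportanceResult:
    """Bootstrap-aggregated regression trees with per-split feature subsampling.

    Importance is the across-tree mean of raw (unnormalized) impurity
    reduction, then max-normalized for reporting. ``n_trees=1`` with
    ``bootstrap=False`` and ``max_features=None`` degenerates to the single
    CART tree.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = features.to_numpy(float)
    y = np.asarray(response, float)
    names = list(features.columns)
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features if max_features is not None else 1.0,
        bootstrap=bootstrap,
        min_samples_leaf=min_leaf,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    raw = pd.Series(
        np.mean(
            [t.tree_.compute_feature_importances(normalize=False) for t in model.estimators_],
            axis=0,
        ),
        index=names,
    )
    return ImportanceResult(table=_table(raw, "full", float(raw.max())), model=model, raw=raw)


def forest_features(study, replicate, traits) -> tuple[pd.DataFrame, pd.Series]:
    """Default forest predictor frame on generator output.

    Columns: pre, age, sex (0/1 male), the causal SNP dosages and their
    visit-4 CpG beta-values, and all background SNP dosages — 113 predictors
    under the default study. Response is Post.
    """
    ped = study.pedigree
    snp_map = study.snp_map
    causal = snp_map[snp_map["role"] == "main_causal"].sort_index()
    background = snp_map[snp_map["role"] == "background"].sort_index()
    causal_cpgs = study.cpg_map[study.cpg_map["role"] == "main_causal"].sort_values("paired_snp")
    frame = pd.concat(
        [
            traits.pre.rename("pre"),
            pd.Series(ped["age"].to_numpy(float), index=traits.pre.index, name="age"),
            pd.Series((ped["sex"].to_numpy() == 1).astype(float), index=traits.pre.index, name="sex"),
            replicate.genotypes.dosages[causal.index].astype(float),
            replicate.methylation.beta_visit4[causal_cpgs.index],
            replicate.genotypes.dosages[background.index].astype(float),
        ],
        axis=1,
    )
    return frame, traits.post


def summarize_forest_ranks(per_replicate_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean, SD and median of each predictor's rank across replicates."""
    if len(per_replicate_tables) < 2:
        raise ValueError("need at least two replicate tables")
    base = set(per_replicate_tables[0]["predictor"])
    for t in per_replicate_tables[1:]:
        if set(t["predictor"]) != base:
            raise ValueError("replicate tables have mismatched predictor sets")
    ranks = pd.concat(
        [t.set_index("predictor")["rank"] for t in per_replicate_tables], axis=1
    )
    return pd.DataFrame(
        {
            "mean_rank": ranks.mean(axis=1),
            "sd_rank": ranks.std(axis=1, ddof=1),
            "median_rank": ranks.median(axis=1),
        }
    ).sort_values("mean_rank")
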