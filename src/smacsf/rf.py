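"""Repeated Random-Forest classification and strict consensus feature
selection.

The procedure: restrict to baseline (T0) samples, split them into stratified
train/test partitions, z-scale features using training statistics only, fit
a Random Forest of depth-limited trees (Gini impurity, at most 3 terminal
nodes per tree), record test accuracy and the top-k proteins by mean
decrease in Gini importance, and repeat over a fixed seed sequence.  The
consensus biomarker set is the strict intersection of every repeat's top-k
list; a per-protein frequency table reports near-misses.

Two forest engines are provided with identical model semantics (bootstrap
aggregation of best-first Gini trees, ``max_leaf_nodes`` terminal-node cap,
sqrt-p features per split): ``"fast"`` drives scikit-learn's tree builder
directly and is roughly an order of magnitude faster for the many small
forests this procedure fits; ``"sklearn"`` is the stock
:class:`~sklearn.ensemble.RandomForestClassifier`.  A cross-check between
the two is part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import IntensityMatrix
from .preprocess import apply_scaler, fit_scaler
from .stats import bh_adjust

__all__ = [
    "RFConfig",
    "RepeatResult",
    "ConsensusResult",
    "stratified_partition",
    "train_and_score",
    "run_consensus",
    "correlate_with_age",
]

_MAX_INT = np.iinfo(np.int32).max


@dataclass
class RFConfig:
    """Hyperparameters of the repeated-forest procedure.

    Defaults follow the study conditions: 1000 trees, at most 3 terminal
    nodes per tree, 80/20 stratified partitions, 100 repeats seeded 1..100,
    top-30 importance lists, sqrt-p features per split.
    """

    n_trees: int = 1000
    max_nodes: int = 3
    train_fraction: float = 0.8
    seeds: tuple[int, ...] = tuple(range(1, 101))
    top_k: int = 30
    features_per_split: int | str = "sqrt"
    engine: str = "fast"
    consensus_min_fraction: float = 1.0  # 1.0 = strict intersection

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_trees < 1 or self.max_nodes < 2 or self.top_k < 1:
            raise ValueError("n_trees >= 1, max_nodes >= 2, top_k >= 1 required")
        if len(self.seeds) == 0:
            raise ValueError("at least one repeat seed required")
        if self.engine not in ("fast", "sklearn"):
            raise ValueError("engine must be 'fast' or 'sklearn'")
        if not 0 < self.consensus_min_fraction <= 1:
            raise ValueError("consensus_min_fraction must lie in (0, 1]")

    @property
    def n_repeats(self) -> int:
        return len(self.seeds)


@dataclass
class RepeatResult:
    seed: int
    train_ids: list[str]
    test_ids: list[str]
    accuracy: float
    importances: pd.Series = field(repr=False)
    top_k_ids: list[str] = field(repr=False)


@dataclass
class ConsensusResult:
    repeats: list[RepeatResult]
    consensus_ids: list[str]
    frequency: pd.Series  # protein -> number of repeats with top-k membership

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.repeats])

    @property
    def modal_accuracy(self) -> float:
        vals, counts = np.unique(np.round(self.accuracies, 12), return_counts=True)
        return float(vals[np.argmax(counts)])


def stratified_partition(
    meta: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Split T0 samples into train/test preserving subtype proportions.

    Per subtype the train count is ``round(train_fraction * group size)``,
    clipped so that at least one sample lands on each side.  Deterministic
    for a given seed; sample IDs are processed in sorted order so the split
    does not depend on metadata row order.
    """
    t0 = meta[meta["timepoint"] == "T0"]
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for subtype in sorted(t0["subtype"].unique()):
        ids = sorted(t0.loc[t0["subtype"] == subtype, "sample_id"])
        if len(ids) < 2:
            raise ValueError(f"subtype {subtype} has fewer than 2 baseline samples")
        n_train = int(np.round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# forest engines


def _resolve_mtry(features_per_split, p: int) -> int:
    if features_per_split == "sqrt":
        return max(1, int(np.sqrt(p)))
    m = int(features_per_split)
    if not 1 <= m <= p:
        raise ValueError("features_per_split out of range")
    return m


def _fit_forest_fast(X, y, n_classes, cfg: RFConfig, seed: int):
    """Bagged best-first Gini trees via scikit-learn's tree builder.

    Returns (importances, predict) where importances are mean per-tree
    normalized Gini importance (renormalized over trees with signal) and
    predict() soft-votes class probabilities exactly as the stock forest.
    """
    from sklearn.tree._criterion import Gini
    from sklearn.tree._splitter import BestSplitter
    from sklearn.tree._tree import BestFirstTreeBuilder, Tree

    n, p = X.shape
    mtry = _resolve_mtry(cfg.features_per_split, p)
    Xf = np.asfortranarray(X, dtype=np.float32)
    y2 = np.ascontiguousarray(y, dtype=np.float64).reshape(-1, 1)
    classes = np.array([n_classes], dtype=np.intp)
    rs = np.random.RandomState(seed)
    splitter = BestSplitter(Gini(1, classes), mtry, 1, 0.0, rs, None)
    builder = BestFirstTreeBuilder(splitter, 2, 1, 0.0, _MAX_INT, cfg.max_nodes, 0.0)
    trees = []
    imp_sum = np.zeros(p)
    n_informative_trees = 0
    for _ in range(cfg.n_trees):
        tree = Tree(p, classes, 1)
        boot = rs.randint(0, n, n)
        weight = np.bincount(boot, minlength=n).astype(np.float64)
        builder.build(tree, Xf, y2, weight, None)
        imp = tree.compute_feature_importances(normalize=False)
        total = imp.sum()
        if total > 0:
            imp_sum += imp / total
            n_informative_trees += 1
        trees.append(tree)
    importances = imp_sum / max(n_informative_trees, 1)

    def predict(X_new: np.ndarray) -> np.ndarray:
        Xn = np.ascontiguousarray(X_new, dtype=np.float32)
        proba = np.zeros((len(Xn), n_classes))
        for tree in trees:
            leaf_value = tree.predict(Xn)
            if leaf_value.ndim == 3:
                leaf_value = leaf_value[:, 0, :]
            proba += leaf_value / leaf_value.sum(axis=1, keepdims=True)
        return proba.argmax(axis=1)

    return importances, predict


def _fit_forest_sklearn(X, y, n_classes, cfg: RFConfig, seed: int):
    from sklearn.ensemble import RandomForestClassifier

    mtry = _resolve_mtry(cfg.features_per_split, X.shape[1])
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_leaf_nodes=cfg.max_nodes,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf.feature_importances_, rf.predict


def train_and_score(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    train_ids: list[str],
    test_ids: list[str],
    cfg: RFConfig,
    seed: int,
) -> RepeatResult:
    """Fit one forest on a train partition and score the held-out test set.

    Feature scaling is fitted on the train partition only (no test-set
    statistic enters the model).  The top-k list sorts by importance
    descending with protein-ID ascending as the tie-break, so row order of
    the input matrix is irrelevant.
    """
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test partitions overlap")
    labels = meta.set_index("sample_id")["subtype"]
    y_train = labels.loc[train_ids]
    if y_train.nunique() < 2:
        raise ValueError("training partition contains a single class")
    class_names = sorted(labels.loc[train_ids + test_ids].unique())
    code = {c: i for i, c in enumerate(class_names)}

    # canonical protein order: the fit must not depend on input row order
    matrix = IntensityMatrix(matrix.values.sort_index())
    scaler = fit_scaler(matrix.subset_samples(train_ids))
    train = apply_scaler(scaler, matrix.subset_samples(train_ids))
    test = apply_scaler(scaler, matrix.subset_samples(test_ids))
    X_train = train.values.to_numpy().T
    X_test = test.values.to_numpy().T
    y_tr = np.array([code[c] for c in y_train])
    y_te = np.array([code[c] for c in labels.loc[test_ids]])

    fit = _fit_forest_fast if cfg.engine == "fast" else _fit_forest_sklearn
    importances, predict = fit(X_train, y_tr, len(class_names), cfg, seed)
    accuracy = float(np.mean(predict(X_test) == y_te))

    imp = pd.Series(importances, index=train.protein_ids, name="importance")
    order = sorted(imp.index, key=lambda pid: (-imp[pid], pid))
    return RepeatResult(
        seed=seed,
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        accuracy=accuracy,
        importances=imp,
        top_k_ids=order[: cfg.top_k],
    )


def run_consensus(matrix: IntensityMatrix, meta: pd.DataFrame, cfg: RFConfig) -> ConsensusResult:
    """Run the full repeated-forest procedure on baseline samples.

    The consensus set is the strict intersection of all top-k lists
    (``consensus_min_fraction`` < 1 relaxes this to a membership-frequency
    threshold, which is *not* the strict rule and is off by default).
    """
    t0_meta = meta[meta["timepoint"] == "T0"]
    t0 = matrix.subset_samples(t0_meta["sample_id"])
    if t0.values.isna().any().any():
        # pipeline order: min-imputation precedes any model fitting
        from .preprocess import impute_min

        t0 = impute_min(t0)
    repeats = []
    for seed in cfg.seeds:
        train_ids, test_ids = stratified_partition(t0_meta, cfg.train_fraction, seed)
        repeats.append(train_and_score(t0, t0_meta, train_ids, test_ids, cfg, seed))
    counts = pd.Series(0, index=sorted(t0.protein_ids), dtype=int)
    for r in repeats:
        counts.loc[r.top_k_ids] += 1
    need = int(np.ceil(cfg.consensus_min_fraction * cfg.n_repeats))
    consensus = sorted(counts.index[counts >= need])
    frequency = counts[counts > 0].sort_values(ascending=False)
    return ConsensusResult(repeats=repeats, consensus_ids=consensus, frequency=frequency)


def correlate_with_age(
    matrix: IntensityMatrix, meta: pd.DataFrame, protein_ids: list[str]
) -> pd.DataFrame:
    """Spearman correlation of baseline abundance with age for a protein set,
    BH-adjusted across the set.  Constant proteins yield NaN rho."""
    t0_meta = meta[meta["timepoint"] == "T0"].set_index("sample_id")
    t0 = matrix.subset_samples(t0_meta.index)
    rows = []
    for pid in protein_ids:
        x = t0.values.loc[pid]
        ok = x.notna()
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 observations for {pid}")
        if x[ok].nunique() == 1:
            rows.append({"protein_id": pid, "rho": np.nan, "p": np.nan})
            continue
        rho, p = sps.spearmanr(x[ok], t0_meta.loc[ok[ok].index, "age_years"])
        rows.append({"protein_id": pid, "rho": float(rho), "p": float(p)})
    table = pd.DataFrame(rows).set_index("protein_id")
    ok = table["p"].notna()
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table
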