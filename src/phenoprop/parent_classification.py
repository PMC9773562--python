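"""Parental-accession classification: PCA contributions, descriptor
weighting, and random-forest classification with OOB error, importances and
a held-out confusion matrix.

The forest follows R randomForest semantics: 100 trees by default, each
grown on a bootstrap sample of a stratified 70% training partition with
mtry = floor(sqrt(p)) candidate descriptors per split; the OOB error is
computed from out-of-bag votes on the training partition, the mean decrease
in accuracy (MDA) from per-tree OOB permutation, the Gini decrease on the
raw impurity-sum scale, and the confusion matrix on the held-out 30%.
Vote ties are broken toward the alphabetically lowest class label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "PcaSummary",
    "ForestReport",
    "fit_pca",
    "descriptor_weights",
    "retained_pcs",
    "train_forest",
    "select_features",
]


@dataclass
class PcaSummary:
    """PCA of the (internally z-scored) parental descriptor table.

    ``contributions`` holds the percent contribution of each descriptor to
    each PC (100 * squared loading / column sum of squared loadings), the
    quantity used downstream for descriptor weighting.
    """

    loadings: pd.DataFrame  # descriptor x PC (unit-norm eigenvectors)
    explained_variance_ratio: pd.Series  # per PC
    contributions: pd.DataFrame  # descriptor x PC, percent

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(table: pd.DataFrame) -> PcaSummary:
    """PCA on a descriptor table (typically the parents only).

    Descriptors are centered and scaled to unit variance internally before
    decomposition. Rank-deficient input limits the number of PCs to the
    data rank with a warning.
    """
    feats = table[[c for c in table.columns if c not in ("unit_id", "class_label")]]
    x = feats.to_numpy(dtype=float)
    n, p = x.shape
    if p < 2 or n < 3:
        raise ValueError("need at least 2 descriptors and 3 units for PCA")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(feats.columns, sd) if s == 0]
        raise ValueError(f"constant descriptor(s) cannot be unit-scaled: {bad}")
    z = (x - x.mean(axis=0)) / sd
    k_max = min(n - 1, p)
    rank = np.linalg.matrix_rank(z)
    if rank < k_max:
        warnings.warn(
            f"rank-deficient input: retaining {rank} of {k_max} possible PCs",
            RuntimeWarning,
            stacklevel=2,
        )
    pca = PCA(n_components=min(rank, k_max)).fit(z)
    pcs = [f"PC{i + 1}" for i in range(pca.n_components_)]
    load = pd.DataFrame(pca.components_.T, index=feats.columns, columns=pcs)
    sq = load**2
    contrib = 100.0 * sq / sq.sum(axis=0)
    evr = pd.Series(pca.explained_variance_ratio_, index=pcs)
    return PcaSummary(loadings=load, explained_variance_ratio=evr, contributions=contrib)


def retained_pcs(summary: PcaSummary, cum_variance: float = 0.80) -> int:
    """Smallest number of leading PCs reaching ``cum_variance`` cumulative
    explained variance (the default retention rule)."""
    cum = summary.explained_variance_ratio.cumsum()
    return int(np.searchsorted(cum.to_numpy(), cum_variance - 1e-12) + 1)


def descriptor_weights(summary: PcaSummary, retained: int | None = None) -> pd.Series:
    """One weight per descriptor from the retained PCs' contributions.

    weight_j  ∝  sum_{k <= retained} contribution[j, k] * EVR[k],
    renormalized to sum to 1. With a single retained PC the weights are
    proportional to its squared loadings.
    """
    if retained is None:
        retained = retained_pcs(summary)
    if not 1 <= retained <= summary.n_components:
        raise ValueError(
            f"retained must be in [1, {summary.n_components}], got {retained}"
        )
    pcs = summary.contributions.columns[:retained]
    w = (summary.contributions[pcs] * summary.explained_variance_ratio[pcs]).sum(axis=1)
    return w / w.sum()


def apply_weights(scaled: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """Multiply standardized descriptor columns by their weights."""
    out = scaled.copy()
    for col, w in weights.items():
        out[col] = out[col] * w
    return out


@dataclass
class ForestReport:
    """Everything the classification stage reports for one component."""

    n_trees: int
    split: tuple[float, float]  # (train_fraction, valid_fraction)
    oob_error: float  # percent
    importance_mda: pd.Series  # mean decrease in OOB accuracy, per descriptor
    importance_gini: pd.Series  # raw-scale mean decrease in node impurity
    confusion: pd.DataFrame  # rows = truth, columns = prediction (counts)
    seed: int | None
    classes: tuple[str, ...]
    valid_index: np.ndarray  # row positions of the held-out 30%
    valid_pred: np.ndarray  # predicted labels for the held-out rows


class _Forest:
    """Bagged classification trees with explicit bootstrap bookkeeping."""

    def __init__(self, n_trees: int, rng: np.random.Generator):
        self.n_trees = n_trees
        self.rng = rng
        self.trees: list[DecisionTreeClassifier] = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, x: np.ndarray, y_codes: np.ndarray, n_classes: int) -> "_Forest":
        n = x.shape[0]
        for _ in range(self.n_trees):
            idx = self.rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=int(self.rng.integers(0, 2**31 - 1)),
            ).fit(x[idx], y_codes[idx])
            self.trees.append(tree)
            self.oob_masks.append(oob)
        self.n_classes = n_classes
        return self

    def votes(self, x: np.ndarray) -> np.ndarray:
        v = np.zeros((x.shape[0], self.n_classes), dtype=np.int64)
        rows = np.arange(x.shape[0])
        for tree in self.trees:
            v[rows, tree.predict(x).astype(int)] += 1
        return v

    def predict_codes(self, x: np.ndarray) -> np.ndarray:
        # argmax takes the first maximum: with classes sorted alphabetically
        # this is the required lowest-label tie-break
        return self.votes(x).argmax(axis=1)

    def oob_votes(self, x: np.ndarray) -> np.ndarray:
        v = np.zeros((x.shape[0], self.n_classes), dtype=np.int64)
        for tree, oob in zip(self.trees, self.oob_masks):
            if oob.any():
                v[np.flatnonzero(oob), tree.predict(x[oob]).astype(int)] += 1
        return v


def train_forest(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_trees: int = 100,
    train_fraction: float = 0.7,
    seed: int | None = None,
    compute_importance: bool = True,
) -> ForestReport:
    """Stratified 70/30 split, bagged-tree fit and full evaluation report.

    The OOB error is computed from out-of-bag votes on the training
    partition; MDA permutes each descriptor within each tree's OOB rows;
    Gini importance is the mean over trees of the total (sample-count
    weighted) impurity decrease; the confusion matrix tabulates the
    held-out 30% (rows = truth, columns = prediction).
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels).astype(str)
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 units, got {counts.to_dict()}")
    code_of = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code_of[c] for c in y])

    rng = np.random.default_rng(seed)
    split_seed = int(rng.integers(0, 2**31 - 1))
    idx_all = np.arange(len(y))
    idx_tr, idx_va = train_test_split(
        idx_all,
        train_size=train_fraction,
        stratify=y_codes,
        random_state=split_seed,
    )
    x_tr, y_tr = x[idx_tr], y_codes[idx_tr]
    forest = _Forest(n_trees, rng).fit(x_tr, y_tr, len(classes))

    oob_v = forest.oob_votes(x_tr)
    seen = oob_v.sum(axis=1) > 0
    oob_pred = oob_v.argmax(axis=1)
    oob_error = 100.0 * float(np.mean(oob_pred[seen] != y_tr[seen]))

    cols = list(features.columns)
    if compute_importance:
        mda = np.zeros(len(cols))
        gini = np.zeros(len(cols))
        for tree, oob in zip(forest.trees, forest.oob_masks):
            gini += tree.tree_.compute_feature_importances(normalize=False) * len(idx_tr)
            if not oob.any():
                continue
            xo, yo = x_tr[oob], y_tr[oob]
            base_acc = float(np.mean(tree.predict(xo) == yo))
            for j in range(len(cols)):
                xp = xo.copy()
                xp[:, j] = rng.permutation(xp[:, j])
                mda[j] += base_acc - float(np.mean(tree.predict(xp) == yo))
        mda /= n_trees
        gini /= n_trees
        importance_mda = pd.Series(mda, index=cols, name="mda")
        importance_gini = pd.Series(gini, index=cols, name="gini")
    else:
        importance_mda = pd.Series(np.nan, index=cols, name="mda")
        importance_gini = pd.Series(np.nan, index=cols, name="gini")

    pred_va = forest.predict_codes(x[idx_va])
    confusion = pd.DataFrame(
        0, index=list(classes), columns=list(classes), dtype=int
    )
    for t_code, p_code in zip(y_codes[idx_va], pred_va):
        confusion.iloc[t_code, p_code] += 1

    return ForestReport(
        n_trees=n_trees,
        split=(train_fraction, 1.0 - train_fraction),
        oob_error=oob_error,
        importance_mda=importance_mda,
        importance_gini=importance_gini,
        confusion=confusion,
        seed=seed,
        classes=classes,
        valid_index=idx_va,
        valid_pred=np.array([classes[c] for c in pred_va]),
    )


def select_features(
    report: ForestReport, gini_min: float = 0.0, mda_min: float = 0.0
) -> list[str]:
    """Descriptors whose Gini decrease and MDA both meet their thresholds,
    ordered by MDA descending; falls back to the top 5 by MDA (with a
    warning) when nothing qualifies."""
    if gini_min < 0 or mda_min < 0:
        raise ValueError("thresholds must be nonnegative")
    ok = (report.importance_gini >= gini_min) & (report.importance_mda >= mda_min)
    chosen = report.importance_mda[ok].sort_values(ascending=False)
    if chosen.empty:
        warnings.warn(
            "no descriptor met both importance thresholds; "
            "falling back to the top 5 by mean decrease in accuracy",
            RuntimeWarning,
            stacklevel=2,
        )
        chosen = report.importance_mda.sort_values(ascending=False).head(5)
    return list(chosen.index)
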