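"""Predicting the direction of age-related expression change from the
early-life epigenome.

Per-gene feature vectors combine mean gene-body and promoter methylation
in young and old animals, gene size, baseline (young) expression, and the
breadth of coverage of each histone-mark peak track over the gene body
(summed peak width within the gene divided by gene length; peaks are
merged per mark first, so breadth lies in [0, 1]).

The labelled table (up- vs down-regulated genes only) is summarized by a
PCA on standardized features and classified with a random forest on a
stratified 70/30 train/validation split.  Feature importance is reported
both as mean decrease in accuracy — per-tree permutation of the feature
within each tree's out-of-bag samples, averaged over trees, the classic
forest estimator, which stays informative when features are strongly
correlated (a whole-forest permutation on a held-out set zeroes out
redundant features because the rest of the forest covers for them) — and
as the forest's total impurity decrease (mean decrease Gini).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlap_width

METHYLATION_FEATURES = (
    "meth_body_young", "meth_body_old", "meth_prom_young", "meth_prom_old",
)


def breadth_of_coverage(genes: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Per-gene breadth: total width of the mark's peaks overlapping the
    gene body, divided by gene length.  Peaks are merged first, so the
    value is bounded by 1."""
    bodies = pd.DataFrame(
        {"chrom": genes["chrom"], "start": genes["start"], "end": genes["end"]}
    ).reset_index(drop=True)
    widths = overlap_width(bodies, merge_intervals(peaks))
    lengths = (genes["end"] - genes["start"]).to_numpy()
    return pd.Series(widths / lengths, index=genes.index)


def build_feature_table(
    body_summary: pd.DataFrame,
    promoter_summary: pd.DataFrame,
    deg_table: pd.DataFrame,
    genes: pd.DataFrame,
    peak_tracks: dict[str, pd.DataFrame],
    base_expression: pd.Series,
    young_group: str = "young",
    old_group: str = "old",
) -> pd.DataFrame:
    """One feature vector per labelled (up/down) gene.

    ``body_summary``/``promoter_summary`` are region-methylation frames
    with ``m_<group>`` columns; genes missing methylation for either
    region are dropped.  Returns a frame with a ``label`` column plus the
    feature columns.
    """
    labelled = deg_table[deg_table["direction"].isin(["up", "down"])]
    if labelled.empty:
        raise ValueError("no labelled (up/down) genes to build features for")
    table = pd.DataFrame(index=labelled.index)
    table["label"] = labelled["direction"]
    table["meth_body_young"] = body_summary[f"m_{young_group}"]
    table["meth_body_old"] = body_summary[f"m_{old_group}"]
    table["meth_prom_young"] = promoter_summary[f"m_{young_group}"]
    table["meth_prom_old"] = promoter_summary[f"m_{old_group}"]
    table["gene_size"] = (genes["end"] - genes["start"]).reindex(table.index)
    table["base_expression"] = base_expression.reindex(table.index)
    for mark, peaks in peak_tracks.items():
        breadth = breadth_of_coverage(genes, peaks)
        table[f"breadth_{mark}"] = breadth.reindex(table.index)
    before = len(table)
    table = table.dropna()
    table.attrs["n_dropped_missing"] = before - len(table)
    if table.empty:
        raise ValueError("every labelled gene lacked a methylation or feature value")
    return table


@dataclass
class PCASummary:
    scores: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray
    feature_correlations: pd.DataFrame  # components x features
    dropped_features: list[str] = field(default_factory=list)


def pca_summary(table: pd.DataFrame, n_components: int = 2) -> PCASummary:
    """PCA of the standardized feature matrix via SVD.

    Reports per-component variance fractions and the Pearson correlation
    of each component's scores with each original feature.  Component
    signs are fixed deterministically: PC1 correlates positively with
    young gene-body methylation when that feature is present; every other
    component has its largest-magnitude feature correlation positive.
    """
    features = [c for c in table.columns if c != "label"]
    X = table[features].to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 3 genes and >= 2 features")
    std = X.std(axis=0, ddof=1)
    dropped = [f for f, s in zip(features, std) if s == 0]
    if dropped:
        warnings.warn(f"dropping constant features before PCA: {dropped}")
        features = [f for f in features if f not in dropped]
        X = table[features].to_numpy(dtype=float)
        std = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / std
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n_components = min(n_components, len(S))
    scores = U[:, :n_components] * S[:n_components]
    var_frac = (S**2 / (S**2).sum())[:n_components]

    corr = np.zeros((n_components, len(features)))
    for i in range(n_components):
        s = scores[:, i]
        s_c = s - s.mean()
        denom = np.sqrt((s_c**2).sum() * (Z**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr[i] = (Z * s_c[:, None]).sum(axis=0) / denom
    # deterministic sign convention
    for i in range(n_components):
        if i == 0 and "meth_body_young" in features:
            anchor = features.index("meth_body_young")
        else:
            anchor = int(np.argmax(np.abs(corr[i])))
        if corr[i, anchor] < 0:
            corr[i] *= -1
            scores[:, i] *= -1
    return PCASummary(
        pd.DataFrame(scores, index=table.index,
                     columns=[f"PC{i + 1}" for i in range(n_components)]),
        var_frac,
        pd.DataFrame(corr, index=[f"PC{i + 1}" for i in range(n_components)],
                     columns=features),
        dropped,
    )


@dataclass
class RFReport:
    accuracy: float
    auc: float
    importance: pd.DataFrame  # feature x (mean_decrease_accuracy, gini_importance)
    seed: int
    train_genes: list[str]
    validation_genes: list[str]
    features: list[str]


def _oob_indices(tree, n_samples: int) -> np.ndarray:
    from sklearn.ensemble import _forest

    try:
        return _forest._generate_unsampled_indices(tree.random_state, n_samples,
                                                   n_samples, None)
    except TypeError:  # older signature without sample_weight
        return _forest._generate_unsampled_indices(tree.random_state, n_samples,
                                                   n_samples)


def oob_permutation_importance(clf, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Mean decrease in accuracy: per tree, permute one feature within the
    tree's out-of-bag samples and record the accuracy drop; average over
    trees."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    drops = np.zeros((len(clf.estimators_), X.shape[1]))
    for t, tree in enumerate(clf.estimators_):
        oob = _oob_indices(tree, n)
        if len(oob) == 0:
            continue
        X_oob = X[oob]
        baseline = (tree.predict(X_oob) == y[oob]).mean()
        for j in range(X.shape[1]):
            permuted = X_oob.copy()
            permuted[:, j] = rng.permutation(permuted[:, j])
            drops[t, j] = baseline - (tree.predict(permuted) == y[oob]).mean()
    return drops.mean(axis=0)


def train_evaluate_rf(
    table: pd.DataFrame,
    train_frac: float = 0.70,
    n_trees: int = 500,
    seed: int = 0,
    feature_subset: list[str] | None = None,
) -> RFReport:
    """Train and evaluate the direction-of-change random forest.

    Stratified ``train_frac`` split; ``feature_subset`` restricts the model
    (e.g. to the methylation + baseline-expression reduced model).  The
    report carries validation accuracy, ROC AUC of the up-class
    probability, and both importance measures.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split

    features = [c for c in table.columns if c != "label"]
    if feature_subset is not None:
        missing = [f for f in feature_subset if f not in features]
        if missing:
            raise ValueError(f"unknown features requested: {missing}")
        features = list(feature_subset)
    labels = table["label"]
    counts = labels.value_counts()
    if set(counts.index) != {"up", "down"}:
        raise ValueError("both up and down labels are required")
    if (counts < 2).any():
        raise ValueError("need >= 2 genes per label for a stratified split")

    X = table[features].to_numpy(dtype=float)
    y = (labels == "up").to_numpy(dtype=int)
    idx_train, idx_val = train_test_split(
        np.arange(len(y)), train_size=train_frac, stratify=y, random_state=seed
    )
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        random_state=seed, n_jobs=1,
    )
    clf.fit(X[idx_train], y[idx_train])
    proba = clf.predict_proba(X[idx_val])[:, 1]
    pred = (proba >= 0.5).astype(int)
    accuracy = float((pred == y[idx_val]).mean())
    auc = float(roc_auc_score(y[idx_val], proba))
    mda = oob_permutation_importance(clf, X[idx_train], y[idx_train], seed)
    importance = pd.DataFrame(
        {
            "mean_decrease_accuracy": mda,
            "gini_importance": clf.feature_importances_,
        },
        index=features,
    )
    return RFReport(
        accuracy=accuracy,
        auc=auc,
        importance=importance,
        seed=seed,
        train_genes=list(table.index[idx_train]),
        validation_genes=list(table.index[idx_val]),
        features=features,
    )
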