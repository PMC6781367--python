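"""Age-related differential expression from raw counts.

Stages:

1. median-of-ratios size factors (reference = per-gene geometric mean over
   samples, genes containing any zero excluded from the reference) and a
   variance-stabilizing stand-in transform ``log2(count / s_j + 1)``;
2. a per-gene ordinary least-squares fit of the transformed value on age +
   sex; genes with an age main effect p < screen_alpha proceed to per-sex
   young-vs-old pairwise contrasts (Conover-Iman rank comparison by
   default, Welch t optionally);
3. BH adjustment of the contrast p-values within each sex, and a DEG call
   at q < alpha together with a fold-change cutoff |FC| > fc_min computed
   on normalized (not transformed) group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import _conover_matrix, bh_adjust, welch_t_matrix
from .types import CountsMatrix

SEXES = ("male", "female")


def estimate_size_factors(counts: CountsMatrix) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Median-of-ratios normalization.

    Returns ``(size_factors, normalized, transformed)`` where ``normalized``
    is counts divided by the per-sample factor and ``transformed`` is
    ``log2(normalized + 1)``.
    """
    matrix = counts.counts.to_numpy(dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("size-factor estimation needs >= 2 samples")
    all_nonzero = (matrix > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider a pseudocount"
        )
    reference = np.exp(np.log(matrix[all_nonzero]).mean(axis=1))
    ratios = matrix[all_nonzero] / reference[:, None]
    factors = np.median(ratios, axis=0)
    size_factors = pd.Series(factors, index=counts.counts.columns, name="size_factor")
    normalized = counts.counts / factors
    transformed = np.log2(normalized + 1.0)
    return size_factors, normalized, transformed


def fit_age_sex_model(transformed: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene OLS of transformed expression on age + sex.

    Returns a frame indexed by gene with the age-effect estimate, its
    two-sided p-value, and a ``constant`` flag for zero-variance genes
    (skipped, reported non-significant).
    """
    samples = list(transformed.columns)
    meta = meta.loc[samples]
    if meta["age"].nunique() < 2 or meta["sex"].nunique() < 2:
        raise ValueError("the design needs both ages and both sexes")
    cell_counts = meta.groupby(["age", "sex"]).size()
    if (cell_counts < 2).any():
        raise ValueError("every age x sex cell needs >= 2 samples")
    age = (meta["age"] == "old").to_numpy(dtype=float)
    sex = (meta["sex"] == "male").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(age), age, sex])
    Y = transformed.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / dof
    se_age = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    constant = transformed.std(axis=1).to_numpy() == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t_age = beta[1] / se_age
    p_age = 2.0 * sps.t.sf(np.abs(t_age), df=dof)
    p_age = np.where(constant | ~np.isfinite(t_age), np.nan, p_age)
    return pd.DataFrame(
        {
            "beta_age": beta[1],
            "p_age": p_age,
            "constant": constant,
        },
        index=transformed.index,
    )


def _sex_contrast(
    transformed: pd.DataFrame, meta: pd.DataFrame, sex: str, method: str
) -> pd.Series:
    in_sex = meta.index[meta["sex"] == sex]
    sub = meta.loc[in_sex]
    young = [s for s in in_sex if sub.loc[s, "age"] == "young"]
    old = [s for s in in_sex if sub.loc[s, "age"] == "old"]
    x = transformed[old].to_numpy()
    y = transformed[young].to_numpy()
    if method == "conover":
        _, p = _conover_matrix(x, y)
    elif method == "ttest":
        _, p = welch_t_matrix(x, y)
    else:
        raise ValueError(f"unknown contrast method {method!r}")
    return pd.Series(p, index=transformed.index)


def _sex_fold_change(
    normalized: pd.DataFrame, meta: pd.DataFrame, sex: str
) -> tuple[pd.Series, pd.Series]:
    in_sex = meta.index[meta["sex"] == sex]
    sub = meta.loc[in_sex]
    young = [s for s in in_sex if sub.loc[s, "age"] == "young"]
    old = [s for s in in_sex if sub.loc[s, "age"] == "old"]
    mean_young = normalized[young].mean(axis=1)
    mean_old = normalized[old].mean(axis=1)
    # 0.5 pseudocount only where a group mean is zero, preserving direction
    needs_pc = (mean_young == 0) | (mean_old == 0)
    fc = (mean_old + 0.5 * needs_pc) / (mean_young + 0.5 * needs_pc)
    return fc, np.log2(fc)


@dataclass
class DEGTables:
    """Per-sex DEG tables plus the cross-sex overlap summary."""

    size_factors: pd.Series
    stats: pd.DataFrame  # age+sex model fit per gene
    per_sex: dict[str, pd.DataFrame]
    overlap: pd.DataFrame
    chi2_p: float
    alpha: float
    fc_min: float


def call_degs(
    counts: CountsMatrix,
    alpha: float = 0.05,
    fc_min: float = 1.25,
    screen_alpha: float = 0.05,
    contrast_method: str = "conover",
) -> DEGTables:
    """Full differential-expression pass: normalize, screen on the age main
    effect, per-sex contrasts, BH within sex, and the FC cutoff."""
    size_factors, normalized, transformed = estimate_size_factors(counts)
    model = fit_age_sex_model(transformed, counts.meta)
    screened = (model["p_age"] < screen_alpha) & ~model["constant"]

    per_sex: dict[str, pd.DataFrame] = {}
    for sex in SEXES:
        p_contrast = _sex_contrast(transformed, counts.meta, sex, contrast_method)
        p_masked = p_contrast.where(screened, np.nan)
        q = bh_adjust(p_masked.to_numpy())
        fc, log2fc = _sex_fold_change(normalized, counts.meta, sex)
        table = pd.DataFrame(
            {
                "gene_id": counts.counts.index,
                "p_age": model["p_age"],
                "p_contrast": p_contrast.where(screened, np.nan),
                "q": q,
                "fc": fc,
                "log2fc": log2fc,
            },
            index=counts.counts.index,
        )
        significant = (table["q"] < alpha) & (
            (table["fc"] > fc_min) | (table["fc"] < 1.0 / fc_min)
        )
        table["direction"] = "ns"
        table.loc[significant & (table["fc"] > 1), "direction"] = "up"
        table.loc[significant & (table["fc"] < 1), "direction"] = "down"
        table.loc[model["constant"], "direction"] = "ns"
        table["reason"] = np.where(model["constant"], "constant", "")
        per_sex[sex] = table

    overlap, chi2_p = deg_overlap(per_sex["male"], per_sex["female"])
    return DEGTables(size_factors, model, per_sex, overlap, chi2_p, alpha, fc_min)


def deg_overlap(male: pd.DataFrame, female: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Cross-sex overlap of DEG calls: shared up/down counts and a 2x2
    chi-square test of independence (no continuity correction) on the
    direction membership of genes DEG in both sexes."""
    m_dir = male.loc[male["direction"] != "ns", "direction"]
    f_dir = female.loc[female["direction"] != "ns", "direction"]
    shared = m_dir.index.intersection(f_dir.index)
    table = np.zeros((2, 2), dtype=int)
    for gene in shared:
        i = 0 if m_dir.loc[gene] == "up" else 1
        j = 0 if f_dir.loc[gene] == "up" else 1
        table[i, j] += 1
    summary = pd.DataFrame(
        {
            "n_male": [int((m_dir == "up").sum()), int((m_dir == "down").sum())],
            "n_female": [int((f_dir == "up").sum()), int((f_dir == "down").sum())],
            "n_shared_same_direction": [int(table[0, 0]), int(table[1, 1])],
        },
        index=["up", "down"],
    )
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return summary, float("nan")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return summary, float(p)
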