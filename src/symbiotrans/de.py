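"""Free-living vs symbiosis differential expression.

Counts are scaled by median-of-ratios size factors, quantile-normalized so
all sample distributions match, per-gene negative-binomial dispersions are
estimated by method of moments pooled across conditions, and a Wald test on
log2 condition-mean fold changes (delta-method standard errors) yields
p-values that are Benjamini-Hochberg adjusted. Genes are then classified as
up / down / neutral / condition-exclusive / not expressed using the study's
thresholds: |log2FC| >= 2, adjusted p < 0.05, and a replicate-sum of
normalized counts > 10 to call a gene expressed in a condition.

The model is NB with variance mu + alpha * mu^2. The Wald statistic uses
log2 fold change of pseudocounted condition means with
Var(log mean_c) ~ (1/mu_c + alpha) / n_c by the delta method; no fold-change
shrinkage is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("symbiotrans")

DISPERSION_FLOOR = 1e-8


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the same distribution (mean of sorted columns).

    Each column's values are replaced by the row means of the column-sorted
    matrix at their rank; ties within a column receive the mean of their tied
    target values. Idempotent on tie-free input (tie averaging feeds back
    into the target, so a second pass can shift tie-free columns slightly
    when other columns contain ties).
    """
    if m.shape[1] == 0 or m.shape[0] == 0:
        raise ValueError("empty matrix")
    x = m.to_numpy(dtype=float)
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        col_sorted = x[order, j]
        assigned = target.copy()
        # runs of tied values share the mean of their target slots
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        for start, stop in zip(
            np.concatenate(([0], boundaries)),
            np.concatenate((boundaries, [len(col_sorted)])),
        ):
            if stop - start > 1:
                assigned[start:stop] = assigned[start:stop].mean()
        out[order, j] = assigned
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    The reference is the per-gene geometric mean across samples, computed
    over genes positive in every sample; each sample's factor is the median
    ratio of its counts to the reference.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with nonzero counts in all samples")
    logx = np.log(x[positive])
    log_ref = logx.mean(axis=1)
    factors = np.exp(np.median(logx - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, quantile: bool = True) -> pd.DataFrame:
    """Size-factor division followed by quantile normalization."""
    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    if quantile:
        norm = quantile_normalize(norm)
    return norm


def estimate_dispersion(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion pooled across conditions.

    For each condition with >= 2 replicates, alpha_c = (s^2 - mu) / mu^2;
    estimates are pooled by a degrees-of-freedom weighted mean and floored.
    Genes with zero mean in all conditions get the floor.
    """
    cond_of = design.set_index("sample")["condition"]
    x = norm.to_numpy(dtype=float)
    cols = list(norm.columns)
    alphas = np.zeros(len(norm))
    weights = np.zeros(len(norm))
    used = 0
    for cond in cond_of.unique():
        idx = [i for i, s in enumerate(cols) if cond_of.get(s) == cond]
        if len(idx) < 2:
            continue
        used += 1
        sub = x[:, idx]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        w = len(idx) - 1
        alphas += np.clip(a, 0.0, None) * w
        weights += w
    if used == 0:
        raise ValueError("need >= 2 replicates in at least one condition")
    out = np.where(weights > 0, alphas / np.maximum(weights, 1), 0.0)
    return pd.Series(np.maximum(out, floor), index=norm.index, name="dispersion")


def nb_wald_test(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    dispersion: pd.Series,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald test of log2 fold change (B over A) between two conditions.

    Returns a frame with columns log2fc, se, p, mean_a, mean_b. Condition
    means are pseudocounted before the log; an all-zero condition is flagged
    in column ``zero_condition``.
    """
    cond_of = design.set_index("sample")["condition"]
    cols = list(norm.columns)
    ia = [i for i, s in enumerate(cols) if cond_of.get(s) == condition_a]
    ib = [i for i, s in enumerate(cols) if cond_of.get(s) == condition_b]
    if not ia or not ib:
        raise ValueError(f"conditions {condition_a!r}/{condition_b!r} not in design")
    x = norm.to_numpy(dtype=float)
    mu_a = x[:, ia].mean(axis=1)
    mu_b = x[:, ib].mean(axis=1)
    alpha = dispersion.reindex(norm.index).to_numpy(dtype=float)
    pa, pb = mu_a + pseudocount, mu_b + pseudocount
    log2fc = np.log2(pb) - np.log2(pa)
    # delta method: Var(log mu_c) ~ (1/mu_c + alpha)/n_c on pseudocounted means
    var_log = (1.0 / pa + alpha) / len(ia) + (1.0 / pb + alpha) / len(ib)
    se = np.sqrt(var_log) / np.log(2.0)
    z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "zero_condition": (mu_a == 0) | (mu_b == 0),
        },
        index=norm.index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must be in [0,1]")
    out = np.full_like(arr, np.nan)
    ok = ~np.isnan(arr)
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def expressed_flag(values: np.ndarray | pd.Series, threshold: float = 10.0) -> bool:
    """A gene is expressed in a condition iff its replicate sum exceeds the threshold (strict)."""
    return float(np.sum(values)) > threshold


def classify_de(
    results: pd.DataFrame,
    lfc_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.Series:
    """Expression class per gene.

    Requires boolean columns ``expressed_a`` / ``expressed_b`` and columns
    ``log2fc`` / ``padj``. Exclusive classes are assigned before
    fold-change classes: not_expressed if expressed in neither condition,
    exclusive_a / exclusive_b if in exactly one, then up (log2fc >= lfc_min
    and padj < alpha), down (log2fc <= -lfc_min and padj < alpha), else
    neutral. Missing padj gives neutral with a warning.
    """
    classes = []
    n_missing = 0
    for _, r in results.iterrows():
        ea, eb = bool(r["expressed_a"]), bool(r["expressed_b"])
        if not ea and not eb:
            classes.append("not_expressed")
        elif ea and not eb:
            classes.append("exclusive_a")
        elif eb and not ea:
            classes.append("exclusive_b")
        else:
            padj = r.get("padj")
            if padj is None or (isinstance(padj, float) and np.isnan(padj)):
                n_missing += 1
                classes.append("neutral")
            elif r["log2fc"] >= lfc_min and padj < alpha:
                classes.append("up")
            elif r["log2fc"] <= -lfc_min and padj < alpha:
                classes.append("down")
            else:
                classes.append("neutral")
    if n_missing:
        log.warning("%d genes lack adjusted p-values; classed neutral", n_missing)
    return pd.Series(classes, index=results.index, name="class")


def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    condition_a: str = "free_living",
    condition_b: str = "symbiosis",
    lfc_min: float = 2.0,
    alpha: float = 0.05,
    expressed_threshold: float = 10.0,
    pseudocount: float = 0.5,
    quantile: bool = True,
) -> pd.DataFrame:
    """Full differential-expression stage on a raw count matrix.

    Returns per-gene log2fc, se, p, padj, per-condition normalized means,
    expressed flags and class.
    """
    norm = normalize_counts(counts, quantile=quantile)
    disp = estimate_dispersion(norm, design)
    res = nb_wald_test(norm, design, disp, condition_a, condition_b, pseudocount)
    res["padj"] = bh_adjust(res["p"].to_numpy())

    cond_of = design.set_index("sample")["condition"]
    cols_a = [s for s in norm.columns if cond_of.get(s) == condition_a]
    cols_b = [s for s in norm.columns if cond_of.get(s) == condition_b]
    res["expressed_a"] = [
        expressed_flag(norm.loc[g, cols_a], expressed_threshold) for g in norm.index
    ]
    res["expressed_b"] = [
        expressed_flag(norm.loc[g, cols_b], expressed_threshold) for g in norm.index
    ]
    res["class"] = classify_de(res, lfc_min=lfc_min, alpha=alpha)
    res.index.name = "gene_id"
    return res
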