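"""Temporal (morning / evening / dark-evening) expression classification.

Counts from the three sampling conditions are normalized jointly with a
single median-of-ratios step (no reference condition), genes are assigned to
the Venn partition of conditions in which their replicate-sum of normalized
counts exceeds 10, the dark response is called from the dark/evening
fold change (two-fold cut, signed-fold-change convention), and Pfam families
are classified as light-modulated / period-of-day-modulated / both / neither
from Wilcoxon rank-sum tests on per-gene condition means.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from symbiotrans.de import size_factors

log = logging.getLogger("symbiotrans")

CONDITIONS = ["morning", "evening", "dark_evening"]


def normalize_joint(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Single median-of-ratios normalization across all samples jointly."""
    cond_of = design.set_index("sample")["condition"]
    missing = [s for s in counts.columns if s not in cond_of.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    return counts.div(size_factors(counts), axis=1)


def _condition_sums(norm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    cond_of = design.set_index("sample")["condition"]
    sums = {}
    for cond in cond_of.unique():
        cols = [s for s in norm.columns if cond_of.get(s) == cond]
        sums[cond] = norm[cols].sum(axis=1)
    return pd.DataFrame(sums)


def condition_expression_sets(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    threshold: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene expression booleans and Venn partition counts.

    A gene is expressed in a condition iff its replicate sum of normalized
    counts is strictly above ``threshold``. Exclusive membership additionally
    requires the other conditions to be strictly below the threshold; a
    replicate sum exactly equal to the threshold satisfies neither strict
    inequality, so such genes drop out of exclusive classes (logged).
    """
    sums = _condition_sums(norm, design)
    conds = list(sums.columns)
    expressed = sums > threshold
    below = sums < threshold

    venn_class = []
    n_boundary = 0
    for g in sums.index:
        exp = [c for c in conds if expressed.loc[g, c]]
        if len(exp) == 1:
            others = [c for c in conds if c != exp[0]]
            if all(below.loc[g, c] for c in others):
                venn_class.append(f"{exp[0]}_only")
            else:
                n_boundary += 1
                venn_class.append("+".join(sorted(exp)))
        elif exp:
            venn_class.append("+".join(sorted(exp)))
        else:
            venn_class.append("none")
    if n_boundary:
        log.info(
            "%d genes at the exact expression threshold excluded from exclusive classes",
            n_boundary,
        )
    out = expressed.add_prefix("expressed_")
    out["venn_class"] = venn_class
    for c in conds:
        out[f"sum_{c}"] = sums[c]

    venn_counts: dict[str, int] = {}
    for size in range(1, len(conds) + 1):
        for combo in itertools.combinations(sorted(conds), size):
            if size == 1:
                key = f"{combo[0]}_only"
            else:
                key = "+".join(combo)
            venn_counts[key] = int((pd.Series(venn_class, index=sums.index) == key).sum())
    return out, venn_counts


def dark_response(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    evening: str = "evening",
    dark: str = "dark_evening",
    fc_cut: float = 2.0,
    pseudocount: float = 0.5,
    expressed_threshold: float = 10.0,
) -> pd.DataFrame:
    """Dark-response class from the dark/evening mean-count ratio.

    Only genes expressed in the evening are classified. ``down`` iff the
    pseudocounted ratio <= 1/fc_cut (a signed fold change below -fc_cut),
    ``up`` iff >= fc_cut, else ``unchanged``. Genes with an evening mean of
    zero are flagged ``undefined``.
    """
    cond_of = design.set_index("sample")["condition"]
    cols_e = [s for s in norm.columns if cond_of.get(s) == evening]
    cols_d = [s for s in norm.columns if cond_of.get(s) == dark]
    if not cols_e or not cols_d:
        raise ValueError("evening and dark conditions must both be present")
    mu_e = norm[cols_e].mean(axis=1)
    mu_d = norm[cols_d].mean(axis=1)
    sum_e = norm[cols_e].sum(axis=1)
    ratio = (mu_d + pseudocount) / (mu_e + pseudocount)
    cls = np.where(
        sum_e <= expressed_threshold,
        "not_expressed_evening",
        np.where(
            mu_e == 0,
            "undefined",
            np.where(
                ratio <= 1.0 / fc_cut, "down", np.where(ratio >= fc_cut, "up", "unchanged")
            ),
        ),
    )
    return pd.DataFrame(
        {"evening_mean": mu_e, "dark_mean": mu_d, "dark_fc": ratio, "dark_class": cls},
        index=norm.index,
    ).rename_axis("gene_id")


def pfam_modulation(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    pfam_of: pd.Series,
    alpha: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per-Pfam modulation class from rank-sum tests on per-gene condition means.

    For each Pfam with >= ``min_genes`` members, Wilcoxon rank-sum tests
    compare the member genes' per-condition mean normalized counts between
    morning and evening (period-of-day contrast) and between evening and
    dark-evening (light contrast). Classes: ``light`` iff only evening vs
    dark is significant, ``period_of_day`` iff only morning vs evening,
    ``both`` / ``neither`` otherwise; groups too small are ``untested``.
    Signed directions of each contrast are reported alongside.
    """
    cond_of = design.set_index("sample")["condition"]
    means = {}
    for cond in CONDITIONS:
        cols = [s for s in norm.columns if cond_of.get(s) == cond]
        if not cols:
            raise ValueError(f"condition {cond!r} missing from design")
        means[cond] = norm[cols].mean(axis=1)
    mdf = pd.DataFrame(means)

    rows = {}
    for pfam, genes in pfam_of.dropna().groupby(pfam_of.dropna()).groups.items():
        genes = [g for g in genes if g in mdf.index]
        if len(genes) < min_genes:
            rows[pfam] = {
                "n_genes": len(genes),
                "p_morning_vs_evening": np.nan,
                "p_evening_vs_dark": np.nan,
                "direction_morning_vs_evening": 0.0,
                "direction_evening_vs_dark": 0.0,
                "modulation": "untested",
            }
            continue
        sub = mdf.loc[genes]
        p_me = stats.ranksums(sub["morning"], sub["evening"]).pvalue
        p_ed = stats.ranksums(sub["evening"], sub["dark_evening"]).pvalue
        sig_me, sig_ed = p_me < alpha, p_ed < alpha
        if sig_ed and not sig_me:
            mod = "light"
        elif sig_me and not sig_ed:
            mod = "period_of_day"
        elif sig_me and sig_ed:
            mod = "both"
        else:
            mod = "neither"
        rows[pfam] = {
            "n_genes": len(genes),
            "p_morning_vs_evening": p_me,
            "p_evening_vs_dark": p_ed,
            "direction_morning_vs_evening": float(
                np.sign(sub["morning"].median() - sub["evening"].median())
            ),
            "direction_evening_vs_dark": float(
                np.sign(sub["evening"].median() - sub["dark_evening"].median())
            ),
            "modulation": mod,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("pfam")


def run_temporal(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    pfam_of: pd.Series | None = None,
    threshold: float = 10.0,
    fc_cut: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Full temporal stage: joint normalization, Venn sets, dark response, Pfam classes."""
    norm = normalize_joint(counts, design)
    sets, venn_counts = condition_expression_sets(norm, design, threshold)
    dark = dark_response(
        norm, design, fc_cut=fc_cut, expressed_threshold=threshold
    )
    per_gene = sets.join(dark[["dark_fc", "dark_class"]])
    out = {"per_gene": per_gene, "venn_counts": venn_counts}
    if pfam_of is not None:
        out["pfam_modulation"] = pfam_modulation(norm, design, pfam_of, alpha=alpha)
    return out
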