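"""Compositional normalization of size-fractionated metatranscriptomes.

TPM tables are compositional: each sample is closed to a fixed total, so
blooms of unrelated taxa distort every gene's apparent abundance and induce
spurious correlations. The remedy implemented here expresses each gene as a
ratio to the geometric mean of a set of stable housekeeping genes selected
by four sequential criteria:

1. retain only samples in which at least 20% of the reference transcriptome
   is detected, and only genes detected in every retained sample;
2. keep genes whose TPM profile has a coefficient of variation below 200
   (percent scale) and a fold change from the mean below 2 in every sample;
3. keep genes with a typical housekeeping annotation (ribosomal proteins,
   tubulin, ATP synthase, ...);
4. k-means cluster the standardized log profiles and keep, from the cluster
   with the most mutually correlated members, the genes whose mean pairwise
   Pearson r with co-cluster members exceeds 0.5.

Ratios to the housekeeping geometric mean are invariant to any per-sample
rescaling, which removes the closure artifact exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from symbiotrans.config import HOUSEKEEPING_PATTERNS

log = logging.getLogger("symbiotrans")


def sample_detection_filter(
    tpm: pd.DataFrame,
    reference_genes: list[str] | pd.Index | None = None,
    min_frac: float = 0.2,
) -> list[str]:
    """Samples in which >= ``min_frac`` of the reference gene set is detected.

    Detection means TPM > 0. The reference defaults to all genes in the table.
    """
    ref = list(reference_genes) if reference_genes is not None else list(tpm.index)
    if len(ref) == 0:
        raise ValueError("empty reference gene set")
    sub = tpm.reindex(ref).fillna(0.0)
    detected_frac = (sub > 0).sum(axis=0) / len(ref)
    retained = [s for s in tpm.columns if detected_frac[s] >= min_frac]
    log.info("detection filter: %d/%d samples retained", len(retained), tpm.shape[1])
    return retained


def ubiquitous_gene_filter(tpm: pd.DataFrame, retained_samples: list[str]) -> list[str]:
    """Genes with TPM > 0 in every retained sample."""
    if len(retained_samples) == 0:
        raise ValueError("no retained samples")
    sub = tpm[retained_samples]
    return list(sub.index[(sub > 0).all(axis=1)])


def stability_filter(
    tpm: pd.DataFrame,
    genes: list[str],
    samples: list[str],
    cv_max: float = 200.0,
    fc_max: float = 2.0,
) -> pd.DataFrame:
    """Stability criteria over the retained samples.

    Keeps genes with CV (sd/mean x 100, percent) < ``cv_max`` and a two-sided
    fold change from the mean, max(x/mean, mean/x), < ``fc_max`` in every
    sample. Zero-mean genes are excluded. Returns a diagnostics frame indexed
    by the surviving genes with columns ``cv_percent`` and ``max_fc``.
    """
    sub = tpm.loc[genes, samples].to_numpy(dtype=float)
    mean = sub.mean(axis=1)
    keep_rows, cvs, fcs = [], [], []
    for i, g in enumerate(genes):
        if mean[i] <= 0:
            continue
        cv = sub[i].std(ddof=1) / mean[i] * 100.0
        with np.errstate(divide="ignore"):
            fc = np.max(np.maximum(sub[i] / mean[i], mean[i] / np.maximum(sub[i], 1e-300)))
        if cv < cv_max and fc < fc_max:
            keep_rows.append(g)
            cvs.append(cv)
            fcs.append(fc)
    return pd.DataFrame({"cv_percent": cvs, "max_fc": fcs}, index=keep_rows).rename_axis(
        "gene_id"
    )


def annotation_whitelist_filter(
    genes: list[str],
    annotations: pd.Series,
    patterns: list[str] | None = None,
) -> list[str]:
    """Genes whose annotation matches a housekeeping pattern (case-insensitive).

    Unannotated genes are excluded and logged.
    """
    patterns = [p.lower() for p in (patterns or HOUSEKEEPING_PATTERNS)]
    kept = []
    n_unannotated = 0
    for g in genes:
        ann = annotations.get(g)
        if ann is None or (isinstance(ann, float) and pd.isna(ann)):
            n_unannotated += 1
            continue
        ann_l = str(ann).lower()
        if any(p in ann_l for p in patterns):
            kept.append(g)
    if n_unannotated:
        log.info("annotation filter: %d unannotated genes excluded", n_unannotated)
    return kept


def correlation_cluster_select(
    tpm: pd.DataFrame,
    genes: list[str],
    samples: list[str],
    k: int = 8,
    r_min: float = 0.5,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Select the co-expressed cluster of stable genes.

    Genes are standardized on log1p profiles over the retained samples and
    k-means clustered (``n_init`` restarts, fixed seed). For each cluster the
    members whose mean pairwise Pearson r with the other members exceeds
    ``r_min`` are counted; the cluster with the most such members wins, and
    those members are returned with diagnostics (cluster id, mean pairwise r).
    Raises if no cluster contains any qualifying member.
    """
    if k > len(genes):
        raise ValueError(f"k={k} exceeds candidate gene count {len(genes)}")
    x = np.log1p(tpm.loc[genes, samples].to_numpy(dtype=float))
    sd = x.std(axis=1, ddof=1)
    mu = x.mean(axis=1)
    z = (x - mu[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(z)

    best_members: list[str] | None = None
    best_r: np.ndarray | None = None
    best_cluster = -1
    best_count = -1
    for c in range(k):
        idx = np.where(labels == c)[0]
        if len(idx) < 2:
            continue
        profiles = x[idx]
        r = np.corrcoef(profiles)
        np.fill_diagonal(r, np.nan)
        mean_r = np.nanmean(r, axis=1)
        qual = mean_r > r_min
        if qual.sum() > best_count:
            best_count = int(qual.sum())
            best_cluster = c
            best_members = [genes[i] for i in idx[qual]]
            best_r = mean_r[qual]
    if not best_members:
        raise ValueError("no stable cluster: no genes with mean pairwise r above r_min")
    return pd.DataFrame(
        {"cluster": best_cluster, "mean_pairwise_r": best_r}, index=best_members
    ).rename_axis("gene_id")


def select_housekeeping(
    tpm: pd.DataFrame,
    annotations: pd.Series,
    min_detect: float = 0.2,
    cv_max: float = 200.0,
    fc_max: float = 2.0,
    patterns: list[str] | None = None,
    k: int = 8,
    r_min: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the four housekeeping criteria in order.

    Returns (housekeeping diagnostics frame, retained sample ids). Each stage
    only shrinks the candidate set.
    """
    samples = sample_detection_filter(tpm, min_frac=min_detect)
    genes = ubiquitous_gene_filter(tpm, samples)
    stab = stability_filter(tpm, genes, samples, cv_max=cv_max, fc_max=fc_max)
    annotated = annotation_whitelist_filter(list(stab.index), annotations, patterns)
    k_eff = min(k, len(annotated))
    if k_eff < 1:
        raise ValueError("no housekeeping candidates after annotation filter")
    cluster = correlation_cluster_select(
        tpm, annotated, samples, k=k_eff, r_min=r_min, seed=seed
    )
    hk = stab.loc[cluster.index].join(cluster)
    hk["annotation"] = [annotations.get(g) for g in hk.index]
    log.info(
        "housekeeping selection: %d samples, %d ubiquitous, %d stable, "
        "%d annotated, %d selected",
        len(samples), len(genes), len(stab), len(annotated), len(hk),
    )
    return hk, samples


def ratio_normalize(
    tpm: pd.DataFrame, hk_genes: list[str], samples: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample ratios to the housekeeping geometric mean.

    Samples where any housekeeping gene has zero TPM are excluded (geometric
    mean undefined) and logged.
    """
    if len(hk_genes) == 0:
        raise ValueError("empty housekeeping set")
    samples = list(samples) if samples is not None else list(tpm.columns)
    hk = tpm.loc[hk_genes, samples].to_numpy(dtype=float)
    ok = (hk > 0).all(axis=0)
    dropped = [s for s, good in zip(samples, ok) if not good]
    if dropped:
        log.warning(
            "ratio normalization: %d samples dropped (zero housekeeping TPM): %s",
            len(dropped), dropped,
        )
    kept = [s for s, good in zip(samples, ok) if good]
    x = tpm[kept].to_numpy(dtype=float)
    h = tpm.loc[hk_genes, kept].to_numpy(dtype=float)
    # geometric mean of per-gene quotients: the per-sample scale cancels in
    # x/h before any rounding, so ratios are exactly invariant to rescaling
    with np.errstate(divide="ignore"):
        log_q = np.log(x[:, None, :] / h[None, :, :])
    ratios = np.exp(log_q.mean(axis=1))
    return pd.DataFrame(ratios, index=tpm.index, columns=kept)


def compare_fractions(
    ratios: pd.DataFrame,
    metadata: pd.DataFrame,
    detected_only: bool = False,
) -> pd.DataFrame:
    """Per-gene mean ratio in each size fraction and enrichment flag.

    ``higher_in_large`` is a strict comparison of the mean ratio over
    large-fraction samples against the small fraction. With
    ``detected_only`` means are computed over samples where the gene is
    detected (ratio > 0); by default zeros count. Genes absent from all
    samples of a fraction are flagged ``undetected_in_fraction`` and never
    ``higher_in_large``.
    """
    frac_of = metadata.set_index("sample")["size_fraction"]
    small = [s for s in ratios.columns if frac_of.get(s) == "small"]
    large = [s for s in ratios.columns if frac_of.get(s) == "large"]
    if not small or not large:
        raise ValueError("both size fractions must be represented")
    xs = ratios[small].to_numpy(dtype=float)
    xl = ratios[large].to_numpy(dtype=float)
    if detected_only:
        with np.errstate(invalid="ignore"):
            mean_s = np.where((xs > 0).any(axis=1),
                              np.nansum(np.where(xs > 0, xs, np.nan), axis=1)
                              / np.maximum((xs > 0).sum(axis=1), 1), 0.0)
            mean_l = np.where((xl > 0).any(axis=1),
                              np.nansum(np.where(xl > 0, xl, np.nan), axis=1)
                              / np.maximum((xl > 0).sum(axis=1), 1), 0.0)
    else:
        mean_s = xs.mean(axis=1)
        mean_l = xl.mean(axis=1)
    undetected = ((xs > 0).sum(axis=1) == 0) | ((xl > 0).sum(axis=1) == 0)
    higher = (mean_l > mean_s) & ~undetected
    return pd.DataFrame(
        {
            "mean_ratio_small": mean_s,
            "mean_ratio_large": mean_l,
            "higher_in_large": higher,
            "undetected_in_fraction": undetected,
        },
        index=ratios.index,
    ).rename_axis("gene_id")
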