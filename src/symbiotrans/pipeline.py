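"""End-to-end synthetic pipeline runner.

Generates all synthetic inputs for one seed, runs every analysis stage, and
writes the stage tables plus a joined headline report. The effective
configuration is embedded in each artifact's metadata header.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from symbiotrans import catalog as cat
from symbiotrans import de as de_mod
from symbiotrans import metaratio, reporting, synthetic, temporal
from symbiotrans.config import PipelineConfig
from symbiotrans.io import write_json, write_matrix, write_table

log = logging.getLogger("symbiotrans")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    n_proteins: int = 400,
    n_genes: int = 1500,
    design: dict[str, int] | None = None,
) -> dict:
    """Simulate -> catalog -> DE -> meta-ratio -> temporal -> report.

    Returns the headline report (also written to ``report.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict()}
    seed = config.seed
    timings = {}

    t0 = time.perf_counter()
    hits, truth = synthetic.gen_annotations(
        n_proteins, frac_transporter=0.3, frac_sugar=0.1, seed=seed
    )
    tm = synthetic.gen_tm_predictions(truth, disagreement_sd=1.0, seed=seed)
    locs = synthetic.gen_localizations(truth, agreement=0.8, seed=seed)
    write_table(out / "annotation_hits.tsv", hits, meta)
    write_table(out / "tm_predictions.tsv", tm, meta)
    write_table(out / "localizations.tsv", locs, meta)
    write_json(out / "truth_catalog.json", truth.to_dict())
    timings["simulate_catalog_inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    vocab = (
        cat.load_compartment_map(config.compartment_map_path)
        if config.compartment_map_path
        else None
    )
    catalog_df, catalog_summary = cat.build_catalog(
        hits,
        tm=tm,
        localizations=locs,
        keywords=config.transporter_keywords,
        sugar_keywords=config.sugar_keywords,
        core_pfams=config.core_sugar_pfams,
        vocab_map=vocab,
        token_mode=config.keyword_token_mode,
        tm_min=config.tm_min,
        tm_diff_max=config.tm_diff_max,
        subfamily_evalue=config.subfamily_evalue,
        deeploc_min=config.deeploc_min,
        strict_and=config.deeploc_strict_and,
    )
    write_table(out / "catalog.tsv", catalog_df.reset_index(), meta)
    write_json(out / "catalog_summary.json", catalog_summary)
    timings["catalog"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    de_design = design or {"free_living": 9, "symbiosis": 17}
    counts, design_df, de_truth = synthetic.gen_counts(
        n_genes, de_design, frac_de=0.1, lfc=3.0, dispersion=0.1, seed=seed
    )
    write_matrix(out / "counts.tsv", counts, meta)
    write_table(out / "design.tsv", design_df, meta)
    de_res = de_mod.run_de(
        counts,
        design_df,
        condition_a="free_living",
        condition_b="symbiosis",
        lfc_min=config.lfc_min,
        alpha=config.alpha,
        expressed_threshold=config.expressed_threshold,
        pseudocount=config.pseudocount,
    )
    write_table(out / "de_results.tsv", de_res.reset_index(), meta)
    timings["differential_expression"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tpm, sample_meta, annotations, meta_truth = synthetic.gen_metatranscriptome(
        n_genes=600, samples_per_fraction=8, n_hk=40, seed=seed
    )
    write_matrix(out / "tpm.tsv", tpm, meta)
    write_table(out / "sample_metadata.tsv", sample_meta, meta)
    hk, retained = metaratio.select_housekeeping(
        tpm,
        annotations,
        min_detect=config.min_detect,
        cv_max=config.cv_max,
        fc_max=config.fc_max,
        patterns=config.housekeeping_patterns,
        k=config.k,
        r_min=config.r_min,
        seed=seed,
    )
    ratios = metaratio.ratio_normalize(tpm, list(hk.index), retained)
    frac_cmp = metaratio.compare_fractions(
        ratios, sample_meta, detected_only=config.fraction_mean_detected_only
    )
    write_table(out / "housekeeping.tsv", hk.reset_index(), meta)
    write_matrix(out / "ratios.tsv", ratios, meta)
    write_table(out / "fraction_comparison.tsv", frac_cmp.reset_index(), meta)
    timings["metatranscriptome_ratio"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    t_design = {"morning": 4, "evening": 4, "dark_evening": 4}
    t_counts, t_design_df, t_truth = synthetic.gen_counts(
        n_genes, t_design, frac_de=0.2, lfc=3.0, dispersion=0.1, seed=seed + 1
    )
    # reuse catalog Pfam families on a synthetic gene<->protein mapping by rank
    pfam_of = pd.Series(index=t_counts.index, dtype=object)
    sugar_prot = catalog_df[catalog_df["is_sugar_transporter"]]
    for i, (pid, row) in enumerate(sugar_prot.iterrows()):
        if i >= len(t_counts.index):
            break
        pfam_of.iloc[i] = row["pfam_family"]
    temporal_out = temporal.run_temporal(
        t_counts,
        t_design_df,
        pfam_of=pfam_of,
        threshold=config.expressed_threshold,
        fc_cut=config.fc_cut_dark,
        alpha=config.alpha,
    )
    write_table(out / "temporal_per_gene.tsv", temporal_out["per_gene"].reset_index(), meta)
    write_json(
        out / "temporal_pfam.json",
        temporal_out["pfam_modulation"].to_dict(orient="index"),
    )
    timings["temporal"] = time.perf_counter() - t0

    class_counts = reporting.per_pfam_class_counts(catalog_df, de_res)
    report = reporting.headline_summary(
        catalog_summary=catalog_summary,
        de_results=de_res,
        class_counts=class_counts,
        temporal=temporal_out,
        fraction_comparison=frac_cmp,
    )
    report["config"] = config.to_dict()
    # timings are logged, not embedded: the report must be byte-identical
    # across runs with the same config and seed
    write_json(out / "report.json", report)
    for stage, dt in timings.items():
        log.info("stage %s: %.2fs", stage, dt)
    return report
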