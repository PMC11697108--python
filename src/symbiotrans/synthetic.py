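"""Synthetic input generators with known ground truth.

Every pipeline stage consumes tables these generators can produce: multi-tool
annotation hit tables with planted transporter / sugar-transporter labels,
paired transmembrane-count predictions with controllable disagreement,
five-tool localization votes, negative-binomial count matrices with planted
differentially expressed genes, and closed (TPM) metatranscriptome tables
across two plankton size fractions with planted stable housekeeping genes,
planted fraction-enriched genes, and compositional distortion.

A single integer seed fans out to independent per-generator streams via
``numpy.random.SeedSequence`` spawn keys, so the same seed yields
byte-identical outputs for each generator independently of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from symbiotrans.config import CORE_SUGAR_PFAMS

# fixed spawn key per generator: reproducibility without cross-generator coupling
_STREAMS = {
    "annotations": 1,
    "tm": 2,
    "localization": 3,
    "counts": 4,
    "meta": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimTruth:
    """Ground-truth labels for one synthetic dataset.

    Every generated entity carries exactly one truth label in its map;
    maps not relevant to a given generator stay empty.
    """

    seed: int
    transporter_labels: dict[str, str] = field(default_factory=dict)
    tm_counts: dict[str, int] = field(default_factory=dict)
    de_labels: dict[str, dict] = field(default_factory=dict)
    hk_labels: dict[str, str] = field(default_factory=dict)
    fraction_enrichment: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def transporters(self) -> set[str]:
        return {
            p
            for p, lab in self.transporter_labels.items()
            if lab in ("transporter", "sugar_transporter")
        }

    @property
    def sugar_transporters(self) -> set[str]:
        return {
            p for p, lab in self.transporter_labels.items() if lab == "sugar_transporter"
        }


# --- annotation tables -------------------------------------------------------

_TRANSPORTER_TEMPLATES = [
    "ABC transporter family protein",
    "cation channel protein",
    "amino acid permease",
    "sodium/proton antiporter",
    "mitochondrial carrier protein",
    "major facilitator superfamily transporter",
    "potassium symporter",
    "anion exchanger",
]

_SUGAR_TEMPLATES = [
    "glucose transporter GLUT-like",
    "sugar transporter SWEET",
    "triose-phosphate transporter, chloroplastic",
    "nucleotide-sugar transporter family",
    "polysaccharide export transporter",
    "carbohydrate transporter/permease",
    "sucrose transport protein",
]

# decoys include hard negatives: morphologically close to keywords but not
# transporter annotations
_DECOY_TEMPLATES = [
    "DNA transposase",
    "transcription factor bZIP",
    "ribosomal protein L7",
    "serine/threonine kinase domain protein",
    "photosystem II protein D1",
    "heat shock protein 70",
    "histone H3",
    "elongation factor 1-alpha",
    "glycoside hydrolase family 16",
    "ubiquitin-conjugating enzyme",
]

_SOURCES = ["interpro", "tcdb", "blast_uniprot", "pfam_hmm", "eggnog"]


def gen_annotations(
    n_proteins: int,
    frac_transporter: float = 0.3,
    frac_sugar: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a merged-style annotation hit table with planted labels.

    Returns a long-format table (protein_id, source, accession, description,
    evalue) and the truth. Planted transporters carry at least one
    keyword-bearing description; planted sugar transporters additionally carry
    a sugar keyword and one of the core sugar Pfam accessions; the rest carry
    decoy descriptions.
    """
    if not isinstance(n_proteins, (int, np.integer)):
        raise TypeError(f"n_proteins must be an integer, got {type(n_proteins)}")
    if not (0 <= frac_sugar <= frac_transporter <= 1):
        raise ValueError(
            "require 0 <= frac_sugar <= frac_transporter <= 1, got "
            f"frac_sugar={frac_sugar}, frac_transporter={frac_transporter}"
        )
    rng = _rng(seed, "annotations")
    ids = [f"P{i:06d}" for i in range(n_proteins)]
    n_trans = int(round(n_proteins * frac_transporter))
    n_sugar = int(round(n_proteins * frac_sugar))
    perm = rng.permutation(n_proteins)
    sugar_ids = {ids[i] for i in perm[:n_sugar]}
    plain_ids = {ids[i] for i in perm[n_sugar:n_trans]}

    truth = SimTruth(seed=seed)
    rows = []
    for pid in ids:
        if pid in sugar_ids:
            truth.transporter_labels[pid] = "sugar_transporter"
            desc = _SUGAR_TEMPLATES[rng.integers(len(_SUGAR_TEMPLATES))]
            pfam = CORE_SUGAR_PFAMS[rng.integers(len(CORE_SUGAR_PFAMS))]
            rows.append((pid, "pfam_hmm", pfam, desc, 10.0 ** -rng.uniform(10, 60)))
            rows.append(
                (pid, "blast_uniprot", f"Q{rng.integers(10000, 99999)}", desc,
                 10.0 ** -rng.uniform(10, 60))
            )
        elif pid in plain_ids:
            truth.transporter_labels[pid] = "transporter"
            desc = _TRANSPORTER_TEMPLATES[rng.integers(len(_TRANSPORTER_TEMPLATES))]
            src = _SOURCES[rng.integers(len(_SOURCES))]
            rows.append(
                (pid, src, f"IPR{rng.integers(1, 50000):06d}", desc,
                 10.0 ** -rng.uniform(6, 60))
            )
        else:
            truth.transporter_labels[pid] = "other"
            desc = _DECOY_TEMPLATES[rng.integers(len(_DECOY_TEMPLATES))]
            src = _SOURCES[rng.integers(len(_SOURCES))]
            rows.append(
                (pid, src, f"IPR{rng.integers(1, 50000):06d}", desc,
                 10.0 ** -rng.uniform(3, 40))
            )
    table = pd.DataFrame(
        rows, columns=["protein_id", "source", "accession", "description", "evalue"]
    )
    return table, truth


def gen_tm_predictions(
    truth: SimTruth, disagreement_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Paired transmembrane-domain counts from two predictors.

    Planted transporters draw counts with mean >= 2 (2 + Poisson(6), matching
    polytopic transporter topology); non-transporters draw sparse counts
    (Poisson(0.5)). The second tool's count is the first plus rounded Gaussian
    noise with sd ``disagreement_sd``, clipped at zero. Planted counts are
    recorded in ``truth.tm_counts``.
    """
    if disagreement_sd < 0:
        raise ValueError("disagreement_sd must be >= 0")
    if not truth.transporter_labels:
        raise ValueError("truth carries no protein labels")
    rng = _rng(seed, "tm")
    pids = sorted(truth.transporter_labels)
    labels = np.array(
        [truth.transporter_labels[p] != "other" for p in pids], dtype=bool
    )
    n = len(pids)
    n1 = np.where(labels, 2 + rng.poisson(6.0, n), rng.poisson(0.5, n))
    noise = np.round(rng.normal(0.0, disagreement_sd, n)).astype(int)
    n2 = np.maximum(0, n1 + noise)
    for pid, c in zip(pids, n1):
        truth.tm_counts[pid] = int(c)
    return pd.DataFrame(
        {"protein_id": pids, "n_tm_tool1": n1.astype(int), "n_tm_tool2": n2.astype(int)}
    )


_LOC_TOOLS = ["deeploc", "targetp", "hectar", "wolf_psort", "mulocdeep"]

# each tool's raw vocabulary for the same harmonized compartment; mirrors the
# heterogeneous vocabularies of the five predictors
_TOOL_VOCAB = {
    "deeploc": {
        "cell_membrane": "Cell membrane",
        "plastid": "Plastid",
        "mitochondrion": "Mitochondrion",
        "golgi": "Golgi apparatus",
        "er": "Endoplasmic reticulum",
        "cytosol": "Cytoplasm",
        "extracellular": "Extracellular",
    },
    "targetp": {
        "cell_membrane": "SP",
        "plastid": "cTP",
        "mitochondrion": "mTP",
        "golgi": "SP",
        "er": "SP",
        "cytosol": "noTP",
        "extracellular": "SP",
    },
    "hectar": {
        "cell_membrane": "signal peptide",
        "plastid": "chloroplast",
        "mitochondrion": "mitochondrion",
        "golgi": "signal peptide",
        "er": "signal peptide",
        "cytosol": "other localisation",
        "extracellular": "signal peptide",
    },
    "wolf_psort": {
        "cell_membrane": "plas",
        "plastid": "chlo",
        "mitochondrion": "mito",
        "golgi": "golg",
        "er": "E.R.",
        "cytosol": "cyto",
        "extracellular": "extr",
    },
    "mulocdeep": {
        "cell_membrane": "Cell membrane",
        "plastid": "Plastid",
        "mitochondrion": "Mitochondria",
        "golgi": "Golgi",
        "er": "ER",
        "cytosol": "Cytoplasm",
        "extracellular": "Secreted",
    },
}

_COMPARTMENTS = ["cell_membrane", "plastid", "mitochondrion", "golgi", "er",
                 "cytosol", "extracellular"]


def gen_localizations(
    truth: SimTruth, agreement: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Five-tool localization votes with controllable agreement.

    Each protein gets a true compartment (transporters biased to membranes);
    each tool reports the true compartment with probability ``agreement``,
    otherwise a random other compartment. Deeploc-role scores are drawn high
    (0.6-1.0) for correct votes and low-to-mid (0.1-0.7) for incorrect ones.
    """
    if not 0 <= agreement <= 1:
        raise ValueError("agreement must be in [0,1]")
    rng = _rng(seed, "localization")
    pids = sorted(truth.transporter_labels)
    rows = []
    for pid in pids:
        is_tr = truth.transporter_labels[pid] != "other"
        if is_tr:
            true_comp = _COMPARTMENTS[rng.choice([0, 1, 3, 4], p=[0.55, 0.2, 0.15, 0.1])]
        else:
            true_comp = _COMPARTMENTS[rng.integers(len(_COMPARTMENTS))]
        for tool in _LOC_TOOLS:
            if rng.random() < agreement:
                comp = true_comp
                score = rng.uniform(0.6, 1.0)
            else:
                others = [c for c in _COMPARTMENTS if c != true_comp]
                comp = others[rng.integers(len(others))]
                score = rng.uniform(0.1, 0.7)
            rows.append(
                (pid, tool, _TOOL_VOCAB[tool][comp],
                 round(score, 4) if tool == "deeploc" else "")
            )
    return pd.DataFrame(rows, columns=["protein_id", "tool", "raw_label", "score"])


# --- count matrices ----------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws under the variance = mu + alpha*mu^2 parameterization."""
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def gen_counts(
    n_genes: int,
    design: dict[str, int],
    frac_de: float = 0.1,
    lfc: float = 2.0,
    dispersion: float = 0.1,
    libsize_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Negative-binomial count matrix with planted differential expression.

    ``design`` maps condition name to replicate count. Planted DE genes get
    a signed two-fold-log effect of magnitude ``lfc`` applied to one
    non-reference condition (the affected condition is recorded in the truth;
    with two conditions it is always the second). Library sizes are
    log-uniform in ``libsize_range``. Returns (counts, sample design table,
    truth).
    """
    if not design:
        raise ValueError("design must name at least one condition")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0,1]")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if lfc < 0:
        raise ValueError("lfc must be >= 0 (sign is assigned per gene)")
    rng = _rng(seed, "counts")
    conditions = list(design)
    samples, cond_of = [], []
    for cond in conditions:
        for r in range(design[cond]):
            samples.append(f"{cond}_{r + 1}")
            cond_of.append(cond)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    baseline = 2.0 ** rng.uniform(3, 10, n_genes)
    libsize = np.exp(
        rng.uniform(np.log(libsize_range[0]), np.log(libsize_range[1]), len(samples))
    )
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.permutation(n_genes)[:n_de]
    signs = rng.choice([-1.0, 1.0], n_de)
    target_conds = (
        [conditions[1]] * n_de
        if len(conditions) == 2
        else [conditions[1 + rng.integers(len(conditions) - 1)] for _ in range(n_de)]
    )

    truth = SimTruth(seed=seed)
    lfc_matrix = np.zeros((n_genes, len(samples)))
    for j, (gi, sgn, cond) in enumerate(zip(de_idx, signs, target_conds)):
        planted = sgn * lfc
        truth.de_labels[genes[gi]] = {
            "label": "null" if lfc == 0 else ("up" if sgn > 0 else "down"),
            "lfc": float(planted),
            "condition": cond,
        }
        mask = np.array([c == cond for c in cond_of])
        lfc_matrix[gi, mask] = planted
    for g in genes:
        if g not in truth.de_labels:
            truth.de_labels[g] = {"label": "null", "lfc": 0.0, "condition": None}

    mu = baseline[:, None] * libsize[None, :] * 2.0 ** lfc_matrix
    counts = _nb_draw(rng, mu, dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene_id"
    design_df = pd.DataFrame(
        {
            "sample": samples,
            "condition": cond_of,
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        }
    )
    return counts_df, design_df, truth


# --- metatranscriptome TPM tables --------------------------------------------

_HK_ANNOTATIONS = [
    "60S ribosomal protein L10",
    "40S ribosomal protein S3",
    "alpha-tubulin",
    "beta-tubulin chain",
    "actin",
    "ATP synthase subunit beta",
    "elongation factor 1-alpha",
    "histone H4",
    "ubiquitin",
    "glyceraldehyde-3-phosphate dehydrogenase GAPDH",
]

_VAR_ANNOTATIONS = [
    "light-harvesting complex protein",
    "sugar transporter SWEET",
    "triose-phosphate transporter, chloroplastic",
    "nitrate reductase",
    "flagellar associated protein",
    "carbonic anhydrase",
    "fucoxanthin chlorophyll a/c protein",
    "unknown protein",
]


def gen_metatranscriptome(
    n_genes: int = 500,
    samples_per_fraction: int = 6,
    n_hk: int = 30,
    detection_profile: np.ndarray | list[float] | None = None,
    compositional_factor: np.ndarray | list[float] | None = None,
    frac_enriched: float = 0.05,
    enrich_lfc: float = 2.0,
    hk_sigma: float = 0.05,
    var_sigma: float = 1.0,
    n_hk_decoys: int = 5,
    bloom_share: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, SimTruth]:
    """Closed TPM tables across two size fractions with planted structure.

    Planted housekeeping genes have low biological variance (log-normal sd
    ``hk_sigma``) and housekeeping-style annotations; ``n_hk_decoys`` variable
    genes also carry housekeeping annotations so the stability criteria are
    load-bearing. Planted fraction-enriched genes are multiplied by
    ``2**enrich_lfc`` in large-fraction samples. ``compositional_factor``
    (one per sample, default log-uniform in [1, 8]) inflates a random 10%
    non-housekeeping "bloom" gene subset before re-closing each column to
    1e6, emulating other community members changing abundance and thereby
    reproducing the spurious-correlation problem of compositional data;
    ``bloom_share`` sets the bloom subset's baseline share of the column
    total before inflation.
    ``detection_profile`` gives each sample's detected fraction of the
    transcriptome; by default two samples per fraction sit below 20%.

    Returns (tpm, sample metadata, per-gene annotation, truth).
    """
    if n_hk >= n_genes:
        raise ValueError("n_hk must be < n_genes")
    rng = _rng(seed, "meta")
    n_samples = 2 * samples_per_fraction
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    fractions = ["small"] * samples_per_fraction + ["large"] * samples_per_fraction
    stations = [f"st{(i % samples_per_fraction) + 1}" for i in range(n_samples)]
    genes = [f"mg{i:05d}" for i in range(n_genes)]

    if detection_profile is None:
        # last sample of each fraction planted below the 20% retention floor
        detection_profile = np.full(n_samples, 0.9)
        detection_profile[samples_per_fraction - 1] = 0.1
        detection_profile[-1] = 0.12
    detection_profile = np.asarray(detection_profile, dtype=float)
    if detection_profile.shape != (n_samples,) or (
        (detection_profile < 0).any() or (detection_profile > 1).any()
    ):
        raise ValueError("detection_profile must be per-sample fractions in [0,1]")
    if compositional_factor is None:
        compositional_factor = np.exp(rng.uniform(0.0, np.log(8.0), n_samples))
    compositional_factor = np.asarray(compositional_factor, dtype=float)
    if compositional_factor.shape != (n_samples,):
        raise ValueError("compositional_factor must be per-sample")

    perm = rng.permutation(n_genes)
    hk_idx = perm[:n_hk]
    decoy_idx = perm[n_hk : n_hk + n_hk_decoys]
    n_enr = int(round(frac_enriched * n_genes))
    enr_idx = perm[n_hk + n_hk_decoys : n_hk + n_hk_decoys + n_enr]
    # the inflated "bloom" subset driving compositional distortion
    n_bloom = max(1, n_genes // 10)
    bloom_idx = perm[n_hk + n_hk_decoys + n_enr : n_hk + n_hk_decoys + n_enr + n_bloom]

    truth = SimTruth(seed=seed)
    annotations = {}
    base = 2.0 ** rng.uniform(2, 12, n_genes)
    # housekeeping genes drawn abundant so they survive realistic dropout
    base[hk_idx] = 2.0 ** rng.uniform(9, 12, n_hk)
    sigma = np.full(n_genes, var_sigma)
    sigma[hk_idx] = hk_sigma
    for i, g in enumerate(genes):
        if i in set(hk_idx):
            truth.hk_labels[g] = "stable"
            annotations[g] = _HK_ANNOTATIONS[rng.integers(len(_HK_ANNOTATIONS))]
        else:
            truth.hk_labels[g] = "variable"
            if i in set(decoy_idx):
                annotations[g] = _HK_ANNOTATIONS[rng.integers(len(_HK_ANNOTATIONS))]
            else:
                annotations[g] = _VAR_ANNOTATIONS[rng.integers(len(_VAR_ANNOTATIONS))]
        truth.fraction_enrichment[g] = float(enrich_lfc) if i in set(enr_idx) else 0.0

    if not 0 < bloom_share < 1:
        raise ValueError("bloom_share must be in (0,1)")
    # rescale the bloom subset so it holds bloom_share of the baseline total
    other_total = base.sum() - base[bloom_idx].sum()
    base[bloom_idx] *= (
        bloom_share / (1.0 - bloom_share) * other_total / base[bloom_idx].sum()
    )

    abundance = base[:, None] * np.exp(
        rng.normal(0.0, 1.0, (n_genes, n_samples)) * sigma[:, None]
    )
    large_mask = np.array([f == "large" for f in fractions])
    abundance[np.ix_(enr_idx, large_mask)] *= 2.0 ** enrich_lfc
    abundance[np.ix_(bloom_idx, np.arange(n_samples))] *= compositional_factor[None, :]

    # dropout: high-detection samples keep housekeeping genes (abundant),
    # low-detection samples lose genes indiscriminately
    for s in range(n_samples):
        p = detection_profile[s]
        if p >= 1.0:
            continue
        if p >= 0.5:
            candidates = np.setdiff1d(np.arange(n_genes), hk_idx)
        else:
            candidates = np.arange(n_genes)
        n_drop = int(round((1 - p) * n_genes))
        n_drop = min(n_drop, len(candidates))
        drop = rng.choice(candidates, size=n_drop, replace=False)
        abundance[drop, s] = 0.0

    colsum = abundance.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("a sample lost all genes; lower dropout")
    tpm = abundance / colsum * 1e6
    tpm_df = pd.DataFrame(tpm, index=genes, columns=samples)
    tpm_df.index.name = "gene_id"
    meta_df = pd.DataFrame(
        {"sample": samples, "size_fraction": fractions, "station": stations}
    )
    ann = pd.Series(annotations, name="annotation")
    ann.index.name = "gene_id"
    return tpm_df, meta_df, ann, truth
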