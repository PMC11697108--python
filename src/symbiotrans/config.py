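"""Pipeline configuration: every numeric threshold used by any stage.

Defaults follow the study design: an absolute log2 fold-change cutoff of 2
with BH-adjusted p < 0.05 for differential expression, a per-condition
replicate-sum of normalized counts > 10 to call a gene expressed, a
transmembrane consensus of at least two domains with the two predictors
disagreeing by at most two, a subfamily HMM E-value ceiling of 1e-23, a
Deeploc-style localization score > 0.5 with at least two agreeing tools,
a 20% transcriptome-detection floor for metatranscriptome samples,
housekeeping stability cutoffs CV < 200 (percent) and fold-change from the
mean < 2 with a correlation floor r > 0.5, and a two-fold dark-response cut.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

TRANSPORTER_KEYWORDS = [
    "carrier",
    "transport",
    "channel",
    "permease",
    "symporter",
    "exchanger",
    "antiporter",
    "periplasmic",
    "facilitator",
]

# "disaccahride" is kept verbatim from the upstream curation alongside the
# corrected spelling; both are matched. "ose" is a token-suffix pattern.
SUGAR_KEYWORDS = [
    "disaccahride",
    "disaccharide",
    "carbohydrate",
    "sugar",
    "ose",
    "saccharide",
    "glucose",
    "polysaccharide",
]

# Pfam families of sugar transporters considered "core": a protein carrying
# one of these domains is a sugar transporter regardless of its description.
CORE_SUGAR_PFAMS = [
    "PF00083",  # sugar (and other) transporter / sugar porter
    "PF03083",  # SWEET
    "PF03151",  # triose-phosphate transporter (TPT)
    "PF04142",  # nucleotide-sugar transporter (NST)
    "PF07690",  # major facilitator superfamily (MFS)
    "PF00230",  # major intrinsic protein (aquaporin / GlpF)
    "PF13347",  # MFS/sugar transport protein
    "PF00474",  # sodium/glucose cotransporter
]

HOUSEKEEPING_PATTERNS = [
    "ribosomal protein",
    "tubulin",
    "actin",
    "ATP synthase",
    "elongation factor",
    "histone",
    "ubiquitin",
    "GAPDH",
]


@dataclass
class PipelineConfig:
    """All stage thresholds plus seed and keyword lists.

    Serializes losslessly to/from YAML via :meth:`to_yaml` / :meth:`from_yaml`.
    """

    # differential expression
    lfc_min: float = 2.0
    alpha: float = 0.05
    expressed_threshold: float = 10.0
    pseudocount: float = 0.5
    dispersion_floor: float = 1e-8
    # transporter catalog
    tm_min: int = 2
    tm_diff_max: int = 2
    subfamily_evalue: float = 1e-23
    deeploc_min: float = 0.5
    deeploc_strict_and: bool = False
    keyword_token_mode: bool = True
    # metatranscriptome ratios
    min_detect: float = 0.2
    cv_max: float = 200.0
    fc_max: float = 2.0
    r_min: float = 0.5
    k: int = 8
    fraction_mean_detected_only: bool = False
    # temporal dynamics
    fc_cut_dark: float = 2.0
    dark_fc_log2: bool = False
    # shared
    seed: int = 0
    transporter_keywords: list[str] = field(
        default_factory=lambda: list(TRANSPORTER_KEYWORDS)
    )
    sugar_keywords: list[str] = field(default_factory=lambda: list(SUGAR_KEYWORDS))
    core_sugar_pfams: list[str] = field(
        default_factory=lambda: list(CORE_SUGAR_PFAMS)
    )
    housekeeping_patterns: list[str] = field(
        default_factory=lambda: list(HOUSEKEEPING_PATTERNS)
    )
    compartment_map_path: str | None = None

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.tm_min < 0 or self.tm_diff_max < 0:
            raise ValueError("TM thresholds must be non-negative")
        if self.subfamily_evalue <= 0:
            raise ValueError("subfamily_evalue must be > 0")
        if not 0 <= self.deeploc_min <= 1:
            raise ValueError("deeploc_min must be in [0,1]")
        if not 0 <= self.min_detect <= 1:
            raise ValueError("min_detect must be in [0,1]")
        if self.cv_max <= 0 or self.fc_max < 1:
            raise ValueError("stability thresholds out of range")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must be in [-1,1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.fc_cut_dark <= 0:
            raise ValueError("fc_cut_dark must be > 0")
        if not self.transporter_keywords:
            raise ValueError("transporter keyword list must be non-empty")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
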