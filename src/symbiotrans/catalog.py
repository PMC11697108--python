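"""Consensus transporter and sugar-transporter cataloguing.

Merges multi-tool annotation hit tables into per-protein records, flags
transporters and sugar transporters by curated keyword lists and core sugar
Pfam domains, assigns sugar-porter/MFS subfamilies from HMM hits under a
stringent E-value ceiling, applies a two-predictor transmembrane-domain
consensus filter, and harmonizes five-tool subcellular localization votes.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from symbiotrans.config import (
    CORE_SUGAR_PFAMS,
    SUGAR_KEYWORDS,
    TRANSPORTER_KEYWORDS,
)

log = logging.getLogger("symbiotrans")

#: Pfam families whose members are eligible for subfamily assignment
SUBFAMILY_PARENT_PFAMS = {"PF00083", "PF07690"}

#: InterPro subfamily domains used in the HMM-search refinement
SUBFAMILY_LABELS = {
    "IPR002439": "GLUT",
    "IPR044775": "ERD6/Tret1",
    "IPR045262": "STP/PLT",
    "IPR044740": "SLC37",
}

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def default_compartment_map() -> dict[str, str]:
    """The shipped raw-label -> harmonized-compartment mapping."""
    text = resources.files("symbiotrans.data").joinpath("compartments.yaml").read_text()
    return {str(k).lower(): v for k, v in yaml.safe_load(text).items()}


def load_compartment_map(path: str | Path) -> dict[str, str]:
    return {str(k).lower(): v for k, v in yaml.safe_load(Path(path).read_text()).items()}


# --- annotation merging -------------------------------------------------------

def merge_annotations(hits: pd.DataFrame) -> pd.DataFrame:
    """Merge long-format annotation hits into one record per protein.

    Duplicate (protein, source, accession) rows with different scores keep
    the best (smallest) E-value, with a warning. Returns a frame indexed by
    protein_id with columns ``descriptions`` (list), ``accessions``
    (dict accession -> best E-value).
    """
    required = {"protein_id", "source", "accession", "description", "evalue"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    if len(hits) == 0:
        return pd.DataFrame(columns=["descriptions", "accessions"]).rename_axis(
            "protein_id"
        )
    if (hits["evalue"] < 0).any():
        raise ValueError("negative E-values in hit table")
    if hits["protein_id"].astype(str).str.len().eq(0).any():
        raise ValueError("empty protein_id in hit table")

    dup = hits.duplicated(["protein_id", "source", "accession"], keep=False)
    if dup.any():
        n_conflict = (
            hits[dup]
            .groupby(["protein_id", "source", "accession"])["evalue"]
            .nunique()
            .gt(1)
            .sum()
        )
        if n_conflict:
            log.warning(
                "%d (protein, source, accession) groups with conflicting scores; "
                "keeping best E-value",
                n_conflict,
            )
    best = hits.sort_values("evalue", kind="stable").drop_duplicates(
        ["protein_id", "source", "accession"], keep="first"
    )

    records = {}
    for pid, grp in best.groupby("protein_id", sort=True):
        acc_best = grp.groupby("accession")["evalue"].min().to_dict()
        records[pid] = {
            "descriptions": sorted(set(grp["description"].astype(str))),
            "accessions": acc_best,
        }
    merged = pd.DataFrame.from_dict(records, orient="index")
    merged.index.name = "protein_id"
    return merged


# --- keyword flagging ---------------------------------------------------------

def _match_keyword(text: str, keyword: str, token_mode: bool) -> bool:
    """Case-insensitive keyword match.

    ``"ose"`` is always a token-suffix pattern (tokens of >= 4 letters ending
    in "ose", so "triose" and "glucose" match but "permease" does not). Other
    keywords match as substrings of alphanumeric tokens in token mode, or as
    bare substrings of the whole description otherwise.
    """
    text_l = text.lower()
    kw = keyword.lower()
    if kw == "ose":
        return any(
            len(tok) >= 4 and tok.endswith("ose") for tok in _TOKEN_RE.findall(text_l)
        )
    if token_mode:
        return any(kw in tok for tok in _TOKEN_RE.findall(text_l))
    return kw in text_l


def _any_match(descriptions: list[str], keywords: list[str], token_mode: bool) -> bool:
    return any(
        _match_keyword(d, kw, token_mode) for d in descriptions for kw in keywords
    )


def flag_transporters(
    merged: pd.DataFrame,
    keywords: list[str] | None = None,
    token_mode: bool = True,
) -> pd.Series:
    """True for proteins whose any description matches any transporter keyword."""
    if keywords is not None and len(keywords) == 0:
        raise ValueError("keyword list must be non-empty")
    keywords = keywords or TRANSPORTER_KEYWORDS
    return pd.Series(
        {
            pid: _any_match(row["descriptions"], keywords, token_mode)
            for pid, row in merged.iterrows()
        },
        dtype=bool,
        name="is_transporter",
    ).reindex(merged.index, fill_value=False)


def flag_sugar_transporters(
    merged: pd.DataFrame,
    is_transporter: pd.Series,
    sugar_keywords: list[str] | None = None,
    core_pfams: list[str] | None = None,
    token_mode: bool = True,
) -> pd.Series:
    """True for sugar transporters.

    Evaluated on proteins flagged as transporters or carrying a core sugar
    Pfam; true iff a sugar keyword matches or a core sugar Pfam is present.
    """
    sugar_keywords = sugar_keywords or SUGAR_KEYWORDS
    core = set(core_pfams or CORE_SUGAR_PFAMS)
    out = {}
    for pid, row in merged.iterrows():
        has_core = bool(core & set(row["accessions"]))
        if not (bool(is_transporter.get(pid, False)) or has_core):
            out[pid] = False
            continue
        out[pid] = has_core or _any_match(row["descriptions"], sugar_keywords, token_mode)
    return pd.Series(out, dtype=bool, name="is_sugar_transporter").reindex(
        merged.index, fill_value=False
    )


# --- subfamily assignment -----------------------------------------------------

def assign_subfamily(
    merged: pd.DataFrame,
    subfamily_hits: pd.DataFrame,
    evalue_max: float = 1e-23,
) -> pd.Series:
    """Best-scoring subfamily domain per protein, E <= ``evalue_max``.

    Only members of the sugar-porter (PF00083) and MFS (PF07690) families are
    eligible; hits on other proteins are ignored with a warning. Ties on
    E-value break by lexicographic accession (logged).
    """
    out = pd.Series(index=merged.index, dtype=object, name="subfamily")
    if len(subfamily_hits) == 0:
        return out
    eligible = {
        pid
        for pid, row in merged.iterrows()
        if SUBFAMILY_PARENT_PFAMS & set(row["accessions"])
    }
    for pid, grp in subfamily_hits.groupby("protein_id"):
        if pid not in eligible:
            log.warning(
                "subfamily hit for %s ignored: not a PF00083/PF07690 member", pid
            )
            continue
        passing = grp[grp["evalue"] <= evalue_max]
        if passing.empty:
            continue
        best_e = passing["evalue"].min()
        best = passing[passing["evalue"] == best_e].sort_values("accession")
        if len(best) > 1:
            log.info(
                "subfamily tie for %s at E=%g; keeping %s",
                pid,
                best_e,
                best.iloc[0]["accession"],
            )
        acc = best.iloc[0]["accession"]
        out[pid] = SUBFAMILY_LABELS.get(acc, acc)
    return out


# --- transmembrane consensus --------------------------------------------------

def tm_consensus_filter(
    tm: pd.DataFrame, tm_min: int = 2, tm_diff_max: int = 2
) -> pd.Series:
    """Two-predictor transmembrane consensus.

    Pass iff both predictors report at least ``tm_min`` domains
    (min of the two counts) and their counts differ by at most
    ``tm_diff_max``. Symmetric in the two tools.
    """
    n1 = tm["n_tm_tool1"]
    n2 = tm["n_tm_tool2"]
    if n1.isna().any() or n2.isna().any():
        missing = tm.loc[n1.isna() | n2.isna(), "protein_id"]
        log.warning("%d proteins missing a TM prediction: fail", len(missing))
    if (n1.fillna(0) < 0).any() or (n2.fillna(0) < 0).any():
        raise ValueError("negative TM counts")
    passed = (
        (n1.combine(n2, min) >= tm_min) & ((n1 - n2).abs() <= tm_diff_max)
    ).fillna(False)
    return pd.Series(
        passed.to_numpy(dtype=bool), index=tm["protein_id"], name="tm_pass"
    )


# --- localization consensus ---------------------------------------------------

def localization_consensus(
    preds: pd.DataFrame,
    vocab_map: dict[str, str] | None = None,
    deeploc_tool: str = "deeploc",
    deeploc_min: float = 0.5,
    strict_and: bool = False,
) -> pd.Series:
    """Harmonized compartment per protein from five-tool votes.

    A compartment is assigned when it holds a strict plurality with at least
    two votes. When the Deeploc-role tool is among the winning voters its
    score must additionally exceed ``deeploc_min``. With ``strict_and`` the
    Deeploc-role tool must itself vote for the winner with a passing score.
    Ties between top compartments each holding >= 2 votes give "unassigned"
    (logged). Unmapped raw labels raise.
    """
    vocab_map = vocab_map or default_compartment_map()
    out = {}
    for pid, grp in preds.groupby("protein_id"):
        votes: dict[str, list[str]] = {}
        deeploc_comp, deeploc_score = None, None
        for _, row in grp.iterrows():
            raw = str(row["raw_label"]).strip().lower()
            if raw not in vocab_map:
                raise ValueError(f"unmapped localization label {row['raw_label']!r}")
            comp = vocab_map[raw]
            votes.setdefault(comp, []).append(row["tool"])
            if row["tool"] == deeploc_tool:
                deeploc_comp = comp
                s = row.get("score")
                deeploc_score = float(s) if s not in ("", None) and pd.notna(s) else None
        counts = {c: len(t) for c, t in votes.items()}
        top = max(counts.values())
        winners = [c for c, n in counts.items() if n == top]
        if top < 2:
            out[pid] = "unassigned"
            continue
        if len(winners) > 1:
            log.info("localization tie for %s between %s", pid, sorted(winners))
            out[pid] = "unassigned"
            continue
        winner = winners[0]
        deeploc_ok = (
            deeploc_comp == winner
            and deeploc_score is not None
            and deeploc_score > deeploc_min
        )
        if strict_and:
            out[pid] = winner if deeploc_ok else "unassigned"
        else:
            if deeploc_comp == winner and not deeploc_ok:
                # Deeploc votes for the winner but too weakly: need two other tools
                n_other = top - 1
                out[pid] = winner if n_other >= 2 else "unassigned"
            else:
                out[pid] = winner
    return pd.Series(out, dtype=object, name="localization")


# --- catalog assembly ---------------------------------------------------------

def _pfam_family(accessions: dict[str, float], core: set[str]) -> str | None:
    """Best core sugar Pfam if any, else best Pfam accession overall."""
    pfams = {a: e for a, e in accessions.items() if a.startswith("PF")}
    core_hits = {a: e for a, e in pfams.items() if a in core}
    pool = core_hits or pfams
    if not pool:
        return None
    return min(pool.items(), key=lambda kv: (kv[1], kv[0]))[0]


def build_catalog(
    hits: pd.DataFrame,
    tm: pd.DataFrame | None = None,
    localizations: pd.DataFrame | None = None,
    subfamily_hits: pd.DataFrame | None = None,
    keywords: list[str] | None = None,
    sugar_keywords: list[str] | None = None,
    core_pfams: list[str] | None = None,
    vocab_map: dict[str, str] | None = None,
    token_mode: bool = True,
    tm_min: int = 2,
    tm_diff_max: int = 2,
    subfamily_evalue: float = 1e-23,
    deeploc_min: float = 0.5,
    strict_and: bool = False,
    id_mismatch_tol: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the consensus catalog and its per-Pfam summary.

    Aborts when the fraction of TM/localization protein ids absent from the
    annotation table exceeds ``id_mismatch_tol``.
    """
    core = set(core_pfams or CORE_SUGAR_PFAMS)
    merged = merge_annotations(hits)
    known = set(merged.index)
    for name, tbl in (("tm", tm), ("localization", localizations)):
        if tbl is not None and len(tbl) and known:
            ids = set(tbl["protein_id"])
            mismatch = len(ids - known) / max(1, len(ids))
            if mismatch > id_mismatch_tol:
                raise ValueError(
                    f"{name} table: {mismatch:.1%} of protein ids unknown to the "
                    f"annotation table (tolerance {id_mismatch_tol:.1%})"
                )

    is_tr = flag_transporters(merged, keywords, token_mode)
    is_sugar = flag_sugar_transporters(
        merged, is_tr, sugar_keywords, core_pfams, token_mode
    )
    is_tr = is_tr | is_sugar  # core-Pfam sugar carriers are transporters
    subfam = (
        assign_subfamily(merged, subfamily_hits, subfamily_evalue)
        if subfamily_hits is not None
        else pd.Series(index=merged.index, dtype=object)
    )
    tm_pass = (
        tm_consensus_filter(tm, tm_min, tm_diff_max).reindex(merged.index)
        if tm is not None
        else pd.Series(index=merged.index, dtype=object)
    ).fillna(False)
    loc = (
        localization_consensus(
            localizations, vocab_map, deeploc_min=deeploc_min, strict_and=strict_and
        ).reindex(merged.index)
        if localizations is not None
        else pd.Series(index=merged.index, dtype=object)
    ).fillna("unassigned")

    catalog = pd.DataFrame(
        {
            "is_transporter": is_tr,
            "is_sugar_transporter": is_sugar,
            "pfam_family": [
                _pfam_family(row["accessions"], core) for _, row in merged.iterrows()
            ],
            "subfamily": subfam,
            "tm_pass": tm_pass.astype(bool),
            "localization": loc,
        },
        index=merged.index,
    )
    catalog.index.name = "protein_id"

    sugar = catalog[catalog["is_sugar_transporter"]]
    per_pfam = (
        sugar["pfam_family"].dropna().value_counts().sort_index().to_dict()
    )
    loc_counts = catalog.loc[catalog["is_transporter"], "localization"].value_counts()
    total_tr = int(catalog["is_transporter"].sum())
    summary = {
        "n_proteins": int(len(catalog)),
        "n_transporters": total_tr,
        "n_sugar_transporters": int(catalog["is_sugar_transporter"].sum()),
        "sugar_genes_per_pfam": per_pfam,
        "transporter_localization_proportions": (
            {c: n / total_tr for c, n in loc_counts.items()} if total_tr else {}
        ),
        "n_tm_pass": int(catalog["tm_pass"].sum()),
    }
    return catalog, summary
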