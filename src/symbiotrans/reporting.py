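"""Summary bookkeeping: per-Pfam class-count tables and headline percentages."""

from __future__ import annotations

import decimal

import pandas as pd

DE_CLASSES = ["down", "neutral", "up"]


def percent(numerator: int, denominator: int, digits: int = 0) -> float:
    """100 * numerator / denominator rounded half-up to ``digits`` decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    value = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    q = decimal.Decimal(1).scaleb(-digits)
    return float(value.quantize(q, rounding=decimal.ROUND_HALF_UP))


def per_pfam_class_counts(
    catalog: pd.DataFrame, de_results: pd.DataFrame
) -> pd.DataFrame:
    """Per-Pfam counts of sugar-transporter genes in each expression class.

    Rows are Pfam families (genes missing from the catalog count under
    ``unassigned``); columns down / neutral / up / total with a ``Total``
    row appended. Only genes classified up, down or neutral (i.e. expressed
    in both conditions) enter the table.
    """
    sugar = catalog[catalog["is_sugar_transporter"]] if len(catalog) else catalog
    rows: dict[str, dict[str, int]] = {}
    for gene, r in de_results.iterrows():
        cls = r["class"]
        if cls not in DE_CLASSES:
            continue
        if gene in sugar.index:
            fam = sugar.loc[gene, "pfam_family"]
            fam = fam if isinstance(fam, str) else "unassigned"
        elif gene in catalog.index:
            continue  # not a sugar transporter
        else:
            fam = "unassigned"
        rows.setdefault(fam, {c: 0 for c in DE_CLASSES})[cls] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=DE_CLASSES, fill_value=0
    ).sort_index()
    table = table.fillna(0).astype(int)
    table["total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "pfam_family"
    return table


def headline_summary(
    catalog_summary: dict | None = None,
    de_results: pd.DataFrame | None = None,
    class_counts: pd.DataFrame | None = None,
    temporal: dict | None = None,
    fraction_comparison: pd.DataFrame | None = None,
) -> dict:
    """Joined report across stages; missing stages yield explicit nulls.

    Every percentage is recorded with its numerator and denominator so it
    can be recomputed from the report alone.
    """
    report: dict = {
        "catalog": catalog_summary,
        "differential_expression": None,
        "per_pfam_class_counts": None,
        "temporal": None,
        "fraction_comparison": None,
        "percentages": {},
    }
    if de_results is not None:
        counts = de_results["class"].value_counts().to_dict()
        n_up = int(counts.get("up", 0))
        n_down = int(counts.get("down", 0))
        n_expressed_both = n_up + n_down + int(counts.get("neutral", 0))
        de_block = {
            "class_counts": {k: int(v) for k, v in counts.items()},
            "n_de": n_up + n_down,
            "n_expressed_both": n_expressed_both,
        }
        report["differential_expression"] = de_block
        if n_expressed_both:
            report["percentages"]["de_of_expressed"] = {
                "numerator": n_up + n_down,
                "denominator": n_expressed_both,
                "percent": percent(n_up + n_down, n_expressed_both),
            }
            report["percentages"]["up_of_expressed"] = {
                "numerator": n_up,
                "denominator": n_expressed_both,
                "percent": percent(n_up, n_expressed_both),
            }
            report["percentages"]["down_of_expressed"] = {
                "numerator": n_down,
                "denominator": n_expressed_both,
                "percent": percent(n_down, n_expressed_both),
            }
    if class_counts is not None:
        report["per_pfam_class_counts"] = {
            str(fam): {c: int(v) for c, v in row.items()}
            for fam, row in class_counts.iterrows()
        }
    if temporal is not None:
        dark = temporal["per_gene"]["dark_class"].value_counts().to_dict()
        report["temporal"] = {
            "venn_counts": {k: int(v) for k, v in temporal["venn_counts"].items()},
            "dark_class_counts": {k: int(v) for k, v in dark.items()},
        }
        n_tested = sum(
            int(v) for k, v in dark.items() if k in ("down", "unchanged", "up")
        )
        if n_tested:
            report["percentages"]["dark_downregulated"] = {
                "numerator": int(dark.get("down", 0)),
                "denominator": n_tested,
                "percent": percent(int(dark.get("down", 0)), n_tested),
            }
    if fraction_comparison is not None:
        report["fraction_comparison"] = {
            "n_genes": int(len(fraction_comparison)),
            "n_higher_in_large": int(fraction_comparison["higher_in_large"].sum()),
            "n_undetected_in_a_fraction": int(
                fraction_comparison["undetected_in_fraction"].sum()
            ),
        }
    return report
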