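"""Readers and writers for the pipeline's tabular formats.

All tables are tab-separated text. Writers prepend ``#``-prefixed metadata
lines (effective configuration, stage name); readers skip them. Gene and
protein identifiers are opaque strings.
"""

from __future__ import annotations

import io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("symbiotrans")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein records as ``(id, sequence)`` pairs.

    Duplicate identifiers and empty files are errors.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def _meta_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def write_table(
    path: str | Path, df: pd.DataFrame, metadata: dict | None = None, index: bool = False
) -> None:
    """Write a DataFrame as TSV with optional ``#`` metadata header lines."""
    with open(path, "w") as fh:
        fh.write(_meta_lines(metadata))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_matrix(
    path: str | Path, matrix: pd.DataFrame, metadata: dict | None = None
) -> None:
    """Write a gene x sample matrix: first column gene ids, header sample ids."""
    with open(path, "w") as fh:
        fh.write(_meta_lines(metadata))
        matrix.to_csv(fh, sep="\t", index=True, index_label="gene_id")


def read_matrix(path: str | Path, kind: str = "counts") -> pd.DataFrame:
    """Read a gene x sample matrix.

    ``kind='counts'`` validates non-negative integers; ``kind='tpm'``
    validates non-negative reals. Ragged rows raise.
    """
    if kind not in ("counts", "tpm"):
        raise ValueError(f"kind must be 'counts' or 'tpm', got {kind!r}")
    # manual ragged-row check: pandas would silently fill NaN
    lines = [
        ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty matrix file {path}")
    widths = {len(ln.split("\t")) for ln in lines if ln.strip()}
    if len(widths) != 1:
        raise ValueError(f"ragged rows in {path}: widths {sorted(widths)}")
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    values = df.to_numpy()
    if np.isnan(values).any():
        raise ValueError(f"missing cells in {path}")
    if (values < 0).any():
        raise ValueError(f"negative values in {path}")
    if kind == "counts":
        if not np.allclose(values, np.round(values)):
            raise ValueError(f"non-integer counts in {path}")
        df = df.astype(np.int64)
    return df


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
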