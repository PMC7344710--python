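"""Plain-text readers and writers for the pipeline's tabular formats.

Count matrices are TSV with a ``gene`` first column and sample ids as the
header; labels are TSV with ``sample_id``, ``status`` and an optional
``group`` column; gene pools are one-symbol-per-line text; flow records
are CSV with columns ``cell_line, replicate, mfi_stained, mfi_unstained``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError
from .phenotyping import FlowRecord

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_labels",
    "write_labels",
    "read_gene_pool",
    "write_gene_pool",
    "read_flow_records",
    "write_flow_records",
    "write_size_factors",
    "write_scores",
]


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise InputError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.empty:
        raise InputError(f"count matrix {path} is empty")
    df.index.name = "gene"
    return df


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.DataFrame:
    """Labels table: sample_id, status (positive/negative), optional group."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise InputError(f"cannot parse labels {path}: {exc}") from exc
    required = {"sample_id", "status"}
    if not required.issubset(df.columns):
        raise InputError(
            f"labels {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = set(df["status"]) - {"positive", "negative"}
    if bad:
        raise InputError(f"labels {path}: unknown status value(s) {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise InputError(f"labels {path}: duplicate sample ids")
    return df.set_index("sample_id")


def write_labels(labels: pd.Series, path: str | Path, groups: pd.Series | None = None) -> None:
    df = pd.DataFrame(
        {"status": labels.map({True: "positive", False: "negative"})}
    ).rename_axis("sample_id")
    if groups is not None:
        df["group"] = groups
    df.to_csv(path, sep="\t")


def read_gene_pool(path: str | Path) -> list[str]:
    genes = [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]
    if not genes:
        raise InputError(f"gene pool {path} is empty")
    return genes


def write_gene_pool(genes: list[str] | tuple[str, ...], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_flow_records(path: str | Path) -> list[FlowRecord]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot parse flow CSV {path}: {exc}") from exc
    required = {"cell_line", "replicate", "mfi_stained", "mfi_unstained"}
    if not required.issubset(df.columns):
        raise InputError(f"flow CSV {path} must have columns {sorted(required)}")
    return [
        FlowRecord(
            cell_line=str(row.cell_line),
            replicate=int(row.replicate),
            mfi_stained=float(row.mfi_stained),
            mfi_unstained=float(row.mfi_unstained),
        )
        for row in df.itertuples()
    ]


def write_flow_records(records: list[FlowRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cell_line": r.cell_line,
                "replicate": r.replicate,
                "mfi_stained": r.mfi_stained,
                "mfi_unstained": r.mfi_unstained,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_size_factors(size_factors: pd.Series, path: str | Path) -> None:
    size_factors.rename("size_factor").rename_axis("sample_id").to_csv(path, sep="\t")


def write_scores(scores: pd.Series, path: str | Path) -> None:
    scores.rename("score").rename_axis("sample_id").to_csv(path, sep="\t")
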