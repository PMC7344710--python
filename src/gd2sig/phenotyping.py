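"""Flow-cytometry RFI computation and three-level GD2 phenotype classes.

Relative fluorescence intensity (RFI) is the ratio of antibody-stained to
unstained mean fluorescence for a cell line, averaged over replicates.
Cell lines are binned into GD2-overexpressing (GD2++), GD2-positive (GD2+)
and GD2-negative (GD2-) classes; the binary collapse treats GD2++ and GD2+
as positive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError

__all__ = [
    "FlowRecord",
    "RFIValue",
    "GD2Class",
    "compute_rfi",
    "classify_rfi",
    "phenotype_table",
    "DEFAULT_LOWER_RFI",
    "DEFAULT_UPPER_RFI",
]

#: Class boundaries. Values strictly above the upper bound are GD2++,
#: strictly below the lower bound GD2-; the closed middle interval
#: (boundaries included) is GD2+.
DEFAULT_LOWER_RFI = 1.5
DEFAULT_UPPER_RFI = 10.0


class GD2Class(enum.Enum):
    """Three-level GD2 surface phenotype with a binary collapse."""

    GD2PP = "GD2++"
    GD2P = "GD2+"
    GD2N = "GD2-"

    @property
    def is_positive(self) -> bool:
        """Binary collapse: GD2++ and GD2+ are positive, GD2- negative."""
        return self is not GD2Class.GD2N

    @property
    def rank(self) -> int:
        """Ordinal level: GD2- < GD2+ < GD2++."""
        return {"GD2-": 0, "GD2+": 1, "GD2++": 2}[self.value]


@dataclass(frozen=True)
class FlowRecord:
    """One replicate of a stained/unstained MFI measurement."""

    cell_line: str
    replicate: int
    mfi_stained: float
    mfi_unstained: float

    def __post_init__(self) -> None:
        if self.mfi_stained <= 0 or self.mfi_unstained <= 0:
            raise InputError(
                f"MFI values must be positive (cell line {self.cell_line!r}, "
                f"replicate {self.replicate})"
            )

    @property
    def ratio(self) -> float:
        return self.mfi_stained / self.mfi_unstained


@dataclass(frozen=True)
class RFIValue:
    cell_line: str
    rfi: float

    def __post_init__(self) -> None:
        if self.rfi <= 0:
            raise InputError(f"RFI must be positive, got {self.rfi}")


def compute_rfi(records: Sequence[FlowRecord]) -> RFIValue:
    """Aggregate one cell line's replicates to its RFI.

    The RFI is the mean over replicates of the per-replicate
    stained/unstained ratio (mean of ratios, not ratio of means).
    """
    if not records:
        raise InputError("compute_rfi requires at least one record")
    names = {r.cell_line for r in records}
    if len(names) != 1:
        raise InputError(f"records mix cell lines: {sorted(names)}")
    rfi = sum(r.ratio for r in records) / len(records)
    return RFIValue(cell_line=records[0].cell_line, rfi=rfi)


def classify_rfi(
    value: RFIValue,
    *,
    lower: float = DEFAULT_LOWER_RFI,
    upper: float = DEFAULT_UPPER_RFI,
) -> GD2Class:
    """Map an RFI to its three-level class.

    ``rfi > upper`` is GD2++, ``rfi < lower`` is GD2-, and the closed
    interval ``[lower, upper]`` (boundary values included) is GD2+.
    """
    if not 0 < lower < upper:
        raise InputError(f"require 0 < lower < upper, got {lower}, {upper}")
    if value.rfi > upper:
        return GD2Class.GD2PP
    if value.rfi < lower:
        return GD2Class.GD2N
    return GD2Class.GD2P


def phenotype_table(
    records: Iterable[FlowRecord],
    *,
    lower: float = DEFAULT_LOWER_RFI,
    upper: float = DEFAULT_UPPER_RFI,
) -> pd.DataFrame:
    """Per-cell-line phenotype summary (rfi, class, binary status).

    Cell lines appear in order of first occurrence in ``records``.
    """
    by_line: dict[str, list[FlowRecord]] = {}
    for rec in records:
        by_line.setdefault(rec.cell_line, []).append(rec)
    if not by_line:
        raise InputError("no flow records supplied")
    rows = []
    for name, recs in by_line.items():
        value = compute_rfi(recs)
        cls = classify_rfi(value, lower=lower, upper=upper)
        rows.append(
            {
                "cell_line": name,
                "rfi": value.rfi,
                "gd2_class": cls.value,
                "binary_status": "positive" if cls.is_positive else "negative",
            }
        )
    return pd.DataFrame(rows).set_index("cell_line")
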