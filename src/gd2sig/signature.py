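"""Additive log10 gene signatures over the ganglioside-synthesis panel.

A signature is an ordered set of (gene, sign) terms; its score for a sample
is the signed sum of that sample's log10 expression values. The six-gene
panel carries a fixed sign convention: genes catalyzing GD2-consuming steps
(ST8SIA5, B3GALT4) enter with a minus sign, all others with a plus sign.
The flagship signature is ST8SIA1+B4GALNT1.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import DegenerateDataError, InputError
from .phenotyping import GD2Class

__all__ = [
    "GenePanel",
    "SignatureSpec",
    "GANGLIOSIDE_PANEL",
    "FLAGSHIP_SIGNATURE",
    "score_signature",
    "enumerate_pair_signatures",
    "check_congruence",
    "check_three_level_congruence",
    "parse_signature_name",
]


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene symbols with their pathway-direction signs (+1 or -1)."""

    terms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.terms]
        if len(set(genes)) != len(genes):
            raise InputError("panel genes must be distinct")
        if any(s not in (1, -1) for _, s in self.terms):
            raise InputError("panel signs must be +1 or -1")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.terms)

    def sign(self, gene: str) -> int:
        for g, s in self.terms:
            if g == gene:
                return s
        raise KeyError(gene)


#: The six ganglioside-biosynthesis genes with their pathway directions:
#: ST8SIA5 and B3GALT4 catalyze GD2-consuming steps and carry sign -1.
GANGLIOSIDE_PANEL = GenePanel(
    terms=(
        ("ST3GAL5", 1),
        ("ST8SIA1", 1),
        ("ST8SIA5", -1),
        ("B3GALT4", -1),
        ("B4GALNT1", 1),
        ("B4GALT6", 1),
    )
)


@dataclass(frozen=True)
class SignatureSpec:
    """An additive log10 signature: ordered (gene, sign) terms.

    The canonical name is a pure function of the (ordered) terms:
    positively signed genes first, then negatively signed ones, each in
    term order and joined by their sign symbols, e.g.
    ``ST8SIA1+B4GALNT1`` or ``B4GALT6-B3GALT4``.
    """

    terms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.terms]
        if not genes:
            raise InputError("signature must have at least one term")
        if len(set(genes)) != len(genes):
            raise InputError(f"signature genes must be distinct: {genes}")
        if any(s not in (1, -1) for _, s in self.terms):
            raise InputError("signature signs must be +1 or -1")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.terms)

    @property
    def name(self) -> str:
        pos = [g for g, s in self.terms if s == 1]
        neg = [g for g, s in self.terms if s == -1]
        parts = [f"+{g}" for g in pos] + [f"-{g}" for g in neg]
        joined = "".join(parts)
        return joined[1:] if joined.startswith("+") else joined

    def to_json(self) -> str:
        return json.dumps({"terms": [[g, s] for g, s in self.terms]})

    @classmethod
    def from_json(cls, text: str) -> "SignatureSpec":
        payload = json.loads(text)
        return cls(terms=tuple((str(g), int(s)) for g, s in payload["terms"]))


def parse_signature_name(name: str) -> SignatureSpec:
    """Parse a canonical signature string like ``ST8SIA1+B4GALNT1`` or
    ``B4GALT6-B3GALT4`` back into a spec."""
    terms: list[tuple[str, int]] = []
    token = ""
    sign = 1
    for ch in name:
        if ch in "+-":
            if token:
                terms.append((token, sign))
            token = ""
            sign = 1 if ch == "+" else -1
        else:
            token += ch
    if token:
        terms.append((token, sign))
    if not terms:
        raise InputError(f"cannot parse signature name {name!r}")
    return SignatureSpec(terms=tuple(terms))


#: The ST8SIA1 + B4GALNT1 signature (both signs +1).
FLAGSHIP_SIGNATURE = SignatureSpec(terms=(("ST8SIA1", 1), ("B4GALNT1", 1)))


def score_signature(logexpr: pd.DataFrame, spec: SignatureSpec) -> pd.Series:
    """Score every sample: signed sum of the signature genes' log10 values.

    Parameters
    ----------
    logexpr
        Genes x samples matrix of log10-transformed normalized expression.
    spec
        The signature to score. A single-gene spec returns that gene's
        (signed) log-expression row.
    """
    missing = [g for g in spec.genes if g not in logexpr.index]
    if missing:
        raise InputError(f"signature gene(s) absent from matrix: {missing}")
    score = sum(sign * logexpr.loc[gene] for gene, sign in spec.terms)
    score.name = spec.name
    return score


def enumerate_pair_signatures(panel: GenePanel) -> list[SignatureSpec]:
    """All unordered 2-gene signatures over the panel, signs from the panel.

    Terms within a spec keep the panel's gene order (so the flagship pair
    reads ``ST8SIA1+B4GALNT1``); the returned list is sorted
    lexicographically by gene pair. A six-gene panel yields C(6,2) = 15
    specs.
    """
    specs = [
        SignatureSpec(terms=((a, panel.sign(a)), (b, panel.sign(b))))
        for a, b in itertools.combinations(panel.genes, 2)
    ]
    return sorted(specs, key=lambda s: tuple(sorted(s.genes)))


def _split_binary(
    scores: pd.Series, status: Mapping[str, bool]
) -> tuple[list[float], list[float]]:
    pos, neg = [], []
    for sample, value in scores.items():
        if sample not in status:
            raise InputError(f"sample {sample!r} has no status")
        (pos if status[sample] else neg).append(float(value))
    return pos, neg


def check_congruence(scores: pd.Series, status: Mapping[str, bool]) -> bool:
    """True iff every positive sample scores strictly above every negative one.

    Ties across the class boundary fail.
    """
    pos, neg = _split_binary(scores, status)
    if not pos or not neg:
        raise DegenerateDataError("both GD2 statuses must be present")
    return min(pos) > max(neg)


def check_three_level_congruence(
    scores: pd.Series, classes: Mapping[str, GD2Class]
) -> bool:
    """True iff scores strictly order GD2++ above GD2+ above GD2-.

    Requires all three classes present; boundary ties fail.
    """
    buckets: dict[GD2Class, list[float]] = {c: [] for c in GD2Class}
    for sample, value in scores.items():
        if sample not in classes:
            raise InputError(f"sample {sample!r} has no GD2 class")
        buckets[classes[sample]].append(float(value))
    if any(not v for v in buckets.values()):
        empty = [c.value for c, v in buckets.items() if not v]
        raise DegenerateDataError(f"empty GD2 class(es): {empty}")
    return (
        min(buckets[GD2Class.GD2PP]) > max(buckets[GD2Class.GD2P])
        and min(buckets[GD2Class.GD2P]) > max(buckets[GD2Class.GD2N])
    )
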