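"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity from its literal definition with
different machinery (the statistics module, Fractions, Pearson correlation)
so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import statistics
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd


def size_factors_oracle(counts: pd.DataFrame) -> dict[str, float]:
    """Literal median-of-ratios: reference genes are those positive in every
    sample; each sample's factor is the median count/geometric-mean ratio."""
    reference = [g for g in counts.index if (counts.loc[g] > 0).all()]
    assert reference, "oracle requires at least one all-positive gene"
    geo = {
        g: statistics.geometric_mean([float(v) for v in counts.loc[g]])
        for g in reference
    }
    return {
        s: statistics.median(float(counts.loc[g, s]) / geo[g] for g in reference)
        for s in counts.columns
    }


def mcc_oracle(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC as the Pearson correlation between expanded binary vectors
    (0 when either vector is constant)."""
    y_true = [1] * tp + [1] * fn + [0] * tn + [0] * fp
    y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    if len(y_true) < 2 or len(set(y_true)) < 2 or len(set(y_pred)) < 2:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(y_true, y_pred)[0, 1]
    return 0.0 if np.isnan(r) else float(r)


def equal_error_oracle(x, y):
    """Exhaustive equal-error threshold search in exact rational arithmetic.

    Candidates are midpoints between consecutive distinct sorted scores plus
    +/-infinity; selection minimizes |FPR - FNR|, ties broken by maximal MCC
    (compared via the exact key num*|num|/denom) and then by the smaller
    threshold. Returns (threshold, (tp, fp, tn, fn)).
    """
    x = [float(v) for v in x]
    y = [bool(v) for v in y]
    n_pos = sum(y)
    n_neg = len(y) - n_pos
    assert n_pos > 0 and n_neg > 0
    distinct = sorted(set(x))
    assert len(distinct) > 1, "degenerate (all-identical) scores"
    candidates = (
        [float("-inf")]
        + [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
        + [float("inf")]
    )
    best_key = None
    best = None
    for t in candidates:
        tp = sum(1 for xi, yi in zip(x, y) if yi and xi >= t)
        fp = sum(1 for xi, yi in zip(x, y) if not yi and xi >= t)
        fn = n_pos - tp
        tn = n_neg - fp
        diff = abs(Fraction(fp, n_neg) - Fraction(fn, n_pos))
        num = tp * tn - fp * fn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc_key = Fraction(num * abs(num), denom) if denom > 0 else Fraction(0)
        key = (diff, -mcc_key, t)
        if best_key is None or key < best_key:
            best_key = key
            best = (t, (tp, fp, tn, fn))
    return best


def confusion_matrices_up_to(total: int):
    """Every (tp, fp, tn, fn) with 1 <= tp+fp+tn+fn <= total."""
    for tp in range(total + 1):
        for fp in range(total + 1 - tp):
            for tn in range(total + 1 - tp - fp):
                for fn in range(total + 1 - tp - fp - tn):
                    if tp + fp + tn + fn > 0:
                        yield tp, fp, tn, fn
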