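"""Binary classification of continuous scores at the equal-error-rate point.

A predictor score is turned into calls via "positive iff score >= threshold",
with the threshold chosen among midpoints between consecutive distinct
scores (plus +/-infinity) to minimize |FPR - FNR|; ties are broken by
maximal MCC and then by the smaller threshold. Performance is the Matthews
Correlation Coefficient at that threshold. Two significance machineries are
provided: a label-permutation p-value per predictor (add-one estimator) and
an empirical null built from random same-sign gene pairs, whose p-value is
the plain strictly-greater frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError
from .signature import GenePanel, SignatureSpec, score_signature

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "NullDistribution",
    "mcc_from_counts",
    "equal_error_threshold",
    "evaluate_predictor",
    "random_pair_null",
    "evaluate_panel",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvaluationResult:
    """One predictor's performance on one labelled cohort."""

    predictor: str
    threshold: float
    confusion: ConfusionCounts
    mcc: float
    p_perm: float
    n_perm: int
    degenerate: bool = False


@dataclass(frozen=True)
class NullDistribution:
    """Empirical MCC null from random gene pairs.

    ``p_value`` is the fraction of null MCCs strictly greater than the
    observed MCC (no add-one correction).
    """

    null_mccs: tuple[float, ...]
    observed_mcc: float
    p_value: float
    n_pairs: int
    seed: int
    observed_name: str = ""
    pairs: tuple[tuple[str, str], ...] = field(default=(), repr=False)


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient from a confusion matrix.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; defined as 0
    when any marginal is empty (continuity convention).
    """
    if c.total == 0:
        raise InputError("cannot compute MCC of an empty confusion matrix")
    num = c.tp * c.tn - c.fp * c.fn
    denom_sq = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom_sq == 0:
        return 0.0
    return num / math.sqrt(denom_sq)


def _as_aligned_arrays(
    scores: pd.Series, labels: Mapping[str, bool] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    missing = [s for s in scores.index if s not in labels]
    if missing:
        raise InputError(f"sample(s) without label: {missing[:5]}")
    y = np.array([bool(labels[s]) for s in scores.index])
    x = scores.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise InputError("scores must be finite")
    if y.all() or not y.any():
        raise DegenerateDataError("both label classes must be nonempty")
    return x, y


def _scan_thresholds(x: np.ndarray, y: np.ndarray) -> tuple[float, ConfusionCounts, float, bool]:
    """Pick the equal-error threshold for "positive iff score >= t".

    Candidates are the midpoints between consecutive distinct sorted scores
    plus +/-infinity. Selection minimizes |FPR - FNR|, breaking ties by
    maximal MCC and then the smaller threshold; the comparisons are done in
    exact integer arithmetic so tie-breaking is reproducible. All-identical
    scores are degenerate: the common value is returned (all predicted
    positive) with the degenerate flag set.
    """
    u, inv = np.unique(x, return_inverse=True)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    pos_at = np.bincount(inv[y], minlength=u.size)
    neg_at = np.bincount(inv[~y], minlength=u.size)

    if u.size == 1:
        conf = ConfusionCounts(tp=n_pos, fp=n_neg, tn=0, fn=0)
        return float(u[0]), conf, mcc_from_counts(conf), True

    # Candidate k predicts positive exactly the scores >= u[k] (k = 0 is
    # -inf / all positive; k = u.size is +inf / all negative).
    cum_pos = np.concatenate(([0], np.cumsum(pos_at)))
    cum_neg = np.concatenate(([0], np.cumsum(neg_at)))
    tp = n_pos - cum_pos
    fp = n_neg - cum_neg
    fn = cum_pos
    tn = cum_neg

    # |FPR - FNR| = |fp*n_pos - fn*n_neg| / (n_pos*n_neg): compare numerators.
    diff = np.abs(fp.astype(np.int64) * n_pos - fn.astype(np.int64) * n_neg)
    best = np.flatnonzero(diff == diff.min())

    if best.size > 1:
        # Exact MCC comparison: MCC is strictly increasing in
        # num*|num|/denom_sq, compared by integer cross-multiplication.
        def mcc_key(k: int) -> tuple[int, int]:
            num = int(tp[k]) * int(tn[k]) - int(fp[k]) * int(fn[k])
            d = (
                (int(tp[k]) + int(fp[k]))
                * (int(tp[k]) + int(fn[k]))
                * (int(tn[k]) + int(fp[k]))
                * (int(tn[k]) + int(fn[k]))
            )
            return (num * abs(num), d) if d > 0 else (0, 1)

        def better(a: int, b: int) -> bool:
            na, da = mcc_key(a)
            nb, db = mcc_key(b)
            if na * db != nb * da:
                return na * db > nb * da
            return a < b  # smaller index = smaller threshold

        chosen = best[0]
        for k in best[1:]:
            if better(int(k), int(chosen)):
                chosen = int(k)
    else:
        chosen = int(best[0])

    if chosen == 0:
        threshold = -math.inf
    elif chosen == u.size:
        threshold = math.inf
    else:
        threshold = float((u[chosen - 1] + u[chosen]) / 2.0)
    conf = ConfusionCounts(
        tp=int(tp[chosen]), fp=int(fp[chosen]), tn=int(tn[chosen]), fn=int(fn[chosen])
    )
    return threshold, conf, mcc_from_counts(conf), False


def equal_error_threshold(
    scores: pd.Series, labels: Mapping[str, bool] | pd.Series
) -> float:
    """Equal-error-rate decision threshold for "positive iff score >= t"."""
    x, y = _as_aligned_arrays(scores, labels)
    threshold, _, _, _ = _scan_thresholds(x, y)
    return threshold


def evaluate_predictor(
    scores: pd.Series,
    labels: Mapping[str, bool] | pd.Series,
    *,
    n_perm: int = 999,
    seed: int = 0,
    name: str | None = None,
) -> EvaluationResult:
    """Threshold, confusion, MCC and label-permutation p-value for one predictor.

    Each permutation shuffles the labels, re-runs the threshold search from
    scratch and records the resulting MCC; the p-value is the add-one
    estimator ``(1 + #{perm MCC >= observed}) / (1 + n_perm)``, so it can
    never be exactly 0. With ``n_perm=0`` the p-value is 1.
    """
    if n_perm < 0:
        raise InputError("n_perm must be >= 0")
    x, y = _as_aligned_arrays(scores, labels)
    threshold, conf, mcc, degenerate = _scan_thresholds(x, y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        _, _, perm_mcc, _ = _scan_thresholds(x, perm)
        if perm_mcc >= mcc:
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_perm)
    return EvaluationResult(
        predictor=name if name is not None else (scores.name or "predictor"),
        threshold=threshold,
        confusion=conf,
        mcc=mcc,
        p_perm=p_perm,
        n_perm=n_perm,
        degenerate=degenerate,
    )


def random_pair_null(
    logexpr: pd.DataFrame,
    labels: Mapping[str, bool] | pd.Series,
    pool: Sequence[str],
    *,
    n_pairs: int = 1000,
    seed: int = 0,
    observed: SignatureSpec,
) -> NullDistribution:
    """Empirical MCC null from random 2-gene sums over a gene pool.

    Draws ``n_pairs`` pairs of distinct pool genes (both signs +1), scores
    each as the sum of the two log10 rows, evaluates the MCC at the
    equal-error threshold, and reports
    ``p = #{null MCC > observed MCC} / n_pairs`` (strictly greater).

    Pool genes absent from the matrix are dropped with a warning; fewer
    than two remaining is fatal. Pairs are drawn independently, so the same
    pair may recur across draws.
    """
    if n_pairs < 1:
        raise InputError("n_pairs must be >= 1")
    present = [g for g in dict.fromkeys(pool) if g in logexpr.index]
    dropped = len(set(pool)) - len(present)
    if dropped:
        logger.warning("dropping %d pool gene(s) absent from the matrix", dropped)
    if len(present) < 2:
        raise DegenerateDataError(
            "fewer than 2 pool genes present in the expression matrix"
        )

    obs_scores = score_signature(logexpr, observed)
    x_obs, y = _as_aligned_arrays(obs_scores, labels)
    _, _, observed_mcc, _ = _scan_thresholds(x_obs, y)

    pool_matrix = logexpr.loc[present].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null_mccs = []
    pairs = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(present), size=2, replace=False)
        pairs.append((present[int(i)], present[int(j)]))
        pair_scores = pool_matrix[i] + pool_matrix[j]
        _, _, mcc, _ = _scan_thresholds(pair_scores, y)
        null_mccs.append(mcc)
    null_arr = np.asarray(null_mccs)
    p_value = float((null_arr > observed_mcc).sum() / n_pairs)
    return NullDistribution(
        null_mccs=tuple(null_mccs),
        observed_mcc=observed_mcc,
        p_value=p_value,
        n_pairs=n_pairs,
        seed=seed,
        observed_name=observed.name,
        pairs=tuple(pairs),
    )


def evaluate_panel(
    logexpr: pd.DataFrame,
    labels: Mapping[str, bool] | pd.Series,
    panel: GenePanel,
    signature: SignatureSpec,
    *,
    n_perm: int = 999,
    seed: int = 0,
) -> list[EvaluationResult]:
    """Evaluate each panel gene individually plus the signature (one row each).

    Single-gene predictors use the gene's raw log10 expression (no panel
    sign applied), matching the per-gene comparisons the signature is
    benchmarked against.
    """
    missing = [g for g in panel.genes if g not in logexpr.index]
    if missing:
        raise InputError(f"panel gene(s) absent from matrix: {missing}")
    results = []
    for gene in panel.genes:
        results.append(
            evaluate_predictor(
                logexpr.loc[gene], labels, n_perm=n_perm, seed=seed, name=gene
            )
        )
    sig_scores = score_signature(logexpr, signature)
    results.append(
        evaluate_predictor(
            sig_scores, labels, n_perm=n_perm, seed=seed, name=signature.name
        )
    )
    return results
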