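"""Cross-validation, performance metrics, ROC/PR curves, calibration.

A trained model scores a site against each of its groups; group scores are
made comparable by subtracting each group's medium-stringency cutoff, and the
site's combined score is the best such margin. Leave-one-out scoring of a
positive removes the peptide from its own group before scoring (closed-form,
no retraining); negatives are always scored against full groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from .grouping import GroupModel
from .training import (
    SP_LEVELS,
    PredictorModel,
    TrainingSet,
    _GroupState,
    _trim_codes,
    group_scores,
    loo_scores_for_members,
    mutate_matrix,
    position_profile,
    sp_cutoff,
    train_weights,
)
from .scoring import N_PAIRS, encode_many

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy, Matthews correlation, precision."""

    sn: float
    sp: float
    ac: float
    mcc: float
    pr: float


@dataclass
class ScoredLabels:
    """Scores with binary labels (True = positive), plus provenance."""

    scores: np.ndarray
    labels: np.ndarray
    provenance: str = "LOO"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal shape")

    def require_both_classes(self) -> None:
        if not (self.labels.any() and (~self.labels).any()):
            raise ValueError("need at least one positive and one negative score")


def metrics(c: ConfusionCounts) -> MetricSet:
    """Standard thresholded metrics; MCC and precision guard a zero
    denominator by returning 0."""
    p = c.tp + c.fn
    n = c.tn + c.fp
    if p == 0 or n == 0:
        raise ValueError("both classes must be represented")
    sn = c.tp / p
    sp = c.tn / n
    ac = (c.tp + c.tn) / (p + n)
    pr = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    denom = math.sqrt(
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = ((c.tp * c.tn - c.fp * c.fn) / denom) if denom > 0 else 0.0
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=mcc, pr=pr)


def confusion_at(sl: ScoredLabels, cutoff: float) -> ConfusionCounts:
    """Counts under the closed lower bound: positive iff score >= cutoff."""
    called = sl.scores >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(called & sl.labels)),
        fp=int(np.sum(called & ~sl.labels)),
        tn=int(np.sum(~called & ~sl.labels)),
        fn=int(np.sum(~called & sl.labels)),
    )


# ---------------------------------------------------------------------------
# model scoring under cross-validation
# ---------------------------------------------------------------------------


def _combined_scores(
    model: PredictorModel, ts: TrainingSet
) -> tuple[np.ndarray, np.ndarray]:
    """(pos_scores, neg_scores): per-site best margin over groups, with
    positives LOO-scored against their own group."""
    pos61 = encode_many([w for _, _, w in ts.positives])
    neg61 = encode_many([w for _, _, w in ts.negatives])
    pos_codes = _trim_codes(pos61, model.m, model.n)
    neg_codes = _trim_codes(neg61, model.m, model.n)

    pos_margin = np.full((pos_codes.shape[0], len(model.groups)), -np.inf)
    neg_margin = np.full((neg_codes.shape[0], len(model.groups)), -np.inf)
    for gi, g in enumerate(model.groups):
        codes = encode_many(g.positives)
        M = g.matrix.as_array()
        F = position_profile(codes)
        w = g.weights.weights
        cut = g.thresholds["medium"]
        pos_margin[:, gi] = group_scores(M, F, w, pos_codes) - cut
        member = np.array(g.member_indices, dtype=np.intp)
        loo = loo_scores_for_members(M, F, w, codes)
        if not np.all(np.isfinite(loo)):
            logger.warning(
                "group %s has a single member; its LOO score falls back to "
                "the other groups", g.group_id,
            )
        pos_margin[member, gi] = loo - cut
        neg_margin[:, gi] = group_scores(M, F, w, neg_codes) - cut
    return pos_margin.max(axis=1), neg_margin.max(axis=1)


def loo_scores(model: PredictorModel, ts: TrainingSet) -> ScoredLabels:
    """Leave-one-out combined scores for every training site."""
    if len(ts.positives) < 2:
        raise ValueError("LOO needs at least 2 positives")
    pos, neg = _combined_scores(model, ts)
    return ScoredLabels(
        scores=np.concatenate([pos, neg]),
        labels=np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)]),
        provenance="LOO",
    )


def _stratified_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold label per item; sizes within the class differ by at most 1."""
    idx = rng.permutation(n)
    folds = np.empty(n, dtype=np.intp)
    folds[idx] = np.arange(n) % k
    return folds


def kfold_scores(
    model: PredictorModel,
    ts: TrainingSet,
    k: int,
    seed: int = 0,
    full_refit: bool = False,
) -> ScoredLabels:
    """Stratified k-fold combined scores.

    In the default fast mode each fold keeps the globally trained weights,
    matrices and group structure and only restricts the group peptide sets to
    the training folds; ``full_refit`` re-runs WT and MaM per fold.
    """
    n_pos = len(ts.positives)
    n_neg = len(ts.negatives)
    if k > n_pos:
        raise ValueError(f"k = {k} exceeds the number of positives ({n_pos})")
    rng = np.random.default_rng(seed)
    pos_fold = _stratified_folds(n_pos, k, rng)
    neg_fold = _stratified_folds(n_neg, k, rng)

    pos61 = encode_many([w for _, _, w in ts.positives])
    neg61 = encode_many([w for _, _, w in ts.negatives])
    pos_codes = _trim_codes(pos61, model.m, model.n)
    neg_codes = _trim_codes(neg61, model.m, model.n)

    pos_scores = np.full(n_pos, -np.inf)
    neg_scores = np.full(n_neg, -np.inf)
    cfg = model.config
    for f in range(k):
        held_pos = np.flatnonzero(pos_fold == f)
        held_neg = np.flatnonzero(neg_fold == f)
        train_neg_codes = neg_codes[neg_fold != f]
        for g in model.groups:
            member = np.array(g.member_indices, dtype=np.intp)
            train_members = member[pos_fold[member] != f]
            if train_members.size == 0:
                logger.warning(
                    "fold %d: group %s lost all members; skipped", f, g.group_id
                )
                continue
            codes = pos_codes[train_members]
            if full_refit:
                st = _GroupState(
                    group_id=g.group_id, kind=g.kind, member_idx=train_members,
                    codes=codes, w=np.ones(codes.shape[1]),
                    pair_deltas=np.zeros(N_PAIRS),
                )
                train_weights(st, train_neg_codes, cfg, seed=seed + 17 * f + 1)
                mutate_matrix(st, train_neg_codes, cfg, seed=seed + 17 * f + 2)
                M, w = st.M, st.w
            else:
                M, w = g.matrix.as_array(), g.weights.weights
            F = position_profile(codes)
            cut = sp_cutoff(
                group_scores(M, F, w, train_neg_codes), SP_LEVELS["medium"]
            )
            sp_h = group_scores(M, F, w, pos_codes[held_pos]) - cut
            sn_h = group_scores(M, F, w, neg_codes[held_neg]) - cut
            pos_scores[held_pos] = np.maximum(pos_scores[held_pos], sp_h)
            neg_scores[held_neg] = np.maximum(neg_scores[held_neg], sn_h)
    return ScoredLabels(
        scores=np.concatenate([pos_scores, neg_scores]),
        labels=np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)]),
        provenance=f"fold-{k}" + ("-refit" if full_refit else "-fast"),
    )


# ---------------------------------------------------------------------------
# threshold-free curves
# ---------------------------------------------------------------------------


def roc_auc(sl: ScoredLabels) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) over all score thresholds, and the AUC.

    The AUC equals the Mann-Whitney probability that a random positive
    outscores a random negative, ties counting one half.
    """
    sl.require_both_classes()
    fpr, tpr, _ = roc_curve(sl.labels.astype(int), sl.scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def pr_curve(sl: ScoredLabels) -> np.ndarray:
    """(recall, precision) points at every distinct score threshold."""
    sl.require_both_classes()
    precision, recall, _ = precision_recall_curve(sl.labels.astype(int), sl.scores)
    return np.column_stack([recall, precision])


def calibrate_thresholds(sl: ScoredLabels) -> dict[str, float]:
    """High/medium/low cutoffs: minimal scores with specificity >= 0.95 /
    0.90 / 0.85 on the negatives."""
    sl.require_both_classes()
    neg = sl.scores[~sl.labels]
    out = {name: sp_cutoff(neg, level) for name, level in SP_LEVELS.items()}
    assert out["high"] >= out["medium"] >= out["low"]
    return out


def evaluation_report(
    sl: ScoredLabels, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """TSV of (threshold, Sn, Sp, Ac, MCC, Pr) over all distinct scores."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("threshold\tsn\tsp\tac\tmcc\tpr\n")
        for t in np.unique(sl.scores):
            ms = metrics(confusion_at(sl, float(t)))
            fh.write(
                f"{t:.6f}\t{ms.sn:.4f}\t{ms.sp:.4f}\t{ms.ac:.4f}\t"
                f"{ms.mcc:.4f}\t{ms.pr:.4f}\n"
            )
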