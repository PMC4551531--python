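"""Multi-label evaluation of masked-annotation recovery.

All bounded metrics are reported on a 0-100 scale.  Definitions:

* per-term AUC / AvgROC — Mann-Whitney AUC with midrank ties, averaged over
  terms having at least one positive and one negative candidate cell;
* 1-RankLoss — per-protein fraction of correctly ordered (positive,
  negative) candidate pairs (ties count 1/2), averaged and scaled;
* Coverage — per-protein rank depth needed to retrieve every masked term,
  minus one, averaged; reported unnormalized;
* Fmax — protein-centric maximum F-measure over a sweep of score
  thresholds (precision averaged over proteins with >= 1 call at the
  threshold, recall over all proteins with >= 1 masked term);
* MacroF1 / RAccuracy — after binarizing each protein's top-r candidates
  (r = that protein's masked count): per-term F1 averaged over terms with a
  positive, and the overall fraction of masked pairs recovered.

Only candidate cells (not annotated pre-mask, not excluded roots) enter any
metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Collection, Iterable

import numpy as np
from scipy import stats

from .predict import ScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    macro_f1: float
    avg_roc: float
    one_minus_rankloss: float
    r_accuracy: float
    fmax: float
    coverage: float
    per_term_auc: dict[str, float] = field(default_factory=dict)
    n_terms_without_positives: int = 0
    n_truth_pairs_ignored: int = 0

    METRIC_NAMES = (
        "macro_f1",
        "avg_roc",
        "one_minus_rankloss",
        "r_accuracy",
        "fmax",
        "coverage",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}

    def to_text(self) -> str:
        lines = [f"{name}\t{value:.4f}" for name, value in self.as_dict().items()]
        return "\n".join(lines) + "\n"


def _truth_pairs(truth) -> set[tuple[str, str]]:
    pairs = getattr(truth, "truth_pairs", truth)
    return set(pairs)


def _midrank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling (equals ROC AUC)."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(scores: ScoreMatrix, truth) -> MetricReport:
    """Score a prediction matrix against the masked ground-truth pairs.

    ``truth`` is either a ``MaskedDataset`` (its ``truth_pairs`` are used) or
    any collection of (protein, term) pairs.  Pairs falling outside the
    candidate cells are ignored with a count.
    """
    pairs = _truth_pairs(truth)
    n, m = scores.scores.shape
    p_index = {p: i for i, p in enumerate(scores.proteins)}
    t_index = {t: j for j, t in enumerate(scores.terms)}
    pos = np.zeros((n, m), dtype=bool)
    ignored = 0
    for protein, term in pairs:
        i, j = p_index.get(protein), t_index.get(term)
        if i is None or j is None or not scores.candidate[i, j]:
            ignored += 1
            continue
        pos[i, j] = True
    if ignored:
        logger.warning("evaluate: %d truth pairs fell outside candidate cells", ignored)

    cand = scores.candidate
    sc = scores.scores

    # ---- per-term AUC and AvgROC
    per_term_auc: dict[str, float] = {}
    n_skipped = 0
    for j, term in enumerate(scores.terms):
        col_mask = cand[:, j]
        if not col_mask.any():
            continue
        y = pos[col_mask, j]
        if not y.any():
            n_skipped += 1
            continue
        if y.all():
            n_skipped += 1
            continue
        per_term_auc[term] = 100.0 * _midrank_auc(sc[col_mask, j], y)
    avg_roc = float(np.mean(list(per_term_auc.values()))) if per_term_auc else float("nan")

    # ---- 1-RankLoss (per-protein pairwise ordering, midrank == row AUC)
    row_aucs = []
    for i in range(n):
        row_mask = cand[i]
        y = pos[i, row_mask]
        if not y.any() or y.all():
            continue
        row_aucs.append(_midrank_auc(sc[i, row_mask], y))
    one_minus_rankloss = 100.0 * float(np.mean(row_aucs)) if row_aucs else float("nan")

    # ---- Coverage and rank-r binarization (deterministic tie order by term id)
    coverages = []
    binarized = np.zeros((n, m), dtype=bool)
    term_keys = np.array(scores.terms)
    recovered = 0
    total_masked = 0
    for i in range(n):
        row_mask = cand[i]
        r = int(pos[i].sum())
        if r == 0:
            continue
        idx = np.where(row_mask)[0]
        order = idx[np.lexsort((term_keys[idx], -sc[i, idx]))]
        pos_positions = np.where(pos[i, order])[0]
        coverages.append(float(pos_positions.max()))  # (1-based depth) - 1
        top_r = order[:r]
        binarized[i, top_r] = True
        recovered += int(pos[i, top_r].sum())
        total_masked += r
    coverage = float(np.mean(coverages)) if coverages else float("nan")
    r_accuracy = 100.0 * recovered / total_masked if total_masked else float("nan")

    # ---- MacroF1 over terms with >= 1 positive
    f1s = []
    for j, term in enumerate(scores.terms):
        col = cand[:, j]
        y = pos[col, j]
        if not y.any():
            continue
        yhat = binarized[col, j]
        tp = int((y & yhat).sum())
        fp = int((~y & yhat).sum())
        fn = int((y & ~yhat).sum())
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    macro_f1 = 100.0 * float(np.mean(f1s)) if f1s else float("nan")

    # ---- Fmax (protein-centric threshold sweep)
    fmax = _fmax(sc, pos, cand)

    return MetricReport(
        macro_f1=macro_f1,
        avg_roc=avg_roc,
        one_minus_rankloss=one_minus_rankloss,
        r_accuracy=r_accuracy,
        fmax=100.0 * fmax,
        coverage=coverage,
        per_term_auc=per_term_auc,
        n_terms_without_positives=n_skipped,
        n_truth_pairs_ignored=ignored,
    )


def _fmax(sc: np.ndarray, pos: np.ndarray, cand: np.ndarray) -> float:
    masked_rows = np.where(pos.any(axis=1))[0]
    if masked_rows.size == 0:
        return float("nan")
    thresholds = np.unique(sc[cand & (sc > 0)])
    if thresholds.size == 0:
        thresholds = np.array([0.0])
    best = 0.0
    for tau in thresholds:
        pred = cand & (sc >= tau)
        precisions = []
        recalls = []
        for i in masked_rows:
            npred = int(pred[i].sum())
            tp = int((pred[i] & pos[i]).sum())
            if npred:
                precisions.append(tp / npred)
            recalls.append(tp / int(pos[i].sum()))
        # proteins without a call at this threshold are excluded from the
        # precision mean; recall averages over every masked protein
        if not precisions:
            continue
        p = float(np.mean(precisions))
        r = float(np.mean(recalls))
        if p + r > 0:
            best = max(best, 2 * p * r / (p + r))
    return best


def auc_delta_by_stratum(
    report_a: MetricReport,
    report_b: MetricReport,
    strata: dict[str, str],
) -> dict[str, dict[str, float]]:
    """Per-term AUC(a) - AUC(b), grouped by sparsity stratum."""
    out: dict[str, dict[str, float]] = {}
    common = set(report_a.per_term_auc) & set(report_b.per_term_auc)
    for term in sorted(common):
        stratum = strata.get(term)
        if stratum is None:
            continue
        out.setdefault(stratum, {})[term] = (
            report_a.per_term_auc[term] - report_b.per_term_auc[term]
        )
    return out


def paired_t_test(xs: Iterable[float], ys: Iterable[float]) -> tuple[float, float]:
    """Paired t-test across repeat runs; returns (statistic, p-value)."""
    res = stats.ttest_rel(list(xs), list(ys))
    return float(res.statistic), float(res.pvalue)


def write_per_term_auc_tsv(
    stream,
    report: MetricReport,
    support: dict[str, int] | None = None,
    strata: dict[str, str] | None = None,
) -> None:
    stream.write("term\tsupport\tstratum\tauc\n")
    for term in sorted(report.per_term_auc):
        sup = support.get(term, "") if support else ""
        stratum = strata.get(term, "") if strata else ""
        stream.write(f"{term}\t{sup}\t{stratum}\t{report.per_term_auc[term]:.4f}\n")
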