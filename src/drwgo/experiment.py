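"""Masking protocols, the repeated-evaluation harness, and rollback checks.

The masking protocol iteratively removes random protein-specific leaf terms:
removing a leaf can promote its parent to a leaf, so deep chains can be
eaten one term per round.  Proteins always retain at least one term, and
unannotated proteins are skipped.  Terms whose every annotation is masked
become "second kind" missing functions: present in the hierarchy, annotated
to nobody.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import AnnotationTable, term_frequency
from .evaluation import MetricReport, evaluate
from .ontology import OntologyDag, protein_leaf_terms
from .predict import (
    DEFAULT_K,
    ScoreMatrix,
    drw_knn_predict,
    drw_predict,
    itss_baseline,
    naive_predict,
    protein_similarity_matrix,
)
from .walk import DEFAULT_ETA, DEFAULT_ITERATIONS

logger = logging.getLogger(__name__)

METHODS = ("drw", "drw-knn", "drw-corpus", "drw-e", "itss", "naive")


@dataclass
class MaskedDataset:
    """A masked table plus the bookkeeping needed for evaluation.

    ``truth_pairs`` are the removed (protein, term) pairs; ``m`` is the
    per-protein mask budget, ``n_masked`` the realized total (N_m), and
    ``second_kind_terms`` the terms stripped of every protein (|T_m^0|).
    """

    masked_table: AnnotationTable
    truth_pairs: set[tuple[str, str]]
    second_kind_terms: set[str]
    m: int
    n_masked: int
    seed: int

    @property
    def truth_pairs_by_protein(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, t in self.truth_pairs:
            out.setdefault(p, set()).add(t)
        return out


def mask_annotations(
    dag: OntologyDag, table: AnnotationTable, m: int, seed: int
) -> MaskedDataset:
    """Iteratively mask up to ``m`` protein-specific leaf terms per protein.

    ``table`` must be true-path propagated.  Each round recomputes the
    protein's leaf frontier on its current set and removes one uniformly
    drawn leaf; masking stops early when a single term remains.
    """
    if m < 1:
        raise ValueError("m must be >= 1 (a no-op mask is a protocol bug)")
    rng = np.random.default_rng(seed)
    masked = table.copy()
    truth: set[tuple[str, str]] = set()
    for protein in table.proteins:
        current = masked.term_sets[protein]
        if len(current) < 2:
            continue
        for _ in range(m):
            if len(current) <= 1:
                break
            leaves = sorted(protein_leaf_terms(dag, current))
            choice = leaves[int(rng.integers(len(leaves)))]
            current.remove(choice)
            truth.add((protein, choice))
    masked_freq = term_frequency(masked)
    original_freq = term_frequency(table)
    second_kind = {
        t for t in table.universe if original_freq[t] > 0 and masked_freq.get(t, 0) == 0
    }
    return MaskedDataset(masked, truth, second_kind, m, len(truth), seed)


# -- repeated masking experiment -----------------------------------------


@dataclass
class ExperimentSummary:
    """Mean/std of every metric per (method, m), plus per-repeat bookkeeping."""

    reports: dict[tuple[str, int], list[MetricReport]]
    n_masked: dict[int, list[int]] = field(default_factory=dict)
    second_kind_counts: dict[int, list[int]] = field(default_factory=dict)

    def mean(self, method: str, m: int, metric: str) -> float:
        values = [getattr(r, metric) for r in self.reports[(method, m)]]
        return float(np.mean(values))

    def std(self, method: str, m: int, metric: str) -> float:
        values = [getattr(r, metric) for r in self.reports[(method, m)]]
        return float(np.std(values)) if len(values) > 1 else 0.0

    def to_tsv(self, stream) -> None:
        stream.write("method\tm\tmetric\tmean\tstd\n")
        for (method, m) in sorted(self.reports):
            for metric in MetricReport.METRIC_NAMES:
                stream.write(
                    f"{method}\t{m}\t{metric}\t"
                    f"{self.mean(method, m, metric):.4f}\t{self.std(method, m, metric):.4f}\n"
                )


def _predict_one(
    method: str,
    dag: OntologyDag,
    masked: AnnotationTable,
    *,
    eta: float,
    iterations: int,
    k: int,
    cache: dict,
) -> ScoreMatrix:
    def drw_scores() -> ScoreMatrix:
        if "drw" not in cache:
            cache["drw"] = drw_predict(dag, masked, "structure", eta=eta, iterations=iterations)
        return cache["drw"]

    def psim() -> np.ndarray:
        if "psim" not in cache:
            cache["psim"] = protein_similarity_matrix(masked, dag=dag)
        return cache["psim"]

    if method == "drw":
        return drw_scores()
    if method == "drw-corpus":
        return drw_predict(dag, masked, "corpus", eta=eta, iterations=iterations)
    if method == "drw-e":
        return drw_predict(dag, masked, "equal", eta=eta, iterations=iterations)
    if method == "drw-knn":
        return drw_knn_predict(drw_scores(), masked, psim(), k=k)
    if method == "itss":
        return itss_baseline(masked, psim(), k=k, dag=dag)
    if method == "naive":
        return naive_predict(masked, dag=dag)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_masking_experiment(
    dag: OntologyDag,
    table: AnnotationTable,
    methods: Sequence[str] = ("drw", "drw-knn", "itss", "naive"),
    m_values: Sequence[int] = (1, 3, 5),
    repeats: int = 10,
    seed: int = 0,
    *,
    eta: float = DEFAULT_ETA,
    iterations: int = DEFAULT_ITERATIONS,
    k: int = DEFAULT_K,
) -> ExperimentSummary:
    """Mask, predict, and evaluate ``repeats`` times for every m value.

    Sub-seeds are ``seed + repeat_index`` so individual repeats can be
    reproduced in isolation.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    reports: dict[tuple[str, int], list[MetricReport]] = {
        (method, m): [] for method in methods for m in m_values
    }
    n_masked: dict[int, list[int]] = {m: [] for m in m_values}
    second_kind: dict[int, list[int]] = {m: [] for m in m_values}
    for m in m_values:
        for rep in range(repeats):
            ds = mask_annotations(dag, table, m, seed + rep)
            n_masked[m].append(ds.n_masked)
            second_kind[m].append(len(ds.second_kind_terms))
            cache: dict = {}
            for method in methods:
                scores = _predict_one(
                    method, dag, ds.masked_table,
                    eta=eta, iterations=iterations, k=k, cache=cache,
                )
                reports[(method, m)].append(evaluate(scores, ds))
            logger.info(
                "mask experiment m=%d repeat=%d: N_m=%d |T_m^0|=%d",
                m, rep, ds.n_masked, len(ds.second_kind_terms),
            )
    return ExperimentSummary(reports, n_masked, second_kind)


# -- historical rollback -------------------------------------------------


@dataclass
class RollbackReport:
    """Top-n global predictions validated against a newer annotation table."""

    top_pairs: list[tuple[str, str, float]]
    n_top: int
    true_positives: set[tuple[str, str]]
    rate: float
    unverifiable: int
    tpr_applied: bool = False
    expanded_pairs: set[tuple[str, str]] = field(default_factory=set)
    expanded_true_positives: set[tuple[str, str]] = field(default_factory=set)
    expanded_rate: float = float("nan")

    def to_text(self) -> str:
        lines = [
            f"top_n\t{self.n_top}",
            f"true_positives\t{len(self.true_positives)}",
            f"rate\t{100.0 * self.rate:.2f}%",
            f"unverifiable\t{self.unverifiable}",
        ]
        if self.tpr_applied:
            lines += [
                f"expanded_predictions\t{len(self.expanded_pairs)}",
                f"expanded_true_positives\t{len(self.expanded_true_positives)}",
                f"expanded_rate\t{100.0 * self.expanded_rate:.2f}%",
            ]
        return "\n".join(lines) + "\n"


def rollback_compare(
    old_table: AnnotationTable,
    new_table: AnnotationTable,
    scores: ScoreMatrix,
    dag: OntologyDag,
    top_n: int = 100,
    apply_tpr: bool = False,
) -> RollbackReport:
    """Validate the globally top-n candidate scores against a newer release.

    A prediction (protein, term) is a true positive when the pair is
    annotated in ``new_table`` but not in ``old_table``.  With ``apply_tpr``
    each top-n pair is expanded with its ancestor pairs before counting, and
    a second rate is computed over the expanded set.  Proteins absent from
    the new table are unverifiable and never count as true positives.
    """
    old_pairs = {
        (p, t) for p in old_table.proteins for t in old_table.term_sets[p]
    }
    new_pairs = {
        (p, t) for p in new_table.proteins for t in new_table.term_sets[p]
    }
    new_proteins = set(new_table.proteins)

    entries: list[tuple[float, str, str]] = []
    for i, p in enumerate(scores.proteins):
        row = scores.candidate[i]
        for j in np.where(row)[0]:
            entries.append((float(scores.scores[i, j]), p, scores.terms[j]))
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    top = entries[: top_n]

    top_pairs = [(p, t, s) for s, p, t in top]
    unverifiable = sum(1 for _, p, _ in top if p not in new_proteins)
    if unverifiable:
        logger.warning("rollback: %d top predictions are for proteins absent from the new table", unverifiable)
    tps = {
        (p, t) for _, p, t in top
        if p in new_proteins and (p, t) in new_pairs and (p, t) not in old_pairs
    }
    rate = len(tps) / len(top) if top else float("nan")

    expanded: set[tuple[str, str]] = set()
    expanded_tps: set[tuple[str, str]] = set()
    expanded_rate = float("nan")
    if apply_tpr:
        for _, p, t in top:
            for a in dag.ancestors_or_self(t) if t in dag else {t}:
                if (p, a) not in old_pairs:
                    expanded.add((p, a))
        expanded_tps = {
            (p, t) for (p, t) in expanded if p in new_proteins and (p, t) in new_pairs
        }
        expanded_rate = len(expanded_tps) / len(expanded) if expanded else float("nan")

    return RollbackReport(
        top_pairs=top_pairs,
        n_top=len(top),
        true_positives=tps,
        rate=rate,
        unverifiable=unverifiable,
        tpr_applied=apply_tpr,
        expanded_pairs=expanded,
        expanded_true_positives=expanded_tps,
        expanded_rate=expanded_rate,
    )
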