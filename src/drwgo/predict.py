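"""Predictors producing N x |T| score matrices.

Implemented methods:

* ``drw_predict`` — downward random walk likelihoods, with a similarity
  variant switch (structure IC, corpus IC, or equal edge weights);
* ``drw_knn_predict`` — kNN fusion of walk likelihoods with neighbour
  annotations (k = 1 reduces exactly to dRW);
* ``itss_baseline`` — the same kNN fusion over binary neighbour annotations
  only (no walk pre-estimation);
* ``naive_predict`` — term-frequency ranking, identical across proteins.

Scores are never renormalized per protein; downstream evaluation is rank- and
threshold-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationTable, term_frequency
from .ontology import OntologyDag
from .semantics import (
    TermPairSimilarity,
    corpus_ic,
    lin_term_similarity,
    protein_similarity,
    structure_ic,
)
from .walk import (
    DEFAULT_ETA,
    DEFAULT_ITERATIONS,
    drw_likelihood,
    stationary_profiles,
    transition_matrix,
)

SIM_VARIANTS = ("structure", "corpus", "equal")

DEFAULT_K = 10


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores with an annotated/candidate mask.

    ``annotated[i, j]`` marks terms already in T_i (the "already annotated"
    sentinel — such cells carry no score); ``candidate`` marks cells that are
    scoreable predictions.  Cells that are neither (e.g. excluded roots) are
    ignored by evaluation.
    """

    proteins: list[str]
    terms: list[str]
    scores: np.ndarray
    annotated: np.ndarray
    candidate: np.ndarray

    def __post_init__(self) -> None:
        self._p_index = {p: i for i, p in enumerate(self.proteins)}
        self._t_index = {t: j for j, t in enumerate(self.terms)}

    def score_of(self, protein: str, term: str) -> float:
        return float(self.scores[self._p_index[protein], self._t_index[term]])

    def is_candidate(self, protein: str, term: str) -> bool:
        return bool(self.candidate[self._p_index[protein], self._t_index[term]])

    def to_tsv(self, stream, header_lines: list[str] | None = None) -> None:
        """Long-form TSV: protein, term, score, flag(annotated|candidate)."""
        for line in header_lines or []:
            stream.write(f"# {line}\n")
        stream.write("protein\tterm\tscore\tflag\n")
        for i, p in enumerate(self.proteins):
            for j, t in enumerate(self.terms):
                if self.annotated[i, j]:
                    stream.write(f"{p}\t{t}\tNA\tannotated\n")
                elif self.candidate[i, j]:
                    stream.write(f"{p}\t{t}\t{self.scores[i, j]:.17g}\tcandidate\n")


def _layout(
    table: AnnotationTable, dag: OntologyDag | None, include_roots: bool
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Term ordering plus annotated/candidate masks for a table."""
    terms = sorted(table.universe)
    t_index = {t: j for j, t in enumerate(terms)}
    n, m = table.n_proteins, len(terms)
    annotated = np.zeros((n, m), dtype=bool)
    for i, p in enumerate(table.proteins):
        for t in table.term_sets[p]:
            annotated[i, t_index[t]] = True
    candidate = ~annotated
    if not include_roots and dag is not None:
        for r in dag.roots():
            j = t_index.get(r)
            if j is not None:
                candidate[:, j] = False
    return terms, annotated, candidate


def term_similarity_for_variant(
    dag: OntologyDag, table: AnnotationTable, sim_variant: str
) -> TermPairSimilarity:
    """The term-pair similarity backing each dRW variant's transition matrix."""
    if sim_variant == "structure":
        return lin_term_similarity(dag, structure_ic(dag))
    if sim_variant == "corpus":
        return lin_term_similarity(dag, corpus_ic(table))
    if sim_variant == "equal":
        return lambda t1, t2: 1.0
    raise ValueError(f"unknown sim_variant {sim_variant!r}; expected one of {SIM_VARIANTS}")


def drw_predict(
    dag: OntologyDag,
    table: AnnotationTable,
    sim_variant: str = "structure",
    *,
    eta: float = DEFAULT_ETA,
    iterations: int = DEFAULT_ITERATIONS,
    include_roots: bool = False,
) -> ScoreMatrix:
    """Downward-random-walk likelihood scores for every protein.

    ``table`` must be true-path propagated.  Walk profiles are computed
    lazily, only for terms that occur in some protein's annotation set.
    Proteins with empty term sets get all-zero rows.
    """
    terms, annotated, candidate = _layout(table, dag, include_roots)
    t_index = {t: j for j, t in enumerate(terms)}
    sim = term_similarity_for_variant(dag, table, sim_variant)
    W = transition_matrix(dag, sim)
    starts: set[str] = set()
    for p in table.proteins:
        starts |= table.term_sets[p]
    profiles = stationary_profiles(W, dag, starts, eta=eta, iterations=iterations)
    universe = table.universe
    scores = np.zeros_like(annotated, dtype=float)
    for i, p in enumerate(table.proteins):
        row = drw_likelihood(profiles, table.term_sets[p], universe, protein=p)
        for t, v in row.scores.items():
            scores[i, t_index[t]] = v
    scores[~candidate] = 0.0
    return ScoreMatrix(list(table.proteins), terms, scores, annotated, candidate)


def protein_similarity_matrix(
    table: AnnotationTable,
    sim: TermPairSimilarity | None = None,
    dag: OntologyDag | None = None,
    exclude_terms: set[str] | frozenset[str] | None = None,
) -> np.ndarray:
    """Pairwise psim over the table's proteins (symmetric, diag 1 for
    annotated proteins).

    ``exclude_terms`` defaults to the namespace roots when a ``dag`` is
    given: roots carry zero IC, are shared by all annotated proteins, and
    would deflate every self-similarity below 1.
    """
    if sim is None:
        if dag is None:
            raise ValueError("either sim or dag must be provided")
        sim = lin_term_similarity(dag, structure_ic(dag))
    if exclude_terms is None:
        exclude_terms = set(dag.roots()) if dag is not None else set()
    sets = [frozenset(table.term_sets[p] - exclude_terms) for p in table.proteins]
    n = len(sets)
    psim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            psim[i, j] = psim[j, i] = protein_similarity(sets[i], sets[j], sim)
    for i, p in enumerate(table.proteins):
        # a protein is maximally similar to itself whenever it is annotated
        # at all; this also keeps kNN fusion at k=1 an exact identity
        if table.term_sets[p]:
            psim[i, i] = 1.0
    return psim


def _knn_fuse(
    base_scores: np.ndarray,
    table: AnnotationTable,
    psim: np.ndarray,
    k: int,
    candidate: np.ndarray,
) -> np.ndarray:
    """Shared kNN fusion: L~(i, v) = (1/k) sum_{j in N_k(i)} psim(i,j) L(j,v).

    ``base_scores`` must already have 1.0 at (j, v in T_j) cells, which is the
    "neighbour annotations count as certain" convention.  N_k(i) is protein i
    itself plus its k-1 most similar proteins (ties to the smaller index).
    """
    n = len(table.proteins)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of proteins ({n})")
    out = np.zeros_like(base_scores)
    order_keys = np.arange(n)
    for i in range(n):
        others = np.delete(order_keys, i)
        # stable sort on negated similarity -> ties resolve to smaller index
        ranked = others[np.argsort(-psim[i, others], kind="stable")]
        neigh = np.concatenate(([i], ranked[: k - 1])).astype(int)
        out[i] = (psim[i, neigh] @ base_scores[neigh]) / k
    out[~candidate] = 0.0
    return out


def drw_knn_predict(
    drw_scores: ScoreMatrix,
    table: AnnotationTable,
    psim: np.ndarray,
    k: int = DEFAULT_K,
) -> ScoreMatrix:
    """Fuse dRW likelihoods with neighbour annotations through a kNN rule.

    For a neighbour j, L(j, v) is 1 when v is annotated to j and the dRW
    score otherwise.  With k = 1 the result is entry-wise equal to dRW.
    """
    base = drw_scores.scores.copy()
    base[drw_scores.annotated] = 1.0
    fused = _knn_fuse(base, table, psim, k, drw_scores.candidate)
    return ScoreMatrix(
        list(drw_scores.proteins),
        list(drw_scores.terms),
        fused,
        drw_scores.annotated.copy(),
        drw_scores.candidate.copy(),
    )


def itss_baseline(
    table: AnnotationTable,
    psim: np.ndarray,
    k: int = DEFAULT_K,
    *,
    dag: OntologyDag | None = None,
    include_roots: bool = False,
) -> ScoreMatrix:
    """kNN transfer of neighbour annotations only (binary base scores).

    Terms annotated to nobody can never be scored above 0: only the first
    kind of missing function is reachable.
    """
    terms, annotated, candidate = _layout(table, dag, include_roots)
    base = annotated.astype(float)
    fused = _knn_fuse(base, table, psim, k, candidate)
    return ScoreMatrix(list(table.proteins), terms, fused, annotated, candidate)


def naive_predict(
    table: AnnotationTable,
    *,
    dag: OntologyDag | None = None,
    include_roots: bool = False,
) -> ScoreMatrix:
    """Frequency ranking: score(i, v) = freq(v) / N on every candidate cell."""
    terms, annotated, candidate = _layout(table, dag, include_roots)
    freq = term_frequency(table)
    n = max(1, table.n_proteins)
    col = np.array([freq[t] / n for t in terms])
    scores = np.tile(col, (table.n_proteins, 1))
    scores[~candidate] = 0.0
    return ScoreMatrix(list(table.proteins), terms, scores, annotated, candidate)
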