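"""Downward random walks with restart on the term DAG.

Transitions exist only along parent -> child edges; each child's incoming
weights are its parents' (filtered) similarities, normalized to sum to 1.
A walk starting at term ``t`` is confined to ``t`` and its descendants, and
after every step the start term keeps exactly ``1 - eta`` of the mass, since
no descendant can feed back into its own ancestor in a DAG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .ontology import OntologyDag
from .semantics import TermPairSimilarity

logger = logging.getLogger(__name__)

DEFAULT_ETA = 0.5
DEFAULT_ITERATIONS = 10


def filtered_similarity(
    dag: OntologyDag, sim: TermPairSimilarity, t1: str, t2: str
) -> float:
    """Similarity gated by direct parenthood: sim(t1,t2) if t1 -> t2 is an
    edge, else 0 (no transition between non-adjacent terms)."""
    if not dag.has_edge(t1, t2):
        return 0.0
    return sim(t1, t2)


@dataclass
class TransitionMatrix:
    """Column-normalized downward transition weights over a fixed term order."""

    terms: list[str]
    matrix: sp.csr_matrix  # W[u, v]: parent u -> child v
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.terms)}

    def weight(self, parent: str, child: str) -> float:
        return float(self.matrix[self.index[parent], self.index[child]])


def transition_matrix(dag: OntologyDag, sim: TermPairSimilarity) -> TransitionMatrix:
    """Build W(t1, t2) = fsim(t1, t2) / sum_t fsim(t, t2).

    Root columns are all zero.  A non-root child whose parent similarities
    all vanish falls back to a uniform split over its parents (logged); the
    normalization is otherwise undefined for it.
    """
    terms = sorted(dag.terms)
    index = {t: i for i, t in enumerate(terms)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    n_fallback = 0
    for child in terms:
        parents = sorted(dag.parents(child))
        if not parents:
            continue
        weights = [sim(p, child) for p in parents]
        total = sum(weights)
        if total <= 0.0:
            n_fallback += 1
            weights = [1.0] * len(parents)
            total = float(len(parents))
        ci = index[child]
        for p, w in zip(parents, weights):
            if w > 0.0:
                rows.append(index[p])
                cols.append(ci)
                vals.append(w / total)
    if n_fallback:
        logger.warning(
            "transition_matrix: %d terms had all-zero parent similarities; "
            "used uniform fallback over their parents",
            n_fallback,
        )
    n = len(terms)
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(terms, mat, index)


@dataclass
class WalkProfile:
    """Stationary-ish walk probabilities R~(t, .) for one start term.

    ``probs`` is supported on ``t`` and its descendants; all values in [0,1].
    """

    start: str
    probs: dict[str, float]
    eta: float
    iterations: int

    def get(self, term: str, default: float = 0.0) -> float:
        return self.probs.get(term, default)


def downward_rwr(
    W: TransitionMatrix,
    dag: OntologyDag,
    t: str,
    eta: float = DEFAULT_ETA,
    iterations: int = DEFAULT_ITERATIONS,
) -> WalkProfile:
    """Iterate R_{s+1}(t, v) = eta * sum_u R_s(t, u) W(u, v) + (1 - eta) e_t
    over ``t`` and its descendants, from R_0 = e_t, for a fixed step count.

    With eta = 0 the update collapses to the start vector; with a leaf start
    the profile is just {t: 1 - eta} after the first step.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    nodes = [t] + sorted(dag.descendants(t))
    pos = [W.index[u] for u in nodes]
    sub = W.matrix[np.ix_(pos, pos)]  # transitions among t and desc(t)
    sub_t = sub.T.tocsr()
    e = np.zeros(len(nodes))
    e[0] = 1.0
    r = e.copy()
    restart = (1.0 - eta) * e
    for _ in range(iterations):
        r = eta * (sub_t @ r) + restart
    return WalkProfile(t, {u: float(x) for u, x in zip(nodes, r)}, eta, iterations)


def stationary_profiles(
    W: TransitionMatrix,
    dag: OntologyDag,
    starts: set[str] | frozenset[str] | list[str],
    eta: float = DEFAULT_ETA,
    iterations: int = DEFAULT_ITERATIONS,
) -> dict[str, WalkProfile]:
    """One :class:`WalkProfile` per start term (deduplicated, order-free)."""
    return {
        t: downward_rwr(W, dag, t, eta=eta, iterations=iterations)
        for t in sorted(set(starts))
    }


@dataclass
class LikelihoodRow:
    """Per-protein likelihood scores over candidate terms (v not in T_i)."""

    protein: str
    scores: dict[str, float]
    theta: float


def drw_likelihood(
    profiles: dict[str, WalkProfile],
    t_i: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    protein: str = "",
) -> LikelihoodRow:
    """Aggregate walk mass onto candidate terms with an adaptive threshold.

    theta is the mean of the pooled nonzero off-start entries of the profiles
    of all t in T_i (start-term diagonals, pinned at 1 - eta, are excluded).
    L(i, v) = sum over t in T_i of R~(t, v) restricted to entries strictly
    above theta, for candidates v in universe \\ T_i.  Empty T_i yields an
    empty row with theta 0.
    """
    pooled: list[float] = []
    for t in sorted(t_i):
        prof = profiles[t]
        pooled.extend(p for v, p in prof.probs.items() if v != t and p > 0.0)
    theta = float(np.mean(pooled)) if pooled else 0.0
    scores: dict[str, float] = {}
    for t in sorted(t_i):
        prof = profiles[t]
        for v, p in prof.probs.items():
            if v == t or v in t_i or v not in universe:
                continue
            if p > theta:
                scores[v] = scores.get(v, 0.0) + p
    return LikelihoodRow(protein, scores, theta)
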