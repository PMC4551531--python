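"""Information content and semantic similarity over terms and proteins.

Two IC flavours are provided: a structure IC driven by descendant counts
(robust to annotation incompleteness) and a corpus IC driven by annotation
frequency.  Term similarity is Lin's measure through the most informative
common ancestor; protein similarity aggregates mutual-best term pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .annotations import AnnotationTable, term_frequency
from .ontology import OntologyDag

#: Contract for a symmetric term-pair similarity in [0, 1].
TermPairSimilarity = Callable[[str, str], float]


@dataclass
class ICMap:
    """Per-term information content in [0, 1].

    ``undefined`` marks terms whose IC has no meaningful value (zero corpus
    frequency); their similarity to every other term is forced to 0.
    """

    values: dict[str, float]
    undefined: frozenset[str] = field(default_factory=frozenset)

    def __getitem__(self, term: str) -> float:
        return self.values[term]

    def __contains__(self, term: str) -> bool:
        return term in self.values

    def get(self, term: str, default: float = 0.0) -> float:
        return self.values.get(term, default)


def structure_ic(dag: OntologyDag) -> ICMap:
    """IC(t) = 1 - log(1 + |desc(t)|) / log|T| over the DAG's term universe.

    Leaves score 1; a term whose descendants cover the rest of the universe
    scores 0.  Values are clamped at 0 for safety against float round-off.
    """
    n = len(dag)
    if n < 2:
        raise ValueError("structure IC needs a universe of >= 2 terms")
    log_n = math.log(n)
    values = {}
    for t in dag.terms:
        ic = 1.0 - math.log(1 + len(dag.descendants(t))) / log_n
        values[t] = max(0.0, ic)
    return ICMap(values)


def corpus_ic(table: AnnotationTable) -> ICMap:
    """Frequency-driven IC: IC(t) = log(N / freq(t)) / log(N), on [0, 1].

    Run on the propagated table.  Terms annotated to nobody get IC 0 and are
    flagged undefined, which zeroes their Lin similarity to every other term.
    """
    n = table.n_proteins
    if n == 0:
        raise ValueError("corpus IC needs at least one protein")
    freq = term_frequency(table)
    if n == 1:
        # log(1) normalizer degenerates; every annotated term is maximally
        # frequent, so IC 0 everywhere is the only consistent assignment.
        values = {t: 0.0 for t in table.universe}
        return ICMap(values, frozenset(t for t, c in freq.items() if c == 0))
    log_n = math.log(n)
    values = {}
    undefined = set()
    for t in table.universe:
        c = freq[t]
        if c == 0:
            values[t] = 0.0
            undefined.add(t)
        else:
            values[t] = min(1.0, max(0.0, math.log(n / c) / log_n))
    return ICMap(values, frozenset(undefined))


def mica(dag: OntologyDag, ic: ICMap, t1: str, t2: str) -> str | None:
    """The most informative common ancestor of two terms.

    Common ancestors include the terms themselves, so when ``t1`` subsumes
    ``t2`` the result is ``t1``.  IC ties break to the lexicographically
    smallest id; ``None`` when no common ancestor exists (distinct roots).
    """
    common = dag.ancestors_or_self(t1) & dag.ancestors_or_self(t2)
    if not common:
        return None
    return min(common, key=lambda t: (-ic.get(t), t))


def lin_similarity(ic: ICMap, dag: OntologyDag, t1: str, t2: str) -> float:
    """Lin similarity 2*IC(t*) / (IC(t1) + IC(t2)), in [0, 1]."""
    if t1 in ic.undefined or t2 in ic.undefined:
        return 0.0
    m = mica(dag, ic, t1, t2)
    if m is None:
        return 0.0
    denom = ic.get(t1) + ic.get(t2)
    if denom <= 0.0:
        return 0.0
    return min(1.0, 2.0 * ic.get(m) / denom)


def lin_term_similarity(dag: OntologyDag, ic: ICMap) -> TermPairSimilarity:
    """A memoised symmetric Lin similarity callable over ``dag``."""
    cache: dict[tuple[str, str], float] = {}

    def sim(t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        val = cache.get(key)
        if val is None:
            val = lin_similarity(ic, dag, t1, t2)
            cache[key] = val
        return val

    return sim


def protein_similarity(
    t_i: set[str] | frozenset[str],
    t_j: set[str] | frozenset[str],
    sim: TermPairSimilarity,
) -> float:
    """Annotation-derived protein similarity from reciprocal term pairs.

    A pair (t1 in T_i, t2 in T_j) is reciprocal when t2 is t1's best match in
    T_j and t1 is t2's best match in T_i (mutual best match; argmax ties break
    to the lexicographically smallest term id).  The score is
    ``2 * sum(sim over reciprocal pairs) / (|T_i| + |T_j|)``; 0 when either
    set is empty.
    """
    if not t_i or not t_j:
        return 0.0
    ti = sorted(t_i)
    tj = sorted(t_j)
    s = {(a, b): sim(a, b) for a in ti for b in tj}
    # sorted iteration + strict '>' makes ties resolve to the lex-smallest id
    best_in_j: dict[str, str] = {}
    for a in ti:
        best, best_val = tj[0], s[(a, tj[0])]
        for b in tj[1:]:
            if s[(a, b)] > best_val:
                best, best_val = b, s[(a, b)]
        best_in_j[a] = best
    best_in_i: dict[str, str] = {}
    for b in tj:
        best, best_val = ti[0], s[(ti[0], b)]
        for a in ti[1:]:
            if s[(a, b)] > best_val:
                best, best_val = a, s[(a, b)]
        best_in_i[b] = best
    total = 0.0
    for a in ti:
        b = best_in_j[a]
        if best_in_i[b] == a:
            total += s[(a, b)]
    return 2.0 * total / (len(ti) + len(tj))
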