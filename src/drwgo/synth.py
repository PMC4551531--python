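"""Seeded synthetic ontologies and true-path-consistent annotation tables.

Generated DAGs have a single root, bounded depth, and optional multiple
inheritance.  Annotations are drawn leaf-first and upward-closed, so every
generated table is its own true-path propagation by construction.  All
output is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotationTable
from .ontology import OntologyDag

SYNTH_NAMESPACE = "synthetic"


@dataclass
class SynthConfig:
    n_terms: int = 50
    max_depth: int = 8
    max_parents: int = 2
    n_proteins: int = 100
    mean_leaf_annotations: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def generate_dag(cfg: SynthConfig) -> OntologyDag:
    """A rooted random DAG: term i draws 1..max_parents parents among the
    earlier terms whose depth is below max_depth (acyclic by construction)."""
    rng = np.random.default_rng(cfg.seed)
    terms = [_term_id(i) for i in range(cfg.n_terms)]
    depth = {terms[0]: 0}
    edges: list[tuple[str, str]] = []
    for i in range(1, cfg.n_terms):
        eligible = [t for t in terms[:i] if depth[t] < cfg.max_depth]
        n_parents = int(rng.integers(1, min(cfg.max_parents, len(eligible)) + 1))
        picked = rng.choice(len(eligible), size=n_parents, replace=False)
        parents = sorted(eligible[int(j)] for j in picked)
        child = terms[i]
        depth[child] = 1 + max(depth[p] for p in parents)
        edges.extend((p, child) for p in parents)
    names = {t: f"synthetic term {i}" for i, t in enumerate(terms)}
    namespaces = {t: SYNTH_NAMESPACE for t in terms}
    return OntologyDag(terms, edges, names, namespaces)


def generate_annotations(dag: OntologyDag, cfg: SynthConfig) -> AnnotationTable:
    """Per protein, draw Poisson(mean_leaf_annotations) distinct DAG leaves
    and upward-close them; proteins drawing 0 leaves stay unannotated."""
    rng = np.random.default_rng(cfg.seed + 1)
    leaves = sorted(t for t in dag.terms if dag.is_leaf(t))
    proteins = [_protein_id(i) for i in range(cfg.n_proteins)]
    term_sets: dict[str, set[str]] = {}
    universe: set[str] = set()
    for p in proteins:
        n_draw = min(int(rng.poisson(cfg.mean_leaf_annotations)), len(leaves))
        picked = rng.choice(len(leaves), size=n_draw, replace=False) if n_draw else []
        closed: set[str] = set()
        for j in picked:
            leaf = leaves[int(j)]
            closed.add(leaf)
            closed |= dag.ancestors(leaf)
        term_sets[p] = closed
        universe |= closed
    return AnnotationTable(proteins, term_sets, universe)


def write_obo(dag: OntologyDag, stream) -> None:
    stream.write("format-version: 1.2\n")
    stream.write(f"default-namespace: {SYNTH_NAMESPACE}\n")
    for t in sorted(dag.terms):
        stream.write("\n[Term]\n")
        stream.write(f"id: {t}\n")
        stream.write(f"name: {dag.names.get(t, t)}\n")
        stream.write(f"namespace: {dag.namespaces.get(t, SYNTH_NAMESPACE)}\n")
        for parent in sorted(dag.parents(t)):
            stream.write(f"is_a: {parent}\n")


def write_gaf(table: AnnotationTable, stream, evidence: str = "IDA", aspect: str = "P") -> None:
    """GAF 2.1 rows, one per (protein, term) pair; unannotated proteins are
    necessarily omitted (a GAF record requires a term)."""
    stream.write("!gaf-version: 2.1\n")
    for p in table.proteins:
        for t in sorted(table.term_sets[p]):
            cols = [
                "SYNTH", p, p, "", t, "SYNTH:0000001", evidence, "", aspect,
                "", "", "protein", "taxon:0", "20150101", "SYNTH", "", "",
            ]
            stream.write("\t".join(cols) + "\n")


def write_fixture(dag: OntologyDag, table: AnnotationTable, directory: str | Path) -> tuple[Path, Path]:
    """Emit an OBO + GAF pair that round-trips through the parsers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    obo_path = directory / "ontology.obo"
    gaf_path = directory / "annotations.gaf"
    with open(obo_path, "wt", encoding="utf-8") as fh:
        write_obo(dag, fh)
    with open(gaf_path, "wt", encoding="utf-8") as fh:
        write_gaf(table, fh)
    return obo_path, gaf_path
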