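import pytest

from drwgo.annotations import AnnotationTable
from drwgo.ontology import OntologyDag
from drwgo.synth import SynthConfig, generate_annotations, generate_dag


@pytest.fixture
def chain_dag():
    """c0 -> c1 -> c2 (single-parent chain)."""
    return OntologyDag(
        ["c0", "c1", "c2"],
        [("c0", "c1"), ("c1", "c2")],
        namespaces={t: "synthetic" for t in ["c0", "c1", "c2"]},
    )


@pytest.fixture
def diamond_dag():
    """d0 -> {d1, d2}; d1 -> d3; d2 -> d3."""
    return OntologyDag(
        ["d0", "d1", "d2", "d3"],
        [("d0", "d1"), ("d0", "d2"), ("d1", "d3"), ("d2", "d3")],
        namespaces={t: "synthetic" for t in ["d0", "d1", "d2", "d3"]},
    )


@pytest.fixture
def chain_table(chain_dag):
    """One protein annotated with the full chain closure."""
    return AnnotationTable(["p0"], {"p0": {"c0", "c1", "c2"}}, {"c0", "c1", "c2"})


def make_random_dag(seed, n_terms=30, max_depth=6, max_parents=3):
    cfg = SynthConfig(n_terms=n_terms, max_depth=max_depth, max_parents=max_parents, seed=seed)
    return generate_dag(cfg)


def make_random_dataset(seed, n_terms=30, n_proteins=20, mean_leaf_annotations=2.0):
    cfg = SynthConfig(
        n_terms=n_terms,
        n_proteins=n_proteins,
        mean_leaf_annotations=mean_leaf_annotations,
        seed=seed,
    )
    dag = generate_dag(cfg)
    table = generate_annotations(dag, cfg)
    return dag, table


@pytest.fixture
def random_dataset():
    return make_random_dataset(seed=11)
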