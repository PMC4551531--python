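# drwgo

Downward random walks with restart on the Gene Ontology DAG for replenishing
missing functions of partially annotated proteins.

Starting from a protein's known GO terms, a restart walk propagates
probability mass downward (parent to child only) with transition weights
derived from Lin's structure-based semantic similarity; an adaptive
threshold turns the walk profiles into per-candidate likelihoods (dRW).
A kNN layer fuses these likelihoods with the annotations of the most
semantically similar proteins (dRW-kNN).  Both methods can score terms that
are present in the hierarchy but annotated to no protein at all.  Baselines
(frequency ranking, annotation-transfer kNN), similarity variants
(corpus IC, equal edge weights), multi-label evaluation metrics, a
leaf-masking experiment protocol, and a historical-rollback comparison are
included, together with a seeded synthetic ontology/annotation generator so
everything is testable offline.

## Layout

| module | contents |
| --- | --- |
| `drwgo.ontology` | OBO parsing, the term DAG, true-path propagation, protein-leaf frontiers |
| `drwgo.annotations` | GAF parsing, evidence-code filtering, support filtering, sparsity strata |
| `drwgo.semantics` | structure/corpus information content, Lin similarity, protein similarity |
| `drwgo.walk` | filtered transition matrix, downward restart walk, likelihood aggregation |
| `drwgo.predict` | dRW, dRW-kNN, ITSS-style and Naive predictors, score matrices |
| `drwgo.evaluation` | MacroF1, AvgROC, 1-RankLoss, RAccuracy, Fmax, Coverage, per-term AUC |
| `drwgo.experiment` | leaf masking, repeated evaluation harness, rollback validation |
| `drwgo.synth` | synthetic DAG + annotation generator, OBO/GAF fixture writer |
| `drwgo.cli` | the `drw` command-line tool |

## CLI

Generate a synthetic fixture, predict, and run the masking experiment:

```sh
drw synth --terms 50 --proteins 100 --seed 1 --out fixture/
drw predict --obo fixture/ontology.obo --gaf fixture/annotations.gaf \
    --method drw-knn --k 10 --eta 0.5 --iters 10 --min-support 3 \
    --out scores.tsv
drw mask-experiment --obo fixture/ontology.obo --gaf fixture/annotations.gaf \
    --methods drw,drw-knn,itss,naive --m 1,3,5 --repeats 10 --seed 7 \
    --out summary.tsv
```

Real GO/GOA inputs work the same way (`--namespace biological_process`
restricts to one sub-ontology; IEA/NR/ND/IC-evidence records are dropped by
default).  To validate predictions made from an older annotation release
against a newer one:

```sh
drw rollback --obo go.obo --old goa_2010.gaf --new goa_2014.gaf \
    --method drw --top 100 --tpr --out rollback.tsv
```

`drw evaluate --scores scores.tsv --truth masked_pairs.tsv --out report.txt`
recomputes all metrics for an existing score table.  A `--config file`
holding `key=value` lines can stand in for repeated flags.

## Acceptance checks

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs every acceptance criterion (closed-form walk oracles, dense-matrix
walk equivalence, the k=1 identity between dRW-kNN and dRW, normalization
and bound checks, masking-protocol invariants, metric sanity cases, a
direction-only recovery comparison against the frequency baseline, and
byte-level determinism) on seeded synthetic data, then writes the target
JSON.  A non-zero exit means a criterion failed.
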