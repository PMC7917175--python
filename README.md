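# immunoscape

A tested, reusable implementation of a tumor immunotyping workflow for bulk
expression cohorts — the kind of analysis used to nominate mRNA-vaccine
antigen candidates in pancreatic adenocarcinoma and to stratify patients
into immune subtypes for vaccination.  The package takes gene-by-sample
FPKM matrices, clinical follow-up, somatic mutation catalogs, immune
infiltration scores and gene-set collections, and provides:

* **Antigen screening** — the intersection of overexpressed
  (|log2FC| > 1, BH q < 0.01, up-regulated), mutated, OS- and RFS-adverse
  (median-split log-rank p < 0.05, HR > 1) and antigen-presenting-cell
  correlated genes (purity-adjusted partial Spearman, p < 0.05), with
  favorable-prognosis genes excluded and reported separately.
* **Consensus subtyping** — PAM over 1 − Pearson distance on bootstrap
  subsamples (80% of patients, without replacement); the consensus-CDF
  area A(k) and delta area Δ(k) = (A(k) − A(k−1))/A(k−1) select k; final
  labels IS1..ISk.
* **Cross-cohort validation** — correlation nearest-centroid projection,
  in-group proportion (IGP) and centroid Pearson correlation.
* **ssGSEA** — rank-weighted single-sample enrichment scores
  (weight rank^0.25), with ANOVA/Kruskal subtype association and BH FDR.
* **Co-expression modules** — |cor|^β adjacency (β = 4), topological
  overlap, average-linkage clustering with a static branch cut
  (min module size 30, merge height 0.25), eigengenes, kME and hub genes
  (kME > 0.9), module survival association.
* **Immune landscape** — a DDRTree-style principal tree (orthonormal
  projection, ≤ 4 components, minimum-spanning-tree-linked centers) with
  branch-based subtype subsets and survival comparison of extreme tree
  positions.
* **Survival statistics** — local Kaplan-Meier, log-rank (two- and
  k-group), Cox PH with Efron ties (Newton-Raphson, step halving), median
  splits, chi-square association, BH FDR.
* **Synthetic cohorts** — a first-class generator planting subtypes,
  modules, antigens, survival and mutation-burden effects, so the whole
  pipeline is testable end to end without any downloads.

See `docs/methods.md` for the models, parameters and design choices.

## Worked example

Discover immune subtypes in a synthetic 200-patient cohort with five
planted subtypes (`examples/03_consensus_subtypes.py`):

```python
from sklearn.metrics import adjusted_rand_score
from immunoscape import (GeneratorConfig, generate_cohort,
                         preprocess_expression, run_consensus)

cfg = GeneratorConfig(n_samples=200, n_genes=300, n_subtypes=5, delta=5.0)
bundle = generate_cohort(cfg, seed=1)
expr = preprocess_expression(bundle.expression)
res = run_consensus(expr.values.T, k_range=range(2, 9), B=100, frac=0.8, seed=1)
```

prints

```
k   A(k)    delta(k)
2  0.494   0.4945
3  0.653   0.3210
4  0.740   0.1321
5  0.804   0.0872
6  0.824   0.0253
7  0.843   0.0231
8  0.861   0.0212
chosen k = 5 (delta_area>=0.05)
subtype sizes: {'IS1': 40, 'IS2': 40, 'IS3': 40, 'IS4': 40, 'IS5': 40}
adjusted Rand index vs planted subtypes: 1.000
```

The consensus-CDF area keeps rising sharply while added clusters are real
(Δ ≥ 0.05 up to k = 5) and collapses once k exceeds the planted number, so
the delta-area rule picks k = 5; the final partition matches the planted
subtypes exactly (ARI 1.0).  The other scripts in `examples/` walk through
cohort simulation, the antigen funnel, cross-cohort validation, signature
scoring, module discovery and the immune landscape in the same style.

## Command line

The same pipeline runs from a shell over a YAML config:

```sh
immunoscape all --config pipeline.yaml --seed 1 --outdir out/
immunoscape cluster --seed 1 --outdir out/        # one stage + prerequisites
```

Every run writes TSV outputs plus `provenance.json` (config hash, seed,
SHA-256 of each output); identical config and seed reproduce byte-identical
files.

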