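# mircausal

Prioritizing **causal** miRNA–disease associations — pairs where the miRNA
is directly involved in the disease mechanism — over merely correlated
(non-causal) ones.

Most miRNA–disease predictors score general association and cannot separate
a miRNA that drives a disease from one that is only differentially expressed
in it. `mircausal` targets exactly that harder discrimination. It is aimed
at computational biologists who have a table of curated causal/non-causal
associations (HMDD-style), miRNA sequences, expression and pathway-enrichment
profiles, and a disease vocabulary with MeSH tree numbers, and who want a
ranked list of candidate causal pairs.

## Model

Let `MD` be the binary `nm × nd` causal association matrix. Four miRNA
similarity matrices are built:

- **Sequence, `MS_S`** — precursor, mature and seed sequences are compared by
  Levenshtein distance, `MS(m1, m2) = 1 − LD(m1, m2)/(len(m1)+len(m2))`
  (for equal-length strings this lies in `[0.5, 1]`), and blended as
  `MS_S = 0.05·MS_SP + 0.05·MS_SM + 0.9·MS_SS`.
- **Expression, `MS_E`** — per cell type, expression is quartile-coded
  `A–D` across all miRNAs; the resulting strings are compared by the same
  edit-distance similarity.
- **Pathway, `MS_P`** — enrichment p-values are graded `C` (< 1e-4),
  `B` (< 0.01), `A` (< 0.05), `N` (non-significant), keeping only pathways
  with ≥ 3 significant miRNAs, and again compared by edit distance.
- **GIP kernel, `GM`** — `exp(−γ‖IP(i)−IP(j)‖²)` over rows of `MD`, with
  `γ` normalized by the mean squared profile norm.

Diseases are compared with Wang-style semantic similarity `DS` over the
MeSH DAG: ancestor contributions decay by `Δ = 0.5` per edge (taking the
max over paths), and two diseases score by the contribution mass of their
shared ancestors.

For each miRNA similarity source `MS ∈ {MS_S, MS_E, MS_P, GM}` a
similarity-regularized factorization finds `k`-dimensional projections
`M` (k×nm) and `D` (k×nd) minimizing

```
Σ_{(i,j): MD(i,j)=1} (MᵀD − 1)²_{ij}  +  λ₁‖MᵀM − MS‖²_F  +  λ₂‖DᵀD − DS‖²_F
```

by monotone alternating block gradient descent. The four score matrices
`MD′ = MᵀD` are integrated as

```
MD′ = 0.35·MD′_S + 0.40·MD′_E + 0.15·MD′_P + 0.10·MD′_G
```

with weights re-fittable by exhaustive search on a 0.05-step simplex
lattice. Evaluation uses leakage-masked k-fold cross-validation (the GIP
kernel and the factorization only ever see the training-masked matrix),
AUROC, and Wilcoxon rank-sum comparisons between the causal, non-causal
and unassociated score groups.

## Worked example

The package ships a synthetic benchmark generator that plants the structure
the model exploits: miRNA sequence families, family-shaped expression and
pathway profiles, a random MeSH-style disease tree, and causal links
concentrated in (family × disease-subtree) blocks with weaker non-causal
labels inside the same blocks.

```
$ mircausal simulate --seed 7 --out demo_data
$ mircausal cross-validate --data demo_data --folds 5 --seed 7 --out cv_report.json
{
  "n_folds": 5,
  "fold_aurocs": [0.8623, 0.8557, 0.8498, 0.8465, 0.8529],
  "pooled_causal_vs_none": 0.8533,
  "macro_causal_vs_none": 0.8534,
  "pooled_causal_vs_noncausal": 0.6991
}
```

Held-out causal pairs are ranked well above unassociated pairs
(AUROC ≈ 0.85) and, more importantly, above non-causal pairs from the very
same blocks (AUROC ≈ 0.70 against a ≈ 0.5 chance baseline) — the
discrimination this model exists for.

```
$ mircausal train --data demo_data --out demo_model
$ mircausal predict --scores demo_model/scores_integrated.tsv \
      --data demo_data --sort disease --out predictions.tsv
$ head -4 predictions.tsv
rank  mirna         disease               score   known_causal
1     hsa-mir-0037  synthetic disease 00  0.8398  1
2     hsa-mir-0043  synthetic disease 00  0.7576  0
3     hsa-mir-0044  synthetic disease 00  0.7233  0
```

Per disease, known causal miRNAs surface at the top and the unlabelled
high-rankers are the model's causal candidates. The same stages are
available from Python:

```python
>>> import mircausal as mc
>>> mc.pair_similarity("AAAA", "CCCC")      # equal-length similarity floor
0.5
>>> dag = mc.build_dag({"glaucoma": ["C11.525.381"]})
>>> mc.semantic_contributions(dag, "glaucoma")
{'C11.525.381': 1.0, 'C11.525': 0.5, 'C11': 0.25}
```

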