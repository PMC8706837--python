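# Methods

## Problem setting

Given a curated set of causal miRNA–disease associations, the package
scores every miRNA–disease pair for causal potential, with the specific aim
of ranking causal pairs above *non-causal* ones (miRNAs differentially
expressed in a disease without mechanistic evidence). The model assumes
that (i) miRNAs similar in sequence, expression context or pathway
footprint tend to cause similar diseases, and (ii) diseases close in the
MeSH hierarchy tend to share causal miRNAs.

## Feature strings and edit-distance similarity

Every miRNA feature is rendered as a string over a small alphabet and pairs
are compared by unit-cost Levenshtein distance (computed with the `edlib`
C library), normalized as `1 − LD/(len1+len2)`. For equal-length strings
at most `max(len)` edits are needed, so the value cannot drop below 0.5;
the all-mismatch case (e.g. `AAAA` vs `CCCC`) attains that floor exactly.
Distances are computed once per unordered pair; the matrix is symmetric
with unit diagonal by construction.

- **Sequences.** Precursor, mature and seed FASTA inputs give `MS_SP`,
  `MS_SM`, `MS_SS`, blended with weights (0.05, 0.05, 0.9) — the seed
  region dominates because it governs target recognition. Mature-arm ids
  (`-5p`/`-3p`) are collapsed onto precursor-level ids, keeping the
  first-listed arm; this is a deliberate convention since no principled
  choice exists between two arms of one hairpin.
- **Expression.** Each cell-type column is quartile-coded A–D across all
  miRNAs using linear-interpolation sample quantiles; a value exactly at a
  cut goes to the lower bin, and missing values take the lowest label
  (absent ≈ not expressed). Per-column (rather than global) quantiles are
  used so that each cell type contributes one comparable character
  regardless of its dynamic range.
- **Pathways.** Pathways with fewer than three miRNAs at p < 0.05 are
  dropped; remaining p-values are graded C (p < 1e-4), B (p < 0.01),
  A (p < 0.05), N otherwise. Boundaries are closed on the more-significant
  side so the mapping is total and deterministic; missing p-values grade N.
  Any bijective renaming of these alphabets leaves all downstream
  distances unchanged (tested).

A miRNA absent from a feature source keeps similarity 1 to itself and 0 to
all others in that source, so no miRNA is silently dropped.

## GIP kernel

`GM(i,j) = exp(−γ‖IP(i)−IP(j)‖²)` over rows of the binary association
matrix, with `γ = γ′/mean(‖IP‖²)` and `γ′ = 1` (the standard choice).
An all-zero matrix degenerates to the identity kernel with a warning.
Because the kernel derives from the labels, it is recomputed from the
training-masked matrix inside every evaluation fold.

## Disease semantic similarity

MeSH tree numbers are expanded into prefix chains (each code points to its
immediate prefix); a disease with several codes owns several chains, and
its ancestor set T(D) is their union. Contributions decay as
`DD(D) = 1`, `DD(d) = max{Δ·DD(d′) : d′ child of d within T(D)}` with
`Δ = 0.5` by default, evaluated in topological order (children before
parents), which equals `Δ^(shortest path)` and is cross-checked against a
path-enumeration oracle. Similarity is
`DSS(Di,Dj) = Σ_{d∈T(Di)∩T(Dj)} (DD_i(d)+DD_j(d)) / (DC(Di)+DC(Dj))`.
Diseases missing from the mapping get 0 off-diagonal with a logged
warning rather than an error, keeping the matrix total.

## Factorization

The objective fits `MᵀD` to 1 on known-positive cells only and pulls the
factor Grams toward the similarity matrices:

```
f(M,D) = Σ_{MD=1}(MᵀD−1)² + λ₁‖MᵀM − MS‖²_F + λ₂‖DᵀD − DS‖²_F.
```

The Gram form (`MᵀM`, nm×nm) is the only reading dimensionally consistent
with `MS`. Zero cells are left unconstrained by the fit term on purpose:
unobserved pairs are scored purely through similarity structure, which is
what allows unseen causal pairs to surface.

The quartic Gram regularizer rules out closed-form alternating least
squares, so the objective is minimized by alternating block gradient
descent: per block, a Barzilai–Borwein step proposal safeguarded by a
backtracking line search that only accepts non-increasing objectives.
This makes every fit trace monotone (asserted on every fit) and typically
converges in ~200 iterations on the benchmark sizes here. Analytic
gradients are verified against central finite differences (≤ 1e-4
relative). Factors initialize uniformly in `[0, 1/√k)` from a seed, so
initial scores have magnitude ~1; fitting is bitwise reproducible per seed.

Defaults: `k = 64`, `λ₁ = λ₂ = 1.0`, `max_iters = 500`, `tol = 1e-6`
(relative objective change), `seed = 0`. These are documented package
choices — reasonable for problems of a few hundred entities per side — and
all are exposed in `ModelConfig`.

## Integration and weight search

Per-source score matrices are combined as
`0.35·S + 0.40·E + 0.15·P + 0.10·G`. Scores are used raw (no per-source
rescaling): all four derive from the same factorization target scale, so
rescaling would only distort the calibrated weights; a min–max switch is
intentionally not enabled by default. The weight search enumerates the full
simplex lattice at a given step (count `C(1/step+3, 3)`), maximizing
validation AUROC with lexicographically-smallest tie-breaking.

## Evaluation protocol

Causal cells are split into balanced folds (or a single independent split
with `|test| = round(fraction·n)`). In each fold the held-out positives are
zeroed before the GIP kernel or any factorization sees the matrix — a
structural leakage guard the tests assert on every fold. Fold AUROC
compares held-out causal scores with all unassociated cells (full
enumeration, for determinism, rather than negative sampling); both pooled
and macro-averaged CV AUROCs are reported. The causal-vs-non-causal AUROC
pools held-out causal scores against the non-causal cells scored by the
same fold's model. AUROC equals the Mann–Whitney pair statistic (ties 0.5);
rank-sum tests use exact enumeration for tie-free groups of ≤ 8 and the
tie- and continuity-corrected normal approximation otherwise. The normal
approximation is only trusted to ~10% relative accuracy outside the deep
tail (p ≳ 0.05), which is how the branch-agreement test is scoped.

## Synthetic benchmark

The generator emulates the structure the model assumes: 60 miRNAs in 6
sequence families (ancestral precursor 80 nt / mature 22 nt / seed 7 nt,
members mutated per-base at rate 0.10), family-mean expression over 20 cell
types (means U(0,10), noise N(0,1)), family-specific significant pathway
sets (12 of 60 pathways per family; significant p ~ U(1e-6, 0.04), others
U(0.06, 1)), and 40 diseases in a random recursive tree serialized as
MeSH-style codes. Each family links to one random mid-sized disease
subtree; block cells are causal with probability 0.8 and otherwise
non-causal with probability 0.15 — non-causal labels live *inside* linked
blocks (same biology, weaker evidence) precisely so that causal/non-causal
discrimination is harder than causal/none. Background cells are labeled at
rate 0.02 per label. All randomness flows from one `numpy` generator
seeded by a single config seed; entities never otherwise mentioned are
pinned into the association table by explicit `none` rows so the universe
is stable.

At these default conditions, 5-fold CV recovers held-out causal pairs with
pooled causal-vs-none AUROC ≈ 0.85 and causal-vs-non-causal ≈ 0.70, while
a label-shuffled null run of the identical pipeline sits near 0.5 — the
package's own recovery experiment, recomputed by the acceptance tests.

What the generator does **not** emulate: realistic miRBase sequence
composition and length variation, HMDD evidence-category structure,
cross-family sequence homology, disease co-annotation biases, and the
scale of real catalogues (hundreds of miRNAs and diseases, 1409 pathways,
137 cell types). Passing tests therefore demonstrate that the machinery
recovers planted structure of the assumed kind at desk scale, not that
real-data accuracy figures are reproduced.

## Numerical conventions and degenerate inputs

Similarity matrices are validated for symmetry/unit diagonal to 1e-12 and
declared bounds to 1e-9. Weight vectors must sum to 1 within 1e-9.
Prediction ranking ties break by (score desc, miRNA id asc, disease id
asc). Two empty strings have undefined similarity (error); an empty
feature map, an all-zero association matrix (identity kernel + warning),
and empty label groups (comparison reported absent) are all handled
explicitly. Problem sizes in the tests (24–60 miRNAs, 12–40 diseases,
k = 6–64) are chosen to keep the full suite in seconds while still
exhibiting the planted-recovery behaviour.

## Known limitations

- Predictions are confined to diseases with at least one known causal
  association; a disease absent from training cannot be ranked sensibly.
- The optimizer guarantees monotone descent to a stationary point, not a
  global optimum; different seeds give slightly different factors (the
  recovery metrics move in the third decimal).
- Integration weights are global, not per-disease.
- The MeSH mapping is consumed as a pre-extracted two-column table; native
  MeSH descriptor files are out of scope.
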