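# Methods

`xenosig` implements a cross-species single-cell analysis chain: quality
control and zonation of hepatocyte scRNA-seq count matrices, extraction of
an up/down differential-expression signature for a reporter-labeled
(p16-high, "Tom+") hepatocyte population, conversion of that mouse
signature into human gene symbols by two independent routes, and per-cell
"Tom scores" that rank human hepatocytes by transcriptomic similarity to
the mouse population. This note records the models, the defaults and why,
and what the synthetic data can and cannot establish.

## Quality control and zonation

A cell is summarized by detected genes, total UMI and mitochondrial UMI
fraction (computed from the `mito` flag in gene metadata, never from symbol
prefixes, to avoid species symbol-dialect bugs). Three named presets carry
the thresholds of the fixed-cell hepatocyte workflow this package mirrors:

| preset            | mito ≤ | genes in        | UMI ≤   |
|-------------------|--------|-----------------|---------|
| `mouse_hepatocyte`| 0.05   | [2000, 10 000]  | 100 000 |
| `mouse_hsc`       | 0.05   | [2000, 7000]    | 50 000  |
| `human_hepatocyte`| 0.05   | [1500, 6000]    | 40 000  |

All comparisons are strict in the exclusion direction ("exceeding",
"fewer than", "greater than"), so boundary values are **kept**.

Normalization is counts-per-10k followed by natural `log1p` (the common
single-cell default; nothing downstream assumes more). Clustering is
k-means over PCA of the top dispersion-ranked highly variable genes
(default 2000 HVGs, 20 PCs, k = 8); a Leiden graph option exists but
k-means is the default because the upstream workflow names no algorithm
and k-means is deterministic given a seed with no extra graph machinery.
Contaminant clusters (immune/stromal/endothelial admixture) are dropped
when their mean marker score (Ptprc/Dcn/Pecam1, or upper-case human
equivalents) exceeds 3x the across-cluster median — the source rule is
qualitative ("clusters expressing ..."), so the multiple is explicit and
configurable — or when the cluster's median detected-gene count falls
below the 10th percentile of cells (also configurable; the source states
no cutoff).

Zonation: per-cell mean log-normalized expression of zone marker pairs
(zone 1 Sds/Cyp2f2, zone 2 Hamp/Igfbp2, zone 3 Glul/Cyp2e1), label =
argmax, exact ties -> `unassigned`.

## Differential expression

Two-sided Wilcoxon rank-sum per gene (exact enumeration when both groups
have ≤ 8 cells, otherwise the tie- and continuity-corrected normal
approximation), Benjamini–Hochberg step-up adjustment across tested genes,
and log2 fold changes on de-logged normalized means with a 1e-9
pseudocount. A gene is called up when log2FC > 0.3 **and** q < 0.05 (both
strict), down symmetrically. Genes detected in fewer than 10% of cells in
both groups are skipped by default (off in oracle tests). The rank-sum
test is the de-facto default of the marker-finding function the workflow
names; the test choice is not stated there.

## GSVA

Implemented from scratch per the published algorithm: (1) a per-gene
kernel CDF across cells — Gaussian kernel with bandwidth sd/4 on log-scale
input (default), Poisson kernel for raw counts, or a plain ECDF mode that
is exactly rank-invariant; constant genes map to 0.5; (2) the symmetric
rank statistic |p/2 − rank|; (3) a weighted KS-like random walk down each
cell's gene ranking with in-set increments ∝ statistic^tau (tau = 1) and
uniform out-of-set decrements. The default score is max positive deviation
plus max negative deviation (`max_diff`, the reference implementation's
default; the variant is not stated by the workflow we mirror), bounded in
[−1, 1]. Set-size limits default to [5, 500]. Ties in the per-cell ranking
break by gene index, which makes scores deterministic and
permutation-equivariant.

## Cross-species conversion

**Homology-key route.** A table of (mouse symbol, human symbol, class key)
rows; a mouse symbol converts to every human symbol sharing one of its
class keys, deduplicated in order of first appearance, with unmapped
symbols reported.

**Macrogene route.** Genes of both species are columns of a nonnegative
weight matrix `W` (M macrogenes x genes), initialized as
`softplus(−dist)` from k-means centroids over protein-embedding vectors,
so genes with similar embeddings start with similar columns. `W` is then
refined by an autoencoder: per-cell macrogene expression `c = x_lognorm ·
W_s^T` (species-restricted columns), a shared linear encoder, a
species-specific linear decoder head with softplus output giving ZINB
means, and per-gene dispersion/dropout parameters. The loss is the ZINB
negative log-likelihood per matrix entry (`L_rc`) plus `lambda_s · L_s`,
where `L_s` is the mean squared difference between weight-column cosine
similarity and protein-embedding cosine similarity over all cross-species
gene pairs — a concrete operationalization of "weights capture
similarities in the embedding space", which has no published closed form.
`lambda_s` defaults to 1.

Training uses Adam (lr 1e-3) on hand-derived analytic gradients
(unit-tested against finite differences); no autodiff framework is
involved. The default is full-batch gradient descent: at desk scale
(hundreds of cells) it is cheap, the recorded loss trace is smooth, and
runs are bitwise-reproducible; a minibatch size can be set for larger
data. Nonnegativity of `W` is enforced by softplus reparameterization so
cosine similarities stay interpretable as overlap of additive gene
groups. All-zero genes are excluded before training (their ZINB fit is
unidentifiable) and reported.

Gene pairing: cosine similarity of the mouse and human weight columns;
pairs above 0.85 (strict) are accepted. The reference configuration for
this framework is M = 5000 macrogenes over 12 000 highly variable genes
per species with 2000 pretraining steps. Two desk-scale configurations
are used here, for two different purposes:

* **trainer characterization** — M = 50 over ~400 genes and 600 cells per
  species, 2000 steps: exercises the optimizer over many genes per
  macrogene and is the configuration of the trainer-sanity and
  ortholog-ranking checks (similarity AUROC is ~1 there regardless).
* **symbol conversion** — M = half the pooled panel (~2 genes per
  macrogene), 300 steps: the pairing *threshold* is what matters for
  conversion, and the fixed 0.85 cutoff is only precise when macrogene
  resolution is fine enough that non-orthologous genes rarely share a
  dominant macrogene. With the isotropic synthetic embeddings the
  reference ratio (~5 genes per macrogene) is still too coarse — weight
  columns are nonnegative, so two genes sharing one dominant macrogene
  cannot fall below ~0.85 cosine no matter how dissimilar their
  embeddings — hence the finer default for the conversion route
  (pipeline stage `crossmap`). Pairing quality there saturates within a
  few hundred steps.

Whether the 0.85 cutoff transfers across scales is unknowable from the
source, so it is exposed as a parameter rather than asserted; pairing can
also be run on the initialized (untrained) weights via `pretrain(...,
steps=0)`, since the source is ambiguous about whether pretraining may be
omitted.

## Tom score

The mouse up and down DEG lists are converted independently; a human gene
reached from both an up and a down mouse gene is removed from both lists
(conservative: one gene must not contribute to both scores) and reported.
Both converted lists are GSVA-scored per human cell; `tom = gsva_up −
gsva_down`. Cells are split into high/medium/low by tertiles of the score
(the source states no cutoffs; fixed numeric cutoffs are supported), with
all-equal scores mapping to `medium`. The Pearson correlation between the
up and down scores is computed across all scored cells; per-cluster means,
group fractions and sizes are tabulated.

## Synthetic data

The generator emulates exactly the structure the pipeline consumes:

* gene-wise ZINB counts (gamma–Poisson with structural dropout),
  lognormal baseline means (meanlog 1.2, sdlog 0.7) shared between
  ortholog partners so cross-species expression programs correlate;
* three zones at configurable fractions, zone markers boosted 8-fold in
  their zone; a signature subpopulation (default 10% of cells, placed in
  zone 3) carrying the up/down program at log2FC 1.5 in both species —
  observable in mouse metadata as a tdTomato-like reporter label, hidden
  in human (truth table only);
* a per-cell library-size factor, lognormal(0, 0.3) clipped to
  [0.6, 2.2] — the clip guarantees that intact cells cannot drift across
  QC thresholds, so planted outliers are exactly the QC exclusions;
* mitochondrial genes (mt-/MT- prefixed and flagged) rescaled to a 2%
  expected UMI fraction;
* outlier cells appended per species, cycling through three kinds that
  each violate exactly one threshold of the preset that species will be
  filtered with: high mito fraction (~25%), high UMI (1.5x the cap), and
  low complexity (counts restricted to a small boosted subpanel);
* a homology table with one class key per ortholog group plus optional
  2-mouse:1-human groups and unmapped orphans; protein embeddings where
  partners share a base vector up to additive noise (sd 0.05) and
  non-orthologs are independent.

Default sizes: 800 cells and 3500 genes per species for QC-scale runs
(3500 genes puts intact cells' detected-gene counts comfortably inside
every preset window); the desk crossmap configuration is 600 cells and
400 genes per species. These sizes, and the pipeline driver's defaults of
400-gene training panels with ratio-2 macrogenes and 300 pretraining
steps (conversion quality saturates well before that at this scale; the
module default remains 2000 steps), are the package's choices for a
complete run on a single CPU.

What the synthetic data does **not** model: batch and patient effects,
ambient RNA, true doublets (only threshold-violating outliers), continuous
zonation gradients (zones are discrete), spliced/unspliced layers, and
real orthology complexity beyond small many-to-many groups. Passing tests
therefore establish correctness of the algorithms and recoverability of
planted structure under ZINB noise — not performance on real cirrhosis
cohorts, which additionally face integration and composition effects that
are out of scope here.

## Numerical choices and degenerate inputs

* ZINB parameterization: mean mu, inverse-dispersion theta
  (Var = mu + mu²/theta), structural-zero probability pi ∈ [0, 1); the
  zero-branch likelihood is computed via `logaddexp` for stability.
* All-zero cells normalize to all-zero rows; constant genes get kernel
  CDF 0.5; a GSVA set equal to the whole panel is a per-set error while
  other sets still score.
* Exact zone-score ties -> `unassigned`; Tom-score ties break by stable
  cell order in the tertile split.
* Identical rank-sum samples return p = 1; zero-variance pooled samples
  short-circuit to p = 1.
* Matrix Market files are 1-indexed on disk (format standard), all
  internal indices 0-based; conversion only at the I/O boundary.
* Every stochastic component takes an explicit seed; there is no hidden
  global RNG state.

## Known limitations

* The macrogene autoencoder is linear apart from the softplus output; it
  is sized for desk-scale panels. At the reference scale (M = 5000,
  12 000 genes) the full-batch default and dense weight matrix would need
  minibatching and more memory.
* GSVA's Gaussian kernel CDF is O(genes x cells²); ~1000 cells x ~3500
  genes costs tens of seconds. The ECDF mode is O(genes x cells log cells)
  when that matters.
* The homology route treats the class-key table as ground truth; symbol
  aliasing and assembly differences in real MGI exports are not handled.
* Group comparison of GSVA scores uses Welch t-tests across cells, which
  ignores within-patient correlation in multi-donor data.
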