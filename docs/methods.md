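# Methods notes

## Scope and model

`lncnet` implements an integrative lncRNA–mRNA analysis for a two-group
bulk-RNA-seq design (6 patients vs 6 healthy controls sequenced; 12 vs 12
in qRT-PCR validation). The pipeline treats the expression matrix as
given (FPKM or counts); read QC, alignment and transcript assembly are
upstream and out of scope, as are the external coding-potential
predictors (pfam/CNCI/PLEK/CPC) and thermodynamic RNA-interaction tools,
for which the package provides pluggable interfaces with deterministic
built-in stand-ins (an ORF-length rule; an additive duplex scorer).

## Differential expression

The per-gene test is a Welch *t* on log₂(FPKM + 1). This is a
deliberately simple stand-in for a count-model test: at n = 6 + 6 with
log-normal abundance it is well calibrated (measured null rejection
rate ≈ 0.045 at α = 0.05 — slightly conservative, as expected for Welch
at small n) and it keeps the stage swappable. The fold-change screen is
two-sided on the pseudocounted ratio `(mean_case + 1)/(mean_control + 1)`
with ε = 1 FPKM. Note a boundary consequence: `(2m + 1)/(m + 1) < 2` for
every finite m, so a gene at *exactly* two-fold never passes a 2.0
threshold — the screen is conservative near the boundary, by design of
the pseudocount. Genes with zero variance in both groups get p = 1 when
the group means are equal and p = 0 otherwise. Raw p-values are screened
by default (matching the workflow's p < 0.05 rule); Benjamini–Hochberg
adjustment is available by flag.

## Coexpression network and MCL

Edges are lncRNA × mRNA pairs with |r| ≥ 0.8 and p < 0.05 on
log₂(FPKM + 1); absolute correlation is used because strong negative
coexpression is equally informative for target inference (a
`positive_only` flag restores the one-sided rule). The top 500 edges are
selected by (p ascending, |r| descending, lnc id, mRNA id) — the id
tie-breaks make selection deterministic under permutation.

MCL is implemented from scratch on a dense column-stochastic matrix with
self-loops of weight equal to the node's maximum incident |r|:
expansion (matrix power e = 2), inflation (entrywise power i = 2.0 then
column renormalization), pruning of entries below 10⁻⁵, until the
maximum entry change falls below 10⁻⁸ (cap 100 iterations, warning on
non-convergence). Clusters are connected components of the attractor
support (rows with nonzero diagonal); a node joins the cluster receiving
most of its steady-state mass, ties to the lowest cluster index.

Two properties of this design worth knowing:

- On a near-complete **bipartite** block (a dense lncRNA × mRNA module)
  inflation 2.0 converges to one hub-centred star attractor per side,
  i.e. the module splits in two. Inflation is MCL's granularity knob;
  at 1.5 such modules come out whole. The default stays at the canonical
  2.0; module-recovery checks run at 1.5.
- With a strong group effect (4-fold at n = 6/6), *every* pair of
  same-signed DE genes correlates at r ≈ δ²/4 / (δ²/4 + σ²) ≈ 0.92
  through the case/control shift alone, so correlation clustering on DE
  genes cannot separate planted modules from the shared-shift block.
  Module recovery is therefore assessed on simulations with the shift
  zeroed, where only the latent module factors drive correlation.

## Target inference

*cis*: distance is the gap between transcript spans (0 on overlap),
strand-agnostic and symmetric; the 300 kb window is inclusive at the
boundary. *trans* requires the coexpression edge, a duplex with
≥ 10 paired bases, and energy ≤ −50; cis pairs are excluded so the two
call sets partition the called pairs.

The duplex scorer searches ungapped antiparallel alignments: seeds of
≥ 6 consecutive exact Watson–Crick pairs extended in both directions
while the score improves (G·C −3, A·T −2, G·U wobble −1; a mismatch
would add +4 and stops extension). Energy is the pair-score sum, so a
stretch needs ~17–25 complementary bases (depending on GC content) to
reach −50. The energy unit is the scorer's own additive scale with the
convention "more negative = stronger"; the threshold "no more than 50"
is interpreted as ≤ −50 on this scale and is configurable. The scorer is
an interface: an adapter for a thermodynamic tool can replace it without
touching the trans-call logic.

## Enrichment

Counts follow the annotated-only convention: genes absent from every
supplied gene set are excluded from both the background N and the query
n. Fold enrichment is (m/n)/(M/N) and significance the hypergeometric
upper tail P(X ≥ m) (scipy survival function, log-space stable). Raw p
is reported; BH adjustment by flag.

## qRT-PCR and ROC

Technical replicates (3 per well) are averaged arithmetically;
ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the mean ΔCt of the
calibrator group (healthy controls — the conventional choice when the
workflow leaves it unstated); relative expression is 2^−ΔΔCt. Adding a
constant to every Ct cancels exactly.

AUC is the Mann-Whitney statistic with ties counted half, divided by
n_case · n_control, auto-oriented to ≥ 0.5 with the flip recorded. The
combined two-marker score is the linear predictor of an unpenalized
binomial logistic model fitted by IRLS (max 50 iterations, tol 10⁻¹⁰)
on standardized markers; under perfect separation the model is
unidentified and the implementation falls back to the better single
marker with a `separation` flag. A logistic combination is linear, so
the combined AUC is not guaranteed to dominate both single markers on
adversarial (XOR-like) inputs; on jointly Gaussian markers it tracks the
normal-theory optimum (checked against Φ(δ) in the tests).

## Synthetic data

The generator emulates the study conditions, not real RNA-seq in full:

- **Abundance**: log-normal, log₂x = μ_g + σ·ε with μ_g ~ N(5, 1.5²)
  and σ = 0.3 (log₂-scale noise SD). No library-size, GC or dispersion
  structure, and no count sampling — so the tests validate the
  statistical machinery, not robustness to sequencing artefacts.
- **DE**: a fraction (default 10%) of genes shifted by ±log₂fc (default
  2, i.e. 4-fold) in the case group, sign random per gene.
- **Modules**: genes drawn from the DE set (with a shared shift sign)
  loaded on one latent factor per module with loading √r, giving
  expected pairwise Pearson r equal to the target (default 0.9,
  measured per-seed mean 0.80–0.94 at n = 12 with the shift zeroed).
  Module genes are split half lncRNA / half mRNA so planted edges cross
  the bipartition.
- **Genome**: genes occupy slots spaced > 300 kb apart on a 4-chromosome
  toy genome; planted cis pairs share a slot with gap < 300 kb, so cis
  recovery is exact by construction (gap > window for every non-planted
  same-chromosome pair).
- **Sequences**: i.i.d. uniform ACGT with exact reverse-complementary
  stretches planted between duplex pairs, preferentially pairing genes
  within the same module so planted trans pairs also carry a
  coexpression edge. Default stretch length 25–40 nt: with pair energies
  −3/−2, 25 nt is the shortest stretch guaranteed to pass the −50 energy
  screen at any base composition (a 12-nt stretch scores only ≈ −30).
- **Ct tables**: reference gene near-constant at Ct ≈ 20; per-gene case
  shift of −log₂fc in Ct; replicate SD 0.15, between-sample SD 0.4.
- **Gene sets**: random terms over the mRNA universe with one term
  spiked with the module mRNAs.

One explicit integer seed drives every generator (internal offsets
separate the sub-streams); identical configs produce byte-identical
GTF/FASTA/TSV/JSON outputs.

## Problem sizes

Default test and acceptance runs use cohorts of 200–320 genes, 10-seed
recovery batches, a 20 × 200-gene null battery, brute-force oracles on
sequences ≤ 40 nt and universes N ≤ 12, and a toy end-to-end config
(320 genes, 120 edges) that completes in a few seconds — sizes chosen so
the full validation battery runs on a laptop in well under a minute per
suite while keeping every Monte-Carlo band meaningful.

## Known limitations

- The DE stand-in does not model count dispersion; results on real
  count data will differ from DESeq-family callers, especially for low
  counts.
- The duplex scorer is not thermodynamic: no nearest-neighbour ΔG,
  bulges or loops; its energy scale is internal and only comparable to
  itself.
- The location filter (same-strand containment in coding exons) and the
  novelty overlap criterion (≥ 50% exonic overlap) are parameterized
  conventions; real catalogs may need different settings per annotation
  source.
- Printed cohort-specific figures (DE counts, 281-node network, AUC
  0.754/0.785/0.871, published fold enrichments) depend on the original
  patient data and an unversioned annotation; they are design anchors
  here, not reproduction targets.
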