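# Methods

This note documents the models behind `cyclegate`, the defaults that matter,
what the synthetic generator does and does not emulate, and the numerical
choices a maintainer would want written down. It states no empirical result
that the test suite does not itself compute.

## Problem setting

Bone-marrow-derived macrophages polarized with IFNG (M1) or IL-4 (M2) do not
respond uniformly: the cell-cycle phase of an individual cell gates both its
transcriptional response and the persistence of induced chromatin. The
pipeline takes scATAC-seq fragments and scRNA-seq counts sharing cell
barcodes across five conditions — M0 (resting), M1, M2, M2p (IL-4 followed
by washout, "primed"), M1rep (IL-4-primed then IFNG-repolarized) — and
produces: per-cell phase calls, cell-cycle-sensitive / phase-biased gene
calls, transient/memory/primed classifications of induced open-chromatin
regions (OCRs), and co-accessibility-based enhancer–gene links.

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED). Fragments are assumed already
Tn5-shifted by upstream preprocessing. Every fragment contributes exactly
two insertion events, at `start` and `end − 1`, each weighted by the
fragment's duplicate count. Log-normalization is
`log2(1 + scale · count / cell_total)` with `scale = 1e4`; cells with zero
total map to zero rows.

## QC

* ATAC: per-barcode TSS enrichment = insertion rate per bp within ±50 bp of
  any TSS divided by the rate in 1901–2000 bp flanks on both sides, floored
  to avoid division by zero and capped at 100. Cells pass with enrichment
  ≥ 4 **and** ≥ 1000 fragments. The window geometry is a fixed convention —
  only the ≥ 4 cutoff feeds the pipeline. All "less than X" filters keep
  values equal to X.
* RNA: keep cells with mitochondrial fraction ≤ 12.5 % and ≥ 200 detected
  features. Doublet scoring is out of scope.

## Union peak set

Per-sample peak calls are re-centered to a fixed width (default 501 bp,
the de-facto standard) and retained greedily by descending score: keep the
best peak, discard everything overlapping it, repeat. Ties break to the
leftmost peak, making the result deterministic and order-invariant. For
equal scores this equals a maximum-cardinality non-overlapping selection
(fixed width ⇒ earliest-endpoint greedy).

## Iterative LSI, clustering, pseudotime

TF-IDF: `tf = count / cell_total`, `idf = log(1 + n_cells / (1 + df))`.
Iteration 1 uses the most abundant features; iteration 2 re-selects the
features most variable across provisional-cluster pseudo-bulk (log2-CPM)
profiles. Embedding = U·S from truncated SVD (scipy `svds` with a seeded
start vector); each component's sign is fixed by forcing its first nonzero
feature loading positive, so results are reproducible bit-for-bit given a
seed. Clustering is k-means (k-means++ with fixed seed) — deterministic and
dependency-light; k defaults to 10 (two clusters per condition, the
cycling/non-cycling split being the dominant within-condition structure).
Pseudotime projects each cell of path cluster *i* onto the segment towards
centroid *i+1* (the last cluster reuses the preceding direction), clips the
normalized projection to [0, 1], and maps to
`100 · (i − 1 + t) / k` — the conventional 0–100 scale. Cells of
off-path clusters get no pseudotime.

## Cell-cycle scoring

Module score = mean log-normalized expression of the signature genes minus
the mean of a control pool: genes are cut into 24 equal-frequency bins by
dataset-average expression and each signature gene draws 100 controls from
its bin (without replacement when the bin is large enough). Phase call:
G1 iff both S and G2M scores ≤ 0, otherwise the larger score wins; the tie
s = g2m > 0 resolves to S (arbitrary, documented). Scores are deterministic
given the seed.

## Differential layer

* **Rank-sum test**: exact enumeration over all C(n1+n2, n1) group
  assignments (midranks, so ties are handled exactly) when both groups have
  ≤ 8 observations; otherwise scipy's tie-corrected normal approximation.
  The two-sided exact p is P(|U − n1·n2/2| ≥ observed), using the symmetry
  of U under exchangeability.
* **Signed-rank test** (paired cluster comparisons): zero differences are
  dropped; no nonzero differences ⇒ p = 1. Exact distribution by dynamic
  programming over doubled midranks for n ≤ 25, tie-corrected normal
  approximation beyond.
* **Fold changes** are computed on the depth-normalized *linear* scale
  (back-transform `2^x − 1` of the log matrix), with
  `log2fc = log2((mean_a + ε)/(mean_b + ε))`, ε = 1/n_cells. Published
  thresholds such as "Log2FC ≥ 1" mean a 2× count-scale change; a ratio of
  log-transformed means would compress a 4× planted effect below every
  stated threshold.
* **BH correction** is statsmodels' step-up implementation, applied across
  features within each contrast.

## Cell-cycle sensitivity and phase bias

Within one condition, all three phase pairs (G1–S, G1–G2M, S–G2M) are
tested; a gene is CC-sensitive when any pair shows |FC| ≥ 1.3 at BH-adjusted
p ≤ 0.001 (the published convention; with cells as replicates the rank-sum
test replaces the original bulk DESeq2 — a deliberate substitution, since
re-implementing DESeq2 is out of scope, with thresholds kept as printed).
The "variance-stabilizing transform" is proxied by log2-normalized
expression: the three per-phase means are z-scaled (population sd, across
phase means rather than across samples — the ambiguity is resolved this way
and the truth labels of the simulator use the identical rule) and the biased
phase is argmax |z|. Note the consequence: a gene *depressed* in exactly one
phase is biased to that phase, and a gene elevated equally in S and G2M has
its largest deviation in G1.

## Chromatin behavior

With differential tables M2-vs-M0 and M2p-vs-M0 over the same peak
universe, a peak is "induced" at log2FC ≥ 1 and FDR ≤ 0.01. Behavior:
induced in M2 only → transient; in both → memory; in M2p only → primed;
otherwise unchanged. "Retained accessibility" is operationalized as
significant induction in M2p vs M0 (not M2p vs M2) — the only reading that
yields three disjoint classes plus a remainder from two
condition-vs-baseline contrasts.

## Co-accessibility and linking

Aggregates are a seed cell's 500 nearest embedding neighbors; candidates
overlapping an accepted aggregate by more than 80 % of their membership are
discarded. Aggregate profiles are depth-normalized by their genome-wide
totals and log2(1+x)-transformed; Pearson correlations are computed for
same-chromosome peak pairs with center distance ≤ 250 kb. Zero-variance
peaks yield correlation 0 with an `undefined` flag. A gene's promoter peaks
overlap TSS ± 1 kb; a peak with center within ±250 kb of the TSS is linked
iff it is co-accessible with a promoter peak at r ≥ 0.45 (the correlation
cutoff is not published; 0.45 is the exposed default). Distances are
center-to-center (pairs) and center-to-TSS (links).

## Synthetic multiome generator

The generator emits, per condition: a fragments table, a jittered
"called-peaks" BED with per-sample scores, and (once, across conditions) an
NB-distributed cells × genes count matrix sharing barcodes with the
fragments — plus a truth table of every planted label.

* **Cells.** Phases are discrete latent labels drawn i.i.d. from
  (0.80, 0.13, 0.07) — a resting-macrophage FACS distribution of ~73/12/6 %
  renormalized over the three phases. Default 600 cells per condition
  (3000 total).
* **RNA.** `counts ~ NB(mean = baseline · 2^(Σ active log2 effects),
  size = 10)`; baselines are lognormal(0, 1.5) — per-gene means spanning
  several decades, as in real libraries — scaled to 10 000 counts per cell
  (the UMI mass of a typical 10x cell concentrated on the 1000-gene panel).
  Gene classes and their activations: S/G2M markers high in their phase in
  every condition (contrast 2^5 ≈ 32×, the on/off specificity of canonical
  proliferation markers — the generic 4× polarization effect is far below
  what real phase markers show and would make zero-threshold phase calling
  impossible for any scorer), with baselines additionally scaled by 0.05 so
  that markers carry only ~1 % of resting UMI mass and their induction does
  not distort per-cell totals (the real-data composition); G1-biased
  induced genes high in
  M1/M2 G1 cells (4×); S-G2M-biased induced genes high in M2 S/G2M cells;
  phase-insensitive induced genes high in all M1/M2 cells; repressed genes
  4× down outside M0. M1rep reuses the induced program with effects
  attenuated ×0.5 in log space (dampened IFNG responsiveness after IL-4
  priming — a modeling choice). Ten null genes are flagged mitochondrial
  and carry ~5 % of baseline counts.
* **ATAC.** Per-cell per-peak fragment counts are Poisson with rates
  proportional to class weights (transient open in M2; memory in M2/M2p;
  primed in M2p; constitutive always open at 4×; null baseline), normalized
  within condition so the expected in-peak fragment count per cell is
  `frip · mean_fragments_per_cell` (0.25 · 2400). Fragment midpoints are
  uniform in their peak; background fragments are uniform over the genome;
  additional short (30–70 bp) fragments centered within ±15 bp of TSSs
  supply the TSS insertion enrichment (factor 10, typical of good
  libraries). Co-accessible pairs: enhancer and promoter peak share a
  per-cell on/off latent (P(on) = 0.5) with probability 0.8 (the planted
  correlation), on-weight 64 vs off-weight 0.5 — a deliberately strong
  regulatory element, needed because only ~40 low-overlapping aggregates of
  500 cells are available at desk scale and the aggregate-level null
  correlation is wide.
* **Genome layout.** Two 20 Mb chromosomes. Each enhancer–promoter–gene
  triple occupies its own 500 kb cassette (25 per chromosome): the promoter
  peak sits on the gene TSS and the enhancer 20–200 kb away, so planted
  pairs are always within the 250 kb window and neighboring cassettes are
  beyond it. Background peaks are evenly spaced in the remaining sequence;
  background gene TSSs sit between peaks, clear of promoter windows. The
  consequence — only planted genes have promoter peaks — means link
  recovery measures correlation recovery, not promoter-annotation
  ambiguity.
* **Determinism.** One `numpy` Generator seeded from the config; identical
  config ⇒ byte-identical outputs (gzip written with mtime = 0).

### What the generator does *not* emulate

Doublets, batch effects, read-level errors, chromatin contact structure,
continuous cell-cycle progression (phases are discrete), fragment-length
nucleosome banding, and realistic peak-count scale (2000 peaks stand in for
~10^5). A green recovery test therefore establishes that each stage
recovers its planted structure under idealized noise — not performance on
real libraries.

## Known limitations

* Phase calling thresholds at zero are only as good as the control-gene
  matching; heavily condition-skewed datasets shift module-score baselines.
* The behavior classifier's recall degrades gracefully when the realized
  (depth-normalized) fold change approaches the threshold; at the default
  600 cells/condition a planted 4× peak lands ~1.2 sd above it, so
  production-size experiments (thousands of cells per condition) are the
  intended regime.
* Aggregate-level co-accessibility with few, overlapping aggregates has a
  wide null; the linking step is protected by the promoter-proximity
  requirement, but raw pair correlations should not be interpreted at
  |r| < ~0.5 when fewer than ~100 aggregates are available.
* The exact rank-sum branch is limited to groups of ≤ 8 cells each
  (enumeration is infeasible for one-vs-rest contrasts otherwise).
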