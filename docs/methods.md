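# Methods

This note documents the models, conventions and design choices behind
`spotscreen`, in the order the pipeline runs.

## Read chemistry and demultiplexing

A chemistry profile declares the barcode-bearing mate as an ordered list
of segments: barcode (8 nt, matched against a whitelist), anchor (a fixed
10-mer ligation linker located with up to 1 substitution inside a ±2 nt
positional window), and UMI (10 nt). The payload mate carries the sgRNA
spacer followed by the first 10 nt of the tracrRNA scaffold, which acts as
the 3′ delimiter. Two variants are modelled: PAC (poly(A) capture — one
A/B layout shared by transcriptome and sgRNA reads) and DC (direct capture
— dedicated C/D barcodes and distinct linkers for the sgRNA mate; read
class is decided by which whitelist pair matches, with linker identity
breaking ties). Linker and flank sequences are configuration values; the
defaults are placeholders used by the simulator.

**Matching model.** All matching is substitution-only Hamming matching
with unique-best-hit semantics: a query maps to the single reference entry
within `max_mm` substitutions and is rejected when two entries tie at the
minimal distance. This reproduces the `-v`/`-m 1` behaviour of a
short-read aligner deterministically, without an aligner dependency.
Defaults: `max_mm` = 1 for 8-mer barcodes, 2 for 18–21-nt spacers, 0 for
UMI whitelist lookup; all configurable. Indel tolerance is deliberately
out of scope.

**Safety of error correction.** Correcting up to *m* substitutions is
unambiguous iff the whitelist's minimum pairwise Hamming distance is
≥ 2*m* + 1; the demultiplexer's 1-mismatch default therefore presumes
distance ≥ 3. The simulator's whitelist generator goes one step further
and designs sets with distance ≥ 4 (2*m* + 2): with distance exactly 3, a
*double* substitution can land within distance 1 of a *wrong* entry and be
silently miscorrected into a wrong channel, whereas distance 4 guarantees
double errors are dropped instead. That is the property a barcode designer
wants when spot identity is at stake.

**UMI whitelist.** Following the production pipeline's construction, the
whitelist is built from the data: candidate UMIs of length 10–12 without
N are truncated to 10 and counted; reads whose UMI is absent from the
whitelist are dropped (configurable to pass-through — the original
pipeline's behaviour for these reads is not documented, so both are
exposed). UMI deduplication keeps distinct (spot, sgRNA, UMI) triples; an
optional directional one-mismatch collapse (merge into a ≥ 2×-more-
abundant neighbour) is off by default since no collapse rule is published.

**Accounting.** Stages run in fixed order (extract → UMI → barcode x →
barcode y → spacer); a read failing several stages is counted once, under
the first. `assigned + Σ dropped = total` holds for every run, and the
whole demultiplexer is deterministic.

## Spot assignment and spatial statistics

The assignment rule is applied literally: ≥ 2 detected sgRNAs resolve to
the top one iff it has ≥ 10 UMIs and every other detected sgRNA has
exactly 1 (for detected sgRNAs, "exactly 1" and "≤ 1" coincide; the
`resolve_other_max` knob exposes the lenient reading). A tie for the top
count is ambiguous — the rule names a single top sgRNA and we decline to
break ties arbitrarily. sgRNA *area* counts spots with ≥ 1 UMI of the
guide, in spot units (×pitch² for physical area; thresholds in the
pipeline always use spot units). Burden is the count/fraction of region
spots carrying any sgRNA; region masks are spot-coordinate lists, not
image polygons.

The colocalization score of an sgRNA pair is a reconstruction (the
phenomenon is reported upstream without a formula): either the Jaccard
overlap of the two detection spot sets, or the fraction of one set's spots
with a partner within Chebyshev radius 1; significance comes from
shuffling both detection sets uniformly over tissue spots (sizes
preserved), p = (1 + #{perm ≥ obs}) / (1 + n_perm).

## Expression normalization and clustering

Raw counts are normalized as log-CPM at 10⁴ (ln(1 + 10⁴·c/libsize)) and
per-gene z-scored with clipping at ±10. This replaces the regularized-NB
variance stabilization used upstream — that transform is third-party
machinery, not method content — and the normalization layer is pluggable.

Clustering is Seurat-style: PCA (the number of PCs is the smallest count
explaining 80% of the variance captured by the top 50 components — a
formalisation of the visual elbow), a shared-nearest-neighbour graph
(Jaccard overlap of k = 20 neighbour sets, pruned below 1/15), and Leiden
modularity optimisation over resolutions 0.2–1.6 (step 0.2). The
resolution is chosen by **maximal average silhouette width among
partitions with more than 3 clusters**, with total within-cluster sum of
squares breaking silhouette ties (and a fallback to all multi-cluster
partitions when none exceeds 3 clusters). Silhouette leads because WSS
decreases almost monotonically with cluster count, so a WSS-first rule
systematically prefers over-split partitions; silhouette-first recovers
planted cluster structure exactly in our tests while still honouring both
criteria. UMAP (min_dist = 0.01) is computed for visualisation only; no
decision depends on it. One seed fans out to PCA/Leiden/UMAP, making every
stochastic output reproducible.

## Perturbation signatures, scores and pUMAP

Only sgRNAs detected with area ≥ 4 spots act as perturbations; spots
uniquely/resolvedly assigned to them are candidates, and the NP pool is
the spots with no sgRNA plus spots assigned to non-targeting controls
(the Mixscape convention for control guides). The signature of a spot is
its lognorm expression minus the mean of its k = 20 nearest NP spots in PC
space, with the neighbour search restricted to the spot's expression
cluster when that cluster holds ≥ k NP spots ("splitting by cluster"),
else the global pool; the spot itself is excluded.

For target *t*, v_t = mean signature(t-spots) − mean signature(NP),
restricted to the top m = 100 genes by |v_t|; the raw score of spot *i* is
⟨s_i, v_t⟩/‖v_t‖. **Scaling convention** (the largest reconstruction in
the package — the upstream scaling is unpublished, only the ±0.2
thresholds are): raw scores are centred at the midpoint between the
t-spot and NP means and divided by the 95th percentile of their absolute
value over t-spots ∪ NP spots. Perturbed spots then sit near +1 and NP
spots near −1, which is the geometry the two-sided ±0.2 filter presumes —
a scaling that leaves NP spots centred at zero would make the "NP if
score < −0.2" selector capture only a noise tail. Both the percentile and
the thresholds are configurable. Targets with < 3 spots get NaN scores and
are excluded with a warning.

The spot × target score matrix, restricted to classified (perturbed ∪ NP)
spots and column-standardised, is clustered exactly like expression
(pUMAP). A perturbation is *major* in a cluster iff its perturbed spots
are strictly > 20% of the cluster; clusters without a major perturbation
are labelled `NP + n` with n the number of distinct perturbations present.

## DE, GSEA and small-RNA statistics

Wilcoxon rank-sum DE runs per gene on the lognorm layer, two-sided. For
groups totalling ≤ 12 spots the p-value is the exact permutation
distribution of the U statistic (complete enumeration, ties included);
larger groups use the tie-corrected normal approximation (a constant gene
is reported at p = 1). log2FC uses expm1 of the lognorm group means with a
10⁻⁹ pseudocount; detection fraction is the share of spots with raw count
≥ 1; BH adjusts across genes. The "pseudo-replicate" variant — the term
is used upstream without a definition — randomly partitions each group
into r = 3 seeded pseudobulks and tests the r-vs-r per-gene means, falling
back to spot-level Wilcoxon (flagged) when a group cannot fill its
replicates with ≥ 5 spots each.

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum with hit
weight |rank|^0.1, set size bounds [2, 500], and seeded gene-label
permutations for p (null scores of the matching sign; NES = ES divided by
the mean |null ES| of that sign). The adaptive multilevel p refinement of
the upstream implementation is not reproduced — it is that library's
internals, and the plain permutation p serves the same inference. Results
drop the pathway names "Translation", "Transcription" and "Gene
Expression" (exact, case-sensitive), mirroring the published exclusion of
over-generic sets. The pipeline feeds log2 fold-changes of genes at
adjusted p < 0.2.

tRNA counts are aggregated per amino-acid isotype by parsing the isotype
token from feature names (`tRNA-His-GTG-1` → His; 20 canonical acids plus
iMet and SeC buckets; unparseable features are collected under `unknown`
with a warning, so per-spot totals are conserved). miRNA–target analysis
is a Spearman correlation across spots on the lognorm layer against a
user-supplied target list (target *prediction* is out of scope); negative
rho flags candidate repression.

## Recapitulation benchmark

The detection table pairs each sgRNA's pooled detection fraction with its
spatial area. Response = area > 2 spots; predictor = pooled fraction,
swept over all distinct thresholds; AUC is trapezoidal, which with the
half-credit tie convention is exactly Mann–Whitney U/(n₁n₀) — a property
the test suite verifies against a brute-force pairwise oracle. The
headline AUC reported for this comparison on real liver-tumor data (0.724)
requires the original sequencing data and is context only; the package
reproduces the construction and verifies it on synthetic tables.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical skeleton of a screen section:

* **geometry** — a random-growth tissue blob (~60% of a 50×50 grid),
  disjoint tumor regions plus parenchyma, and contiguous single-sgRNA
  clones (Poisson sizes, mean 55; seeded preferentially into tumor
  regions) that may overlap and share guides;
* **library** — 20 guides (18 targets + 2 NTCs) with random spacers at
  pairwise distance ≥ 6, standing in for a screen-scale library;
  only ~60% of guides ever form clones, so the rest provide true
  negatives for the benchmark;
* **molecules** — Poisson(40) UMIs per clone (spot, guide) pair, sparse
  1–2-UMI ambient background drawn from the clones present, 3 reads per
  UMI (~2×10⁵ read pairs at the defaults — sized so the whole pipeline
  runs in minutes), i.i.d. substitution errors at a configurable rate;
* **expression** — a 600-gene panel (500 coding, 40 tRNA over 20
  isotypes, 30 miRNA, 30 lncRNA) with log-normal baseline means (median
  1 count/spot) and NB dispersion ~0.3; each target multiplies 50 genes
  (half up ×f, half down ×1/f). Effect genes are drawn from the upper
  half of baseline expression, since an effect on a near-silent gene is
  unobservable at realistic depth;
* **pooled assay** — per-lobe detection probability logistic in clone
  size (floor 0.05 for absent guides), binomial over 10 lobes.

Not emulated: indels and quality-score structure in reads, PCR chimeras,
segmentation noise in tissue masks, cell-type compositional structure,
spatial expression gradients beyond clone geometry, and UMI collisions
beyond what uniform 10-mer sampling produces. Passing tests therefore
demonstrate correctness of the algorithms under a faithful molecular
bookkeeping model, not robustness to every artefact of real libraries.

## Numerical and determinism choices

* All randomness flows from explicit `numpy.random.Generator` seeds; the
  pipeline derives per-stage seeds as CRC32(global seed, stage) mod 2³¹.
  Reruns with an identical config are byte-identical (gzip members are
  written with mtime = 0 for this reason); manifests record parameters,
  seeds and output checksums and differ only in their timestamp.
* Anchor search prefers the expected offset, then scans by increasing
  positional deviation; exact flank hits beat closer inexact ones.
* Colocalization and GSEA p-values use the add-one permutation estimator,
  so p ∈ (0, 1].
* Spots with zero total counts are dropped at normalization with a
  warning; zero-variance genes scale to 0; silhouette is skipped for
  single-cluster partitions.
* The benchmark drops NaN scores with a warning and refuses single-class
  responses ("degenerate ROC").

## Known limitations

* The perturbation-score scaling is a reconstruction; absolute score
  values are comparable within a dataset, not across pipelines.
* Pseudo-replicate DE at r = 3 has a granular exact p (minimum 0.1); it
  ranks genes more than it sizes effects.
* The SNN/Leiden resolution selection optimises silhouette over a fixed
  grid; data with genuinely hierarchical structure may be summarised at
  either level depending on the grid.
* Demultiplexing is substitution-only; reads with indels in the fixed
  prefix are dropped at the anchor stage rather than rescued.
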