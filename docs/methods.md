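# Methods

This note documents the models and procedures tcellkit implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Single-cell QC (`tcellkit.qc`)

Barcode and gene filters act on smoothed densities of log10-transformed
marginals of the gene-by-barcode UMI matrix. The density is a Gaussian KDE
with Silverman's bandwidth by default (`bandwidth` is configurable, in
log10 units), evaluated on a 1,024-point grid spanning the data ± 3
bandwidths; all extremum locations are read off this grid, with ties
broken toward smaller x.

* **Cell calling**: the threshold is the smallest local *minimum* of the
  density of log10(#UMIs per barcode) whose location exceeds 2 (i.e. 100
  UMIs); barcodes below it are removed. "Above 2" refers to the x-axis
  location, not the density value.
* **Gene filtering**: the same rule on log10(#barcodes per gene), floor 3.
* **No-threshold results are explicit.** When no qualifying minimum
  exists, the `Threshold` object reports `found=False` and the pipeline
  leaves that axis unfiltered — never a silent default.
* **Prominence.** A candidate minimum (or mode) must differ from its
  flanking opposite extrema by at least 10 % of their density. Raw KDE
  output on skewed unimodal data carries shallow ripples whose "minima"
  are artifacts; without the prominence rule, the filter pipeline would
  not be idempotent (it would keep shaving the distribution's edge on
  re-application). The 10 % figure is far below the depth of any valley
  separating genuine empty/cell or cell/multiplet components.
* **Multiplets**: in each of the log10(#genes) and log10(#UMIs)
  distributions, a local mode qualifies iff (a) its x-location exceeds
  1.5× the x-location of the global mode and (b) its basin — barcodes
  between the flanking local minima — holds fewer than 5 % of barcodes.
  Both clauses operate on the log10 axis. Flags from the two
  distributions are combined by union by default (`combine`
  configurable to intersection; whether the original procedure used one
  or the other is not determinable, and union is the conservative,
  more-removing choice).
* **Normalization**: `ln(count / depth × 10⁴ + 1)` per barcode; zeros map
  to zero, the result is invariant to uniform depth rescaling of a
  barcode, and a zero-depth barcode is an error naming the barcode.

The pipeline (barcode filter → gene filter → multiplet removal) is
idempotent: its output passes through a second application unchanged.

## Gene-family counting (`tcellkit.famcount`)

Input is a table of conserved-domain genomic hits (0-based half-open
coordinates; GTF-style inputs must be converted on read). Counting a
gene family proceeds in four steps.

1. **Concordance filter**: keep hits of rank ≤ 10 whose reciprocal best
   domain equals the initiating domain.
2. **Classification**: hits overlapping annotated family-member genes are
   `annotated`; hits inside non-family genes are removed; unannotated hits
   within `synteny_window` (default 1 Mb — the original criterion states
   "proximity" without a distance, so this is an explicit parameter) of a
   family gene on the same scaffold are `syntenic_unannotated`, the rest
   `nonsyntenic_unannotated`; hits in caller-supplied elimination
   intervals are removed. A hit overlapping both a family and a
   non-family annotation is a contradictory annotation and raises.
3. **Cutoff calibration**: among annotated hits, adjacent same-scaffold
   pairs yield gap distances (`next.start − prev.end`, floored at 0)
   labeled intragenic (same gene) or intergenic. The cutoff maximizing
   the F-measure of "gap < cutoff ⇒ intragenic" is selected from the
   midpoints of consecutive sorted unique distances plus sentinels; the
   smallest optimum is returned on ties. F is F1 = 2pr/(p+r); the variant
   pr/(p+r) (`formula="half"`) is exposed because it is a strictly
   monotone transform of F1 — the argmax is provably identical, and the
   tests assert this. If intragenic gaps are systematically larger than
   intergenic ones the best achievable F is returned with a warning.
   Cutoffs are per species, with a pooled fallback for species lacking
   two-class calibration data.
4. **Grouping**: per scaffold, hits are chained left to right from the
   most upstream hit; a hit joins its upstream neighbor's gene iff the
   gap separating them is below the cutoff. Gene count is therefore the
   number of chain breaks plus the number of scaffolds with hits, and the
   output partitions the input. Strand is ignored in ordering and
   grouping (positional rule only). Single-domain families (TCR variable
   regions) are counted one gene per hit after merging overlapping
   same-family hits (`group_hits` at cutoff 0).

Benchmarking against an annotation reports the false-negative rate
(annotated family genes with no overlapping call) and the unannotated-call
fraction, an upper bound on the false-positive rate since unannotated
calls may be genuine unannotated pseudogenes.

## Phylogenetic least squares (`tcellkit.pgls`)

Family sizes across species are phylogenetically dependent; the model is

    y = Xβ + ε,  ε ~ N(0, σ²C),  C_ij = depth of MRCA(i, j)

with C computed from a rooted tree with branch lengths (ultrametry not
required). Estimation is closed-form ML: β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y,
σ̂² = rᵀC⁻¹r/n (REML available behind a flag). Numerics: whitening by
Cholesky; if C is numerically singular (effectively identical tips) the
fit projects onto the non-degenerate eigenspace (pseudo-inverse
semantics) and warns. Wald intervals use the small-sample covariance
s²(XᵀC⁻¹X)⁻¹ with s² = RSS/(n−p) and t quantiles; simulation shows
~95 % coverage at 64 tips.

Residuals are reported raw (y − Xβ̂) — per-species deviations on the
trait scale, which is what a per-species "more/less than expected"
display needs; whitened residuals are available as a property.
Goodness of fit is the likelihood-based Nagelkerke/Cragg–Uhler pseudo-R²
against the intercept-only fit, clamped to [0, 1] (with continuous data
the raw ratio can stray slightly outside when densities exceed 1).
Predictors are not standardized. Tree/trait matching is exact-string.
`log_ratio` computes per-species ln((a+c)/(b+c)) with pseudocount c = 0
by default and a hard error on 0/0.

## Clonotype calling (`tcellkit.clonotype`)

The module consumes parsed per-read records (upstream consensus calling,
demultiplexing, UMI deduplication and genome mapping are existing tools'
jobs, run at their stated settings); each record carries the cell
barcode, the constant region's locus, candidate V/D/J lists that may
retain comma-separated ambiguity, E-values, productivity and CDR3.

* **Gating**: reads must contain a constant region and be ≤ 700 bp
  (longer reads would let the aligner report junctions unrealistically
  downstream). The length rule discards by default; a truncation mode is
  available since either reading of "limited to 700 bp" is defensible.
* **Record filter**: V or J E-value > 0.001, or an unproductive
  rearrangement, removes the read; allele suffixes (`*NN`) are stripped
  and duplicate candidates collapsed.
* **Locus resolution**: V/J loci must agree with the constant locus. The
  only resolvable disagreement is α/δ (their V genes are co-encoded and
  cross-match); it resolves to the constant locus. Anything else removes
  the read.
* **Clustering**: per cell × locus, greedy length-sorted clustering
  (ties by read id) with CD-HIT-style thresholds: identity ≥ 0.97,
  coverage of the longer read ≥ 0.95 with ≤ 100 unaligned bases, coverage
  of the shorter ≥ 0.99 with ≤ 30 unaligned bases. Alignment is local
  Smith–Waterman (match 2 / mismatch −3 / gap open −5 / extend −2,
  configurable); exact-substring pairs short-circuit the aligner with the
  identical result. Within a cluster each V/D/J slot resolves to the
  intersection of members' candidate lists iff that intersection is a
  single identifier — this is how a short read's `J2-3,J2-4`-style
  ambiguity is resolved by a longer sibling. Empty intersections flag the
  cluster unresolvable.
* **Cell calling**: a cell is clonotyped iff it has exactly one resolved
  chain per member of a valid pair (α+β or γ+δ) and a resolved D on the
  β/δ chain. Orphan-chain cells, cells with chains from both lineages,
  and cells with multiple *distinct* resolved chains of one locus
  (putative doublets — a conservative choice; identical duplicate calls
  are merged first) are removed, each under one named ledger rule, and
  read-stage removals reconcile exactly to input − output.
* **Single-chain mode**: a sensitivity mode keying clonotypes on the γ
  (γδ) or β (αβ) chain alone; paired-mode keys are a refinement of these.

The clonotype key is the exact tuple of constant/V(/D)/J identifiers plus
CDR3 amino-acid sequences of both chains, serialized VJ-chain first.

## Diversity, contrasts and networks (`tcellkit.diversity`)

Per sample (and subset), three plug-in estimators with pᵢ = nᵢ/n:
Hill number of order 0 (richness), Shannon entropy −Σpᵢ ln pᵢ (nats) and
Gini–Simpson 1 − Σpᵢ². Bias-corrected variants are deliberately not the
default (the plug-in forms are the stated estimators); a general-order
Hill number is exposed separately. Publicity is the fraction of unique
clonotypes seen in ≥ 2 samples; dominance is the per-sample modal-clonotype
cell fraction with mean ± SE across samples.

**Bootstrap contrasts.** The group-contrast procedure is a declared
approximation (the original's internals are not fully specified): the
statistic is T = mean per-sample metric in group A − group B; each of B
(default 5,000) replicates resamples every sample's cells with
replacement — equivalently a multinomial draw over its clonotype
abundances, which is how it is computed — and the two-sided p-value is
2·min(Pr(T* ≤ 0), Pr(T* ≥ 0)) with a +1 continuity correction;
Benjamini–Hochberg FDR is applied across all contrasts and metrics in a
batch. Calibration measured under a shared-frequency null (8 samples ×
500 cells from one Dirichlet(1) 100-clonotype distribution, B = 500, 100
simulations): type-I error at α = 0.05 is ≈ 2–6 % for Shannon and
Gini–Simpson. For the order-0 Hill number the same procedure is markedly
*conservative* (type-I ≈ 0): resampled richness regresses toward a
bias-dominated value, shrinking group differences — a known property of
bootstrapping plug-in richness. Power is unaffected in practice: a
ten-fold planted richness difference (200 vs 20 clonotypes, 4 samples per
group) is detected (BH-adjusted p < 0.05 on the Hill number) in 100 % of
simulations.

**Networks.** CDR3 distance is `max(S(a,a), S(b,b)) − S(a,b)` with S the
BLOSUM62 global alignment score (gap open 10 / extend 1), so identical
sequences score 0 and the value grows with dissimilarity. Two clonotypes
are connected iff both arms' (VJ-chain and VDJ-chain CDR3) distances are
≤ 15 — the cutoff is treated as a distance ceiling, configurable, since
"cutoff score" could also denote a similarity floor. Clusters are the
connected components of this graph; components supported by fewer than 3
cells are dropped. Node metadata carries per-sample and per-subset cell
counts.

## Synthetic data (`tcellkit.simulate`)

The generators define the study conditions the tests and acceptance runs
measure recovery under. All are deterministic given their spec's seed.

* **Barcodes**: per-barcode totals are 10^Normal draws from up to three
  components — empty (log10 mean 1.5, sd 0.207), cell (3.0, 0.18) and
  multiplet (cell mean × `multiplet_fold`, default 1.8, on the log10
  axis, matching the filter's fold rule). The default 10,000 + 8,000
  empty/cell mixture places the analytic density minimum at
  log10 ≈ 2.30, chosen by solving the mixture, and counts are spread
  over 300 genes with log-normal weights by one multinomial per barcode.
  Log-normal components are a minimal model with a controllable valley;
  real droplet data have heavier ambient tails and gene-specific
  structure the filters never see.
* **Domain hits**: genes are laid down sequentially per scaffold —
  intergenic gap (truncated normal, default N(20000, 3000²), floor 1 bp),
  then 3 domain hits of 200 bp separated by intragenic gaps
  (N(500, 100²)) — so planted genes cannot overlap and every hit belongs
  to exactly one truth gene. A chosen fraction of genes is annotated.
  Truncated normals match the requirement of two separable gap classes
  without committing to a distribution family real genomes do not state.
* **Brownian traits**: x ~ N(0, σx²C) on the tree, y = β₀ + β₁x + ε with
  ε ~ N(0, σe²C), drawn through a jittered Cholesky factor so zero-length
  branches (perfectly correlated tips) remain factorizable.
* **Repertoire**: a global pool of clonotypes; clone 0 is the planted
  dominant, present in every sample at `dominant_fraction` (default
  0.34) with the canonical γδ key (TRGC4 / TRGV4-2 / TRGJ5-3 /
  CDR3 TYWDSNYAKK paired with TRDC / TRDV1-4 / TRDD3 / TRDJ2 /
  CDR3 ALWELRTGGITAQLV); remaining frequency mass is a symmetric
  Dirichlet draw shared across samples, so non-dominant clonotypes also
  recur across samples and simulated publicity is far higher than a real
  repertoire's. Each cell emits 1 + Poisson(2) reads per chain as
  prefixes of the clonotype's chain sequence (shortfall ≤ 30 bases, so
  reads of one rearrangement co-cluster under the identity/coverage
  thresholds); δ-chain dropout (probability `chain_dropout_alpha_delta`)
  creates truth orphan cells; J ambiguity (probability `ambiguity_rate`,
  J only — the canonical ambiguity case; the true J is always among the
  candidates) is injected only on chains with ≥ 2 reads, keeping one
  read unambiguous, so every planted ambiguity is resolvable within its
  cell. The default repertoire is all-γδ, the focal compartment; αβ
  logic is exercised by explicit unit-test fixtures. Not emulated:
  sequencing error, PCR chimeras, partial IgBLAST output, cross-cell
  barcode collisions — passing tests demonstrate rule correctness and
  truth recovery under clean reads, not robustness to base-level noise.

## Problem sizes

Tests and the acceptance script run at: 20,000 barcodes (QC), 50 genes ×
3 domains (family counting), 64-tip trees × 200 replicates (PGLS
recovery), 2,000 cells / 4 samples / 200 clonotypes (clonotyping), 100
null + 60 power simulations at B = 500 (contrast calibration), and ~480
clonotypes (network brute-force comparison). These sizes give stable
statistics for every recovery criterion while keeping a full run in the
low minutes on one CPU.

## Known limitations

* The KDE prominence rule (10 %) is a smoothing-robustness device; data
  whose genuine valley is shallower than 10 % of its flanking modes will
  return a no-threshold result.
* The bootstrap contrast is an approximation to an unspecified original;
  its richness-metric conservativeness is documented above.
* The synteny criterion and elimination intervals are caller-supplied
  parameters, not inferred.
* CD-HIT emulation reproduces the documented threshold semantics, not
  CD-HIT's word-filter heuristics; on reads that are near-exact nested
  prefixes the two agree by construction.
* `single_chain_mode` requires a resolved D for β chains; γ chains have
  no D by definition.
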