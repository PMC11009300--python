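# tcellkit

A toolkit for comparative single-cell T-cell receptor (TCR) repertoire
analysis, built for studies that contrast T-cell biology across mammals —
in particular species, such as the naked mole-rat, whose genomes encode
unusually expanded γ/δ variable-region repertoires and whose T-cell
compartments are dominated by γδ clonotypes. It implements, as a tested
and reusable library, the bespoke computational steps such a study needs
between the off-the-shelf tools:

1. **Single-cell QC** (`tcellkit.qc`) — cell calling by the first local
   minimum above `log10 = 2` in the smoothed distribution of per-barcode
   log10(#UMIs); gene filtering by the analogous minimum above `log10 = 3`
   of per-gene log10(#barcodes); multiplet removal via secondary local
   modes whose x-location exceeds 1.5× the global mode and whose basin
   holds < 5 % of barcodes; depth normalization
   `ln(count / depth × 10⁴ + 1)`.
2. **Gene-family counting** (`tcellkit.famcount`) — turning reciprocal
   conserved-domain hits (tBLASTn → rpsBLAST concordance, top ten hits)
   into per-species family sizes: annotated / syntenic-unannotated /
   non-syntenic classification, calibration of an intragenic-vs-intergenic
   gap cutoff by F-measure maximization (F1 = 2pr/(p+r)), and greedy
   most-upstream-first chaining of hits into genes.
3. **Phylogenetic least squares** (`tcellkit.pgls`) — ML generalized least
   squares with the Brownian-motion covariance `C_ij = depth(MRCA(i,j))`,
   raw per-species residuals, Nagelkerke pseudo-R², and ln family-size
   ratios (e.g. ln #MHC-I / #MHC-II).
4. **Clonotype calling** (`tcellkit.clonotype`) — from barcoded long-read
   V(D)J hit records: ≤ 700 bp constant-region gating, E-value ≤ 0.001 and
   productivity filters, α/δ locus-discordance resolution, per-cell greedy
   identity clustering (identity ≥ 0.97, coverage 0.95/100 and 0.99/30 on
   the longer/shorter read) with candidate-intersection V/D/J resolution,
   and paired-chain cell calling (α+β or γ+δ, D required on β/δ; orphans
   and doublets removed, every removal attributed in a ledger).
5. **Diversity statistics** (`tcellkit.diversity`) — Hill number (order 0),
   Shannon entropy, Gini–Simpson index; clonotype publicity and dominance;
   within-sample bootstrap group contrasts (B = 5000 default) with
   Benjamini–Hochberg FDR; clonotype networks linking clonotypes whose
   CDR3s are within a BLOSUM62 alignment distance of 15 on both chains,
   keeping clusters of ≥ 3 cells.
6. **Synthetic data** (`tcellkit.simulate`) — generators for every input
   above with known ground truth (barcode mixtures with a planted valley,
   planted multi-domain gene families, Brownian traits on trees, and
   multi-sample repertoires with a planted dominant public clonotype,
   chain dropout and J-call ambiguity), so the whole pipeline is testable
   without any sequencing data.

## Worked example

Simulate a four-sample γδ repertoire of 2,000 cells with a dominant public
clonotype planted at frequency 0.34, 30 % δ-chain dropout and 20 % J-call
ambiguity, then call clonotypes and summarize:

```python
from tcellkit.simulate import RepertoireSimSpec, simulate_repertoire
from tcellkit.clonotype import assign_clonotypes
from tcellkit import diversity as dv

spec = RepertoireSimSpec(n_cells_per_sample=500, n_samples=4,
                         n_clonotypes=200, dominant_fraction=0.34,
                         chain_dropout_alpha_delta=0.3, ambiguity_rate=0.2,
                         seed=7)
records, seqs, truth = simulate_repertoire(spec)
result = assign_clonotypes(records, seqs)
table = result.table.merge(truth[["cell_barcode", "sample_id"]],
                           on="cell_barcode")
print(len(result.table), "cells clonotyped")
print(dv.dominance(table)["mean"], "+/-", dv.dominance(table)["se"])
print(result.ledger.to_string(index=False))
```

prints (seed 7):

```
1416 cells clonotyped
0.3517458982487241 +/- 0.011396627509430017
 stage                  rule   n
  gate    no_constant_region   0
  gate           over_length   0
filter                evalue   0
filter          unproductive   0
 locus     locus_discordance   0
  cell unresolved_chain_only   0
  cell          orphan_chain 584
  cell      lineage_conflict   0
  cell   multi_chain_doublet   0
  cell             missing_d   0
  cell          invalid_pair   0
```

1,416 of 2,000 cells survive the paired-chain rules (the 584 removals are
exactly the cells whose δ chain was lost to the simulated capture dropout),
every retained cell matches its ground-truth clonotype, and the dominant
clone's mean per-sample frequency (35.2 % ± 1.1) recovers the planted 34 %.

A command-line surface wraps the same functions:

```bash
tcellkit simulate repertoire out/ --seed 7
tcellkit clonotype out/records.tsv out/reads.fasta calls/
tcellkit diversity calls/clonotypes.tsv div/ --mode metrics
```

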