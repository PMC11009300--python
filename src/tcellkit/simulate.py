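"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate, at the parsed-record level, the data shapes the
pipeline consumes:

* ``simulate_barcodes`` — droplet barcode UMI totals as a mixture of
  log-normal components (ambient/empty droplets, cells, multiplets),
  spread over genes multinomially; the multiplet mode sits at
  ``multiplet_fold`` times the cell mode's location on the log10 axis,
  matching how the multiplet filter compares mode locations.
* ``simulate_domain_hits`` — scaffolds carrying planted multi-domain
  genes whose intragenic domain gaps are small and whose intergenic gaps
  are large (truncated normals, floor 1 bp), with a chosen fraction of
  genes annotated.
* ``simulate_brownian_traits`` — a Brownian trait x on a species tree and
  a linear response y = β₀ + β₁x + ε with phylogenetically correlated
  noise, for GLS parameter-recovery studies.
* ``simulate_repertoire`` — multi-sample single-cell TCR read/hit records
  with a planted dominant public clonotype, per-cell chain dropout
  (creating truth orphan cells) and comma-list J ambiguity on a fraction
  of reads, resolvable from a sibling read of the same cell.

All generators are deterministic given their spec's seed; each draws its
own child stream so modules are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pgls import brownian_cov
from .qc import CountMatrix

__all__ = [
    "BarcodeSimSpec",
    "GenomeSimSpec",
    "RepertoireSimSpec",
    "simulate_barcodes",
    "simulate_domain_hits",
    "simulate_brownian_traits",
    "simulate_repertoire",
    "DOMINANT_VJ_CHAIN",
    "DOMINANT_VDJ_CHAIN",
]


# ---------------------------------------------------------------------------
# barcodes


@dataclass(frozen=True)
class BarcodeSimSpec:
    """Log-normal mixture of droplet barcode totals.

    Modes are log10-UMI locations; the multiplet component's mode is
    ``cell_log10_umi_mean * multiplet_fold`` (a fold on the log10 axis,
    the scale on which the multiplet filter compares mode locations).
    The default empty/cell components (10,000 + 8,000 barcodes) place the
    analytic density minimum — the valley the barcode filter must find —
    at log10(#UMIs) ≈ 2.30.
    """

    n_cell_barcodes: int = 8000
    n_empty_barcodes: int = 10000
    n_multiplet_barcodes: int = 0
    cell_log10_umi_mean: float = 3.0
    cell_log10_umi_sd: float = 0.18
    empty_log10_umi_mean: float = 1.5
    empty_log10_umi_sd: float = 0.207
    multiplet_fold: float = 1.8
    n_genes: int = 300
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cell_barcodes", "n_empty_barcodes", "n_multiplet_barcodes", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.multiplet_fold <= 1:
            raise ValueError("multiplet_fold must exceed 1")
        if self.cell_log10_umi_sd <= 0 or self.empty_log10_umi_sd <= 0:
            raise ValueError("component sds must be positive")


def simulate_barcodes(spec: BarcodeSimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Gene-by-barcode counts plus truth labels per barcode.

    Per-barcode totals are 10^Normal draws from the component the barcode
    belongs to; counts are spread over genes with log-normal gene weights
    via one multinomial per barcode (multiplets therefore also capture
    more distinct genes). Truth labels: empty / cell / multiplet.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    parts = []
    for label, n, mean, sd in (
        ("empty", spec.n_empty_barcodes, spec.empty_log10_umi_mean, spec.empty_log10_umi_sd),
        ("cell", spec.n_cell_barcodes, spec.cell_log10_umi_mean, spec.cell_log10_umi_sd),
        ("multiplet", spec.n_multiplet_barcodes,
         spec.cell_log10_umi_mean * spec.multiplet_fold, spec.cell_log10_umi_sd),
    ):
        if n:
            parts.append((label, 10 ** rng.normal(mean, sd, size=n)))
    labels = np.concatenate([[lab] * len(v) for lab, v in parts])
    totals = np.maximum(np.round(np.concatenate([v for _, v in parts])), 1).astype(np.int64)

    weights = rng.lognormal(0.0, 1.0, size=spec.n_genes)
    weights /= weights.sum()
    n_bc = totals.size
    cols, rows_idx, data = [], [], []
    for b in range(n_bc):
        counts = rng.multinomial(totals[b], weights)
        nz = np.flatnonzero(counts)
        rows_idx.append(nz)
        cols.append(np.full(nz.size, b))
        data.append(counts[nz])
    counts = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows_idx), np.concatenate(cols))),
        shape=(spec.n_genes, n_bc), dtype=np.int64,
    )
    barcodes = [f"BC{i:06d}" for i in range(n_bc)]
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]
    truth = pd.DataFrame({"barcode": barcodes, "label": labels})
    return CountMatrix(genes, barcodes, counts), truth


# ---------------------------------------------------------------------------
# domain hits


@dataclass(frozen=True)
class GenomeSimSpec:
    """Planted gene families with bimodal domain-gap distributions."""

    n_scaffolds: int = 5
    genes_per_scaffold: int = 10
    domains_per_gene: int = 3
    intragenic_gap_mean: float = 500.0
    intragenic_gap_sd: float = 100.0
    intergenic_gap_mean: float = 20000.0
    intergenic_gap_sd: float = 3000.0
    annotated_fraction: float = 1.0
    hit_length: int = 200
    family: str = "MHC-I"
    domain_id: str = "MHC_I_alpha"
    seed: int = 0

    def validate(self) -> None:
        if self.intergenic_gap_mean <= self.intragenic_gap_mean:
            raise ValueError("intergenic_gap_mean must exceed intragenic_gap_mean")
        if not 0 <= self.annotated_fraction <= 1:
            raise ValueError("annotated_fraction must lie in [0, 1]")
        if min(self.n_scaffolds, self.genes_per_scaffold, self.domains_per_gene,
               self.hit_length) < 1:
            raise ValueError("counts and hit_length must be >= 1")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, size: int,
                  floor: float = 1.0) -> np.ndarray:
    return np.maximum(np.round(rng.normal(mean, sd, size=size)), floor).astype(np.int64)


def simulate_domain_hits(spec: GenomeSimSpec
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(hits, annotations, truth) for a planted multi-domain gene family.

    Genes are laid down sequentially along each scaffold (intergenic gap,
    then ``domains_per_gene`` hits separated by intragenic gaps), so
    planted genes can never overlap. Truth maps every hit to exactly one
    gene; a fraction ``annotated_fraction`` of genes (chosen at random)
    also appears in the annotation table as family members. Hits are
    emitted sorted by scaffold then start, rank 1, with the reciprocal
    best domain equal to ``spec.domain_id``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hit_rows, ann_rows, truth_rows = [], [], []
    gene_counter = 0
    for s in range(spec.n_scaffolds):
        scaffold = f"scaffold{s:03d}"
        pos = int(_trunc_normal(rng, spec.intergenic_gap_mean,
                                spec.intergenic_gap_sd, 1)[0])
        for _ in range(spec.genes_per_scaffold):
            gene_id = f"gene{gene_counter:05d}"
            gene_start = pos
            for d in range(spec.domains_per_gene):
                if d:
                    pos += int(_trunc_normal(rng, spec.intragenic_gap_mean,
                                             spec.intragenic_gap_sd, 1)[0])
                hit_id = f"hit{len(hit_rows):06d}"
                hit_rows.append({
                    "hit_id": hit_id, "scaffold": scaffold, "start": pos,
                    "end": pos + spec.hit_length, "strand": "+",
                    "domain_id": spec.domain_id, "family": spec.family,
                    "rank": 1, "reciprocal_best_domain": spec.domain_id,
                })
                truth_rows.append({"hit_id": hit_id, "gene_id": gene_id})
                pos += spec.hit_length
            ann_rows.append({
                "scaffold": scaffold, "start": gene_start, "end": pos,
                "strand": "+", "gene_id": gene_id,
                "orthogroup_id": f"OG_{spec.family}", "is_family_member": True,
            })
            gene_counter += 1
            pos += int(_trunc_normal(rng, spec.intergenic_gap_mean,
                                     spec.intergenic_gap_sd, 1)[0])
    hits = pd.DataFrame(hit_rows).sort_values(["scaffold", "start"]).reset_index(drop=True)
    annotations = pd.DataFrame(ann_rows)
    n_annotated = int(round(spec.annotated_fraction * len(annotations)))
    keep = rng.choice(len(annotations), size=n_annotated, replace=False)
    annotations = annotations.iloc[np.sort(keep)].reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return hits, annotations, truth


# ---------------------------------------------------------------------------
# Brownian traits


def simulate_brownian_traits(tree: dendropy.Tree, beta0: float, beta1: float,
                             sigma_x: float, sigma_e: float, seed: int = 0,
                             ) -> pd.DataFrame:
    """Tip table (species, x, y) under Brownian evolution on ``tree``.

    x ~ N(0, σx² C) with C the tree's Brownian covariance; the response
    is y = β₀ + β₁ x + ε, ε ~ N(0, σe² C). With both sigmas zero the
    relationship is exact and x is constant across tips.
    """
    C, taxa = brownian_cov(tree)
    rng = np.random.default_rng(seed)
    n = len(taxa)
    # Cholesky with a tiny jitter so zero-length terminal branches
    # (perfectly correlated tips) remain factorizable
    jitter = 1e-12 * max(np.diag(C).max(), 1.0)
    L = np.linalg.cholesky(C + jitter * np.eye(n))
    x = sigma_x * (L @ rng.standard_normal(n))
    y = beta0 + beta1 * x + sigma_e * (L @ rng.standard_normal(n))
    return pd.DataFrame({"species": taxa, "x": x, "y": y})


# ---------------------------------------------------------------------------
# repertoire


# The planted dominant public clonotype's gene ids and CDR3s (a highly
# dominant cytotoxic γδ clonotype of the kind this pipeline is built to
# recover).
DOMINANT_VJ_CHAIN = {"constant_id": "TRGC4", "v": "TRGV4-2", "d": None,
                     "j": "TRGJ5-3", "cdr3": "TYWDSNYAKK"}
DOMINANT_VDJ_CHAIN = {"constant_id": "TRDC", "v": "TRDV1-4", "d": "TRDD3",
                      "j": "TRDJ2", "cdr3": "ALWELRTGGITAQLV"}

_TRG_V = [f"TRGV{i}-{j}" for i in range(1, 8) for j in (1, 2)]
_TRG_J = [f"TRGJ{i}-{j}" for i in range(1, 6) for j in (1, 3)]
_TRG_C = [f"TRGC{i}" for i in range(1, 5)]
_TRD_V = [f"TRDV{i}-{j}" for i in range(1, 9) for j in (1, 4)]
_TRD_D = [f"TRDD{i}" for i in range(1, 4)]
_TRD_J = [f"TRDJ{i}" for i in range(1, 5)]
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepertoireSimSpec:
    """Multi-sample γδ TCR cell population with a planted public dominant
    clonotype, chain dropout and J-call ambiguity."""

    n_cells_per_sample: int = 500
    n_samples: int = 4
    n_clonotypes: int = 200
    dominant_fraction: float = 0.34
    clone_freq_concentration: float = 1.0
    chain_dropout_alpha_delta: float = 0.0
    ambiguity_rate: float = 0.0
    mean_reads_per_chain: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.dominant_fraction <= 1:
            raise ValueError("dominant_fraction must lie in (0, 1]")
        if self.n_clonotypes < 1 or self.n_samples < 1 or self.n_cells_per_sample < 1:
            raise ValueError("counts must be >= 1")
        if self.n_clonotypes == 1 and self.dominant_fraction != 1:
            raise ValueError("a single clonotype must have dominant_fraction 1")
        for name in ("chain_dropout_alpha_delta", "ambiguity_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.clone_freq_concentration <= 0:
            raise ValueError("clone_freq_concentration must be positive")
        if self.mean_reads_per_chain <= 0:
            raise ValueError("mean_reads_per_chain must be positive")


def _random_cdr3(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA20, size=rng.integers(9, 17)))


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def _make_clonotypes(spec: RepertoireSimSpec, rng: np.random.Generator) -> list[dict]:
    clones = []
    seen_keys = set()
    for k in range(spec.n_clonotypes):
        if k == 0:
            vj, vdj = dict(DOMINANT_VJ_CHAIN), dict(DOMINANT_VDJ_CHAIN)
        else:
            vj = {"constant_id": str(rng.choice(_TRG_C)), "v": str(rng.choice(_TRG_V)),
                  "d": None, "j": str(rng.choice(_TRG_J)), "cdr3": _random_cdr3(rng)}
            vdj = {"constant_id": "TRDC", "v": str(rng.choice(_TRD_V)),
                   "d": str(rng.choice(_TRD_D)), "j": str(rng.choice(_TRD_J)),
                   "cdr3": _random_cdr3(rng)}
        key = (vj["constant_id"], vj["v"], vj["j"], vj["cdr3"],
               vdj["constant_id"], vdj["v"], vdj["d"], vdj["j"], vdj["cdr3"])
        while key in seen_keys:  # CDR3 collision across clonotypes: redraw
            vj["cdr3"] = _random_cdr3(rng)
            key = key[:3] + (vj["cdr3"],) + key[4:]
        seen_keys.add(key)
        clones.append({
            "clonotype_id": f"clone{k:04d}",
            "vj": vj, "vdj": vdj,
            "vj_seq": _random_nt(rng, int(rng.integers(560, 680))),
            "vdj_seq": _random_nt(rng, int(rng.integers(560, 680))),
        })
    return clones


def _chain_key_str(chain: dict) -> str:
    return "|".join([chain["constant_id"], chain["v"], chain["d"] or "-",
                     chain["j"], chain["cdr3"]])


def simulate_repertoire(spec: RepertoireSimSpec
                        ) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """(hit records, read sequences, truth table) for a γδ repertoire.

    Clonotype 0 is the planted dominant, present in every sample at
    frequency ``dominant_fraction``; the rest of the frequency mass is a
    symmetric Dirichlet draw shared across samples (the pool is global,
    so non-dominant clonotypes may also recur across samples). Each cell
    emits 1 + Poisson reads per chain; with probability
    ``chain_dropout_alpha_delta`` a cell loses its δ-chain reads (truth
    orphan). With probability ``ambiguity_rate`` a read's J call is
    emitted as a two-candidate comma list — only on chains with at least
    two reads, keeping one read unambiguous, so every planted ambiguity
    is resolvable within its cell.

    Read sequences are prefixes of the clonotype's chain sequence
    (shortfall ≤ 30 bases), so reads of one rearrangement co-cluster
    under the identity/coverage thresholds of the clonotype pipeline.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    clones = _make_clonotypes(spec, rng)

    if spec.n_clonotypes > 1:
        rest = rng.dirichlet(np.full(spec.n_clonotypes - 1,
                                     spec.clone_freq_concentration))
        freqs = np.concatenate([[spec.dominant_fraction],
                                (1 - spec.dominant_fraction) * rest])
    else:
        freqs = np.array([1.0])

    records, sequences, truth_rows = [], {}, []
    read_counter = 0
    for s in range(spec.n_samples):
        sample_id = f"S{s + 1}"
        assignment = rng.choice(spec.n_clonotypes, size=spec.n_cells_per_sample, p=freqs)
        for c, clone_idx in enumerate(assignment):
            clone = clones[clone_idx]
            cell = f"{sample_id}_BC{c:05d}"
            dropped = bool(rng.random() < spec.chain_dropout_alpha_delta)
            truth_rows.append({
                "cell_barcode": cell, "sample_id": sample_id,
                "clonotype_id": clone["clonotype_id"],
                "clonotype": _chain_key_str(clone["vj"]) + "+" + _chain_key_str(clone["vdj"]),
                "delta_dropped": dropped,
            })
            for chain_name, locus in (("vj", "TRG"), ("vdj", "TRD")):
                if chain_name == "vdj" and dropped:
                    continue
                chain = clone[chain_name]
                full = clone[f"{chain_name}_seq"]
                n_reads = 1 + rng.poisson(spec.mean_reads_per_chain - 1)
                ambiguous = np.zeros(n_reads, dtype=bool)
                if n_reads >= 2 and spec.ambiguity_rate > 0:
                    ambiguous = rng.random(n_reads) < spec.ambiguity_rate
                    if ambiguous.all():
                        ambiguous[int(rng.integers(n_reads))] = False
                for r in range(n_reads):
                    read_id = f"read{read_counter:07d}"
                    read_counter += 1
                    seq = full[: len(full) - int(rng.integers(0, 31))]
                    sequences[read_id] = seq
                    j_call = chain["j"]
                    if ambiguous[r]:
                        pool = _TRG_J if locus == "TRG" else _TRD_J
                        alt = str(rng.choice([x for x in pool if x != chain["j"]]))
                        j_call = f"{chain['j']},{alt}"
                    records.append({
                        "read_id": read_id, "cell_barcode": cell,
                        "sample_id": sample_id, "locus": locus,
                        "constant_id": chain["constant_id"], "length": len(seq),
                        "constant_region_present": True,
                        "v_call": chain["v"], "d_call": chain["d"] or "",
                        "j_call": j_call,
                        "v_evalue": float(10 ** rng.uniform(-40, -20)),
                        "j_evalue": float(10 ** rng.uniform(-40, -20)),
                        "productive": True, "cdr3_aa": chain["cdr3"],
                    })
    records_df = pd.DataFrame(records)
    truth = pd.DataFrame(truth_rows)
    return records_df, sequences, truth


# ---------------------------------------------------------------------------
# writers (plain-text artifact formats)


def write_repertoire(outdir: str | Path, records: pd.DataFrame,
                     sequences: dict[str, str], truth: pd.DataFrame) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / "records.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "reads.fasta", "w") as fh:
        for read_id, seq in sequences.items():
            fh.write(f">{read_id}\n{seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
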