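"""Paired-chain TCR clonotype assignment from barcoded long reads.

Input is the parsed per-read level of a hybridization-capture single-cell
TCR experiment: each circular-consensus read carries a cell barcode, the
TCR locus of the constant region it was captured with, and a V(D)J hit
record (candidate gene lists that may retain comma-separated ambiguity,
E-values, productivity, CDR3 amino-acid sequence). The pipeline:

1. ``gate_reads`` — keep reads ≤ 700 bp that contain a constant region
   and belong to a QC-retained cell barcode;
2. ``filter_records`` — drop reads with V or J E-value > 0.001 or an
   unproductive rearrangement; strip allele suffixes (``*NN``) and
   collapse duplicate candidates;
3. ``resolve_locus`` — reconcile V/J locus labels with the constant
   region's locus; only α/δ disagreements are resolvable (the loci share
   V genes), anything else is removed;
4. ``cluster_cell_chains`` — per cell and locus, greedy length-sorted
   identity clustering (identity ≥ 0.97; coverage of the longer read
   ≥ 0.95 with ≤ 100 unaligned bases; coverage of the shorter ≥ 0.99
   with ≤ 30 unaligned bases), after which each V/D/J slot is resolved
   to the intersection of the cluster members' candidate lists;
5. ``call_cells`` — a cell is clonotyped iff it has exactly one resolved
   chain for each member of a valid pair (α+β or γ+δ) and the β/δ chain
   has a resolved D; orphan-chain cells, cells lacking D, and
   cross-lineage or multi-chain cells are removed.

Every removal is attributed to exactly one named rule in a ledger that
reconciles to input − output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "gate_reads",
    "filter_records",
    "resolve_locus",
    "cluster_cell_chains",
    "call_cells",
    "single_chain_mode",
    "assign_clonotypes",
    "clonotype_key",
    "ClusterParams",
    "ClonotypeResult",
]

LOCI = ("TRA", "TRB", "TRG", "TRD")
VDJ_LOCI = {"TRB", "TRD"}          # loci whose chains carry a D segment
PAIRS = {"ab": ("TRA", "TRB"), "gd": ("TRG", "TRD")}


def _locus_of(gene_id: str) -> str:
    prefix = gene_id[:3].upper()
    if prefix not in LOCI:
        raise ValueError(f"cannot infer TCR locus from accession {gene_id!r}")
    return prefix


def _split_candidates(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return [tok.strip() for tok in str(value).split(",") if tok.strip()]


def _strip_allele(accession: str) -> str:
    base = accession.split("*")[0].strip()
    if not base or not base[:2].upper() == "TR":
        raise ValueError(f"malformed gene accession {accession!r}")
    return base


# ---------------------------------------------------------------------------
# read-level steps


def gate_reads(reads: pd.DataFrame, max_len: int = 700,
               retained_barcodes: set[str] | None = None,
               truncate: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Constant-region and length gate.

    Keeps reads with a sequenced constant region and length ≤ ``max_len``
    (``truncate=True`` instead clips the stored length, discarding
    nothing by length), restricted to QC-retained barcodes when a set is
    given. Returns (retained reads, removal ledger).
    """
    out = reads.copy()
    removals = []

    no_const = ~out["constant_region_present"].astype(bool)
    removals.append(("gate", "no_constant_region", int(no_const.sum())))
    out = out.loc[~no_const]

    if truncate:
        out = out.assign(length=out["length"].clip(upper=max_len))
        removals.append(("gate", "over_length", 0))
    else:
        too_long = out["length"] > max_len
        removals.append(("gate", "over_length", int(too_long.sum())))
        out = out.loc[~too_long]

    if retained_barcodes is not None:
        bad = ~out["cell_barcode"].isin(retained_barcodes)
        removals.append(("gate", "barcode_not_retained", int(bad.sum())))
        out = out.loc[~bad]

    return out.reset_index(drop=True), pd.DataFrame(removals, columns=["stage", "rule", "n"])


def filter_records(records: pd.DataFrame, max_evalue: float = 0.001
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """E-value / productivity filter plus allele stripping.

    Drops records whose V or J E-value exceeds ``max_evalue`` (not a TCR
    transcript) or that are unproductive; allele suffixes are removed
    from every candidate and duplicates collapsed, preserving order.
    """
    out = records.copy()
    removals = []

    bad_e = (out["v_evalue"] > max_evalue) | (out["j_evalue"] > max_evalue)
    removals.append(("filter", "evalue", int(bad_e.sum())))
    out = out.loc[~bad_e]

    unprod = ~out["productive"].astype(bool)
    removals.append(("filter", "unproductive", int(unprod.sum())))
    out = out.loc[~unprod].reset_index(drop=True)

    for col in ("v_call", "d_call", "j_call"):
        cleaned = []
        for raw in out[col]:
            cands = _split_candidates(raw)
            stripped = list(dict.fromkeys(_strip_allele(c) for c in cands))
            cleaned.append(",".join(stripped))
        out[col] = cleaned
    return out, pd.DataFrame(removals, columns=["stage", "rule", "n"])


def resolve_locus(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconcile V/J locus labels with the constant region's locus.

    A discordance is resolvable only when it involves exactly the α and δ
    loci (whose V genes are interleaved on one locus and match each
    other): the read is assigned the constant region's locus and, where
    possible, candidates are narrowed to that locus. Any other
    discordance removes the read.
    """
    keep_rows, removals_n = [], 0
    resolved_records = records.copy().reset_index(drop=True)
    for i, rec in resolved_records.iterrows():
        constant = rec["locus"]
        loci = {constant}
        cand_loci: dict[str, set[str]] = {}
        for col in ("v_call", "j_call"):
            cands = _split_candidates(rec[col])
            if cands:
                cand_loci[col] = {_locus_of(c) for c in cands}
                loci |= cand_loci[col]
        if len(loci) == 1:
            keep_rows.append(i)
            continue
        if loci <= {"TRA", "TRD"} and constant in {"TRA", "TRD"}:
            for col in ("v_call", "d_call", "j_call"):
                cands = _split_candidates(resolved_records.at[i, col])
                narrowed = [c for c in cands if _locus_of(c) == constant]
                if narrowed:
                    resolved_records.at[i, col] = ",".join(narrowed)
            keep_rows.append(i)
        else:
            removals_n += 1
    out = resolved_records.loc[keep_rows].reset_index(drop=True)
    ledger = pd.DataFrame([("locus", "locus_discordance", removals_n)],
                          columns=["stage", "rule", "n"])
    return out, ledger


# ---------------------------------------------------------------------------
# per-cell chain clustering


@dataclass(frozen=True)
class ClusterParams:
    """Greedy identity-clustering thresholds (CD-HIT-style semantics)."""

    identity: float = 0.97
    cov_long: float = 0.95
    max_unaligned_long: int = 100
    cov_short: float = 0.99
    max_unaligned_short: int = 30


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = 2
    aln.mismatch_score = -3
    aln.open_gap_score = -5
    aln.extend_gap_score = -2
    return aln


_NT_ALIGNER = _aligner()


def _pair_stats(seq_long: str, seq_short: str) -> tuple[float, float, int, float, int]:
    """(identity, cov_long, unaligned_long, cov_short, unaligned_short)
    of the best local alignment; exact-substring pairs skip alignment."""
    if seq_short in seq_long:
        cov_l = len(seq_short) / len(seq_long)
        return 1.0, cov_l, len(seq_long) - len(seq_short), 1.0, 0
    alignment = _NT_ALIGNER.align(seq_long, seq_short)[0]
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    blocks_l, blocks_s = alignment.aligned
    span_l = int(blocks_l[-1][1] - blocks_l[0][0])
    span_s = int(blocks_s[-1][1] - blocks_s[0][0])
    return (identity, span_l / len(seq_long), len(seq_long) - span_l,
            span_s / len(seq_short), len(seq_short) - span_s)


def _joins(seed: str, other: str, p: ClusterParams) -> bool:
    a, b = (seed, other) if len(seed) >= len(other) else (other, seed)
    ident, cov_l, un_l, cov_s, un_s = _pair_stats(a, b)
    return (ident >= p.identity and cov_l >= p.cov_long and un_l <= p.max_unaligned_long
            and cov_s >= p.cov_short and un_s <= p.max_unaligned_short)


def cluster_cell_chains(records: pd.DataFrame, sequences: dict[str, str],
                        params: ClusterParams | None = None) -> pd.DataFrame:
    """Per-cell, per-locus greedy clustering and V/D/J slot resolution.

    Reads are sorted by length descending (ties broken by read_id); the
    longest unassigned read seeds a cluster and subsequent reads join the
    first cluster whose seed they match under the identity/coverage
    thresholds. Each V/D/J slot of a cluster resolves to the intersection
    of its members' candidate lists iff that intersection is a single
    identifier; an empty intersection flags the cluster unresolvable.

    Returns one row per cluster (a candidate chain call) with resolution
    status.
    """
    p = params or ClusterParams()
    rows = []
    for (cell, locus), group in records.groupby(["cell_barcode", "locus"], sort=True):
        reads = group.to_dict("records")
        for r in reads:
            r["_seq"] = sequences[r["read_id"]]
        reads.sort(key=lambda r: (-len(r["_seq"]), r["read_id"]))
        clusters: list[list[dict]] = []
        for r in reads:
            for cl in clusters:
                if _joins(cl[0]["_seq"], r["_seq"], p):
                    cl.append(r)
                    break
            else:
                clusters.append([r])
        for cl in clusters:
            rows.append(_resolve_cluster(cell, locus, cl))
    columns = ["cell_barcode", "locus", "constant_id", "v_id", "d_id", "j_id",
               "cdr3_aa", "n_reads", "resolved", "unresolved_slots"]
    return pd.DataFrame(rows, columns=columns)


def _resolve_slot(members: list[dict], col: str):
    """Intersection of non-empty candidate lists; (id, ok) with id=None
    when the slot is absent from every member."""
    sets = [set(_split_candidates(m.get(col))) for m in members]
    sets = [s for s in sets if s]
    if not sets:
        return None, True          # slot absent (e.g. D on an alpha/gamma chain)
    inter = set.intersection(*sets)
    if len(inter) == 1:
        return next(iter(inter)), True
    return None, False             # ambiguous (>1) or contradictory (0)


def _resolve_cluster(cell: str, locus: str, members: list[dict]) -> dict:
    v_id, v_ok = _resolve_slot(members, "v_call")
    d_id, d_ok = _resolve_slot(members, "d_call")
    j_id, j_ok = _resolve_slot(members, "j_call")
    cdr3_values = [m.get("cdr3_aa") for m in members if isinstance(m.get("cdr3_aa"), str)]
    cdr3 = pd.Series(cdr3_values).mode().iloc[0] if cdr3_values else None
    const_values = [m.get("constant_id") for m in members if isinstance(m.get("constant_id"), str)]
    constant = pd.Series(const_values).mode().iloc[0] if const_values else None
    unresolved = [s for s, ok in (("v", v_ok), ("d", d_ok), ("j", j_ok)) if not ok]
    resolved = (v_ok and d_ok and j_ok and v_id is not None and j_id is not None
                and cdr3 is not None)
    return {"cell_barcode": cell, "locus": locus, "constant_id": constant,
            "v_id": v_id, "d_id": d_id, "j_id": j_id, "cdr3_aa": cdr3,
            "n_reads": len(members), "resolved": resolved,
            "unresolved_slots": unresolved}


# ---------------------------------------------------------------------------
# cell-level calling


def _chain_key(chain: pd.Series) -> str:
    d = chain["d_id"] if isinstance(chain["d_id"], str) else "-"
    return f"{chain['constant_id']}|{chain['v_id']}|{d}|{chain['j_id']}|{chain['cdr3_aa']}"


def clonotype_key(vj_chain: pd.Series, vdj_chain: pd.Series) -> str:
    """Serialize a paired clonotype: C/V(/D)/J ids + CDR3 aa of both
    chains, VJ chain (α or γ) first. Equality of keys is exact equality
    of every component."""
    return _chain_key(vj_chain) + "+" + _chain_key(vdj_chain)


def call_cells(chain_calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-chain clonotype per retained cell.

    Retention requires exactly one resolved chain for each member of a
    valid pair (α+β or γ+δ) with a resolved D on the β/δ chain. Removal
    rules, each exclusive and counted per cell: ``unresolved_chain_only``
    (no resolved chain at all), ``orphan_chain``, ``lineage_conflict``
    (resolved chains from both lineages), ``multi_chain_doublet`` (two
    resolved chains of one locus), ``missing_d``, ``invalid_pair``.
    """
    rows = []
    removals = {"unresolved_chain_only": 0, "orphan_chain": 0, "lineage_conflict": 0,
                "multi_chain_doublet": 0, "missing_d": 0, "invalid_pair": 0}
    for cell, group in chain_calls.groupby("cell_barcode", sort=True):
        resolved = group.loc[group["resolved"]]
        if resolved.empty:
            removals["unresolved_chain_only"] += 1
            continue
        # identical resolved calls of one locus are one rearrangement split
        # across clusters, not a doublet — only *distinct* chains count
        resolved = resolved.drop_duplicates(
            subset=["locus", "constant_id", "v_id", "d_id", "j_id", "cdr3_aa"])
        by_locus = {locus: sub for locus, sub in resolved.groupby("locus")}
        if any(len(sub) > 1 for sub in by_locus.values()):
            removals["multi_chain_doublet"] += 1
            continue
        loci = set(by_locus)
        lineages = {lin for lin, pair in PAIRS.items() if loci & set(pair)}
        if len(lineages) > 1:
            removals["lineage_conflict"] += 1
            continue
        if len(loci) == 1:
            removals["orphan_chain"] += 1
            continue
        lineage = next(iter(lineages))
        vj_locus, vdj_locus = PAIRS[lineage]
        if loci != {vj_locus, vdj_locus}:
            removals["invalid_pair"] += 1
            continue
        vdj_chain = by_locus[vdj_locus].iloc[0]
        if not isinstance(vdj_chain["d_id"], str):
            removals["missing_d"] += 1
            continue
        vj_chain = by_locus[vj_locus].iloc[0]
        rows.append({
            "cell_barcode": cell, "lineage": lineage,
            "clonotype": clonotype_key(vj_chain, vdj_chain),
            "vj_cdr3": vj_chain["cdr3_aa"], "vdj_cdr3": vdj_chain["cdr3_aa"],
        })
    ledger = pd.DataFrame([("cell", rule, n) for rule, n in removals.items()],
                          columns=["stage", "rule", "n"])
    return pd.DataFrame(rows, columns=["cell_barcode", "lineage", "clonotype",
                                       "vj_cdr3", "vdj_cdr3"]), ledger


def single_chain_mode(chain_calls: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity mode: clonotypes keyed on the γ chain (γδ cells) or the
    β chain (αβ cells) alone.

    A cell is clonotyped iff it has exactly one resolved γ or β chain
    (with resolved D for β); paired-mode clonotypes are a refinement of
    these keys.
    """
    rows = []
    for cell, group in chain_calls.groupby("cell_barcode", sort=True):
        resolved = group.loc[group["resolved"] & group["locus"].isin(["TRG", "TRB"])]
        resolved = resolved.drop_duplicates(
            subset=["locus", "constant_id", "v_id", "d_id", "j_id", "cdr3_aa"])
        if len(resolved) != 1:
            continue
        chain = resolved.iloc[0]
        if chain["locus"] == "TRB" and not isinstance(chain["d_id"], str):
            continue
        rows.append({
            "cell_barcode": cell,
            "lineage": "gd" if chain["locus"] == "TRG" else "ab",
            "clonotype": _chain_key(chain),
            "vj_cdr3": chain["cdr3_aa"] if chain["locus"] == "TRG" else None,
            "vdj_cdr3": chain["cdr3_aa"] if chain["locus"] == "TRB" else None,
        })
    return pd.DataFrame(rows, columns=["cell_barcode", "lineage", "clonotype",
                                       "vj_cdr3", "vdj_cdr3"])


# ---------------------------------------------------------------------------
# pipeline wrapper


@dataclass
class ClonotypeResult:
    table: pd.DataFrame            # cell_barcode, lineage, clonotype, CDR3s
    chain_calls: pd.DataFrame
    ledger: pd.DataFrame           # stage, rule, n
    n_input_reads: int
    n_retained_reads: int

    def reconciles(self) -> bool:
        """Read-level removals must account exactly for input − retained."""
        read_stages = self.ledger.loc[self.ledger["stage"].isin(["gate", "filter", "locus"])]
        return int(read_stages["n"].sum()) == self.n_input_reads - self.n_retained_reads


def assign_clonotypes(records: pd.DataFrame, sequences: dict[str, str],
                      retained_barcodes: set[str] | None = None,
                      max_len: int = 700, truncate: bool = False,
                      params: ClusterParams | None = None,
                      single_chain: bool = False) -> ClonotypeResult:
    """Full pipeline: gate → filter → locus resolution → clustering →
    cell calling. ``records`` must carry the read-level AIRR-like columns
    (read_id, cell_barcode, locus, constant_id, length,
    constant_region_present, v_call, d_call, j_call, v_evalue, j_evalue,
    productive, cdr3_aa)."""
    n_input = len(records)
    ledgers = []
    gated, led = gate_reads(records, max_len=max_len,
                            retained_barcodes=retained_barcodes, truncate=truncate)
    ledgers.append(led)
    filtered, led = filter_records(gated)
    ledgers.append(led)
    concordant, led = resolve_locus(filtered)
    ledgers.append(led)
    chain_calls = cluster_cell_chains(concordant, sequences, params)
    if single_chain:
        table = single_chain_mode(chain_calls)
        cell_ledger = pd.DataFrame(columns=["stage", "rule", "n"])
    else:
        table, cell_ledger = call_cells(chain_calls)
    ledgers.append(cell_ledger)
    ledger = pd.concat(ledgers, ignore_index=True)
    return ClonotypeResult(table, chain_calls, ledger, n_input, len(concordant))
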