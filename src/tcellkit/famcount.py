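"""Gene-family counting from conserved-domain genomic hits.

Immune gene families (MHC-I/II, TCR variable and constant regions) evolve
by rapid birth and death, so annotation alone undercounts them: anciently
pseudogenized copies still carry recognizable conserved-domain matches.
This module turns a table of reciprocal-BLAST conserved-domain hits into
per-species family counts:

1. concordance filtering — keep hits of rank ≤ 10 whose reciprocal best
   domain is the domain the search was initiated with;
2. classification — hits overlapping annotated family members are
   *annotated*; hits inside non-family genes are removed; unannotated
   hits near family genes are *syntenic_unannotated*, the rest
   *nonsyntenic_unannotated*;
3. multi-exon families (MHC): adjacent-hit gap distances within annotated
   genes (intragenic) vs between genes (intergenic) calibrate a distance
   cutoff by F-measure maximization, after which hits are greedily chained
   into genes scaffold by scaffold, starting from the most upstream hit;
4. single-domain families (TCR variable regions): one gene per hit.

Coordinates are 0-based half-open throughout; the gap between adjacent
hits is ``next.start − prev.end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionSummary",
    "reciprocal_filter",
    "classify_hits",
    "gap_table",
    "f_measure",
    "optimize_cutoff",
    "group_hits",
    "count_families",
    "benchmark_against_annotation",
]

HIT_COLUMNS = ["scaffold", "start", "end", "strand", "domain_id", "family",
               "rank", "reciprocal_best_domain"]


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary confusion counts for intragenic-vs-intergenic gap calls.

    Positives are intragenic gaps (gap < cutoff predicts intragenic).
    """

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else np.nan

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else np.nan

    @property
    def f1(self) -> float:
        return f_measure(self, "f1")


def f_measure(summary: ConfusionSummary, formula: str = "f1") -> float:
    """F-measure of a confusion summary.

    ``f1`` is the harmonic mean 2pr/(p+r); ``half`` is pr/(p+r), i.e.
    half of it — a strictly monotone transform, so any cutoff argmax is
    identical under either. Undefined precision or recall propagates as
    NaN rather than being coerced to zero.
    """
    p, r = summary.precision, summary.recall
    if np.isnan(p) or np.isnan(r):
        return np.nan
    if p + r == 0:
        return np.nan
    if formula == "f1":
        return 2 * p * r / (p + r)
    if formula == "half":
        return p * r / (p + r)
    raise ValueError(f"unknown formula {formula!r}")


def reciprocal_filter(hits: pd.DataFrame, initiating_domain: str,
                      max_rank: int = 10) -> pd.DataFrame:
    """Keep hits of rank ≤ ``max_rank`` whose reciprocal best domain is the
    initiating domain (reciprocal-BLAST concordance)."""
    for col in ("rank", "reciprocal_best_domain"):
        if col not in hits.columns:
            raise KeyError(f"hits table lacks required column {col!r}")
    keep = (hits["rank"] <= max_rank) & (hits["reciprocal_best_domain"] == initiating_domain)
    return hits.loc[keep].reset_index(drop=True)


def _overlaps(start: int, end: int, istart: np.ndarray, iend: np.ndarray) -> np.ndarray:
    return (start < iend) & (istart < end)


def classify_hits(hits: pd.DataFrame, annotations: pd.DataFrame,
                  elimination: pd.DataFrame | None = None,
                  synteny_window: int = 1_000_000) -> pd.DataFrame:
    """Assign each hit a status and drop disallowed hits.

    Returns the input hits with added ``status`` ∈ {annotated,
    syntenic_unannotated, nonsyntenic_unannotated, removed} and, where
    applicable, ``gene_id`` of the overlapped annotated family gene and a
    ``removal_reason``. Rules, per hit:

    * inside an elimination interval → removed;
    * overlapping an annotated family-member gene → annotated;
    * overlapping a non-family annotated gene → removed;
    * otherwise, within ``synteny_window`` bp of a family-member gene on
      the same scaffold → syntenic_unannotated, else
      nonsyntenic_unannotated.

    A hit overlapping both a family and a non-family gene is a
    contradictory annotation and raises an error listing the conflicts.
    """
    out = hits.copy().reset_index(drop=True)
    status = np.empty(len(out), dtype=object)
    gene_id = np.full(len(out), None, dtype=object)
    reason = np.full(len(out), None, dtype=object)

    ann_by_scaf = {s: g for s, g in annotations.groupby("scaffold")}
    elim_by_scaf = ({s: g for s, g in elimination.groupby("scaffold")}
                    if elimination is not None and len(elimination) else {})

    conflicts = []
    for i, hit in out.iterrows():
        s, st, en = hit["scaffold"], int(hit["start"]), int(hit["end"])
        elim = elim_by_scaf.get(s)
        if elim is not None and _overlaps(st, en, elim["start"].to_numpy(),
                                          elim["end"].to_numpy()).any():
            status[i], reason[i] = "removed", "elimination_interval"
            continue
        ann = ann_by_scaf.get(s)
        if ann is not None:
            ov = _overlaps(st, en, ann["start"].to_numpy(), ann["end"].to_numpy())
            if ov.any():
                fam = ann.loc[ov, "is_family_member"].to_numpy(dtype=bool)
                if fam.any() and (~fam).any():
                    conflicts.append((hit.get("hit_id", i), sorted(ann.loc[ov, "gene_id"])))
                    continue
                if fam.any():
                    status[i] = "annotated"
                    gene_id[i] = ann.loc[ov, "gene_id"].iloc[np.argmax(fam)]
                else:
                    status[i], reason[i] = "removed", "non_family_gene"
                continue
            fam_ann = ann.loc[ann["is_family_member"].astype(bool)]
            if len(fam_ann):
                dist = np.maximum(fam_ann["start"].to_numpy() - en,
                                  st - fam_ann["end"].to_numpy())
                if (dist <= synteny_window).any():
                    status[i] = "syntenic_unannotated"
                    continue
        status[i] = "nonsyntenic_unannotated"

    if conflicts:
        raise ValueError(f"hits overlap contradictory annotations: {conflicts}")
    out["status"] = status
    out["gene_id"] = gene_id
    out["removal_reason"] = reason
    return out


def gap_table(hits: pd.DataFrame) -> pd.DataFrame:
    """Adjacent-hit gap distances among annotated hits, with truth labels.

    One row per genomically adjacent pair of annotated hits on the same
    scaffold: ``distance = next.start − prev.end`` (floored at 0) and
    ``truth`` = *intragenic* iff both hits lie in the same annotated gene,
    else *intergenic*. Scaffolds with a single annotated hit contribute
    nothing; an entirely empty result is returned as an (empty) table for
    the caller to flag.
    """
    ann = hits.loc[hits["status"] == "annotated"].sort_values(["scaffold", "start", "end"])
    rows = []
    for _, group in ann.groupby("scaffold"):
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        genes = group["gene_id"].to_numpy()
        for k in range(len(group) - 1):
            rows.append({
                "distance": max(int(starts[k + 1] - ends[k]), 0),
                "truth": "intragenic" if genes[k + 1] == genes[k] else "intergenic",
            })
    return pd.DataFrame(rows, columns=["distance", "truth"])


def _confusion_at(distances: np.ndarray, intragenic: np.ndarray, cutoff: float) -> ConfusionSummary:
    pred = distances < cutoff
    return ConfusionSummary(
        TP=int((pred & intragenic).sum()),
        FP=int((pred & ~intragenic).sum()),
        FN=int((~pred & intragenic).sum()),
        TN=int((~pred & ~intragenic).sum()),
    )


def optimize_cutoff(gaps: pd.DataFrame, formula: str = "f1") -> tuple[float, ConfusionSummary]:
    """Distance cutoff maximizing the F-measure of intragenic/intergenic
    gap classification (gap < cutoff ⇒ intragenic).

    Candidates are the midpoints between consecutive sorted unique
    distances plus sentinels below the minimum and above the maximum; the
    smallest optimal cutoff is returned on ties. Both truth classes must
    be present. If intragenic gaps tend to be *larger* than intergenic
    ones the best achievable F is still returned, with a warning.
    """
    if len(gaps) == 0 or gaps["truth"].nunique() < 2:
        raise ValueError("cutoff optimization needs both intragenic and intergenic gaps")
    d = gaps["distance"].to_numpy(dtype=float)
    intra = (gaps["truth"] == "intragenic").to_numpy()
    uniq = np.unique(d)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + 1.0]])
    best_cut, best_f, best_summary = None, -np.inf, None
    for c in candidates:
        summary = _confusion_at(d, intra, c)
        f = f_measure(summary, formula)
        if not np.isnan(f) and f > best_f + 1e-15:
            best_cut, best_f, best_summary = float(c), f, summary
    if best_summary is None:
        raise ValueError("no candidate cutoff yields a defined F-measure")
    if np.median(d[intra]) > np.median(d[~intra]):
        warnings.warn("intragenic gaps are larger than intergenic gaps; "
                      "cutoff direction may be inverted", stacklevel=2)
    return best_cut, best_summary


def group_hits(hits: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Greedy chaining of hits into genes at a fixed gap cutoff.

    Per scaffold, hits are visited from the most upstream; a hit joins
    its upstream neighbor's gene iff the gap separating them
    (``start − prev.end``) is below ``cutoff``, else it opens a new gene.
    Output: one row per gene with ``gene_index``, ``scaffold``, span
    (``start``/``end``), ``n_hits``, member ``hit_rows`` (input row
    labels), and modal ``status`` if present. The rows partition the
    input hits.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    genes = []
    idx = 0
    for scaffold, group in hits.sort_values(["scaffold", "start", "end"]).groupby("scaffold", sort=True):
        members: list = []
        prev_end = None
        for row_label, hit in group.iterrows():
            if prev_end is not None and (hit["start"] - prev_end) >= cutoff:
                genes.append(_gene_row(idx, scaffold, members, hits))
                idx += 1
                members = []
            members.append(row_label)
            prev_end = int(hit["end"])
        if members:
            genes.append(_gene_row(idx, scaffold, members, hits))
            idx += 1
    return pd.DataFrame(genes, columns=["gene_index", "scaffold", "start", "end",
                                        "n_hits", "hit_rows", "status"])


def _gene_row(idx: int, scaffold, members: list, hits: pd.DataFrame) -> dict:
    sub = hits.loc[members]
    if "status" in sub.columns:
        counts = sub["status"].value_counts()
        status = counts.index[0] if len(counts) else None
    else:
        status = None
    return {"gene_index": idx, "scaffold": scaffold,
            "start": int(sub["start"].min()), "end": int(sub["end"].max()),
            "n_hits": len(sub), "hit_rows": list(members), "status": status}


_MULTI_DOMAIN_FAMILIES = {"MHC-I", "MHC-II"}


def count_families(hits_by_species: dict[str, pd.DataFrame],
                   cutoffs: dict[str, float] | float | None = None,
                   pooled_cutoff: float | None = None) -> pd.DataFrame:
    """Species-by-family gene-count table (the phyletic pattern).

    MHC families are counted by ``group_hits`` at a per-species cutoff
    (``cutoffs`` dict keyed by species, a single float, or
    ``pooled_cutoff`` as fallback); single-domain TCR families count one
    gene per hit after merging overlapping same-family hits. Derived sums
    ``Va+Vb``, ``Vg+Vd``, are appended when their parts are present.
    """
    records = []
    for species, hits in hits_by_species.items():
        for family, fam_hits in hits.groupby("family"):
            if "status" in fam_hits.columns:
                fam_hits = fam_hits.loc[fam_hits["status"] != "removed"]
            if family in _MULTI_DOMAIN_FAMILIES:
                if isinstance(cutoffs, dict):
                    cutoff = cutoffs.get(species, pooled_cutoff)
                elif cutoffs is not None:
                    cutoff = float(cutoffs)
                else:
                    cutoff = pooled_cutoff
                if cutoff is None:
                    raise ValueError(f"no distance cutoff for species {species!r}")
                count = len(group_hits(fam_hits, cutoff))
            else:
                # single-domain regions: merge overlapping hits, one gene per hit
                count = len(group_hits(fam_hits, 0.0))
            records.append({"species": species, "family": family, "count": int(count)})
    table = (pd.DataFrame(records)
             .pivot(index="species", columns="family", values="count")
             .fillna(0).astype(int))
    for label, parts in (("Va+Vb", ("TRAV", "TRBV")), ("Vg+Vd", ("TRGV", "TRDV"))):
        if all(p in table.columns for p in parts):
            table[label] = table[list(parts)].sum(axis=1)
    return table


def benchmark_against_annotation(gene_calls: pd.DataFrame,
                                 annotations: pd.DataFrame) -> dict:
    """False-negative rate and unannotated-call proportions.

    FN rate = fraction of annotated family-member genes with no
    overlapping gene call; the unannotated-call fraction serves as an
    upper bound on the false-positive rate (an unannotated call may be a
    real unannotated pseudogene). Per-status call proportions included.
    """
    fam = annotations.loc[annotations["is_family_member"].astype(bool)]
    missed = 0
    for _, gene in fam.iterrows():
        calls = gene_calls.loc[gene_calls["scaffold"] == gene["scaffold"]]
        if not _overlaps(int(gene["start"]), int(gene["end"]),
                         calls["start"].to_numpy(), calls["end"].to_numpy()).any():
            missed += 1
    fn_rate = missed / len(fam) if len(fam) else np.nan
    status = gene_calls["status"].fillna("unknown")
    props = status.value_counts(normalize=True).to_dict() if len(gene_calls) else {}
    unannotated = sum(v for k, v in props.items() if k.endswith("unannotated"))
    return {"fn_rate": fn_rate, "n_annotated_family_genes": int(len(fam)),
            "n_missed": missed, "unannotated_call_fraction": unannotated,
            "status_proportions": props}
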