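"""Clonotypic diversity, publicity, dominance, bootstrap contrasts and
clonotype networks.

Works on a cell-level clonotype table (one row per cell: sample, optional
subset and age-group labels, clonotype key, per-chain CDR3s). Diversity of
a sample is summarized by three plug-in estimators capturing different
facets: the Hill number of order 0 (richness — number of distinct
clonotypes), Shannon entropy (evenness-weighted, nats) and the
Gini–Simpson index (1 minus the probability that two random cells share a
clonotype; emphasizes rare clonotypes). Group contrasts resample cells
with replacement within each sample, compare group means of the
per-sample metric, and adjust p-values by Benjamini–Hochberg FDR across
the batch. Clonotype networks connect clonotypes whose CDR3s are within
an alignment-distance cutoff on both the VJ (α/γ) and VDJ (β/δ) arms,
keeping connected components supported by at least three cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "diversity_metrics",
    "metrics_table",
    "publicity",
    "dominance",
    "bootstrap_contrast",
    "cdr3_distance",
    "build_network",
    "ClonotypeNetwork",
]

METRICS = ("hill_q0", "shannon", "gini_simpson")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# metrics


def diversity_metrics(abundances) -> tuple[int, float, float]:
    """(hill_q0, shannon, gini_simpson) of a clonotype abundance vector.

    hill_q0 = number of clonotypes with positive abundance; shannon =
    −Σ pᵢ ln pᵢ in nats; gini_simpson = 1 − Σ pᵢ². All are plug-in
    estimators with pᵢ = abundance / total.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or a.sum() <= 0:
        raise ValueError("abundance vector must be non-empty with positive total")
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    p = a / a.sum()
    return int(p.size), float(-(p * np.log(p)).sum()), float(1.0 - (p ** 2).sum())


def hill_number(abundances, q: float = 0.0) -> float:
    """Hill diversity of order q (effective number of clonotypes)."""
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    p = a / a.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p ** q).sum() ** (1.0 / (1.0 - q)))


def _abundances(cells: pd.Series) -> np.ndarray:
    return cells.value_counts().to_numpy()


def metrics_table(table: pd.DataFrame, by=("sample_id", "subset")) -> pd.DataFrame:
    """Per-group diversity summary of a cell-level clonotype table."""
    by = [b for b in by if b in table.columns]
    if not by:
        h, s, g = diversity_metrics(_abundances(table["clonotype"]))
        return pd.DataFrame([{"n_cells": len(table), "hill_q0": h,
                              "shannon": s, "gini_simpson": g}])
    rows = []
    for keys, group in table.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        h, s, g = diversity_metrics(_abundances(group["clonotype"]))
        rows.append(dict(zip(by, keys)) | {"n_cells": len(group), "hill_q0": h,
                                           "shannon": s, "gini_simpson": g})
    return pd.DataFrame(rows)


def publicity(table: pd.DataFrame, subset: str | None = None) -> float:
    """Fraction of unique clonotypes observed in more than one sample."""
    sub = table if subset is None else table.loc[table["subset"] == subset]
    if sub["sample_id"].nunique() < 2:
        raise ValueError("publicity needs >= 2 samples")
    per_clone = sub.groupby("clonotype")["sample_id"].nunique()
    return float((per_clone > 1).mean())


def dominance(table: pd.DataFrame, subset: str | None = None) -> dict:
    """Per-sample modal-clonotype cell fraction, with mean ± SE.

    Matches 'mean X% ± Y' style reporting: SE is the standard error of
    the per-sample fractions across samples.
    """
    sub = table if subset is None else table.loc[table["subset"] == subset]
    per_sample = {}
    for sample, group in sub.groupby("sample_id"):
        counts = group["clonotype"].value_counts()
        per_sample[sample] = float(counts.iloc[0] / counts.sum())
    vals = np.array(list(per_sample.values()))
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
    return {"per_sample": per_sample, "mean": float(vals.mean()), "se": se}


# ---------------------------------------------------------------------------
# bootstrap contrasts


def _metric_matrix(counts: np.ndarray, n: int, metric: str) -> np.ndarray:
    """Metric of each row of a (B x K) resampled count matrix."""
    if metric == "hill_q0":
        return (counts > 0).sum(axis=1).astype(float)
    p = counts / n
    if metric == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return -terms.sum(axis=1)
    if metric == "gini_simpson":
        return 1.0 - (p ** 2).sum(axis=1)
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_contrast(table: pd.DataFrame, grouping: dict,
                       metrics=METRICS, B: int = 5000,
                       seed: int | None = None) -> pd.DataFrame:
    """Bootstrap group contrasts of per-sample diversity, FDR-adjusted.

    ``grouping`` maps a contrast label to a pair of sample-id lists
    (group A, group B). For each contrast and metric the observed
    statistic is ``T = mean_A(metric per sample) − mean_B``; each of the
    ``B`` replicates resamples every sample's cells with replacement
    (multinomial over its clonotype abundances) and recomputes T. The
    two-sided p-value is ``2·min(Pr(T* ≤ 0), Pr(T* ≥ 0))`` with a +1
    continuity correction; Benjamini–Hochberg adjustment is applied
    across all contrasts and metrics of the batch. Contrasts with an
    empty group are skipped with a warning column rather than an error.
    """
    rng = np.random.default_rng(seed)
    sample_counts = {s: _abundances(g["clonotype"])
                     for s, g in table.groupby("sample_id")}

    rows = []
    for label, (group_a, group_b) in grouping.items():
        group_a = [s for s in group_a if s in sample_counts]
        group_b = [s for s in group_b if s in sample_counts]
        if not group_a or not group_b:
            import warnings
            warnings.warn(f"contrast {label!r} skipped: empty group", stacklevel=2)
            continue
        boot = {}
        obs = {}
        for s in group_a + group_b:
            c = sample_counts[s]
            n = int(c.sum())
            resampled = rng.multinomial(n, c / n, size=B)
            boot[s] = {m: _metric_matrix(resampled, n, m) for m in metrics}
            obs[s] = {m: _metric_matrix(c[None, :], n, m)[0] for m in metrics}
        for m in metrics:
            T = (np.mean([obs[s][m] for s in group_a])
                 - np.mean([obs[s][m] for s in group_b]))
            Ts = (np.mean([boot[s][m] for s in group_a], axis=0)
                  - np.mean([boot[s][m] for s in group_b], axis=0))
            p_lo = (1 + (Ts <= 0).sum()) / (B + 1)
            p_hi = (1 + (Ts >= 0).sum()) / (B + 1)
            p = min(1.0, 2.0 * min(p_lo, p_hi))
            rows.append({"contrast": label, "metric": m, "observed": float(T),
                         "B": B, "p_raw": float(p)})
    out = pd.DataFrame(rows, columns=["contrast", "metric", "observed", "B", "p_raw"])
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out


# ---------------------------------------------------------------------------
# CDR3 distances and networks


def _aa_aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -10
    aln.extend_gap_score = -1
    return aln


_AA_ALIGNER = _aa_aligner()
_B62 = substitution_matrices.load("BLOSUM62")


def _self_score(seq: str) -> float:
    return float(sum(_B62[c, c] for c in seq))


@lru_cache(maxsize=200_000)
def cdr3_distance(cdr3_a: str, cdr3_b: str) -> float:
    """Alignment distance between two CDR3 amino-acid sequences.

    ``max(S(a,a), S(b,b)) − S(a,b)`` with S the BLOSUM62 global alignment
    score (gap open 10 / extend 1): identical sequences score 0 and the
    value grows with dissimilarity. Symmetric by construction.
    """
    for seq in (cdr3_a, cdr3_b):
        if not seq or not set(seq) <= _AA:
            raise ValueError(f"invalid amino-acid sequence {seq!r}")
    if cdr3_a == cdr3_b:
        return 0.0
    score = _AA_ALIGNER.score(cdr3_a, cdr3_b)
    return float(max(_self_score(cdr3_a), _self_score(cdr3_b)) - score)


@dataclass
class ClonotypeNetwork:
    """Clonotype clusters: connected components of the thresholded
    CDR3-distance graph, filtered by supporting-cell count."""

    graph: nx.Graph                # nodes = clonotype keys (kept clusters only)
    clusters: list[set[str]]       # each set = clonotype keys of one cluster
    node_table: pd.DataFrame       # per-cluster metadata (pie-chart-ready)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(table: pd.DataFrame, cutoff: float = 15.0,
                  min_cells: int = 3) -> ClonotypeNetwork:
    """Clonotype cluster network from a cell-level clonotype table.

    Two clonotypes are connected iff the CDR3 distances of *both* arms
    (VJ and VDJ chains) are ≤ ``cutoff``. Clusters are connected
    components; components with fewer than ``min_cells`` supporting cells
    are dropped. ``node_table`` reports, per cluster, total cells and
    per-sample / per-subset compositions.
    """
    cols = ["clonotype", "vj_cdr3", "vdj_cdr3"]
    uniq = table[cols].drop_duplicates("clonotype").reset_index(drop=True)
    G = nx.Graph()
    G.add_nodes_from(uniq["clonotype"])
    keys = uniq["clonotype"].tolist()
    vj = uniq["vj_cdr3"].tolist()
    vdj = uniq["vdj_cdr3"].tolist()
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if cdr3_distance(vj[i], vj[j]) > cutoff:
                continue
            if cdr3_distance(vdj[i], vdj[j]) > cutoff:
                continue
            G.add_edge(keys[i], keys[j])

    cell_counts = table["clonotype"].value_counts()
    clusters, rows = [], []
    for comp in nx.connected_components(G):
        total = int(sum(cell_counts.get(k, 0) for k in comp))
        if total < min_cells:
            continue
        clusters.append(set(comp))
        members = table.loc[table["clonotype"].isin(comp)]
        row = {"cluster_id": len(clusters) - 1, "n_clonotypes": len(comp),
               "n_cells": total}
        if "sample_id" in members.columns:
            row["cells_per_sample"] = members["sample_id"].value_counts().to_dict()
        if "subset" in members.columns:
            row["cells_per_subset"] = members["subset"].value_counts().to_dict()
        rows.append(row)
    kept = set().union(*clusters) if clusters else set()
    return ClonotypeNetwork(G.subgraph(kept).copy(), clusters, pd.DataFrame(rows))
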