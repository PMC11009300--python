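"""Single-cell barcode/gene quality control.

Filters a gene-by-barcode UMI count matrix the way droplet scRNA-seq data
are commonly cleaned when no external cell-calling tool is used:

* barcodes are called as cells by locating the first local minimum above
  ``log10 = 2`` in the smoothed distribution of per-barcode log10(#UMIs)
  (the valley between the ambient/empty-droplet mode and the cell mode);
* genes captured too sparsely are dropped via the analogous first local
  minimum above ``log10 = 3`` of per-gene log10(#barcodes);
* multiplet barcodes are sought as secondary local modes of the
  log10(#genes) and log10(#UMIs) distributions whose x-location exceeds
  1.5x the global mode's x-location and whose basin holds under 5% of
  barcodes;
* retained counts are depth-normalized as ``ln(count / depth * 1e4 + 1)``.

Densities are Gaussian-kernel estimates (Silverman bandwidth by default);
extrema are read off a dense evaluation grid, with ties broken toward
smaller x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.stats import gaussian_kde

__all__ = [
    "CountMatrix",
    "Threshold",
    "QcReport",
    "barcode_threshold",
    "gene_threshold",
    "detect_multiplets",
    "normalize",
    "run_qc",
]

_GRID_SIZE = 1024


@dataclass
class CountMatrix:
    """Gene-by-barcode UMI count matrix with identifier sidecars.

    ``counts`` is stored as CSR with genes on rows and barcodes on
    columns; marginals are computed lazily from it so they can never
    drift out of sync.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcode identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    # -- marginals -------------------------------------------------------
    def umis_per_barcode(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_barcode(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def barcodes_per_gene(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        genes: Sequence[str] | None = None,
        barcodes: Sequence[str] | None = None,
    ) -> "CountMatrix":
        gidx = np.arange(len(self.genes))
        bidx = np.arange(len(self.barcodes))
        if genes is not None:
            keep = set(genes)
            gidx = np.array([i for i, g in enumerate(self.genes) if g in keep], dtype=int)
        if barcodes is not None:
            keep = set(barcodes)
            bidx = np.array([i for i, b in enumerate(self.barcodes) if b in keep], dtype=int)
        return CountMatrix(
            [self.genes[i] for i in gidx],
            [self.barcodes[i] for i in bidx],
            self.counts[gidx][:, bidx],
        )

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_mtx(cls, matrix: str | Path, genes: str | Path, barcodes: str | Path) -> "CountMatrix":
        counts = sp.csr_matrix(scipy.io.mmread(str(matrix)))
        gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str).tolist()
        barcode_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        return cls(gene_ids, barcode_ids, counts)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.astype(str).tolist(), df.columns.astype(str).tolist(),
                   sp.csr_matrix(df.to_numpy()))

    def to_mtx(self, outdir: str | Path, prefix: str = "matrix") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / f"{prefix}.mtx"), sp.coo_matrix(self.counts))
        pd.Series(self.genes).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(self.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)


@dataclass(frozen=True)
class Threshold:
    """Outcome of a local-minimum scan.

    ``found=False`` is an explicit no-threshold result (no local minimum
    above the floor); callers decide what to do — nothing is filtered by
    default in that case.
    """

    found: bool
    value: float | None
    floor: float
    minima: tuple[float, ...] = ()
    modes: tuple[float, ...] = ()


@dataclass
class QcReport:
    barcode_threshold: Threshold | None = None
    gene_threshold: Threshold | None = None
    multiplet_barcodes: set[str] = field(default_factory=set)
    retained_barcodes: list[str] = field(default_factory=list)
    retained_genes: list[str] = field(default_factory=list)
    n_input_barcodes: int = 0
    n_input_genes: int = 0

    def to_json(self, path: str | Path) -> None:
        def _thr(t: Threshold | None):
            if t is None:
                return None
            return {"found": t.found, "value": t.value, "floor": t.floor,
                    "minima": list(t.minima), "modes": list(t.modes)}

        payload = {
            "barcode_threshold": _thr(self.barcode_threshold),
            "gene_threshold": _thr(self.gene_threshold),
            "multiplet_barcodes": sorted(self.multiplet_barcodes),
            "n_retained_barcodes": len(self.retained_barcodes),
            "n_retained_genes": len(self.retained_genes),
            "n_input_barcodes": self.n_input_barcodes,
            "n_input_genes": self.n_input_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# density machinery


def _density_grid(values: np.ndarray, bandwidth: float | None):
    """Gaussian-KDE density of ``values`` on a dense grid.

    ``bandwidth`` is in the units of ``values`` (log10 counts); ``None``
    selects Silverman's rule.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for density estimation")
    std = values.std(ddof=1)
    if std == 0:
        # degenerate spike: single mode at the common value
        grid = np.linspace(values[0] - 1, values[0] + 1, _GRID_SIZE)
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - values[0]))] = 1.0
        return grid, dens
    if bandwidth is None:
        kde = gaussian_kde(values, bw_method="silverman")
    else:
        kde = gaussian_kde(values, bw_method=bandwidth / std)
    h = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, _GRID_SIZE)
    return grid, kde(grid)


# relative density contrast an extremum must have against its flanking
# opposite extrema to count as a genuine valley/mode (suppresses KDE ripples)
_PROMINENCE = 0.10


def _minima_idx(dens: np.ndarray) -> np.ndarray:
    """Indices of strict-left local minima (ties toward smaller x)."""
    return 1 + np.flatnonzero((dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:]))


def _maxima_idx(dens: np.ndarray) -> np.ndarray:
    return 1 + np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))


def _prominent_minima(dens: np.ndarray) -> np.ndarray:
    """Minima at least ``_PROMINENCE`` below both flanking maxima."""
    mins, maxs = _minima_idx(dens), _maxima_idx(dens)
    keep = []
    for i in mins:
        left = maxs[maxs < i]
        right = maxs[maxs > i]
        if not left.size or not right.size:
            continue
        lowest_flank = min(dens[left.max()], dens[right.min()])
        if dens[i] <= (1 - _PROMINENCE) * lowest_flank:
            keep.append(i)
    return np.array(keep, dtype=int)


def _prominent_maxima(dens: np.ndarray) -> np.ndarray:
    """Maxima at least ``_PROMINENCE`` above both flanking minima (the
    data's outer edges count as flanks)."""
    mins, maxs = _minima_idx(dens), _maxima_idx(dens)
    keep = []
    for i in maxs:
        left = mins[mins < i]
        right = mins[mins > i]
        left_floor = dens[left.max()] if left.size else dens[:i].min()
        right_floor = dens[right.min()] if right.size else dens[i:].min()
        if dens[i] * (1 - _PROMINENCE) >= max(left_floor, right_floor):
            keep.append(i)
    return np.array(keep, dtype=int)


def _first_minimum_above(values: np.ndarray, floor: float,
                         bandwidth: float | None) -> Threshold:
    grid, dens = _density_grid(values, bandwidth)
    min_x = grid[_prominent_minima(dens)]
    mode_x = grid[_maxima_idx(dens)]
    above = min_x[min_x > floor]
    if above.size == 0:
        return Threshold(False, None, floor, tuple(min_x), tuple(mode_x))
    return Threshold(True, float(above.min()), floor, tuple(min_x), tuple(mode_x))


# ---------------------------------------------------------------------------
# public operations


def barcode_threshold(matrix: CountMatrix, bandwidth: float | None = None,
                      floor: float = 2.0) -> Threshold:
    """First local minimum above ``floor`` of per-barcode log10(#UMIs)."""
    totals = matrix.umis_per_barcode()
    totals = totals[totals > 0]
    if totals.size < 2:
        raise ValueError("need >= 2 barcodes with positive totals")
    return _first_minimum_above(np.log10(totals), floor, bandwidth)


def gene_threshold(matrix: CountMatrix, bandwidth: float | None = None,
                   floor: float = 3.0) -> Threshold:
    """First local minimum above ``floor`` of per-gene log10(#barcodes)."""
    prevalence = matrix.barcodes_per_gene()
    prevalence = prevalence[prevalence > 0]
    if prevalence.size < 2:
        raise ValueError("need >= 2 genes with positive prevalence")
    return _first_minimum_above(np.log10(prevalence), floor, bandwidth)


def _qualifying_basins(values: np.ndarray, fold: float, max_fraction: float,
                       bandwidth: float | None) -> list[tuple[float, float]]:
    """Basins (flanking-minima intervals) of modes satisfying the
    fold-location and basin-occupancy rules, on one distribution."""
    grid, dens = _density_grid(values, bandwidth)
    minima = grid[_minima_idx(dens)]
    maxima = grid[_prominent_maxima(dens)]
    if maxima.size == 0:
        return []
    global_mode = float(grid[np.argmax(dens)])
    basins = []
    n = values.size
    for m in maxima:
        if m <= fold * global_mode:
            continue
        left = minima[minima < m]
        right = minima[minima > m]
        lo = left.max() if left.size else -np.inf
        hi = right.min() if right.size else np.inf
        members = (values > lo) & (values <= hi)
        if members.sum() < max_fraction * n:
            basins.append((float(lo), float(hi)))
    return basins


def detect_multiplets(matrix: CountMatrix, bandwidth: float | None = None,
                      fold: float = 1.5, max_fraction: float = 0.05,
                      combine: str = "union") -> set[str]:
    """Barcodes in inflated secondary modes of log10(#genes) / log10(#UMIs).

    A local mode qualifies iff its x-location exceeds ``fold`` times the
    global mode's x-location AND its basin (between the flanking local
    minima) contains under ``max_fraction`` of barcodes. Flags from the
    two distributions are combined by ``union`` (default) or
    ``intersection``.
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    barcodes = np.asarray(matrix.barcodes)
    flagged: list[set[str]] = []
    for raw in (matrix.genes_per_barcode(), matrix.umis_per_barcode()):
        positive = raw > 0
        values = np.log10(raw[positive])
        names = barcodes[positive]
        hits: set[str] = set()
        if values.size >= 2:
            for lo, hi in _qualifying_basins(values, fold, max_fraction, bandwidth):
                hits.update(names[(values > lo) & (values <= hi)])
        flagged.append(hits)
    return flagged[0] | flagged[1] if combine == "union" else flagged[0] & flagged[1]


def normalize(matrix: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Depth-normalized expression: ``ln(count / depth * scale + 1)``.

    Returns a dense genes-x-barcodes float array; zeros stay zero and the
    result is invariant to uniform depth rescaling of a barcode.
    """
    totals = matrix.umis_per_barcode()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            "zero-total barcode(s): " + ", ".join(matrix.barcodes[i] for i in zero[:10])
        )
    x = matrix.counts.astype(float).toarray()
    return np.log1p(x / totals[None, :] * scale)


def run_qc(matrix: CountMatrix, bandwidth: float | None = None,
           combine: str = "union") -> tuple[CountMatrix, QcReport]:
    """Full filter pipeline: barcode valley, gene valley, multiplet modes.

    A no-threshold result leaves the corresponding axis unfiltered; the
    pipeline is idempotent (its output passes through unchanged).
    """
    report = QcReport(n_input_barcodes=len(matrix.barcodes),
                      n_input_genes=len(matrix.genes))

    bthr = barcode_threshold(matrix, bandwidth)
    report.barcode_threshold = bthr
    totals = matrix.umis_per_barcode()
    keep_bc = np.ones(len(matrix.barcodes), dtype=bool)
    if bthr.found:
        with np.errstate(divide="ignore"):
            keep_bc = np.log10(np.maximum(totals, 1e-300)) >= bthr.value
    current = matrix.subset(barcodes=[b for b, k in zip(matrix.barcodes, keep_bc) if k])

    gthr = gene_threshold(current, bandwidth)
    report.gene_threshold = gthr
    if gthr.found:
        prev = current.barcodes_per_gene()
        with np.errstate(divide="ignore"):
            keep_g = np.log10(np.maximum(prev, 1e-300)) >= gthr.value
        current = current.subset(genes=[g for g, k in zip(current.genes, keep_g) if k])

    multiplets = detect_multiplets(current, bandwidth, combine=combine)
    report.multiplet_barcodes = multiplets
    if multiplets:
        current = current.subset(barcodes=[b for b in current.barcodes if b not in multiplets])

    report.retained_barcodes = list(current.barcodes)
    report.retained_genes = list(current.genes)
    return current, report
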