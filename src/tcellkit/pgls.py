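"""Phylogenetic least squares under a Brownian-motion covariance.

Cross-species regressions of gene-family sizes (e.g. the summed γ+δ
variable TCR regions on the summed α+β variable regions, or ln MHC-I/MHC-II
ratios) cannot treat species as independent observations: trait covariance
accumulates along shared branches. Under Brownian motion the expected
covariance of two tips equals the depth of their most recent common
ancestor, so the model is GLS with that covariance,

    y = Xβ + ε,   ε ~ N(0, σ² C),   C_ij = depth(MRCA(i, j)).

Fitting is by maximum likelihood (closed form for fixed C):
β̂ = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹ y and σ̂² = r'C⁻¹r / n. Residuals are reported raw
(y − Xβ̂), i.e. per-species deviations on the trait scale, with
phylogenetically whitened residuals also available. Goodness of fit uses
the likelihood-based Nagelkerke pseudo-R² against the intercept-only fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_tree",
    "brownian_cov",
    "fit_pgls",
    "nagelkerke_r2",
    "log_ratio",
    "PGLSFit",
]


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree from a path or a newick string."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return dendropy.Tree.get(data=text, schema="newick")


def brownian_cov(tree: dendropy.Tree, taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of a rooted tree.

    ``C[i, i]`` is the root-to-tip path length of species *i* and
    ``C[i, j]`` the depth (root distance) of the most recent common
    ancestor of *i* and *j*. Rows follow ``taxa`` when given (an error
    names any species absent from the tree), else the tree's leaf order.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if taxa is None:
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise KeyError(f"species not in tree: {missing}")

    # ancestor sets once per tip, then MRCA depth = deepest shared ancestor
    ancestors: dict[str, dict[int, float]] = {}
    for name in taxa:
        node = leaves[name]
        chain: dict[int, float] = {}
        while node is not None:
            chain[id(node)] = node.root_distance or 0.0
            node = node.parent_node
        ancestors[name] = chain

    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = leaves[a].root_distance or 0.0
        for j in range(i + 1, n):
            shared = ancestors[a].keys() & ancestors[taxa[j]].keys()
            depth = max(ancestors[a][k] for k in shared)
            C[i, j] = C[j, i] = depth
    return C, list(taxa)


@dataclass
class PGLSFit:
    """Maximum-likelihood GLS fit under a fixed phylogenetic covariance."""

    coefficients: np.ndarray      # (p,) — intercept first when X has one
    sigma2: float                 # ML rate estimate
    log_likelihood: float
    residuals: np.ndarray         # raw, y - X beta
    fitted: np.ndarray
    cov_beta: np.ndarray          # small-sample (n-p) covariance of beta
    C: np.ndarray
    n: int
    species: list[str] | None = None

    @property
    def whitened_residuals(self) -> np.ndarray:
        L = np.linalg.cholesky(self.C)
        return np.linalg.solve(L, self.residuals)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import t

        p = self.coefficients.size
        q = t.ppf(0.5 + level / 2, df=self.n - p)
        se = np.sqrt(np.diag(self.cov_beta))
        return np.column_stack([self.coefficients - q * se, self.coefficients + q * se])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species if self.species is not None else range(self.n),
            "fitted": self.fitted,
            "residual": self.residuals,
        })


def fit_pgls(y: np.ndarray, X: np.ndarray, C: np.ndarray,
             species: list[str] | None = None, reml: bool = False) -> PGLSFit:
    """GLS fit of ``y`` on ``X`` with error covariance ``σ² C``.

    ``X`` should include an intercept column (a 1-D X is promoted to
    ``[1, x]``). σ² is the ML estimator ``r'C⁻¹r / n`` by default
    (``reml=True`` divides by n − p instead and adjusts the likelihood).
    With ``C = I`` the estimates reduce to OLS.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = np.column_stack([np.ones_like(X), X])
    n, p = X.shape
    if y.size != n or C.shape != (n, n):
        raise ValueError("y, X and C dimensions disagree")

    try:
        L = np.linalg.cholesky(C)
        yw = np.linalg.solve(L, y)
        Xw = np.linalg.solve(L, X)
        logdetC = 2.0 * np.log(np.diag(L)).sum()
    except np.linalg.LinAlgError:
        # numerically singular C (e.g. effectively identical tips):
        # whiten with a clipped eigendecomposition pseudo-inverse
        import warnings

        warnings.warn("C is numerically singular; using pseudo-inverse whitening",
                      stacklevel=2)
        w, V = np.linalg.eigh(C)
        tol = w.max() * n * np.finfo(float).eps
        keep = w > tol
        # project onto the non-degenerate subspace (pseudo-inverse semantics)
        W = np.diag(1.0 / np.sqrt(w[keep])) @ V[:, keep].T
        yw = W @ y
        Xw = W @ X
        logdetC = float(np.log(w[keep]).sum())
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("X'C^-1X is singular")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = y - X @ beta
    rw = yw - Xw @ beta
    rss = float(rw @ rw)

    if reml:
        sigma2 = rss / (n - p)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logdetC
                     + np.log(np.linalg.det(XtX)) + (n - p))
    else:
        sigma2 = rss / n
        if sigma2 > 0:
            ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetC + n)
        else:  # perfect fit: likelihood unbounded; report +inf
            ll = np.inf
    s2 = rss / (n - p) if n > p else np.nan
    cov_beta = s2 * np.linalg.inv(XtX)
    return PGLSFit(beta, float(sigma2), float(ll), resid, X @ beta, cov_beta,
                   np.asarray(C, dtype=float), n, species)


def nagelkerke_r2(fit: PGLSFit, null_fit: PGLSFit) -> float:
    """Likelihood-based Nagelkerke (Cragg–Uhler) pseudo-R².

    ``R² = [1 − (L₀/L₁)^(2/n)] / [1 − L₀^(2/n)]`` with L₀ the
    intercept-only likelihood. Requires the null to be nested in (and no
    better than) the full fit on the same data.
    """
    if null_fit.n != fit.n:
        raise ValueError("fits are on different data")
    if fit.log_likelihood < null_fit.log_likelihood - 1e-9:
        raise ValueError("full fit has lower likelihood than null — misordered fits?")
    n = fit.n
    if np.isinf(fit.log_likelihood):
        return 1.0
    num = 1.0 - np.exp(2.0 / n * (null_fit.log_likelihood - fit.log_likelihood))
    den = 1.0 - np.exp(2.0 / n * null_fit.log_likelihood)
    # with continuous data the null density can exceed 1 and push the raw
    # ratio slightly outside [0, 1]; clamp to the index's range
    return float(min(max(num / den, 0.0), 1.0))


def log_ratio(count_a: np.ndarray, count_b: np.ndarray,
              pseudocount: float = 0.0) -> np.ndarray:
    """Per-species ``ln((a + pseudocount) / (b + pseudocount))``.

    Used for family-size contrasts such as ln(#MHC-I / #MHC-II). With
    pseudocount 0 any species with a zero count in either family is an
    error rather than a silent ±inf.
    """
    a = np.asarray(count_a, dtype=float) + pseudocount
    b = np.asarray(count_b, dtype=float) + pseudocount
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if np.any(a == 0) or np.any(b == 0):
        raise ValueError("zero count with zero pseudocount — ratio undefined")
    return np.log(a / b)
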