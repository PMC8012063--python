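"""Signed co-expression network connectivity between gene sets.

Pipeline: robust pairwise correlation (biweight midcorrelation with
outlier-quantile capping) -> signed adjacency a_ij = ((1 + cor_ij)/2)^beta
-> topological overlap matrix (TOM) -> connectivity between two gene
sets X and Y defined on their non-shared members,

    k_{X,Y} = sum_{x in X\\Y} sum_{y in Y\\X} tom_{x,y},

tested one-sided (right tail) against an empirical null of random
index-set pairs of matched sizes drawn without replacement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from xte._resampling import sample_index_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "TOMatrix",
    "ConnectivityResult",
    "bicor_matrix",
    "signed_tom",
    "set_connectivity",
    "connectivity_p",
    "scale_free_fit",
]


@dataclass
class TOMatrix:
    """Symmetric gene x gene topological overlap values in [0, 1]."""

    genes: list[str]
    tom: np.ndarray
    beta: float
    correlation_type: str = "bicor"
    max_p_outliers: float = 0.1

    def __post_init__(self) -> None:
        self.tom = np.asarray(self.tom, dtype=float)
        n = len(self.genes)
        if self.tom.shape != (n, n):
            raise ValueError("TOM shape does not match the gene list")
        if not np.allclose(self.tom, self.tom.T, atol=1e-10):
            raise ValueError("TOM must be symmetric")
        if np.any(self.tom < -1e-12) or np.any(self.tom > 1 + 1e-12):
            raise ValueError("TOM values must lie in [0, 1]")

    def index_of(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        known = [g for g in genes if g in pos]
        unknown = sorted(set(genes) - set(known))
        if unknown:
            logger.warning("dropping %d gene(s) not in the TOM: %s", len(unknown), unknown)
        return np.array(sorted(pos[g] for g in known), dtype=int)


@dataclass
class ConnectivityResult:
    """Connectivity between two gene sets with a one-sided empirical p."""

    set_x: str
    set_y: str
    k_xy: float
    one_sided_p: float
    n_draws: int
    size_x_only: int
    size_y_only: int


def bicor_matrix(expr, max_p_outliers: float = 0.1) -> np.ndarray:
    """Pairwise biweight midcorrelation of rows (genes) across columns.

    Each gene is centered at its median and weighted with Tukey
    biweights u = (x - med) / (9 * MAD); observations with |u| >= 1 get
    weight 0.  `max_p_outliers` caps how much of each tail may be
    zero-weighted: per gene and side, u is rescaled so the value at the
    max_p_outliers (resp. 1 - max_p_outliers) quantile sits exactly at
    |u| = 1 whenever it would exceed it.  Genes with zero MAD fall back
    to Pearson standardization for that gene (with a warning); genes
    that are constant outright get correlation 0.
    """
    X = np.asarray(expr, dtype=float)
    if X.ndim != 2:
        raise ValueError("expression matrix must be 2-D (genes x samples)")
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError("at least 3 samples are required")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix must be finite")
    if not (0 <= max_p_outliers <= 1):
        raise ValueError("max_p_outliers must lie in [0, 1]")

    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    u[zero_mad] = 0.0

    if max_p_outliers < 0.5:
        qlo = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
        qhi = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
        neg_scale = np.where(qlo < -1.0, -qlo, 1.0)
        pos_scale = np.where(qhi > 1.0, qhi, 1.0)
        u = np.where(u < 0, u / neg_scale, u / pos_scale)

    wgt = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    centered = (X - med) * wgt

    if zero_mad.any():
        warnings.warn(
            f"{int(zero_mad.sum())} gene(s) with zero MAD fell back to Pearson",
            RuntimeWarning,
            stacklevel=2,
        )
        means = X[zero_mad].mean(axis=1, keepdims=True)
        centered[zero_mad] = X[zero_mad] - means

    norms = np.sqrt(np.sum(np.square(centered), axis=1))
    degenerate = norms == 0
    if degenerate.any():
        logger.warning("%d fully degenerate (constant) gene(s); correlations set to 0",
                       int(degenerate.sum()))
        norms[degenerate] = 1.0

    unit = centered / norms[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def signed_tom(corr, beta: float = 26.0, genes=None) -> TOMatrix:
    """Signed topological overlap matrix from a correlation matrix.

    Adjacency a_ij = ((1 + cor_ij) / 2)^beta with a_ii excluded from all
    internal sums; tom_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij) with k_i = sum_u a_iu; the diagonal is
    reported as 1.  The default beta = 26 matches a soft threshold
    chosen by scale-free-fit diagnostics at full study scale; see
    :func:`scale_free_fit`.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(C < -1 - 1e-9) or np.any(C > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    n = C.shape[0]
    if genes is None:
        genes = [f"G{i}" for i in range(n)]

    A = np.power((1.0 + np.clip(C, -1.0, 1.0)) / 2.0, beta)
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    numer = A @ A + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMatrix(genes=list(genes), tom=tom, beta=float(beta))


def scale_free_fit(corr, betas=(2, 6, 10, 14, 18, 22, 26, 30)) -> list[dict]:
    """Diagnostic scale-free-topology fit R^2 and mean connectivity per beta.

    Reported for soft-threshold inspection only; beta is never
    auto-chosen.
    """
    C = np.asarray(corr, dtype=float)
    out = []
    for beta in betas:
        A = np.power((1.0 + np.clip(C, -1.0, 1.0)) / 2.0, float(beta))
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        mean_k = float(k.mean())
        pos = k[k > 0]
        if pos.size < 10:
            out.append({"beta": float(beta), "r_squared": float("nan"),
                        "mean_connectivity": mean_k})
            continue
        n_bins = min(10, max(3, pos.size // 5))
        hist, edges = np.histogram(pos, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        logk = np.log10(centers[keep])
        logp = np.log10(hist[keep] / hist.sum())
        if keep.sum() < 3:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(logk, logp)[0, 1] ** 2)
        out.append({"beta": float(beta), "r_squared": r2, "mean_connectivity": mean_k})
    return out


def _restricted_indices(idx_x: np.ndarray, idx_y: np.ndarray):
    shared = np.intersect1d(idx_x, idx_y)
    x_only = np.setdiff1d(idx_x, shared)
    y_only = np.setdiff1d(idx_y, shared)
    return x_only, y_only


def set_connectivity(tom: TOMatrix, set_x, set_y) -> float:
    """k_{X,Y}: sum of TOM entries between the non-shared members.

    Returns 0 when one residual side is empty by containment; NaN
    (flagged in the log) when both residual sides are empty.
    """
    idx_x = set_x if isinstance(set_x, np.ndarray) else tom.index_of(set_x)
    idx_y = set_y if isinstance(set_y, np.ndarray) else tom.index_of(set_y)
    x_only, y_only = _restricted_indices(idx_x, idx_y)
    if x_only.size == 0 and y_only.size == 0:
        logger.warning("set_connectivity: both residual sets empty; undefined")
        return float("nan")
    if x_only.size == 0 or y_only.size == 0:
        return 0.0
    return float(tom.tom[np.ix_(x_only, y_only)].sum())


def connectivity_p(
    tom: TOMatrix,
    set_x,
    set_y,
    n_draws: int = 10000,
    seed=None,
    name_x: str = "X",
    name_y: str = "Y",
) -> ConnectivityResult:
    """One-sided (right tail) empirical p for the connectivity of X and Y.

    The null draws `n_draws` pairs of index sets of sizes |X| and |Y|,
    each without replacement from all TOM indices; the two drawn sets
    may intersect each other, and the X\\Y / Y\\X restriction is then
    applied exactly as for the observed pair.  p_hat = (r+1)/(N+1) with
    r = #{null k >= observed k}.
    """
    idx_x = tom.index_of(set_x)
    idx_y = tom.index_of(set_y)
    n = len(tom.genes)
    if idx_x.size > n or idx_y.size > n:
        raise ValueError("set sizes exceed the gene count")
    if idx_x.size == 0 or idx_y.size == 0:
        raise ValueError("both sets must map at least one gene into the TOM")
    observed = set_connectivity(tom, idx_x, idx_y)
    x_only, y_only = _restricted_indices(idx_x, idx_y)

    rng = np.random.default_rng(seed)
    draws_x = sample_index_matrix(rng, n, idx_x.size, n_draws)
    draws_y = sample_index_matrix(rng, n, idx_y.size, n_draws)
    M = tom.tom
    r = 0
    for j in range(n_draws):
        xo, yo = _restricted_indices(draws_x[j], draws_y[j])
        if xo.size == 0 or yo.size == 0:
            k_null = 0.0
        else:
            k_null = M[np.ix_(xo, yo)].sum()
        if k_null >= observed:
            r += 1
    return ConnectivityResult(
        set_x=name_x,
        set_y=name_y,
        k_xy=observed,
        one_sided_p=(r + 1) / (n_draws + 1),
        n_draws=n_draws,
        size_x_only=int(x_only.size),
        size_y_only=int(y_only.size),
    )
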