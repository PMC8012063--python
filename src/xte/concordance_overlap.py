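"""Downstream comparative statistics.

Set-overlap tests (two-sided Fisher exact on a 2x2 table against a
stated gene universe), cross-study direction concordance (exact
two-sided binomial tests against 0.5, per stratum and pooled), and
weighted Pearson correlation of fold-changes with an
effective-sample-size t approximation for the p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from xte.core_model import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapTest",
    "ConcordanceResult",
    "overlap_test",
    "overlap_test_batch",
    "direction_concordance",
    "weighted_correlation",
]


@dataclass
class OverlapTest:
    """Fisher exact test of the overlap of two gene sets in a universe."""

    size_a: int
    size_b: int
    universe_size: int
    overlap: int
    odds_ratio: float
    haldane_corrected: bool
    p: float
    fdr: float = float("nan")


@dataclass
class ConcordanceResult:
    """Direction agreement between two DEG tables in one stratum."""

    stratum: str
    n_same: int
    n_opposite: int
    fraction_same: float
    p: float
    n_excluded_zero: int = 0


def overlap_test(set_a, set_b, universe) -> OverlapTest:
    """Two-sided Fisher exact test on the 2x2 overlap table.

    Both sets must be contained in the universe.  The odds ratio is the
    sample (unconditional) odds ratio, with a Haldane 0.5 correction
    applied and flagged when any cell is zero.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = sorted((a | b) - u)
    if stray:
        raise ValueError(f"sets contain genes outside the universe: {stray}")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(u) - n11 - n12 - n21
    table = np.array([[n11, n12], [n21, n22]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    haldane = bool((table == 0).any())
    t = table + 0.5 if haldane else table.astype(float)
    odds = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    return OverlapTest(
        size_a=len(a), size_b=len(b), universe_size=len(u), overlap=n11,
        odds_ratio=odds, haldane_corrected=haldane, p=p,
    )


def overlap_test_batch(pairs, universe) -> list[OverlapTest]:
    """Run overlap tests for (set_a, set_b) pairs and fill joint BH-FDR."""
    results = [overlap_test(a, b, universe) for a, b in pairs]
    if results:
        qvals = bh_fdr([r.p for r in results])
        for res, q in zip(results, qvals):
            res.fdr = float(q)
    return results


def _signs(table: pd.DataFrame) -> pd.Series:
    if "sign" in table.columns:
        s = np.sign(pd.to_numeric(table["sign"]))
    elif "log2fc" in table.columns:
        s = np.sign(pd.to_numeric(table["log2fc"]))
    else:
        raise ValueError("table needs a 'sign' or 'log2fc' column")
    return pd.Series(s.to_numpy(), index=table["gene"].to_numpy())


def direction_concordance(
    deg_table: pd.DataFrame,
    reference_table: pd.DataFrame,
    strata: pd.Series | None = None,
) -> list[ConcordanceResult]:
    """Direction agreement of shared genes, per stratum plus pooled.

    Both tables need columns `gene` and either `sign` or `log2fc`; an
    optional `stratum` column (or the `strata` argument aligned with
    `deg_table`) splits the comparison, e.g. by tissue.  Genes with a
    zero fold-change in either table are excluded and counted.  Each
    stratum and the pooled counts get an exact two-sided binomial test
    with success probability 0.5.
    """
    deg = deg_table.copy()
    if strata is not None:
        deg["stratum"] = np.asarray(strata)
    if "stratum" not in deg.columns:
        deg["stratum"] = "all"
    ref_signs = _signs(reference_table)
    if "stratum" in reference_table.columns:
        ref_by_stratum = {
            s: _signs(sub) for s, sub in reference_table.groupby("stratum")
        }
    else:
        ref_by_stratum = None

    results: list[ConcordanceResult] = []
    pooled_same = pooled_opp = pooled_zero = 0
    any_shared = False
    for stratum, sub in deg.groupby("stratum", sort=True):
        d = _signs(sub)
        ref = ref_by_stratum.get(stratum, ref_signs) if ref_by_stratum else ref_signs
        shared = d.index.intersection(ref.index)
        if len(shared) == 0:
            logger.warning("direction_concordance: no shared genes in stratum %r", stratum)
            continue
        any_shared = True
        ds, rs = d.loc[shared], ref.loc[shared]
        zero = (ds == 0) | (rs == 0)
        n_zero = int(zero.sum())
        ds, rs = ds[~zero], rs[~zero]
        same = int((ds == rs).sum())
        opp = int(len(ds) - same)
        total = same + opp
        p = float(stats.binomtest(same, total, 0.5).pvalue) if total else float("nan")
        results.append(ConcordanceResult(
            stratum=str(stratum), n_same=same, n_opposite=opp,
            fraction_same=same / total if total else float("nan"),
            p=p, n_excluded_zero=n_zero,
        ))
        pooled_same += same
        pooled_opp += opp
        pooled_zero += n_zero
    if not any_shared:
        raise ValueError("no shared genes between the two tables")
    pooled_total = pooled_same + pooled_opp
    results.append(ConcordanceResult(
        stratum="pooled", n_same=pooled_same, n_opposite=pooled_opp,
        fraction_same=pooled_same / pooled_total if pooled_total else float("nan"),
        p=float(stats.binomtest(pooled_same, pooled_total, 0.5).pvalue) if pooled_total else float("nan"),
        n_excluded_zero=pooled_zero,
    ))
    return results


def weighted_correlation(x, y, weights) -> tuple[float, float]:
    """Weighted Pearson correlation with an effective-sample-size p-value.

    R uses weighted means/variances.  The p-value comes from the usual
    t approximation with the effective sample size
    n_eff = (sum w)^2 / sum w^2 (documented choice).  Zero-weight
    points are dropped; fewer than 3 nonzero-weight points is
    undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != y.shape or x.shape != w.shape:
        raise ValueError("x, y and weights must be aligned")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(w)):
        raise ValueError("inputs must be finite")
    keep = w > 0
    x, y, w = x[keep], y[keep], w[keep]
    if x.size < 3:
        logger.warning("weighted_correlation: fewer than 3 nonzero-weight points")
        return float("nan"), float("nan")
    wsum = w.sum()
    mx = np.sum(w * x) / wsum
    my = np.sum(w * y) / wsum
    cov = np.sum(w * (x - mx) * (y - my)) / wsum
    vx = np.sum(w * np.square(x - mx)) / wsum
    vy = np.sum(w * np.square(y - my)) / wsum
    if vx == 0 or vy == 0:
        return float("nan"), float("nan")
    r = float(cov / np.sqrt(vx * vy))
    r = float(np.clip(r, -1.0, 1.0))
    n_eff = wsum**2 / np.sum(np.square(w))
    df = n_eff - 2
    if df <= 0:
        return r, float("nan")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p
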