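"""Differential expression and gene-set over-representation.

Per-gene two-sided Wilcoxon rank-sum (Mann-Whitney) tests with
Benjamini-Hochberg correction, plus hypergeometric over-representation
of gene sets among the significant genes, summarised — as pathway plots
in this field usually are — by the *fraction of the affected genes* that
fall in each set.

The Wilcoxon p-value is exact (full enumeration of rank splits) for
small tie-free samples (combined n <= 20) and a tie- and
continuity-corrected normal approximation otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import FormatError
from .io_qc import NormalizedMatrix

__all__ = ["wilcoxon_test", "bh_adjust", "de_compare", "ora", "ORAResult"]

# below this combined sample size, tie-free data gets the exact test
EXACT_CUTOFF = 20
# genes expressed in fewer than this fraction of cells in BOTH groups are
# excluded before testing
MIN_EXPR_FRACTION = 0.05


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U of x, p).

    Exact by full enumeration of the C(n+m, n) equally likely rank
    assignments when n + m <= 20 and the pooled data are tie-free;
    otherwise the normal approximation with tie correction and
    continuity correction. Ties in the small-sample regime also fall
    back to the approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size + y.size <= EXACT_CUTOFF and not _has_ties(x, y):
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_compare(n: NormalizedMatrix, group_a, group_b,
               padj_threshold: float = 0.05) -> pd.DataFrame:
    """Gene-wise Wilcoxon + BH differential expression A vs B.

    ``group_a``/``group_b`` are disjoint cell-id collections, each with
    at least two cells. Genes expressed (count > 0) in fewer than 5% of
    cells in *both* groups are excluded before testing; they appear in
    the output with ``tested = False`` and NaN statistics, so the
    exclusion is recorded rather than silent.

    Returns one row per gene: ``lfc`` (log2 ratio of expm1-backtransformed
    group means, pseudocount 1), ``p``, ``padj`` (BH across tested
    genes), ``frac_a``/``frac_b`` (fraction of expressing cells),
    ``significant`` (padj < threshold).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise FormatError("groups overlap: "
                          f"{sorted(set(group_a) & set(group_b))[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 cells")
    ia = n.cell_index(group_a)
    ib = n.cell_index(group_b)
    va = n.values[:, ia].toarray()
    vb = n.values[:, ib].toarray()

    frac_a = (va > 0).mean(axis=1)
    frac_b = (vb > 0).mean(axis=1)
    tested = (frac_a >= MIN_EXPR_FRACTION) | (frac_b >= MIN_EXPR_FRACTION)

    mean_a = np.expm1(va).mean(axis=1)
    mean_b = np.expm1(vb).mean(axis=1)
    lfc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)

    pvals = np.full(n.shape[0], np.nan)
    for gi in np.flatnonzero(tested):
        _, pvals[gi] = wilcoxon_test(va[gi], vb[gi])
    padj = np.full(n.shape[0], np.nan)
    padj[tested] = bh_adjust(pvals[tested])

    out = pd.DataFrame({
        "gene": n.gene_ids,
        "lfc": lfc,
        "p": pvals,
        "padj": padj,
        "frac_a": frac_a,
        "frac_b": frac_b,
        "tested": tested,
        "significant": (padj < padj_threshold) & tested,
    })
    out.attrs["n_a"] = len(group_a)
    out.attrs["n_b"] = len(group_b)
    out.attrs["padj_threshold"] = padj_threshold
    return out


@dataclass(frozen=True)
class ORAResult:
    """Over-representation of one gene set among the selected genes."""

    name: str
    overlap: int
    set_size: int
    selected_size: int
    universe_size: int
    p: float
    padj: float            # NaN until adjusted across sets
    fraction: float        # overlap / selected: share of affected genes


def ora(selected, pathway, universe, name: str = "") -> ORAResult:
    """Hypergeometric over-representation test of one gene set.

    p = P(X >= overlap) with population = |universe|, successes =
    |pathway|, draws = |selected|. ``fraction`` is overlap/|selected| —
    the share of the affected genes that belong to the set.
    """
    selected, pathway, universe = set(selected), set(pathway), set(universe)
    if not selected <= universe:
        raise FormatError(
            f"selected genes outside universe: "
            f"{sorted(selected - universe)[:5]}")
    if not pathway <= universe:
        raise FormatError(
            f"pathway genes outside universe: "
            f"{sorted(pathway - universe)[:5]}")
    k = len(selected & pathway)
    N, K, n_draw = len(universe), len(pathway), len(selected)
    p = float(hypergeom.sf(k - 1, N, K, n_draw))  # P(X >= k)
    frac = k / n_draw if n_draw else 0.0
    return ORAResult(name=name, overlap=k, set_size=K,
                     selected_size=n_draw, universe_size=N,
                     p=min(p, 1.0), padj=float("nan"), fraction=frac)


def ora_table(selected, pathways: dict, universe) -> pd.DataFrame:
    """Run :func:`ora` over named gene sets and BH-adjust across sets."""
    rows = [ora(selected, genes, universe, name)
            for name, genes in pathways.items()]
    padj = bh_adjust([r.p for r in rows]) if rows else []
    return pd.DataFrame([{
        "set": r.name, "overlap": r.overlap, "set_size": r.set_size,
        "selected_size": r.selected_size, "universe_size": r.universe_size,
        "fraction": r.fraction, "p": r.p, "padj": adj,
    } for r, adj in zip(rows, padj)])
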