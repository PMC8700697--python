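"""Rank-rank hypergeometric overlap (RRHO) between two DE signatures.

Both gene lists are ranked by a signed significance metric
(-log10 p x sign of fold change, most-up-regulated first). For every
pair of rank thresholds (i*step, j*step) the overlap between the two
top-lists is scored with an exact hypergeometric upper tail; the grid of
p-values is corrected for multiple testing (BH by default) and reported
as signed -log10 adjusted p — positive where the overlap exceeds its
expectation under independence, negative where it falls short. A strong
diagonal signal means the two signatures agree along their length.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata

from .errors import FormatError
from .stats import bh_adjust

__all__ = ["hypergeom_tail", "rank_profile", "rrho_map", "RRHOMap"]

P_FLOOR = 1e-300  # keeps -log10 finite for numerically-zero p-values


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeom(N, K, n).

    Summed in log space (log-gamma terms + logsumexp) so deep tails do
    not underflow before the final exponentiation.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent parameters N={N}, K={K}, n={n}, k={k}")
    if n < K:  # tail is symmetric in (K, n); canonical order keeps the
        K, n = n, K  # float summation bit-identical under swaps
    if k <= max(0, n + K - N):
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    kk = np.arange(k, hi + 1)
    logpmf = (gammaln(K + 1) - gammaln(kk + 1) - gammaln(K - kk + 1)
              + gammaln(N - K + 1) - gammaln(n - kk + 1)
              - gammaln(N - K - n + kk + 1)
              + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1))
    m = logpmf.max()
    return float(min(1.0, np.exp(m + np.log(np.exp(logpmf - m).sum()))))


def rank_profile(de: pd.DataFrame, p_col: str = "p", lfc_col: str = "lfc"
                 ) -> pd.DataFrame:
    """Build a signed ranked profile from a DE table.

    metric = -log10(max(p, 1e-300)) * sign(lfc); rank 1 is the most
    up-regulated gene. Ties are broken by gene id so the ranking is
    deterministic. Untested genes (NaN p) count as p = 1.
    """
    if de["gene"].duplicated().any():
        dup = de["gene"][de["gene"].duplicated()].tolist()
        raise FormatError(f"duplicated genes in DE table: {dup[:5]}")
    p = de[p_col].to_numpy(dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    lfc = de[lfc_col].to_numpy(dtype=float)
    metric = -np.log10(np.maximum(p, P_FLOOR)) * np.sign(lfc)
    out = pd.DataFrame({"gene": de["gene"].to_numpy(), "metric": metric})
    out = out.sort_values(["metric", "gene"],
                          ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


@dataclass
class RRHOMap:
    """Signed -log10 adjusted-p grid over rank-threshold pairs.

    Entry [i, j] corresponds to thresholds ((i+1)*step, (j+1)*step) into
    profiles a (rows) and b (columns).
    """

    values: np.ndarray
    thresholds: np.ndarray
    step: int
    correction: str
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.thresholds, name="threshold_a"),
            columns=pd.Index(self.thresholds, name="threshold_b"))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# step={self.step} correction={self.correction} "
                     f"n_genes={self.n_genes} "
                     f"metric=-log10(p)*sign(lfc)\n")
            self.to_frame().to_csv(fh, sep="\t")


def rrho_map(a: pd.DataFrame, b: pd.DataFrame, step: int | None = None,
             correction: str = "bh") -> RRHOMap:
    """Compute the RRHO grid between two ranked profiles.

    ``a`` and ``b`` must rank the identical gene universe. ``step``
    defaults to N // 50 (minimum 1). At each grid point the top-i list
    of ``a`` is intersected with the top-j list of ``b``; signs follow
    the overlap's deviation from its expectation i*j/N.
    """
    ga, gb = set(a["gene"]), set(b["gene"])
    if ga != gb:
        raise FormatError(
            f"gene universes differ (symmetric difference "
            f"{len(ga ^ gb)} genes)")
    N = len(ga)
    if step is None:
        step = max(1, N // 50)
    if step < 1:
        raise ValueError("step must be >= 1")
    if correction not in ("bh", "none"):
        raise ValueError("correction must be 'bh' or 'none'")

    rank_a = a.set_index("gene")["rank"]
    rank_b = b.set_index("gene")["rank"].reindex(rank_a.index)
    ra = rank_a.to_numpy()
    rb = rank_b.to_numpy()

    thresholds = np.arange(step, N + 1, step)
    T = len(thresholds)
    # overlap[i, j] = #genes with rank_a <= thresholds[i] and
    # rank_b <= thresholds[j]; cumulative 2-D histogram over rank bins.
    bins_a = np.minimum((ra - 1) // step, T - 1)
    bins_b = np.minimum((rb - 1) // step, T - 1)
    joint = np.zeros((T, T))
    # genes with rank > thresholds[-1] never enter any top-list
    in_a = ra <= thresholds[-1]
    in_b = rb <= thresholds[-1]
    use = in_a & in_b
    np.add.at(joint, (bins_a[use], bins_b[use]), 1.0)
    overlap = joint.cumsum(axis=0).cumsum(axis=1)

    pvals = np.empty((T, T))
    for i, ti in enumerate(thresholds):
        for j, tj in enumerate(thresholds):
            pvals[i, j] = hypergeom_tail(N, int(ti), int(tj),
                                         int(overlap[i, j]))
    if correction == "bh":
        padj = bh_adjust(pvals.ravel()).reshape(pvals.shape)
    else:
        padj = pvals
    expect = thresholds[:, None] * thresholds[None, :] / N
    sign = np.where(overlap > expect, 1.0, -1.0)
    values = sign * (-np.log10(np.maximum(padj, P_FLOOR)))
    return RRHOMap(values=values, thresholds=thresholds, step=step,
                   correction=correction, n_genes=N)
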