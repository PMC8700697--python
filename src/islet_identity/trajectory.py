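"""Expression summaries along the pseudo-temporal ordering.

Moving averages over windows of *cells* (not score intervals, so sparse
stretches of the score axis never yield empty windows): window j covers
ordered cells [j*k, j*k + w). A trailing partial window is kept when it
holds at least w/2 cells, otherwise it is merged into the previous
window. Each window is summarised by its mean calibrated score (the
window "center") and per-gene mean log-normalized expression.

``scale_genewise`` z-scores each gene across windows (the heatmap-style
"scaled expression" view); ``peak_position`` reads off where along the
score axis a gene's profile peaks, which is how the relative timing of
the three UPR arms is quantified.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_qc import NormalizedMatrix

__all__ = ["TrajectoryProfile", "ScaledProfile", "moving_average",
           "scale_genewise", "peak_position"]

log = logging.getLogger(__name__)


@dataclass
class TrajectoryProfile:
    """Windowed expression along the ordering: one row per window."""

    window_centers: np.ndarray          # mean calibrated score per window
    means: pd.DataFrame                 # windows x genes
    window: int
    stride: int

    @property
    def genes(self) -> list[str]:
        return list(self.means.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.means.copy()
        out.insert(0, "window_center", self.window_centers)
        return out


@dataclass
class ScaledProfile:
    """Gene-wise z-scored trajectory (constant genes map to all-zero)."""

    window_centers: np.ndarray
    values: pd.DataFrame                # windows x genes, z-scored per gene
    arms: dict[str, list[str]]

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "window_center", self.window_centers)
        return out


def _window_slices(n_cells: int, w: int, k: int) -> list[slice]:
    """Cell-index slices for each window, applying the partial-window
    rule: a trailing window with < w/2 cells is merged into the previous
    one."""
    slices = []
    start = 0
    while start < n_cells:
        end = min(start + w, n_cells)
        slices.append(slice(start, end))
        if end == n_cells:
            break
        start += k
    if len(slices) > 1:
        last = slices[-1]
        if (last.stop - last.start) < w / 2.0:
            prev = slices[-2]
            slices[-2] = slice(prev.start, last.stop)
            slices.pop()
    return slices


def moving_average(ordered: pd.DataFrame, n: NormalizedMatrix,
                   genes: Sequence[str], w: int = 31, k: int = 10
                   ) -> TrajectoryProfile:
    """Per-gene moving averages across the pseudo-temporal ordering.

    Parameters
    ----------
    ordered
        Identity table with ``cell_id``, ``calibrated_score`` and
        ``pseudo_rank`` columns (from :func:`identity.order_cells`).
    n
        Log-normalized expression matrix containing the ordered cells.
    genes
        Genes to profile (all must be present in the matrix).
    w, k
        Window size and stride in cells. w=31, k=10 by default: an odd
        window (defined center cell) with ~3x overlap for smoothness.
    """
    if w < 1 or k < 1:
        raise ValueError("window and stride must be >= 1")
    n_cells = len(ordered)
    if w > n_cells:
        raise ValueError(f"window {w} exceeds number of cells {n_cells}")
    by_rank = ordered.sort_values("pseudo_rank")
    cell_idx = n.cell_index(by_rank["cell_id"].tolist())
    gene_idx = n.gene_index(list(genes))
    expr = n.values[gene_idx][:, cell_idx].toarray()       # genes x cells
    scores = by_rank["calibrated_score"].to_numpy(dtype=float)

    slices = _window_slices(n_cells, w, k)
    centers = np.array([scores[sl].mean() for sl in slices])
    means = np.stack([expr[:, sl].mean(axis=1) for sl in slices])
    return TrajectoryProfile(
        window_centers=centers,
        means=pd.DataFrame(means, columns=list(genes)),
        window=w, stride=k)


def scale_genewise(p: TrajectoryProfile,
                   arms: dict[str, Sequence[str]] | None = None
                   ) -> ScaledProfile:
    """Z-score each gene's window means (mean 0, sd 1 across windows).

    Genes constant across windows have no scale; they map to all-zero
    rows with a logged note. Requires at least two windows.
    """
    vals = p.means.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("need >= 2 windows to scale gene-wise")
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        log.info("constant across windows, scaled to zero: %s",
                 [g for g, f in zip(p.means.columns, flat) if f])
    z = np.zeros_like(vals)
    nz = ~flat
    z[:, nz] = (vals[:, nz] - mu[nz]) / sd[nz]
    return ScaledProfile(
        window_centers=p.window_centers.copy(),
        values=pd.DataFrame(z, columns=p.means.columns),
        arms={k: list(v) for k, v in (arms or {}).items()})


def peak_position(p: TrajectoryProfile, gene: str) -> float:
    """Calibrated score at which a gene's windowed mean peaks.

    Ties take the earliest (smallest-center) window, so a flat profile
    reports the start of the axis.
    """
    if gene not in p.means.columns:
        raise KeyError(f"gene {gene!r} not in profile")
    series = p.means[gene].to_numpy(dtype=float)
    order = np.argsort(p.window_centers, kind="stable")
    centers = p.window_centers[order]
    series = series[order]
    return float(centers[int(np.argmax(series))])
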