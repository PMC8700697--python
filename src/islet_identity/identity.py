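"""The alpha/beta cell-identity score.

The core quantity of the pipeline: a per-cell scalar that places each
cell on the beta-to-alpha axis.

1. ``raw_identity``: r = alpha_score / (alpha_score + beta_score), the
   alpha share of total signature signal — bounded in [0, 1], 0 for pure
   beta signal, 1 for pure alpha, and invariant to joint rescaling of the
   two scores.
2. ``calibrate``: an affine rescaling anchored on the *medians* of two
   reference populations (canonical beta and canonical alpha cells from
   intact islets), so that the calibrated score s is 0 at the beta
   reference median and 1 at the alpha reference median. Medians keep the
   anchors robust to skewed reference peaks; traced cells never
   calibrate themselves.
3. ``classify``: population mean/sd bands. A cell is an *intermediate*
   when its calibrated score lies above the beta band (mu_b + 2 sigma_b)
   and below the alpha band (mu_a - 2 sigma_a); boundary values belong
   to the canonical classes.
4. ``order_cells``: pseudo-temporal ordering = ascending calibrated
   score, ties broken by cell id. Rank is a surrogate for conversion
   progress, not physical time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (DegenerateCalibrationError, OverlappingBandsError,
                     UndefinedScoreError)

__all__ = ["PopStats", "raw_identity", "calibrate", "pop_stats",
           "classify", "order_cells", "identity_table"]

CLASS_BETA = "nonconverted_beta"
CLASS_INTERMEDIATE = "intermediate"
CLASS_ALPHA = "converted_alpha"


@dataclass(frozen=True)
class PopStats:
    """Mean/sd of calibrated scores in one reference population."""

    label: str
    n: int
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def raw_identity(alpha_score, beta_score):
    """Raw identity ratio r = alpha / (alpha + beta), elementwise.

    Both inputs must be non-negative; a cell with zero signal in both
    signatures has no defined ratio and raises
    :class:`UndefinedScoreError` (callers should exclude and report such
    cells rather than impute them).
    """
    a = np.asarray(alpha_score, dtype=float)
    b = np.asarray(beta_score, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("signature scores must be non-negative")
    tot = a + b
    if (tot == 0).any():
        n_bad = int((tot == 0).sum()) if tot.ndim else 1
        raise UndefinedScoreError(
            f"{n_bad} cell(s) with zero signal in both signatures")
    r = a / tot
    return float(r) if r.ndim == 0 else r


def calibrate(r_all, r_beta_ref, r_alpha_ref):
    """Median-anchored affine calibration of raw identity scores.

    s = (r - m_beta) / (m_alpha - m_beta) where m_* are the medians of
    the raw scores over the two reference populations. By construction
    the beta reference median maps to 0 and the alpha reference median
    to 1; individual cells may fall outside [0, 1].
    """
    r_beta_ref = np.asarray(r_beta_ref, dtype=float)
    r_alpha_ref = np.asarray(r_alpha_ref, dtype=float)
    if r_beta_ref.size == 0 or r_alpha_ref.size == 0:
        raise DegenerateCalibrationError("empty calibration reference")
    m_b = float(np.median(r_beta_ref))
    m_a = float(np.median(r_alpha_ref))
    if m_a == m_b:
        raise DegenerateCalibrationError(
            f"reference medians coincide (both {m_b:.6g})")
    r = np.asarray(r_all, dtype=float)
    s = (r - m_b) / (m_a - m_b)
    return float(s) if s.ndim == 0 else s


def pop_stats(s, label: str = "") -> PopStats:
    """Sample mean and sd (n-1 denominator) of calibrated scores."""
    s = np.asarray(s, dtype=float)
    if s.size < 2:
        raise ValueError(
            f"population '{label}' needs >= 2 cells, got {s.size}")
    return PopStats(label=label, n=int(s.size), mu=float(s.mean()),
                    sigma=float(s.std(ddof=1)))


def classify(s, beta_stats: PopStats, alpha_stats: PopStats):
    """Classify calibrated scores by the mu +/- 2 sigma band rule.

    nonconverted_beta  if s <= mu_b + 2 sigma_b
    converted_alpha    if s >= mu_a - 2 sigma_a
    intermediate       otherwise.

    Boundary points go to the canonical classes. The beta upper band must
    lie strictly below the alpha lower band, otherwise the intermediate
    class is empty/ambiguous and :class:`OverlappingBandsError` is
    raised.
    """
    hi_b = beta_stats.mu + 2.0 * beta_stats.sigma
    lo_a = alpha_stats.mu - 2.0 * alpha_stats.sigma
    if not hi_b < lo_a:
        raise OverlappingBandsError(
            f"beta band (..., {hi_b:.4g}] overlaps alpha band "
            f"[{lo_a:.4g}, ...)")
    s_arr = np.asarray(s, dtype=float)
    out = np.where(s_arr <= hi_b, CLASS_BETA,
                   np.where(s_arr >= lo_a, CLASS_ALPHA, CLASS_INTERMEDIATE))
    return str(out) if s_arr.ndim == 0 else out


def order_cells(table: pd.DataFrame,
                score_col: str = "calibrated_score") -> pd.DataFrame:
    """Assign pseudo-temporal ranks: sort ascending by calibrated score,
    ties broken lexicographically by cell_id (stable and deterministic).

    Returns a copy with a ``pseudo_rank`` column (0 .. n-1) in the
    original row order.
    """
    if score_col not in table.columns or "cell_id" not in table.columns:
        raise KeyError(f"need columns cell_id and {score_col}")
    order = np.lexsort((table["cell_id"].to_numpy(),
                        table[score_col].to_numpy(dtype=float)))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(len(table))
    out = table.copy()
    out["pseudo_rank"] = ranks
    return out


def identity_table(cell_ids, alpha_scores, beta_scores,
                   beta_ref_mask, alpha_ref_mask,
                   stats_on: str = "reference") -> tuple[pd.DataFrame,
                                                         PopStats, PopStats]:
    """End-to-end identity scoring for one dataset.

    Computes raw ratios, calibrates on the reference masks, derives the
    two populations' mean/sd bands, classifies every cell and assigns
    pseudo-temporal ranks. Cells with zero signal in both signatures are
    excluded from the result (their ids appear in the table's ``attrs``
    under ``"excluded"``).
    """
    cell_ids = list(cell_ids)
    a = np.asarray(alpha_scores, dtype=float)
    b = np.asarray(beta_scores, dtype=float)
    beta_ref_mask = np.asarray(beta_ref_mask, dtype=bool)
    alpha_ref_mask = np.asarray(alpha_ref_mask, dtype=bool)

    ok = (a + b) > 0
    excluded = [cell_ids[i] for i in np.flatnonzero(~ok)]
    a, b = a[ok], b[ok]
    kept_ids = [cell_ids[i] for i in np.flatnonzero(ok)]
    beta_ref_mask = beta_ref_mask[ok]
    alpha_ref_mask = alpha_ref_mask[ok]

    r = raw_identity(a, b)
    s = calibrate(r, r[beta_ref_mask], r[alpha_ref_mask])
    b_stats = pop_stats(s[beta_ref_mask], "beta_ref")
    a_stats = pop_stats(s[alpha_ref_mask], "alpha_ref")
    labels = classify(s, b_stats, a_stats)

    table = pd.DataFrame({
        "cell_id": kept_ids,
        "raw_score": r,
        "calibrated_score": s,
        "class": labels,
    })
    table = order_cells(table)
    table.attrs["excluded"] = excluded
    return table, b_stats, a_stats
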