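"""Synthetic islet scRNA-seq generator with planted ground truth.

Emulates a dispersion/reaggregation experiment in which lineage-traced
beta cells drift toward an alpha identity. Every cell carries a latent
conversion coordinate ``t`` in [0, 1] (0 = canonical beta, 1 = canonical
alpha). Along ``t``:

* beta-signature genes decay log-linearly from their beta-state mean to
  that mean divided by ``signature_fold``; alpha-signature genes mirror
  this, rising toward their alpha-state mean;
* IRE1a- and PERK-arm UPR genes receive a transient multiplicative bump
  ``exp(A * exp(-(t - c)^2 / (2 w^2)))`` centred at arm-specific positions
  (IRE1a before PERK, with ATF3 shifted later still), truncated to exact
  baseline beyond ``|t - c| > 3w`` so cells far from the window are
  genuinely unperturbed;
* ATF6 declines linearly to ``atf6_floor`` at t=1, while its negative
  regulator WFS1 follows the mirrored rising ramp;
* housekeeping and background genes are flat.

Counts are negative binomial around ``library_factor * expected_profile``,
with log-normal per-cell library factors — the standard generative model
for overdispersed plate-based scRNA-seq counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyResultError, FormatError
from .io_qc import CountMatrix
from .panel import GenePanel, default_panel

__all__ = [
    "PopulationConfig", "expected_profile", "expected_profiles",
    "simulate_counts", "simulate_dataset", "write_truth_table",
    "population_config_from_yaml",
]

# Gaussian bump support, in units of the bump width: beyond this the
# multiplier is exactly 1, so distant cells are bit-identical to baseline.
_BUMP_SUPPORT = 3.0


@dataclass(frozen=True)
class PopulationConfig:
    """Cell-population layout of one simulated experiment.

    ``traced_mixture`` = (w_nonconv, w_conv, w_transit): fractions of
    lineage-traced cells that remain beta-like (t near 0), have fully
    converted (t near 1), or are in transit (t uniform on [0, 1]).
    ``endpoint_jitter`` is the half-normal spread of t around the
    endpoints; ``library_size_log_sd`` the sd of log library factors.
    """

    n_beta: int = 500
    n_alpha: int = 500
    n_traced: int = 2000
    traced_mixture: tuple[float, float, float] = (0.85, 0.09, 0.06)
    endpoint_jitter: float = 0.03
    library_size_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if min(self.n_beta, self.n_alpha, self.n_traced) < 0:
            raise FormatError("cell counts must be non-negative")
        w = np.asarray(self.traced_mixture, dtype=float)
        if w.shape != (3,) or (w < 0).any():
            raise FormatError("traced_mixture needs 3 non-negative weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise FormatError(
                f"traced_mixture must sum to 1 (got {w.sum():.12g})")
        if self.endpoint_jitter <= 0:
            raise FormatError("endpoint_jitter must be positive")
        if self.library_size_log_sd < 0:
            raise FormatError("library_size_log_sd must be >= 0")


def _interp_log(high: np.ndarray, low: np.ndarray, t) -> np.ndarray:
    """Log-linear interpolation high -> low as t goes 0 -> 1."""
    t = np.asarray(t, dtype=float)
    return np.exp(np.log(high) * (1.0 - t) + np.log(low) * t)


def expected_profiles(panel: GenePanel, t) -> np.ndarray:
    """Noise-free expected counts (genes x cells) at conversion stages `t`.

    Vectorised core of :func:`expected_profile`; ``t`` may be a scalar or
    a 1-D array of conversion coordinates.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if ((t < 0) | (t > 1)).any():
        raise ValueError("conversion coordinate t must lie in [0, 1]")
    mu = np.repeat(panel.base_mean[:, None], len(t), axis=1)

    fold = panel.signature_fold
    bi = panel.index_of(panel.beta_genes)
    ai = panel.index_of(panel.alpha_genes)
    mu[bi] = _interp_log(panel.base_mean[bi, None],
                         panel.base_mean[bi, None] / fold, t[None, :])
    mu[ai] = _interp_log(panel.base_mean[ai, None] / fold,
                         panel.base_mean[ai, None], t[None, :])

    w = panel.bump_width
    for g in list(panel.ire1a_genes) + list(panel.perk_genes):
        gi = panel.index_of([g])[0]
        c = panel.gene_center(g)
        d = np.abs(t - c)
        bump = np.where(d <= _BUMP_SUPPORT * w,
                        np.exp(panel.bump_amplitude
                               * np.exp(-(t - c) ** 2 / (2 * w ** 2))),
                        1.0)
        mu[gi] = mu[gi] * bump

    rising = set(panel.atf6_rising_genes)
    for g in panel.atf6_genes:
        gi = panel.index_of([g])[0]
        if g in rising:
            ramp = panel.atf6_floor + (1.0 - panel.atf6_floor) * t
        else:
            ramp = 1.0 - (1.0 - panel.atf6_floor) * t
        mu[gi] = mu[gi] * ramp
    return mu


def expected_profile(panel: GenePanel, t: float) -> np.ndarray:
    """Per-gene expected count vector at a single conversion stage t."""
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must lie in [0, 1], got {t}")
    return expected_profiles(panel, t)[:, 0]


def _draw_t(config: PopulationConfig, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (true_type, t) for every cell in config order."""
    j = config.endpoint_jitter
    types: list[str] = (["beta"] * config.n_beta
                        + ["alpha"] * config.n_alpha
                        + ["traced"] * config.n_traced)
    t = np.empty(len(types))
    nb, na, nt = config.n_beta, config.n_alpha, config.n_traced
    t[:nb] = np.clip(np.abs(rng.normal(0.0, j, nb)), 0.0, 1.0)
    t[nb:nb + na] = np.clip(1.0 - np.abs(rng.normal(0.0, j, na)), 0.0, 1.0)
    if nt:
        comp = rng.choice(3, size=nt, p=np.asarray(config.traced_mixture))
        tt = np.empty(nt)
        m0, m1, m2 = comp == 0, comp == 1, comp == 2
        tt[m0] = np.clip(np.abs(rng.normal(0.0, j, int(m0.sum()))), 0, 1)
        tt[m1] = np.clip(1 - np.abs(rng.normal(0.0, j, int(m1.sum()))), 0, 1)
        tt[m2] = rng.uniform(0.0, 1.0, int(m2.sum()))
        t[nb + na:] = tt
    return np.array(types), t


def simulate_counts(panel: GenePanel, config: PopulationConfig
                    ) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a count matrix and its ground-truth table.

    Returns
    -------
    counts : CountMatrix
        genes x cells negative binomial counts.
    truth : pandas.DataFrame
        One row per cell: ``cell_id``, ``true_type`` (beta/alpha/traced),
        ``t`` (conversion coordinate) and ``library_factor``. This table
        plays the role of the experiment's lineage-tracing labels.

    The same seed yields bit-identical output.
    """
    n_cells = config.n_beta + config.n_alpha + config.n_traced
    if n_cells == 0:
        raise EmptyResultError("no cells requested (all n_* are zero)")
    rng = np.random.default_rng(config.seed)
    types, t = _draw_t(config, rng)
    lib = np.exp(rng.normal(0.0, config.library_size_log_sd, n_cells))

    mu = expected_profiles(panel, t) * lib[None, :]
    theta = panel.dispersion[:, None]
    # NB via gamma-Poisson mixture: lam ~ Gamma(theta, mu/theta)
    lam = rng.gamma(np.broadcast_to(theta, mu.shape), mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    width = len(str(n_cells))
    cell_ids = [f"cell{str(i + 1).zfill(width)}" for i in range(n_cells)]
    cm = CountMatrix(gene_ids=list(panel.gene_ids), cell_ids=cell_ids,
                     counts=counts)
    truth = pd.DataFrame({
        "cell_id": cell_ids,
        "true_type": types,
        "t": t,
        "library_factor": lib,
    })
    return cm, truth


def simulate_dataset(config: Optional[PopulationConfig] = None,
                     panel: Optional[GenePanel] = None
                     ) -> tuple[CountMatrix, pd.DataFrame, GenePanel]:
    """Convenience wrapper: default panel + config unless overridden."""
    panel = panel if panel is not None else default_panel()
    config = config if config is not None else PopulationConfig()
    cm, truth = simulate_counts(panel, config)
    return cm, truth, panel


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def population_config_from_yaml(path: str | Path) -> PopulationConfig:
    """Load a PopulationConfig from a YAML mapping (unknown keys error)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(PopulationConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise FormatError(f"unknown generator config keys: {sorted(unknown)}")
    if "traced_mixture" in raw:
        raw["traced_mixture"] = tuple(float(x) for x in raw["traced_mixture"])
    return PopulationConfig(**raw)
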