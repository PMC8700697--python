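"""Gene panel: the gene universe of a simulated islet experiment.

A :class:`GenePanel` bundles the gene identifiers with the signature sets
used throughout the pipeline (beta identity, alpha identity, the three
unfolded-protein-response arms, housekeeping) and the per-gene negative
binomial parameters used by the count simulator:

``base_mean``
    expected transcript count at unit library size in the gene's "home"
    state -- the beta state for beta-signature genes, the alpha state for
    alpha-signature genes, the bump-free baseline for UPR genes.
``dispersion``
    inverse-overdispersion theta of the negative binomial,
    Var = mu + mu^2 / theta; larger theta means closer to Poisson.

The default panel models a human islet: INS/GCG dominate their cell type's
transcriptome (plate-based islet libraries devote a large fraction of reads
to the hormone genes), transcription factors sit one to two orders of
magnitude lower, and a background of non-signature genes fills out the
universe so that differential-expression and overlap analyses have a
realistic gene space to operate on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import FormatError

__all__ = ["GenePanel", "default_panel", "read_gene_list", "write_gene_list"]

# Signature gene sets. Beta/alpha lists are canonical islet identity
# markers; UPR arms group genes by the sensor whose programme they report
# (IRE1a: XBP1 splicing axis; PERK: ATF4/CHOP axis; ATF6 plus its negative
# regulator WFS1, which moves opposite to ATF6 itself).
BETA_GENES = ("INS", "IAPP", "PDX1", "MAFA", "NKX6-1", "ADCYAP1")
ALPHA_GENES = ("GCG", "ARX", "IRX2", "CHGB", "TTR", "ALDH1A1", "LOXL4", "GC")
IRE1A_GENES = ("XBP1", "ERN1")
PERK_GENES = ("ATF4", "DDIT3", "TRIB3", "PPP1R15A", "ATF3", "EIF2AK3")
ATF6_GENES = ("ATF6", "WFS1")
HOUSEKEEPING_GENES = ("ACTB", "GAPDH", "B2M", "RPL13A", "TUBB")

_DEFAULT_BASE_MEAN = {
    # beta signature, beta-state means
    "INS": 2000.0, "IAPP": 600.0, "PDX1": 80.0, "MAFA": 50.0,
    "NKX6-1": 60.0, "ADCYAP1": 120.0,
    # alpha signature, alpha-state means
    "GCG": 1800.0, "ARX": 60.0, "IRX2": 50.0, "CHGB": 300.0,
    "TTR": 700.0, "ALDH1A1": 80.0, "LOXL4": 60.0, "GC": 90.0,
    # UPR baselines (bump-free)
    "XBP1": 150.0, "ERN1": 40.0,
    "ATF4": 200.0, "DDIT3": 30.0, "TRIB3": 25.0, "PPP1R15A": 60.0,
    "ATF3": 20.0, "EIF2AK3": 30.0,
    "ATF6": 60.0, "WFS1": 80.0,
    # housekeeping
    "ACTB": 800.0, "GAPDH": 500.0, "B2M": 600.0, "RPL13A": 400.0,
    "TUBB": 300.0,
}

# theta: markers/UPR/housekeeping are abundant, well-measured transcripts
# (biological CV^2 ~ 4%); background genes are noisier.
_MARKER_DISPERSION = 25.0
_BACKGROUND_DISPERSION = 2.0


@dataclass(frozen=True)
class GenePanel:
    """Gene universe plus per-gene simulation parameters.

    ``bump_center``/``bump_width``/``bump_amplitude`` parameterise the
    transient Gaussian activation of IRE1a- and PERK-arm genes along the
    conversion coordinate t; ``atf6_floor`` is the terminal level of the
    declining ATF6 ramp; genes in ``atf6_rising_genes`` (WFS1 by default)
    follow the mirrored, rising ramp. ``signature_fold`` is the ratio of a
    signature gene's home-state mean to its level in the opposite cell
    type.
    """

    gene_ids: tuple[str, ...]
    beta_genes: tuple[str, ...]
    alpha_genes: tuple[str, ...]
    ire1a_genes: tuple[str, ...]
    perk_genes: tuple[str, ...]
    atf6_genes: tuple[str, ...]
    housekeeping_genes: tuple[str, ...]
    base_mean: np.ndarray
    dispersion: np.ndarray
    signature_fold: float = 50.0
    bump_center: Mapping[str, float] = field(default_factory=dict)
    bump_width: float = 0.10
    bump_amplitude: float = float(np.log(3.0))
    atf6_floor: float = 0.4
    atf6_rising_genes: tuple[str, ...] = ("WFS1",)

    # default arm centers; individual genes may be overridden via
    # ``bump_center`` (the panel below shifts ATF3, a late PERK target).
    IRE1A_CENTER = 0.35
    PERK_CENTER = 0.50

    def __post_init__(self):
        ids = self.gene_ids
        if len(set(ids)) != len(ids):
            dup = sorted({g for g in ids if list(ids).count(g) > 1})
            raise FormatError(f"duplicate gene ids in panel: {dup[:5]}")
        for name in ("beta_genes", "alpha_genes", "ire1a_genes",
                     "perk_genes", "atf6_genes", "housekeeping_genes"):
            missing = set(getattr(self, name)) - set(ids)
            if missing:
                raise FormatError(
                    f"{name} not in gene_ids: {sorted(missing)}")
        if set(self.beta_genes) & set(self.alpha_genes):
            raise FormatError("beta and alpha signatures overlap")
        bm = np.asarray(self.base_mean, dtype=float)
        disp = np.asarray(self.dispersion, dtype=float)
        if bm.shape != (len(ids),) or disp.shape != (len(ids),):
            raise FormatError("base_mean/dispersion length != n genes")
        if not (bm > 0).all():
            raise FormatError("base_mean must be positive for every gene")
        if not (disp > 0).all():
            raise FormatError("dispersion must be positive for every gene")
        object.__setattr__(self, "base_mean", bm)
        object.__setattr__(self, "dispersion", disp)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in genes], dtype=int)

    def gene_center(self, gene: str) -> float:
        """Bump center for an IRE1a/PERK gene (per-gene override wins)."""
        if gene in self.bump_center:
            return float(self.bump_center[gene])
        if gene in self.ire1a_genes:
            return self.IRE1A_CENTER
        if gene in self.perk_genes:
            return self.PERK_CENTER
        raise KeyError(f"{gene} has no bump center (not IRE1a/PERK)")


def default_panel(n_background: int = 471, background_seed: int = 20210923
                  ) -> GenePanel:
    """Build the default islet panel.

    Parameters
    ----------
    n_background
        Number of non-signature background genes appended to the panel
        (default brings the universe to 500 genes). Their base means are
        drawn log-normally (median ~5 counts) from a fixed internal seed,
        so the default panel is identical across calls.
    """
    named = (list(BETA_GENES) + list(ALPHA_GENES) + list(IRE1A_GENES)
             + list(PERK_GENES) + list(ATF6_GENES)
             + list(HOUSEKEEPING_GENES))
    rng = np.random.default_rng(background_seed)
    bg_ids = [f"BG{i:04d}" for i in range(1, n_background + 1)]
    bg_means = np.exp(rng.normal(np.log(5.0), 1.0, size=n_background))
    bg_means = np.clip(bg_means, 0.2, 200.0)

    gene_ids = tuple(named + bg_ids)
    base_mean = np.concatenate([
        np.array([_DEFAULT_BASE_MEAN[g] for g in named]), bg_means])
    dispersion = np.concatenate([
        np.full(len(named), _MARKER_DISPERSION),
        np.full(n_background, _BACKGROUND_DISPERSION)])
    return GenePanel(
        gene_ids=gene_ids,
        beta_genes=BETA_GENES,
        alpha_genes=ALPHA_GENES,
        ire1a_genes=IRE1A_GENES,
        perk_genes=PERK_GENES,
        atf6_genes=ATF6_GENES,
        housekeeping_genes=HOUSEKEEPING_GENES,
        base_mean=base_mean,
        dispersion=dispersion,
        bump_center={"ATF3": 0.60},  # late PERK target
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text signature file, one gene symbol per line.

    Blank lines and ``#`` comments are ignored; duplicates are an error.
    """
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if g and not g.startswith("#"):
            genes.append(g)
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise FormatError(f"duplicate gene in {path}: {dup}")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
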