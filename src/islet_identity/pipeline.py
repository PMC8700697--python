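"""End-to-end pipeline: simulate/ingest -> QC -> normalize -> cell typing
-> identity scoring -> trajectories -> DE -> ORA -> RRHO.

One :func:`run_all` call executes the whole analysis into a run
directory with a machine-readable summary (TSV key/value plus a JSON
mirror) and a log. Every stage is a pure function of (inputs, config);
a single global seed is expanded into per-stage child seeds by hashing
the stage name, so adding a stage never shifts another stage's random
stream. Two runs with the same config are byte-identical.
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .celltyping import assign_type, score_cells
from .errors import StageError
from .identity import identity_table
from .io_qc import CountMatrix, normalize, qc_filter, read_counts, write_counts
from .panel import GenePanel, default_panel, read_gene_list
from .rrho import rank_profile, rrho_map
from .simulate import PopulationConfig, simulate_counts
from .stats import de_compare, ora_table
from .trajectory import moving_average, peak_position, scale_genewise

__all__ = ["PipelineConfig", "run_all", "child_seed"]

log = logging.getLogger(__name__)


def child_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: stage-name CRC folded into the global seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``input_dir`` (a counts triplet + optional truth.tsv) or the
    generator settings are used; with no ``input_dir`` the run starts by
    simulating. Signature files override the built-in panel signatures
    when ``signature_dir`` is set (expects beta.txt / alpha.txt /
    ire1a.txt / perk.txt / atf6.txt).
    """

    out_dir: str = "islet_run"
    seed: int = 0
    # generator
    generator: PopulationConfig = field(default_factory=PopulationConfig)
    n_background: int = 471
    # or ingest
    input_dir: Optional[str] = None
    signature_dir: Optional[str] = None
    # QC / normalization
    min_counts: int = 1000
    min_genes: int = 200
    scale_factor: float = 10_000.0
    pseudocount: float = 1.0
    # cell typing / trajectory / DE / RRHO
    min_margin: float = 0.25
    window: int = 31
    stride: int = 10
    trajectory_genes: Optional[list[str]] = None
    padj_threshold: float = 0.05
    rrho_step: Optional[int] = None
    run_rrho: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", {})
        cfg = cls(**raw)
        if gen:
            cfg.generator = PopulationConfig(**{
                **gen, "seed": gen.get("seed", cfg.seed)})
        return cfg

    def validate(self) -> None:
        if self.input_dir is not None:
            d = Path(self.input_dir)
            for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
                if not (d / f).exists():
                    raise FileNotFoundError(f"missing input file: {d / f}")
        if self.signature_dir is not None:
            d = Path(self.signature_dir)
            for f in ("beta.txt", "alpha.txt"):
                if not (d / f).exists():
                    raise FileNotFoundError(f"missing signature file: {d / f}")


def _signatures(panel: GenePanel, cfg: PipelineConfig) -> dict[str, list[str]]:
    sigs = {
        "beta": list(panel.beta_genes),
        "alpha": list(panel.alpha_genes),
        "ire1a": list(panel.ire1a_genes),
        "perk": list(panel.perk_genes),
        "atf6": list(panel.atf6_genes),
    }
    if cfg.signature_dir is not None:
        d = Path(cfg.signature_dir)
        for name in sigs:
            f = d / f"{name}.txt"
            if f.exists():
                sigs[name] = read_gene_list(f)
    return sigs


def run_all(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the run directory.

    Writes counts (if simulated), QC report, identity table, trajectory
    profiles, DE tables (intermediate vs traced beta-like, intermediate
    vs traced alpha-like, traced beta-like vs canonical beta), ORA over
    the UPR arms, an RRHO map between the two intermediate-centred DE
    signatures, and ``summary.tsv`` / ``summary.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("islet_identity")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    summary: dict[str, object] = {"version": __version__,
                                  "seed": config.seed}
    try:
        # ---- ingest or simulate -------------------------------------
        stage = "simulate"
        panel = default_panel(n_background=config.n_background)
        truth: Optional[pd.DataFrame] = None
        if config.input_dir is not None:
            d = Path(config.input_dir)
            cm = read_counts(d / "matrix.mtx", d / "genes.tsv",
                             d / "barcodes.tsv")
            if (d / "truth.tsv").exists():
                truth = pd.read_csv(d / "truth.tsv", sep="\t")
        else:
            gen = PopulationConfig(**{
                **config.generator.__dict__,
                "seed": child_seed(config.seed, "simulate")})
            cm, truth = simulate_counts(panel, gen)
            write_counts(cm, out / "counts")
            truth.to_csv(out / "counts" / "truth.tsv", sep="\t",
                         index=False)
        summary["n_cells_input"] = len(cm.cell_ids)

        # ---- QC + normalization -------------------------------------
        stage = "qc"
        cm, report = qc_filter(cm, config.min_counts, config.min_genes)
        report.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        summary["n_cells_pass_qc"] = len(cm.cell_ids)
        stage = "normalize"
        nm = normalize(cm, config.scale_factor, config.pseudocount)

        # ---- cell typing --------------------------------------------
        stage = "celltype"
        sigs = _signatures(panel, config)
        scores = assign_type(
            score_cells(nm, {"beta": sigs["beta"], "alpha": sigs["alpha"]}),
            config.min_margin)
        scores.to_csv(out / "celltypes.tsv", sep="\t", index=False)

        # ---- identity scoring ---------------------------------------
        stage = "score"
        if truth is not None:
            tmap = truth.set_index("cell_id")["true_type"].reindex(
                cm.cell_ids)
            beta_ref = (tmap == "beta").to_numpy()
            alpha_ref = (tmap == "alpha").to_numpy()
            traced = (tmap == "traced").to_numpy()
        else:
            lab = scores["assigned_type"].to_numpy()
            beta_ref = lab == "beta"
            alpha_ref = lab == "alpha"
            traced = np.zeros(len(lab), dtype=bool)
        ident, b_stats, a_stats = identity_table(
            cm.cell_ids,
            scores["score_alpha"].to_numpy(),
            scores["score_beta"].to_numpy(),
            beta_ref, alpha_ref)
        ident.to_csv(out / "identity.tsv", sep="\t", index=False)
        summary["beta_ref_mu"] = round(b_stats.mu, 6)
        summary["beta_ref_sigma"] = round(b_stats.sigma, 6)
        summary["alpha_ref_mu"] = round(a_stats.mu, 6)
        summary["alpha_ref_sigma"] = round(a_stats.sigma, 6)

        kept = ident.set_index("cell_id")
        traced_ids = [c for c, tr in zip(cm.cell_ids, traced)
                      if tr and c in kept.index]
        tr_class = kept.loc[traced_ids, "class"] if traced_ids else \
            pd.Series(dtype=object)
        for cls in ("nonconverted_beta", "intermediate", "converted_alpha"):
            summary[f"traced_{cls}"] = int((tr_class == cls).sum())
        n_traced = len(traced_ids)
        summary["traced_total"] = n_traced
        summary["intermediate_pct"] = (
            round(100.0 * (tr_class == "intermediate").sum() / n_traced, 4)
            if n_traced else 0.0)
        if not n_traced:
            log.info("no traced cells: intermediate fraction is 0 and "
                     "traced-vs-canonical DE is skipped")

        # ---- trajectory ---------------------------------------------
        stage = "trajectory"
        traj_genes = config.trajectory_genes or (
            sigs["ire1a"] + sigs["perk"] + sigs["atf6"]
            + ["INS", "GCG", "PDX1", "ARX"])
        traj_genes = [g for g in traj_genes if g in set(nm.gene_ids)]
        ordered = ident
        if len(ordered) >= config.window:
            prof = moving_average(ordered, nm, traj_genes,
                                  config.window, config.stride)
            prof.to_frame().to_csv(out / "trajectory.tsv", sep="\t",
                                   index=False)
            scaled = scale_genewise(prof, arms={
                k: sigs[k] for k in ("ire1a", "perk", "atf6")})
            scaled.to_frame().to_csv(out / "trajectory_scaled.tsv",
                                     sep="\t", index=False)
            for g in ("XBP1", "DDIT3", "ATF3", "ATF6"):
                if g in prof.means.columns:
                    summary[f"peak_{g}"] = round(peak_position(prof, g), 4)

        # ---- differential expression --------------------------------
        stage = "de"
        groups = {
            cls: kept.loc[[c for c in traced_ids
                           if kept.loc[c, "class"] == cls]].index.tolist()
            for cls in ("nonconverted_beta", "intermediate",
                        "converted_alpha")}
        canon_beta = [c for c, b in zip(cm.cell_ids, beta_ref)
                      if b and c in kept.index]
        de_tables = {}
        comparisons = {
            "intermediate_vs_traced_beta":
                (groups["intermediate"], groups["nonconverted_beta"]),
            "intermediate_vs_traced_alpha":
                (groups["intermediate"], groups["converted_alpha"]),
            "traced_beta_vs_canonical_beta":
                (groups["nonconverted_beta"], canon_beta),
        }
        for name, (ga, gb) in comparisons.items():
            if len(ga) < 2 or len(gb) < 2:
                log.info("skipping DE %s (groups of %d and %d cells)",
                         name, len(ga), len(gb))
                continue
            de = de_compare(nm, ga, gb, config.padj_threshold)
            de.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
            de_tables[name] = de
            summary[f"de_{name}_significant"] = int(de["significant"].sum())

        # ---- over-representation ------------------------------------
        stage = "ora"
        key = "intermediate_vs_traced_beta"
        if key in de_tables:
            de = de_tables[key]
            tested = de[de["tested"]]
            selected = tested.loc[tested["significant"], "gene"].tolist()
            if selected:
                pathways = {k: sigs[k] for k in ("ire1a", "perk", "atf6")}
                universe = tested["gene"].tolist()
                pathways = {k: [g for g in v if g in set(universe)]
                            for k, v in pathways.items()}
                tab = ora_table(selected, pathways, universe)
                tab.to_csv(out / "ora.tsv", sep="\t", index=False)
                for _, row in tab.iterrows():
                    summary[f"ora_{row['set']}_fraction"] = round(
                        float(row["fraction"]), 4)

        # ---- RRHO ----------------------------------------------------
        stage = "rrho"
        if (config.run_rrho
                and "intermediate_vs_traced_beta" in de_tables
                and "intermediate_vs_traced_alpha" in de_tables):
            pa = rank_profile(de_tables["intermediate_vs_traced_beta"])
            pb = rank_profile(de_tables["intermediate_vs_traced_alpha"])
            m = rrho_map(pa, pb, step=config.rrho_step)
            m.write_tsv(out / "rrho.tsv")
            summary["rrho_max_signed"] = round(float(m.values.max()), 4)

        # ---- summary -------------------------------------------------
        stage = "summary"
        with open(out / "summary.tsv", "w") as f:
            for k, v in summary.items():
                f.write(f"{k}\t{v}\n")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=False) + "\n")
    except Exception as e:
        if isinstance(e, StageError):
            raise
        raise StageError(stage, str(e)) from e
    finally:
        root.removeHandler(fh)
        fh.close()
    return out
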