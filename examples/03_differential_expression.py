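"""Differential expression of intermediate cells and UPR over-representation.

Compares intermediate traced cells against traced cells that kept beta
identity (Wilcoxon rank-sum per gene, Benjamini-Hochberg corrected), then
asks what fraction of the affected genes belong to each UPR arm.
"""
from islet_identity import (PopulationConfig, de_compare, default_panel,
                            identity_table, normalize, ora_table,
                            score_cells, simulate_counts)

panel = default_panel()
counts, truth = simulate_counts(panel, PopulationConfig(seed=1))
norm = normalize(counts)
scores = score_cells(norm, {"beta": panel.beta_genes,
                            "alpha": panel.alpha_genes})
true_type = truth.set_index("cell_id")["true_type"].reindex(counts.cell_ids)
table, _, _ = identity_table(
    counts.cell_ids,
    scores["score_alpha"].to_numpy(), scores["score_beta"].to_numpy(),
    (true_type == "beta").to_numpy(), (true_type == "alpha").to_numpy())

by_cell = table.set_index("cell_id")
traced = set(truth.loc[truth["true_type"] == "traced", "cell_id"])
intermediate = [c for c in by_cell.index
                if c in traced and by_cell.loc[c, "class"] == "intermediate"]
traced_beta = [c for c in by_cell.index
               if c in traced
               and by_cell.loc[c, "class"] == "nonconverted_beta"]

de = de_compare(norm, intermediate, traced_beta, padj_threshold=0.05)
tested = de[de["tested"]]
significant = tested[tested["significant"]]
print(f"{len(intermediate)} intermediate vs {len(traced_beta)} "
      f"beta-like traced cells")
print(f"tested {len(tested)} genes, {len(significant)} significant "
      f"at padj < 0.05")
print(significant.nlargest(5, "lfc")[["gene", "lfc", "padj"]]
      .to_string(index=False))

arms = {"ire1a": panel.ire1a_genes, "perk": panel.perk_genes,
        "atf6": panel.atf6_genes}
universe = tested["gene"].tolist()
arms = {k: [g for g in v if g in set(universe)] for k, v in arms.items()}
enrichment = ora_table(significant["gene"].tolist(), arms, universe)
print(enrichment.to_string(index=False))
print("-> 'fraction' is each arm's share of all affected genes; small "
      "hypergeometric p-values mean the arm is over-represented among "
      "the genes that change in intermediate cells.")
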