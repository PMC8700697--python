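# Methods

## The generative model behind the simulator

The simulator emulates a plate-based (SORT-seq-style) islet scRNA-seq
experiment in which β-cells were lineage-labelled before islet dispersion
and reaggregation, so that each labelled cell can later be found anywhere
along a β→α conversion axis. Each cell carries a latent conversion
coordinate `t ∈ [0, 1]`:

* canonical β cells: `t = |N(0, j)|` clipped to [0, 1] (default jitter
  `j = 0.03`);
* canonical α cells: the mirror image around 1;
* lineage-traced cells: a three-component mixture — still β-like
  (`t ≈ 0`), fully converted (`t ≈ 1`), or in transit
  (`t ~ Uniform(0, 1)`) — with default weights 0.85 / 0.09 / 0.06.

Expected expression at `t` is deterministic per gene:

* β-signature genes decay log-linearly from their β-state mean to that
  mean divided by the signature fold (default 50); α-signature genes
  mirror this. Log-linear interpolation keeps profiles positive and makes
  the log-expression of signature genes linear in `t`.
* IRE1α- and PERK-arm UPR genes get a transient multiplicative bump
  `exp(A·exp(−(t−c)²/2w²))` with amplitude `A = log 3`, width `w = 0.10`
  and arm centers `c` = 0.35 (IRE1α) and 0.50 (PERK); ATF3, a late PERK
  target, uses `c = 0.60`. The bump is truncated to exactly 1 beyond
  `|t−c| > 3w`, so cells far from the window are bit-identical to
  baseline and the peak-to-baseline ratio is exactly `e^A`.
* ATF6 declines linearly to 0.4× at `t = 1`; its negative regulator WFS1
  follows the mirrored rising ramp. Housekeeping and background genes are
  flat.

Counts are negative binomial, `mean = library_factor × profile(t)` with
gene-wise inverse-overdispersion θ (variance `μ + μ²/θ`), sampled as a
gamma–Poisson mixture; library factors are log-normal (log-sd 0.35,
median library ≈ 10,000 counts). Named marker/UPR/housekeeping genes use
θ = 25 (≈20% biological CV, typical for abundant transcripts); the 471
background genes use θ = 2. Hormone genes dominate their home state (INS
2,000 cpm, GCG 1,800 cpm), transcription factors sit at 50–120 cpm —
roughly the composition of real islet plate-based libraries.

What the generator does **not** emulate: UMI collapse, spike-ins,
doublets, ambient RNA, batch/donor structure (a donor factor exists but
is off by default), non-endocrine islet cell types, and any
transcriptome-wide co-regulation beyond the planted signature/UPR
structure. Passing recovery tests therefore demonstrates that the
*algorithms* recover planted structure under realistic count noise — not
that real islet data satisfy the model.

## Identity score

`r = a/(a+b)` on the mean log-normalized signature expressions is
bounded, 0 for pure β signal, 1 for pure α, and invariant to joint
rescaling. Calibration anchors on reference **medians** (robust to the
skewed β peak real traced populations show); classification bands use
mean ± 2 sd to match the population-statistics convention. The two
choices are deliberately different and are isolated behind `calibrate`
and `pop_stats`. The band rule requires `μ_β + 2σ_β < μ_α − 2σ_α`;
overlapping bands raise an error rather than silently producing an empty
intermediate class. Cells with zero signal in both signatures are
excluded and reported, never imputed. The 2σ rule admits ≈95% of
near-normal canonical cells by construction, so ≈2.5% of genuinely
β-like cells are expected above the β band; the intermediate percentage
is consequently a slightly conservative over-count at the margins.

Classification is applied to **calibrated** scores (the band statistics
are computed on the same scale, so the choice is a labelling convention;
raw-scale bands would give identical labels after the affine map).

## Trajectory summaries

Windows are cell-count based (default w = 31 cells, odd so the center
cell is defined; stride k = 10), never score-interval based, so sparse
score regions cannot produce empty windows. A trailing window with fewer
than w/2 cells merges into its predecessor. Gene-wise z-scoring across
windows uses the n−1 sd; constant genes map to all-zero with a note.
Peak positions are argmax window centers with ties resolved to the
earliest center, making flat profiles report the axis start rather than
an arbitrary window.

## Differential expression and over-representation

Wilcoxon rank-sum, two-sided: exact by enumeration semantics (via the
exact method of the Mann–Whitney implementation) when combined n ≤ 20
and the pooled sample is tie-free; otherwise the normal approximation
with tie and continuity corrections. Ties in the small-sample regime
fall back to the approximation. Genes expressed in <5% of cells in both
groups are excluded *and recorded* before testing; BH correction runs
across the tested genes only. The reported fold change is
`log2((Ā+1)/(B̄+1))` on expm1-backtransformed group means — an
interpretable effect size stored alongside the rank-based p, not the
test statistic. Over-representation is the exact hypergeometric upper
tail; the headline summary per gene set is its *fraction of the affected
genes* (overlap / selected), matching how pathway involvement of an
affected cell population is usually quoted.

## RRHO

Both profiles are ranked by `−log10(max(p, 1e-300)) × sign(lfc)`, most
up-regulated first, ties broken by gene id. For thresholds `(i·step,
j·step)` the top-list overlap is scored with an exact hypergeometric
upper tail summed in log space; the whole grid is BH-corrected (the
correction method and step are configurable and recorded in the map
header; step defaults to N/50). Signs follow the deviation of the
overlap from its independence expectation `i·j·step²/N`. The tail
function canonicalizes its (successes, draws) argument order, making
`rrho_map(a, b)` exactly the transpose of `rrho_map(b, a)` in floating
point, not merely up to rounding.

## Pipeline determinism

One global seed is expanded per stage as `seed XOR crc32(stage_name)`
(masked to 31 bits), so inserting a stage never shifts another stage's
stream; two runs with the same config produce byte-identical outputs.
Summaries are written as flat TSV key/value plus a JSON mirror.

## Problem sizes and test design

The default experiment (3,000 cells × 500 genes) runs in ~1 s, so
recovery properties are tested over 5–20 replicate seeds. The DE
null-calibration experiment uses 8-vs-8 cells per group: combined n = 16
keeps every gene in the exact-test regime, the attainable p-value just
below 0.05 gives a rejection rate of 0.050, and the smallest attainable
p (2/C(16,8) ≈ 1.5×10⁻⁴) exceeds the rank-1 BH threshold at 2,000
genes, so a clean null yields zero BH discoveries structurally rather
than probabilistically. Planted-effect DE benchmarks shift background
genes with base mean ≥ 1 cpm: doubling the hormone genes would move a
fifth of the library and turn every other gene's CPM into a genuine
compositional difference, confounding the false-positive count.

## Known limitations

* The global Spearman correlation between the planted conversion
  coordinate and the calibrated score over *all* traced cells is ≈0.6
  under the default mixture, not higher: 85% of traced cells sit at
  `t ≈ 0` where the within-cluster spread of `t` (sd ≈ 0.018) is smaller
  than the score's count-sampling noise (sd ≈ 0.04, dominated by
  near-zero counts of the opposite signature — the per-gene noise of
  log1p counts has a floor of ≈ 1/√θ). Where conversion actually varies
  (transit cells, `t ∈ (0.1, 0.9)`) the score is almost perfectly
  monotone (ρ ≈ 0.99, unit-tested). A global rank correlation over an
  endpoint-concentrated population is thus a poor summary of ordering
  quality; the package reports it but the per-range correlation is the
  meaningful diagnostic.
* The identity score presumes exactly two endpoint identities; branching
  fates, dedifferentiation to progenitor states, RNA velocity and
  probabilistic state assignment are out of scope.
* `pseudo_rank` is conversion ordering, not physical time.
* Compositional effects of normalization are not corrected; strong
  shifts in highly expressed genes propagate into other genes' CPM
  values (see the DE benchmark note above).
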