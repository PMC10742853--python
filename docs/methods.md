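# Methods

This note documents the models, conventions and design choices behind
`refquant`, at the level a user needs to interpret its output and to
know what the synthetic-data tests do and do not demonstrate.

## Data model

A `CtMatrix` is an assays × samples grid of cycle-threshold values with
one condition label per sample and a detection ceiling (default 34
cycles). Undetermined wells — amplification curves that never crossed
the threshold — are held as NaN; they are data, not errors, everywhere
except among stability candidates (see below). Ct values are validated
to lie in (0, 45]; values above the ceiling are kept verbatim and left
to the expression screen to flag, because clamping would silently
distort SD-based statistics. Parsing is dot-decimal only, with no
thousands separators, so files read identically across locales.

## Expression screen

An assay's summary Ct is the arithmetic mean of its detected wells in
one *basis condition*, default the control group: the control is the
stable baseline and screening should not be confounded by treatment
effects. Classes follow the chip's reliability bands: `high` strictly
below 28 cycles, `low` on the closed interval [28, 34], `undetected`
above 34. The boundary convention is deliberate — "before cycle 28"
reads as strict, the low band includes both endpoints — and is pinned by
tests (28.0 → low, 34.0 → low, 34.0 + ε → undetected). An assay with
fewer than `min_detected` (default 3 of 8) detected basis wells is
`undetected` regardless of its mean, so a single stray well cannot
promote a gene. Only `high` genes enter quantification by default;
preamplification rescue of low expressers is out of scope.

## Stability statistics

All four statistics operate on a one-condition candidate matrix with no
undetermined cells; a gap among candidates is a hard error rather than
an imputation, because imputed values would feed directly into the SDs
being compared. Sample SD (n−1) is used throughout.

* **Comparative ΔCt** — `score_i = mean_{j≠i} SD(Ct_i − Ct_j)`. Pairwise
  differencing cancels per-sample loading offsets exactly.
* **BestKeeper** — `score_i = SD(Ct_i)`, plus `CV% = 100·SD/mean`.
  Deliberately offset-*sensitive*: it answers a different question (raw
  dispersion including loading artifacts). Ranking uses the SD; the
  index-correlation part of the original tool is not implemented.
* **NormFinder** (single-group form) — two-way additive model
  `Ct_ij = a_i + b_j + e_ij`, `Var(e_ij) = s_i²`. The naive residual
  variances `v_i` from the two-way fit mix the genes' variances; the
  moment correction `s_i² = k/(k−2)·(v_i − Σv/(k(k−1)))` (k genes)
  unmixes them, and the score is `sqrt(max(0, s_i²))`. Negative
  estimates (possible at small n) truncate to zero. At least three
  genes are required — with two the decomposition is unidentifiable.
  The two-group variant with an inter-group bias term is intentionally
  not implemented: conditions are ranked separately here.
* **geNorm** — M on the current set equals the comparative-ΔCt score
  (same formula; the two independent code paths are asserted bit-equal
  in tests). The gene with the largest M is removed and M recomputed
  until two genes remain; a gene's reported M is its value at removal,
  the final pair share the M of their two-gene set. Pairwise variation
  `V_k = SD(NF_k − NF_{k+1})` is computed over genes added in stability
  order, with the normalization factor of a sample taken as the mean of
  the included genes' mean-centred Ct (the log2 geometric-mean factor up
  to sign and centring). V_k is reported; the "how many reference genes
  suffice" cutoff decision (commonly V < 0.15) is left to the user.

## Rank aggregation and reference selection

Each method's scores become ordinal ranks, 1 = most stable;
full-precision ties break by panel order (documented, deterministic —
the behaviour of the aggregating web tools on exact ties is not
specified anywhere authoritative). A gene's comprehensive score is the
geometric mean of its four ranks; a gene ranked k by all four methods
gets exactly k. Conditions are ranked separately and combined as
`summary = comp_control + comp_treated`; the minimal summary wins, ties
again by panel order. Published tables of this kind print comprehensive
scores at 2 d.p. and sum those rounded values into the summary column;
the library keeps full precision and rounds only for display, and the
reproduction tests feed 2-d.p. comprehensives into the summary exactly
as the printed table does. One transcription quirk matters: in the
published per-method rank table the tied final geNorm pair both carry
rank 1 (so the next gene is rank 3); the packaged fixture preserves
this, while ranks computed by this package are always a permutation of
1..n.

## Relative quantification

`ΔCt = Ct(gene) − Ct(ref)` per sample; the per-gene baseline is the
arithmetic mean of control-group ΔCt (median available as an option —
some protocols are ambiguous between "mean control" and "median
control"); `ΔΔCt = ΔCt − baseline`; `fold = 2^−ΔΔCt`, assuming perfect
doubling per cycle (no Pfaffl efficiency correction, single reference
gene only). With the mean baseline, the geometric mean of control-group
folds is identically 1 — asserted to 1e−12 — and per-sample loading
offsets cancel entirely. Undetermined target wells propagate as missing
folds; a gene needs at least 2 detected control wells or it is dropped
with a warning. Group summaries report the geometric mean fold and the
arithmetic mean ± SEM.

## Group statistics

Shapiro–Wilk per group (needs n ≥ 3; genes with smaller groups are
skipped with a warning), then an unpaired two-sided Student's t-test
with pooled variance (Welch optional). Groups are ordered
alphabetically by label so the sign of t is a function of the label
pair, not of column order. The degenerate zero-variance case is defined
explicitly: equal means → t = 0, p = 1. Tests run on fold values by
default (ΔΔCt optional); significance is flagged at p ≤ 0.05 with no
multiple-testing correction by default — matching common single-gene
qPCR reporting — but a Benjamini–Hochberg column is available, and with
~60 genes per run the uncorrected flags should be read with that in
mind.

## Synthetic-data generator

`Ct_gs = b_g + α_s − f_g·[s treated] + ε_gs`, `ε ~ N(0, σ_g)`, with
cells above the ceiling emitted as undetermined. Defaults emulate the
targeted study design: 2 × 8 samples; 101 targets whose baselines are
drawn inside their class windows (high [20, 26.5], low [29, 33],
undetected [36, 40] — margins wide enough that class recovery is exact
at the default noise); σ = 0.3 cycles for targets; loading offsets
α ~ N(0, 0.5); 20 target genes carry a planted expression log2 fold
change of −1 (the downregulated-gene count and magnitude typical of the
emulated lesion model). Among the 11 HKG candidates one is planted
stable (σ = 0.15, f = 0); seven are noise-unstable with σ drawn uniform
from [0.3, 1.0]; three are condition-shifted (f = −0.6, +0.5, +0.8)
with σ = 0.5. The shifted candidates carry moderate noise deliberately:
a pure between-condition shift is invisible to per-condition stability
ranking, so a shifted-but-ultra-quiet gene would be structurally
indistinguishable from the planted reference — and a treatment-
responsive gene that is otherwise quieter than every stable gene is not
a realistic failure mode.

What the generator does *not* model: amplification-efficiency variation
(the 2^−ΔΔCt assumption is built in), fluorescence-curve shape, chip
spatial effects, and non-Gaussian well failures. Passing recovery tests
therefore demonstrate correctness of the statistics under the stated
model, not robustness to efficiency artifacts.

## Problem sizes and stochastic guarantees

The planted-truth guarantees are run at the design size (112 × 16) over
100 seeds: the planted stable HKG wins the summary ranking in ≥ 90/100
runs (measured: 98/100), and the mean estimated log2 fold change over
the 20 planted-effect genes lands within ±0.2 of the planted −1 in
≥ 95/100 runs (measured: 98/100). The fold-recovery statistic is the
*mean over the planted genes* per run: a single gene's estimate at
n = 8 and σ = 0.3 has a standard error of ≈ 0.17 cycles, so a per-gene
±0.2 band could never be met 95 times in 100 — averaging over the
planted set is the statistic the design supports, with a run-level SD
of ≈ 0.08.

## Known limitations

Single reference gene only (no multi-gene geometric-mean normalizer);
no efficiency correction; no nonparametric fallback when Shapiro–Wilk
rejects; per-condition NormFinder only. The per-method stability
*scores* of any particular published table cannot be reproduced without
its raw Ct data — only the aggregation layer is anchored numerically —
which is exactly what the packaged rank fixture covers.
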