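# Methods

`smokesig` implements an end-to-end analysis for identifying tobacco-exposure
DNA-methylation signatures in lung-adenocarcinoma cohorts and tracing their
downstream regulatory partners. This note records the statistical model at
each stage, the defaults and why, the design choices that were genuinely
open, and what the synthetic-data benchmarks do and do not demonstrate.

## Inputs and preprocessing

The pipeline consumes a probe × sample matrix of Infinium 450K β-values
(methylated / total signal, in [0, 1]), a gene × sample log2 expression
matrix, a probe manifest (chromosome, ordered gene symbols, CpG zone), sample
metadata (smoking status plus age, gender, stage, vital status, survival
time), and a STRING-style weighted protein-interaction edge list with
combined scores on the 0–1000 integer scale.

Filtering proceeds in a fixed order: (1) probes/genes missing in every
sample; (2) samples lacking any required clinical field; (3) everything on
chrX/chrY (mixed-sex smoking cohorts; sex-chromosome probes confound the
contrast). Gene chromosomes are inferred from the manifest via the probes
that carry the symbol; genes the manifest never mentions are retained, since
no location evidence exists for them. The optional expression transform is
`log2(x + 1)` and is gated by a flag rather than auto-detected: public β-value
matrices arrive untransformed while many expression matrices arrive already
on the log scale, and silent double-transforms are worse than an explicit
switch. The offset `+1` keeps zero counts finite; no offset convention is
universal, so it is documented rather than configurable.

Normality is audited per probe with the Jarque–Bera statistic
JB = (n/6)(S² + (K−3)²/4) using biased (1/n) central moments and the
asymptotic χ²(2) p-value — the classical definition. The audit reports the
fraction of probes with uncorrected p ≥ α (default α = 0.05). No multiplicity
correction is applied here because the audit is descriptive: it motivates the
choice of a rank test, it is not an inference procedure.

Annotation summaries attribute each multi-gene probe to the **first** listed
symbol (manifests order symbols by likelihood). Zone percentages are
100·count/total rounded half-away-from-zero to one decimal; with 20 of 105
probes on shores this yields 19.0 (19.05 rounds down under this rule), a
0.1-point difference from some printed summaries of the same table that is
documented rather than forced.

## Prescreen

Each probe is tested current- versus never-smokers with the two-sided
Wilcoxon rank-sum test: the exact null distribution when n₁ + n₂ ≤ 20 with no
ties, otherwise the normal approximation with midrank tie correction and
continuity correction. Records whose only status is "ever" are excluded from
the contrast with a warning — they cannot be assigned to either side.
P-values are adjusted with Benjamini–Hochberg step-up across all tested
probes; the default FDR level is q = 0.05. Exhaustive enumeration of all 65
possible U outcomes at n₁ = n₂ = 8 bounds the continuity-corrected
approximation error by 0.0109, which the tests freeze as a 0.011 tolerance.

## Deep selecting (PLS-DA recursive elimination)

With p ≫ n (thousands of probes, ≲ 200 samples), a one-shot variable
selection is hopeless; the deep-selecting loop removes the least informative
probes a little at a time, re-estimating importances after every removal
because the relative contributions shift once noise variables leave the
model.

Labels are coded +1 (current) / −1 (never) and a PLS1 regression (NIPALS,
columns centred and unit-variance scaled by default — β ranges differ
systematically between methylated and unmethylated probe classes) is fitted;
class prediction is the sign of the continuous prediction, with an exact 0
called +1. Per iteration:

1. stratified 5-fold cross-validation over a component grid (default 1–5;
   pooled held-out predictions; most-accurate, smallest-on-ties component
   count wins);
2. a full-data fit at that component count;
3. probe importance by VIP,
   VIP_j = √( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ),
   whose squares average to 1 by construction (a tested invariant);
   |coefficient| ranking is available as an alternative;
4. removal of the lowest-ranked 10 % (floor one probe).

The loop stops when the best cross-validated accuracy has not improved for
`patience` = 5 consecutive iterations, or when another removal would cross
`min_probes` = 10. The returned signature is the probe set at the
best-accuracy iteration, first occurrence on ties — deliberately
conservative: when a smaller set merely matches (rather than beats) a larger
one, the larger, earlier set is kept. The elimination fraction, patience and
floor are conventional recursive-feature-elimination choices; a 10 %/round
geometric schedule traverses 10⁵ → 10² probes in roughly 40 rounds. External
cohorts are scored by refitting on the full training data restricted to the
signature and reporting sensitivity, specificity and accuracy. Validation
cohorts play no role in stopping by default; selection driven partly by
validation performance would leak information into the signature.

Caveat: cross-validated accuracy both steers elimination and is reported, so
the reported CV accuracy is optimistically biased; unbiased error estimation
would need a nested design, which is out of scope.

## Differential correlation (DCS)

For every (signature probe, gene) pair, within-group correlations r_current
and r_never are computed with either the biweight midcorrelation or
Spearman's rank correlation. The bicor uses the classical Tukey-biweight
formulation: u_i = (x_i − med)/(9·MAD) with the **unscaled** MAD (no 1.4826
consistency factor — the 9·MAD tuning constant belongs to the unscaled
convention), weights (1 − u²)² 1{|u| < 1}, normalised weighted deviations,
result clipped to [−1, 1]. A zero-MAD vector (≥ half the values tied at the
median) falls back to the Pearson normalisation with a warning, or raises
under strict mode. Both correlations are separable into per-vector
normalisations, so the probe × gene table is computed as one matrix product
per group.

A pair is selected when its correlation magnitude is **high in one group and
low in the other**: (|r_c| ≥ TS2 ∧ |r_n| ≤ TS1) ∨ (|r_n| ≥ TS2 ∧ |r_c| ≤ TS1),
with TS1 = 0.3, TS2 = 0.6 and inclusive comparisons. This is the natural
reading of two thresholds named TS1 < TS2 for differential correlation —
coupling that is present in one exposure state and absent in the other — and
the rule is pluggable for other conventions. Selection is monotone in TS2 and
anti-monotone in TS1 (property-tested). The gene sets found by the two
correlation methods are intersected to give the high-confidence set.

## Gene weight network

Genes linked by DCS form an unsigned soft-threshold co-expression network:
a_ij = |cor(GE_i, GE_j)|^β. Pearson correlation is the default for this
stage (co-expression weight networks conventionally use it; bicor is
selectable), β = 6 is the conventional unsigned soft power (a scale-free-fit
chooser is provided), and connectivity k_i = Σ_{j≠i} a_ij. Genes with
k > 10.75 are flagged as hubs; the cutoff is a plain parameter whose default
mirrors the connectivity threshold used in the study this pipeline
re-implements.

## PPI shortest-path tracing

Edges below a combined score of 400 (STRING "medium confidence") are dropped
by default; duplicate undirected edges keep the maximum score. The distance
transform is d = 1001 − score: strictly positive and strictly decreasing.
Because two decreasing transforms need not induce the same paths when hop
counts differ, the transform is exposed (−ln(score/1000) is the alternative).

For each unordered seed pair, **one** shortest path is traced (Dijkstra).
Among tied-cost paths the lexicographically smallest node sequence from the
alphabetically first endpoint is chosen, making results deterministic and
seed-order invariant: the reconstruction walks greedily from s, at each step
taking the smallest neighbour v with d(cur,v) + dist(v,t) = dist(cur,t).
Brandes-style all-tied-paths counting sits behind a flag. Each non-seed
interior protein of a chosen path gains one betweenness count; seeds are
never ranked as intermediates. Unreachable pairs are recorded, not fatal.

The permutation background repeats the trace on `n_rounds` = 100 uniformly
drawn random seed sets of the same size and counts, per protein, the rounds
in which it reached the betweenness floor; proteins above a removal fraction
(default 0.5) of rounds are promiscuous connectors (the TP53/UBC class of
universal hubs) and are excluded from the final ranking. The betweenness
floor for reporting is a plain parameter (the study used 3000 genome-scale;
100/200 for network views).

## Synthetic data: what it emulates, what it does not

The generator plants known structure so every stage has a recovery test:

- **Methylation.** β ~ Beta(μκ, (1−μ)κ) per probe with κ = 30 and probe-level
  μ from a bimodal mixture (0.6 weight on Beta(2,10), 0.4 on Beta(10,2)),
  reproducing the methylated/unmethylated modes of real arrays; the marginal
  law of real β-values is not published for this design, so the mixture is
  this package's choice. Signature probes (default 50 of 2000) take a
  central baseline μ ∈ (0.2, 0.8) shifted ±Δβ (default 0.25, alternating
  sign) in current-smokers; a Δβ that would push a mean outside (0, 1) is a
  parameter error. Probe-level parameters depend only on the config seed, so
  a validation cohort drawn with a fresh sample seed shares the probe laws —
  the two-cohort train/validate design.
- **Cohort.** Defaults 102 current / 43 never match the discovery-cohort
  structure of the study; benchmarks that specify 70/30 set it explicitly.
- **Expression.** Background genes are independent Gaussians on the log2
  scale. Each planted pair couples gene to probe linearly with noise
  calibrated so the within-group correlation targets r_high = 0.9 in one
  randomly chosen smoking group, and r_low = 0 (independence) in the other.
  Achieved correlations are verified empirically, not imposed.
- **Manifest.** CpG zones sampled at open sea 45.7 % / island 25.7 % /
  shore 19.1 % / shelf 9.5 % (N/S split evenly); ~20 % of background probes
  are gene-less; ~2 % sit on chrX/chrY to exercise the filter (never
  signature probes).
- **PPI.** A preferential-attachment backbone with background scores in
  [401, 950]; seeds are partitioned across 5 bridge proteins, with
  seed–bridge and bridge–bridge edges at score 1000 (distance 1). Any
  background detour costs ≥ 51, so each bridge provably carries the shortest
  paths of its seed block and the truth set is exactly recoverable.

Not emulated: genomic coordinates, batch effects, cell-type composition,
Infinium type-I/II chemistry, survival structure (clinical fields are
carried but unused), and realistic PPI degree distributions. Passing
recovery tests therefore demonstrates correctness of the algorithms under a
clean planted model — strong effect sizes, independent noise — not expected
performance on real cohorts, where effect sizes near Δβ = 0.25 are rare and
confounding is the norm.

## Benchmark problem sizes

The packaged benchmarks use 2000 probes × 100 samples (70/30) for signature
recovery and the 102/43 default cohort with 50 probes × 1000 genes for
differential-correlation recovery, 10 independent seeds each; these sizes
give stable medians while keeping the full suite fast. At these settings the
planted signature is recovered essentially completely (the prescreen alone
isolates it at Δβ = 0.25), DCS recovers ≳ 95 % of planted pairs, and the
null false-pair rate stays below 1 per 10⁴ — with only ~30 never-smokers the
null tail P(|r| ≥ 0.6) ≈ 3·10⁻⁴ would break that bound, which is why the
correlation benchmark keeps the 43-never cohort.

## Numerical conventions and degenerate inputs

- Percentages: round half away from zero, one decimal.
- Wilcoxon: ties force the asymptotic branch (the exact distribution assumes
  continuity); identical multisets give p = 1.
- PLS: zero-variance columns are dropped with a warning when scaling;
  prediction ties at exactly 0 are called +1.
- bicor: zero MAD → Pearson fallback with warning (or error); constant
  vectors are errors everywhere a correlation is undefined.
- DCS: NaN correlations (skipped pairs) are never selected.
- Graphs: self-loops dropped; duplicate edges keep max score; empty graphs
  warn; malformed edge rows fail with line numbers.
- All randomness flows through explicit integer seeds (numpy Generator);
  integer structure is platform-stable, floats are reproducible to rounding.
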