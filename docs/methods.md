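# Methods

## Design and data model

The unit of analysis is a 2×2 complete diallel cross: inbred families
`A` and `D` and their reciprocal hybrids `B` (A♀×D♂) and `C` (D♀×A♂).
A *triad* is one hybrid considered with the two inbreds. Phenotypes are
individual-level trait measurements (shell dimensions in mm, weights in
g); expression is a genes × samples matrix of nonnegative values tagged
as raw counts or FPKM, with samples mapped to (family, replicate). All
tables are plain CSV/TSV; gene ids and family labels are opaque strings.
Validation rejects malformed rows with the offending row/column named —
nothing is silently dropped.

## Mid-parent heterosis

MPH% = (F1 − MP)·100/MP with F1 the unweighted mean of the two hybrid
family means and MP the unweighted mean of the two inbred family means.
Family means are plain means over individuals; no weighting by unequal n.
MPH is symmetric in the hybrids and in the inbreds and invariant to
rescaling the trait. Family comparisons use one-way ANOVA followed by
all-pairs Tukey HSD (statsmodels) at α = 0.05 (configurable); the compact
letter display is computed by insert-and-absorb over the adjusted
p-matrix, treating p ≤ α as a significant separation and breaking ties
alphabetically, so letter assignment is deterministic given the p-matrix.

On the published adult growth-table means the formula returns 12.95,
14.81, 18.16, 17.23 and 33.21 % for shell length, height, width, weight
and total weight. Four of the five round to the printed values; shell
height rounds to 14.8 where 14.9 is printed — the source's own rounding,
flagged here rather than absorbed. The source also prints shell-weight
MPH as 19.3 % in one place and 17.2 % elsewhere; this package follows the
growth table (17.2).

## Differential expression

Between two families, per gene: log₂ ratio of pseudo-shifted family means
(pseudo-value c = 0.25 FPKM or 0.5 counts, configurable, to stabilise
logs at zero) and a two-sided two-sample t-test on log₂(x + c) across
replicates — pooled variance by default, Welch optional — with
Benjamini–Hochberg FDR across genes. A gene is a DEG when
|log₂ ratio| > 1 and FDR ≤ 0.001 (both thresholds configurable). This is
a deliberate re-design: the original MA-plot random-sampling DEG caller
is replicate-free and non-transparent; a replicate-aware t-test matches
the triad t-test machinery used downstream and is fully testable.
Genes with zero variance in both groups get p = 1 (equal means) or p = 0
(unequal) by convention.

A triad DEG set is the intersection of the hybrid-vs-parent-1 and
hybrid-vs-parent-2 DEG sets, restricted to genes moving in the same
direction relative to both parents; direction-discordant genes are
excluded and reported separately. Whether the original analysis required
both-parent significance and concordance is not stated; the intersection
+ concordance rule is this package's documented choice, consistent with
single up/down counts per triad.

## Inheritance-mode classification

Inputs are summary statistics (mean, SD, n) per group, so classification
works identically from raw replicates or from published mean ± SD tables.
The mid-parent comparison group is a pseudo-group with mean (P1+P2)/2,
n = min(n₁, n₂) and SD = √((sd₁² + sd₂²)/4) — the variance of the average
of the two parental means carried back to a per-observation scale; the
source does not define this variance and this is one defensible reading.

Decision tree at α = 0.05 (two-tailed pooled t-test throughout):
p_mid > α → additive; otherwise, hybrid above the high parent with
p ≤ α → overdominance; below the low parent with p ≤ α → underdominance;
indistinguishable from exactly one parent → dominance toward that parent;
anything else → ambiguous. If the hybrid mean equals a parent mean
exactly, only the dominance branches are eligible. Parents are re-ordered
by mean internally, so the caller's parent order never matters.
"Nonadditive" means everything except additive (ambiguous counted as
nonadditive but reported separately), matching the arithmetic of the
published percentages (e.g. 69/79 = 87.3 %); percentages use the triad
DEG total as denominator (36/79 = 45.6 % fixes this).

## Enrichment

One-sided hypergeometric over-representation per term: p = P(X ≥ k) with
background N = expression-detected genes ∩ annotation map, gene-set size
n counted among annotated genes only, K the term's annotated background
genes, k the hits. Terms with K < 3 are skipped by default; BH-FDR across
tested terms. The test choice and the detected-gene background are
package decisions (the source states neither); ontologies are user input.

## qPCR

2^−ΔΔCt with amplification efficiency fixed at 2: per replicate
ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the calibrator family's
mean ΔCt per gene (calibrator defaults to inbred A); mean and SD are taken
over the per-replicate 2^−ΔΔCt values, so the calibrator's *geometric*
anchoring leaves its reported mean ≈ 1 (exactly 1 when replicates agree).
Concordance with RNA-seq compares the sign of every hybrid-vs-parent fold
change across platforms and reports the concordant fraction.

## Synthetic data

Phenotypes: individual values are Normal(family mean, cv·mean), truncated
at zero by resampling; the within-family distribution is an assumption
(only mean ± SD are reported for real data). Hybrid family means are set
to MP·(1 + MPH_target/100), with the reciprocal hybrids offset ±¼ of the
heterosis increment so their average hits the target F1. Defaults
reproduce the adult growth table: parental means per trait, target MPH
12.9–33.2 %, CVs 0.05–0.17, n = 50 individuals per family.

Expression: per gene a baseline mean is drawn uniformly from
`baseline_mean_range` (default 20–500 counts, the range of moderately
expressed genes at typical depth) and a mode is planted by exact
largest-remainder allocation of `mode_fractions` (default 90 % no-change).
Group means follow the mode: separation modes split the parents by
±effect_log2fc/2 in log₂ space (hybrid at mid-parent or at one parent);
over-/underdominance keep parents equal and move the hybrid by
±effect_log2fc. Counts are negative binomial with var = μ + αμ²
(default α = 0.05). Both hybrids share each gene's mode and the same
parental samples, mirroring the study layout. The generator does not
model library-size or GC biases, gene–gene correlation, or
parent-of-origin effects, so passing recovery tests demonstrates the
statistics' correctness, not robustness to those real-data features.

### What the calibration experiments show

With 1000 genes, effect_log2fc = 2, dispersion 0.01 and 3 replicates,
classification recovers over- and underdominant genes essentially
perfectly and planted-additive genes at ≈ 1 − α. Dominance-mode recovery
plateaus at ≈ 0.90–0.93 under these exact conditions: the
hybrid–mid-parent contrast for a dominance gene is only half the effect,
Poisson noise dominates the NB variance at counts of 20–500 even as the
dispersion parameter → 0, and ~α of dominance genes falsely reject
equality with their matching parent and fall into a neighbouring class.
Recovery is monotone in effect size and replicate count; raising
baselines or replicates lifts the dominance plateau, but the defaults are
kept at the realistic settings above rather than at settings chosen to
flatter the classifier.

## Numerical choices

* Pseudo-value c = 0.25 FPKM / 0.5 counts before logs.
* Degenerate t-tests: both SDs zero → p = 1 (equal means) else p = 0.
* FPKM = count·10⁹/(length·library size); FPKM input is accepted as
  given and never re-derived unless gene lengths are supplied.
* Output floats are written at 6 significant digits; write→read
  round-trips preserve values to that precision.
* All generators take a single integer seed; a fixed seed makes every
  table byte-reproducible.

## Problem sizes

The bundled tests and the reproduction script run on synthetic data sized
for a laptop: 300–2000 genes, 3 replicates, 20–400 individuals per
family, 20–400 simulation seeds per calibration experiment. These sizes
give standard errors comfortably inside the asserted bounds while keeping
the full suite at a couple of minutes.
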