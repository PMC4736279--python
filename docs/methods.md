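# Methods

## Scope and model

`tssbreadth` analyzes the *breadth* of the H3K4me3 chromatin mark around
transcription start sites (TSSs) and its association with differential
transcription between a control and a disease condition (modeled on SLE
monocytes). The analysis chain is:

1. **Coverage.** ChIP-seq reads are extended to 200 bp toward their 3' end
   (the approximate fragment size of a mononucleosomal ChIP library) and
   per-base coverage around each TSS is averaged into 41 bins of 50 bp
   spanning −1025..+1025 bp in the direction of transcription, so the 21st
   bin is centered on the TSS. A −1..+1 kb window at 50 bp yields 40
   intervals; the TSS-centered 41st bin is what makes the grid symmetric
   around the start site, hence the half-bin overhang of the window.
   Minus-strand profiles are mirrored so the last column is always the far
   downstream bin; without this flip the asymmetric (upstream/downstream
   extended) patterns would be meaningless.
2. **Normalization.** Each sample's background level is estimated as the
   median cell of its binned input-control matrix; the normalized value is
   log2(depth / background), so +1.0 and −1.0 mean exactly twice and half
   the background. Dividing each sample by its own input-derived background
   both removes library-size differences between samples and subtracts the
   input-measured background in log space. The exact between-sample
   normalization used for the original patient data is not published in
   detail; only the ±1 = 2-fold contract is treated as normative here. The
   group matrix is the mean of the per-sample log2 matrices.
3. **Region summaries.** Three regions are scored as means over the bins
   whose centers fall inside them: TSS (−250..+250 bp, 11 bins), upstream
   (−500..−400 bp, 3 bins) and downstream (+600..+700 bp, 3 bins). The two
   classification statistics are the upstream−TSS and downstream−TSS
   differences. The source analysis gives two versions of the upstream
   window (400–500 bp upstream in its processing description, −400..−300 bp
   in one figure); the processing coordinates are the default and
   `upstream_window="figure"` selects the other. The discrepancy is
   surfaced, not resolved.
4. **Mixtures and classification.** All three decision statistics are
   bimodal, and each is modeled as a two-component univariate normal
   mixture fitted by EM (written in-house; `sklearn` serves only as an
   independent cross-check in the tests). A TSS is *marked* when the
   posterior of the upper component of the TSS-region mixture is ≥ 0.95.
   On each difference axis, fitted over marked TSSs only, the high-mean
   ("small drop") component means the mark is *extended* on that side;
   calls require posterior ≥ 0.8 ("extended") or ≤ 0.2 ("not extended")
   per axis, otherwise the TSS stays unclassified. The per-axis confidence
   of 0.8 is not stated in the source; it was chosen once as the value
   that leaves an intermediate band of genuinely ambiguous sites and is
   exposed in the configuration. Labels: neither side extended →
   narrow peak; upstream only → upstream extended; downstream only →
   downstream extended; both → broad symmetric.
5. **Association statistics.** Expression level per pattern is compared to
   the unclassified reference group by the % difference of linear-scale
   means and a two-sided Wilcoxon rank-sum test (normal approximation with
   tie correction above group size 50, exact below). Between-sample
   variance is detrended by a Loess fit (span 0.5) of log variance on mean
   log2 expression. Pattern × differential-expression association uses the
   cross-product odds ratio with two-sided Fisher exact p and log-OR
   standard error √(Σ 1/cell); a zero cell triggers the Haldane +0.5
   correction for the OR and SE only, never for the exact p. Gene-set
   overrepresentation uses the upper-tail hypergeometric test against the
   marked-TSS background, the cross-product OR of the 2×2 background
   partition (enrichment-only upper tail, matching the "relative
   enrichment" framing; the conditional-MLE OR is not used) and
   Benjamini–Hochberg FDR across sets. Genes whose multiple TSSs carry
   different patterns are excluded before gene-level association.
6. **Dose–response.** Per-gene % H3K4me3 change per region is computed on
   the linear background-relative scale, 100·(2^Δlog2 − 1), because the
   effect sizes of interest are phrased in percent change. Each region's
   change is residualized by OLS on the other two regions' raw changes with
   the grand mean added back, so "increased/decreased" keeps its sign
   meaning for the fraction-increased summary. The response curve bins
   genes by integer % change (−10..+10) and fits an unweighted
   least-squares slope of the bin means against bin centers over 1–10 %.
   Zero-centered region-change summaries for external gene lists subtract
   the all-gene mean per region before averaging within each list
   (one-sample t standard errors over genes; whether error bars should run
   over genes or samples is not specified in the source — over genes is
   used).
7. **Motifs.** Promoter windows (−1..+1 kb, TSS-oriented) are scanned with
   PWM log-odds scores (uniform background, pseudocount 1e-3, via
   Biopython's PSSM machinery) on both strands; a match requires ≥ 80 % of
   the motif's maximum achievable score, reverse-strand hits are reported
   at the forward coordinate, and a position matching on both strands is
   counted once. Per-pattern positional densities (50 bp bins) are divided
   by the marked-TSS background density; the "enriched" flag requires an
   overall density ratio ≥ 1.2. The original match criterion and motif
   collection are unspecified, so absolute motif counts are treated as
   non-reproducible; only the machinery is provided.

## Agreement between classifications

Two pattern call sets are compared on the TSSs holding a four-pattern label
in both: percent agreement is the diagonal fraction of the 4×4 table and
Cohen's κ = (p_o − p_e)/(1 − p_e) corrects for chance agreement from the
marginals. The p-value is the one-sided asymptotic normal test for κ > 0
with the null standard error
√(p_e + p_e² − Σᵢ p_{i·}p_{·i}(p_{i·}+p_{·i})) / ((1−p_e)√n).

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
under which the pipeline is validated. Defaults encode the effect sizes the
analysis is designed to detect:

| parameter | default | meaning |
|---|---|---|
| `pattern_proportions` | 0.0515 / 0.1854 / 0.16995 / 0.10815 / 0.485 | narrow, upstream-, downstream-extended, broad, unmarked; conditional on the four patterns this is exactly 0.10 : 0.36 : 0.33 : 0.21, and the 48.5 % unmarked mass reproduces a cohort in which roughly half of all TSSs carry no mark |
| `signal_height` | 2.0 log2 units | marked plateau over background (4×) |
| `background_depth` | 10 reads/bp | flat Poisson background and input level |
| `de_prob_by_pattern` | 0.026 / 0.12 / 0.225 / 0.13 (unmarked 0.10) | P(significantly increased transcription) per pattern; derived by odds algebra so the marginal odds ratios under the classified proportions are 0.139 (narrow) and 2.371 (downstream extended) |
| `persist_prob` | 0.948 | probability a non-narrow pattern keeps its label in disease; narrow peaks and unmarked sites never switch, and switchers move uniformly to one of the other two non-narrow patterns |
| `beta_down` | 1.5 %/% | transcription response per 1 % downstream H3K4me3 change (`beta_tss` = `beta_up` = 0: only the downstream region drives transcription directly) |
| `frac_increase_by_region` | 0.788 / 0.550 / 0.471 | P(positive region change) for DE-up genes (downstream, TSS, upstream); mirrored for DE-down genes, centered for the rest |
| `expr_multiplier_by_pattern` | 1.0 / 1.8 / 2.51 / 1.9 (unmarked 1.0) | linear expression factor vs the unclassified reference; 2.51 gives the +151 % downstream-extended premium |

Archetype elevation intervals are aligned to bin boundaries (narrow
−275..+275; upstream extended from −525; downstream extended to +675) so
the plateau covers bin centers out to −500 and +650 bp. Fragments of 200 bp
are placed with piecewise-constant center rates equal to depth/200, giving
expected coverage equal to the 200 bp moving average of the archetype;
each fragment is observed as a 50 bp read from a uniformly chosen end.
Disease samples apply each gene's true % region changes as depth
multipliers over whole thirds of the window (boundaries ±350 bp) so
fragment-size blur cannot leak a neighboring region's multiplier into the
scored bins.

Region changes are normal with the mean set by σ·Φ⁻¹(p) so the increase
probabilities hold exactly; transcription change is the linear response
plus Gaussian noise (σ = 3 %), with the noise of DE genes resampled from
the sign-consistent truncated normal so DE flags always agree with the
sign of the change. The truncation leaves the marginal region-change
distributions untouched. Two consequences are documented rather than
hidden: with `beta_down = 0` exact decoupling holds only among non-DE
genes (DE genes keep a weak association through their flag), and the
binned slope estimator carries a small attenuation (≈ −0.02 at the default
conditions) from bin-composition effects and the truncation.

Inter-region coupling defaults to zero (region changes independent given
the DE status); a `region_coupling_sd` knob adds a shared component across
the three regions for exercising the residualization machinery. Reported
p-values for synthetic DE calls are drawn annotations consistent with the
flags (log-uniform below 0.01 for DE genes, uniform above for the rest),
not recomputed tests — with six samples per group a recomputed test would
not reliably reproduce the planted flags.

What the generator does *not* emulate: fragment-size variability, GC and
mappability bias, overdispersed (negative-binomial) counts, correlated
biological replicates, multi-TSS genes, genome-scale background outside
the promoter windows, and realistic promoter sequence composition. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to every artifact of real
ChIP-seq data. The original study's depth-noise parameters are unpublished,
so the defaults are plausible rather than calibrated.

## Numerical choices

- log2 values are floored at −3 so zero-depth bins stay finite and the EM
  fits remain stable.
- EM: median-split initialization, 5 restarts (random soft responsibilities
  thereafter), relative log-likelihood tolerance 1e-8, component SD floor
  1e-9 × data scale; a fit collapsing below the floor on every restart
  raises a degenerate-fit error. Components are reported in ascending-mean
  order; the log-likelihood trace is asserted non-decreasing in the tests.
- Response-curve bins are nearest-integer bins ([j−0.5, j+0.5)); empty bins
  are omitted from the slope fit.
- Residualization falls back to a single-regressor fit when the regressors
  are collinear, with a warning.
- Seeds: every stochastic step takes an explicit seed or derives one from
  the generator config; identical config + seed reproduces byte-identical
  outputs.

## Problem sizes

The bundled analysis scripts and tests run at desk scale: 500–600 TSSs with
six samples per group for the profile-level pipeline (read-level simulation
of ~2M reads), and 5000–8399 genes for the label/expression-level cohorts.
These sizes put every Monte-Carlo standard error well inside the tolerances
asserted by the tests while keeping a full run in seconds.

## Known limitations

- The between-sample normalization and background estimator of the original
  patient pipeline are reproduced only through the ±1 = 2-fold contract.
- Narrow-peak × DE-up association involves a ~22-gene cell at the cohort
  size used, so single-cohort odds ratios for it carry a log-SE of ~0.22;
  recovery tests pool replicate cohorts for a sharper comparison.
- Motif match counts depend strongly on the unstated score threshold; the
  80 %-of-max default is a convention, not a reproduction.
- The classifier assumes both difference statistics are well described by
  exactly two normal components; heavy-tailed or trimodal real data would
  need a model extension.
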