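# Methods

`translight` implements the computational core of a high-content screen for
mRNA-selective translation modulators, end to end on synthetic data with
known ground truth.  This note documents the models, the statistical
procedures, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Codon-pair signatures

A two-tRNA FRET reporter is selective for one mRNA only if its consecutive
in-frame codon pair is rare transcriptome-wide and the target carries most
of the ribosomal traffic across that pair.  We model the occupancy of
transcript *t* at pair *c* multiplicatively,

    O_t(c) = A_t · r_t · n_{t,c},

with abundance `A_t` (arbitrary expression units such as TPM), relative
ribosome density `r_t`, and in-frame occurrence count `n_{t,c}`, and define

    SNR(c) = O_target(c) / Σ_{t ≠ target} O_t(c).

The denominator is the **sum** over competing transcripts — the reporter
signal competes against the *total* off-target occupancy, not the average —
with a mean-denominator variant available.  A per-codon-pair dwell-time
weight table can be supplied; the default weight is 1, under which dwell
times cancel in the ratio.  Pairs unique to the target have no competing
signal; their SNR is the `inf` sentinel and ranks above all finite scores,
with ties broken toward lower transcriptome prevalence, then lexicographic
pair order.  Only frame-0 pairs are counted; overlapping occurrences count
separately; counting is per transcript (one canonical transcript per gene,
duplicates rejected).

Anticodons are reported as the standard 5'→3' reverse complement in the
RNA alphabet (CAA → UUG).

## Corrected FRET and screen statistics

Per cell the assay records donor (I_DD), acceptor (I_AA) and raw FRET
(I_DA) channel intensities.  Sensitized emission is recovered as

    cFRET = I_DA − β·I_DD − α·I_AA,

with β and α estimated as median ratios over donor-only and acceptor-only
control cells (medians because segmentation outliers are routine).
Negative cFRET values are retained — clamping would break the symmetry of
the null distribution.  Normalized cFRET divides by total labeled-tRNA
signal I_DD + I_AA (NaN when the denominator is zero; such cells are
excluded from intensity summaries).

Wells are summarized into a fixed 10-feature profile: median and mean
normalized cFRET, median raw cFRET, median I_DD, median I_AA, median
total-tRNA signal, FRET-positive cell fraction, cell count, normalized-cFRET
interdecile range, and transfection-pass fraction.  The composition is
configurable; the transfection and FRET-positivity cut-offs default to
plate-derived quantiles (10th percentile of total signal; plate-median
normalized cFRET) so the fraction features vary between wells.

The vehicle (DMSO) reference population H₀ is modeled robustly: per-feature
median location, 1.4826·MAD scale (features with zero scale are dropped and
recorded), and a correlation matrix of the robust z-scores shrunk as
R ← (1−λ)R + λI with ridge λ = 0.05 to guarantee invertibility.  The screen
score of a well profile x is the Mahalanobis distance

    S = sqrt(zᵀ R⁻¹ z),   z = (x − m) / s,

a deviation in SD units; it is invariant under affine rescaling of
individual features and reduces to the root-sum-of-squares of z under
R = I.  The aggregated p-value is either the parametric upper chi-square
tail of S² with k degrees of freedom (exact under multivariate normality)
or the empirical plug-in tail of the H₀ score distribution,
p = (1 + #{S_H0 ≥ S})/(n+1), which is distribution-free; the empirical
route is the default and requires at least 99 reference wells.  Hits
require S > 4 **and** p < 0.01; the reference is per-plate by default.
Well medians are not exactly multivariate normal, so the parametric tail is
approximate; the empirical tail is exact by construction, which is why it
drives the null-calibration guarantees.

## RBP binding-density enrichment

Coordinates are 0-based half-open internally; GTF (1-based closed) is
converted on read and BED6 consumed natively.  Each binding site is
assigned to the gene/region with maximal overlap length; ties break
3'UTR > 5'UTR > CDS > intron (favoring the regulatory regions the analysis
targets); sites matching no region on their strand are intergenic.
Introns are derived as gaps between exons.  Genes with several transcripts
keep the one with the longest 3'UTR.

For a regulated (DE) gene set, each RBP's 3'UTR site density (sites/kb) in
the DE genes is compared with its density over all annotated genes; the DE
genes remain in the background by default (the comparison is against the
transcriptome, as in an enrichment against genome-wide site distributions),
with an exclusion flag available.  Significance is a one-sided binomial
test of the DE site count among the RBP's 3'UTR sites against the length
proportion kb_DE/kb_background, BH-corrected across RBPs.  When the DE set
is a small fraction of the transcriptome — the realistic regime — the
include-DE background biases the fold only marginally (a planted 3× fold
on a 3% DE set is estimated around 2.8×).

Motif calls are deliberately simple and configurable: AU-rich elements are
counted as possibly-overlapping AUUUA pentamers (T ≡ U); pyrimidine-rich
stretches as a sliding 20-nt window with ≥ 80% C/U.  UpSet-style
intersection counts are exclusive (each universe element counted once
under its exact combination; counts always sum to the universe size).
RBP functional categories (stress granule, P-body, m6A reader, splicing)
ship as a static TSV configuration table rather than live ontology
queries.

## CETSA isothermal dose-response

The compressed-format assay yields, per protein, soluble fraction relative
to vehicle (= 1.0) at seven concentrations (0.1–100 µM) in two replicates,
temperature challenge already pooled upstream.  Per protein we fit the
log-logistic shift

    y(c) = 1 + A / (1 + (EC50/c)^h)

by bounded least squares from multiple starts (|A| ≤ 2, EC50 within a
decade of the tested range, h ∈ [0.3, 5]).  Significance against the flat
model (one fitted mean) is an F-statistic.  Under the flat null EC50 and h
are unidentified — only the amplitude is an effective extra parameter — so
the statistic is referred to F(1, n−3) rather than F(2, n−3); in null
simulations the nominal-df version rejects at ~1.3% for α = 0.05 while the
1-df version sits at ~4–5%, and the BH-adjusted target rule
(|A| > 0.2, adjusted p < 0.05) yields essentially no false targets on flat
lysates.  Non-convergent fits fall back to the top-concentration mean
shift with a one-sample t-test.

## Translational efficiency (simplified ΔTE)

Paired mRNA and ribosome-protected-fragment (RPF) count matrices are
normalized by median-of-ratios size factors (geometric-mean reference over
genes positive in all samples; total-count fallback).  Per assay and gene,
log2 fold-change is computed on normalized group means with a 0.5
pseudo-count, and its Wald statistic uses a delta-method standard error
under a negative-binomial variance μ + αμ² with α estimated per gene by
method of moments (floored at 1e−8), referred to a t distribution with
n₁+n₂−2 degrees of freedom — the normal reference is visibly
anticonservative at three replicates per arm (~11% rejections at α = 0.05
in null simulations versus ~4–5% for the t).  A label-permutation p-value
is available as an alternative.  TE is the RPF/mRNA ratio, so on the log2
scale ΔTE = lfc_RPF − lfc_mRNA identically.  Genes are classified
mrna_only / rpf_only / both / none at |lfc| > 1 (2-fold) and p < 0.05 per
assay, mirroring volcano-plot cut-offs.  This is a deliberate
simplification of negative-binomial GLM frameworks; matrices are plain TSV
and exportable to external tools.

## Dose-response panel

Viability curves (10 points, 3.16-fold dilutions from 30 µM) are fit with
a four-parameter logistic, y = bottom + (top−bottom)/(1 + (c/EC50)^s),
s > 0, initialized from the data extremes and midpoint crossing, EC50
bounded within a decade of the tested range; the reported hill slope is −s
(negative for inhibition).  pEC50 = −log10(EC50 in molar).  Two named
responsiveness rules are exposed: `methods` (EC50 < 6 µM and hill in
[−3.5, −1]; the default) and `steep` (pEC50 > 5.5 and hill < −3.5).  They
disagree by construction on steep potent curves (e.g. EC50 = 2 µM,
hill = −5); the rule used is recorded in every output, and neither is
treated as the correct one.

Group contrasts use Welch's t-test (Satterthwaite degrees of freedom) and
Tukey–Kramer comparison circles: with pooled SD s, error df ν and
studentized-range quantile q(α, k, ν), each group's circle has radius
(q/√2)·s/√n_i, and two groups differ when their center distance exceeds
sqrt(r_i² + r_j²) — algebraically identical to the Tukey–Kramer HSD
criterion, which the implementation matches decision-for-decision against
an independent HSD oracle in the tests.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of parameters and seed (byte-identical
reruns), and emits a truth table whose positives are exactly the entities
carrying a planted effect.  A single global seed is split into per-stage
substreams.

* **Transcriptome** — random CDS sets scrubbed of accidental planted-pair
  occurrences, with the pair planted into a chosen number of transcripts
  and one designated target given elevated abundance × density (default
  boost 8, echoing a high-single-digit signal-to-noise regime).  Codon
  usage is uniform — no real codon bias, GC structure or homology.
* **Screening plates** — cell-level feature vectors mu + b_w + e_c with
  multivariate-normal well effects (SD 0.3) and cell noise (SD 1) sharing
  one correlation matrix; ~200 cells/well (Poisson).  Active-well shifts
  are expressed in SD units of the null *well-median profile*
  (sqrt(well² + cell²·(π/2)/n)), the scale on which screen scores live.
  Channel-level plates (I_DD/I_AA/I_DA with bleedthrough β = 0.25,
  α = 0.10, FRET efficiency ~0.15 reduced in active wells) exercise the
  cFRET path; no spatial plate effects, edge effects or segmentation
  artifacts are simulated.
* **eCLIP sites** — Poisson site counts per 3'UTR at a uniform per-kb
  density (default 4/kb on a compact ~1 Mb synthetic genome; chosen for
  stable density estimates at desk scale, higher than genome-wide
  averages), with enriched RBPs multiplying density inside DE-gene 3'UTRs.
  No crosslink-position biases, no peak-width/score structure.
* **CETSA** — flat non-targets at 1.0, targets following the log-logistic
  shift, multiplicative Gaussian noise (CV 5% default).
* **Counts** — negative binomial with variance μ + αμ² (α default 0.05),
  gene means log-normal around 300; stabilized-but-repressed genes get
  +1.5 log2 mRNA with unchanged RPF.  No gene length, GC or batch effects.
* **Dose panel** — responsive lines draw EC50 ∈ [0.3, 3] µM and hill
  ∈ [−3.2, −1.2] (inside the default responsiveness window),
  non-responsive lines EC50 ∈ [15, 120] µM with shallow slopes;
  CRISPR-style dependency scores are shifted −0.4 in the responsive group.

Passing tests therefore demonstrate statistical correctness and calibration
of the procedures under their stated assumptions — not robustness to the
biological and technical structure of real screens (codon bias, plate
effects, crosslink artifacts, batch variation), which the generators do not
contain.

## Numerical and design choices

* Robust location/scale (median, 1.4826·MAD) throughout the screen model,
  because screening plates contain outlier wells by design.
* Ridge 0.05 on the H₀ correlation guarantees invertibility even with few
  reference wells; configurable.
* Empirical aggregated p-values use the plug-in (1+m)/(n+1) estimator, so
  the smallest attainable p is 1/(n+1).
* Curve fits use multiple starting points with bounds; degenerate inputs
  (flat curves, all-zero wells, empty controls) return flagged results or
  raise typed errors rather than propagating NaN.
* Concentrations are handled in µM in tables (the assay's unit); pEC50
  converts to molar.
* Sizes used in the shipped checks (5,000 null wells; 1,000 CETSA
  proteins; 4,000 genes with 150 affected; 500-gene genomes over 20
  seeds; 1,000 Tukey datasets) were chosen so Monte Carlo error is small
  relative to each guarantee while a full run stays in the minutes range
  on one CPU.

## Known limitations

* The ΔTE statistic is not a replacement for negative-binomial GLM
  analyses; it has no shrinkage, no cooks-distance outlier handling, and
  per-gene dispersions at n = 3 are noisy (the t reference absorbs most,
  not all, of that noise).
* The CETSA F-test assumes roughly Gaussian residuals on the soluble
  fraction; heavy-tailed proteomic noise would need the permutation or
  rank alternatives this package does not implement.
* Region assignment uses one canonical transcript per gene; overlapping
  genes on the same strand resolve by overlap length and may mis-assign
  sites in dense loci.
* The parametric aggregated p-value is only as good as the multivariate
  normality of well profiles; use the empirical route when enough vehicle
  wells exist (the default).
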