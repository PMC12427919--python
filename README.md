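# translight

Analytics for high-content screens that look for **mRNA-selective
translation modulators** — compounds that silence translation of one
oncogenic transcript (the motivating case is *MYC*) without touching its
mRNA level.  The package implements the full computational chain of such a
screen and exercises it end to end on synthetic data with known ground
truth:

1. **Codon-pair signatures** — find a consecutive in-frame codon pair rare
   enough across the transcriptome that FRET between two labeled tRNAs
   reports translation of (mostly) one target mRNA.  Occupancy is modeled
   as O_t(c) = A_t·r_t·n_{t,c} (abundance × ribosome density × occurrence
   count) and pairs are ranked by SNR(c) = O_target/Σ_background.
2. **Corrected-FRET screen statistics** — bleedthrough correction
   cFRET = I_DA − β·I_DD − α·I_AA, robust 10-feature well profiles, a
   DMSO reference population (median/MAD location-scale, ridge-shrunk
   correlation R), screen score S = √(zᵀR⁻¹z) in SD units, aggregated
   p-values (chi-square or empirical tail), hits at S > 4 and p < 0.01.
3. **RBP binding-site enrichment** — assign eCLIP-style peaks to
   5'UTR/CDS/3'UTR/intron, test per-RBP 3'UTR site-density enrichment of a
   regulated gene set against the transcriptome background (one-sided
   binomial, BH), scan AU-rich/pyrimidine-rich motifs, UpSet-style
   intersection counts.
4. **Downstream hit characterization** — CETSA isothermal dose-response
   fits y = 1 + A/(1+(EC50/c)^h) with target calling at |A| > 0.2 and
   adjusted p < 0.05; simplified ΔTE = lfc_RPF − lfc_mRNA analysis with
   2-fold/p < 0.05 classification; 4PL viability fits with pEC50 and
   named responsiveness rules; Welch's t-test and Tukey–Kramer comparison
   circles for group contrasts.
5. **Synthetic data generators** for every input above, each emitting a
   machine-readable truth table, so calibration and recovery are testable
   without any external download.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Run the full pipeline on generated data:

```bash
translight demo --seed 1 --outdir demo_out
```

This writes each stage's inputs (CDS FASTA + expression TSV, per-cell
channel table, GTF + BED6 sites, CETSA/count/viability tables), its result
tables (`signature_ranking.tsv`, `screen_hits.tsv`, `rbp_enrichment.tsv`,
`cetsa_volcano.tsv`, `te_results.tsv`, `panel_fits.tsv`, …) and a
`report.json` whose stage summaries for seed 1 read:

```
signature: planted_pair_prevalence 6, top_pair TCG|CAA, planted_pair_snr 3.13
screen:    beta_donor 0.2503, alpha_acceptor 0.0994, n_hits 8,
           hit_sensitivity 1.0, false_hits 0
enrich:    planted_recovery 1.0 (RBP00-02), mean_planted_fold 2.48
cetsa:     6 targets called, target_recovery 1.0, no false targets
te:        sensitivity_mrna_only 0.90, null_misclassification 0.0
panel:     15/43 lines responsive, responsive_recovery 0.92,
           Welch dependency t = -4.50, p = 0.00016
```

Reading the numbers: the planted signature pair `TCG|CAA` occurs in 6 of
300 synthetic transcripts and tops the ranking for the designated target;
the bleedthrough coefficients recover the generator's β = 0.25, α = 0.10;
all 8 spiked compound wells are called hits with no false positives among
120 DMSO wells; the three RBPs planted at 3× 3'UTR density are all
BH-significant (fold estimated ≈ 2.5 against a background that includes
the regulated genes); all 6 planted CETSA targets at amplitude 0.4 are
recovered; 90% of stabilized-but-repressed genes are classified
`mrna_only` (mRNA up ≥ 2-fold, ribosome footprints flat — translational
efficiency down); and the responsive cell-line group shows the planted
dependency shift by Welch's t-test.  Re-running with the same seed
reproduces every file byte-for-byte.

The same stages are available on your own files via `translight sig rank`,
`translight screen`, `translight enrich` and `translight assay
cetsa|te|panel`; every threshold defaults to the standard hit rule of the
corresponding stage (see `--help`).

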