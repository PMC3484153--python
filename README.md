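# sirnakit

A toolkit for designing small interfering RNAs (siRNAs) and analysing how
well they silence their targets. It covers the full desk-side workflow of
an endogenous RNAi knockdown screen:

- **Design** — enumerate every 21-nt target window of an annotated mRNA,
  score it with a trainable linear model over guide-strand features
  (position-specific nucleotides plus 1–3-mer motif counts), correct the
  score for the target site's location (5′UTR / CDS / 3′UTR) and its
  distance from the transcript 5′ end, then filter (score > 80 %, CDS
  only, no polynucleotide tracts, no off-targets) and pick well-spaced
  candidates.
- **Off-target screening** — a bit-parallel shift-add matcher (the
  Baeza-Yates/Gonnet counting scheme, per-position saturating counters
  packed into one integer) finds every alignment of a siRNA in a
  transcript databank within *k* mismatches (default 3), with exact
  mismatch positions; guide seed complements (positions 2–8) are profiled
  against 3′UTRs, miRNA-style.
- **Quantification** — knockdown from qPCR cycle-threshold tables using
  the efficiency-corrected comparative-Ct ratio
  `Q = E_t^(Ct_t,cal − Ct_t,s) / E_ref^(Ct_ref,cal − Ct_ref,s)`,
  with dual reference-gene normalization (geometric-mean pooling),
  replicate averaging on the log₂ scale, positive-control run validation
  and HIGH (≥ 70 %) / MODERATE (50–70 %) / INEFFICIENT (< 50 %) grading.
- **Efficacy analysis** — a thirteen-covariate linear model of measured
  efficacy (score, gene, position, location, off-target and seed counts,
  polynucleotide tract, transcriptome hits, exon context, accessibility)
  with sequential ANOVA, a reduced `efficacy ~ gene + location + position`
  model, and a within-gene positional test.
- **Synthetic data** — generators for random transcriptomes with UTR/CDS/
  exon structure, planted near-match off-target sites, Ct plates with
  replicate noise, and efficacies drawn from an additive generating model
  (gene offsets + location offsets + positional slope + Gaussian noise),
  so the whole pipeline is testable without downloads.

The central empirical model is the reduced linear fit

```
efficacy_i = μ + gene(i) + location(i) + β · position_i / 100 + ε_i
```

with defaults β = −1 % per 100 bp and CDS/3′UTR sites more potent than
5′UTR sites by +39 / +13 points — potency falls as the target site moves
away from the transcript 5′ end, and UTR sites silence less well.

## Worked example

`examples/` holds one short script per capability. Fitting the covariate
models on one simulated 88-siRNA screen
(`python examples/efficacy_analysis.py`) prints:

```
sequential ANOVA (significant terms at 5%):
  C(gene)        F =   31.80  p = 5.94e-19
  C(location)    F =  112.96  p = 3.45e-22
  position_bp    F =   61.08  p = 5.17e-11

reduced model (refs: gene BCL2L1, location FIVE_UTR):
  positional slope: -1.08% per 100 bp (p = 9.1e-12)
  CDS vs 5'UTR:     +37.3% (location p = 7.8e-24)
  3'UTR vs 5'UTR:   +16.5%
```

Of the thirteen candidate covariates only the target gene, the target-site
location and its position come out significant — exactly the three effects
the generator plants — and the reduced model recovers the planted decay
(−1 %/100 bp) and location contrasts (+39/+13) up to sampling noise in a
single screen. `python examples/positional_recovery.py` repeats the fit
over 25 screens and shows the averages converge on the generating values.

## Command line

```bash
sirnakit design    --fasta t.fa --annot t.tsv --training-tsv pairs.tsv --out cand.tsv
sirnakit offtarget --sirna-tsv cand.tsv --databank bank.fa --mismatches 3 --out ot.tsv
sirnakit quantify  --ct-tsv ct.tsv --target-gene CSNK2B --normalizers 36B4,HPRT --out kd.tsv
sirnakit analyze   --table-tsv covariates.tsv --out-prefix results/analysis
sirnakit simulate  transcriptome --seed 1 --out-dir fixtures/
sirnakit run       --config run.cfg
```

All reports are TSV with commented provenance headers (version, config
hash, seed); identical configs reproduce byte-identical outputs. See
`docs/methods.md` for the models, conventions and their limitations.
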