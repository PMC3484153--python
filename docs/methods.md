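# Methods

## Coordinates, strands and regions

All interface coordinates are 1-based inclusive, measured from the
transcript 5′ end. Sequences are normalized to uppercase DNA on read
(U → T); guides and sense strands are emitted as RNA only in reports.
A transcript is partitioned into 5′UTR `[1, cds_start−1]`,
CDS `[cds_start, cds_end]` and 3′UTR `[cds_end+1, length]`. A 21-nt site
is labelled with the region holding the majority of its bases; exact ties
break toward the more 3′ region (a site must be labelled with exactly one
region, and boundary-spanning behaviour has to be fixed by convention —
the 3′ tie-break is ours). The guide (antisense) strand is the reverse
complement of the target window, numbered 5′→3′; guide position *p* pairs
with window position 22 − *p*.

## Efficacy scoring model

Predicted extinction (%) is an affine function of a 168-dimensional
encoding of the 21-nt guide: 84 position × nucleotide indicators and 84
counts of every 1-, 2- and 3-mer. The k ≤ 3 motif inventory keeps the
design matrix well-conditioned at screen scale (hundreds of training
pairs) while still covering the dinucleotide/trinucleotide motifs that
sequence-based efficacy predictors rely on. The default estimator is
ridge regression (closed-form, deterministic; `regularization` is the
ridge penalty λ, default 1.0); lasso is available as an option.
Predictions are clipped to [0, 100]. Exact recovery of a planted linear
model from noise-free data as λ → 0 is part of the test suite.

## Positional correction

`corrected = clip(base + location_offset[region] + slope × (start−1)/100, 0, 100)`

with defaults slope = −1.0 % per 100 bp and location offsets expressed
against the CDS at position 1 as the reference: 5′UTR −39, CDS 0,
3′UTR −26 (i.e. CDS and 3′UTR sites are more potent than 5′UTR sites by
39 and 13 points). The correction's functional form — additive on the
percent scale — is our choice; the fitted effects it encodes come from
the covariate analysis below. Position is measured from the transcript
5′ end by default; a start-codon-relative variant can be had by shifting
`start` by `cds_start − 1` before calling, since both definitions differ
only by a per-gene constant that the gene term absorbs in the analysis
model. The selection threshold ("> 80 % predicted") is strict and applies
to the base score, with both scores reported.

## Off-target matcher

The matcher implements the shift-add counting scheme: for a pattern of
length *m* ≤ 32, one mismatch counter per pattern position is packed into
a single integer, B = ⌈log₂(k+1)⌉ + 1 bits each. Per text character the
state is shifted by B and a precomputed per-symbol mismatch mask is
added; a counter whose high (saturation) bit fires is zeroed and recorded
in a sticky overflow register shifted in lockstep, so counts never carry
into a neighbouring counter. An alignment ending at text position *j* is
a hit iff its full-pattern counter never saturated and its final value is
≤ k; mismatch positions are then read off by direct comparison of the
window. Equality with a naive sliding-window Hamming scan — including
positions — is asserted on thousands of random instances.

Scanning convention: the 21-nt **sense** sequence is the pattern (a
transcript that near-matches the sense strand is a potential cleavage
target of the guide); a 19-nt-core scan can be had by passing a trimmed
pattern. The per-transcript off-target count is the number of distinct
transcripts with ≥ 1 hit; per-position hits are retained in the hit list.
Seed profiling takes the reverse complement of guide positions 2–8 as the
mRNA-side site (the miRNA seed-match convention) and counts exact,
possibly overlapping occurrences per 3′UTR, classing UTRs by 1 / 2 / ≥ 3
occurrences; a strict-identity mode (matching the heptamer itself) is
provided because either reading of "identity between mRNA and siRNA
seed-regions" is defensible.

## qPCR quantification

Per replicate and normalizer,
`q = E_t^(Ct_t,cal − Ct_t,rep) / E_n^(Ct_n,cal − Ct_n,rep)`, where
calibrator Cts are replicate-averaged, E defaults to 2.0 and is a
per-gene user input. Replicate ratios are averaged on the log₂ scale
(Ct noise is additive there, making the estimator unbiased for log₂ q —
verified by simulation); with two normalizers the per-normalizer ratios
are pooled by geometric mean. Dispersion is reported as the SD of
per-replicate log₂ q, NaN for single replicates. This log-scale
aggregation is a deliberately simple estimator: it does not model shared
run/plate structure between estimates, only replicate noise. Run
validation requires the positive-control siRNA to reach 80 % knockdown by
default (70 % is a supported variant, as both thresholds are in use).
Knockdown = 100 × (1 − q); grading is ≥ 70 HIGH, [50, 70) MODERATE,
< 50 INEFFICIENT, with negative knockdown (apparent up-regulation)
graded INEFFICIENT.

## Covariate analysis

The covariate table has one row per siRNA with thirteen candidate
predictors and the measured efficacy (allowed range [−50, 100] to admit
noise-driven apparent up-regulation). The full model is an OLS fit with
gene and location as factors; significance is judged by **sequential
(type-I) ANOVA in the fixed covariate order** (score, gene, position,
location, off-targets, polynucleotide tract, transcriptome hits, seed
classes, exon length, junction, accessibility), with a marginal (type-II)
option. Sequential sums of squares add to the total sum of squares, which
the tests assert. One structural note: the seed-match total `seed_n_seqs`
equals the sum of the three hit-class counts by construction, so it is
exactly aliased with them; it stays in the table as a derived column but
the model includes only the three class counts. Missing accessibility
drops that covariate with a log note rather than being imputed.
Rank-deficient designs are an error naming the aliased columns.

The reduced model `efficacy ~ gene + location + position` is refit with
BCL2L1 and the 5′UTR as reference levels, reporting gene offsets,
location contrasts, the slope per 100 bp, per-term p-values and fitted
values for measured-vs-fitted plots. The within-gene positional test is a
simple regression of efficacy on position over one gene's CDS sites
(two-sided slope test); fewer than 4 usable records is "not testable",
never p = 1.

## Synthetic generating model

`efficacy = 45 + gene_offset + location_offset + slope·(position−1)/100 + N(0, 10)`,
clipped to [−50, 100]. Defaults: gene offsets (vs BCL2L1) HDAC6 −22,
ERCC2 −11, ERCC1 +7, CSNK2A1 +9, CSNK2A2 +10, CSNK2B +8, HIF1A 0;
location offsets (vs 5′UTR) CDS +39, 3′UTR +13; slope −1 % per 100 bp;
noise SD 10 points; baseline 45 chosen so typical CDS sites land in the
60–90 % band a successful screen reports. The synthetic transcriptome
uses the eight screened genes' real total/CDS lengths and exon counts
(transcripts 1128–4099 nt) with uniform-random sequence; the non-coding
length is split 25 % / 75 % between the 5′ and 3′ UTRs, reflecting that
mammalian 3′UTRs are typically several-fold longer. Per-gene siRNA counts
(12, 10, 10, 10, 9, 15, 9, 13 = 88) match the screen layout; sites are
drawn uniformly over each transcript.

What the generator does *not* emulate: realistic base composition or
codon usage, secondary structure, shared plate/run error structure,
thermodynamic asymmetry of real guides, or any sequence-dependence of
efficacy beyond the planted positional/location/gene effects. Passing the
recovery tests therefore demonstrates that the fitting pipeline is
unbiased and calibrated for the planted effects under the screen's
layout — not that those effects hold in new wet-lab data.

## Simulation studies and problem sizes

Parameter recovery refits the reduced model on 200 independent synthetic
screens (88 siRNAs each; ~17,600 records overall) and compares the mean
recovered slope and CDS contrast with the generating values within three
Monte-Carlo standard errors; 200 repetitions put those standard errors
near 0.014 (%/100 bp) and 0.28 (%). Type-I calibration fits the full
model on 1000 pure-noise screens and checks each term's rejection rate at
α = 0.05. Matcher validation uses 1000 random instances with patterns
4–21 nt, texts up to 5 kb and k ≤ 3. All studies are seeded and
deterministic.

## Numerical choices and degenerate inputs

Ridge uses the SVD solver; training is deterministic given inputs.
Predicted and corrected scores clip to [0, 100]. Spaced selection is
greedy by descending corrected score with ties broken toward the smaller
start; `min_gap` is a start-to-start distance, so `min_gap=0` reduces to
top-k. Transcripts shorter than 21 nt yield an empty candidate list
(logged), not an error. Patterns longer than 32 nt are rejected with an
instruction to chunk. Empty databanks give zero counts/profiles. Single
qPCR replicates flag dispersion as undefined rather than fabricating an
SD.

## Known limitations

- The scoring model's weights are whatever the training pairs imply; no
  pretrained weight set ships with the package.
- The off-target scan is exhaustive per transcript (no index); it is
  meant for transcriptome slices and screens, not genome-scale databanks.
- The qPCR estimator ignores inter-run calibration and treats normalizer
  choice as exchangeable beyond the geometric-mean pooling.
- Sequential ANOVA is order-dependent by design; the documented covariate
  order is part of the method.
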