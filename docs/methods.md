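# Methods

`methsig` re-creates, as a tested pipeline, the derivation and evaluation
of a DNA-methylation signature that predicts response (complete remission,
CR, vs refractory disease, RD) to an azacytidine-containing induction
regimen in AML. Real patient data for this design are not publicly
deposited, so the package ships a synthetic cohort generator that emulates
the study's three measurement platforms and the pipeline is exercised — and
its statistical behavior quantified — entirely against planted truth.

## The synthetic cohort

One latent methylation state per (region, sample) drives all three
platforms, so cross-platform coherence holds by construction:

* **Enrichment-seq bin counts.** The genome is a fixed grid of 500-bp bins
  (default 20,000 bins across eight chromosomes including chr3, chr11 and
  chrX so the exclusion rules have targets). Counts are negative binomial:
  `count ~ NB(mean = lib_s * a_b * fold, dispersion phi)` with per-bin
  abundance `a_b` lognormal (median 1.5e-6 of the library, sigma 1) and
  library sizes lognormal around 5e6 reads (sigma 0.25). These depths give
  a mean of ~7.5–12 reads per bin per sample, matching a ~5e6-read library
  spread over ~6.6e5 informative bins; an optional low-count outlier
  (<1e6 reads) per arm exercises the sample-QC rule. The dispersion
  default 0.1 corresponds to a ~30% between-patient biological CV.
* **Planted differential methylation.** 50 regions per treatment arm
  (default) carry a 2.5-fold count difference (`planted_log2fc =
  log2 2.5`) between response groups of the designated arm, in a random
  direction (hyper- or hypomethylated in RD). Placement is uniform over
  the genome, so some planted regions intentionally land on excluded
  chromosomes. Arm sets are disjoint unless `force_overlap` is set.
* **Response model.** Each sample has a latent burden `u ~ N(0,1)`;
  response is Bernoulli with `P(CR) = sigmoid(c0 + c1*u)`; the default
  `c0 = 0.2` gives ~55% CR. Planted effects are applied by realized
  response group, so the 2.5-fold calibration is exact in expectation.
* **Array layer.** Candidate regions (planted plus an equal number of
  null regions) are covered by 1–7 probes with probability 0.8; probe
  betas are `Beta(theta*s, (1-theta)*s)` with precision `s = 30` around
  the region's methylation level theta (base U(0.35, 0.65), planted shift
  0.2).
* **Mass-spec layer.** Each probe contributes 1–3 CpG units; a unit value
  is theta plus truncated Gaussian noise (sd 0.05). Entries are missing
  completely at random (rate 0.05), and 10% of units are degraded to 30%
  missingness to exercise the >20% QC filter.

What the generator does **not** emulate: read-level artifacts (GC bias,
mapping, duplicates), copy-number coupling between karyotype and counts,
batch effects between platforms, and informative (non-random)
missingness. Passing tests therefore demonstrate the pipeline's
statistical correctness under the declared model, not robustness to those
real-data failure modes.

## Screening (bin-level differential methylation)

Bins with reads in fewer than two samples are removed; samples with a
total read count strictly below 1e6 are flagged and dropped. Testing
follows the classic count-based two-group pipeline, re-implemented:

1. **TMM normalization** — per-sample factors from weighted trimmed means
   of log-ratios against a reference sample (30% log-ratio trim, 5%
   intensity trim, inverse-variance weights; bins with a zero in either
   sample excluded; factors scaled to geometric mean 1).
2. **Quantile adjustment** to a common (geometric-mean) library size,
   averaging normal and gamma approximations of the NB quantile map; the
   map is the identity when effective libraries are equal.
3. **Dispersion** by conditional maximum likelihood on the pseudo-counts
   (two refinement passes), then per-bin moderation toward the common
   value on a log-spaced grid with a prior weight of 10 degrees of
   freedom over the residual degrees of freedom.
4. **Exact conditional test**: group pseudo-count sums are NB; given the
   total, the two-sided p-value sums the probabilities of all partitions
   no more likely than the observed one. At dispersion 0 this reduces
   exactly to the conditional-binomial (Poisson) exact test.

Benjamini–Hochberg step-up q-values control FDR within each arm; the CR
vs RD contrast runs separately in the EXP and STD arms. `logFC` is
log2(mean CR / mean RD); a 0.125 pseudo-mean enters only when one group
mean is zero.

Because the test is discrete, its null rejection fraction at p < 0.05 is
~0.033 rather than 0.05 at these depths — a property shared by the
reference implementation of this test family, not an artifact of this
package; BH discoveries on null cohorts are ~0, as expected.

## Top-list selection

Candidates need q < 0.05 **and** effect-size consistency: every sample of
the higher response group is compared against 2.5x the lower group's
median normalized count, and at least 50% must pass (the comparator is
configurable to the mean). Records on chr3, chr11, chrX, chrY are
excluded (recurrent cytogenetics and cohort sex imbalance could mimic
differential methylation), as is any record overlapping a significant
record of the other arm (candidate chemotherapy-backbone effects). The
survivors are ranked by q (ties: larger |logFC|, then genomic order) and
truncated to k = 50.

A caveat established by simulation: when the *true* planted fold equals
the 2.5x gate, the per-sample pass probability is ~0.5 by scale
equivariance (the threshold sits at the higher group's median), so the
consistency gate passes only ~half of genuinely 2.5-fold regions; the
gate is sharp only against effects comfortably above the threshold.

## Array confirmation

Each candidate probe must satisfy, within the arm whose signature is
derived: (i) Spearman rho between its betas and the region RPKM strictly
above the cohort median rho — computed over the *entire* candidate-probe
panel, the only reading consistent with a ~90% pass rate among top
probes; (ii) direction concordance between the beta difference and the
enrichment logFC; (iii) a two-sided Mann–Whitney group difference at
p < 0.2 (deliberately lenient for small cohorts). Regions are
`confirmed_all` / `confirmed_partial` / `failed` by probe aggregation.
M values are `log2(b/(1-b))` with betas clipped at 1e-3.

## In-silico mass spectrometry

The T-cleavage reaction is modeled literally: the strand addressed by the
reaction is bisulfite converted (C→T outside CpG; the CpG cytosine is the
variable site), the transcript is the RNA reverse complement, and RNase A
cuts 3' of every U. A CpG reads A unmethylated and G methylated, so each
methylated CpG adds exactly the G−A residue difference (+16.00 Da) to its
fragment. Ribonucleotide masses are the standard average residue masses
(A 329.21, C 305.18, G 345.21, U 306.17; +18.02 terminal water); only
differences are contract-critical. A unit (all CpGs of one fragment) is
informative when every mass state (base + 16k Da) lies in the detectable
window (default 1500–7000 Da) and collides with no state of another
fragment within 1.0 Da — window and tolerance follow common EpiTYPER
practice and are configurable. Assay design checks: amplicon 200–500 bp,
primer Tm difference ≤5 °C (nearest-neighbour Tm via Biopython), no CpG
in primers, informative/total CpG ratio ≥0.7, plus soft scores for primer
length (ideal 22–25 bp), Tm near 60 °C, low T content and C-rich 3' ends.

Unit QC drops units with >20% missing values, imputes the rest by the
mean of the k = 5 nearest units (nan-Euclidean distance on
pairwise-complete sample vectors; observed entries never change) and
averages units per parent probe.

## Signature training and refinement

`PenalizedLogisticSignature` minimizes
`-(1/n) loglik + lambda [alpha ||b||_1 + (1-alpha) ||b||_2^2 / 2]`
(glmnet convention) via saga, with features standardized internally and
coefficients reported on the input scale. Lambda is chosen by stratified
5-fold CV minimizing mean binomial deviance over a log-spaced path from
the all-zero lambda down by 1e-3 (lambda-min rule: the study's screening
model fits its training data perfectly, implying weak shrinkage). The
intercept is polished by exact 1-D Newton steps after saga (it is
unpenalized, so its optimum solves mean(p) = mean(y)). First-pass
training uses alpha = 0.5 on confirmed-probe M values; refinement keeps
units Mann–Whitney significant (p < 0.05, two-sided; exact for n ≤ 12
without ties) in the EXP arm but not the STD arm, and the recomposed
signature is a lasso (alpha = 1) on the retained units.

## Evaluation

AUC is the rank-based Mann–Whitney statistic (ties one half); confusion
rates treat CR as the positive class. The 0.632+ bootstrap draws B
resamples (pipeline default 100; redrawn if either class has <2 members
in-bag),
computes the leave-one-out bootstrap error as each sample's mean
out-of-bag error averaged over samples (replicate-pooled form by flag),
and blends with the apparent error through `w = 0.632/(1 - 0.368 R)`
against the no-information rate `gamma = p(1-q) + (1-p)q`; the AUC
analogue substitutes 1−AUC with gamma 0.5. Crucially, the trainer handed
to the bootstrap re-runs the *entire* procedure — per-unit Mann–Whitney
screening and CV-based lambda selection — inside every replicate; leaving
feature selection outside inflates a null cohort's bootstrap AUC from
~0.5 to ~0.95. The confounder model is unpenalized ML logistic regression
(Wald 95% CIs) of response on the signature score plus covariates, with
karyotype groups under 3 samples merged into "other", rank-deficiency
flagged, and an L2 fallback on perfect separation.

## Pipeline and problem sizes

`run_all` executes synth → screen → select → confirm → unit-QC →
train/refine/recompose → evaluate (EXP, then the same report on the STD
arm) from one resolved config and root seed; per-stage RNG streams make
reruns bit-identical, and the resolved config re-runs to the same report.
In a null-signal demo the top list is empty; confirmation then carries
the whole candidate panel forward (flagged in the report) so the chance
level of the full procedure is still quantified, and an empty retained
set yields an explicitly degenerate signature rather than an abort.

Default problem sizes (20,000 bins, 20–40 samples per arm, B = 100,
20-step lambda path) are the package's desk-scale working points: large
enough for the calibration and recovery behavior described above to be
measurable, small enough for the full suite and the acceptance script to
run in minutes.

## Known limitations

* The exact conditional NB test is conservative at low counts
  (discreteness), as is its reference implementation.
* The consistency gate is intrinsically marginal for effects exactly at
  its fold threshold (see above).
* The EpiTYPER model omits primer tags, incomplete conversion,
  peak-intensity deconvolution and abundance-dependent missingness.
* The confounder model's Wald intervals are unreliable near separation;
  the penalized fallback reports coefficients without intervals.
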