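# Methods

## The screening statistic

For every chromosome N the caller standardizes the sample's unique-read share
against a euploid reference panel,

z_N = (%chrN_test − mean(%chrN_ref)) / SD(%chrN_ref),

with panel mean and SD the sample moments (n−1 denominator) of per-sample
proportions. The closed interval [−3, 3] is screen-negative; positivity
requires |z| > 3 strictly, so boundary ties go to negative. chr21/18/13
excesses map to T21/T18/T13; any other autosomal deviation is a rare
autosomal aneuploidy (trisomy above, monosomy below); multiple simultaneous
autosomal findings are allowed. The same statistic at 100 kb bin resolution
feeds the CNV scan.

Panels are sex-stratified (`female_fetus` / `male_fetus`), and a sample is
always scored against the stratum of its *called* sex. This matters more than
it first appears: chrX/chrY dosage varies with fetal fraction in male
pregnancies, and through the genome-wide normalization this couples a small
FF-dependent term into every autosome. A sex-matched panel absorbs both the
mean shift and the extra variance, keeping autosomal z calibrated for both
sexes; a pooled panel would mis-center male chrX by tens of SDs.

## Generative model

**Cohort.** Fetal states are drawn per pregnancy at configured prevalences
(defaults: SCAs 0.41%, RAAs 0.15%, CNVs 0.08%, T21 0.05%, T13 0.03%,
T18 0.01%; remainder euploid). Fetal sex is a fair Bernoulli unless the state
forces it (XO/XXX female, XXY/XYY male). Maternal age and gestational age are
truncated normals on [18, 34] years and [11, 23] weeks whose *truncated*
means equal the targets 29.6 y and 15.4 wk (the underlying location is solved
numerically); SDs of 3.5 y and 2.0 wk are field-realistic choices, since the
emulated study reports only standard errors. RAA states are drawn mosaic
(mosaic fraction ~ U(0.1, 1), monosomy probability 2.46%) from autosomes
excluding chr13/18/21 and the never-observed chr1/chr19. CNV segments are
~80% larger than 5 Mb (U(5, 20) Mb, else U(1, 5) Mb), duplications with
probability 0.58.

**Fetal fraction.** FF ~ LogNormal(median 9.2%, σ = 0.40) truncated to
(0.5%, 40%). This puts ≈85% of mass in the 5–16% band and ≈0.8% below the
3.5% QC cutoff, matching the band frequencies and second-draw rate of the
emulated programme; the distribution family itself is a modelling choice
since only band frequencies are published.

**Placental discordance.** cfDNA reports the placenta, so counts are always
generated from the *placental* state. With probability `cpm_fp_rate`
(default 0.0043 ≈ 260/60193) a euploid fetus carries a discordant abnormal
placental line — category weights follow the observed false-positive mix,
mosaic fraction U(0.2, 0.8), sex-compatible — and with probability
`cpm_fn_rate` (default 0.006 ≈ 2/330) an abnormal fetus has a euploid
placenta. These two knobs are the only biological sources of false calls;
everything else is sampling noise.

**Counts.** Expected proportions come from a single-normalization dosage
mixture: maternal euploid-female weights f_N (GRCh37 length shares plus a
2×10⁻⁴ chrY mismapping background) combined with placental weights
f_N·(c_N/2) at weight FF, where the effective copy number interpolates the
carrier and non-carrier values by the mosaic fraction. An affected region
with copy number c therefore carries the multiplier 1 + m·FF·(c−2)/2 before
one genome-wide renormalization — identical to enumerating maternal and
fetal genome copies and normalizing once, which the tests use as an oracle.
A single fetal Y contributes its length share scaled by an effective
mappability factor 0.4 (unique chrY coverage is far below its nominal
length), giving a pure-male chrY read share of ≈0.42%. Reads are multinomial
at 8×10⁶ unique reads per sample; bin-resolution sampling (within-chromosome
uniform by bin width) is used where a sub-chromosomal segment is in play.

## Fetal fraction estimation and QC

A sample is called male when its chrY share exceeds the female-stratum
background by >3 panel SDs. Male FF inverts the dosage mixture exactly at
the chrY proportion (the estimator is unbiased by construction; ±0.002 SD at
8×10⁶ reads). The vendor-style genome-wide regression for female fetuses is
out of scope: in simulation the configured truth is passed through, and in
data mode the estimate is NaN — QC cannot fail on it, which is the honest
behaviour available without that regression. QC passes iff FF ≥ 3.5%
(inclusive); one redraw (a fresh count simulation) is allowed before a
no-call, and no-calls leave every performance denominator.

## Sex-chromosome calls

Female fetuses: maternal and fetal X dosage coincide at baseline, so chrX
share is FF-invariant and plain z_X against the female panel decides —
z_X < −3 → XO, z_X > 3 → XXX.

Male fetuses: marginal z-scores against a pregnancy panel lose power (the
panel's chrX/chrY SDs are dominated by FF spread) and cannot separate XXY
from XYY — both produce the same chrX excess relative to the FF implied by a
single-Y assumption. The caller instead scores candidate karyotypes
{XY, XXY, XYY} jointly: each candidate's Y copy count implies an FF from the
chrY dosage, hence an expected chrX share, and the chrX z under each
candidate uses a variance that propagates the chrY counting noise through
the implied FF. Normal XY is rejected when |z_X|XY| > 3; the better-fitting
abnormal candidate is reported. Calls are categorical — no mosaic fraction
is estimated from z magnitude, matching the adjudication convention that any
mosaic degree of the named chromosome counts as concordant.

## CNV scan

Per-bin z values are winsorised at ±3 (a lone outlier bin can never drive a
call), then summed over sliding windows at geometrically growing scales
starting at `min_consecutive_bins` (default 10 bins = 1 Mb; presets for the
>5 Mb and ≥10 Mb clinical conventions are a parameter away). A window is a
candidate when its Stouffer statistic |Σz|/√w exceeds 5.0 — chosen so the
expected number of false windows per euploid genome (~10⁴ overlapping tests)
stays well below one, which the null tests confirm. Same-sign overlapping
windows merge; boundaries are refined by a maximum-sum subarray with a
per-bin extension penalty of half the estimated segment effect (plain Kadane
over-extends into noise drift); segments covering >90% of a chromosome are
suppressed in favour of the aneuploidy call. A run-of-threshold-bins rule
was rejected at design time: at FF = 12% and 8×10⁶ reads a heterozygous
deletion shifts each 100 kb bin by only ~1 SD, so any rule demanding
per-bin |z| > 3 in sequence has essentially zero power, while the windowed
scan recovers a 10 Mb deletion with ≥80% overlap in ≈99% of replicates.

## Follow-up cascade

Positive screens accept amniocentesis with probability 0.9565; accepted
cases are adjudicated against the fetal truth (category level; RAAs match on
chromosome identity alone; CNVs on overlap and direction). Confirmed true
positives terminate at category rates 1.0 (T21/T18/T13), 0.7807 (SCAs),
0.7949 (RAAs), 0.6739 (CNVs); confirmed false positives deliver at 0.9890
with the remainder split between termination and stillbirth. Refusals follow
the observed refusal outcome mix, and 61.5% of them are still resolved by
postnatal testing — unresolved refusals are excluded from performance
denominators. The source tables are internally inconsistent about
common-trisomy stillbirths (a printed 100% termination rate beside a 43/47
row); the configuration follows the printed rate, and the fixture keeps the
row verbatim.

## Calibration facts and limitations

* **Null calibration.** Pooled over the 22 autosomes, 10⁴ euploid samples
  against 100-sample panels flag at ≈0.004 per autosome test — above the
  ideal 2·Φ(−3) = 0.0027 because panel moments are estimated (a t-like
  inflation ~n_ref⁻¹) and because the FF-coupled normalization gives male
  large-chromosome z a mildly heavy right tail. Both effects are properties
  of the statistic, not bugs; the documented acceptance band is
  [0.002, 0.005].
* **Held-out calibration is a large-sample property.** With a 100-sample
  panel the held-out z mean and SD wander by ±0.1 and ±0.07 from panel
  estimation noise alone, so the per-chromosome mean ∈ [−0.1, 0.1],
  SD ∈ [0.9, 1.1] bands are asserted with 5000 panel and 5000 held-out
  samples, where those bands are ≈5 SDs wide.
* **Genome-wide positivity is higher than any real programme's.** Strict
  |z| > 3 on 22 autosomes plus the sex chromosomes yields ≈6–8% positive
  euploid samples under ideal multinomial noise — versus 0.99% in the
  emulated cohort. Real pipelines reach their low effective false-positive
  rates through normalization, blacklisting and secondary review that are
  not part of the published method description. Consequently simulated
  per-category PPVs (RAAs especially) sit far below the published ones, and
  the package validates PPV structure through the Bayes identity
  (PPV = sens·prev / (sens·prev + FPR·(1−prev))) at the run's *own*
  empirical rates rather than against the printed PPVs; `calibrate-cpm`
  reports the biological FP rates any target PPV implies.
* **What passing tests do not show.** The generator has no GC/mappability
  structure, no between-sample overdispersion beyond FF, no twin or
  vanishing-twin biology, no maternal malignancy or sex-discordant CPM, and
  fetal-fraction is independent of aneuploidy state. Calibration results
  here bound what the statistic can do under its own assumptions, not
  performance on real plasma.
* **Problem sizes.** Default runs use 8×10⁶ reads, 100 kb bins, 100-sample
  panels; test-suite simulations use 10⁴ null samples, 500 power samples per
  FF cell, 100–200 recovery replicates, and a 4000-pregnancy end-to-end
  screen with T21 prevalence raised to 1% so the Bayes check has enough
  positives. All randomness descends from one seeded generator per run;
  equal seeds reproduce every table bitwise.
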