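# Methods

`vfdna` analyses droplet digital PCR (ddPCR) measurements of DNA isolated
from vitreous fluid of eyes with uveal melanoma, and turns droplet counts
into a per-sample molecular profile: how much cell-free DNA the sample
holds, what share of it is melanoma-cell derived, which driver mutations
are present, whether chromosome 3p or 8q is copy-number altered, and which
prognostic subtype the tumour belongs to. This note records the underlying
models, the tunable parameters, and the design choices made where the
procedure was genuinely open.

## Partition statistics

A ddPCR well partitions a reaction into droplets of nominal volume
0.85 nL. Target molecules distribute across droplets approximately as a
Poisson process, so with `k` positive droplets out of `N` accepted the
mean occupancy estimate is

    lambda_hat = -ln(1 - k/N)        (molecules per droplet)

and the concentration in the reaction is `lambda_hat / v` with
`v = 0.85e-3 µL`. Concentrations are rescaled to copies per µL of
vitreous fluid through the volume plan (defaults: 150 µL vitreous in,
35 µL eluate, 3.5 µL eluate per 22 µL reaction), giving a scale factor of
`(22/3.5)·(35/150) ≈ 1.467`. The droplet volume is the manufacturer's
convention for the instrument class modelled here and is configurable in
`VolumePlan`; when a sample sheet omits the vitreous input volume the
midpoint of the 100–200 µL workflow range (150 µL) is assumed and a
warning logged.

The standard error of `lambda_hat` comes from the delta method on the
binomial positive fraction, `SE = sqrt(p(1-p)/N)/(1-p)`, with a
symmetric normal interval floored at zero. A simulation in the test
suite confirms ≥97.5% empirical coverage of the nominal 99% interval at
occupancies 0.01–1. Saturated wells (`k = N`) are continuity-corrected
(`k → N − 0.5`) and flagged rather than returned as infinite; wells with
a positive fraction above 0.999 are flagged as beyond the assay's
dynamic range.

Replicate wells of one assay (up to three in this workflow) are merged
by summing droplet counts channel-wise before estimation; because the
per-well likelihoods share one occupancy parameter, estimating on the
pooled counts *is* the joint maximum-likelihood estimate (verified
against brute-force grid search in the tests).

Two quality rules apply throughout, both boundary-inclusive: a well (or
merge) needs ≥10,000 accepted droplets to pass QC, and a target needs
≥3 positive droplets to count as detectable.

## DNA composition and triage

The tumour's Gαq-pathway driver mutation (GNAQ, GNA11, CYSLTR2 or
PLCB4) is clonal and near-universal in uveal melanoma, so its mutant
allele concentration `[mut]` tracks melanoma-cell DNA while `[wt]`
aggregates all cells:

    total vfDNA      = [mut] + [wt]
    melanoma fraction = 2·[mut] / ([mut] + [wt])

The factor 2 reflects heterozygosity (a pure-tumour sample has
`[mut] = [wt]`). Raw fractions above 1 — possible under mutant-allele
imbalance or sampling noise — are clamped to 1 for reporting with the
raw value retained. Non-melanoma DNA is `[wt] − [mut]`, floored at 0.
Samples triage into vfDNA−/UM− (neither allele detectable),
vfDNA+/UM− (wild-type only) and vfDNA+/UM+ (mutant detectable), always
on counts merged across the available replicate wells. Tumours with two
clonal drivers are analysed per driver and the strongest mutant signal
drives triage.

## Mutation calling (BAP1 / SF3B1 / EIF1AX)

Secondary "BSE" mutations are interpreted qualitatively: a handful of
mutant molecules proves presence, so `detected` simply requires ≥3
mutant-evidence droplets over the merged wells with QC pass. For
targeted duplex assays the evidence is the mutant-channel count; for
drop-off assays (where a probe spanning the mutation site fails on
mutant molecules) it is the reference-only droplet cluster, i.e.
reference-channel positives minus double positives — wild-type molecules
co-encapsulated with mutant ones land in the double-positive cluster and
are deliberately not counted. A uniform ≥3-droplet rule is used for all
assays; no per-assay limit-of-detection calibration is attempted.

Variants with no covering assay are `not_measured`: the registry covers
EIF1AX exons 1–2 (drop-off), the SF3B1 p.R625C/H hotspot, and BAP1 only
where a variant-specific assay is registered, reflecting that BAP1
mutations are scattered and essentially private. Unparseable variant
notations degrade to `not_measured` with a warning at cohort level.

## Copy-number estimation and calling

Two estimators, on the scale where 2 = unaltered:

* classic: `cn = 2·[target]/[reference]`, target PPARG (3p) or PTK2
  (8q) against a stable reference gene, TERT (5p) by default with TTC5
  (14q) as fallback;
* SNP-based: `cn = 1 + [var1]/[var2]` from the allelic imbalance of a
  heterozygous germline SNP, the denominator allele assumed haploid and
  copy-stable.

The SNP estimator needs no stable reference and is empirically more
precise, so it is preferred whenever a heterozygous SNP is genotyped;
among several, the one with the highest expected droplet count is used
(merging across distinct loci is not attempted). The 99% interval comes
from the delta method on the log-ratio of the two occupancy estimates
(`SE(log R)² = SE₁²/λ₁² + SE₂²/λ₂²`, normal quantile, exponentiated,
then scaled/shifted per estimator); this closed form was chosen for
testability and is validated by coverage and false-positive simulations
(≤1.5% calls at cn = 2 under the nominal 1% two-sided level). An empty
numerator channel gets a conservative upper bound via a half-droplet
continuity floor. Copy-number values are never truncated; calls rely on
the interval only: `loss` when the estimate and its whole interval lie
below 2, `gain` when above, `no_change` otherwise, and `no_call` when
the sample is underpowered or QC failed. Under a subclonal alteration
carried by a proportion `q` of tumour cells the expected value
attenuates to `2 − f·q` (loss), which is why heterogeneous tumours can
stay undetected — recorded, not corrected.

## Power simulation and gating

Copy-number detectability is sample-specific: it depends on the total
DNA and melanoma fraction measured by the Gαq assay. Before any
copy-number call, the planned experiment is simulated: per-species
occupancies are derived from the sample's own measurements under a
clonal loss (copy number 1, for 3p) or gain (copy number 3, for 8q),
droplet counts are drawn binomially, and the 99%-CI caller is applied.
Sensitivity is the fraction of simulated experiments detecting the
alteration *in the correct direction* (wrong-direction false positives
do not count as successes). Simulated experiments use the fixed
configurations 15,000 droplets (single) and 45,000 (a merge of three),
with 1,000 simulations per condition by default and optional early
stopping once the Wilson 99% bound clears the threshold. A sample is
*underpowered* when sensitivity at 45,000 droplets is below 80%
(exactly 80% counts as powered); underpowered samples receive no
copy-number call, which avoids reporting false negatives and wasting
scarce material. Power is computed for the method actually used
downstream (SNP when available, else classic).

## Subtype inference

Poor prognosis: BAP1 mutation detected and/or a (powered) 3p loss.
Better prognosis: EIF1AX or SF3B1 mutation detected and/or powered 3p
disomy. Positive evidence is always usable; negative evidence (an
absence) only when the sample was powered to detect the alternative —
an unpowered "no change" proves nothing. The exact inferability rule is
not uniquely determined by the source workflow, so this reconstruction
is explicit and configurable in code; conflicts resolve conservatively
to poor prognosis with a warning, and 8q gain is carried as annotation
without assigning a subtype by itself.

## Cohort statistics

Triage tallies and percentages; BSE concordance whose denominator
excludes `not_measured`; copy-number concordance counted only among
powered samples; Mann-Whitney U (tie-corrected normal approximation),
Fisher's exact and Spearman's rank tests, all two-sided, chosen for
small non-normal samples; Kaplan-Meier melanoma-related survival with
medians reported to one decimal year (undefined while the curve stays
above 0.5) and the log-rank test across inferred-subtype groups, with
and without the not-inferable stratum. Records missing survival fields
are excluded listwise from survival analysis only; tests with groups
smaller than three are skipped with a note.

## Synthetic cohorts

The generator emulates the structure of a per-sample clinical summary
table so that every stage is testable without protected data. Per
sample: a triage class (2/65, 18/65, 45/65); total vfDNA log-uniform
over the observed ranges (UM+ 2.6–5585.3, UM− 1.1–1588.4 copies/µL
vitreous); melanoma fraction log-normal with median 15.5%
(σ_ln = 2.0) clipped to [0.03%, 95%] — a log-uniform family over the
same range is available via `fraction_median=None` but its median
(≈1.7%) is far below the observed one and leaves ~85% of UM+ samples
underpowered; a subtype (55% BAP1-type / 25% SF3B1 / 20% EIF1AX,
matching the per-gene composition of the emulated cohort) with the
implied 3p/8q genotype, 10% of alterations subclonal (clonality
U(0.2, 0.6)); assay availability BAP1 20%, SF3B1 80%, EIF1AX 100%;
heterozygous-SNP availability 90% (3p, six panel SNPs) and 65% (8q,
two); prominence `5.5 + 1.8·log10([mut]+1) + N(0, 3)` mm, calibrated to
the observed medians (≈5.5 mm without, ≈8 mm with melanoma DNA) and a
Spearman correlation near 0.46; tumour diameter and Bruch's-membrane
breach independent of triage; survival exponential with median 5.8 y
(poor prognosis) versus 25 y (better), censored uniformly at 2–15 y.
Droplet counts for every assay are then drawn from the same occupancy
model the power simulator uses (three wells of 15,000 droplets per
assay), with drop-off assays simulated in their cluster geometry.

What the generator does **not** model — droplet volume variability,
"rain" (partial amplitude) droplets, probe cross-reactivity,
misclassification, DNA degradation, reference-chromosome instability —
bounds what passing tests show: they validate the statistical machinery
under the stated model, not robustness to instrument artefacts.

## Problem sizes and reproducibility

Default verification scales, chosen to keep the whole suite at desk
scale: 100 random instances for the MLE oracle; 500 replicates per
condition for copy-number bias and power monotonicity; 2,000
simulations for false-positive and coverage checks; a 200-sample cohort
for parameter recovery (fraction-regression slope within 1 ± 0.05,
subtype accuracy ≥95% among samples with fraction ≥0.1 and predicted
3p sensitivity ≥0.95 — the regression uses samples with ≥100 merged
Gαq-positive droplets, a precision filter independent of the fraction);
and a 65-sample paper-like cohort for the end-to-end report. All
randomness flows from a single seed through `numpy.random.SeedSequence`
derivation, so every report is bit-reproducible.

## Known limitations

* The delta-method intervals are asymptotic; at very low occupancy
  (a few positive droplets) they are conservative near zero rather than
  exact.
* The half-droplet continuity floor for empty numerator channels is a
  pragmatic convention; exact binomial ratio intervals would be an
  alternative at higher computational cost.
* Subtype inferability depends on the reconstruction rule above;
  cohorts scored under a different rule may count differently.
* The generator's distribution families (log-uniform / log-normal /
  exponential) are pragmatic summaries of printed medians and ranges,
  not fitted distributions.
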