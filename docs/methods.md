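# Methods

This note documents the models, estimators, defaults and numerical
choices behind `methpop`, and what the synthetic cohorts do and do not
establish about real data.

## Normalization model

Raw two-channel intensities (methylated M, unmethylated U per site and
sample) are processed as a single-probe-type bead array delivers them:

1. subtract the per-sample, per-channel mean negative-control intensity
   (the array's estimate of optical/background signal for that dye);
2. clamp negative intensities to zero;
3. quantile-normalize the pooled per-sample intensity vector (M stacked
   on U) across samples, separately within each dye channel;
4. recompute β = M/(M+U). No denominator offset is added, and no
   between-channel or probe-type correction is applied (single-type
   design).

Tie handling in quantile normalization is deterministic: tied values in
a sample receive the mean of the reference order statistics spanning
their rank range. Whether M and U should be normalized jointly within a
channel (as here, matching how the scanner reports a channel's
intensities) or as separate M/U vectors is underdetermined; the joint
choice changes β only marginally because the two alternatives share the
background-subtraction and ratio steps.

Quantile normalization forces all samples within a channel onto a common
intensity distribution. It is therefore exactly invertible only when the
per-sample distributions already agree; on heterogeneous samples it
perturbs β slightly (on simulated cohorts the normalized-vs-true β
correlation is ≳ 0.999). A site whose normalized M + U is zero yields a
missing β and is logged.

**QC.** A site fails for a sample when its detection P-value exceeds
0.05 — i.e. the signal is indistinguishable from background — or when
fewer than 5 beads measured it; a sample passes when its failing
fraction is strictly below 5%. The batch-effect check compares
within-batch pairwise Pearson correlations of β profiles against all
pairwise correlations with a two-sided Wilcoxon rank-sum test. Note a
batch effect must perturb profile *shape* (per-site biases) to be
visible to this check; a constant offset common to all sites of a
sample leaves Pearson correlations unchanged.

## Population differences

Two-sided Wilcoxon rank-sum per CpG over all samples of each population
(children included; the randomization FDR, not the test statistic,
accounts for family structure). Exact enumeration is used when both
groups have ≤ 10 samples and no ties; otherwise the normal
approximation with tie correction and a 0.5 continuity correction. At
90 vs 90 the approximation is the only practical choice. The internal
vectorized implementation computes ranks once per data set — ranks do
not depend on group labels — so each of thousands of label
randomizations costs one masked rank sum.

FDR at threshold t = mean over randomizations of (null sites with
P < t) / (observed sites with P < t). Two schemes: `individual`
permutes population labels over samples; `trio` permutes labels over
whole trios (balanced: the number of trios per label is preserved), so
the null retains within-family correlation. Zero observed discoveries
yields a NaN sentinel with a warning rather than a number.

## Heritability

Per site and population, h² is the Pearson correlation between the
midparent β and the child β across trios (≥ 3 complete trios required;
zero-variance vectors yield a missing estimate). Estimates can be
negative at these sample sizes. Under the standard additive model with
unrelated mates, var(midparent) = ½ var(offspring), so the expected
*correlation* is h²/√2 while the offspring-on-midparent *regression
slope* is h²; the estimator reports the correlation as defined, and the
recovery experiments target h²/√2. The estimator assumes no shared
parent-offspring environment and no direct germline transmission of
somatic methylation; violations inflate it toward the broad-sense H².

**Heritable-site count.** Null h² distributions are generated by
permuting children among the population's trios (parents stay
together), preserving every marginal exactly. The count per
randomization is Σ over histogram bins on the positive side of
max(0, real − null), with bin width 0.05 over [−1, 1]; the estimate is
the mean over randomizations (default R = 1000; calibration experiments
use R = 200, which only affects Monte-Carlo error of the mean). Two
properties to keep in mind:

* the per-bin clipping at zero gives the estimator a positive bias
  under the null of order √(mean bin count) × number of positive bins
  (~5% of sites in a 20-trio null cohort) — the procedure counts
  heritable sites, it does not certify zero;
* the count is insensitive to bin width within 0.02–0.10 (property
  tested), and no per-site FDR is attached because the procedure
  identifies *how many* sites are heritable, not *which*.

Variant-overlapping probes are **not** excluded from heritability or
population-difference analyses — the artifact mechanism fabricates
genotype associations, which matters for mSNP mapping only.

## mSNP mapping

Per population: for each non-excluded CpG, all SNPs on the same
chromosome within 100 kb and with minor-allele count ≥ 5 among the
population's 90 samples (children included) are tested by |Pearson r|
between dosage and β. The sign is discarded (0/1/2 coding is
arbitrary). The best SNP per CpG is reported with deterministic
tie-breaking: larger |r|, then smaller CpG–SNP distance, then
lexicographic SNP id; hits require |r| > 0.6 (variance explained
> 36%). Rare missing dosages are mean-imputed within the scan to keep
it vectorized.

**Probe exclusion.** A probe is excluded for a population when any
catalog variant of that population lies within the probe's 1-based
inclusive interval. Exclusion applies only to scanning.

**FDR.** Each randomization re-pairs methylation profiles with
genotypes within the population (trio scheme: whole trios' three
profiles move against trios' genotypes), rescans and counts hits. The
heritable tier repeats the computation restricted to CpGs with
h² > 0.2 from this package's own estimates. Calibration experiments
use reduced hit thresholds (|r| > 0.3–0.35) because at |r| > 0.6 and
n = 90 chance hits are essentially nonexistent and the FDR ratio is
0/0; at reduced thresholds the null hit rate is measurable and the
heritable tier shows the expected FDR drop.

**Specificity.** For each CpG that is a hit in either population, the
best local |r| per population (possibly different SNPs) is compared by
Fisher's r-to-z with n−3 per-population sample counts, two-sided,
flagged at P < 0.005. Using |r| on both sides can only understate the
difference; trio non-independence is ignored here (a documented
limitation — the randomization FDR machinery, not this test, carries
the family structure). |r| = 1 is clamped at 1 − 1e−12.

**Attribution.** For sites differing between populations (P < 0.001),
the local SNP most correlated with β across all 180 pooled samples —
restricted to SNPs adequately polymorphic (MAC ≥ 5) in both
populations — enters a joint OLS of β on centered dosage and a 0/1
population indicator; the site is `snp_stronger` when the dosage
coefficient's |t| exceeds the population coefficient's. Predictors are
not standardized (|t| is scale-invariant). A site with no shared local
SNP defaults to `population_stronger` and is flagged.

## Synthetic cohorts

Defaults (`SimConfig`): 30 trios per population; 2,000 CpG sites on
synthetic chromosomes of 100 sites spaced 1 Mb apart (so 100 kb scan
windows never overlap neighboring CpGs); 6,000 decoy SNPs placed 75%
inside / 25% outside the window; Fst = 0.15; 20% of sites shifted by
0.1 β; 5% heritable at h² = 0.5; 20 cis-mSNPs targeting |r| = 0.8
(variance explained 64%, the middle of the published 36–92% range),
80% of them active in exactly one population while remaining
polymorphic (frequency clipped to [0.2, 0.8]) in both; 10% of probes
overlapping a common variant whose dosage distorts the readout by 1.0
on the latent scale; latent noise SD 0.35.

Construction: ancestral frequencies are Uniform; per-population
frequencies follow Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F);
parents are Hardy–Weinberg, children Mendelian. Methylation is built on
a latent logit scale — baseline + shift + mSNP effect × dosage +
polygenic value + artifact distortion + Gaussian noise — and mapped
through the inverse logit. The child's polygenic value is the midparent
average plus segregation noise with half the additive variance, giving
h² exactly and corr(midparent, child) = h²/√2. Effect calibration:

* mSNP effect sizes are set per population from the realized dosage SD
  so the latent-scale correlation equals the target |r|;
* population shifts are calibrated per site by root finding (Brent) on
  the latent offset so the realized mean β difference matches the
  requested magnitude to < 0.005;
* planted sites draw baselines within ±0.5 logit — intermediate
  methylation, where variably methylated promoter sites actually sit
  and where the inverse logit is effectively linear (< 1% attenuation
  of the planted correlations, verified against a 4,000-trio oracle
  run); null sites are bimodal like real promoter methylomes.

A single seed expands into named substreams (genotypes, layout,
methylation, polygenics, intensities), so changing the number of sites
never perturbs genotypes, and identical seeds give byte-identical
datasets.

**What the generator does not emulate.** Cell-type mixtures,
imprinting, sex chromosomes, probe cross-hybridization beyond the
variant-overlap mechanism, linkage disequilibrium between SNPs (decoys
are independent draws), and realistic effect-size spectra (plants use a
single target |r|). Two deliberate divergences from the published data:
artifact probes here are *heritable* readouts (they track a transmitted
variant's dosage), whereas the study found variant-overlapping probes
no more heritable than others; and both populations share the same
planted polygenic architecture, so per-site h² correlates between
populations instead of being uncorrelated. Passing recovery tests
therefore demonstrates estimator correctness under the stated additive
model, not robustness to everything real arrays do.

## Problem sizes and determinism

Calibration and recovery experiments (`methpop.experiments`) run at
desk scale: 2,000-site cohorts and R = 200 randomizations for FDR
calibration (pooled over 5 replicate cohorts as a ratio of summed
counts, the stable way to combine small-count FDRs), 500 sites × 30
trios for heritability recovery, 10 seeds × 2,000 sites for the
heritable-count recovery, and 90 samples/population for mSNP recall and
specificity power. All randomness flows from a single integer seed
through named SeedSequence substreams; every pipeline stage is a pure
function of (inputs, config, seed), and the end-to-end pipeline writes
a config hash and seed into its summary for reproducibility.
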