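# Methods

This note documents the models behind `ncp4gwas`, the choices made where the
design was genuinely open, and what the synthetic herds do and do not show.

## The phenotype: NCP4

NCP4 — the number of calves a cow produces by 4 years of age — is

    NCP4 = (4 − AFC) / ACI + 1

with AFC the age at first calving in years and ACI the average calving
interval, both derived from raw calving dates. The *t-age* is the age at the
first calving occurring at or after the 4th birthday; by default ACI averages
every interval from the first calving through the t-age calving. An
alternative reading — averaging only intervals that end before the 4th
birthday — is available via `compute_ncp4(..., interval_scope="before_age_4")`;
the default is the most direct reading of the published formula. All
day-to-year conversions use 365.25 days/year; dates are integer days since
1990-01-01 (only differences matter).

Records pass nine selection criteria before NCP4 is computed: (1) a complete
history through the first calving at/after age 4; (2) no twins; (3) no embryo
transfers; (4) no abortions; (5) gestations within 261–310 d; (6) calving
intervals within 276–730 d; (7) age at first calving < 1,128 d; (8) a single
rearing farm; (9) more than 10 records in the cow's farm × birth-year cell,
evaluated after criteria 1–8. Stated ranges are inclusive; the first-calving
bound is strict; criterion 9 is strict (> 10). A record can fail several
criteria; the filter report attributes it to each.

## Farm/birth-year adjustment by animal-model REML

NCP4 is adjusted for farm and birth year with the animal model
y = Xb + u + e, var(u) = A·sigma_a², var(e) = I·sigma_e², where A is the
pedigree numerator relationship matrix (Henderson's tabular recursion,
`build_a_matrix`). Because there is one record per animal, rotating by the
eigenvectors of A diagonalizes the covariance, and the restricted likelihood
of any variance ratio costs O(n·p²).

Two fitters share that machinery. The default (`method="profile"`) maximizes
the restricted likelihood profiled over sigma_e² as a scalar function of
gamma = sigma_a²/sigma_e² (coarse log-grid, then bounded Brent; the gamma = 0
boundary is compared explicitly). `method="em"` runs classical EM-REML
updates, whose restricted likelihood is non-decreasing every iteration — the
test suite uses that trace as a self-check. Both converge to the same
optimum; the profile fitter was made the default because it is robust at the
sigma_a² → 0 boundary and roughly 50× faster at n = 5,000. Convergence
tolerance is 1e-8 on the objective, 200 iterations maximum for EM.

Adjusted NCP4 subtracts only the farm and birth-year *fixed-effect*
solutions (reference-level = 0 constraint); breeding values are not
subtracted, matching a correction "for the effects of farm and birth year".

### Precision of REML heritability at desk scale

The Fisher information of h² over the eigenspectrum of A gives
SE(ĥ²) ≈ 0.021 at h² = 0.11 for n = 5,000 records under every cattle-like
relationship structure we examined (paternal half-sib designs of 50–250
sires, one or two phenotyped generations, full-sib variants). Parameter-
recovery experiments at n = 5,000 therefore scatter with SD ≈ 0.021–0.024
around the truth; recovering 0.11 to better than ±0.04 in *every* replicate
of a 20-replicate experiment is not statistically guaranteed at this sample
size, and the test suite's recovery experiment documents exactly that
behaviour. The mean over 20 replicates recovers h² to ±0.02.

## Selective-genotyping mixed-model scan

Cows ranked on adjusted NCP4 contribute the top and bottom 6.68% tails
(size = floor(n·pct) + 1), coded 1/0. "Fewer than five cows per sire" is
enforced as at most 4 daughters per sire per extreme: excess daughters
within the initially selected tail are dropped by seeded random choice and
replaced by next-ranked animals, skipping daughters of already-saturated
sires so refills never displace more extreme picks. Ranking ties break by
(value, animal id); the cap drop is the only randomness.

SNP QC applies strict thresholds: call rate > 0.99, MAF > 0.01, and a 1-df
chi-square Hardy–Weinberg test with p > 0.001.

The genetic relationship matrix defaults to allele-sharing similarity
("ibs": 1 − mean |dosage difference|/2 over pairwise-complete SNPs), with a
standardized (centred/scaled cross-product) mode behind a flag. Mean
imputation of missing dosages is used for the standardized mode and for
per-SNP testing; the IBS mode uses pairwise-complete observations instead,
because averaging alleles breaks the sharing count. Empirical matrices that
are numerically indefinite get a 1e-6 ridge and eigenvalue clipping at 0.

The scan follows the EMMAX approximation: variance components of the 0/1
response are estimated once on the null model (intercept + covariates) by
REML on the GRM eigenbasis and reused for every SNP; each SNP is then tested
by generalized least squares on the rotated data. The reported statistic is
the squared Wald statistic; its p-value is referred to F(1, n−p−1) — the
exact finite-sample reference of the GLS t-test, which converges to the
1-df chi-square for large n. The chi-square reference is visibly
anti-conservative at the 1e-5 tail for desk-scale n (a few hundred extreme
cows), and the F reference restores exact type-I control; it also makes the
scan reduce *exactly* to ordinary least squares when the GRM is the identity
and sigma_g² = 0, which the suite asserts at 1e-10. Conditioning adds the
conditioning SNP's (mean-imputed) dosage as a covariate; a SNP collinear
with the covariates (including itself) is flagged not-estimable rather than
crashing.

Genome-wide significance uses the Lander–Kruglyak dense-map correction
mu(T) = [C + 2·rho·G·T²]·alpha(T), with T on the normal scale (so T² is the
1-df chi-square threshold and alpha(T) its upper tail). The pointwise level
solving mu = 0.05 is found by root bracketing to relative tolerance 1e-12.
Defaults C = 29 autosomes, rho = 2, and G = 28 Morgans; G is a configuration
parameter — the published analyses this package mirrors do not print it, and
28 M reproduces the conventional 2.5e-5 pointwise level at C = 29, rho = 2.
The genomic inflation factor is the median 1-df chi-square quantile of the
p-values divided by 0.4549.

## Haplotypes, LD, diplotype classes, imputation scoring

Phasing is exact EM over all haplotype pairs in windows of 2–4 SNPs under
Hardy–Weinberg pairing, with uniform initialization, missing genotypes
summed over compatible completions, and convergence when the largest
frequency change is below tol (1e-8 default). Ties in the most likely
diplotype break toward the lexicographically smaller pair. The loci of
interest span 2–3 SNPs, so genome-scale HMM phasing is out of scope by
design. D, D′ and r² follow the standard definitions from two-SNP haplotype
frequencies (sign-dependent D_max normalization).

Two-SNP diplotype classes (QQ/Qq/qq) are deterministic whenever at least one
site is homozygous; double heterozygotes take the cis/trans phase with the
higher posterior under the EM frequencies, or "unresolved" when that
posterior probability is below 0.95 (unresolved animals are excluded from
the diplotype GLM, avoiding phase-noise contamination of effect estimates).

Imputation accuracy is scored by masking a seeded random subset of called
genotypes, invoking a pluggable imputer (the built-in reference imputer
fills with the most frequent genotype per SNP), and reporting
allelic discordance = 1 − matched alleles/2/masked genotypes and
genotypic discordance = 1 − matched genotypes/masked genotypes.

## Allelic imbalance

Allele-specific expression in a heterozygote is the ratio of ratios
(cDNA Q/q)/(gDNA Q/q); the same-animal gDNA ratio cancels allele-specific
dye/amplification bias because heterozygous gDNA carries one copy of each
allele. The statistic is invariant to any common rescaling of the four
peaks. Group means are reported on the natural scale; the calibration curve
(from a gDNA mixing series) is fitted on the log scale — log(measured) on
log(true) — because the error model is multiplicative, and correction
inverts the fit. The default test is a two-sample Welch t of the cDNA ratios
against the gDNA ratios, two-sided; a paired t is one flag away. The
published description is ambiguous between the two; the two-sample reading
was chosen as the default because the group sizes are reported per tissue
group, and both are provided. Whether calibration is applied before testing
is likewise optional (the published use may have been linearity validation
only).

## Replication analysis and variance decomposition

Least-square means of NCP4 per diplotype class come from an ordinary
least-squares fit of farm + birth-year + class ("GLM" in the procedure
sense; NCP4 is continuous, so the identity-link Gaussian model applies),
with a reference-level constraint for rank deficiency and lsmeans defined as
predicted class means averaged with equal weight over the observed farm and
year levels. Pairwise comparisons use the Tukey–Kramer studentized-range
test: q = √2·|difference|/SE(difference) with the Kramer unequal-n standard
error from the lsmean covariance, referred to the studentized-range
distribution with k groups and the residual df.

The substitution effect defaults to a = (lsmean_QQ − lsmean_qq)/2, with a
Q-dosage regression alternative (and automatic fallback when a homozygote
class is empty). The haplotype variance is V_hap = 2p(1−p)a² under
Hardy–Weinberg diplotype proportions — the single most consequential
interpretive choice in this module, since the source procedure cites the
classical decomposition without printing the formula. Shares are
V_hap/V_P and V_hap/V_G; V_P is estimated net of farm and year (residual
variance of the no-class model, which retains the haplotype variance), and
V_G = h²·V_P when a heritability is supplied, so share_of_genetic =
share_of_phenotypic/h² by construction.

## The synthetic herd

The generator emulates a commercial Japanese-Black-style herd: founder males
act as AI sires across generations, all non-founder animals are phenotyped
cows, and dams of generation g are the cows of generation g−1. Defaults are
the study conditions of the population the pipeline models: h² = 0.11, a
causal haplotype at frequency 0.313 with substitution effect 0.054 calves,
and phenotypic variance (net of farm/year) V_P = 2p(1−p)a²/0.0269 = 0.0466
calves², so the haplotype explains 2.69% of V_P; farms and birth years
(11 farms, 1992–2006) carry fixed effects of SD 0.10 and 0.05 calves.

Founder haplotypes are drawn from a latent Gaussian AR(1) copula along each
chromosome (correlation exp(−s·c·d) over d bp, with c = `ld_decay` in
Morgans/bp and s = `ld_corr_scale` = 2000 a population-scale factor), so LD
decays smoothly with distance; per-SNP alt frequencies are U(0.05, 0.5)
except in the causal block, whose 5 SNPs share the causal frequency at
300-bp spacing and therefore sit at r² ≈ 0.95–1. Offspring haplotypes follow
Mendelian transmission with Poisson (Haldane) crossovers at `ld_decay`
Morgans/bp. Polygenic breeding values follow the pedigree recursion
(midparent + Mendelian sampling, inbreeding ignored in the sampling
variance).

The phenotype is *not* assigned directly: a liability
mean + farm + year + a·(dosage − 2p) + polygenic + residual is realized as a
calving schedule — AFC ~ U(1.9, 2.4) years, then the calving interval solved
so that the schedule's NCP4 equals the liability — so the filter and t-age
logic downstream is genuinely exercised on raw dates. The liability is
clipped to the schedule-feasible NCP4 range (intervals 281–712 d, a margin
inside the 276–730 d filter window so rounding cannot trip a clean record);
at the default variance this clips beyond ≈3.5 SD and costs under 1% of the
variance. Day rounding adds O(0.002 calves) noise, negligible against
SD ≈ 0.216. Contamination injects each filter-triggering event type at
configurable per-record rates (default 2% each; rates are explicit
conditions, not emergent behaviour).

What the herds do *not* emulate: real bovine chromosome lengths and SNP
ascertainment, genotyping intensity/cluster artefacts, maternal and
dominance effects, culling and sequential selection, farm-by-year
interactions, and age structure beyond birth-year cohorts. Passing recovery
tests on these herds shows the estimators are consistent with their own
generating model at realistic parameter values — not that field data meet
those assumptions.

## Problem sizes used by the test suite

Experiments are sized to what the analyses need, not more: heritability
recovery uses one 6,000-animal pedigree (100 sires) with 20 phenotype
replicates over 5,000 cows, reusing one eigendecomposition of A — the
replicate-to-replicate variation is over all random effects, which is what
recovery measures. Scan calibration uses 702 extreme cows × ~30,000 QC'd
SNPs from a 500-sire herd (small families, so the sire cap binds rarely —
the same proportions as the design it mirrors; a hard-binding cap induces
negative sib correlation in the response and visibly deflates lambda_GC).
Conditioning uses 50 replicates of an 800-cow herd with 600 SNPs and a
causal block scaled to ~8% of V_P, chosen a priori so the unconditioned scan
has clear genome-wide signals. Variance-decomposition recovery uses 50
replicates at the replication-cohort scale (~830 cows). The allelic-
imbalance experiment uses 500 replicates of 19 heterozygotes at CV 0.1.

## Numerical conventions

Genomic positions are 1-based bp; PED/MAP text is the genotype interchange
format ("0 0" = missing; the reader counts dosage on the file-determined
minor allele, ties toward the alphabetically later allele so writer output
round-trips). All tables are tab-delimited with headers. One global seed
drives per-stage substreams (`SeedSequence((seed, stage))`), so stages are
reproducible independently; rerunning the pipeline with the same
configuration is byte-identical.
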