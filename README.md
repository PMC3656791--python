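# ncp4gwas

Calving efficiency — a beef cow's ability to produce calves within a fixed
window — is summarized by **NCP4**, the number of calves produced by 4 years
of age:

    NCP4 = (4 − AFC) / ACI + 1

where AFC is the age at first calving (years) and ACI the average calving
interval through the *t-age* calving (the first calving at or after the 4th
birthday). `ncp4gwas` implements, end to end, the quantitative-genetics
pipeline used to map a QTL for this trait in Japanese Black cattle:

1. **Phenotype construction** — nine record-selection criteria over raw
   calving histories, the NCP4/t-age formula, and farm/birth-year adjustment
   by animal-model REML on the pedigree numerator relationship matrix
   (y = Xb + u + e, var(u) = A·σ²a).
2. **Selective-genotyping GWAS** — upper/lower phenotype extremes (6.68%
   tails, at most 4 daughters per sire per extreme) scored 1/0, SNP QC
   (call rate > 99%, MAF > 0.01, HWE p > 0.001), an EMMAX-style mixed-model
   scan (variance components estimated once on the null model with a
   genotype-based relationship matrix, then per-SNP generalized least
   squares), per-group allele frequencies and odds ratios, the genomic
   inflation factor λGC, conditional scans, and the Lander–Kruglyak
   genome-wide threshold μ(T) = [C + 2ρGT²]α(T).
3. **Haplotype/LD analysis** — exact EM phasing of 2–4-SNP windows, D′ and
   r², QQ/Qq/qq diplotype classes, and masking/concordance scoring of
   imputation accuracy.
4. **Allelic imbalance** — the ratio of cDNA to gDNA Q/q peak-height ratios
   in heterozygotes, gDNA mixing-series calibration, and t-tests.
5. **Replication/variance decomposition** — least-square means of NCP4 per
   diplotype class with farm/year effects, Tukey–Kramer comparisons, the
   Q-to-q substitution effect a, and the haplotype variance 2p(1−p)a² as a
   share of phenotypic and genetic variance.
6. **A synthetic herd generator** — pedigrees with AI-sire structure,
   phased genotypes carrying a causal haplotype block in strong LD, calving
   histories whose NCP4 realizes an additive liability (so the filters and
   t-age logic run on raw dates), and Sanger peak-height tables. Defaults
   match the study population this pipeline models: h² = 0.11, causal
   haplotype frequency 0.313, substitution effect 0.054 calves (2.69% of
   phenotypic variance).

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
from ncp4gwas import SimulationConfig, PipelineConfig, run_pipeline

sim = SimulationConfig(seed=12, n_founders=400, male_founder_fraction=0.25,
                       n_generations=1, n_animals=1500, n_farms=4,
                       birth_year_range=(1996, 1999), n_snps=800,
                       n_chromosomes=8, causal_chromosome=8)
summary = run_pipeline(PipelineConfig(sim=sim), "demo_run")

ph, gw, rep = (summary["stages"][k] for k in ("phenotype", "gwas", "replication"))
print(f"records kept: {ph['records_out']}/{ph['records_in']}, REML h2 = {ph['heritability']:.3f}")
print(f"scan: {gw['n_upper']}+{gw['n_lower']} extremes, lambda_GC = {gw['lambda_gc']:.4f}, "
      f"pointwise alpha = {gw['pointwise_alpha']:.2e}")
print(f"top SNP {gw['top_snp']} (p = {gw['top_p']:.2e}); significant: "
      f"{gw['n_significant']} -> {gw['n_significant_after_conditioning']} after conditioning")
print(f"replication: a = {rep['substitution_effect']:.3f} calves, "
      f"share of V_P = {rep['share_of_phenotypic']:.4f}")
```

prints

```
records kept: 1282/1500, REML h2 = 0.118
scan: 86+86 extremes, lambda_GC = 0.9713, pointwise alpha = 2.47e-05
top SNP SNP8_2450600 (p = 6.25e-07); significant: 4 -> 0 after conditioning
replication: a = 0.015 calves, share of V_P = 0.0036
```

Reading the output: 1,282 of 1,500 simulated records survive the nine
selection criteria; REML on the pedigree recovers the simulated h² = 0.11
within sampling error. The scan of the 172 extreme cows is well calibrated
(λGC ≈ 0.97), four SNPs in the simulated causal block exceed the
genome-wide threshold (pointwise α = 2.47×10⁻⁵, i.e. −log10 ≈ 4.6), and
conditioning on the top SNP removes all of them — the single-QTL signature.
The replication stage re-estimates the substitution effect from the
non-extreme cows using EM-phased tag-SNP diplotypes; at this demo scale its
standard error is ≈ 0.012 calves, so the estimate scatters widely around
the simulated 0.054 (here a low draw, further attenuated by tag-SNP r² < 1
and by range restriction from removing the extremes). The recovery tests in
`tests/test_acceptance.py` average 50 such replicates and recover both the
effect and the variance share.

Every stage writes a tab-delimited table into the run directory
(`ncp4.tsv`, `association.tsv`, `ld_r2.tsv`, `replication.tsv`, ...) plus a
machine-readable `summary.json`; rerunning with the same configuration is
byte-identical. The same stages are available from the shell:

```sh
ncp4gwas all --out demo_run --seed 12
ncp4gwas gwas --ped g.ped --map g.map --pheno ncp4.tsv --out assoc.tsv
```

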