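"""Configuration objects for the synthetic herd and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: record-contamination event types, keyed by the filter they are meant to trip
CONTAMINATION_KEYS = (
    "incomplete",        # history truncated before the first calving at age >= 4 y
    "twin",              # a twin parturition
    "embryo_transfer",   # an embryo-transfer event
    "abortion",          # an abortion event
    "gestation",         # a gestation length outside 261-310 d
    "calving_interval",  # a calving interval outside 276-730 d
    "late_first_calving",  # age at first calving >= 1,128 d
    "multi_farm",        # the cow moved between farms
)


def default_contamination_rates() -> dict[str, float]:
    return {k: 0.02 for k in CONTAMINATION_KEYS}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic herd generator.

    The genetic defaults are the study conditions of the cattle population
    this package models: NCP4 heritability 0.11, a causal haplotype at
    frequency 0.313 with a Q-to-q substitution effect of 0.054 calves, and a
    phenotypic variance (net of farm and birth-year effects) such that the
    haplotype explains 2.69% of it: V_P = 2p(1-p)a^2 / 0.0269 = 0.0466.
    """

    seed: int = 0
    n_founders: int = 500
    n_generations: int = 2
    n_animals: int = 2000          # phenotyped cows (non-founder females)
    n_farms: int = 11
    birth_year_range: tuple[int, int] = (1992, 2006)
    heritability: float = 0.11
    phenotypic_variance: float = 0.0466   # calves^2, net of farm/year
    causal_haplotype_freq: float = 0.313
    substitution_effect: float = 0.054    # calves per Q allele
    n_snps: int = 3000
    ld_decay: float = 1e-8                # Morgans per bp (meiosis + founder LD)
    contamination_rates: dict[str, float] = field(default_factory=default_contamination_rates)
    # genome layout (a configurable map, not a replica of the bovine genome)
    n_chromosomes: int = 29
    snp_spacing_bp: int = 50_000
    causal_chromosome: int = 12
    causal_block_size: int = 5
    causal_block_spacing_bp: int = 300
    missing_rate: float = 0.002
    # phenotype construction
    mean_ncp4: float = 2.7
    farm_sd: float = 0.10                 # SD of fixed farm effects, calves
    year_sd: float = 0.05                 # SD of fixed birth-year effects, calves
    male_founder_fraction: float = 0.10
    ld_corr_scale: float = 2000.0         # population scaling of ld_decay into founder LD

    @property
    def qtl_variance(self) -> float:
        p, a = self.causal_haplotype_freq, self.substitution_effect
        return 2.0 * p * (1.0 - p) * a * a

    @property
    def qtl_variance_share(self) -> float:
        return self.qtl_variance / self.phenotypic_variance

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_generations > 0 and self.n_animals <= 0:
            raise ValueError("n_animals must be positive")
        if self.n_farms <= 0 or self.n_snps <= 0 or self.n_chromosomes <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be in [0, 1]")
        if self.phenotypic_variance <= 0:
            raise ValueError("phenotypic_variance must be positive")
        if not 0.0 < self.causal_haplotype_freq < 1.0:
            raise ValueError("causal_haplotype_freq must be strictly inside (0, 1)")
        if self.heritability + self.qtl_variance_share > 1.0 + 1e-12:
            raise ValueError("heritability + QTL variance share exceeds 1")
        if self.qtl_variance_share > self.heritability + 1e-12 and self.substitution_effect != 0:
            raise ValueError(
                "infeasible variance partition: QTL share exceeds heritability "
                f"({self.qtl_variance_share:.4f} > {self.heritability:.4f})"
            )
        for k, r in self.contamination_rates.items():
            if k not in CONTAMINATION_KEYS:
                raise ValueError(f"unknown contamination type {k!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"contamination rate {k} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        if self.ld_decay < 0:
            raise ValueError("ld_decay must be >= 0")
        y0, y1 = self.birth_year_range
        if y1 < y0:
            raise ValueError("birth_year_range reversed")

    def rng(self, stage: int) -> np.random.Generator:
        """Per-stage substream of the one global seed."""
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), int(stage))))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["birth_year_range"] = list(self.birth_year_range)
        return d


def clean_config(**overrides) -> SimulationConfig:
    """A SimulationConfig with all contamination switched off."""
    cfg = SimulationConfig(contamination_rates={k: 0.0 for k in CONTAMINATION_KEYS}, **overrides)
    cfg.validate()
    return cfg
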