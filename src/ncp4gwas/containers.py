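"""Shared in-memory containers for the pipeline.

Dosages are coded on the alt allele (0/1/2) with ``MISSING`` (-1) as the
missing sentinel; genomic positions are 1-based bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: days per year used everywhere ages in days are converted to years
DAYS_PER_YEAR = 365.25


@dataclass
class GenotypePanel:
    """Animals x SNPs dosage matrix plus the SNP map.

    ``snps`` is a DataFrame with columns snp_id, chrom, pos, ref, alt
    (one row per SNP, in matrix column order).
    """

    animal_ids: np.ndarray
    snps: pd.DataFrame
    dosages: np.ndarray  # int8, shape (n_animals, n_snps), MISSING for no-call

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.animal_ids), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or the missing sentinel")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def observed(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.dosages != MISSING

    def call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over called genotypes."""
        obs = self.observed()
        d = np.where(obs, self.dosages, 0).astype(float)
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return d.sum(axis=0) / (2.0 * n)

    def minor_allele_freq(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def subset_animals(self, ids) -> "GenotypePanel":
        idx = pd.Index(self.animal_ids).get_indexer(np.asarray(ids))
        if (idx < 0).any():
            missing = np.asarray(ids)[idx < 0]
            raise KeyError(f"animals not in panel: {missing[:5].tolist()}")
        return GenotypePanel(np.asarray(ids), self.snps, self.dosages[idx])

    def subset_snps(self, snp_ids) -> "GenotypePanel":
        idx = pd.Index(self.snps["snp_id"]).get_indexer(np.asarray(snp_ids))
        if (idx < 0).any():
            raise KeyError("SNP ids not in panel")
        return GenotypePanel(
            self.animal_ids, self.snps.iloc[idx].reset_index(drop=True), self.dosages[:, idx]
        )

    def snp_index(self, snp_id: str) -> int:
        pos = pd.Index(self.snps["snp_id"]).get_loc(snp_id)
        return int(pos)


@dataclass
class ReproductionRecord:
    """One cow's calving history.

    Dates are integer days since the epoch (1990-01-01 by convention of the
    simulator; only differences matter). Event flags are per calving.
    """

    cow_id: str
    sire_id: str
    dam_id: str
    farm_id: int
    birth_date: int
    birth_year: int
    calving_dates: list[int] = field(default_factory=list)
    gestation_lengths: list[int] = field(default_factory=list)
    twin_flags: list[bool] = field(default_factory=list)
    et_flags: list[bool] = field(default_factory=list)
    abortion_flags: list[bool] = field(default_factory=list)
    farm_history: list[int] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.calving_dates)
        if any(len(v) != n for v in (self.gestation_lengths, self.twin_flags,
                                     self.et_flags, self.abortion_flags)):
            raise ValueError(f"record {self.cow_id}: per-calving fields have unequal lengths")
        if any(b <= a for a, b in zip(self.calving_dates, self.calving_dates[1:])):
            raise ValueError(f"record {self.cow_id}: calving_dates not strictly increasing")
        if any(g <= 0 for g in self.gestation_lengths):
            raise ValueError(f"record {self.cow_id}: non-positive gestation length")
        if n and self.calving_dates[0] <= self.birth_date:
            raise ValueError(f"record {self.cow_id}: calving before birth")

    def calving_ages_days(self) -> np.ndarray:
        return np.asarray(self.calving_dates) - self.birth_date

    def calving_intervals_days(self) -> np.ndarray:
        return np.diff(np.asarray(self.calving_dates))
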