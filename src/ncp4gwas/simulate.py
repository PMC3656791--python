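"""Synthetic herd generator.

Produces pedigrees, SNP panels carrying a causal haplotype block, calving
histories whose NCP4 realizes an additive liability, and Sanger peak-height
tables — the inputs every downstream stage consumes.

Mating design: founder males act as AI sires for every generation (as in
commercial beef herds); all non-founder animals are female and become the
phenotyped cows. Dams of generation g are the females of generation g-1.

Founder haplotypes are drawn from a latent Gaussian AR(1) copula along each
chromosome, so linkage disequilibrium decays smoothly with bp distance; the
causal block shares one allele frequency across its SNPs so that complete
linkage yields r^2 = 1. Offspring haplotypes follow Mendelian transmission
with Poisson (Haldane) crossovers at ``ld_decay`` Morgans/bp.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SimulationConfig
from .containers import DAYS_PER_YEAR, MISSING, GenotypePanel, ReproductionRecord

EPOCH_YEAR = 1990  # day 0 of integer dates

_STAGE_PEDIGREE, _STAGE_GENOTYPES, _STAGE_RECORDS, _STAGE_PEAKS = range(4)


# ---------------------------------------------------------------------------
# pedigree

def simulate_pedigree(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a pedigree table (animal, sire, dam, sex, birth_year, farm).

    Founders have unknown parents (``"0"``); every non-founder's parents
    precede it in the table. Deterministic under a fixed seed.
    """
    config.validate()
    rng = config.rng(_STAGE_PEDIGREE)
    n_sires = max(1, round(config.male_founder_fraction * config.n_founders))
    n_sires = min(n_sires, config.n_founders - 1)  # always at least one dam
    n_dams = config.n_founders - n_sires

    y0, y1 = config.birth_year_range
    rows = []
    sire_ids = [f"S{i + 1:04d}" for i in range(n_sires)]
    dam_ids = [f"D{i + 1:04d}" for i in range(n_dams)]
    for sid in sire_ids:
        rows.append((sid, "0", "0", "M", y0, int(rng.integers(1, config.n_farms + 1))))
    for did in dam_ids:
        rows.append((did, "0", "0", "F", y0, int(rng.integers(1, config.n_farms + 1))))

    if config.n_generations > 0:
        per_gen = [config.n_animals // config.n_generations] * config.n_generations
        for i in range(config.n_animals % config.n_generations):
            per_gen[i] += 1
        n_years = y1 - y0 + 1
        dams_prev = dam_ids
        counter = 0
        for g, n_off in enumerate(per_gen, start=1):
            gen_ids = []
            lo = y0 + (g - 1) * n_years // config.n_generations
            hi = y0 + g * n_years // config.n_generations - 1
            hi = max(lo, hi)
            for _ in range(n_off):
                counter += 1
                aid = f"C{counter:06d}"
                sire = sire_ids[int(rng.integers(0, n_sires))]
                dam = dams_prev[int(rng.integers(0, len(dams_prev)))]
                year = int(rng.integers(lo, hi + 1))
                farm = int(rng.integers(1, config.n_farms + 1))
                rows.append((aid, sire, dam, "F", year, farm))
                gen_ids.append(aid)
            dams_prev = gen_ids

    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "birth_year", "farm"])


def _pedigree_indices(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """sire/dam row indices (-1 for unknown), validating that parents precede."""
    pos = {a: i for i, a in enumerate(pedigree["animal"])}
    if len(pos) != len(pedigree):
        raise ValueError("duplicate animal ids in pedigree")
    si = np.full(len(pedigree), -1, dtype=np.int64)
    di = np.full(len(pedigree), -1, dtype=np.int64)
    for i, (s, d) in enumerate(zip(pedigree["sire"], pedigree["dam"])):
        for arr, parent in ((si, s), (di, d)):
            if parent != "0":
                j = pos.get(parent)
                if j is None:
                    raise ValueError(f"parent {parent} of {pedigree['animal'].iloc[i]} not in pedigree")
                if j >= i:
                    raise ValueError(f"parent {parent} does not precede offspring")
                arr[i] = j
    return si, di


# ---------------------------------------------------------------------------
# genotypes

def _snp_map(config: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """SNP map plus the column indices of the causal block (centre = causal)."""
    per_chrom = [config.n_snps // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_snps % config.n_chromosomes):
        per_chrom[i] += 1
    chroms, positions = [], []
    for c, m in enumerate(per_chrom, start=1):
        chroms.extend([c] * m)
        positions.extend(config.snp_spacing_bp * (j + 1) for j in range(m))
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)

    causal_chrom = min(config.causal_chromosome, config.n_chromosomes)
    on_chrom = np.flatnonzero(chroms == causal_chrom)
    k = min(config.causal_block_size, len(on_chrom))
    start = len(on_chrom) // 2 - k // 2
    block = on_chrom[start:start + k]
    # compress the block to tight spacing so it forms one LD block
    positions[block] = positions[block[0]] + config.causal_block_spacing_bp * np.arange(k)

    snp_ids = [f"SNP{c}_{p}" for c, p in zip(chroms, positions)]
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=config.n_snps)
    alt = (ref + rng.integers(1, 4, size=config.n_snps)) % 4
    snps = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chroms, "pos": positions,
        "ref": bases[ref], "alt": bases[alt],
    })
    return snps, block


def _founder_haplotypes(config: SimulationConfig, snps: pd.DataFrame, block: np.ndarray,
                        n_haplotypes: int, rng: np.random.Generator) -> np.ndarray:
    """Latent AR(1) copula haplotypes, one row per founder haplotype."""
    m = len(snps)
    freq = rng.uniform(0.05, 0.5, size=m)
    freq[block] = config.causal_haplotype_freq
    thresh = norm.ppf(freq)

    chroms = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    new_chrom = np.r_[True, chroms[1:] != chroms[:-1]]
    gap = np.r_[0, np.maximum(np.diff(pos), 0)]
    rho = np.exp(-config.ld_corr_scale * config.ld_decay * gap)
    rho[new_chrom] = 0.0
    out = np.empty((n_haplotypes, m), dtype=np.int8)
    z = np.empty(n_haplotypes)
    for j in range(m):
        noise = rng.standard_normal(n_haplotypes)
        if rho[j] == 0.0:
            z = noise
        else:
            z = rho[j] * z + math.sqrt(1.0 - rho[j] ** 2) * noise
        out[:, j] = z < thresh[j]
    return out


def _meiosis(hap_pair: np.ndarray, chrom_slices: list[slice], pos: np.ndarray,
             morgans: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a (2, m) parental haplotype pair."""
    gamete = np.empty(hap_pair.shape[1], dtype=np.int8)
    for sl, L in zip(chrom_slices, morgans):
        start = int(rng.integers(0, 2))
        n_x = rng.poisson(L)
        if n_x == 0:
            gamete[sl] = hap_pair[start, sl]
            continue
        p = pos[sl]
        cuts = np.sort(rng.uniform(p[0], p[-1], size=n_x))
        seg = start + np.searchsorted(cuts, p, side="right")
        gamete[sl] = np.take_along_axis(hap_pair[:, sl], (seg % 2)[None, :], axis=0)[0]
    return gamete


def simulate_genotypes(config: SimulationConfig, pedigree: pd.DataFrame
                       ) -> tuple[GenotypePanel, np.ndarray, dict]:
    """Simulate phased genotypes down the pedigree.

    Returns the dosage panel, the true phased haplotypes (n, 2, m) and a
    truth dict with the causal annotation (block column indices, causal SNP,
    per-animal Q dosage, realized founder Q frequency).
    """
    config.validate()
    si, di = _pedigree_indices(pedigree)
    rng = config.rng(_STAGE_GENOTYPES)
    snps, block = _snp_map(config, rng)

    n = len(pedigree)
    m = len(snps)
    founders = np.flatnonzero((si < 0) & (di < 0))
    fhap = _founder_haplotypes(config, snps, block, 2 * len(founders), rng)

    chroms = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy().astype(float)
    chrom_slices = []
    start = 0
    for c in np.unique(chroms):
        stop = start + int((chroms == c).sum())
        chrom_slices.append(slice(start, stop))
        start = stop
    morgans = np.array([config.ld_decay * (pos[sl][-1] - pos[sl][0]) for sl in chrom_slices])

    hap = np.empty((n, 2, m), dtype=np.int8)
    f_iter = iter(range(2 * len(founders)))
    for i in range(n):
        if si[i] < 0 and di[i] < 0:
            hap[i, 0] = fhap[next(f_iter)]
            hap[i, 1] = fhap[next(f_iter)]
        else:
            hap[i, 0] = _meiosis(hap[si[i]], chrom_slices, pos, morgans, rng)
            hap[i, 1] = _meiosis(hap[di[i]], chrom_slices, pos, morgans, rng)

    dosages = hap.sum(axis=1, dtype=np.int8)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)

    causal_col = int(block[len(block) // 2])
    truth = {
        "block_cols": block,
        "block_snps": snps["snp_id"].iloc[block].tolist(),
        "causal_col": causal_col,
        "causal_snp": snps["snp_id"].iloc[causal_col],
        "q_dosage": hap[:, :, causal_col].sum(axis=1).astype(np.int8),
        "founder_q_freq": float(fhap[:, causal_col].mean()),
    }
    panel = GenotypePanel(pedigree["animal"].to_numpy(), snps, dosages)
    return panel, hap, truth


# ---------------------------------------------------------------------------
# reproduction records

# schedule-feasible calving intervals, with a margin inside the 276-730 d
# filter window so that day rounding cannot push a clean record over an edge
_ACI_MIN_Y = 281 / DAYS_PER_YEAR
_ACI_MAX_Y = 712 / DAYS_PER_YEAR


def _schedule_from_target(ncp4: float, afc_years: float, birth_date: int,
                          rng: np.random.Generator) -> tuple[list[int], list[int], float]:
    """Calving dates realizing the target NCP4 at the given age at first calving."""
    lo = 1.0 + (4.0 - afc_years) / _ACI_MAX_Y
    hi = 1.0 + (4.0 - afc_years) / _ACI_MIN_Y
    y = min(max(ncp4, lo), hi)
    aci = (4.0 - afc_years) / (y - 1.0)
    k = math.ceil((4.0 - afc_years) / aci - 1e-9)
    ages = afc_years + aci * np.arange(k + 1)
    dates = birth_date + np.rint(ages * DAYS_PER_YEAR).astype(int)
    gest = np.clip(np.rint(rng.normal(285.0, 5.0, size=k + 1)), 265, 305).astype(int)
    return dates.tolist(), gest.tolist(), y


def _contaminate(rec: ReproductionRecord, kinds: list[str], config: SimulationConfig,
                 rng: np.random.Generator) -> None:
    for kind in kinds:
        n = len(rec.calving_dates)
        j = int(rng.integers(0, n))
        if kind == "incomplete":
            keep = max(1, int(np.sum(rec.calving_ages_days() < 4 * DAYS_PER_YEAR)))
            for name in ("calving_dates", "gestation_lengths", "twin_flags",
                         "et_flags", "abortion_flags"):
                setattr(rec, name, getattr(rec, name)[:keep])
        elif kind == "twin":
            rec.twin_flags[j] = True
        elif kind == "embryo_transfer":
            rec.et_flags[j] = True
        elif kind == "abortion":
            rec.abortion_flags[j] = True
        elif kind == "gestation":
            rec.gestation_lengths[j] = int(rng.choice([250, 255, 315, 320]))
        elif kind == "calving_interval":
            if n >= 2:
                shift = 750 - (rec.calving_dates[1] - rec.calving_dates[0])
                if shift > 0:
                    rec.calving_dates = rec.calving_dates[:1] + [d + shift for d in rec.calving_dates[1:]]
        elif kind == "late_first_calving":
            shift = int(1150 - (rec.calving_dates[0] - rec.birth_date))
            if shift > 0:
                rec.calving_dates = [d + shift for d in rec.calving_dates]
        elif kind == "multi_farm":
            other = 1 + (rec.farm_id % config.n_farms)
            rec.farm_history = [rec.farm_id, other]


def simulate_records(config: SimulationConfig, pedigree: pd.DataFrame,
                     truth: dict | None = None
                     ) -> tuple[list[ReproductionRecord], pd.DataFrame]:
    """Simulate calving histories for every non-founder female.

    The latent liability is farm + birth-year + QTL + polygenic + residual
    (variances per the config partition); the calving schedule is solved so
    the cow's NCP4 equals the (feasibility-clipped) liability. Returns the
    records and a truth table (breeding values, liability, target NCP4).
    """
    config.validate()
    rng = config.rng(_STAGE_RECORDS)
    v_p = config.phenotypic_variance
    v_qtl = config.qtl_variance if truth is not None and config.substitution_effect else 0.0
    v_poly = config.heritability * v_p - v_qtl
    if v_poly < -1e-12:
        raise ValueError("infeasible variance partition: polygenic variance negative")
    v_poly = max(v_poly, 0.0)
    v_e = (1.0 - config.heritability) * v_p

    farm_eff = rng.normal(0.0, config.farm_sd, size=config.n_farms)
    y0, y1 = config.birth_year_range
    year_eff = rng.normal(0.0, config.year_sd, size=y1 - y0 + 1)

    si, di = _pedigree_indices(pedigree)
    n = len(pedigree)
    bv = np.zeros(n)
    sd_poly = math.sqrt(v_poly)
    mendelian = rng.standard_normal(n)
    for i in range(n):
        if si[i] < 0 and di[i] < 0:
            bv[i] = sd_poly * mendelian[i]
        else:
            mid = 0.0
            k = 2
            if si[i] >= 0:
                mid += 0.5 * bv[si[i]]
                k -= 1
            if di[i] >= 0:
                mid += 0.5 * bv[di[i]]
                k -= 1
            bv[i] = mid + math.sqrt((2 + k) / 4) * sd_poly * mendelian[i]

    p = config.causal_haplotype_freq
    a = config.substitution_effect
    qd = (np.asarray(truth["q_dosage"], dtype=float) if truth is not None
          else np.full(n, 2.0 * p))

    is_cow = (pedigree["sex"].to_numpy() == "F") & (si >= 0)
    resid = rng.normal(0.0, math.sqrt(v_e), size=n)
    farms = pedigree["farm"].to_numpy()
    years = pedigree["birth_year"].to_numpy()

    # pre-draw contamination events so the schedule RNG stream stays aligned
    records: list[ReproductionRecord] = []
    truth_rows = []
    for i in np.flatnonzero(is_cow):
        liability = (config.mean_ncp4 + farm_eff[farms[i] - 1] + year_eff[years[i] - y0]
                     + a * (qd[i] - 2.0 * p) + bv[i] + resid[i])
        afc = rng.uniform(1.9, 2.4)
        birth_date = int(round((years[i] - EPOCH_YEAR) * DAYS_PER_YEAR + rng.uniform(0, 364)))
        dates, gest, realized = _schedule_from_target(liability, afc, birth_date, rng)
        rec = ReproductionRecord(
            cow_id=pedigree["animal"].iloc[i], sire_id=pedigree["sire"].iloc[i],
            dam_id=pedigree["dam"].iloc[i], farm_id=int(farms[i]),
            birth_date=birth_date, birth_year=int(years[i]),
            calving_dates=dates, gestation_lengths=gest,
            twin_flags=[False] * len(dates), et_flags=[False] * len(dates),
            abortion_flags=[False] * len(dates), farm_history=[int(farms[i])],
        )
        kinds = [k for k in config.contamination_rates
                 if config.contamination_rates[k] > 0 and rng.random() < config.contamination_rates[k]]
        if kinds:
            _contaminate(rec, kinds, config, rng)
        rec.validate()
        records.append(rec)
        truth_rows.append((rec.cow_id, bv[i], a * (qd[i] - 2.0 * p), liability, realized,
                           int(qd[i]) if truth is not None else -1))

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["animal", "polygenic_bv", "qtl_effect", "liability", "target_ncp4", "q_dosage"],
    )
    return records, truth_df


# ---------------------------------------------------------------------------
# Sanger peak traces

def simulate_peak_traces(n_animals: int, true_ratio: float, noise_cv: float,
                         seed: int, tissue: str = "tissue") -> pd.DataFrame:
    """Peak-height table for heterozygotes: columns animal_id, tissue,
    cdna_Q, cdna_q, gdna_Q, gdna_q.

    The gDNA Q:q ratio is centred (median) at 1 — a heterozygote carries one
    copy of each allele — and the cDNA ratio at ``true_ratio``, both with
    multiplicative lognormal noise of coefficient of variation ``noise_cv``.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _STAGE_PEAKS)))
    sigma = math.sqrt(math.log1p(noise_cv ** 2))
    base_g = 1000.0 * rng.uniform(0.5, 1.5, size=n_animals)
    base_c = 1000.0 * rng.uniform(0.5, 1.5, size=n_animals)
    ratio_g = np.exp(sigma * rng.standard_normal(n_animals))
    ratio_c = true_ratio * np.exp(sigma * rng.standard_normal(n_animals))
    return pd.DataFrame({
        "animal_id": [f"H{i + 1:04d}" for i in range(n_animals)],
        "tissue": tissue,
        "cdna_Q": base_c * ratio_c,
        "cdna_q": base_c,
        "gdna_Q": base_g * ratio_g,
        "gdna_q": base_g,
    })
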