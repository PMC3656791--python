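"""Selective-genotyping mixed-model association scan.

Workflow: rank cows on adjusted NCP4, take the upper/lower tails with a
per-sire cap, code the response 0/1, QC the SNP panel, build a genetic
relationship matrix, estimate the polygenic variance once on the null model
(the EMMAX approximation) and test each SNP by generalized least squares on
the rotated data. Genome-wide significance uses the Lander-Kruglyak dense-map
correction mu(T) = [C + 2 rho G T^2] alpha(T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, f as f_dist

from .containers import MISSING, GenotypePanel
from .mixedmodel import reml_fit, rotate

CHI2_1DF_MEDIAN = float(chi2.ppf(0.5, 1))  # 0.4549364...


@dataclass
class ExtremeDesign:
    upper_ids: list[str]
    lower_ids: list[str]
    upper_percentile: float
    lower_percentile: float
    per_sire_cap: int

    @property
    def animal_ids(self) -> np.ndarray:
        return np.asarray(self.upper_ids + self.lower_ids)

    @property
    def response(self) -> np.ndarray:
        return np.r_[np.ones(len(self.upper_ids)), np.zeros(len(self.lower_ids))]


@dataclass
class GeneticRelationshipMatrix:
    animal_ids: np.ndarray
    matrix: np.ndarray
    mode: str


@dataclass
class ThresholdSpec:
    n_chromosomes: int
    rho: float
    genome_length_morgans: float
    genomewide_alpha: float
    pointwise_alpha: float
    chi2_threshold: float  # 1-df chi-square statistic at the pointwise level


@dataclass
class QcReport:
    n_in: int
    n_retained: int
    failed_call_rate: int
    failed_maf: int
    failed_hwe: int


# ---------------------------------------------------------------------------
# extreme-group selection

def _tail_size(n: int, pct: float) -> int:
    return int(math.floor(n * pct)) + 1


def _cap_tail(ranked: list[tuple[str, str]], size: int, cap: int,
              rng: np.random.Generator) -> list[str]:
    """Take the first ``size`` animals of a ranked (animal, sire) list,
    enforcing the per-sire cap.

    Within the initially selected tail, excess daughters of an
    over-represented sire are dropped by seeded random choice; dropped slots
    are refilled with the next-ranked animals, skipping daughters of sires
    already at the cap (so refills never evict earlier, more extreme picks).
    """
    tail = ranked[:size]
    rest = ranked[size:]
    members: dict[str, list[int]] = {}
    for idx, (_, sire) in enumerate(tail):
        members.setdefault(sire, []).append(idx)
    keep = np.ones(len(tail), dtype=bool)
    counts: dict[str, int] = {}
    for sire, idxs in members.items():
        if len(idxs) > cap:
            drop = rng.choice(len(idxs), size=len(idxs) - cap, replace=False)
            for d in drop:
                keep[idxs[d]] = False
        counts[sire] = min(len(idxs), cap)
    chosen = [aid for (aid, _), k in zip(tail, keep) if k]
    for aid, sire in rest:
        if len(chosen) >= size:
            break
        if counts.get(sire, 0) >= cap:
            continue
        chosen.append(aid)
        counts[sire] = counts.get(sire, 0) + 1
    return chosen


def select_extremes(ncp4: pd.DataFrame, *, value_col: str = "adjusted_ncp4",
                    upper_pct: float = 0.0668, lower_pct: float = 0.0668,
                    per_sire_cap: int = 4, seed: int = 0) -> ExtremeDesign:
    """Select upper/lower phenotype extremes with a per-sire cap.

    ``ncp4`` needs columns animal, sire and ``value_col``. Tail size is
    floor(n * pct) + 1. Ranking ties break by (value, animal id); the only
    randomness is the seeded choice of which over-cap daughters to drop.
    """
    if upper_pct + lower_pct >= 1.0:
        raise ValueError("upper and lower percentiles overlap")
    df = ncp4.sort_values([value_col, "animal"], kind="mergesort").reset_index(drop=True)
    n = len(df)
    n_up = _tail_size(n, upper_pct)
    n_lo = _tail_size(n, lower_pct)
    if n_up + n_lo > n:
        raise ValueError("percentiles too large for the sample")
    rng = np.random.default_rng(seed)
    pairs = list(zip(df["animal"], df["sire"].astype(str)))
    upper = _cap_tail(pairs[::-1], n_up, per_sire_cap, rng)
    lower = _cap_tail(pairs, n_lo, per_sire_cap, rng)
    if set(upper) & set(lower):
        raise ValueError("upper and lower extremes overlap")
    return ExtremeDesign(upper, lower, upper_pct, lower_pct, per_sire_cap)


# ---------------------------------------------------------------------------
# SNP quality control

def hwe_chi2_p(dosages: np.ndarray) -> float:
    """1-df chi-square HWE test from called genotype counts at one SNP."""
    d = dosages[dosages != MISSING]
    n = len(d)
    if n == 0:
        return 1.0
    counts = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()], float)
    p_alt = (counts[1] + 2 * counts[2]) / (2 * n)
    if p_alt in (0.0, 1.0):
        return 1.0
    exp = n * np.array([(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt ** 2])
    stat = float(np.sum((counts - exp) ** 2 / exp))
    return float(chi2.sf(stat, 1))


def qc_snps(panel: GenotypePanel, *, call_rate_min: float = 0.99,
            maf_min: float = 0.01, hwe_p_min: float = 0.001
            ) -> tuple[list[str], QcReport]:
    """Retain SNPs with call rate > min, MAF > min and HWE p > min (all strict)."""
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    cr = panel.call_rate()
    maf = panel.minor_allele_freq()
    hwe = np.array([hwe_chi2_p(panel.dosages[:, j]) for j in range(panel.n_snps)])
    ok_cr = cr > call_rate_min
    ok_maf = np.nan_to_num(maf, nan=0.0) > maf_min
    ok_hwe = hwe > hwe_p_min
    keep = ok_cr & ok_maf & ok_hwe
    report = QcReport(panel.n_snps, int(keep.sum()),
                      int((~ok_cr).sum()), int((~ok_maf).sum()), int((~ok_hwe).sum()))
    return panel.snps["snp_id"].to_numpy()[keep].tolist(), report


# ---------------------------------------------------------------------------
# genetic relationship matrix

def mean_imputed(panel: GenotypePanel) -> np.ndarray:
    """Float dosage matrix with missing calls replaced by the SNP mean."""
    d = panel.dosages.astype(float)
    obs = panel.observed()
    means = np.where(obs, d, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    return np.where(obs, d, means[None, :])


def compute_grm(panel: GenotypePanel, mode: str = "ibs") -> GeneticRelationshipMatrix:
    """Genetic relationship matrix from genotypes.

    ``ibs``: pairwise fraction of shared alleles (1 - mean |dosage diff| / 2)
    over pairwise-complete SNPs. ``standardized``: cross-product of centred,
    variance-scaled dosages over the SNP count (missing mean-imputed).
    """
    if panel.n_snps < 2:
        raise ValueError("at least 2 SNPs required for a GRM")
    if mode == "ibs":
        obs = panel.observed().astype(np.float32)
        onehot = [(np.where(panel.observed(), panel.dosages, -9) == k).astype(np.float32)
                  for k in (0, 1, 2)]
        a0, a1, a2 = onehot
        diff = a0 @ a1.T + a1 @ a2.T + 2.0 * (a0 @ a2.T)
        diff = diff + diff.T
        n_pair = obs @ obs.T
        sim = 1.0 - diff.astype(float) / (2.0 * np.maximum(n_pair.astype(float), 1))
        sim = 0.5 * (sim + sim.T)
        return GeneticRelationshipMatrix(panel.animal_ids, sim, "ibs")
    if mode == "standardized":
        d = mean_imputed(panel)
        f = d.mean(axis=0) / 2.0
        sd = np.sqrt(2.0 * f * (1.0 - f))
        keep = sd > 0
        z = (d[:, keep] - 2.0 * f[keep]) / sd[keep]
        g = z @ z.T / keep.sum()
        return GeneticRelationshipMatrix(panel.animal_ids, g, "standardized")
    raise ValueError(f"unknown GRM mode {mode!r}")


# ---------------------------------------------------------------------------
# EMMAX-style scan

@dataclass
class ScanResult:
    table: pd.DataFrame
    pseudo_heritability: float
    sigma_g2: float
    sigma_e2: float
    lambda_gc: float
    conditioned_on: list[str] = field(default_factory=list)


def emmax_scan(response: np.ndarray, panel: GenotypePanel,
               grm: GeneticRelationshipMatrix,
               covariates: np.ndarray | None = None,
               condition_snps: list[str] | None = None,
               design: ExtremeDesign | None = None,
               null_variances: tuple[float, float] | None = None) -> ScanResult:
    """Mixed-model association of a 0/1 extreme-group response with each SNP.

    Variance components are estimated once on the null model (intercept +
    covariates) by REML on the GRM eigenbasis, then every SNP is tested by
    GLS on the rotated data with a 1-df chi-square Wald statistic. A SNP
    whose residual variance after projecting on the covariates is ~0 (e.g.
    conditioning on itself) is flagged not-estimable. ``null_variances``
    allows fixing (sigma_g2, sigma_e2), e.g. (0, v) for the OLS limit.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if panel.n_animals != n or grm.matrix.shape[0] != n:
        raise ValueError("response, panel and GRM are not aligned on animals")

    cov_cols = [np.ones(n)]
    cond_ids = list(condition_snps or [])
    dos = mean_imputed(panel)
    for sid in cond_ids:
        cov_cols.append(dos[:, panel.snp_index(sid)])
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        cov_cols.extend(cov.T)
    x = np.column_stack(cov_cols)

    try:
        rot = rotate(y, x, kinship=grm.matrix)
    except ValueError:  # near-PSD empirical matrix: small ridge, then clip
        rot = rotate(y, x, kinship=grm.matrix + 1e-6 * np.eye(n))
    if null_variances is None:
        res = reml_fit(rot, method="profile")
        sigma_g2, sigma_e2 = res.sigma_a2, res.sigma_e2
    else:
        sigma_g2, sigma_e2 = null_variances
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)

    # weights known up to a scalar; the scalar is re-estimated per SNP so the
    # sigma_g2 = 0, GRM = I limit reduces exactly to OLS
    v = sigma_g2 * rot.eigvals + sigma_e2
    w = 1.0 / v
    xr = rot.x_rot
    p_cov = xr.shape[1]
    xw = xr * w[:, None]
    xtwx_inv = np.linalg.inv(xr.T @ xw)
    g_rot = rot.eigvecs.T @ dos                      # rotated dosages, n x m
    g_perp = g_rot - xr @ (xtwx_inv @ (xw.T @ g_rot))
    denom = np.einsum("ij,ij->j", g_perp * w[:, None], g_perp)
    y_perp = rot.y_rot - xr @ (xtwx_inv @ (xw.T @ rot.y_rot))
    numer = (g_perp * w[:, None]).T @ y_perp
    ypwy = float(np.sum(w * y_perp * y_perp))

    estimable = denom > 1e-10 * max(float(denom.max()), 1.0)
    df_resid = n - p_cov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(estimable, numer / denom, np.nan)
        rss = np.maximum(ypwy - numer * numer / np.where(estimable, denom, np.nan), 0.0)
        scale = rss / df_resid
        se = np.sqrt(scale / denom)
        stat = beta * beta * denom / scale
        # squared-Wald statistic referred to F(1, df): the exact finite-sample
        # reference of the GLS t-test (chi-square in the large-n limit)
        pval = np.where(estimable, f_dist.sf(stat, 1, df_resid), np.nan)

    tab = panel.snps[["snp_id", "chrom", "pos"]].copy()
    tab["beta"] = beta
    tab["se"] = se
    tab["chisq"] = stat
    tab["p"] = pval
    tab["estimable"] = estimable
    if design is not None:
        fu, fl, orr = [], [], []
        for sid in tab["snp_id"]:
            u, l, o = group_frequencies_and_or(panel, design, sid)
            fu.append(u)
            fl.append(l)
            orr.append(o)
        tab["freq_upper"] = fu
        tab["freq_lower"] = fl
        tab["odds_ratio"] = orr
    lam = genomic_inflation(tab.loc[tab["estimable"], "p"].to_numpy())
    return ScanResult(tab, h2, sigma_g2, sigma_e2, lam, cond_ids)


# ---------------------------------------------------------------------------
# group frequencies / odds ratio

def odds_ratio(freq_upper: float, freq_lower: float) -> float:
    """Odds ratio of one allele between extremes: [f_u/(1-f_u)] / [f_l/(1-f_l)]."""
    if freq_upper in (0.0, 1.0) or freq_lower in (0.0, 1.0):
        return math.inf
    return (freq_upper / (1.0 - freq_upper)) / (freq_lower / (1.0 - freq_lower))


def group_frequencies_and_or(panel: GenotypePanel, design: ExtremeDesign,
                             snp_id: str) -> tuple[float, float, float]:
    """Per-extreme frequency of the upper-enriched allele, plus its odds ratio."""
    j = panel.snp_index(snp_id)
    idx = pd.Index(panel.animal_ids)
    rows_u = idx.get_indexer(design.upper_ids)
    rows_l = idx.get_indexer(design.lower_ids)
    if (rows_u < 0).any() or (rows_l < 0).any():
        raise KeyError("extreme animals missing from panel")

    def _freq(rows: np.ndarray) -> float:
        d = panel.dosages[rows, j]
        d = d[d != MISSING]
        if len(d) == 0:
            raise ValueError(f"SNP {snp_id} not genotyped in one extreme")
        return float(d.sum()) / (2.0 * len(d))

    fu, fl = _freq(rows_u), _freq(rows_l)
    if fu < fl:  # report the allele enriched in the upper extreme
        fu, fl = 1.0 - fu, 1.0 - fl
    return fu, fl, odds_ratio(fu, fl)


# ---------------------------------------------------------------------------
# scan diagnostics

def genomic_inflation(p_values: np.ndarray) -> float:
    """lambda_GC: median 1-df chi-square quantile of the p-values over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values outside (0, 1]")
    return float(np.median(chi2.isf(p, 1)) / CHI2_1DF_MEDIAN)


def lander_kruglyak_threshold(n_chromosomes: int = 29, rho: float = 2.0,
                              genome_length_morgans: float = 28.0,
                              genomewide_alpha: float = 0.05) -> ThresholdSpec:
    """Solve [C + 2 rho G T^2] alpha(T) = genome-wide alpha for the pointwise level.

    T is the normal-scale statistic, so T^2 is the 1-df chi-square threshold
    and alpha(T) its upper-tail probability. Solved by root bracketing to
    relative tolerance 1e-10; the left-hand side is increasing in alpha, so
    the root is unique in (0, genomewide_alpha].
    """
    c, g = n_chromosomes, genome_length_morgans
    if c < 1 or g < 0 or rho <= 0 or not 0 < genomewide_alpha < 1:
        raise ValueError("invalid threshold parameters")

    def f(alpha: float) -> float:
        t2 = chi2.isf(alpha, 1)
        return (c + 2.0 * rho * g * t2) * alpha - genomewide_alpha

    lo = 1e-300
    if f(genomewide_alpha) < 0:
        raise ValueError("no root at or below the genome-wide level")
    alpha = brentq(f, lo, genomewide_alpha, rtol=1e-12, xtol=1e-300)
    return ThresholdSpec(c, rho, g, genomewide_alpha, float(alpha),
                         float(chi2.isf(alpha, 1)))
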