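"""Windowed EM haplotype phasing, linkage disequilibrium, diplotype classes
and imputation-accuracy scoring.

Phasing is exact EM over all haplotype pairs in short windows (k <= 4 SNPs),
assuming Hardy-Weinberg pairing of haplotypes; the loci of interest here span
2-3 SNPs, so genome-scale HMM phasing is deliberately out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .containers import MISSING, GenotypePanel


@dataclass
class HaplotypeFrequencySet:
    snp_ids: list[str]
    haplotypes: list[str]          # strings like "A-G" (one allele per SNP)
    hap_alleles: np.ndarray        # (H, k) 0 = ref, 1 = alt
    frequencies: np.ndarray        # (H,), sums to 1
    loglik: float
    n_iter: int
    converged: bool

    def freq_of(self, alleles: tuple[int, ...]) -> float:
        match = (self.hap_alleles == np.asarray(alleles)).all(axis=1)
        return float(self.frequencies[match].sum())


@dataclass
class ConcordanceReport:
    masked_genotypes: int
    matched_alleles: int
    matched_genotypes: int

    @property
    def allelic_discordance(self) -> float:
        return 1.0 - self.matched_alleles / 2.0 / self.masked_genotypes

    @property
    def genotypic_discordance(self) -> float:
        return 1.0 - self.matched_genotypes / self.masked_genotypes


def _compatible_pairs(genotype: np.ndarray, haps: np.ndarray) -> list[tuple[int, int]]:
    """Ordered haplotype-index pairs consistent with a (possibly missing) genotype."""
    obs = genotype != MISSING
    pairs = []
    for i, j in itertools.product(range(len(haps)), repeat=2):
        s = haps[i] + haps[j]
        if np.array_equal(s[obs], genotype[obs]):
            pairs.append((i, j))
    return pairs


def em_phase(genotypes: np.ndarray, snp_ids: list[str] | None = None,
             alleles: list[tuple[str, str]] | None = None,
             tol: float = 1e-8, max_iter: int = 1000
             ) -> tuple[HaplotypeFrequencySet, list[tuple[int, int]]]:
    """EM haplotype-frequency estimation for a window of k <= 4 SNPs.

    ``genotypes`` is (n, k) dosages with the missing sentinel allowed
    (missing sites are summed over compatible completions). Initialization is
    uniform; convergence when the largest frequency change is below ``tol``.
    Returns the frequency set and the most likely diplotype per animal
    (ordered pair of haplotype indices; ties break toward the
    lexicographically smaller pair).
    """
    g = np.asarray(genotypes)
    n, k = g.shape
    if not 2 <= k <= 4:
        raise ValueError("window size must be 2..4 SNPs")
    haps = np.array(list(itertools.product((0, 1), repeat=k)), dtype=np.int8)
    H = len(haps)
    pair_lists = [_compatible_pairs(g[i], haps) for i in range(n)]
    if any(len(p) == 0 for p in pair_lists):
        bad = [i for i, p in enumerate(pair_lists) if not p]
        raise ValueError(f"genotype rows {bad[:5]} incompatible with any diplotype")

    f = np.full(H, 1.0 / H)
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(H)
        ll = 0.0
        for pairs in pair_lists:
            probs = np.array([f[i] * f[j] for i, j in pairs])
            tot = probs.sum()
            ll += np.log(tot) if tot > 0 else -np.inf
            if tot <= 0:
                continue
            post = probs / tot
            for (i, j), w in zip(pairs, post):
                counts[i] += w
                counts[j] += w
        f_new = counts / (2.0 * n)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        loglik = ll
        if delta < tol:
            converged = True
            break

    best_pairs = []
    for pairs in pair_lists:
        probs = [f[i] * f[j] for i, j in pairs]
        order = sorted(range(len(pairs)),
                       key=lambda t: (-probs[t], tuple(haps[pairs[t][0]]), tuple(haps[pairs[t][1]])))
        i, j = pairs[order[0]]
        best_pairs.append((min(i, j), max(i, j)))

    if snp_ids is None:
        snp_ids = [f"snp{t + 1}" for t in range(k)]
    if alleles is None:
        alleles = [("0", "1")] * k
    hap_strings = ["-".join(alleles[t][h[t]] for t in range(k)) for h in haps]
    return (HaplotypeFrequencySet(list(snp_ids), hap_strings, haps, f, float(loglik),
                                  it, converged),
            best_pairs)


def window_loglik(genotypes: np.ndarray, frequencies: np.ndarray) -> float:
    """Observed-data log-likelihood of a haplotype-frequency vector (any k)."""
    g = np.asarray(genotypes)
    k = g.shape[1]
    haps = np.array(list(itertools.product((0, 1), repeat=k)), dtype=np.int8)
    ll = 0.0
    for row in g:
        pairs = _compatible_pairs(row, haps)
        tot = sum(frequencies[i] * frequencies[j] for i, j in pairs)
        ll += np.log(tot) if tot > 0 else -np.inf
    return float(ll)


# ---------------------------------------------------------------------------
# linkage disequilibrium

@dataclass
class LdStats:
    snp_a: str
    snp_b: str
    d: float
    d_prime: float
    r_squared: float


def ld_from_haplotypes(freqs: HaplotypeFrequencySet) -> LdStats:
    """D, D' and r^2 for a two-SNP haplotype frequency set (alt alleles)."""
    if freqs.hap_alleles.shape[1] != 2:
        raise ValueError("LD statistics need a two-SNP frequency set")
    p_ab = freqs.freq_of((1, 1))
    p_a = freqs.freq_of((1, 0)) + p_ab
    p_b = freqs.freq_of((0, 1)) + p_ab
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("LD undefined: monomorphic SNP in window")
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d == 0 else d / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdStats(freqs.snp_ids[0], freqs.snp_ids[1], d, d_prime, r2)


def ld_from_phased(h_a: np.ndarray, h_b: np.ndarray,
                   ids: tuple[str, str] = ("a", "b")) -> LdStats:
    """LD from known phase: two equal-length 0/1 haplotype allele vectors."""
    h_a = np.asarray(h_a).ravel()
    h_b = np.asarray(h_b).ravel()
    f = np.zeros(4)
    for a, b in ((0, 0), (0, 1), (1, 0), (1, 1)):
        f[2 * a + b] = np.mean((h_a == a) & (h_b == b))
    fs = HaplotypeFrequencySet(list(ids), ["0-0", "0-1", "1-0", "1-1"],
                               np.array([(0, 0), (0, 1), (1, 0), (1, 1)], dtype=np.int8),
                               f, 0.0, 0, True)
    return ld_from_haplotypes(fs)


def pairwise_r2(panel: GenotypePanel, snp_ids: list[str]) -> np.ndarray:
    """Symmetric r^2 matrix over a SNP list, each pair phased by two-SNP EM."""
    k = len(snp_ids)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    cols = [panel.snp_index(s) for s in snp_ids]
    for i in range(k):
        for j in range(i + 1, k):
            g = panel.dosages[:, [cols[i], cols[j]]]
            freqs, _ = em_phase(g, snp_ids=[snp_ids[i], snp_ids[j]])
            try:
                out[i, j] = out[j, i] = ld_from_haplotypes(freqs).r_squared
            except ValueError:
                pass
    return out


# ---------------------------------------------------------------------------
# diplotype classes

def assign_diplotype_classes(genotypes: np.ndarray, q_alleles: tuple[int, int],
                             freqs: HaplotypeFrequencySet,
                             posterior_threshold: float = 0.95) -> list[str]:
    """QQ/Qq/qq class per animal for a two-SNP window.

    ``q_alleles`` gives the Q-haplotype allele (0 = ref, 1 = alt) at each
    SNP. Animals whose phase is forced by homozygosity are assigned
    deterministically; double heterozygotes take the more probable phase
    under the EM frequencies, or ``"unresolved"`` when its posterior
    probability is below the threshold.
    """
    g = np.asarray(genotypes)
    if g.shape[1] != 2:
        raise ValueError("diplotype classes are defined on a two-SNP window")
    haps = np.array(list(itertools.product((0, 1), repeat=2)), dtype=np.int8)
    q_idx = int(2 * q_alleles[0] + q_alleles[1])
    labels = {0: "qq", 1: "Qq", 2: "QQ"}
    out = []
    for row in g:
        pairs = _compatible_pairs(row, haps)
        qcounts = {(i, j): int(i == q_idx) + int(j == q_idx) for i, j in pairs}
        distinct = set(qcounts.values())
        if len(distinct) == 1:
            out.append(labels[distinct.pop()])
            continue
        probs = np.array([freqs.frequencies[i] * freqs.frequencies[j] for i, j in pairs])
        tot = probs.sum()
        if tot <= 0:
            out.append("unresolved")
            continue
        post = probs / tot
        # aggregate by Q count (cis/trans resolution for double heterozygotes)
        by_count: dict[int, float] = {}
        for (pair, pp) in zip(pairs, post):
            by_count[qcounts[pair]] = by_count.get(qcounts[pair], 0.0) + pp
        best = max(sorted(by_count), key=lambda c: by_count[c])
        if by_count[best] < posterior_threshold:
            out.append("unresolved")
        else:
            out.append(labels[best])
    return out


# ---------------------------------------------------------------------------
# imputation scoring

def naive_imputer(panel: GenotypePanel) -> np.ndarray:
    """Fill missing calls with the most frequent observed genotype per SNP
    (ties toward the smaller dosage). The reference imputer for scoring."""
    d = panel.dosages.copy()
    for j in range(panel.n_snps):
        col = d[:, j]
        obs = col[col != MISSING]
        if len(obs) == 0:
            fill = 0
        else:
            counts = [(col == k).sum() for k in (0, 1, 2)]
            fill = int(np.argmax(counts))
        col[col == MISSING] = fill
    return d


def mask_and_score(panel: GenotypePanel, mask_fraction: float, imputer,
                   seed: int = 0) -> ConcordanceReport:
    """Mask a seeded random subset of called genotypes, impute, and score.

    Allelic discordance = 1 - matched alleles / 2 / masked genotypes;
    genotypic discordance = 1 - matched genotypes / masked genotypes.
    """
    rng = np.random.default_rng(seed)
    obs = panel.observed()
    mask = obs & (rng.random(obs.shape) < mask_fraction)
    n_masked = int(mask.sum())
    if n_masked == 0:
        raise ValueError("no genotypes masked; raise mask_fraction")
    masked = GenotypePanel(panel.animal_ids, panel.snps,
                           np.where(mask, np.int8(MISSING), panel.dosages))
    imputed = np.asarray(imputer(masked))
    truth = panel.dosages[mask].astype(int)
    guess = imputed[mask].astype(int)
    matched_alleles = int(np.sum(np.maximum(2 - np.abs(truth - guess), 0)))
    matched_genotypes = int(np.sum(truth == guess))
    return ConcordanceReport(n_masked, matched_alleles, matched_genotypes)
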