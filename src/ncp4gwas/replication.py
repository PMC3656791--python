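"""Replication-stage analysis: least-square means of NCP4 by diplotype class
with farm and birth-year fixed effects, Tukey-Kramer pairwise comparisons,
the Q-to-q substitution effect, and the variance explained by the haplotype
(2p(1-p)a^2 under Hardy-Weinberg diplotype proportions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CLASS_ORDER = ("QQ", "Qq", "qq")


@dataclass
class LsMeansResult:
    classes: list[str]
    lsmeans: np.ndarray
    covariance: np.ndarray       # covariance of the lsmeans
    residual_df: int
    residual_variance: float
    coef: np.ndarray
    design_info: dict


@dataclass
class DiplotypeEffectSummary:
    lsmeans: dict
    standard_errors: dict
    residual_df: int
    tukey_p: dict                       # pair -> adjusted p
    substitution_effect: float
    haplotype_frequency: float
    haplotype_variance: float
    phenotypic_variance: float
    genetic_variance: float | None
    share_of_phenotypic: float
    share_of_genetic: float | None
    warnings: list[str] = field(default_factory=list)


def _design(farm, year, klass, classes):
    """Full-rank design: intercept + treatment-coded farm, year and class."""
    farm = np.asarray(farm)
    year = np.asarray(year)
    klass = np.asarray(klass)
    f_levels = sorted(set(farm))
    y_levels = sorted(set(year))
    cols = [np.ones(len(farm))]
    names = ["intercept"]
    for f in f_levels[1:]:
        cols.append((farm == f).astype(float))
        names.append(f"farm:{f}")
    for y in y_levels[1:]:
        cols.append((year == y).astype(float))
        names.append(f"year:{y}")
    for c in classes[1:]:
        cols.append((klass == c).astype(float))
        names.append(f"class:{c}")
    return np.column_stack(cols), names, f_levels, y_levels


def glm_lsmeans(ncp4: np.ndarray, farm, year, diplotype_class) -> LsMeansResult:
    """OLS fit of NCP4 on farm + birth-year + diplotype class; least-square
    means are predicted class means averaged with equal weight over the
    observed farm and year levels (reference-level constraint resolves the
    rank deficiency). Empty classes are omitted with a warning recorded in
    ``design_info``."""
    y = np.asarray(ncp4, float)
    klass = np.asarray(diplotype_class)
    present = [c for c in CLASS_ORDER if (klass == c).sum() > 0]
    extra = sorted(set(klass) - set(CLASS_ORDER) - {"unresolved"})
    present += extra
    warnings = [f"class {c} empty; omitted" for c in CLASS_ORDER if c not in present]
    keep = np.isin(klass, present)
    y, klass = y[keep], klass[keep]
    farm = np.asarray(farm)[keep]
    year = np.asarray(year)[keep]

    x, names, f_levels, y_levels = _design(farm, year, klass, present)
    n, p = x.shape
    if n <= p:
        raise ValueError("not enough records for the fixed-effect model")
    xtx = x.T @ x
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("factors fully confounded with diplotype class")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (x.T @ y)
    resid = y - x @ coef
    df = n - p
    s2 = float(resid @ resid) / df

    # lsmean contrast rows: intercept 1, each non-reference farm/year dummy at
    # 1/#levels (equal weight over observed levels), class dummy 0/1
    rows = []
    for c in present:
        row = np.zeros(p)
        row[0] = 1.0
        j = 1
        for _ in f_levels[1:]:
            row[j] = 1.0 / len(f_levels)
            j += 1
        for _ in y_levels[1:]:
            row[j] = 1.0 / len(y_levels)
            j += 1
        for cc in present[1:]:
            if cc == c:
                row[j] = 1.0
            j += 1
        rows.append(row)
    lmat = np.vstack(rows)
    lsm = lmat @ coef
    cov = s2 * (lmat @ xtx_inv @ lmat.T)
    return LsMeansResult(present, lsm, cov, df, s2, coef,
                         {"names": names, "lmat": lmat, "warnings": warnings})


def tukey_kramer(lsmeans: np.ndarray, covariance: np.ndarray,
                 residual_df: int) -> dict[tuple[int, int], float]:
    """Tukey-Kramer adjusted p per pair of least-square means.

    q = sqrt(2) |difference| / SE(difference), referred to the studentized
    range with k groups and the residual df (Kramer's unequal-n standard
    error comes in through the lsmean covariance)."""
    k = len(lsmeans)
    if k < 2:
        raise ValueError("need at least 2 classes")
    if residual_df <= 0:
        raise ValueError("residual df must be positive")
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se2 = covariance[i, i] + covariance[j, j] - 2 * covariance[i, j]
            if se2 <= 0:
                out[(i, j)] = 1.0
                continue
            q = np.sqrt(2.0) * abs(lsmeans[i] - lsmeans[j]) / np.sqrt(se2)
            out[(i, j)] = float(stats.studentized_range.sf(q, k, residual_df))
    return out


def substitution_effect(lsmeans: dict, method: str = "homozygote_contrast",
                        dosage: np.ndarray | None = None,
                        ncp4: np.ndarray | None = None,
                        farm=None, year=None) -> tuple[float, list[str]]:
    """Q-to-q substitution effect a.

    ``homozygote_contrast`` (default): a = (lsmean_QQ - lsmean_qq)/2.
    ``dosage_regression``: slope of NCP4 on Q-dosage (0/1/2) with farm and
    year fixed effects (also the fallback when a homozygote class is absent).
    """
    warnings = []
    if method == "homozygote_contrast":
        if "QQ" in lsmeans and "qq" in lsmeans:
            return (lsmeans["QQ"] - lsmeans["qq"]) / 2.0, warnings
        warnings.append("missing homozygote class; falling back to dosage regression")
        method = "dosage_regression"
    if method != "dosage_regression":
        raise ValueError(f"unknown method {method!r}")
    if dosage is None or ncp4 is None:
        raise ValueError("dosage regression needs ncp4 and Q-dosage")
    cols = [np.ones(len(dosage)), np.asarray(dosage, float)]
    names_after = 2
    if farm is not None:
        farm = np.asarray(farm)
        for f in sorted(set(farm))[1:]:
            cols.append((farm == f).astype(float))
    if year is not None:
        year = np.asarray(year)
        for yv in sorted(set(year))[1:]:
            cols.append((year == yv).astype(float))
    x = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(x, np.asarray(ncp4, float), rcond=None)
    del names_after
    return float(coef[1]), warnings


def haplotype_variance(p: float, a: float, v_p: float,
                       v_g: float | None = None) -> dict:
    """V_hap = 2p(1-p)a^2 and its shares of phenotypic/genetic variance."""
    if not 0.0 < p < 1.0:
        raise ValueError("haplotype frequency must be in (0, 1)")
    if v_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    v_hap = 2.0 * p * (1.0 - p) * a * a
    out = {"haplotype_variance": v_hap,
           "share_of_phenotypic": v_hap / v_p,
           "share_of_genetic": None}
    if v_g is not None:
        if not 0.0 < v_g <= v_p:
            raise ValueError("genetic variance must be in (0, phenotypic variance]")
        out["share_of_genetic"] = v_hap / v_g
    if out["share_of_phenotypic"] > 1.0:
        raise ValueError("haplotype variance exceeds phenotypic variance: inconsistent inputs")
    return out


def replication_summary(ncp4: np.ndarray, farm, year, diplotype_class,
                        heritability: float | None = None,
                        effect_method: str = "homozygote_contrast",
                        q_dosage: np.ndarray | None = None) -> DiplotypeEffectSummary:
    """Full replication-stage summary.

    Phenotypic variance is estimated net of farm and year (residual variance
    of the model without the class term); haplotype frequency comes from the
    class counts (or the supplied Q-dosage); genetic variance is
    ``heritability * V_P`` when a heritability is given.
    """
    y = np.asarray(ncp4, float)
    klass = np.asarray(diplotype_class)
    res = glm_lsmeans(y, farm, year, klass)
    lsm = dict(zip(res.classes, res.lsmeans))
    ses = dict(zip(res.classes, np.sqrt(np.diag(res.covariance))))
    tk = tukey_kramer(res.lsmeans, res.covariance, res.residual_df)
    tk_named = {(res.classes[i], res.classes[j]): p for (i, j), p in tk.items()}

    if q_dosage is not None:
        d = np.asarray(q_dosage, float)
        p_hat = float(d.mean() / 2.0)
    else:
        counts = {c: int((klass == c).sum()) for c in ("QQ", "Qq", "qq")}
        tot = sum(counts.values())
        p_hat = (2 * counts["QQ"] + counts["Qq"]) / (2.0 * tot)

    dosage = (q_dosage if q_dosage is not None
              else np.select([klass == "QQ", klass == "Qq"], [2.0, 1.0], 0.0))
    a_hat, warnings = substitution_effect(lsm, effect_method, dosage=dosage,
                                          ncp4=y, farm=farm, year=year)
    warnings += res.design_info["warnings"]

    # phenotypic variance net of farm/year: residual variance of the
    # no-class model (includes the haplotype variance)
    x0, *_ = _design(farm, year, np.asarray(["_"] * len(y)), ["_"])
    coef0, *_ = np.linalg.lstsq(x0, y, rcond=None)
    r0 = y - x0 @ coef0
    v_p = float(r0 @ r0) / (len(y) - x0.shape[1])
    v_g = heritability * v_p if heritability is not None else None
    hv = haplotype_variance(p_hat, a_hat, v_p, v_g)
    return DiplotypeEffectSummary(
        lsmeans=lsm, standard_errors=ses, residual_df=res.residual_df,
        tukey_p=tk_named, substitution_effect=a_hat, haplotype_frequency=p_hat,
        haplotype_variance=hv["haplotype_variance"], phenotypic_variance=v_p,
        genetic_variance=v_g, share_of_phenotypic=hv["share_of_phenotypic"],
        share_of_genetic=hv["share_of_genetic"], warnings=warnings)
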