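"""NCP4 phenotype construction: record filtering, the NCP4/t-age formula,
the pedigree numerator relationship matrix, and farm/birth-year adjustment
via an animal-model REML.

NCP4 (number of calves produced by 4 years of age) is
``(4 - AFC) / ACI + 1`` with AFC the age at first calving in years and ACI
the average calving interval up to the t-age calving — the first calving at
or after the 4th birthday. Ages convert at 365.25 days/year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DAYS_PER_YEAR, ReproductionRecord
from .mixedmodel import RemlResult, RotatedDesign, gls_fixed_effects, reml_fit, rotate

FOUR_YEARS_DAYS = 4.0 * DAYS_PER_YEAR

#: short descriptions of the nine record-selection criteria, keyed 1..9
CRITERIA = {
    1: "complete history from first calving to the first calving at/after age 4",
    2: "no twin parturitions",
    3: "no embryo transfers",
    4: "no abortions",
    5: "all gestation lengths within 261-310 days",
    6: "all calving intervals within 276-730 days",
    7: "age at first calving less than 1,128 days",
    8: "reared at a single farm",
    9: "more than 10 records per farm x birth-year",
}


@dataclass
class FilterReport:
    records_in: int
    records_out: int
    excluded_by: dict[int, int] = field(default_factory=dict)  # criterion -> count

    def __post_init__(self) -> None:
        for c in CRITERIA:
            self.excluded_by.setdefault(c, 0)


@dataclass
class Ncp4Value:
    cow_id: str
    age_first_calving: float   # years
    t_age: float               # years
    avg_calving_interval: float  # years
    ncp4: float
    adjusted_ncp4: float | None = None


@dataclass
class NumeratorRelationshipMatrix:
    animal_ids: np.ndarray
    matrix: np.ndarray

    def subset(self, ids) -> "NumeratorRelationshipMatrix":
        idx = pd.Index(self.animal_ids).get_indexer(np.asarray(ids))
        if (idx < 0).any():
            raise KeyError("animals missing from relationship matrix")
        return NumeratorRelationshipMatrix(np.asarray(ids), self.matrix[np.ix_(idx, idx)])


@dataclass
class VarianceComponents:
    additive_variance: float
    residual_variance: float
    heritability: float
    farm_solutions: dict            # farm level -> fixed-effect solution
    year_solutions: dict            # birth year -> fixed-effect solution
    intercept: float
    converged: bool
    n_iter: int
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the nine selection criteria

def _record_failures(rec: ReproductionRecord,
                     gestation_range: tuple[int, int],
                     interval_range: tuple[int, int],
                     max_afc_days: int) -> list[int]:
    """Criteria 1-8 failed by one record (criterion 9 is a group property)."""
    rec.validate()
    fails = []
    ages = rec.calving_ages_days()
    if len(ages) < 2 or ages.max() < FOUR_YEARS_DAYS:
        fails.append(1)
    if any(rec.twin_flags):
        fails.append(2)
    if any(rec.et_flags):
        fails.append(3)
    if any(rec.abortion_flags):
        fails.append(4)
    lo, hi = gestation_range
    if any(not lo <= g <= hi for g in rec.gestation_lengths):
        fails.append(5)
    lo, hi = interval_range
    if any(not lo <= iv <= hi for iv in rec.calving_intervals_days()):
        fails.append(6)
    if len(ages) and not ages[0] < max_afc_days:
        fails.append(7)
    if len(set(rec.farm_history)) > 1:
        fails.append(8)
    return fails


def apply_filters(records: list[ReproductionRecord], *,
                  gestation_range: tuple[int, int] = (261, 310),
                  interval_range: tuple[int, int] = (276, 730),
                  max_afc_days: int = 1128,
                  min_farm_year_records: int = 10
                  ) -> tuple[list[ReproductionRecord], FilterReport]:
    """Apply the nine selection criteria.

    Ranges are inclusive; the first-calving age bound is strict (< 1,128 d);
    criterion 9 keeps farm x birth-year cells with strictly more than
    ``min_farm_year_records`` records, evaluated after criteria 1-8.
    """
    report = FilterReport(records_in=len(records), records_out=0)
    survivors: list[ReproductionRecord] = []
    for rec in records:
        fails = _record_failures(rec, gestation_range, interval_range, max_afc_days)
        for c in fails:
            report.excluded_by[c] += 1
        if not fails:
            survivors.append(rec)

    cell_counts: dict[tuple[int, int], int] = {}
    for rec in survivors:
        key = (rec.farm_id, rec.birth_year)
        cell_counts[key] = cell_counts.get(key, 0) + 1
    retained = []
    for rec in survivors:
        if cell_counts[(rec.farm_id, rec.birth_year)] > min_farm_year_records:
            retained.append(rec)
        else:
            report.excluded_by[9] += 1
    report.records_out = len(retained)
    return retained, report


# ---------------------------------------------------------------------------
# NCP4

def compute_ncp4(record: ReproductionRecord,
                 interval_scope: str = "through_t_age") -> Ncp4Value:
    """NCP4 of one record.

    ``interval_scope`` picks which calving intervals enter the average:
    ``"through_t_age"`` (default) averages all intervals from the first
    calving up to and including the one ending at the t-age calving;
    ``"before_age_4"`` averages only intervals ending before the 4th
    birthday.
    """
    ages = record.calving_ages_days() / DAYS_PER_YEAR
    at_or_after_4 = np.flatnonzero(ages >= 4.0)
    if len(at_or_after_4) == 0 or len(ages) < 2:
        raise ValueError(
            f"record {record.cow_id}: no calving at/after age 4 years (criterion 1)")
    t_idx = int(at_or_after_4[0])
    if t_idx == 0:
        raise ValueError(f"record {record.cow_id}: first calving already after age 4")
    intervals = np.diff(ages)
    if interval_scope == "through_t_age":
        used = intervals[:t_idx]
    elif interval_scope == "before_age_4":
        used = intervals[np.flatnonzero(ages[1:] < 4.0)]
        if len(used) == 0:
            used = intervals[:t_idx]
    else:
        raise ValueError(f"unknown interval_scope {interval_scope!r}")
    afc = float(ages[0])
    aci = float(np.mean(used))
    return Ncp4Value(record.cow_id, afc, float(ages[t_idx]), aci,
                     (4.0 - afc) / aci + 1.0)


def ncp4_table(records: list[ReproductionRecord],
               interval_scope: str = "through_t_age") -> pd.DataFrame:
    """Per-cow NCP4 table (cow, sire, farm, birth_year, afc, t_age, aci, ncp4)."""
    rows = []
    for rec in records:
        v = compute_ncp4(rec, interval_scope)
        rows.append((v.cow_id, rec.sire_id, rec.farm_id, rec.birth_year,
                     v.age_first_calving, v.t_age, v.avg_calving_interval, v.ncp4))
    return pd.DataFrame(rows, columns=["animal", "sire", "farm", "birth_year",
                                       "afc", "t_age", "aci", "ncp4"])


# ---------------------------------------------------------------------------
# numerator relationship matrix (Henderson's tabular method)

def build_a_matrix(pedigree: pd.DataFrame) -> NumeratorRelationshipMatrix:
    """Additive relationship matrix by the tabular recursion.

    Requires parents to precede offspring (rejects cyclic/unsorted input).
    Founders get diagonal 1; a(i,j) = [a(j,sire_i) + a(j,dam_i)]/2 and
    a(i,i) = 1 + a(sire_i, dam_i)/2.
    """
    from .simulate import _pedigree_indices  # shares the ordering validation

    si, di = _pedigree_indices(pedigree)
    n = len(pedigree)
    a = np.zeros((n, n))
    for i in range(n):
        row = np.zeros(i)
        if si[i] >= 0:
            row += 0.5 * a[si[i], :i]
        if di[i] >= 0:
            row += 0.5 * a[di[i], :i]
        a[i, :i] = row
        a[:i, i] = row
        inb = 0.5 * a[si[i], di[i]] if (si[i] >= 0 and di[i] >= 0) else 0.0
        a[i, i] = 1.0 + inb
    return NumeratorRelationshipMatrix(pedigree["animal"].to_numpy(), a)


# ---------------------------------------------------------------------------
# animal-model REML and adjustment

def design_matrix(farm: np.ndarray, year: np.ndarray
                  ) -> tuple[np.ndarray, list, list]:
    """Intercept + treatment-coded farm and year dummies (first level = reference)."""
    farm_levels = sorted(set(farm))
    year_levels = sorted(set(year))
    n = len(farm)
    x = [np.ones(n)]
    for f in farm_levels[1:]:
        x.append((np.asarray(farm) == f).astype(float))
    for yv in year_levels[1:]:
        x.append((np.asarray(year) == yv).astype(float))
    return np.column_stack(x), farm_levels, year_levels


def reml_animal_model(y: np.ndarray, farm: np.ndarray, year: np.ndarray,
                      a_matrix: NumeratorRelationshipMatrix | None = None,
                      *, design: RotatedDesign | None = None,
                      method: str = "profile", tol: float = 1e-8,
                      max_iter: int = 200) -> VarianceComponents:
    """REML variance components of y = farm + year + animal + residual.

    ``a_matrix`` must cover every phenotyped animal (it is subset to them by
    position: pass the matrix already aligned to y). A precomputed rotated
    design can be supplied to reuse an eigendecomposition across fits.
    """
    y = np.asarray(y, dtype=float)
    x, farm_levels, year_levels = design_matrix(np.asarray(farm), np.asarray(year))
    if design is None:
        if a_matrix is None:
            raise ValueError("a_matrix or a precomputed design is required")
        if a_matrix.matrix.shape[0] != len(y):
            raise ValueError("relationship matrix not aligned with phenotypes")
        design = rotate(y, x, kinship=a_matrix.matrix)
    res: RemlResult = reml_fit(design, method=method, tol=tol, max_iter=max_iter)
    if not res.converged:
        raise RuntimeError(
            f"REML did not converge in {res.n_iter} iterations; "
            f"log-likelihood trace tail: {res.loglik_trace[-5:]}")
    beta, _ = gls_fixed_effects(design, res.sigma_a2, res.sigma_e2)
    nf = len(farm_levels) - 1
    farm_sol = {farm_levels[0]: 0.0}
    farm_sol.update({f: float(b) for f, b in zip(farm_levels[1:], beta[1:1 + nf])})
    year_sol = {year_levels[0]: 0.0}
    year_sol.update({yv: float(b) for yv, b in zip(year_levels[1:], beta[1 + nf:])})
    return VarianceComponents(
        additive_variance=res.sigma_a2, residual_variance=res.sigma_e2,
        heritability=res.heritability, farm_solutions=farm_sol,
        year_solutions=year_sol, intercept=float(beta[0]),
        converged=res.converged, n_iter=res.n_iter, loglik=res.loglik,
        loglik_trace=res.loglik_trace)


def adjust_phenotypes(y: np.ndarray, farm: np.ndarray, year: np.ndarray,
                      components: VarianceComponents) -> np.ndarray:
    """Raw NCP4 minus the farm and birth-year fixed-effect solutions."""
    y = np.asarray(y, dtype=float)
    try:
        f_adj = np.array([components.farm_solutions[f] for f in np.asarray(farm)])
        y_adj = np.array([components.year_solutions[v] for v in np.asarray(year)])
    except KeyError as err:
        raise KeyError(f"no fixed-effect solution for factor level {err.args[0]!r}") from err
    return y - f_adj - y_adj
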