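"""Nine selection criteria, the NCP4/t-age formula, the numerator
relationship matrix and the animal-model REML."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_record
from ncp4gwas.config import clean_config
from ncp4gwas.containers import DAYS_PER_YEAR
from ncp4gwas.mixedmodel import reml_fit, rotate
from ncp4gwas.phenotype import (adjust_phenotypes, apply_filters, build_a_matrix,
                                compute_ncp4, ncp4_table, reml_animal_model)
from ncp4gwas.simulate import simulate_pedigree, simulate_records


class TestFilters:
    def test_short_gestation_attributed_to_criterion_5(self):
        rec = make_record(gestations=[260, 285, 285])
        kept, report = apply_filters([rec], min_farm_year_records=0)
        assert kept == [] and report.excluded_by[5] == 1

    def test_boundary_values_inclusive(self):
        # gestation exactly 261/310 and one interval exactly 730 d retained
        rec = make_record(ages_days=(800, 1530, 1806), gestations=[261, 310, 285])
        kept, report = apply_filters([rec], min_farm_year_records=0)
        assert len(kept) == 1

    def test_afc_1128_days_excluded_strictly(self):
        rec = make_record(ages_days=(1128, 1500, 1872))
        _, report = apply_filters([rec], min_farm_year_records=0)
        assert report.excluded_by[7] == 1
        rec2 = make_record(ages_days=(1127, 1499, 1871))
        kept, _ = apply_filters([rec2], min_farm_year_records=0)
        assert len(kept) == 1

    def test_embryo_transfer_toy_set(self):
        recs = [make_record(cow_id=f"c{i}") for i in range(5)]
        recs[2].et_flags[1] = True
        kept, report = apply_filters(recs, min_farm_year_records=0)
        assert len(kept) == 4 and report.excluded_by[3] == 1

    def test_farm_year_cell_needs_more_than_ten(self):
        recs = [make_record(cow_id=f"c{i}", farm=1) for i in range(10)]
        _, report = apply_filters(recs)   # exactly 10: excluded (strict >)
        assert report.records_out == 0 and report.excluded_by[9] == 10
        recs.append(make_record(cow_id="c10", farm=1))
        kept, _ = apply_filters(recs)
        assert len(kept) == 11

    def test_conservation_of_counts(self, small_herd):
        import dataclasses
        cfg = dataclasses.replace(small_herd["config"],
                                  contamination_rates={k: 0.05 for k in
                                  small_herd["config"].contamination_rates})
        records, _ = simulate_records(cfg, small_herd["pedigree"])
        kept, report = apply_filters(records)
        excluded = report.records_in - report.records_out
        assert excluded <= sum(report.excluded_by.values())  # multiple attributions allowed
        assert report.records_out == len(kept)

    def test_unordered_dates_rejected_with_field(self):
        rec = make_record()
        rec.calving_dates = [1500, 800, 1900]
        with pytest.raises(ValueError, match="calving_dates"):
            apply_filters([rec])


class TestNcp4:
    def test_formula_examples(self):
        # calvings at ages 2,3,4 years: (4-2)/1 + 1 = 3
        ages = [int(round(a * DAYS_PER_YEAR)) for a in (2, 3, 4)]
        assert compute_ncp4(make_record(ages_days=ages)).ncp4 == pytest.approx(3.0, abs=5e-3)
        # AFC 2.5, intervals 1.25: 1.5/1.25 + 1 = 2.2
        ages = [int(round(a * DAYS_PER_YEAR)) for a in (2.5, 3.75, 5.0)]
        assert compute_ncp4(make_record(ages_days=ages)).ncp4 == pytest.approx(2.2, abs=5e-3)

    def test_day_convention_hand_value(self):
        v = compute_ncp4(make_record(ages_days=(900, 1300, 1700)))
        assert v.ncp4 == pytest.approx(2.402, abs=5e-4)
        assert v.t_age == pytest.approx(1700 / DAYS_PER_YEAR)
        assert v.avg_calving_interval == pytest.approx(400 / DAYS_PER_YEAR)

    def test_no_calving_after_four_signals_criterion_1(self):
        with pytest.raises(ValueError, match="criterion 1"):
            compute_ncp4(make_record(ages_days=(800, 1180)))

    def test_interval_scope_switch(self):
        # calvings at 2.0, 3.0, 4.5 y: default averages both intervals,
        # "before_age_4" only the first
        ages = [int(round(a * DAYS_PER_YEAR)) for a in (2.0, 3.0, 4.5)]
        v_def = compute_ncp4(make_record(ages_days=ages))
        v_alt = compute_ncp4(make_record(ages_days=ages), interval_scope="before_age_4")
        assert v_def.avg_calving_interval == pytest.approx(1.25, abs=5e-3)
        assert v_alt.avg_calving_interval == pytest.approx(1.0, abs=5e-3)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(afc=st.floats(1.6, 2.9), aci1=st.floats(0.8, 1.9), aci2=st.floats(0.8, 1.9))
    def test_monotonicity(self, afc, aci1, aci2):
        """NCP4 strictly decreases in ACI at fixed AFC and in AFC at fixed ACI."""
        def ncp4(afc_y, aci_y):
            ages = [afc_y]
            while ages[-1] < 4.0:
                ages.append(ages[-1] + aci_y)
            days = [int(round(a * DAYS_PER_YEAR)) for a in ages]
            return compute_ncp4(make_record(ages_days=days)).ncp4

        lo, hi = sorted([aci1, aci2])
        if hi - lo > 1e-3:
            assert ncp4(afc, lo) > ncp4(afc, hi)
        assert ncp4(afc, aci1) > ncp4(afc + 0.3, aci1)


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        ped = pd.DataFrame({"animal": ["a", "b"], "sire": ["0", "0"],
                            "dam": ["0", "0"]})
        assert np.allclose(build_a_matrix(ped).matrix, np.eye(2))

    def test_trio_relationships(self):
        ped = pd.DataFrame({"animal": ["s", "d", "o"], "sire": ["0", "0", "s"],
                            "dam": ["0", "0", "d"]})
        a = build_a_matrix(ped).matrix
        assert a[2, 0] == 0.5 and a[2, 2] == 1.0

    def test_full_sib_mating_inbred_diagonal(self):
        ped = pd.DataFrame({"animal": list("sdabx"),
                            "sire": ["0", "0", "s", "s", "a"],
                            "dam": ["0", "0", "d", "d", "b"]})
        a = build_a_matrix(ped).matrix
        assert a[4, 4] == pytest.approx(1.25)

    def test_unsorted_pedigree_rejected(self):
        ped = pd.DataFrame({"animal": ["o", "s", "d"], "sire": ["s", "0", "0"],
                            "dam": ["d", "0", "0"]})
        with pytest.raises(ValueError, match="precede"):
            build_a_matrix(ped)

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_random_pedigrees_psd(self, seed):
        cfg = clean_config(seed=seed, n_founders=12, n_generations=3, n_animals=40)
        a = build_a_matrix(simulate_pedigree(cfg)).matrix
        assert np.linalg.eigvalsh(a).min() >= -1e-8


class TestReml:
    def test_zero_additive_variance_boundary(self):
        rng = np.random.default_rng(12)
        s, k = 120, 10
        n = s * k
        y = rng.normal(0, 1, n) + np.repeat(rng.normal(0, 0.3, s) * 0, k)
        a = np.kron(np.eye(s), np.full((k, k), 0.25)) + 0.75 * np.eye(n)
        rot = rotate(y, np.ones((n, 1)), kinship=a)
        res = reml_fit(rot, "profile")
        assert res.heritability < 0.02

    def test_balanced_half_sib_matches_anova(self):
        """Animal-model REML equals the one-way ANOVA sire-component estimator
        on a balanced paternal half-sib design (4 x between-sire component)."""
        rng = np.random.default_rng(13)
        s, k = 60, 10
        n = s * k
        bv = rng.normal(0, np.sqrt(0.3), s)
        y = np.repeat(0.5 * bv, k) + rng.normal(0, np.sqrt(0.75 * 0.3 + 0.7), n)
        a = np.kron(np.eye(s), np.full((k, k), 0.25)) + 0.75 * np.eye(n)
        res = reml_fit(rotate(y, np.ones((n, 1)), kinship=a), "profile")
        ybar = y.reshape(s, k).mean(1)
        msb = k * np.var(ybar, ddof=1)
        w = (y.reshape(s, k) - ybar[:, None]).ravel()
        msw = (w @ w) / (s * (k - 1))
        sigma_a2_anova = 4 * (msb - msw) / k
        assert res.sigma_a2 == pytest.approx(sigma_a2_anova, rel=1e-3)

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(14)
        s, k = 40, 8
        n = s * k
        y = np.repeat(rng.normal(0, 0.4, s), k) + rng.normal(0, 1, n)
        a = np.kron(np.eye(s), np.full((k, k), 0.25)) + 0.75 * np.eye(n)
        res = reml_fit(rotate(y, np.ones((n, 1)), kinship=a), "em", max_iter=80)
        trace = res.loglik_trace
        assert all(b - a_ >= -1e-9 for a_, b in zip(trace, trace[1:]))

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            rotate(np.zeros(2), np.ones((2, 1)), kinship=bad)


class TestAdjustment:
    def _fit(self, y, farm, year, ped_ids):
        ped = pd.DataFrame({"animal": ped_ids, "sire": "0", "dam": "0"})
        amat = build_a_matrix(ped)
        return reml_animal_model(y, farm, year, amat)

    def test_zero_solutions_identity(self):
        rng = np.random.default_rng(15)
        n = 200
        y = rng.normal(2.7, 0.2, n)
        farm = np.ones(n, dtype=int)
        year = np.full(n, 1995)
        vc = self._fit(y, farm, year, [f"a{i}" for i in range(n)])
        adj = adjust_phenotypes(y, farm, year, vc)
        # single farm/year: solutions are zero by the reference constraint
        assert np.allclose(adj, y)

    def test_two_farm_offset_removed(self):
        rng = np.random.default_rng(16)
        n = 2000
        farm = rng.integers(1, 3, n)
        year = np.full(n, 1995)
        y = rng.normal(2.7, 0.2, n) + 0.5 * (farm == 2)
        vc = self._fit(y, farm, year, [f"a{i}" for i in range(n)])
        adj = adjust_phenotypes(y, farm, year, vc)
        gap = adj[farm == 2].mean() - adj[farm == 1].mean()
        assert abs(gap) < 0.05
        assert vc.farm_solutions[2] == pytest.approx(0.5, abs=0.05)

    def test_unseen_level_signaled(self):
        rng = np.random.default_rng(17)
        n = 100
        y = rng.normal(size=n)
        farm = np.ones(n, dtype=int)
        year = np.full(n, 1995)
        vc = self._fit(y, farm, year, [f"a{i}" for i in range(n)])
        with pytest.raises(KeyError, match="level"):
            adjust_phenotypes(y, np.full(n, 9), year, vc)
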