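"""Synthetic herd generator: pedigree structure, genotype LD, record
construction and peak traces."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ncp4gwas.config import SimulationConfig, clean_config
from ncp4gwas.phenotype import apply_filters, build_a_matrix, ncp4_table
from ncp4gwas.simulate import (simulate_genotypes, simulate_peak_traces,
                               simulate_pedigree, simulate_records)
from ncp4gwas.imbalance import peak_ratios


class TestPedigree:
    def test_no_generations_gives_identity_a_matrix(self):
        cfg = clean_config(seed=1, n_founders=30, n_generations=0, n_animals=0)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 30
        assert (ped["sire"] == "0").all() and (ped["dam"] == "0").all()
        a = build_a_matrix(ped).matrix
        assert np.allclose(a, np.eye(30))

    def test_seeded_determinism(self):
        cfg = clean_config(seed=42, n_founders=50, n_generations=2, n_animals=200)
        p1 = simulate_pedigree(cfg)
        p2 = simulate_pedigree(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        assert p1.to_csv() == p2.to_csv()

    def test_two_founders_forced_full_sibs(self):
        cfg = clean_config(seed=3, n_founders=2, n_generations=1, n_animals=10)
        ped = simulate_pedigree(cfg)
        off = ped[ped["sire"] != "0"]
        assert len(off) == 10
        assert set(off["sire"]) == {"S0001"} and set(off["dam"]) == {"D0001"}
        a = build_a_matrix(ped).matrix
        # all offspring pairwise full sibs: relationship 0.5
        sub = a[2:, 2:]
        off_diag = sub[~np.eye(10, dtype=bool)]
        assert np.allclose(off_diag, 0.5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clean_config(n_founders=1).validate()
        with pytest.raises(ValueError):
            clean_config(n_generations=-1).validate()


class TestGenotypes:
    def test_founder_causal_frequency_binomial(self):
        cfg = clean_config(seed=5, n_founders=1000, n_generations=0, n_animals=0,
                          n_snps=60, n_chromosomes=2, causal_chromosome=2)
        ped = simulate_pedigree(cfg)
        _, hap, truth = simulate_genotypes(cfg, ped)
        p = cfg.causal_haplotype_freq
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(truth["founder_q_freq"] - p) < 3 * se

    def test_no_recombination_perfect_block_ld(self):
        cfg = clean_config(seed=6, n_founders=500, n_generations=0, n_animals=0,
                          n_snps=40, n_chromosomes=1, causal_chromosome=1,
                          ld_decay=0.0)
        ped = simulate_pedigree(cfg)
        _, hap, truth = simulate_genotypes(cfg, ped)
        h = hap.reshape(-1, hap.shape[2])
        cols = truth["block_cols"]
        c = np.corrcoef(h[:, cols[0]], h[:, cols[1]])[0, 1]
        assert c ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_mean_r2_non_increasing_with_distance(self):
        """Average founder r^2 over replicates decays with bp distance."""
        sums = np.zeros(3)
        counts = np.zeros(3)
        edges = [0, 100_000, 400_000, 2_000_000]
        for rep in range(50):
            cfg = clean_config(seed=900 + rep, n_founders=150, n_generations=0,
                              n_animals=0, n_snps=30, n_chromosomes=1,
                              causal_chromosome=1)
            ped = simulate_pedigree(cfg)
            panel, hap, _ = simulate_genotypes(cfg, ped)
            h = hap.reshape(-1, hap.shape[2]).astype(float)
            keep = (h.mean(0) > 0.02) & (h.mean(0) < 0.98)
            h = h[:, keep]
            pos = panel.snps["pos"].to_numpy()[keep]
            r = np.corrcoef(h.T) ** 2
            d = np.abs(pos[:, None] - pos[None, :])
            iu = np.triu_indices_from(r, 1)
            which = np.digitize(d[iu], edges[1:-1])
            for b in range(3):
                m = which == b
                sums[b] += r[iu][m].sum()
                counts[b] += m.sum()
        means = sums / counts
        assert means[0] >= means[1] >= means[2]

    def test_mendelian_consistency_without_recombination(self):
        cfg = clean_config(seed=8, n_founders=40, n_generations=1, n_animals=100,
                          n_snps=60, n_chromosomes=3, ld_decay=0.0,
                          missing_rate=0.0)
        ped = simulate_pedigree(cfg)
        panel, hap, _ = simulate_genotypes(cfg, ped)
        pos = {a: i for i, a in enumerate(ped["animal"])}
        chroms = panel.snps["chrom"].to_numpy()
        slices = [np.flatnonzero(chroms == c) for c in np.unique(chroms)]
        for i, row in ped.iterrows():
            if row["sire"] == "0":
                continue
            s, d = pos[row["sire"]], pos[row["dam"]]
            # without recombination each chromosome copies one parental haplotype
            for sl in slices:
                assert any(np.array_equal(hap[i, 0, sl], hap[s, k, sl]) for k in (0, 1))
                assert any(np.array_equal(hap[i, 1, sl], hap[d, k, sl]) for k in (0, 1))
            assert np.array_equal(panel.dosages[i], hap[i].sum(0))


class TestRecords:
    def test_no_genetics_no_parent_offspring_resemblance(self):
        cfg = clean_config(seed=9, heritability=0.0, substitution_effect=0.0,
                          n_founders=1000, n_generations=2, n_animals=5000)
        ped = simulate_pedigree(cfg)
        records, _ = simulate_records(cfg, ped)
        tab = ncp4_table(records).set_index("animal")
        dam_of = dict(zip(ped["animal"], ped["dam"]))
        pairs = [(a, dam_of[a]) for a in tab.index
                 if dam_of.get(a) in tab.index]
        x = np.array([tab.loc[d, "ncp4"] for _, d in pairs])
        y = np.array([tab.loc[a, "ncp4"] for a, _ in pairs])
        slope = np.polyfit(x, y, 1)[0]
        assert abs(slope) < 0.03

    def test_clean_generator_passes_all_filters(self):
        cfg = clean_config(seed=10, n_founders=100, n_generations=1,
                          n_animals=600, n_farms=3, birth_year_range=(1996, 1998))
        ped = simulate_pedigree(cfg)
        records, _ = simulate_records(cfg, ped)
        kept, report = apply_filters(records)
        assert report.records_out == report.records_in == len(records)
        assert all(v == 0 for v in report.excluded_by.values())

    def test_contamination_triggers_each_filter(self):
        rates = {k: 0.0 for k in SimulationConfig().contamination_rates}
        for kind, crit in [("incomplete", 1), ("twin", 2), ("embryo_transfer", 3),
                           ("abortion", 4), ("gestation", 5), ("calving_interval", 6),
                           ("late_first_calving", 7), ("multi_farm", 8)]:
            cfg = clean_config(seed=11, n_founders=60, n_generations=1,
                              n_animals=300, n_farms=2, birth_year_range=(1996, 1997))
            cfg = dataclasses.replace(cfg, contamination_rates={**rates, kind: 0.3})
            ped = simulate_pedigree(cfg)
            records, _ = simulate_records(cfg, ped)
            _, report = apply_filters(records)
            assert report.excluded_by[crit] > 0, kind

    def test_variance_accounting(self):
        """Empirical phenotypic variance (net of farm/year) matches the config."""
        realized = []
        for rep in range(20):
            cfg = clean_config(seed=300 + rep, n_founders=1000, n_generations=1,
                              n_animals=5000)
            ped = simulate_pedigree(cfg)
            records, _ = simulate_records(cfg, ped)
            tab = ncp4_table(records)
            resid = tab["ncp4"] - tab.groupby(["farm", "birth_year"])["ncp4"].transform("mean")
            n_cells = len(tab.groupby(["farm", "birth_year"]))
            v = float((resid ** 2).sum() / (len(tab) - n_cells))
            realized.append(v)
        v_mean = np.mean(realized)
        assert abs(v_mean - 0.0466) / 0.0466 < 0.10

    def test_infeasible_variance_partition_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            clean_config(heritability=0.001, substitution_effect=0.054).validate()

    def test_records_deterministic(self, small_herd):
        cfg = small_herd["config"]
        r1, t1 = simulate_records(cfg, small_herd["pedigree"], small_herd["truth"])
        r2, t2 = simulate_records(cfg, small_herd["pedigree"], small_herd["truth"])
        assert [r.calving_dates for r in r1] == [r.calving_dates for r in r2]
        pd.testing.assert_frame_equal(t1, t2)


class TestPeakTraces:
    def test_noiseless_ratios_exact(self):
        for ratio in (1.0, 2.0):
            tr = simulate_peak_traces(8, ratio, 0.0, seed=1)
            ror = peak_ratios(tr)["ratio_of_ratios"]
            assert np.allclose(ror, ratio)

    def test_mean_near_truth(self):
        tr = simulate_peak_traces(200, 1.33, 0.1, seed=2)
        assert abs(peak_ratios(tr)["ratio_of_ratios"].mean() - 1.33) < 0.05

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            simulate_peak_traces(5, -1.0, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_peak_traces(5, 1.0, -0.1, seed=0)
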