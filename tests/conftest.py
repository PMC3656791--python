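import numpy as np
import pandas as pd
import pytest

from ncp4gwas.config import clean_config
from ncp4gwas.containers import GenotypePanel, ReproductionRecord
from ncp4gwas.simulate import simulate_genotypes, simulate_pedigree, simulate_records


def make_record(cow_id="cow", ages_days=(800, 1180, 1560), farm=1, birth_year=1995,
                gestations=None, birth_date=0, **flags):
    """A clean record calving at the given ages (days); flags override per-event
    lists (twin_flags/et_flags/abortion_flags/farm_history)."""
    k = len(ages_days)
    rec = ReproductionRecord(
        cow_id=cow_id, sire_id="sire", dam_id="dam", farm_id=farm,
        birth_date=birth_date, birth_year=birth_year,
        calving_dates=[birth_date + int(a) for a in ages_days],
        gestation_lengths=list(gestations) if gestations else [285] * k,
        twin_flags=[False] * k, et_flags=[False] * k, abortion_flags=[False] * k,
        farm_history=[farm],
    )
    for name, val in flags.items():
        setattr(rec, name, val)
    return rec


def make_panel(dosages, freqs=None, chrom=None, pos=None):
    """Panel from a raw dosage matrix (rows = animals)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else [1] * m,
        "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "ref": ["A"] * m, "alt": ["G"] * m,
    })
    return GenotypePanel(np.array([f"a{i}" for i in range(n)]), snps, d)


@pytest.fixture(scope="session")
def small_herd():
    """A small clean herd shared by read-only tests."""
    cfg = clean_config(seed=7, n_founders=120, n_generations=1, n_animals=600,
                      n_farms=3, birth_year_range=(1996, 1998), n_snps=120,
                      n_chromosomes=4, causal_chromosome=4)
    ped = simulate_pedigree(cfg)
    panel, hap, truth = simulate_genotypes(cfg, ped)
    records, truth_df = simulate_records(cfg, ped, truth)
    return {"config": cfg, "pedigree": ped, "panel": panel, "haplotypes": hap,
            "truth": truth, "records": records, "truth_df": truth_df}
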