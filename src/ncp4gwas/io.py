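"""Readers and writers: PLINK PED/MAP text genotypes and the tab-delimited
tables the pipeline exchanges (pedigree, reproduction records, NCP4, truth
sidecars). All genomic positions are 1-based bp; missing genotypes are
"0 0" in PED files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypePanel, ReproductionRecord

VALID_ALLELES = set("ACGT0")


# ---------------------------------------------------------------------------
# PLINK PED/MAP text

def write_plink(panel: GenotypePanel, ped_path, map_path) -> None:
    """Write a panel as PLINK text. Dosage 0/1/2 counts the alt allele;
    missing becomes "0 0"; sex and phenotype columns are written as 0."""
    snps = panel.snps
    with open(map_path, "w") as fh:
        for _, s in snps.iterrows():
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    ref = snps["ref"].to_numpy()
    alt = snps["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(panel.animal_ids):
            fields = ["FAM", str(aid), "0", "0", "0", "0"]
            d = panel.dosages[i]
            for j in range(panel.n_snps):
                if d[j] == MISSING:
                    fields += ["0", "0"]
                elif d[j] == 0:
                    fields += [ref[j], ref[j]]
                elif d[j] == 1:
                    fields += [ref[j], alt[j]]
                else:
                    fields += [alt[j], alt[j]]
            fh.write("\t".join(fields) + "\n")


def read_plink_text(ped_path, map_path) -> GenotypePanel:
    """Read PLINK PED/MAP text into a panel.

    The dosage is counted on the minor allele as determined from the file
    (ties broken toward the alphabetically later allele, so a 50/50 SNP
    written by :func:`write_plink` round-trips). Malformed lines are
    rejected with their line number.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    snp_ids = [r[1] for r in map_rows]
    if len(set(snp_ids)) != len(snp_ids):
        dup = pd.Series(snp_ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ValueError(f"{map_path}: duplicated SNP id {dup!r}")
    m = len(map_rows)

    animal_ids = []
    allele_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 or (len(parts) - 6) % 2 != 0:
                raise ValueError(f"{ped_path}:{ln}: odd allele count ({len(parts) - 6} fields)")
            if (len(parts) - 6) // 2 != m:
                raise ValueError(
                    f"{ped_path}:{ln}: {(len(parts) - 6) // 2} genotypes for {m} mapped SNPs")
            for a in parts[6:]:
                if a not in VALID_ALLELES:
                    raise ValueError(f"{ped_path}:{ln}: invalid allele {a!r}")
            animal_ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows).reshape(len(animal_ids), m, 2)

    dosages = np.full((len(animal_ids), m), MISSING, dtype=np.int8)
    ref_out, alt_out = [], []
    for j in range(m):
        col = alleles[:, j, :]
        called = col[col != "0"]
        uniq, counts = np.unique(called, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"{ped_path}: SNP {snp_ids[j]} has >2 alleles: {uniq.tolist()}")
        if len(uniq) == 0:
            ref_out.append("0")
            alt_out.append("0")
            continue
        if len(uniq) == 1:
            major, minor = uniq[0], uniq[0]
        else:
            order = np.lexsort((uniq, counts))  # count asc, then allele asc
            minor, major = uniq[order[0]], uniq[order[1]]
            if counts[order[0]] == counts[order[1]]:
                minor, major = max(uniq), min(uniq)
        ok = (col != "0").all(axis=1)
        dosages[ok, j] = (col[ok] == minor).sum(axis=1)
        ref_out.append(str(major))
        alt_out.append(str(minor))

    snps = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": [int(r[0]) if str(r[0]).isdigit() else r[0] for r in map_rows],
        "pos": [r[2] for r in map_rows],
        "ref": ref_out, "alt": alt_out,
    })
    return GenotypePanel(np.array(animal_ids), snps, dosages)


# ---------------------------------------------------------------------------
# tab-delimited tables

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def records_to_table(records: list[ReproductionRecord]) -> pd.DataFrame:
    def join(vals):
        return ",".join(str(int(v)) for v in vals)

    rows = []
    for r in records:
        rows.append({
            "cow_id": r.cow_id, "sire_id": r.sire_id, "dam_id": r.dam_id,
            "farm_id": r.farm_id, "birth_date": r.birth_date, "birth_year": r.birth_year,
            "calving_dates": join(r.calving_dates),
            "gestation_lengths": join(r.gestation_lengths),
            "twin_flags": join(r.twin_flags), "et_flags": join(r.et_flags),
            "abortion_flags": join(r.abortion_flags),
            "farm_history": join(r.farm_history),
        })
    return pd.DataFrame(rows)


def table_to_records(df: pd.DataFrame) -> list[ReproductionRecord]:
    def ints(cell):
        return [int(v) for v in str(cell).split(",")] if str(cell) else []

    def bools(cell):
        return [bool(v) for v in ints(cell)]

    out = []
    for _, r in df.iterrows():
        rec = ReproductionRecord(
            cow_id=str(r.cow_id), sire_id=str(r.sire_id), dam_id=str(r.dam_id),
            farm_id=int(r.farm_id), birth_date=int(r.birth_date),
            birth_year=int(r.birth_year),
            calving_dates=ints(r.calving_dates),
            gestation_lengths=ints(r.gestation_lengths),
            twin_flags=bools(r.twin_flags), et_flags=bools(r.et_flags),
            abortion_flags=bools(r.abortion_flags),
            farm_history=ints(r.farm_history),
        )
        out.append(rec)
    return out


def require_inputs(stage: str, **paths) -> None:
    """Raise with the stage name if any declared input file is absent."""
    for name, p in paths.items():
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"stage {stage!r}: required input {name} missing ({p})")
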