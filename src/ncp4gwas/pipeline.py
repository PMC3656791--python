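"""End-to-end orchestration: filter -> NCP4 -> REML adjust -> extreme
selection -> SNP QC -> mixed-model scan -> threshold -> conditioned scan ->
LD/haplotype -> replication, each stage writing its table into a run
directory plus a machine-readable summary.json.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from . import io as nio
from .gwas import (compute_grm, emmax_scan, lander_kruglyak_threshold, qc_snps,
                   select_extremes)
from .haplotypes import assign_diplotype_classes, em_phase, pairwise_r2
from .imbalance import imbalance_test
from .phenotype import (adjust_phenotypes, apply_filters, build_a_matrix,
                        ncp4_table, reml_animal_model)
from .replication import replication_summary
from .simulate import (simulate_genotypes, simulate_peak_traces,
                       simulate_pedigree, simulate_records)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # optional pre-existing inputs; when None the simulate stage writes them
    records_path: str | None = None
    pedigree_path: str | None = None
    ped_path: str | None = None
    map_path: str | None = None
    peaks_path: str | None = None
    # filter thresholds
    gestation_range: tuple[int, int] = (261, 310)
    interval_range: tuple[int, int] = (276, 730)
    max_afc_days: int = 1128
    min_farm_year_records: int = 10
    # SNP QC
    call_rate_min: float = 0.99
    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    # extreme selection
    upper_pct: float = 0.0668
    lower_pct: float = 0.0668
    per_sire_cap: int = 4
    # genome-wide threshold
    n_chromosomes: int = 29
    rho: float = 2.0
    genome_length_morgans: float = 28.0
    genomewide_alpha: float = 0.05
    grm_mode: str = "ibs"
    # allelic imbalance simulation
    imbalance_true_ratio: float = 1.33
    imbalance_noise_cv: float = 0.1
    imbalance_n: int = 19


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage into ``outdir``; returns the summary dict
    (also written to summary.json). Rerunning with the same config
    reproduces identical outputs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.sim.seed,
                     "config": {**asdict(config), "sim": config.sim.to_dict()},
                     "stages": {}}
    log: list[str] = []

    def done(stage: str, **info):
        summary["stages"][stage] = info
        log.append(stage)

    # --- simulate ---------------------------------------------------------
    if config.records_path is None:
        try:
            ped = simulate_pedigree(config.sim)
            panel, hap, truth = simulate_genotypes(config.sim, ped)
            records, truth_df = simulate_records(config.sim, ped, truth)
            peaks = simulate_peak_traces(config.imbalance_n, config.imbalance_true_ratio,
                                         config.imbalance_noise_cv, config.sim.seed,
                                         tissue="ovary")
        except Exception as err:
            raise PipelineError(f"stage 'simulate': {err}") from err
        nio.write_table(ped, out / "pedigree.tsv")
        nio.write_table(nio.records_to_table(records), out / "records.tsv")
        nio.write_plink(panel, out / "genotypes.ped", out / "genotypes.map")
        nio.write_table(truth_df, out / "truth_records.tsv")
        nio.write_table(pd.DataFrame({"block_snp": truth["block_snps"]}),
                        out / "truth_causal.tsv")
        nio.write_table(peaks, out / "peaks.tsv")
        config = PipelineConfig(**{**asdict(config), "sim": config.sim,
                                   "records_path": str(out / "records.tsv"),
                                   "pedigree_path": str(out / "pedigree.tsv"),
                                   "ped_path": str(out / "genotypes.ped"),
                                   "map_path": str(out / "genotypes.map"),
                                   "peaks_path": str(out / "peaks.tsv")})
        done("simulate", n_animals=len(ped), n_records=len(records),
             n_snps=panel.n_snps, causal_snp=truth["causal_snp"])

    # --- phenotype --------------------------------------------------------
    try:
        nio.require_inputs("phenotype", records=config.records_path,
                           pedigree=config.pedigree_path)
        records = nio.table_to_records(nio.read_table(config.records_path))
        ped = nio.read_table(config.pedigree_path)
        ped = ped.astype({"animal": str, "sire": str, "dam": str})
        retained, report = apply_filters(
            records, gestation_range=config.gestation_range,
            interval_range=config.interval_range, max_afc_days=config.max_afc_days,
            min_farm_year_records=config.min_farm_year_records)
        if not retained:
            raise ValueError("no records survive the nine selection criteria")
        tab = ncp4_table(retained)
        amat = build_a_matrix(ped).subset(tab["animal"].to_numpy())
        vc = reml_animal_model(tab["ncp4"].to_numpy(), tab["farm"].to_numpy(),
                               tab["birth_year"].to_numpy(), amat)
        tab["adjusted_ncp4"] = adjust_phenotypes(
            tab["ncp4"].to_numpy(), tab["farm"].to_numpy(),
            tab["birth_year"].to_numpy(), vc)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage 'phenotype': {err}") from err
    nio.write_table(tab, out / "ncp4.tsv")
    filt = pd.DataFrame({"criterion": list(report.excluded_by),
                         "description": [f"criterion {c}" for c in report.excluded_by],
                         "excluded": list(report.excluded_by.values())})
    nio.write_table(filt, out / "filter_report.tsv")
    done("phenotype", records_in=report.records_in, records_out=report.records_out,
         heritability=vc.heritability, sigma_a2=vc.additive_variance,
         sigma_e2=vc.residual_variance)

    # --- gwas -------------------------------------------------------------
    try:
        nio.require_inputs("gwas scan", ped=config.ped_path, map=config.map_path)
        panel = nio.read_plink_text(config.ped_path, config.map_path)
        design = select_extremes(tab, upper_pct=config.upper_pct,
                                 lower_pct=config.lower_pct,
                                 per_sire_cap=config.per_sire_cap,
                                 seed=config.sim.seed)
        sub = panel.subset_animals(design.animal_ids)
        kept, qc = qc_snps(sub, call_rate_min=config.call_rate_min,
                           maf_min=config.maf_min, hwe_p_min=config.hwe_p_min)
        if len(kept) < 2:
            raise ValueError("fewer than 2 SNPs survive QC")
        sub = sub.subset_snps(kept)
        grm = compute_grm(sub, config.grm_mode)
        scan = emmax_scan(design.response, sub, grm, design=design)
        spec = lander_kruglyak_threshold(config.n_chromosomes, config.rho,
                                         config.genome_length_morgans,
                                         config.genomewide_alpha)
        top = scan.table.loc[scan.table["p"].idxmin()]
        cond = emmax_scan(design.response, sub, grm,
                          condition_snps=[top["snp_id"]], design=design)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage 'gwas scan': {err}") from err
    assoc = scan.table.copy()
    assoc["genomewide_significant"] = assoc["p"] < spec.pointwise_alpha
    nio.write_table(assoc, out / "association.tsv")
    nio.write_table(cond.table, out / "association_conditioned.tsv")
    qq = assoc.loc[assoc["estimable"]].sort_values("p")[["snp_id", "p"]].copy()
    qq["expected_p"] = (np.arange(1, len(qq) + 1) - 0.5) / len(qq)
    nio.write_table(qq, out / "qq.tsv")
    done("gwas", n_upper=len(design.upper_ids), n_lower=len(design.lower_ids),
         snps_tested=int(qc.n_retained), lambda_gc=scan.lambda_gc,
         pseudo_heritability=scan.pseudo_heritability,
         pointwise_alpha=spec.pointwise_alpha, top_snp=str(top["snp_id"]),
         top_p=float(top["p"]),
         n_significant=int(assoc["genomewide_significant"].sum()),
         n_significant_after_conditioning=int(
             (cond.table["p"] < spec.pointwise_alpha).sum()))

    # --- ld / haplotypes ---------------------------------------------------
    try:
        chrom = top["chrom"]
        on_chrom = scan.table[scan.table["chrom"] == chrom]
        window = on_chrom.iloc[
            (on_chrom["pos"] - top["pos"]).abs().argsort()[:8]].sort_values("pos")
        window_ids = window["snp_id"].tolist()
        r2 = pairwise_r2(sub, window_ids)
        best2 = on_chrom.sort_values("p")["snp_id"].head(2).tolist()
        cols = [sub.snp_index(s) for s in best2]
        freqs, _ = em_phase(sub.dosages[:, cols], snp_ids=best2)
        hap_tab = pd.DataFrame({"haplotype": freqs.haplotypes,
                                "frequency": freqs.frequencies})
    except Exception as err:
        raise PipelineError(f"stage 'ld': {err}") from err
    ld_tab = pd.DataFrame(r2, index=window_ids, columns=window_ids)
    ld_tab.insert(0, "snp_id", window_ids)
    nio.write_table(ld_tab, out / "ld_r2.tsv")
    nio.write_table(hap_tab, out / "haplotype_frequencies.tsv")
    done("ld", window=window_ids, tag_snps=best2,
         max_offdiag_r2=float(np.nanmax(np.where(np.eye(len(r2)), np.nan, r2))))

    # --- imbalance ---------------------------------------------------------
    try:
        nio.require_inputs("imbalance", peaks=config.peaks_path)
        peaks = nio.read_table(config.peaks_path)
        est = imbalance_test(peaks)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage 'imbalance': {err}") from err
    nio.write_table(pd.DataFrame([{"tissue": est.tissue, "n": est.n,
                                   "mean_ratio": est.mean_ratio,
                                   "t": est.t_statistic, "p": est.p_value}]),
                    out / "imbalance.tsv")
    done("imbalance", tissue=est.tissue, mean_ratio=est.mean_ratio, p=est.p_value)

    # --- replication -------------------------------------------------------
    try:
        gwas_ids = set(design.animal_ids.tolist())
        rep = tab[~tab["animal"].isin(gwas_ids)]
        rep_panel = panel.subset_animals(rep["animal"].to_numpy())
        cols = [rep_panel.snp_index(s) for s in best2]
        # Q is the haplotype associated with higher NCP4: at each tag SNP take
        # the allele whose dosage has a positive scan effect
        betas = [float(scan.table.loc[scan.table["snp_id"] == s, "beta"].iloc[0])
                 for s in best2]
        q_alleles = tuple(1 if b > 0 else 0 for b in betas)
        classes = assign_diplotype_classes(rep_panel.dosages[:, cols], q_alleles, freqs)
        keep = [c != "unresolved" for c in classes]
        summary_rep = replication_summary(
            rep["ncp4"].to_numpy()[keep], rep["farm"].to_numpy()[keep],
            rep["birth_year"].to_numpy()[keep],
            np.asarray(classes)[keep], heritability=vc.heritability)
    except Exception as err:
        raise PipelineError(f"stage 'replication': {err}") from err
    nio.write_table(pd.DataFrame([{
        "haplotype_frequency": summary_rep.haplotype_frequency,
        "heritability": vc.heritability,
        "share_of_phenotypic": summary_rep.share_of_phenotypic,
        "substitution_effect": summary_rep.substitution_effect,
        "tukey_p_QQ_qq": summary_rep.tukey_p.get(("QQ", "qq"), float("nan")),
    }]), out / "replication.tsv")
    done("replication", n=int(np.sum(keep)),
         substitution_effect=summary_rep.substitution_effect,
         share_of_phenotypic=summary_rep.share_of_phenotypic)

    summary["input_hashes"] = {
        name: _sha1(p) for name, p in
        [("records", config.records_path), ("pedigree", config.pedigree_path),
         ("ped", config.ped_path), ("map", config.map_path),
         ("peaks", config.peaks_path)] if p and Path(p).exists()}
    summary["stage_order"] = log
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True,
                                                 default=str))
    return summary
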