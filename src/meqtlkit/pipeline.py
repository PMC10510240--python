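"""End-to-end pipeline: ancestry -> EWAS -> meQTL -> pleiotropy -> MR.

Each stage reads the bundle TSVs, writes its own TSV artifact under the
output directory and logs survivor counts; a stage left with zero records
stops the run with a stage-named error. Given a fixed seed the stage
outputs are byte-identical across reruns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import AncestryModel
from .config import PipelineConfig
from .ewas import EwasModel
from .io_formats import read_catalog, read_gene_bed, read_genotypes, \
    read_methylation, read_summary_stats
from .meqtl import CisMeqtlModel
from .mr import MRModel, harmonize, select_ivs
from .pleiotropy import intersect_findings, phewas_lookup, trait_enrichment
from .meqtl import genotype_qc

logger = logging.getLogger("meqtlkit")

__all__ = ["PipelineError", "load_bundle", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage produced zero surviving records (stage named in message)."""


def load_bundle(bundle_dir, cohorts=("450K", "EPIC")) -> dict:
    """Read every bundle artifact into memory."""
    d = Path(bundle_dir)
    bundle = {
        "reference": read_genotypes(d / "reference_genotypes.tsv", "dosage"),
        "ref_labels": pd.read_csv(d / "reference_labels.tsv", sep="\t"),
        "cohort": read_genotypes(d / "cohort_genotypes.tsv", "dosage"),
        "covariates": pd.read_csv(d / "covariates.tsv", sep="\t",
                                  dtype={"sample": str}),
        "catalog": read_catalog(d / "catalog.tsv"),
        "genes": read_gene_bed(d / "genes.bed"),
        "cell_reference": pd.read_csv(d / "cell_reference.tsv", sep="\t",
                                      index_col=0),
        "methylation": {}, "control": {}, "detection_p": {},
        "outcome": {},
    }
    for cohort in cohorts:
        bundle["methylation"][cohort] = read_methylation(
            d / f"methylation_{cohort}.tsv", d / "probes.tsv", "m", cohort)
        bundle["control"][cohort] = pd.read_csv(
            d / f"control_{cohort}.tsv", sep="\t", index_col=0)
        bundle["detection_p"][cohort] = pd.read_csv(
            d / f"detection_{cohort}.tsv", sep="\t", index_col=0)
    for path in sorted(d.glob("outcome_*.tsv")):
        trait = path.stem.removeprefix("outcome_").replace("_", " ")
        bundle["outcome"][trait] = read_summary_stats(path)
    return bundle


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, bundle_dir=None, out_dir=None) -> dict:
    """Execute every stage in order; returns the in-memory results.

    Stage TSVs land in ``out_dir``: ancestry.tsv, ewas_meta.tsv,
    candidates.tsv, meqtl_pairs.tsv, index_meqtls.tsv, phewas_hits.tsv,
    enrichment.tsv, mr_results.tsv.
    """
    bundle_dir = Path(bundle_dir or config.bundle_dir)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b = load_bundle(bundle_dir, config.cohorts)

    # --- ancestry -----------------------------------------------------
    anc = AncestryModel(b["reference"], b["cohort"],
                        b["ref_labels"]["population"].tolist(),
                        prune_r2=config.prune_r2, k=config.knn_k,
                        seed=config.seed).fit()
    anc.to_tsv(out / "ancestry.tsv")
    logger.info("stage ancestry: %d samples labelled", len(anc.table))

    # --- genotype QC (shared by meQTL and MR stages) ------------------
    G = genotype_qc(b["cohort"], config.maf_min, config.miss_max,
                    config.hwe_p_min)
    if G.n_variants == 0:
        raise PipelineError("genotype_qc: zero variants survive QC")

    # --- EWAS ---------------------------------------------------------
    ewas = EwasModel(b["methylation"], b["covariates"], b["control"],
                     b["cell_reference"], snp_positions=G.variants,
                     detection_p=b["detection_p"],
                     candidate_p=config.candidate_meta_p,
                     detection_p_max=config.detection_p_max,
                     snp_window=config.snp_exclusion_bp).fit()
    _write(ewas.meta, out / "ewas_meta.tsv")
    _write(ewas.candidates, out / "candidates.tsv")
    if ewas.candidates.empty:
        raise PipelineError("ewas: zero candidates at meta p < "
                            f"{config.candidate_meta_p:g}")

    # --- cis-meQTL ----------------------------------------------------
    meqtl = CisMeqtlModel(b["methylation"], G, ewas.covariates, ewas.candidates,
                          window=config.cis_window, fdr_level=config.fdr_level,
                          clump_r2=config.clump_r2, genes=b["genes"]).fit()
    _write(meqtl.all_pairs, out / "meqtl_pairs.tsv")
    _write(meqtl.index_meqtls, out / "index_meqtls.tsv")
    if meqtl.significant.empty:
        raise PipelineError("meqtl: zero FDR-significant pairs")

    # --- pleiotropy ---------------------------------------------------
    hits = phewas_lookup(meqtl.index_meqtls, b["catalog"],
                         gw_threshold=config.phewas_genomewide_p,
                         alpha=config.phewas_alpha)
    _write(hits, out / "phewas_hits.tsv")
    enr = trait_enrichment(set(meqtl.significant["variant"]), b["catalog"],
                           set(G.variants["id"]))
    _write(enr, out / "enrichment.tsv")
    phe_traits = hits.loc[hits["significant"], "trait"].unique().tolist()
    enr_traits = enr.loc[enr["p_one_sided"] < config.enrichment_alpha,
                         "trait"].tolist()
    overlap = intersect_findings(phe_traits, enr_traits)
    logger.info("stage pleiotropy: %d PheWAS traits, %d enriched, %d overlap",
                len(phe_traits), len(enr_traits), len(overlap))
    if not overlap:
        raise PipelineError("pleiotropy: zero overlap traits for MR")

    # --- MR -----------------------------------------------------------
    cov = b["covariates"]
    y = cov.set_index("sample").loc[G.samples, "exposure"].to_numpy()
    ivs = select_ivs(meqtl.significant, G, y, p_max=config.iv_p)
    datasets = {}
    for trait in overlap:
        key = next((k for k in b["outcome"] if k.lower() == trait.lower()), None)
        if key is None:
            logger.warning("no outcome summary statistics for trait %r", trait)
            continue
        datasets[(trait, f"gwas_{key.replace(' ', '_')}")] = harmonize(
            ivs, b["outcome"][key])
    if not datasets:
        raise PipelineError("mr: no outcome summary statistics for the "
                            "overlap traits")
    mr = MRModel(datasets, alpha=config.mr_alpha, seed=config.seed).fit()
    _write(mr.table, out / "mr_results.tsv")

    return {"ancestry": anc, "ewas": ewas, "meqtl": meqtl, "phewas": hits,
            "enrichment": enr, "overlap_traits": overlap, "mr": mr,
            "genotypes_qc": G, "out_dir": out}
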