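"""cis-meQTL mapping for candidate CpGs.

For each candidate CpG, every QC-passing SNP within +/-500 kb is tested by
per-pair OLS of the methylation M-value on the dosage plus the EWAS
covariate set (M = b0 + b1 X + sum b_{i+1} C_i). Cohort results are pooled
by fixed-effects meta-analysis; Benjamini-Hochberg FDR is applied once
across all tested pairs; significant pairs are LD-clumped per CpG
(r^2 > 0.1, smallest-p lead = index meQTL) and annotated with the nearest
gene.

The per-pair fit uses Frisch-Waugh-Lovell residualisation: M and X are
residualised on the covariates once, then each pair reduces to a simple
regression whose coefficient, SE and t-test (at the full model's residual
degrees of freedom) are identical to the joint OLS fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, MethylationMatrix, align_samples, log_filter

logger = logging.getLogger("meqtlkit")

__all__ = [
    "hwe_test",
    "genotype_qc",
    "cis_pairs",
    "fit_meqtl",
    "bh_fdr",
    "clump",
    "nearest_gene",
    "CisMeqtlModel",
    "CisMeqtlResults",
]


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts come from the estimated allele frequency; monomorphic
    sites return p = 1 by convention.
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("empty genotype counts")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p_hat ** 2, 2 * n * p_hat * (1 - p_hat),
                    n * (1 - p_hat) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, 1))


def genotype_qc(G: GenotypeMatrix, maf_min: float = 0.05,
                miss_max: float = 0.05, hwe_p_min: float = 1e-6) -> GenotypeMatrix:
    """Variant QC: MAF, missingness and Hardy-Weinberg filters.

    Removal rules (kept at equality): MAF < ``maf_min``, missing rate >
    ``miss_max``, HWE p < ``hwe_p_min``. Dosages are rounded to genotype
    classes for the HWE counts.
    """
    dos = G.dosages
    n = dos.shape[0]
    miss = np.isnan(dos).sum(axis=0) / n
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    hwe = np.empty(G.n_variants)
    g = np.rint(dos)
    for j in range(G.n_variants):
        col = g[:, j]
        col = col[~np.isnan(col)]
        hwe[j] = hwe_test(int((col == 2).sum()), int((col == 1).sum()),
                          int((col == 0).sum()))
    keep = (maf >= maf_min) & (miss <= miss_max) & (hwe >= hwe_p_min)
    out = G.subset_variants(keep)
    log_filter(f"genotype_qc(maf>={maf_min}, miss<={miss_max}, hwe_p>={hwe_p_min:g})",
               G.n_variants, out.n_variants)
    return out


def cis_pairs(cpgs: pd.DataFrame, variants: pd.DataFrame,
              window: int = 500_000) -> pd.DataFrame:
    """Same-chromosome (variant, cpg) pairs with |pos difference| <= window.

    The window is inclusive at the boundary on both sides.
    """
    rows = []
    for chrom, cg in cpgs.groupby("chrom"):
        vg = variants.loc[variants["chrom"] == chrom]
        if vg.empty:
            continue
        vpos = vg["pos"].to_numpy()
        order = np.argsort(vpos)
        vpos_s = vpos[order]
        vids = vg["id"].to_numpy()[order]
        for cid, cpos in zip(cg["id"], cg["pos"]):
            lo = np.searchsorted(vpos_s, cpos - window, side="left")
            hi = np.searchsorted(vpos_s, cpos + window, side="right")
            for v in vids[lo:hi]:
                rows.append((v, cid))
    return pd.DataFrame(rows, columns=["variant", "cpg"])


def _residualize(Y: np.ndarray, C: np.ndarray):
    X = np.column_stack([np.ones(len(Y))] + ([C] if C.size else []))
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef, X.shape[1]


def fit_meqtl(M: MethylationMatrix, G: GenotypeMatrix, covariates: pd.DataFrame,
              pairs: pd.DataFrame, cohort: str | None = None) -> pd.DataFrame:
    """Per-pair OLS of M-values on dosage with the covariate set.

    Missing dosages are mean-imputed within the fit. Variants monomorphic
    in-sample yield a record with p = 1 and ``degenerate=True``. Exact
    equivalence with the joint OLS fit is achieved by FWL residualisation
    with degrees of freedom n - (k + 2).
    """
    if pairs.empty:
        raise ValueError("empty cis-pair list")
    align_samples(M.samples, G.samples)
    C = covariates.to_numpy(dtype=float)
    Mr, k_cov = _residualize(M.values, C)
    dos = G.dosages.copy()
    if np.isnan(dos).any():
        mean = np.nanmean(dos, axis=0)
        idx = np.where(np.isnan(dos))
        dos[idx] = mean[idx[1]]
    Gr, _ = _residualize(dos, C)
    n = len(Mr)
    df = n - (k_cov + 1)  # intercept+covariates already in k_cov, +1 for dosage

    cpg_j = {c: j for j, c in enumerate(M.probes["id"])}
    var_i = {v: i for i, v in enumerate(G.variants["id"])}
    mono = np.nanstd(G.dosages, axis=0) == 0

    vi = pairs["variant"].map(var_i).to_numpy()
    cj = pairs["cpg"].map(cpg_j).to_numpy()
    if np.isnan(vi.astype(float)).any() or np.isnan(cj.astype(float)).any():
        raise KeyError("pair references a variant or CpG absent from the data")

    x = Gr[:, vi]                       # (n, n_pairs)
    y = Mr[:, cj]
    sxx = (x ** 2).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    syy = (y ** 2).sum(axis=0)
    degenerate = mono[vi] | (sxx <= 1e-12)
    sxx_safe = np.where(degenerate, 1.0, sxx)
    beta = sxy / sxx_safe
    rss = syy - beta ** 2 * sxx_safe
    se = np.sqrt(np.maximum(rss, 0) / df / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    pval = 2 * stats.t.sf(np.abs(tval), df=df)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.nan, se)
    pval = np.where(degenerate, 1.0, pval)
    return pd.DataFrame({
        "variant": pairs["variant"].to_numpy(), "cpg": pairs["cpg"].to_numpy(),
        "beta": beta, "se": se, "p": np.clip(pval, np.finfo(float).tiny, 1.0),
        "cohort": cohort if cohort is not None else M.cohort,
        "n": n, "degenerate": degenerate,
    })


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} (p_(j) * m / j)``, capped at 1, returned in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def clump(records: pd.DataFrame, G: GenotypeMatrix, r2_min: float = 0.1) -> pd.DataFrame:
    """Greedy LD clumping of one CpG's significant meQTL records.

    Repeatedly the smallest-p unassigned variant becomes a new clump index;
    every unassigned variant whose in-sample dosage r^2 with the index
    exceeds ``r2_min`` joins that clump. Ties on p are broken by the lower
    genomic position. Adds ``clump_id`` and ``is_index`` columns.
    """
    rec = records.copy()
    var_i = {v: i for i, v in enumerate(G.variants["id"])}
    missing = [v for v in rec["variant"] if v not in var_i]
    if missing:
        raise KeyError(f"dosages unavailable for {missing[:3]}")
    dos = G.dosages[:, [var_i[v] for v in rec["variant"]]]
    if np.isnan(dos).any():
        mean = np.nanmean(dos, axis=0)
        idx = np.where(np.isnan(dos))
        dos[idx] = mean[idx[1]]
    pos = G.variants.set_index("id").loc[rec["variant"], "pos"].to_numpy()
    order = np.lexsort((pos, rec["p"].to_numpy()))
    sd = dos.std(axis=0)
    n_rec = len(rec)
    clump_id = np.full(n_rec, -1)
    is_index = np.zeros(n_rec, dtype=bool)
    cid = 0
    for i in order:
        if clump_id[i] >= 0:
            continue
        clump_id[i] = cid
        is_index[i] = True
        free = clump_id < 0
        if free.any() and sd[i] > 0:
            with np.errstate(invalid="ignore"):
                r = np.where(
                    sd > 0,
                    ((dos - dos.mean(axis=0)).T @ (dos[:, i] - dos[:, i].mean()))
                    / (len(dos) * sd * sd[i]),
                    0.0,
                )
            clump_id[free & (r ** 2 > r2_min)] = cid
        cid += 1
    rec["clump_id"] = clump_id
    rec["is_index"] = is_index
    return rec


def nearest_gene(positions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest-gene annotation for a table of (chrom, pos) rows.

    Positions inside a gene get that gene with class ``genic``; others get
    the minimal-distance gene with class ``intergenic``. Ties go to the
    lower-coordinate (start, then name) gene; a chromosome absent from the
    gene model yields label ``NA``.
    """
    out_gene = np.full(len(positions), "NA", dtype=object)
    out_class = np.full(len(positions), "NA", dtype=object)
    positions = positions.reset_index(drop=True)
    for chrom, grp in positions.groupby("chrom"):
        gg = genes.loc[genes["chrom"] == chrom].sort_values(["start", "name"])
        if gg.empty:
            continue
        starts = gg["start"].to_numpy()
        ends = gg["end"].to_numpy()
        names = gg["name"].to_numpy()
        for row in grp.itertuples():
            p = row.pos
            dist = np.where(p < starts, starts - p,
                            np.where(p > ends, p - ends, 0))
            best = dist.min()
            cand = np.flatnonzero(dist == best)
            j = cand[np.lexsort((names[cand], starts[cand]))[0]]
            out_gene[row.Index] = names[j]
            out_class[row.Index] = "genic" if best == 0 else "intergenic"
    res = positions.copy()
    res["gene"] = out_gene
    res["region_class"] = out_class
    return res


# ---------------------------------------------------------------------------
# model facade


@dataclass
class CisMeqtlResults:
    all_pairs: pd.DataFrame      # META rows with fdr
    significant: pd.DataFrame    # FDR < level, clumped, annotated
    per_cohort: dict
    fdr_level: float

    @property
    def index_meqtls(self) -> pd.DataFrame:
        return self.significant.loc[self.significant["is_index"]].reset_index(drop=True)

    def summary(self) -> str:
        return "\n".join([
            "cis-meQTL scan (meta-analysed, BH-FDR corrected)",
            f"  SNP-CpG pairs tested: {len(self.all_pairs)}",
            f"  pairs at FDR < {self.fdr_level:g}: {len(self.significant)}",
            f"  index meQTLs after clumping: {len(self.index_meqtls)}",
        ])


class CisMeqtlModel:
    """cis-meQTL scan for candidate CpGs across two cohorts.

    Covariate designs are per cohort (the EWAS technical covariates,
    optionally without the residual PCs - the meQTL covariate list uses
    the control-probe PCs only by default, ``include_residual_pcs`` adds
    them back).
    """

    def __init__(self, methylation: dict, genotypes: GenotypeMatrix,
                 covariates: dict, candidates: pd.DataFrame,
                 window: int = 500_000, fdr_level: float = 0.05,
                 clump_r2: float = 0.1, genes: pd.DataFrame | None = None,
                 include_residual_pcs: bool = False):
        self.methylation = methylation
        self.genotypes = genotypes
        self.covariates = covariates
        self.candidates = candidates
        self.window = window
        self.fdr_level = fdr_level
        self.clump_r2 = clump_r2
        self.genes = genes
        self.include_residual_pcs = include_residual_pcs

    def _design(self, cohort: str) -> pd.DataFrame:
        C = self.covariates[cohort]
        if not self.include_residual_pcs:
            C = C[[c for c in C.columns if not c.startswith("residPC")]]
        return C

    def fit(self) -> CisMeqtlResults:
        cand_probes = self.candidates[["cpg", "chrom", "pos"]].rename(
            columns={"cpg": "id"})
        pairs = cis_pairs(cand_probes, self.genotypes.variants, self.window)
        if pairs.empty:
            raise ValueError("no cis pairs within the window")
        per_cohort = {}
        for cohort, M in self.methylation.items():
            Mc = M.subset_probes(list(self.candidates["cpg"]))
            Gc = self.genotypes.subset_samples(M.samples)
            per_cohort[cohort] = fit_meqtl(Mc, Gc, self._design(cohort),
                                           pairs, cohort)
        cohorts = list(per_cohort)
        from .ewas import meta_fixed  # same pooling as the EWAS stage

        a, b = per_cohort[cohorts[0]].copy(), per_cohort[cohorts[1]].copy()
        a["pair"] = a["variant"] + "|" + a["cpg"]
        b["pair"] = b["variant"] + "|" + b["cpg"]
        meta = meta_fixed(a[["pair", "beta", "se", "p", "n"]],
                          b[["pair", "beta", "se", "p", "n"]], key="pair")
        meta[["variant", "cpg"]] = meta["pair"].str.split("|", expand=True)
        meta = meta.drop(columns="pair")
        # one FDR family across all tested pairs
        meta["fdr"] = bh_fdr(meta["p"].to_numpy())
        sig = meta.loc[meta["fdr"] < self.fdr_level].copy()
        log_filter(f"meqtl_fdr<{self.fdr_level:g}", len(meta), len(sig))

        clumped = []
        for cpg, grp in sig.groupby("cpg"):
            clumped.append(clump(grp, self.genotypes, self.clump_r2)
                           .assign(clump_id=lambda d, c=cpg: c + ":" +
                                   d["clump_id"].astype(str)))
        sig = (pd.concat(clumped, ignore_index=True)
               if clumped else sig.assign(clump_id=[], is_index=[]))

        if self.genes is not None and not sig.empty:
            vmeta = self.genotypes.variants.set_index("id")
            ann = nearest_gene(
                pd.DataFrame({"chrom": vmeta.loc[sig["variant"], "chrom"].to_numpy(),
                              "pos": vmeta.loc[sig["variant"], "pos"].to_numpy()}),
                self.genes)
            sig["gene"] = ann["gene"].to_numpy()
            sig["region_class"] = ann["region_class"].to_numpy()
        return CisMeqtlResults(meta, sig.reset_index(drop=True), per_cohort,
                               self.fdr_level)
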