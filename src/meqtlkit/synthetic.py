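"""Ground-truth synthetic data emulating an admixed meQTL/EWAS/MR study.

The generator produces every input the pipeline consumes, with the planted
effects recorded so downstream stages can be tested against known truth:

* a labelled reference genotype panel drawn from four ancestral populations
  under the Balding-Nichols allele-frequency model;
* an admixed study cohort measured on two methylation arrays ("450K",
  N=423 and "EPIC", N=388) with batch structure, control probes and
  cell-type mixtures;
* a binary exposure partially driven by genotype (logistic model);
* CpG M-values carrying planted cis SNP effects and exposure effects;
* an independent outcome cohort summarised as per-variant GWAS statistics,
  with a planted causal effect of the exposure and optional horizontal
  pleiotropy;
* a GWAS-catalog-style trait table whose "enriched" traits over-sample
  their risk variants from the true meQTLs.

Linkage disequilibrium is modelled block-wise: variants within a block
share an allele frequency and haplotypes copy a block-level template with
probability sqrt(r), which makes the expected within-block dosage
correlation exactly ``r``. This is deliberately simpler than coalescent
simulation - LD pruning and clumping only need a controllable r^2.

Every function is a pure function of (config, seed); reruns reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_formats import (
    GenotypeMatrix,
    MethylationMatrix,
    write_dosage_tsv,
    write_methylation_tsv,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "simulate_reference_panel",
    "simulate_admixed_cohort",
    "simulate_exposure",
    "simulate_methylome",
    "simulate_outcome_gwas",
    "simulate_catalog",
    "simulate_bundle",
    "write_bundle",
]

CELL_TYPES = ["CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran"]
POPULATIONS = ["AFR", "EUR", "EAS", "SAS"]


@dataclass
class SimConfig:
    """Study-scale parameters for the synthetic cohort.

    Cohort sizes follow the study design being emulated (423 samples on the
    450K array, 388 on EPIC, ~36% exposed); marker counts are scaled down
    to 2,000 SNPs / 1,000 CpGs so the full pipeline runs in minutes.
    Planted effect sizes (cis effect 0.5 M-units per allele, exposure shift
    0.5 M-units, exposure log-OR 0.4 per allele, causal effect 0.3) are
    chosen for comfortable statistical power at these sample sizes.
    """

    # population structure
    n_pops: int = 4
    fst: float = 0.1
    n_ref_per_pop: int = 200
    admixed_fraction: float = 0.1
    # genome layout
    n_chrom: int = 4
    chrom_length: int = 10_000_000
    n_snps: int = 2000
    n_cpgs: int = 1000
    ld_block_size: int = 10
    ld_r: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    n_genes: int = 100
    # cohort
    n_450k: int = 423
    n_epic: int = 388
    # planted structure
    n_true_meqtls: int = 50
    meqtl_effect: float = 0.5
    n_true_exposure_cpgs: int = 60
    exposure_cpg_effect: float = 0.5
    n_exposure_snps: int = 30
    exposure_snp_logodds: float = 0.4
    exposure_prevalence: float = 0.361
    cis_window: int = 500_000
    # methylome nuisance structure
    noise_sd: float = 0.5
    n_cell_types: int = 6
    cell_alpha: tuple = (7.0, 4.0, 1.0, 2.0, 3.0, 16.0)
    cell_profile_sd: float = 1.5
    cell_profile_bg_sd: float = 0.3
    n_cell_ref_cpgs: int = 200
    n_control_probes: int = 100
    batch_shift_sd: float = 0.3
    technical_loading_sd: float = 0.3
    n_hidden_factors: int = 5
    hidden_loading_sd: float = 0.4
    covariate_cpg_fraction: float = 0.1
    # outcome GWAS / MR
    outcome_gwas_n: int = 5000
    causal_gamma: float = 0.3
    # catalog
    n_null_traits: int = 20
    n_enriched_traits: int = 3
    enrichment_factor: float = 5.0
    risk_variants_per_trait: int = 40
    seed: int = 0

    def __post_init__(self):
        counts = [self.n_pops, self.n_ref_per_pop, self.n_chrom, self.n_snps,
                  self.n_cpgs, self.ld_block_size, self.n_450k, self.n_epic,
                  self.n_cell_types, self.n_control_probes, self.outcome_gwas_n]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.ld_r < 1):
            raise ValueError("ld_r must lie in [0, 1)")
        if not (0 < self.fst <= 0.5):
            raise ValueError("fst must lie in (0, 0.5]")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class SyntheticTruth:
    """Planted parameters, keyed by variant/CpG id (never by position)."""

    meqtl_effects: dict = field(default_factory=dict)        # (variant, cpg) -> beta
    exposure_cpg_effects: dict = field(default_factory=dict)  # cpg -> alpha
    exposure_snp_effects: dict = field(default_factory=dict)  # variant -> log-odds
    causal_gamma: dict = field(default_factory=dict)          # trait -> gamma
    pleiotropic_variants: dict = field(default_factory=dict)  # trait -> {variant: direct effect}
    ancestry_labels: list = field(default_factory=list)       # per cohort sample
    cell_proportions: "pd.DataFrame | None" = None            # samples x cell types
    ld_block_of: dict = field(default_factory=dict)           # variant -> block id
    enriched_traits: list = field(default_factory=list)

    def to_json(self, path) -> None:
        d = {
            "meqtl_effects": [
                {"variant": v, "cpg": c, "beta": b}
                for (v, c), b in self.meqtl_effects.items()
            ],
            "exposure_cpg_effects": self.exposure_cpg_effects,
            "exposure_snp_effects": self.exposure_snp_effects,
            "causal_gamma": self.causal_gamma,
            "pleiotropic_variants": self.pleiotropic_variants,
            "ancestry_labels": self.ancestry_labels,
            "ld_block_of": self.ld_block_of,
            "enriched_traits": self.enriched_traits,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        t = cls()
        t.meqtl_effects = {(r["variant"], r["cpg"]): r["beta"] for r in d["meqtl_effects"]}
        t.exposure_cpg_effects = d["exposure_cpg_effects"]
        t.exposure_snp_effects = d["exposure_snp_effects"]
        t.causal_gamma = d["causal_gamma"]
        t.pleiotropic_variants = d["pleiotropic_variants"]
        t.ancestry_labels = d["ancestry_labels"]
        t.ld_block_of = d["ld_block_of"]
        t.enriched_traits = d["enriched_traits"]
        return t


# ---------------------------------------------------------------------------
# genome layout and allele frequencies


def _variant_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    per_chrom[: cfg.n_snps % cfg.n_chrom] += 1
    rows = []
    i = 0
    bases = np.array(list("ACGT"))
    for c in range(cfg.n_chrom):
        pos = np.sort(rng.choice(cfg.chrom_length, size=per_chrom[c], replace=False)) + 1
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append({"id": f"rs{i:05d}", "chrom": f"chr{c + 1}", "pos": int(p),
                         "ref": bases[ref], "alt": bases[alt]})
            i += 1
    return pd.DataFrame(rows)


def _block_ids(cfg: SimConfig, variants: pd.DataFrame) -> np.ndarray:
    """Consecutive same-chromosome variants form LD blocks of fixed size."""
    block = np.empty(len(variants), dtype=int)
    b = 0
    for _, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for start in range(0, len(idx), cfg.ld_block_size):
            block[idx[start:start + cfg.ld_block_size]] = b
            b += 1
    return block


def balding_nichols_freqs(cfg: SimConfig, blocks: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-population allele frequencies, shared within each LD block.

    Ancestral frequency p0 ~ Uniform(maf range); each population drifts as
    Beta(p0(1-F)/F, (1-p0)(1-F)/F). As F -> 0 the Beta concentrates at p0.
    """
    n_blocks = blocks.max() + 1
    p0 = rng.uniform(*cfg.maf_range, size=n_blocks)
    F = max(cfg.fst, 1e-8)
    a = p0 * (1 - F) / F
    b = (1 - p0) * (1 - F) / F
    pk_block = rng.beta(a[None, :], b[None, :],
                        size=(cfg.n_pops, n_blocks))
    pk_block = np.clip(pk_block, 1e-4, 1 - 1e-4)
    return pk_block[:, blocks]  # (n_pops, n_snps)


def simulate_reference_panel(cfg: SimConfig, rng=None, variants=None, freqs=None):
    """Labelled reference genotypes: Binomial(2, p_k) draws per population.

    Returns ``(GenotypeMatrix, labels, freqs)`` where ``freqs`` is the
    (n_pops, n_snps) frequency matrix reused by the admixed cohort.
    Reference individuals carry the same block LD as the cohort (one-hot
    ancestry through the shared haplotype-copy scheme), as a real shared
    reference panel would.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if variants is None:
        variants = _variant_table(cfg, rng)
    blocks = _block_ids(cfg, variants)
    if freqs is None:
        freqs = balding_nichols_freqs(cfg, blocks, rng)
    n = cfg.n_ref_per_pop
    props = np.zeros((n * cfg.n_pops, cfg.n_pops))
    for k in range(cfg.n_pops):
        props[k * n:(k + 1) * n, k] = 1.0
    dos = simulate_admixed_cohort(freqs, props, cfg, rng, variants, blocks,
                                  sample_ids=[f"tmp{i}" for i in range(n * cfg.n_pops)]
                                  ).dosages
    labels = [POPULATIONS[k] for k in range(cfg.n_pops) for _ in range(n)]
    samples = [f"ref_{lab}_{i}" for k, lab in enumerate(POPULATIONS[: cfg.n_pops])
               for i in range(n)]
    return GenotypeMatrix(dos, samples, variants), labels, freqs


def simulate_admixed_cohort(freqs: np.ndarray, props: np.ndarray, cfg: SimConfig,
                            rng: np.random.Generator, variants: pd.DataFrame,
                            blocks: np.ndarray, sample_ids=None,
                            ld: bool = True) -> GenotypeMatrix:
    """Genotypes for samples with per-sample ancestry proportions.

    Per-variant frequency is the proportion-weighted mixture of population
    frequencies; haplotypes are drawn with block-template copying so the
    within-block dosage correlation is ``cfg.ld_r`` in expectation.
    """
    props = np.asarray(props, dtype=float)
    if np.any(props < 0) or np.any(np.abs(props.sum(axis=1) - 1) > 1e-8):
        raise ValueError("admixture proportions must be >= 0 and sum to 1")
    n = props.shape[0]
    p = props @ freqs  # (n_samples, n_snps) mixture frequency
    if not ld or cfg.ld_r == 0:
        dos = rng.binomial(2, p).astype(float)
    else:
        w = np.sqrt(cfg.ld_r)
        n_blocks = blocks.max() + 1
        dos = np.zeros((n, p.shape[1]))
        for _hap in range(2):
            u_block = rng.random((n, n_blocks))[:, blocks]
            u_fresh = rng.random(p.shape)
            copy = rng.random(p.shape) < w
            u = np.where(copy, u_block, u_fresh)
            dos += (u < p)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n)]
    return GenotypeMatrix(dos.astype(float), list(sample_ids), variants.copy())


# ---------------------------------------------------------------------------
# exposure


def simulate_exposure(G: GenotypeMatrix, truth: SyntheticTruth, cfg: SimConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Binary exposure from a logistic model on planted SNP dosages.

    The intercept is tuned numerically so the expected prevalence matches
    ``cfg.exposure_prevalence``.
    """
    eta = np.zeros(G.n_samples)
    if truth.exposure_snp_effects:
        idx = {v: i for i, v in enumerate(G.variants["id"])}
        for v, eff in truth.exposure_snp_effects.items():
            d = G.dosages[:, idx[v]]
            d = np.where(np.isnan(d), np.nanmean(d), d)
            eta += eff * d

    def mean_prev(c):
        return expit(c + eta).mean() - cfg.exposure_prevalence

    intercept = brentq(mean_prev, -30.0, 30.0)
    return (rng.random(G.n_samples) < expit(intercept + eta)).astype(int)


# ---------------------------------------------------------------------------
# methylome


def _cpg_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chrom, cfg.n_cpgs // cfg.n_chrom)
    per_chrom[: cfg.n_cpgs % cfg.n_chrom] += 1
    rows, i = [], 0
    for c in range(cfg.n_chrom):
        pos = np.sort(rng.choice(cfg.chrom_length, size=per_chrom[c], replace=False)) + 1
        for p in pos:
            rows.append({"id": f"cg{i:05d}", "chrom": f"chr{c + 1}", "pos": int(p)})
            i += 1
    return pd.DataFrame(rows)


def simulate_methylome(G: GenotypeMatrix, y: np.ndarray, truth: SyntheticTruth,
                       cfg: SimConfig, rng: np.random.Generator,
                       cpgs: pd.DataFrame, covariates: pd.DataFrame):
    """M-value matrices for both array cohorts plus nuisance structure.

    M = cell-mixture term + cis SNP effects + exposure effects + small
    covariate effects + cohort batch shift + technical factor + hidden
    batch factors + noise. The technical factor also drives the control
    probes (so control-probe PCs can recover it); the hidden factors do
    not, leaving them for the stage-1 residual PCs. Returns a dict with per-cohort methylation,
    control-probe and detection-p matrices, the cell-reference profile
    matrix and the true cell proportions.
    """
    n, n_cpgs = G.n_samples, len(cpgs)
    baseline_beta = rng.uniform(0.1, 0.9, size=n_cpgs)
    baseline = np.log2(baseline_beta / (1 - baseline_beta))

    # cell profiles: distinct at the designated reference CpGs, mild elsewhere
    delta = rng.normal(0, cfg.cell_profile_bg_sd, size=(n_cpgs, cfg.n_cell_types))
    ref_idx = np.arange(cfg.n_cell_ref_cpgs)
    delta[ref_idx] = rng.normal(0, cfg.cell_profile_sd,
                                size=(cfg.n_cell_ref_cpgs, cfg.n_cell_types))
    profiles = baseline[:, None] + delta
    w = rng.dirichlet(cfg.cell_alpha, size=n)  # true proportions
    M = w @ profiles.T

    cpg_idx = {c: j for j, c in enumerate(cpgs["id"])}
    var_idx = {v: i for i, v in enumerate(G.variants["id"])}
    for (v, c), beta in truth.meqtl_effects.items():
        d = G.dosages[:, var_idx[v]]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        M[:, cpg_idx[c]] += beta * d
    for c, alpha in truth.exposure_cpg_effects.items():
        M[:, cpg_idx[c]] += alpha * y

    # mild covariate structure (age, tobacco) on a fraction of CpGs
    n_cov_cpg = int(cfg.covariate_cpg_fraction * n_cpgs)
    if n_cov_cpg:
        age = (covariates["age"].to_numpy() - covariates["age"].mean())
        tob = covariates["tobacco"].to_numpy().astype(float)
        tgt = rng.choice(n_cpgs, size=n_cov_cpg, replace=False)
        M[:, tgt[: n_cov_cpg // 2]] += np.outer(age, rng.normal(0, 0.02, n_cov_cpg // 2))
        M[:, tgt[n_cov_cpg // 2:]] += np.outer(tob, rng.normal(0, 0.3,
                                                               n_cov_cpg - n_cov_cpg // 2))

    tech = rng.normal(0, 1, size=n)  # per-sample technical factor
    load = rng.normal(0, cfg.technical_loading_sd, size=n_cpgs)
    M += np.outer(tech, load)

    # hidden batch factors (plate/chip-like structure): drive the methylome
    # but NOT the control probes, so only the stage-1 residual PCs can
    # capture them - the reason that stage exists
    if cfg.n_hidden_factors:
        hidden = rng.normal(0, 1, size=(n, cfg.n_hidden_factors))
        hload = rng.normal(0, cfg.hidden_loading_sd,
                           size=(n_cpgs, cfg.n_hidden_factors))
        M += hidden @ hload.T

    out = {"cell_reference": pd.DataFrame(profiles[ref_idx],
                                          index=cpgs["id"].iloc[ref_idx],
                                          columns=CELL_TYPES[: cfg.n_cell_types]),
           "cell_proportions": pd.DataFrame(w, index=covariates["sample"],
                                            columns=CELL_TYPES[: cfg.n_cell_types]),
           "methylation": {}, "control": {}, "detection_p": {}}

    cohort_of = covariates["cohort"].to_numpy()
    for cohort in ("450K", "EPIC"):
        rows = np.flatnonzero(cohort_of == cohort)
        batch = rng.normal(0, cfg.batch_shift_sd, size=n_cpgs)
        Mc = M[rows] + batch[None, :] + rng.normal(0, cfg.noise_sd,
                                                   size=(len(rows), n_cpgs))
        samples = covariates["sample"].iloc[rows].tolist()
        out["methylation"][cohort] = MethylationMatrix(Mc, samples, cpgs.copy(), cohort)
        ctrl = (np.outer(tech[rows], rng.normal(1.0, 0.3, cfg.n_control_probes))
                + rng.normal(0, 0.2, size=(len(rows), cfg.n_control_probes)))
        out["control"][cohort] = pd.DataFrame(
            ctrl, index=samples,
            columns=[f"ctrl{j:03d}" for j in range(cfg.n_control_probes)])
        det = np.full((len(rows), n_cpgs), 1e-20)
        out["detection_p"][cohort] = pd.DataFrame(det, index=samples,
                                                  columns=cpgs["id"])
    return out


# ---------------------------------------------------------------------------
# outcome GWAS and catalog


def simulate_outcome_gwas(freqs: np.ndarray, props_sampler, truth: SyntheticTruth,
                          cfg: SimConfig, rng: np.random.Generator,
                          variants: pd.DataFrame, blocks: np.ndarray,
                          trait: str) -> pd.DataFrame:
    """Summary statistics from a fresh outcome cohort (two-sample design).

    outcome = gamma * exposure + direct pleiotropic effects + N(0, 1);
    each variant is summarised by its marginal OLS slope and SE.
    """
    n = cfg.outcome_gwas_n
    props = props_sampler(n, rng)
    G = simulate_admixed_cohort(freqs, props, cfg, rng, variants, blocks,
                                sample_ids=[f"out{i}" for i in range(n)])
    y = simulate_exposure(G, truth, cfg, rng)
    gamma = truth.causal_gamma.get(trait, 0.0)
    outcome = gamma * y + rng.normal(0, 1, size=n)
    for v, eff in truth.pleiotropic_variants.get(trait, {}).items():
        i = G.variants.index[G.variants["id"] == v][0]
        outcome += eff * G.dosages[:, i]

    X = G.dosages
    xc = X - X.mean(axis=0)
    yc = outcome - outcome.mean()
    sxx = (xc ** 2).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = (xc * yc[:, None]).sum(axis=0) / sxx
    resid_var = ((yc ** 2).sum() - beta ** 2 * sxx) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    from scipy import stats
    p = 2 * stats.t.sf(np.abs(beta / se), df=n - 2)
    return pd.DataFrame({
        "variant": G.variants["id"], "effect_allele": G.variants["alt"],
        "other_allele": G.variants["ref"], "beta": beta, "se": se, "p": p,
        "n": n,
    })


def simulate_catalog(truth: SyntheticTruth, cfg: SimConfig, rng: np.random.Generator,
                     meqtl_variants: list, universe: list,
                     enrichment_factor: float | None = None) -> pd.DataFrame:
    """GWAS-catalog-style table with planted trait enrichment.

    Enriched traits draw their risk variants from the true-meQTL set at
    ``enrichment_factor`` times the background rate; null traits draw
    uniformly from the variant universe. Enriched-trait rows get very small
    p-values (so they also surface in the PheWAS screen); null-trait rows
    get p-values spread over (1e-7, 0.05).
    """
    if enrichment_factor is None:
        enrichment_factor = cfg.enrichment_factor
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    universe = list(universe)
    meqtl_set = [v for v in meqtl_variants if v in set(universe)]
    T, Mn, R = len(universe), len(meqtl_set), cfg.risk_variants_per_trait
    rows = []
    domains = ["cardiovascular", "psychiatric", "metabolic", "immunological",
               "skeletal", "nutritional"]

    non_meqtl = [v for v in universe if v not in set(meqtl_set)]

    def pick_risk(enrich):
        if enrich == 1.0:
            # uniform draw from the universe: overlap is exactly hypergeometric
            return list(rng.choice(universe, size=R, replace=False))
        n_from_meqtl = min(Mn, R, rng.binomial(R, min(1.0, enrich * Mn / T)))
        chosen = list(rng.choice(meqtl_set, size=n_from_meqtl, replace=False))
        chosen += list(rng.choice(non_meqtl, size=R - n_from_meqtl, replace=False))
        return chosen

    for t in range(cfg.n_enriched_traits):
        trait = truth.enriched_traits[t] if t < len(truth.enriched_traits) \
            else f"enriched_trait_{t}"
        for v in pick_risk(enrichment_factor):
            rows.append({"variant": v, "trait": trait,
                         "domain": domains[t % len(domains)],
                         "p": 10 ** rng.uniform(-15, -9),
                         "study": f"study_enr_{t}"})
    for t in range(cfg.n_null_traits):
        for v in pick_risk(1.0):
            rows.append({"variant": v, "trait": f"null_trait_{t}",
                         "domain": domains[(t + 3) % len(domains)],
                         "p": 10 ** rng.uniform(-7, np.log10(0.05)),
                         "study": f"study_null_{t}"})
    return pd.DataFrame(rows, columns=["variant", "trait", "domain", "p", "study"])


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class SyntheticBundle:
    cfg: SimConfig
    variants: pd.DataFrame
    blocks: np.ndarray
    freqs: np.ndarray
    reference: GenotypeMatrix
    ref_labels: list
    cohort: GenotypeMatrix
    covariates: pd.DataFrame
    exposure: np.ndarray
    methylome: dict
    outcome_gwas: dict
    catalog: pd.DataFrame
    genes: pd.DataFrame
    truth: SyntheticTruth


def _cohort_props(n: int, cfg: SimConfig, rng: np.random.Generator):
    """Mostly AFR-dominant cohort with an admixed minority."""
    props = np.zeros((n, cfg.n_pops))
    admixed = rng.random(n) < cfg.admixed_fraction
    # non-admixed members are near-pure (a few percent residual ancestry);
    # the admixed minority has substantial multi-population composition
    q_main = 1.0 - 0.04 * rng.beta(1.0, 3.0, size=n)
    for i in range(n):
        if admixed[i]:
            props[i] = rng.dirichlet([2.0, 2.0, 1.0, 1.0][: cfg.n_pops])
        else:
            props[i, 0] = q_main[i]
            rest = rng.dirichlet(np.ones(cfg.n_pops - 1)) * (1 - q_main[i])
            props[i, 1:] = rest
    labels = ["ADMIXED" if a else "AFR" for a in admixed]
    return props, labels


def _gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    per_chrom = cfg.n_genes // cfg.n_chrom
    g = 0
    for c in range(cfg.n_chrom):
        starts = np.sort(rng.choice(cfg.chrom_length - 60_000, size=per_chrom,
                                    replace=False)) + 1
        for s in starts:
            length = int(rng.integers(5_000, 50_000))
            rows.append({"chrom": f"chr{c + 1}", "start": int(s),
                         "end": int(s + length), "name": f"GENE{g:03d}"})
            g += 1
    return pd.DataFrame(rows)


def simulate_bundle(cfg: SimConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Generate the complete input bundle with recorded ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    variants = _variant_table(cfg, rng)
    blocks = _block_ids(cfg, variants)
    freqs = balding_nichols_freqs(cfg, blocks, rng)
    reference, ref_labels, _ = simulate_reference_panel(cfg, rng, variants, freqs)

    n_cohort = cfg.n_450k + cfg.n_epic
    props, anc_labels = _cohort_props(n_cohort, cfg, rng)
    cohort = simulate_admixed_cohort(freqs, props, cfg, rng, variants, blocks,
                                     sample_ids=[f"s{i:04d}" for i in range(n_cohort)])

    cpgs = _cpg_table(cfg, rng)
    truth = SyntheticTruth(ancestry_labels=anc_labels)
    truth.ld_block_of = dict(zip(variants["id"], (f"b{b}" for b in blocks)))

    # plant exposure-associated CpGs; a subset also carries a cis meQTL,
    # placed on distinct LD blocks so clump indices are interpretable
    exp_cpgs = rng.choice(cfg.n_cpgs, size=cfg.n_true_exposure_cpgs, replace=False)
    for j in exp_cpgs:
        truth.exposure_cpg_effects[cpgs["id"].iloc[j]] = cfg.exposure_cpg_effect
    used_blocks: set = set()
    meqtl_variants = []
    for j in exp_cpgs:
        if len(meqtl_variants) >= cfg.n_true_meqtls:
            break
        chrom, pos = cpgs["chrom"].iloc[j], cpgs["pos"].iloc[j]
        cand = variants.index[(variants["chrom"] == chrom)
                              & (np.abs(variants["pos"] - pos) <= cfg.cis_window)]
        # plant only on variants common in the (AFR-dominant) study
        # population, so the planted truth survives MAF/HWE QC
        cand = [i for i in cand if blocks[i] not in used_blocks
                and 0.1 <= freqs[0, i] <= 0.9]
        if not cand:
            continue
        i = int(rng.choice(cand))
        used_blocks.add(blocks[i])
        v, c = variants["id"].iloc[i], cpgs["id"].iloc[j]
        truth.meqtl_effects[(v, c)] = cfg.meqtl_effect
        meqtl_variants.append(v)

    for v in meqtl_variants[: cfg.n_exposure_snps]:
        truth.exposure_snp_effects[v] = cfg.exposure_snp_logodds

    exposure = simulate_exposure(cohort, truth, cfg, rng)

    n = n_cohort
    covariates = pd.DataFrame({
        "sample": cohort.samples,
        "cohort": ["450K"] * cfg.n_450k + ["EPIC"] * cfg.n_epic,
        "exposure": exposure,
        "age": np.round(rng.normal(49.0, 7.0, n), 1),
        "tobacco": (rng.random(n) < (0.45 + 0.35 * exposure)).astype(int),
        "alcohol": (rng.random(n) < (0.33 + 0.18 * exposure)).astype(int),
        "log10_viral_load": np.round(rng.normal(2.5, 1.35, n), 3),
        "adherence": (rng.random(n) < 0.76).astype(int),
        "wbc": np.round(rng.normal(5.8, 1.5, n), 2),
    })

    meth = simulate_methylome(cohort, exposure, truth, cfg, rng, cpgs, covariates)
    truth.cell_proportions = meth["cell_proportions"]

    truth.enriched_traits = ["hypertension", "neuroticism", "eosinophil count"][
        : cfg.n_enriched_traits]
    truth.causal_gamma = {t: cfg.causal_gamma for t in truth.enriched_traits}
    if truth.enriched_traits and meqtl_variants:
        # one trait carries a single strongly pleiotropic instrument
        outlier = meqtl_variants[0]
        truth.pleiotropic_variants = {truth.enriched_traits[-1]: {outlier: 1.0}}

    def props_sampler(m, r):
        return _cohort_props(m, cfg, r)[0]

    outcome_gwas = {
        t: simulate_outcome_gwas(freqs, props_sampler, truth, cfg, rng,
                                 variants, blocks, t)
        for t in truth.enriched_traits
    }

    # catalog risk pools come from the planted variants and their LD blocks
    planted_blocks = {truth.ld_block_of[v] for v in meqtl_variants}
    block_members = [v for v in variants["id"]
                     if truth.ld_block_of[v] in planted_blocks]
    catalog = simulate_catalog(truth, cfg, rng, block_members,
                               list(variants["id"]))

    genes = _gene_table(cfg, rng)
    return SyntheticBundle(cfg, variants, blocks, freqs, reference, ref_labels,
                           cohort, covariates, exposure, meth, outcome_gwas,
                           catalog, genes, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> Path:
    """Write every bundle artifact as plain TSV/BED/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_dosage_tsv(bundle.reference, out / "reference_genotypes.tsv")
    pd.DataFrame({"sample": bundle.reference.samples,
                  "population": bundle.ref_labels}).to_csv(
        out / "reference_labels.tsv", sep="\t", index=False)
    write_dosage_tsv(bundle.cohort, out / "cohort_genotypes.tsv")
    bundle.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    meth = bundle.methylome
    first = next(iter(meth["methylation"].values()))
    first.probes.to_csv(out / "probes.tsv", sep="\t", index=False)
    for cohort, mm in meth["methylation"].items():
        write_methylation_tsv(mm, out / f"methylation_{cohort}.tsv")
        meth["control"][cohort].rename_axis("sample").to_csv(
            out / f"control_{cohort}.tsv", sep="\t")
        meth["detection_p"][cohort].rename_axis("sample").to_csv(
            out / f"detection_{cohort}.tsv", sep="\t")
    meth["cell_reference"].rename_axis("id").to_csv(
        out / "cell_reference.tsv", sep="\t")
    for trait, df in bundle.outcome_gwas.items():
        safe = trait.replace(" ", "_")
        df.to_csv(out / f"outcome_{safe}.tsv", sep="\t", index=False)
    bundle.catalog.to_csv(out / "catalog.tsv", sep="\t", index=False)
    bed = bundle.genes.copy()
    bed["start"] -= 1  # back to BED half-open
    bed.to_csv(out / "genes.bed", sep="\t", index=False, header=False)
    bundle.truth.to_json(out / "truth.json")
    return out
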