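"""Two-sample Mendelian randomization with meQTL instruments.

Instruments are index meQTLs whose dosage associates with the binary
exposure at p < 0.05 in a *linear* regression (reproducing the common
PLINK-style linear fit on a 0/1 trait; the caveat is documented rather
than idealised away). Exposure-side and outcome-side effects are
harmonized to a shared effect allele (sign flips on allele swaps;
strand-ambiguous A/T and C/G variants dropped), then three estimators are
applied:

* IVW - fixed-effect inverse-variance-weighted regression of outcome betas
  on exposure betas through the origin, weights 1/se_out^2;
* weighted median - the interpolated weighted median of per-variant Wald
  ratios (weights bx^2/se_out^2), robust to <50% invalid weight, SE by
  parametric bootstrap;
* MR-PRESSO - simulation-based global heterogeneity test on leave-one-out
  weighted residuals, per-variant outlier test (Bonferroni across
  variants), and IVW re-estimation after outlier removal.

Family-wise significance uses alpha / (n trait-study pairs x 3 methods).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

logger = logging.getLogger("meqtlkit")

__all__ = [
    "select_ivs",
    "harmonize",
    "mr_ivw",
    "mr_weighted_median",
    "mr_presso",
    "correct_mr",
    "MRModel",
    "MRResults",
]

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def select_ivs(meqtls: pd.DataFrame, G: GenotypeMatrix, y: np.ndarray,
               p_max: float = 0.05, index_only: bool = True) -> pd.DataFrame:
    """Instrument selection: exposure-associated meQTLs.

    The 0/1 exposure is regressed linearly on each candidate variant's
    dosage (slope = exposure effect per effect-allele copy); variants
    with p < ``p_max`` are retained. ``index_only`` keeps one variant per
    clump (the index meQTLs) so instruments are LD-independent.
    """
    if not (0 < p_max <= 1):
        raise ValueError("p_max must lie in (0, 1]")
    rec = meqtls
    if index_only and "is_index" in rec:
        rec = rec.loc[rec["is_index"]]
    variants = rec["variant"].unique()
    var_i = {v: i for i, v in enumerate(G.variants["id"])}
    y = np.asarray(y, dtype=float)
    n = len(y)
    rows = []
    yc = y - y.mean()
    syy = (yc ** 2).sum()
    for v in variants:
        d = G.dosages[:, var_i[v]]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        xc = d - d.mean()
        sxx = (xc ** 2).sum()
        if sxx == 0:
            continue
        beta = (xc * yc).sum() / sxx
        rss = syy - beta ** 2 * sxx
        se = np.sqrt(max(rss, 0.0) / (n - 2) / sxx)
        p = 2 * stats.t.sf(abs(beta / se), df=n - 2)
        rows.append({"variant": v, "beta_exposure": beta, "se_exposure": se,
                     "p_exposure": p})
    out = pd.DataFrame(rows)
    out = out.loc[out["p_exposure"] < p_max].reset_index(drop=True)
    if out.empty:
        raise ValueError("no instruments: no variant associates with the "
                         f"exposure at p < {p_max}")
    vmeta = G.variants.set_index("id")
    out["effect_allele"] = vmeta.loc[out["variant"], "alt"].to_numpy()
    out["other_allele"] = vmeta.loc[out["variant"], "ref"].to_numpy()
    logger.info("select_ivs: %d of %d candidate variants retained (p<%g)",
                len(out), len(variants), p_max)
    return out


def harmonize(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    When the outcome row's effect allele equals the exposure's other
    allele (and vice versa) the outcome beta's sign is flipped and the
    alleles swapped. Strand-ambiguous (A/T, C/G) variants are dropped with
    a ``palindromic`` flag; rows with irreconcilable alleles are dropped
    as ``mismatch``. Zero overlapping variants is an error.
    """
    exp = exposure_stats.set_index("variant")
    out = outcome_stats.set_index("variant")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise ValueError("no overlapping variants to harmonize")
    rows = []
    for v in shared:
        ea_x, oa_x = exp.loc[v, "effect_allele"], exp.loc[v, "other_allele"]
        ea_y, oa_y = out.loc[v, "effect_allele"], out.loc[v, "other_allele"]
        if (str(ea_x).upper(), str(oa_x).upper()) in _PALINDROMIC:
            rows.append({"variant": v, "status": "palindromic"})
            continue
        by = float(out.loc[v, "beta"])
        if (ea_y, oa_y) == (ea_x, oa_x):
            status = "aligned"
        elif (ea_y, oa_y) == (oa_x, ea_x):
            by, status = -by, "flipped"
        else:
            rows.append({"variant": v, "status": "mismatch"})
            continue
        rows.append({
            "variant": v, "status": status,
            "beta_exposure": float(exp.loc[v, "beta_exposure"]),
            "se_exposure": float(exp.loc[v, "se_exposure"]),
            "beta_outcome": by, "se_outcome": float(out.loc[v, "se"]),
        })
    df = pd.DataFrame(rows)
    kept = df.loc[df["status"].isin(["aligned", "flipped"])].reset_index(drop=True)
    dropped = len(df) - len(kept)
    if dropped:
        logger.info("harmonize: dropped %d variants (%s)", dropped,
                    df.loc[~df["status"].isin(['aligned', 'flipped']),
                           "status"].value_counts().to_dict())
    return kept


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    p: float
    n_iv: int
    outliers: list = field(default_factory=list)
    global_p: float | None = None
    significant: bool | None = None


def mr_ivw(data: pd.DataFrame) -> MRResult:
    """Fixed-effect IVW estimate: weighted no-intercept regression.

    estimate = sum(w bx by) / sum(w bx^2), se = 1/sqrt(sum(w bx^2)) with
    w = 1/se_out^2; two-sided normal p.
    """
    bx = data["beta_exposure"].to_numpy(dtype=float)
    by = data["beta_outcome"].to_numpy(dtype=float)
    w = 1.0 / data["se_outcome"].to_numpy(dtype=float) ** 2
    swx2 = (w * bx ** 2).sum()
    if swx2 == 0:
        raise ValueError("all exposure betas are zero")
    est = (w * bx * by).sum() / swx2
    se = 1.0 / np.sqrt(swx2)
    p = 2 * stats.norm.sf(abs(est / se))
    return MRResult("IVW", float(est), float(se), float(max(p, np.finfo(float).tiny)),
                    len(bx))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (cumulative weight crossing 0.5)."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, r))


def mr_weighted_median(data: pd.DataFrame, n_boot: int = 1000,
                       seed: int = 0) -> MRResult:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Per-variant Wald ratios by/bx are weighted by bx^2/se_out^2 (the
    inverse variance of the ratio under leading-order error in by).
    """
    if len(data) < 3:
        raise ValueError("weighted median needs >= 3 variants")
    if n_boot < 100:
        logger.warning("mr_weighted_median: n_boot=%d is small; SE unstable", n_boot)
    bx = data["beta_exposure"].to_numpy(dtype=float)
    by = data["beta_outcome"].to_numpy(dtype=float)
    sx = data["se_exposure"].to_numpy(dtype=float)
    sy = data["se_outcome"].to_numpy(dtype=float)
    est = _weighted_median(by / bx, bx ** 2 / sy ** 2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        boots[b] = _weighted_median(bys / bxs, bxs ** 2 / sy ** 2)
    se = float(boots.std(ddof=1))
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    return MRResult("WM", float(est), se, float(max(p, np.finfo(float).tiny)),
                    len(bx))


def _loo_ivw(bx, by, w):
    """Leave-one-out IVW estimates for every variant, via sum subtraction."""
    num, den = (w * bx * by).sum(), (w * bx ** 2).sum()
    return (num - w * bx * by) / (den - w * bx ** 2)


def mr_presso(data: pd.DataFrame, n_sim: int = 1000, sig: float = 0.05,
              seed: int = 0) -> MRResult:
    """MR-PRESSO: global heterogeneity test, outlier flagging, re-estimate.

    Observed RSS is the sum of weighted squared leave-one-out residuals
    (by_i minus its LOO-IVW prediction). The null distribution comes from
    simulating by* ~ N(LOO prediction, se_out) and recomputing the RSS;
    global p is the empirical exceedance. Per-variant outlier p-values are
    the exceedance of each observed weighted residual-squared within its
    simulated distribution, Bonferroni-corrected across variants. The
    reported estimate is IVW on the data with outliers removed (identical
    to :func:`mr_ivw` on the reduced set).
    """
    k = len(data)
    if k < 4:
        raise ValueError("MR-PRESSO needs >= 4 variants")
    bx = data["beta_exposure"].to_numpy(dtype=float)
    by = data["beta_outcome"].to_numpy(dtype=float)
    sx = data["se_exposure"].to_numpy(dtype=float)
    sy = data["se_outcome"].to_numpy(dtype=float)
    w = 1.0 / sy ** 2

    theta_loo = _loo_ivw(bx, by, w)
    obs_resid2 = w * (by - theta_loo * bx) ** 2
    rss_obs = obs_resid2.sum()

    rng = np.random.default_rng(seed)
    # simulate outcome betas about the LOO predictions; include exposure
    # resampling so instrument uncertainty propagates
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    w_row = w[None, :]
    num = (w_row * bx_sim * by_sim).sum(axis=1, keepdims=True)
    den = (w_row * bx_sim ** 2).sum(axis=1, keepdims=True)
    theta_sim = (num - w_row * bx_sim * by_sim) / (den - w_row * bx_sim ** 2)
    resid2_sim = w_row * (by_sim - theta_sim * bx_sim) ** 2
    rss_sim = resid2_sim.sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    outlier_p = (1 + (resid2_sim >= obs_resid2[None, :]).sum(axis=0)) / (n_sim + 1)
    outliers = np.flatnonzero(outlier_p * k < sig)
    outlier_ids = data["variant"].to_numpy()[outliers].tolist() \
        if "variant" in data else outliers.tolist()
    keep = np.setdiff1d(np.arange(k), outliers)
    if keep.size == 0:
        raise ValueError("no instruments remain after outlier removal")
    reduced = data.iloc[keep]
    base = mr_ivw(reduced)
    return MRResult("MR-PRESSO", base.estimate, base.se, base.p,
                    n_iv=len(keep), outliers=outlier_ids, global_p=global_p)


def correct_mr(results: list, n_pairs: int, n_methods: int = 3,
               alpha: float = 0.05) -> list:
    """Family-wise Bonferroni flags: p < alpha / (n_pairs * n_methods)."""
    if n_pairs < 1 or n_methods < 1:
        raise ValueError("counts must be >= 1")
    cutoff = alpha / (n_pairs * n_methods)
    for r in results:
        r.significant = r.p < cutoff
    return results


# ---------------------------------------------------------------------------
# model facade


@dataclass
class MRResults:
    table: pd.DataFrame          # trait, study, method, estimate, se, p, ...
    cutoff: float

    def summary(self) -> str:
        lines = [f"Mendelian randomization (family cutoff p < {self.cutoff:.3g})"]
        for row in self.table.itertuples():
            star = " *" if row.significant else ""
            lines.append(
                f"  {row.trait} [{row.study}] {row.method:9s} "
                f"estimate={row.estimate:+.4f} se={row.se:.4f} p={row.p:.3g}{star}")
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        t = self.table
        ypos = np.arange(len(t))[::-1]
        ax.errorbar(t["estimate"], ypos, xerr=1.96 * t["se"], fmt="o", ms=4)
        ax.axvline(0, color="grey", lw=1)
        ax.set_yticks(ypos)
        ax.set_yticklabels(t["trait"] + " / " + t["method"])
        ax.set_xlabel("causal estimate")
        return ax


class MRModel:
    """All-methods MR over one or more harmonized trait datasets.

    ``datasets`` maps (trait, study) -> harmonized :func:`harmonize` frame.
    """

    def __init__(self, datasets: dict, alpha: float = 0.05, n_boot: int = 1000,
                 n_sim: int = 1000, seed: int = 0):
        self.datasets = datasets
        self.alpha = alpha
        self.n_boot = n_boot
        self.n_sim = n_sim
        self.seed = seed

    def fit(self) -> MRResults:
        rows = []
        results = []
        for i, ((trait, study), data) in enumerate(sorted(self.datasets.items())):
            for res in (mr_ivw(data),
                        mr_weighted_median(data, self.n_boot, seed=self.seed + 7 * i),
                        mr_presso(data, self.n_sim, seed=self.seed + 7 * i + 3)):
                results.append(res)
                rows.append({"trait": trait, "study": study, "method": res.method,
                             "estimate": res.estimate, "se": res.se, "p": res.p,
                             "n_iv": res.n_iv,
                             "outliers": ";".join(map(str, res.outliers)),
                             "global_p": res.global_p})
        n_pairs = len(self.datasets)
        correct_mr(results, n_pairs, 3, self.alpha)
        table = pd.DataFrame(rows)
        table["significant"] = [r.significant for r in results]
        return MRResults(table, self.alpha / (n_pairs * 3))
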