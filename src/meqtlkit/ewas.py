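"""Exposure-associated CpG selection (two-stage EWAS with meta-analysis).

Per array cohort the model is the two-stage linear regression

    stage 1:  M ~ technical covariates        ->  top-5 residual PCs
    stage 2:  M = a0 + a1*Y + sum_i a_{i+1} C_i

where Y is the binary exposure and the covariates C comprise demographic/
clinical variables, reference-based cell-type proportions, the top 20
control-probe PCs and the 5 stage-1 residual PCs. Stage 1 deliberately
excludes the exposure so batch-capturing PCs cannot absorb signal.
Cohorts are combined by fixed-effects inverse-variance meta-analysis and
candidates are selected at meta p < 1e-4.

P-values use the t distribution with residual degrees of freedom (exact at
small n); the meta-analysis p-value is normal, as is conventional for
inverse-variance pooling of large-sample estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .io_formats import MethylationMatrix, align_samples, log_filter

logger = logging.getLogger("meqtlkit")

__all__ = [
    "filter_probes",
    "control_probe_pcs",
    "estimate_cell_proportions",
    "residual_pcs",
    "fit_ewas",
    "meta_fixed",
    "select_candidates",
    "genomic_lambda",
    "EwasModel",
    "EwasResults",
]

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.45494


def filter_probes(M: MethylationMatrix, detection_p: pd.DataFrame | None,
                  snp_positions: pd.DataFrame | None,
                  detection_p_max: float = 1e-12,
                  snp_window: int = 10) -> MethylationMatrix:
    """Probe QC: detection-p failures and SNP-proximal probes are dropped.

    A CpG is removed when any sample's detection p exceeds
    ``detection_p_max``, or when a SNP lies at the probe coordinate or
    within ``snp_window`` bp on either side (inclusive).
    """
    n_in = M.n_cpgs
    keep = np.ones(n_in, dtype=bool)
    if detection_p is not None:
        det = detection_p[M.probes["id"]].to_numpy(dtype=float)
        keep &= ~(det > detection_p_max).any(axis=0)
    if snp_positions is not None and len(snp_positions):
        for chrom, grp in M.probes.groupby("chrom"):
            sp = np.sort(snp_positions.loc[snp_positions["chrom"] == chrom,
                                           "pos"].to_numpy())
            if sp.size == 0:
                continue
            pos = grp["pos"].to_numpy()
            left = np.searchsorted(sp, pos - snp_window, side="left")
            right = np.searchsorted(sp, pos + snp_window, side="right")
            keep[grp.index.to_numpy()] &= (right - left) == 0
    out = M.subset_probes(keep)
    log_filter(f"probe_qc(det_p<={detection_p_max:g}, snp±{snp_window}bp)",
               n_in, out.n_cpgs)
    return out


def _pca_scores(X: np.ndarray, n_pc: int):
    """Column-centred PCA scores with a deterministic sign convention
    (largest-magnitude loading of each component is positive)."""
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum()) if S.size else 0
    if n_pc > rank:
        raise ValueError(f"n_pc={n_pc} exceeds matrix rank {rank}")
    for k in range(n_pc):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    return U[:, :n_pc] * S[:n_pc], S


def control_probe_pcs(control: pd.DataFrame | np.ndarray, n_pc: int = 20) -> np.ndarray:
    """Top ``n_pc`` PC scores of the samples x control-probes matrix."""
    X = control.to_numpy(dtype=float) if isinstance(control, pd.DataFrame) else np.asarray(control, float)
    scores, _ = _pca_scores(X, n_pc)
    return scores


def estimate_cell_proportions(m_sample: np.ndarray, cell_profiles: np.ndarray,
                              tol: float = 1e-10) -> np.ndarray:
    """Reference-based cell-proportion estimate (constrained projection).

    Solves ``min_w || m - P w ||^2`` subject to ``w >= 0`` and
    ``sum(w) <= 1``, where P is the CpGs x cell-types reference profile
    matrix. This is the constrained-projection form of reference-based
    deconvolution for whole-blood methylation.
    """
    P = np.asarray(cell_profiles, dtype=float)
    m = np.asarray(m_sample, dtype=float)
    k = P.shape[1]
    if np.linalg.matrix_rank(P) < k:
        raise ValueError("singular cell-reference matrix")
    PtP, Ptm = P.T @ P, P.T @ m

    def obj(w):
        return 0.5 * w @ PtP @ w - Ptm @ w

    def grad(w):
        return PtP @ w - Ptm

    res = minimize(obj, np.full(k, 1.0 / k), jac=grad, method="SLSQP",
                   bounds=[(0.0, 1.0)] * k,
                   constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                                 "jac": lambda w: -np.ones(k)}],
                   options={"maxiter": 200, "ftol": tol})
    return np.clip(res.x, 0.0, 1.0)


def _check_full_rank(X: np.ndarray, names) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0) * 1e3
    if bad.any():
        raise ValueError(f"collinear covariates: {[names[i] for i in np.flatnonzero(bad)]}")


def residual_pcs(M: MethylationMatrix | np.ndarray, covariates: pd.DataFrame,
                 n_pc: int = 5) -> np.ndarray:
    """Top PCs of the residual matrix after per-CpG OLS on covariates.

    Captures remaining batch structure orthogonal to the modelled
    technical covariates. Collinear covariates raise an error naming the
    offending columns.
    """
    Y = M.values if isinstance(M, MethylationMatrix) else np.asarray(M, float)
    X = np.column_stack([np.ones(len(Y)), covariates.to_numpy(dtype=float)])
    _check_full_rank(X, ["intercept"] + list(covariates.columns))
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    scores, _ = _pca_scores(resid, n_pc)
    return scores


def fit_ewas(M: MethylationMatrix, y: np.ndarray, covariates: pd.DataFrame,
             cohort: str | None = None) -> pd.DataFrame:
    """Per-CpG OLS of M-values on the exposure plus covariates.

    Returns one row per CpG with the exposure coefficient (alpha1), its
    SE and the two-sided t-test p-value at residual degrees of freedom.
    Complete cases only; a zero-variance exposure is an error.
    """
    y = np.asarray(y, dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("exposure has zero variance")
    C = covariates.to_numpy(dtype=float)
    ok = ~np.isnan(y)
    if C.size:
        ok &= ~np.isnan(C).any(axis=1)
    n_in = len(y)
    if ok.sum() < n_in:
        logger.info("fit_ewas: %d of %d samples are complete cases", ok.sum(), n_in)
    X = np.column_stack([np.ones(ok.sum()), y[ok]] +
                        ([C[ok]] if C.size else []))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few complete cases (n={n}) for {p} parameters")
    Y = M.values[ok]
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)                     # (p, n_cpgs)
    resid = Y - X @ B
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    alpha1 = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = alpha1 / se
    pval = 2 * stats.t.sf(np.abs(tval), df=df)
    return pd.DataFrame({
        "cpg": M.probes["id"], "chrom": M.probes["chrom"], "pos": M.probes["pos"],
        "beta": alpha1, "se": se, "p": np.clip(pval, np.finfo(float).tiny, 1.0),
        "cohort": cohort if cohort is not None else M.cohort, "n": n,
    })


def meta_fixed(r1: pd.DataFrame, r2: pd.DataFrame, key: str = "cpg") -> pd.DataFrame:
    """Fixed-effects inverse-variance meta-analysis of two cohort tables.

    ``w_i = 1/se_i^2``; ``beta = sum(w b)/sum(w)``; ``se = 1/sqrt(sum w)``;
    two-sided normal p. Tables must cover the same keys.
    """
    a = r1.set_index(key)
    b = r2.set_index(key)
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError(f"mismatched {key} ids between cohorts")
        b = b.loc[a.index]
    w1, w2 = 1.0 / a["se"] ** 2, 1.0 / b["se"] ** 2
    beta = (w1 * a["beta"] + w2 * b["beta"]) / (w1 + w2)
    se = 1.0 / np.sqrt(w1 + w2)
    z = beta / se
    out = pd.DataFrame({
        key: a.index,
        "beta": beta.to_numpy(), "se": se.to_numpy(),
        "p": np.clip(2 * stats.norm.sf(np.abs(z.to_numpy())),
                     np.finfo(float).tiny, 1.0),
        "cohort": "META",
        "n": (a["n"] + b["n"]).to_numpy() if "n" in a and "n" in b else np.nan,
    })
    for col in ("chrom", "pos"):
        if col in a:
            out[col] = a[col].to_numpy()
    return out.reset_index(drop=True)


def select_candidates(meta: pd.DataFrame, p_threshold: float = 1e-4) -> pd.DataFrame:
    """Candidate CpGs at meta p below threshold, with effect direction.

    Direction is "hyper" for a positive exposure coefficient (higher
    methylation in the exposed) and "hypo" for negative.
    """
    sel = meta.loc[meta["p"] < p_threshold].copy()
    sel["direction"] = np.where(sel["beta"] >= 0, "hyper", "hypo")
    log_filter(f"candidates(meta_p<{p_threshold:g})", len(meta), len(sel))
    return sel.reset_index(drop=True)


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median association chi^2 / null median."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


# ---------------------------------------------------------------------------
# model facade


@dataclass
class EwasResults:
    per_cohort: dict            # cohort -> per-CpG table
    meta: pd.DataFrame
    candidates: pd.DataFrame
    lambda_gc: float
    covariates: dict = field(default_factory=dict)  # cohort -> assembled design

    @property
    def n_hyper(self) -> int:
        return int((self.candidates["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.candidates["direction"] == "hypo").sum())

    def summary(self) -> str:
        lines = [
            "EWAS candidate selection (fixed-effects meta-analysis)",
            f"  CpGs tested: {len(self.meta)}",
            f"  genomic inflation lambda: {self.lambda_gc:.3f}",
            f"  candidates (meta p < threshold): {len(self.candidates)} "
            f"({self.n_hypo} hypo-, {self.n_hyper} hypermethylated)",
        ]
        return "\n".join(lines)

    def plot_qq(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        p = np.sort(self.meta["p"].to_numpy())
        exp = -np.log10((np.arange(len(p)) + 0.5) / len(p))
        ax.scatter(exp, -np.log10(p), s=4)
        lim = max(exp.max(), -np.log10(p.min()))
        ax.plot([0, lim], [0, lim], "r--", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax


class EwasModel:
    """Two-stage EWAS across two array cohorts with meta-analysis.

    Parameters
    ----------
    methylation
        dict cohort -> :class:`MethylationMatrix` (M-values, probe QC not
        yet applied).
    covariates
        sample table with columns ``sample, cohort, exposure`` plus the
        clinical covariates; sample order must match each cohort's
        methylation matrix after subsetting.
    control, detection_p
        dict cohort -> samples x probes DataFrames.
    cell_reference
        CpGs x cell-types reference profile matrix (indexed by CpG id).
    snp_positions
        variant table with ``chrom, pos`` for SNP-proximity probe removal.
    """

    CLINICAL = ["age", "tobacco", "alcohol", "log10_viral_load",
                "adherence", "wbc"]

    def __init__(self, methylation: dict, covariates: pd.DataFrame,
                 control: dict, cell_reference: pd.DataFrame,
                 snp_positions: pd.DataFrame | None = None,
                 detection_p: dict | None = None,
                 candidate_p: float = 1e-4, detection_p_max: float = 1e-12,
                 snp_window: int = 10, n_control_pcs: int = 20,
                 n_residual_pcs: int = 5):
        self.methylation = methylation
        self.covariates = covariates
        self.control = control
        self.cell_reference = cell_reference
        self.snp_positions = snp_positions
        self.detection_p = detection_p or {}
        self.candidate_p = candidate_p
        self.detection_p_max = detection_p_max
        self.snp_window = snp_window
        self.n_control_pcs = n_control_pcs
        self.n_residual_pcs = n_residual_pcs

    def _assemble(self, cohort: str, M: MethylationMatrix):
        cov = self.covariates.loc[self.covariates["cohort"] == cohort]
        align_samples(M.samples, cov["sample"], self.control[cohort].index)
        C = cov[self.CLINICAL].reset_index(drop=True).astype(float)

        # reference-based cell proportions on the overlapping reference CpGs
        ref = self.cell_reference.loc[self.cell_reference.index.isin(M.probes["id"])]
        cols = {c: j for j, c in enumerate(M.probes["id"])}
        ref_j = [cols[c] for c in ref.index]
        P = ref.to_numpy(dtype=float)
        props = np.vstack([estimate_cell_proportions(row, P)
                           for row in M.values[:, ref_j]])
        # drop the last cell type to avoid near-collinearity with the intercept
        for j, name in enumerate(ref.columns[:-1]):
            C[f"cell_{name}"] = props[:, j]

        cpcs = control_probe_pcs(self.control[cohort], self.n_control_pcs)
        for j in range(self.n_control_pcs):
            C[f"ctrlPC{j + 1}"] = cpcs[:, j]

        rpcs = residual_pcs(M, C, self.n_residual_pcs)  # stage 1: no exposure
        for j in range(self.n_residual_pcs):
            C[f"residPC{j + 1}"] = rpcs[:, j]
        return cov["exposure"].to_numpy(dtype=float), C, props

    def fit(self) -> EwasResults:
        per_cohort, designs = {}, {}
        filtered = {}
        for cohort, M in self.methylation.items():
            filtered[cohort] = filter_probes(
                M, self.detection_p.get(cohort), self.snp_positions,
                self.detection_p_max, self.snp_window)
        # analyse the probes surviving QC in every cohort
        common = set.intersection(*(set(m.probes["id"]) for m in filtered.values()))
        for cohort, M in filtered.items():
            M = M.subset_probes(list(common))
            y, C, _ = self._assemble(cohort, M)
            per_cohort[cohort] = fit_ewas(M, y, C, cohort)
            designs[cohort] = C
        cohorts = list(per_cohort)
        meta = meta_fixed(per_cohort[cohorts[0]], per_cohort[cohorts[1]]) \
            if len(cohorts) == 2 else per_cohort[cohorts[0]].assign(cohort="META")
        candidates = select_candidates(meta, self.candidate_p)
        if candidates.empty:
            logger.warning("ewas: zero candidates at meta p < %g", self.candidate_p)
        return EwasResults(per_cohort, meta, candidates,
                           genomic_lambda(meta["p"]), designs)
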