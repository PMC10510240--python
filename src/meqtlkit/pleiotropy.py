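"""Cross-trait screening of index meQTLs.

Two complementary screens:

* PheWAS lookup - for the genome-wide-significant index meQTLs
  (meta p < 5e-8), catalog associations at p < 0.05 are collected and kept
  when they pass a Bonferroni threshold of
  alpha / (n selected variants x n catalog studies); with 62 variants and
  4,756 studies this is 0.05/62/4756 = 1.70e-7.
* Trait enrichment - per trait a 2x2 table of (meQTL, risk-variant)
  membership over the tested-variant universe T, tested one-sided for
  enrichment by Fisher's exact test. The one-sided (greater) Fisher p
  equals the hypergeometric upper tail, which is how it is computed here.

Traits surfacing in both screens feed the Mendelian-randomization stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("meqtlkit")

__all__ = [
    "bonferroni_threshold",
    "fisher_one_sided",
    "phewas_lookup",
    "trait_enrichment",
    "intersect_findings",
]


def bonferroni_threshold(alpha: float = 0.05, n_variants: int = 1,
                         n_studies: int = 1) -> float:
    """Per-test threshold ``alpha / (n_variants * n_studies)``."""
    if n_variants < 1 or n_studies < 1:
        raise ValueError("counts must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / (n_variants * n_studies)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment / greater) Fisher exact p for a 2x2 table.

    Table layout: a = in both, b = row1 only, c = col1 only, d = neither.
    Equals the hypergeometric upper tail P(X >= a) with population a+b+c+d,
    successes a+b, draws a+c.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))


def phewas_lookup(index_meqtls: pd.DataFrame, catalog: pd.DataFrame,
                  gw_threshold: float = 5e-8, alpha: float = 0.05,
                  screen_p: float = 0.05) -> pd.DataFrame:
    """PheWAS over the genome-wide-significant index meQTLs.

    ``index_meqtls`` needs columns ``variant, p`` (meta p). Catalog rows at
    p < ``screen_p`` for the selected variants form the candidate hit list;
    hits passing ``alpha / (n selected x n studies in catalog)`` are
    returned with the family threshold attached.
    """
    sel = index_meqtls.loc[index_meqtls["p"] < gw_threshold, "variant"].unique()
    if len(sel) == 0:
        logger.warning("phewas_lookup: no index meQTL passes p < %g", gw_threshold)
        return pd.DataFrame(columns=["variant", "trait", "domain", "p", "study",
                                     "family_threshold", "significant"])
    n_studies = catalog["study"].nunique()
    thr = bonferroni_threshold(alpha, len(sel), n_studies)
    hits = catalog.loc[catalog["variant"].isin(sel)
                       & (catalog["p"] < screen_p)].copy()
    hits["family_threshold"] = thr
    hits["significant"] = hits["p"] < thr
    logger.info("phewas_lookup: %d selected variants, %d studies, threshold %.3g, "
                "%d candidate rows, %d significant",
                len(sel), n_studies, thr, len(hits), int(hits["significant"].sum()))
    return hits.reset_index(drop=True)


@dataclass
class TraitEnrichmentResult:
    trait: str
    T: int
    M: int
    R: int
    MR: int
    odds_ratio: float
    p_one_sided: float
    flag: str = ""


def trait_enrichment(meqtl_variants, catalog: pd.DataFrame, universe,
                     alternative: str = "greater") -> pd.DataFrame:
    """Per-trait 2x2 Fisher enrichment of meQTLs among trait risk variants.

    Universe T = all variants tested in the meQTL step; M = meQTL variants
    (meta-FDR significant); R = the trait's risk variants intersected with
    the universe; MR = their overlap. Cells are
    (MR, R-MR, M-MR, T-R-M+MR). OR = ad/bc, infinite when bc = 0; a trait
    with no in-universe risk variants is emitted with a ``no-overlap``
    flag. One-sided (greater) by default; ``alternative="two-sided"`` uses
    scipy's exact two-sided test.
    """
    universe = set(universe)
    mset = set(meqtl_variants)
    if not mset <= universe:
        raise ValueError("meqtl_variants must be a subset of the universe")
    T, M = len(universe), len(mset)
    rows = []
    for trait, grp in catalog.groupby("trait", sort=True):
        risk_all = set(grp["variant"])
        risk = risk_all & universe
        if len(risk) < len(risk_all):
            logger.info("trait %r: %d of %d risk variants outside universe",
                        trait, len(risk_all) - len(risk), len(risk_all))
        R = len(risk)
        MR = len(risk & mset)
        a, b, c, d = MR, R - MR, M - MR, T - R - M + MR
        flag = ""
        if R == 0 or M == 0 or (b + d) == 0 or (c + d) == 0:
            flag = "no-overlap" if R == 0 else "degenerate"
        if b * c == 0:
            orat = np.inf if a * d > 0 else (0.0 if a == 0 else np.nan)
        else:
            orat = (a * d) / (b * c)
        if a == 0:
            orat = 0.0 if (b * c) > 0 else np.nan
        if alternative == "greater":
            p = fisher_one_sided(a, b, c, d)
        else:
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(TraitEnrichmentResult(trait, T, M, R, MR, orat, p, flag))
    return pd.DataFrame([r.__dict__ for r in rows])


def _norm(label: str) -> str:
    return " ".join(str(label).lower().split())


def intersect_findings(phewas_traits, enrichment_traits) -> list:
    """Case/whitespace-normalised exact-label intersection of the screens.

    Returns the overlapping trait labels (original casing from the PheWAS
    list), which define the outcome set for Mendelian randomization.
    """
    enr = {_norm(t) for t in enrichment_traits}
    seen, out = set(), []
    for t in phewas_traits:
        k = _norm(t)
        if k in enr and k not in seen:
            seen.add(k)
            out.append(t)
    return out
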