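"""Readers and writers for the on-disk artifacts of the pipeline.

Conventions used throughout the package:

* Coordinates are 1-based inclusive (VCF convention). The gene-model BED
  reader converts BED's half-open 0-based intervals at the boundary.
* The effect allele is always the VCF ALT / dosage-counted allele; every
  downstream regression coefficient is per copy of that allele.
* Dosage-TSV dialect: variants as rows; leading metadata columns
  ``id``, ``chrom``, ``pos``, ``effect_allele`` (an optional ``ref`` column
  may follow); remaining columns are samples; missing dosage is ``NA``.
* Methylation matrices are stored with samples as rows and CpG probes as
  columns; betas are converted to M-values on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("meqtlkit")

__all__ = [
    "GenotypeMatrix",
    "MethylationMatrix",
    "beta_to_m",
    "m_to_beta",
    "read_genotypes",
    "write_dosage_tsv",
    "read_methylation",
    "write_methylation_tsv",
    "read_catalog",
    "read_gene_bed",
    "read_summary_stats",
    "align_samples",
    "log_filter",
]

#: clamp applied before the logit-like M transform so beta 0/1 stay finite
_BETA_EPS = 1e-6


def beta_to_m(beta):
    """M-value transform ``M = log2(beta / (1 - beta))``.

    Betas are clamped to ``[1e-6, 1 - 1e-6]`` so boundary values map to
    large finite M-values instead of +/-inf.
    """
    b = np.clip(np.asarray(beta, dtype=float), _BETA_EPS, 1.0 - _BETA_EPS)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse M transform, ``beta = 2^M / (2^M + 1)``."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def log_filter(rule: str, n_in: int, n_out: int) -> None:
    """Log a filtering step as (n_in, n_out, rule); tests assert on counts."""
    logger.info("filter %s: %d -> %d", rule, n_in, n_out)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    dosages
        float array of shape ``(n_samples, n_variants)`` with values in
        ``[0, 2]``; missing entries are ``NaN``.
    samples
        ordered sample identifiers.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` (``ref`` may be
        ``"N"`` when the source format carries only the effect allele).
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = list(self.samples)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        """Explicit sample selection (never silent reindexing)."""
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(self.dosages[rows], list(sample_ids), self.variants.copy())

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, tuple, set, pd.Index)):
            keep = self.variants["id"].isin(set(mask_or_ids)).to_numpy()
        else:
            keep = np.asarray(mask_or_ids, dtype=bool)
        return GenotypeMatrix(
            self.dosages[:, keep], self.samples, self.variants.loc[keep].reset_index(drop=True)
        )

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per variant, ignoring missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class MethylationMatrix:
    """Samples x CpGs matrix of M-values with probe coordinates.

    ``probes`` has columns ``id, chrom, pos``; ``cohort`` labels the array
    platform (e.g. ``"450K"`` or ``"EPIC"``).
    """

    values: np.ndarray
    samples: list[str]
    probes: pd.DataFrame
    cohort: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.samples = list(self.samples)
        if self.values.shape != (len(self.samples), len(self.probes)):
            raise ValueError(
                f"methylation shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.probes)} probes"
            )
        if self.probes["id"].duplicated().any():
            raise ValueError("duplicate probe id")
        self.probes = self.probes.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_cpgs(self) -> int:
        return len(self.probes)

    def subset_probes(self, mask_or_ids) -> "MethylationMatrix":
        if isinstance(mask_or_ids, (list, tuple, set, pd.Index)):
            keep = self.probes["id"].isin(set(mask_or_ids)).to_numpy()
        else:
            keep = np.asarray(mask_or_ids, dtype=bool)
        return MethylationMatrix(
            self.values[:, keep], self.samples, self.probes.loc[keep].reset_index(drop=True),
            self.cohort,
        )


def align_samples(*sample_lists) -> None:
    """Verify that all inputs share an identical ordered sample id list.

    Any mismatch is an error: the pipeline never silently reindexes.
    """
    ref = list(sample_lists[0])
    for other in sample_lists[1:]:
        if list(other) != ref:
            raise ValueError(
                "sample lists are not aligned; explicit subsetting is required "
                f"(first mismatch near index "
                f"{next((i for i, (a, b) in enumerate(zip(ref, other)) if a != b), min(len(ref), len(other)))})"
            )


# ---------------------------------------------------------------------------
# genotypes


def _read_vcf(path: str) -> GenotypeMatrix:
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # malformed header
        raise ValueError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vf.header.samples)
    rows, meta = [], []
    for rec in vf:
        alt = rec.alts[0] if rec.alts else "N"
        meta.append(
            {"id": rec.id or f"{rec.chrom}:{rec.pos}", "chrom": rec.chrom,
             "pos": rec.pos, "ref": rec.ref, "alt": alt}
        )
        dos = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            if "DS" in call and call["DS"] is not None:
                dos[i] = float(call["DS"])
            else:
                gt = call.get("GT")
                if gt is not None and None not in gt:
                    dos[i] = float(sum(1 for a in gt if a != 0))
        rows.append(dos)
    vf.close()
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, samples, variants)


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    required = ["id", "chrom", "pos", "effect_allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"malformed dosage header in {path}: missing columns {missing}")
    meta_cols = required + (["ref"] if "ref" in df.columns else [])
    sample_cols = [c for c in df.columns if c not in meta_cols]
    variants = pd.DataFrame(
        {
            "id": df["id"],
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int),
            "ref": df["ref"] if "ref" in df.columns else "N",
            "alt": df["effect_allele"],
        }
    )
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, sample_cols, variants)


def read_genotypes(path, format: str = "dosage") -> GenotypeMatrix:
    """Read a genotype dosage matrix from VCF or the dosage-TSV dialect.

    ``format`` is ``"vcf"`` or ``"dosage"``. VCF genotypes use the DS field
    when present, otherwise the ALT-allele count of GT; ``./.`` becomes a
    missing (NaN) dosage.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "id": G.variants["id"],
            "chrom": G.variants["chrom"],
            "pos": G.variants["pos"],
            "effect_allele": G.variants["alt"],
            "ref": G.variants["ref"],
        }
    )
    dos = pd.DataFrame(G.dosages.T, columns=G.samples)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# methylation


def read_methylation(path, probe_annotation, value_kind: str = "m",
                     cohort: str = "") -> MethylationMatrix:
    """Read a methylation TSV (rows = samples, header = CpG ids).

    ``probe_annotation`` is a TSV path or DataFrame with columns
    ``id, chrom, pos``. Betas (``value_kind="beta"``) must lie in [0, 1]
    and are converted to M-values; probes without coordinates are dropped
    with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if isinstance(probe_annotation, (str, bytes)) or hasattr(probe_annotation, "__fspath__"):
        ann = pd.read_csv(probe_annotation, sep="\t", dtype={"id": str, "chrom": str})
    else:
        ann = probe_annotation.copy()
    ann = ann.set_index("id")
    known = [c for c in df.columns if c in ann.index]
    dropped = [c for c in df.columns if c not in ann.index]
    if dropped:
        logger.warning("dropping %d probes without coordinates (e.g. %s)",
                       len(dropped), dropped[0])
    df = df[known]
    values = df.to_numpy(dtype=float)
    if value_kind == "beta":
        if np.nanmin(values) < 0 or np.nanmax(values) > 1:
            raise ValueError("beta values outside [0, 1]")
        values = beta_to_m(values)
    elif value_kind != "m":
        raise ValueError(f"unknown value_kind {value_kind!r}")
    probes = pd.DataFrame(
        {"id": known, "chrom": ann.loc[known, "chrom"].to_numpy(),
         "pos": ann.loc[known, "pos"].astype(int).to_numpy()}
    )
    return MethylationMatrix(values, list(df.index.astype(str)), probes, cohort)


def write_methylation_tsv(M: MethylationMatrix, path, annotation_path=None) -> None:
    pd.DataFrame(M.values, index=pd.Index(M.samples, name="sample"),
                 columns=M.probes["id"]).to_csv(path, sep="\t")
    if annotation_path is not None:
        M.probes.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# catalog, gene model, summary statistics


def read_catalog(path) -> pd.DataFrame:
    """Read a GWAS-catalog-style association TSV.

    Expected columns: ``variant, trait, p`` plus optional ``domain`` and
    ``study``. Rows whose p-value does not parse are rejected with a logged
    line number; an empty file yields an empty frame with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        logger.warning("catalog %s is empty", path)
        return pd.DataFrame(columns=["variant", "trait", "domain", "p", "study"])
    for col, default in (("domain", "unknown"), ("study", "NA")):
        if col not in df.columns:
            df[col] = default
    p = pd.to_numeric(df["p"], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1)
    for idx in df.index[bad]:
        logger.warning("catalog %s: rejected row at line %d (unparseable p=%r)",
                       path, idx + 2, df.loc[idx, "p"])
    df = df.loc[~bad].copy()
    df["p"] = p[~bad]
    return df[["variant", "trait", "domain", "p", "study"]].reset_index(drop=True)


def read_gene_bed(path) -> pd.DataFrame:
    """Read a gene-model BED and convert to 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"],
                     usecols=[0, 1, 2, 3], dtype={0: str, 3: str})
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["start"].astype(int) + 1,
         "end": df["end"].astype(int), "name": df["name"]}
    )
    if (out["end"] < out["start"]).any():
        raise ValueError("gene interval with end < start after BED conversion")
    return out


def read_summary_stats(path) -> pd.DataFrame:
    """Read an outcome-GWAS summary-statistic TSV.

    Columns: ``variant, effect_allele, other_allele, beta, se, p, n``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant": str})
    required = ["variant", "effect_allele", "other_allele", "beta", "se"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stat file {path} missing columns {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("non-positive SE in summary statistics")
    return df
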