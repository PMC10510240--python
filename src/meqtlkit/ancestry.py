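"""Genotype-based global ancestry assignment.

The procedure mirrors standard reference-panel workflows: LD-prune the
shared variant set (greedy windowed scan at r^2 <= 0.02), run PCA on the
reference panel and project the study samples, estimate K=4 supervised
admixture proportions by per-sample EM with reference allele frequencies
held fixed, flag admixed samples by their distance to reference-population
centroids on PC1-PC3, and finally classify each study sample by k=20
nearest neighbours in the joint (10 PCs + 4 proportions) feature space,
with a seeded admixed training subset.

Supervised (rather than unsupervised block-relaxation) admixture is used
because the reference panel defines the ancestral groups; per-sample EM on
the binomial admixture likelihood is deterministic and fast at this scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .io_formats import GenotypeMatrix

logger = logging.getLogger("meqtlkit")

__all__ = [
    "ld_prune",
    "genotype_pca",
    "supervised_admixture",
    "detect_admixed",
    "knn_classify",
    "AncestryModel",
    "AncestryResults",
]


def _impute_mean(dos: np.ndarray) -> np.ndarray:
    """Column-mean imputation of missing dosages (used by PCA/pruning)."""
    if not np.isnan(dos).any():
        return dos
    col_mean = np.nanmean(dos, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    out = dos.copy()
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out


def ld_prune(G: GenotypeMatrix, r2_max: float = 0.02, window: int = 50) -> list:
    """Greedy left-to-right LD pruning within sliding variant-count windows.

    A variant is dropped when its squared dosage correlation with any
    already-retained variant in the trailing window exceeds ``r2_max``.
    Monomorphic variants have undefined r^2 and are retained (treated as
    r^2 = 0). Returns the retained variant ids in input order.
    """
    if G.n_variants < 2:
        return list(G.variants["id"])
    X = _impute_mean(G.dosages)
    sd = X.std(axis=0)
    retained_idx: list[int] = []
    for j in range(G.n_variants):
        if sd[j] == 0:
            retained_idx.append(j)
            continue
        drop = False
        recent = [i for i in retained_idx if j - i <= window and sd[i] > 0]
        if recent:
            r = np.corrcoef(X[:, recent + [j]], rowvar=False)[-1, :-1]
            drop = np.any(r ** 2 > r2_max)
        if not drop:
            retained_idx.append(j)
    ids = G.variants["id"].iloc[retained_idx].tolist()
    logger.info("filter ld_prune(r2<=%g): %d -> %d", r2_max, G.n_variants, len(ids))
    return ids


def genotype_pca(G_ref: GenotypeMatrix, G_query: GenotypeMatrix | None,
                 n_pc: int = 10):
    """Reference PCA with projection of query samples onto its loadings.

    Variants are centred and scaled to unit variance using the *reference*
    mean and SD (PLINK-style per-variant scaling); missing dosages are
    mean-imputed per variant; zero-variance variants are dropped with a
    warning. Returns ``(ref_scores, query_scores, loadings)`` where scores
    are ``n x n_pc`` arrays.
    """
    if n_pc < 1:
        raise ValueError("n_pc must be >= 1")
    Xr = _impute_mean(G_ref.dosages)
    mean, sd = Xr.mean(axis=0), Xr.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("genotype_pca: dropping %d zero-variance variants",
                       int((~keep).sum()))
    Xr = (Xr[:, keep] - mean[keep]) / sd[keep]
    if n_pc > min(Xr.shape):
        raise ValueError(f"n_pc={n_pc} exceeds matrix rank bound {min(Xr.shape)}")
    U, S, Vt = np.linalg.svd(Xr, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_pc):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    loadings = Vt[:n_pc].T  # (n_variants_kept, n_pc)
    ref_scores = U[:, :n_pc] * S[:n_pc]
    query_scores = None
    if G_query is not None:
        if list(G_query.variants["id"]) != list(G_ref.variants["id"]):
            raise ValueError("query and reference must share the variant set")
        Xq = _impute_mean(G_query.dosages)
        Xq = (Xq[:, keep] - mean[keep]) / sd[keep]
        query_scores = Xq @ loadings
    return ref_scores, query_scores, loadings


def supervised_admixture(G_query: GenotypeMatrix, ref_freqs: np.ndarray,
                         max_iter: int = 1000, tol: float = 1e-6,
                         return_loglik: bool = False):
    """Per-sample admixture proportions by EM with fixed reference frequencies.

    Maximises the binomial admixture log-likelihood
    ``sum_j [ g_j log(sum_k q_k p_kj) + (2 - g_j) log(sum_k q_k (1 - p_kj)) ]``
    over the simplex. Frequencies are clamped to [1e-6, 1-1e-6]. The EM
    update is the standard ancestry-responsibility average; the likelihood
    is non-decreasing and iteration stops when the gain falls below ``tol``.
    """
    P = np.clip(np.asarray(ref_freqs, dtype=float), 1e-6, 1 - 1e-6)  # (K, J)
    K, J = P.shape
    Gd = _impute_mean(G_query.dosages)  # (N, J), values in [0, 2]
    N = Gd.shape[0]
    Q = np.full((N, K), 1.0 / K)
    prev_ll = np.full(N, -np.inf)
    converged = np.zeros(N, dtype=bool)
    ll = prev_ll
    for it in range(max_iter):
        mix_alt = Q @ P            # (N, J): allele-level ALT frequency
        mix_ref = Q @ (1.0 - P)
        ll = (Gd * np.log(mix_alt) + (2.0 - Gd) * np.log(mix_ref)).sum(axis=1)
        gain = ll - prev_ll
        converged = gain < tol
        if converged.all():
            break
        prev_ll = ll
        # responsibilities for ALT and REF allele copies, averaged over 2J
        # draws; looped over K to avoid an (N, K, J) temporary
        Qn = np.empty_like(Q)
        alt_term = Gd / mix_alt
        ref_term = (2.0 - Gd) / mix_ref
        for k in range(K):
            Qn[:, k] = Q[:, k] * (alt_term @ P[k] + ref_term @ (1.0 - P[k]))
        Q = Qn / (2.0 * J)
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)
    else:
        logger.warning("supervised_admixture: %d samples not converged after "
                       "%d iterations; returning best iterate",
                       int((~converged).sum()), max_iter)
    if return_loglik:
        return Q, ll
    return Q


def detect_admixed(query_scores: np.ndarray, ref_scores: np.ndarray,
                   ref_labels, quantile: float = 0.99) -> np.ndarray:
    """Flag query samples far from every reference-population centroid.

    Centroids are computed from labelled reference scores on PC1-PC3; a
    query sample is flagged when its minimal centroid distance exceeds the
    ``quantile`` (default 99th percentile) of within-class reference
    distances. The cutoff is data-driven rather than a fixed constant.
    """
    ref_labels = np.asarray(ref_labels)
    ref3, q3 = ref_scores[:, :3], query_scores[:, :3]
    classes = pd.unique(ref_labels)
    centroids, within = [], []
    for c in classes:
        rows = ref3[ref_labels == c]
        if len(rows) < 2:
            raise ValueError(f"reference class {c!r} has fewer than 2 samples")
        cen = rows.mean(axis=0)
        centroids.append(cen)
        within.append(np.linalg.norm(rows - cen, axis=1))
    cutoff = np.quantile(np.concatenate(within), quantile)
    d = np.linalg.norm(q3[:, None, :] - np.asarray(centroids)[None, :, :], axis=2)
    return d.min(axis=1) > cutoff


@dataclass
class AncestryCall:
    label: str
    neighbor_votes: dict


def knn_classify(query_features: np.ndarray, train_features: np.ndarray,
                 train_labels, k: int = 20) -> list:
    """Majority vote over k Euclidean nearest neighbours.

    Features are standardised to the training mean/SD. Ties are broken by
    the smallest mean neighbour distance among the tied labels
    (deterministic). Returns one :class:`AncestryCall` per query row.
    """
    train_labels = np.asarray(train_labels)
    if k > len(train_labels):
        raise ValueError(f"k={k} exceeds training size {len(train_labels)}")
    mean, sd = train_features.mean(axis=0), train_features.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xt = (train_features - mean) / sd
    Xq = (query_features - mean) / sd
    nn = NearestNeighbors(n_neighbors=k).fit(Xt)
    dist, idx = nn.kneighbors(Xq)
    calls = []
    for row_d, row_i in zip(dist, idx):
        labs = train_labels[row_i]
        votes: dict = {}
        dist_by_label: dict = {}
        for lab, d in zip(labs, row_d):
            votes[lab] = votes.get(lab, 0) + 1
            dist_by_label.setdefault(lab, []).append(d)
        top = max(votes.values())
        tied = [lab for lab, v in votes.items() if v == top]
        winner = min(tied, key=lambda lab: (np.mean(dist_by_label[lab]), lab))
        calls.append(AncestryCall(winner, votes))
    return calls


# ---------------------------------------------------------------------------
# model facade


@dataclass
class AncestryResults:
    """Per-sample ancestry table produced by :class:`AncestryModel.fit`."""

    table: pd.DataFrame  # sample, PC1..PC10, q_*, min_centroid_distance, label
    n_pruned_variants: int

    def summary(self) -> str:
        counts = self.table["label"].value_counts()
        lines = ["Ancestry assignment",
                 f"  pruned variants used: {self.n_pruned_variants}",
                 "  label counts:"]
        lines += [f"    {lab:8s} {n}" for lab, n in counts.items()]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot_pcs(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        for lab, grp in self.table.groupby("label"):
            ax.scatter(grp["PC1"], grp["PC2"], s=8, label=lab)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        return ax


class AncestryModel:
    """End-to-end ancestry assignment against a labelled reference panel.

    Parameters
    ----------
    reference, query
        genotype matrices sharing one variant set (query samples are the
        study cohort).
    ref_labels
        per-reference-sample population labels (K populations).
    """

    def __init__(self, reference: GenotypeMatrix, query: GenotypeMatrix,
                 ref_labels, prune_r2: float = 0.02, n_pc: int = 10,
                 k: int = 20, n_admixed_train: int = 20, seed: int = 0):
        self.reference = reference
        self.query = query
        self.ref_labels = list(ref_labels)
        self.prune_r2 = prune_r2
        self.n_pc = n_pc
        self.k = k
        self.n_admixed_train = n_admixed_train
        self.seed = seed

    def fit(self) -> AncestryResults:
        keep = ld_prune(self.reference, r2_max=self.prune_r2)
        ref = self.reference.subset_variants(keep)
        qry = self.query.subset_variants(keep)

        ref_scores, q_scores, _ = genotype_pca(ref, qry, n_pc=self.n_pc)

        # supervised allele frequencies from the labelled reference
        labels = np.asarray(self.ref_labels)
        pops = list(pd.unique(labels))
        freqs = np.vstack([
            np.nanmean(ref.dosages[labels == p], axis=0) / 2.0 for p in pops
        ])
        q_admix = supervised_admixture(qry, freqs)
        ref_admix = supervised_admixture(ref, freqs)

        admixed = detect_admixed(q_scores, ref_scores, labels)
        rng = np.random.default_rng(self.seed)
        adm_idx = np.flatnonzero(admixed)
        n_train = min(self.n_admixed_train, len(adm_idx))
        train_adm = rng.choice(adm_idx, size=n_train, replace=False) \
            if n_train else np.array([], dtype=int)

        feat_ref = np.hstack([ref_scores, ref_admix])
        feat_q = np.hstack([q_scores, q_admix])
        train_X = np.vstack([feat_ref, feat_q[train_adm]])
        train_y = np.concatenate([labels, np.array(["ADMIXED"] * n_train)])
        calls = knn_classify(feat_q, train_X, train_y, k=self.k)

        d = np.linalg.norm(
            q_scores[:, None, :3]
            - np.asarray([ref_scores[labels == p, :3].mean(axis=0)
                          for p in pops])[None, :, :], axis=2).min(axis=1)
        table = pd.DataFrame({"sample": self.query.samples})
        for j in range(self.n_pc):
            table[f"PC{j + 1}"] = q_scores[:, j]
        for i, p in enumerate(pops):
            table[f"q_{p}"] = q_admix[:, i]
        table["min_centroid_distance"] = d
        table["admixed_flag"] = admixed
        # distance-flagged samples form the admixed group; KNN (which can
        # itself vote ADMIXED near the boundary) maps the remaining samples
        table["label"] = np.where(admixed, "ADMIXED",
                                  [c.label for c in calls])
        return AncestryResults(table, n_pruned_variants=len(keep))
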