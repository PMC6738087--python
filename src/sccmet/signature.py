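"""Metabolic gene-signature derivation for SCC vs AdC vs normal lung.

The selection reproduces a three-criterion screen on a genes x samples cohort:

1. genes driving the separation of SCC samples on PC1 or PC3 (top loading
   quantile of a mean-centred PCA on log2 NC-median ratios),
2. genes inside hierarchical-clustering gene clusters whose SCC centroid
   exceeds both the NC and AdC centroids (Eisen defaults: uncentred
   correlation distance, average linkage),
3. genes statistically overexpressed in SCC vs NC (one-way ANOVA + Tukey HSD,
   Bonferroni-scaled across genes, adjusted p < 0.05).

The signature is the intersection.  Scoring a sample is the mean log2 ratio
over the signature genes, with an upper-tertile flag for survival-style
stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .stats import anova_tukey_bonferroni, bh_adjust

__all__ = [
    "ExpressionCohort",
    "PROCESS_CLASSES",
    "filter_metabolic_genes",
    "normalize_to_nc_median",
    "hierarchical_cluster",
    "run_pca",
    "select_signature",
    "overlap_top_genes",
    "signature_score",
    "SignatureModel",
    "SignatureResults",
]

logger = logging.getLogger(__name__)

PROCESS_CLASSES = frozenset({"sugar", "amino-acid", "nucleotide", "energy"})
TISSUES = ("NC", "AdC", "SCC")


@dataclass
class ExpressionCohort:
    """Genes x samples expression matrix with per-sample tissue labels.

    `matrix` holds strictly positive linear-scale intensities indexed by gene
    id; `metadata` is indexed by sample id with a ``tissue`` column in
    {NC, AdC, SCC} and an optional ``subject_id`` for tumour/NC pairing.
    """

    matrix: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if "tissue" not in self.metadata.columns:
            raise ValueError("metadata needs a 'tissue' column")
        if not set(self.metadata.index) >= set(self.matrix.columns):
            missing = set(self.matrix.columns) - set(self.metadata.index)
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        bad = set(self.metadata["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue classes: {sorted(bad)}")
        if (self.matrix.to_numpy() <= 0).any():
            raise ValueError("expression matrix must be strictly positive")
        self.metadata = self.metadata.loc[self.matrix.columns]

    @property
    def tissue(self) -> pd.Series:
        return self.metadata["tissue"]

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.tissue.index[self.tissue == tissue])

    def subset_genes(self, genes) -> "ExpressionCohort":
        return ExpressionCohort(self.matrix.loc[list(genes)], self.metadata)


def filter_metabolic_genes(
    cohort: ExpressionCohort, annotation: pd.DataFrame
) -> ExpressionCohort:
    """Keep genes with catalytic molecular function and >= 1 metabolic class.

    `annotation` is indexed by gene id with ``catalytic`` (bool/0-1) and
    ``classes`` (set, list, or semicolon-joined string drawn from
    ``{sugar, amino-acid, nucleotide, energy}``).  Genes absent from the
    annotation are dropped with a logged count.
    """
    ann = annotation.copy()
    covered = cohort.matrix.index.intersection(ann.index)
    dropped = len(cohort.matrix.index) - len(covered)
    if dropped:
        logger.info("filter_metabolic_genes: %d genes lack annotation", dropped)
    keep = []
    for gene in covered:
        row = ann.loc[gene]
        classes = _parse_classes(row["classes"])
        if bool(row["catalytic"]) and classes:
            keep.append(gene)
    if not keep:
        raise ValueError("no genes pass the metabolic-enzyme filter")
    return cohort.subset_genes(keep)


def _parse_classes(raw) -> frozenset:
    if isinstance(raw, str):
        items = frozenset(c.strip() for c in raw.split(";") if c.strip())
    elif raw is None or (np.isscalar(raw) and pd.isna(raw)):
        items = frozenset()
    else:
        items = frozenset(raw)
    bad = items - PROCESS_CLASSES
    if bad:
        raise ValueError(f"unknown metabolic process classes: {sorted(bad)}")
    return items


def normalize_to_nc_median(cohort: ExpressionCohort) -> pd.DataFrame:
    """Divide each gene by its median expression over NC samples.

    Genes whose NC median is zero or undefined are dropped with a warning.
    The per-gene NC median of the output is exactly 1.
    """
    nc = cohort.samples_of("NC")
    if not nc:
        raise ValueError("cohort has no NC samples to normalise against")
    med = cohort.matrix[nc].median(axis=1)
    ok = med > 0
    if (~ok).any():
        logger.warning("normalize_to_nc_median: dropping %d genes with "
                       "non-positive NC median", int((~ok).sum()))
    return cohort.matrix.loc[ok].div(med[ok], axis=0)


# ---------------------------------------------------------------------------
# clustering and PCA
# ---------------------------------------------------------------------------

def uncentered_correlation_distance(X: np.ndarray) -> np.ndarray:
    """Condensed pairwise 1 - uncentred-correlation over rows of X.

    The uncentred (cosine-about-zero) correlation is the Eisen-Cluster
    default similarity.  Zero-norm rows get similarity 0 to every other row
    (distance 1), a guard for constant-at-zero genes.
    """
    X = np.asarray(X, dtype=float)
    norms = np.sqrt((X ** 2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        logger.warning("uncentred correlation: %d zero-norm rows guarded",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    U = X / safe[:, None]
    U[zero] = 0.0
    sim = np.clip(U @ U.T, -1.0, 1.0)
    d = 1.0 - sim
    iu = np.triu_indices(len(X), k=1)
    return np.maximum(d[iu], 0.0)


@dataclass
class GeneClustering:
    linkage: np.ndarray
    labels: pd.Series        # gene -> flat cluster id (1..k)
    k: int


def hierarchical_cluster(
    log_ratios: pd.DataFrame, k: int = 8
) -> GeneClustering:
    """Average-linkage gene clustering on uncentred-correlation distance."""
    if len(log_ratios) < 2:
        raise ValueError("need at least 2 genes to cluster")
    dist = uncentered_correlation_distance(log_ratios.to_numpy())
    Z = sch.linkage(dist, method="average")
    flat = sch.fcluster(Z, t=min(k, len(log_ratios)), criterion="maxclust")
    return GeneClustering(
        linkage=Z, labels=pd.Series(flat, index=log_ratios.index), k=k
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame     # samples x components
    loadings: pd.DataFrame   # genes x components, unit-norm columns
    r2x: np.ndarray          # fraction of total variance per component


def run_pca(log_ratios: pd.DataFrame, n_components: int | None = None
            ) -> PCAResult:
    """Mean-centred PCA of samples over genes (SVD; components truncated to
    matrix rank)."""
    if log_ratios.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    # samples are observations, genes are variables
    X = log_ratios.to_numpy().T
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    ncomp = rank if n_components is None else min(n_components, rank)
    total_var = float((s ** 2).sum())
    r2x = (s[:ncomp] ** 2) / total_var if total_var > 0 else np.zeros(ncomp)
    comp_names = [f"PC{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame(U[:, :ncomp] * s[:ncomp], index=log_ratios.columns,
                          columns=comp_names)
    loadings = pd.DataFrame(Vt[:ncomp].T, index=log_ratios.index,
                            columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, r2x=r2x)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class SignatureResult:
    """Selected genes with per-criterion flags and statistics."""

    genes: list[str]
    flags: pd.DataFrame      # columns criterion1..3 (bool), cluster, loadings, adj p
    thresholds: dict = field(default_factory=dict)


def select_signature(
    pca: PCAResult,
    clustering: GeneClustering,
    log_ratios: pd.DataFrame,
    tissue: pd.Series,
    loading_quantile: float = 0.25,
    components: tuple[str, str] = ("PC1", "PC3"),
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> SignatureResult:
    """Intersect the three selection criteria on a common gene set.

    criterion1: |loading| in the top `loading_quantile` on either component.
    criterion2: member of a flat cluster whose SCC centroid exceeds both the
    NC and the AdC centroid (centroid = mean log2 ratio over cluster genes
    within a tissue group).
    criterion3: Tukey SCC-vs-NC p, Bonferroni-scaled by the number of genes
    (or BH-adjusted with ``adjust="bh"``), below `alpha`.
    """
    genes = log_ratios.index
    if not (genes.equals(pca.loadings.index)
            and genes.equals(clustering.labels.index)):
        raise ValueError("pca, clustering and ratio matrix must share genes")

    comps = [c for c in components if c in pca.loadings.columns]
    crit1 = pd.Series(False, index=genes)
    for c in comps:
        absload = pca.loadings[c].abs()
        thr = absload.quantile(1.0 - loading_quantile)
        crit1 |= absload >= thr

    centroids = {}
    for cl in sorted(clustering.labels.unique()):
        members = clustering.labels.index[clustering.labels == cl]
        sub = log_ratios.loc[members]
        centroids[cl] = {
            t: float(sub[tissue.index[tissue == t]].to_numpy().mean())
            for t in TISSUES
        }
    up_clusters = {
        cl for cl, c in centroids.items()
        if c["SCC"] > c["NC"] and c["SCC"] > c["AdC"]
    }
    if not up_clusters:
        logger.warning("select_signature: no cluster has an SCC-dominant "
                       "centroid; criterion2 set is empty")
    crit2 = clustering.labels.isin(up_clusters)

    values = log_ratios.to_numpy()
    groups_idx = {t: np.flatnonzero((tissue.loc[log_ratios.columns] == t)
                                    .to_numpy()) for t in TISSUES}
    raw_p = _tukey_scc_nc_pvalues(values, groups_idx)
    if adjust == "bonferroni":
        adj_p = np.minimum(raw_p * len(genes), 1.0)
    elif adjust == "bh":
        adj_p = bh_adjust(raw_p)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    scc_mean = log_ratios[tissue.index[tissue == "SCC"]].mean(axis=1)
    nc_mean = log_ratios[tissue.index[tissue == "NC"]].mean(axis=1)
    crit3 = pd.Series((adj_p < alpha), index=genes) & (scc_mean > nc_mean)

    flags = pd.DataFrame({
        "criterion1": crit1, "criterion2": crit2, "criterion3": crit3,
        "cluster": clustering.labels,
        "p_scc_vs_nc_adj": adj_p,
    })
    for c in comps:
        flags[f"loading_{c}"] = pca.loadings[c]
    selected = list(genes[(crit1 & crit2 & crit3).to_numpy()])
    return SignatureResult(
        genes=selected,
        flags=flags,
        thresholds={
            "loading_quantile": loading_quantile,
            "components": list(comps),
            "alpha": alpha, "adjust": adjust, "cluster_k": clustering.k,
        },
    )


def _tukey_scc_nc_pvalues(
    values: np.ndarray, groups_idx: dict[str, np.ndarray]
) -> np.ndarray:
    """Vectorised Tukey HSD SCC-vs-NC p values over all gene rows.

    Identical to calling :func:`sccmet.stats.anova_tukey_bonferroni` per gene
    and reading the (NC, SCC) comparison (the agreement is asserted in the
    test suite); one batched studentized-range call keeps large cohorts fast.
    """
    import scipy.stats as sps

    k = len(groups_idx)
    n_total = sum(idx.size for idx in groups_idx.values())
    df_within = n_total - k
    sse = np.zeros(values.shape[0])
    for idx in groups_idx.values():
        sub = values[:, idx]
        sse += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    mse = sse / df_within
    nc, scc = groups_idx["NC"], groups_idx["SCC"]
    diff = np.abs(values[:, scc].mean(axis=1) - values[:, nc].mean(axis=1))
    denom = np.sqrt(mse / 2.0 * (1.0 / nc.size + 1.0 / scc.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(denom > 0, diff / denom, np.inf)
        q = np.where((denom == 0) & (diff == 0), 0.0, q)
    p = np.ones_like(q)
    finite = np.isfinite(q)
    p[finite] = sps.studentized_range.sf(q[finite], k, df_within)
    p[~finite] = 0.0
    return np.clip(p, 0.0, 1.0)


def overlap_top_genes(
    ranked_lists: list[list[str]],
    top_frac: float = 0.05,
    min_lists: int = 3,
) -> set[str]:
    """Genes in the top `top_frac` head of at least `min_lists` ranked lists."""
    if len(ranked_lists) < min_lists:
        raise ValueError(
            f"need >= {min_lists} lists, got {len(ranked_lists)}"
        )
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    counts: dict[str, int] = {}
    for ranked in ranked_lists:
        head = ranked[: max(1, int(round(top_frac * len(ranked))))]
        for g in set(head):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_lists}


def signature_score(
    ratios: pd.DataFrame,
    signature_genes: list[str],
    tertile_pct: float = 67.0,
) -> pd.DataFrame:
    """Mean log2 ratio over signature genes, with an upper-tertile flag.

    The flag marks samples at or above the `tertile_pct` percentile of the
    score distribution (midpoint interpolation, so n = 9 flags exactly 3).
    `ratios` is the NC-median ratio matrix on the linear scale.
    """
    present = [g for g in signature_genes if g in ratios.index]
    if not present:
        raise ValueError("none of the signature genes are in the matrix")
    scores = np.log2(ratios.loc[present]).mean(axis=0)
    cut = np.percentile(scores.to_numpy(), tertile_pct, method="midpoint")
    return pd.DataFrame({
        "score": scores,
        "upper_tertile": scores >= cut,
    })


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------

@dataclass
class SignatureResults:
    """Fitted signature-derivation results."""

    selection: SignatureResult
    ratios: pd.DataFrame          # linear NC-median ratios
    log_ratios: pd.DataFrame
    pca: PCAResult
    clustering: GeneClustering
    scores: pd.DataFrame
    n_genes_filtered: int

    @property
    def genes(self) -> list[str]:
        return self.selection.genes

    def summary(self) -> str:
        r2 = ", ".join(
            f"R2X[{i + 1}]={v * 100:.1f}%" for i, v in
            enumerate(self.pca.r2x[:3])
        )
        f = self.selection.flags
        lines = [
            "Metabolic gene-signature selection",
            "=" * 45,
            f"genes after enzyme filter: {self.n_genes_filtered}",
            f"PCA: {r2}",
            f"criterion1 (loadings):  {int(f['criterion1'].sum())}",
            f"criterion2 (clusters):  {int(f['criterion2'].sum())}",
            f"criterion3 (Tukey+adj): {int(f['criterion3'].sum())}",
            f"selected (intersection): {len(self.genes)}",
            "-" * 45,
            ", ".join(self.genes) if self.genes else "(none)",
        ]
        return "\n".join(lines)


class SignatureModel:
    """End-to-end signature derivation on one cohort.

    Pipeline: enzyme filter -> NC-median normalisation -> log2 ->
    hierarchical clustering + PCA -> three-criterion selection -> scoring.
    """

    def __init__(
        self,
        cohort: ExpressionCohort,
        annotation: pd.DataFrame | None = None,
        cluster_k: int = 8,
        loading_quantile: float = 0.25,
        components: tuple[str, str] = ("PC1", "PC3"),
        alpha: float = 0.05,
        adjust: str = "bonferroni",
    ) -> None:
        self.cohort = cohort
        self.annotation = annotation
        self.cluster_k = cluster_k
        self.loading_quantile = loading_quantile
        self.components = components
        self.alpha = alpha
        self.adjust = adjust

    def fit(self) -> SignatureResults:
        cohort = self.cohort
        if self.annotation is not None:
            cohort = filter_metabolic_genes(cohort, self.annotation)
        ratios = normalize_to_nc_median(cohort)
        log_ratios = np.log2(ratios)
        clustering = hierarchical_cluster(log_ratios, k=self.cluster_k)
        pca = run_pca(log_ratios)
        selection = select_signature(
            pca, clustering, log_ratios, cohort.tissue,
            loading_quantile=self.loading_quantile,
            components=self.components, alpha=self.alpha, adjust=self.adjust,
        )
        scores = (
            signature_score(ratios, selection.genes)
            if selection.genes else
            pd.DataFrame(columns=["score", "upper_tertile"])
        )
        return SignatureResults(
            selection=selection, ratios=ratios, log_ratios=log_ratios,
            pca=pca, clustering=clustering, scores=scores,
            n_genes_filtered=len(ratios),
        )
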