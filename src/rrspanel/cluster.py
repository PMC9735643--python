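"""PCA of genotype dosages, BIC-based k-means cluster selection, and DAPC.

The workflow mirrors the adegenet-style population-structure analysis:

1. :func:`genotype_pca` — principal components of the individuals x loci
   dosage matrix (missing calls imputed with the locus mean, columns
   centered, no scaling by default);
2. :func:`kmeans_bic_scan` — k-means over a range of candidate cluster
   numbers, scoring each k with BIC(k) = n*ln(WSS/n) + k*ln(n) and selecting
   the minimum (the full curve is kept so an elbow can be read off instead);
   by convention the cluster search runs on the *full* PC score matrix —
   truncation loses nothing for clustering and near-noise-free truncated
   scores degenerate the BIC criterion;
3. :func:`dapc_fit` — linear discriminant analysis on the PCs retaining
   ~40% of variance with the k-means clusters as classes, keeping all k-1
   discriminants; posterior group membership comes from the shared-covariance
   Gaussian classifier in discriminant space (the assignplot quantity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PCAResult",
    "ClusterScan",
    "DAPCResult",
    "genotype_pca",
    "kmeans_bic_scan",
    "dapc_fit",
    "assignplot_table",
]


@dataclass
class PCAResult:
    """Principal components of an imputed, centered dosage matrix."""

    scores: np.ndarray  # (n_individuals, n_components)
    loadings: np.ndarray  # (n_loci, n_components)
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    n_retained: int
    retain_variance: float
    individuals: list[str] = field(default_factory=list)

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)

    def retained_scores(self, retain_variance: float | None = None) -> np.ndarray:
        """Scores truncated to the smallest PC count reaching the target
        cumulative variance fraction (default: the fraction fitted with)."""
        if retain_variance is None:
            return self.scores[:, : self.n_retained]
        return self.scores[:, : n_components_for(self, retain_variance)]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "variance_fraction": self.explained_variance_ratio,
                "cumulative_variance": self.cumulative_variance,
            }
        )


def n_components_for(pca: PCAResult, retain_variance: float) -> int:
    """Smallest component count whose cumulative variance reaches the target."""
    cum = pca.cumulative_variance
    if len(cum) == 0:
        return 0
    reached = np.nonzero(cum >= retain_variance - 1e-12)[0]
    return int(reached[0]) + 1 if len(reached) else len(cum)


@dataclass
class ClusterScan:
    """BIC curve over candidate cluster numbers and the selected k."""

    k_values: list[int]
    bic: list[float]
    wss: list[float]
    labels_per_k: dict[int, np.ndarray]
    selected_k: int
    seed: int

    @property
    def selected_labels(self) -> np.ndarray:
        return self.labels_per_k[self.selected_k]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "WSS": self.wss, "BIC": self.bic})


@dataclass
class DAPCResult:
    """Discriminant functions and posterior memberships of a DAPC fit."""

    n_pcs: int
    pc_variance_fraction: float
    cluster_labels: np.ndarray
    clusters: list[int]
    discriminant_scores: np.ndarray  # (n_individuals, n_discriminants)
    posterior: np.ndarray  # (n_individuals, n_clusters), rows sum to 1
    assignments: np.ndarray
    individuals: list[str] = field(default_factory=list)

    @property
    def n_discriminants(self) -> int:
        return self.discriminant_scores.shape[1]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individuals
                or [str(i) for i in range(len(self.assignments))],
                "assigned_cluster": self.assignments,
                "max_posterior": self.posterior.max(axis=1),
            }
        )


def impute_and_center(gm: GenotypeMatrix, scale: bool = False) -> np.ndarray:
    """Dosage matrix with locus-mean imputation and column centering."""
    x = gm.dosages.astype(float)
    x[gm.dosages == MISSING] = np.nan
    col_means = np.nanmean(x, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    x = np.where(np.isnan(x), col_means[None, :], x)
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    return x


def genotype_pca(
    gm: GenotypeMatrix, retain_variance: float = 0.80, scale: bool = False
) -> PCAResult:
    """PCA of the genotype matrix by singular value decomposition.

    Missing dosages are imputed with the locus mean; columns are centered and
    (optionally) scaled.  ``n_retained`` is the smallest number of components
    whose cumulative variance fraction reaches ``retain_variance``.  A
    zero-variance matrix yields a single trivial component with a warning.
    """
    if gm.n_individuals < 2 or gm.n_loci < 1:
        raise ValueError("PCA needs at least two individuals and one locus")
    x = impute_and_center(gm, scale=scale)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    eigenvalues = (s**2) / (n - 1)
    total = eigenvalues.sum()
    if total <= 0:
        import warnings

        warnings.warn("zero-variance genotype matrix; PCA is trivial", stacklevel=2)
        return PCAResult(
            scores=np.zeros((n, 1)),
            loadings=np.zeros((gm.n_loci, 1)),
            eigenvalues=np.zeros(1),
            explained_variance_ratio=np.array([1.0]),
            n_retained=1,
            retain_variance=retain_variance,
            individuals=list(gm.individuals),
        )
    ratio = eigenvalues / total
    scores = u * s
    pca = PCAResult(
        scores=scores,
        loadings=vt.T,
        eigenvalues=eigenvalues,
        explained_variance_ratio=ratio,
        n_retained=1,
        retain_variance=retain_variance,
        individuals=list(gm.individuals),
    )
    pca.n_retained = n_components_for(pca, retain_variance)
    return pca


def kmeans_bic_scan(
    scores: np.ndarray,
    k_range: Sequence[int] = range(1, 16),
    n_starts: int = 10,
    seed: int = 0,
) -> ClusterScan:
    """k-means over candidate k, scored by BIC(k) = n*ln(WSS/n) + k*ln(n).

    For each k the best of ``n_starts`` random initialisations (lowest
    within-cluster sum of squares) is kept; the selected k minimises BIC.
    Candidate k exceeding the number of points are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    k_values: list[int] = []
    bics: list[float] = []
    wsss: list[float] = []
    labels_per_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 1 or k > n:
            import warnings

            warnings.warn(f"skipping k={k}: outside 1..{n}", stacklevel=2)
            continue
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
        labels = km.fit_predict(scores)
        wss = float(km.inertia_)
        # ln(0) guard: a perfect fit gets the strongest possible support
        bic = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
        k_values.append(k)
        wsss.append(wss)
        bics.append(float(bic))
        labels_per_k[k] = labels + 1  # clusters numbered 1..k
    if not k_values:
        raise ValueError("no valid k in k_range")
    selected = k_values[int(np.argmin(bics))]
    return ClusterScan(
        k_values=k_values,
        bic=bics,
        wss=wsss,
        labels_per_k=labels_per_k,
        selected_k=selected,
        seed=seed,
    )


def dapc_fit(
    pca: PCAResult,
    cluster_labels: np.ndarray,
    retain_variance: float = 0.40,
) -> DAPCResult:
    """Linear discriminant analysis on retained PCs with clusters as classes.

    Retains the smallest PC count reaching ``retain_variance`` cumulative
    variance (at least as many PCs as discriminants), keeps all k-1
    discriminants, and computes posterior memberships under the
    shared-within-class-covariance Gaussian model.
    """
    labels = np.asarray(cluster_labels)
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("DAPC needs at least two clusters")
    n_pcs = max(n_components_for(pca, retain_variance), len(clusters) - 1)
    n_pcs = min(n_pcs, pca.scores.shape[1])
    x = pca.scores[:, :n_pcs]
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(x, labels)
    posterior = lda.predict_proba(x)
    scores = lda.transform(x)
    assignments = np.array([lda.classes_[i] for i in posterior.argmax(axis=1)])
    return DAPCResult(
        n_pcs=n_pcs,
        pc_variance_fraction=float(pca.cumulative_variance[n_pcs - 1]),
        cluster_labels=labels,
        clusters=[int(c) for c in lda.classes_],
        discriminant_scores=scores,
        posterior=posterior,
        assignments=assignments,
        individuals=list(pca.individuals),
    )


def assignplot_table(
    dapc: DAPCResult, variety_labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Long-format posterior membership table (one row per individual x cluster).

    Suitable for drawing an assignplot or cross-tabulating inferred clusters
    against declared varieties.
    """
    n, k = dapc.posterior.shape
    individuals = dapc.individuals or [str(i) for i in range(n)]
    if variety_labels is not None and len(variety_labels) != n:
        raise ValueError("variety_labels length does not match individuals")
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(
                {
                    "individual": individuals[i],
                    "cluster": dapc.clusters[j],
                    "posterior": float(dapc.posterior[i, j]),
                    "assigned_cluster": int(dapc.assignments[i]),
                    "true_variety": variety_labels[i] if variety_labels is not None else None,
                }
            )
    return pd.DataFrame(rows)
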