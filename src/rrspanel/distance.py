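"""Nei's (1972) standard genetic distance, distance matrices, and NJ trees.

For two populations with per-locus allele frequency vectors x_l and y_l, the
identity components are arithmetic means over loci

    Jx  = mean_l sum_a x_la^2
    Jy  = mean_l sum_a y_la^2
    Jxy = mean_l sum_a x_la * y_la

and the normalized identity I = Jxy / sqrt(Jx * Jy) gives the standard
distance D = -ln I.  D is 0 for identical frequency vectors and nonnegative
by the Cauchy-Schwarz inequality.  Loci with no called genotype in either
population are excluded pairwise.  Frequencies are plain genotype-count
estimates (no model-based correction), matching the convention of the
standard population-genetics implementations of this distance.

Individual-level distances (allele mismatch or Euclidean on mean-imputed
dosages) and neighbor-joining tree construction are provided for unrooted
tree visualisation of population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "NeiComponents",
    "allele_frequencies",
    "nei_distance",
    "nei_distance_matrix",
    "distance_summary",
    "individual_distance",
    "nj_tree",
]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_tsv(cls, path, **metadata) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float),
                   metadata=metadata)

    def to_tsv(self, path, decimals: int | None = 4) -> None:
        df = self.to_frame()
        if decimals is not None:
            df = df.round(decimals)
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class NeiComponents:
    """Identity components behind one pairwise Nei's D."""

    jx: float
    jy: float
    jxy: float
    identity: float
    d: float
    n_loci: int


def allele_frequencies(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Per-variety alt-allele frequencies.

    Returns the variety labels (in order of first appearance) and a
    (n_varieties, n_loci) array of alt frequencies; NaN where a variety has
    no called genotype at a locus.
    """
    if any(v == "" for v in gm.varieties):
        raise ValueError("every individual needs a variety label; attach a popmap")
    labels = list(dict.fromkeys(gm.varieties))
    freqs = np.full((len(labels), gm.n_loci), np.nan)
    varieties = np.asarray(gm.varieties, dtype=object)
    for vi, label in enumerate(labels):
        rows = gm.dosages[varieties == label]
        called = rows != MISSING
        totals = 2 * called.sum(axis=0)
        alt = np.where(called, rows, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[vi] = np.where(totals > 0, alt / totals, np.nan)
    return labels, freqs


def nei_distance(x: np.ndarray, y: np.ndarray) -> NeiComponents:
    """Nei's standard distance between two alt-allele frequency vectors.

    ``x`` and ``y`` are per-locus alt frequencies of biallelic loci; each
    locus contributes allele frequencies (p, 1-p).  Loci NaN in either vector
    are excluded pairwise; having no shared defined locus is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    shared = ~np.isnan(x) & ~np.isnan(y)
    if not shared.any():
        raise ValueError("no locus with defined frequencies in both populations")
    xs, ys = x[shared], y[shared]
    jx = float(np.mean(xs**2 + (1 - xs) ** 2))
    jy = float(np.mean(ys**2 + (1 - ys) ** 2))
    jxy = float(np.mean(xs * ys + (1 - xs) * (1 - ys)))
    identity = jxy / np.sqrt(jx * jy)
    # floating point can nudge I a hair above 1 for identical inputs
    d = -np.log(min(identity, 1.0))
    return NeiComponents(jx=jx, jy=jy, jxy=jxy, identity=float(identity),
                         d=float(max(d, 0.0)), n_loci=int(shared.sum()))


def nei_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Nei's D between all varieties of a labelled genotype matrix."""
    labels, freqs = allele_frequencies(gm)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nei_distance(freqs[i], freqs[j]).d
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        labels=labels,
        values=values,
        metadata={"measure": "nei_1972", "n_loci": gm.n_loci},
    )


def distance_summary(dm: DistanceMatrix) -> dict:
    """Row means, global minimum pair, and ranked distinct distances.

    ``row_means`` maps each label to the mean of its off-diagonal entries
    (its average distance to every other population).  ``min_pair`` is the
    globally closest pair; ``ranked_values`` lists distinct off-diagonal
    values ascending.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two labels to summarize")
    off = ~np.eye(n, dtype=bool)
    row_means = {
        label: float(dm.values[i, off[i]].mean()) for i, label in enumerate(dm.labels)
    }
    iu = np.triu_indices(n, k=1)
    pair_values = dm.values[iu]
    order = np.argsort(pair_values, kind="stable")
    ranked_pairs = [
        ((dm.labels[iu[0][k]], dm.labels[iu[1][k]]), float(pair_values[k]))
        for k in order
    ]
    distinct = sorted(set(float(v) for v in pair_values))
    min_pair, min_value = ranked_pairs[0]
    return {
        "row_means": row_means,
        "min_pair": min_pair,
        "min_value": min_value,
        "ranked_pairs": ranked_pairs,
        "ranked_values": distinct,
    }


def individual_distance(
    gm: GenotypeMatrix, measure: str = "allele_mismatch"
) -> DistanceMatrix:
    """Pairwise distances between individuals.

    ``allele_mismatch``: mean over jointly called loci of |dosage difference|
    / 2 (0 for identical genotypes, 1 for opposite homozygotes at every
    locus); a pair with no jointly called locus is an error.  ``euclidean``:
    Euclidean distance on locus-mean-imputed dosages.
    """
    if gm.n_individuals < 2:
        raise ValueError("need at least two individuals")
    if measure == "allele_mismatch":
        d = gm.dosages.astype(float)
        d[gm.dosages == MISSING] = np.nan
        n = gm.n_individuals
        values = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(d[i] - d[i + 1:]) / 2.0  # (n-i-1, loci)
            shared = ~np.isnan(diff)
            counts = shared.sum(axis=1)
            if np.any(counts == 0):
                j = i + 1 + int(np.argmax(counts == 0))
                raise ValueError(
                    f"individuals {gm.individuals[i]} and {gm.individuals[j]} "
                    "share no called locus"
                )
            means = np.nansum(diff, axis=1) / counts
            values[i, i + 1:] = means
            values[i + 1:, i] = means
    elif measure == "euclidean":
        d = gm.dosages.astype(float)
        d[gm.dosages == MISSING] = np.nan
        col_means = np.nanmean(d, axis=0)
        col_means = np.nan_to_num(col_means)
        filled = np.where(np.isnan(d), col_means, d)
        from scipy.spatial.distance import pdist, squareform

        values = squareform(pdist(filled, metric="euclidean"))
    else:
        raise ValueError("measure must be 'allele_mismatch' or 'euclidean'")
    return DistanceMatrix(
        labels=list(gm.individuals),
        values=values,
        metadata={"measure": measure, "n_loci": gm.n_loci},
    )


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as a newick string.

    Standard NJ agglomeration with negative branch lengths clamped to zero
    (deficit shifted to the sister branch).  The leaf set equals the matrix
    labels; the tree is unrooted (trifurcating root in the newick text).
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    sk_dm = SkbioDM(dm.values, ids=list(dm.labels))
    tree = skbio_nj(sk_dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
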