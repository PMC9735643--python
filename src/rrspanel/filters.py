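"""Variant filter cascade, candidate-region intersection, and panel reduction.

The cascade mirrors common VCFtools-style hard filtering of a multi-sample
SNP call set:

1. per-genotype depth masking (DP below threshold -> missing call),
2. removal of poorly sequenced individuals (missing-call fraction),
3. site filters: quality, minor allele count, call rate, minor allele
   frequency, and mean depth across all individuals,

followed by two panel-reduction steps: a stricter minor-allele-frequency cut
and positional thinning so that retained SNPs are at least a fixed genomic
distance apart (markers likely to be inherited independently).  Every stage
logs its attrition so that input = output + sum(removed per stage).

All depth/quality/frequency thresholds are inclusive ("at least").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FilterConfig",
    "AttritionLog",
    "mask_low_depth_genotypes",
    "remove_poor_individuals",
    "apply_site_filters",
    "intersect_candidate_regions",
    "reduce_by_maf",
    "thin_by_distance",
    "run_filter_cascade",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the hard-filter cascade and panel reduction.

    Defaults follow the workflow this package models: genotype DP >= 5,
    MAC >= 3, site quality >= 30, call rate >= 0.80, MAF >= 0.05, mean site
    depth >= 25; panel reduction at MAF >= 0.35 with 1 Mb thinning; candidate
    gene windows extended 500 kb each side.
    """

    min_genotype_depth: int = 5
    max_individual_missing: float = 0.5
    min_q: float = 30.0
    min_mac: int = 3
    max_missing_callrate: float = 0.80
    min_maf: float = 0.05
    min_mean_depth: float = 25.0
    reduced_maf: float = 0.35
    thin_distance: int = 1_000_000
    thin_mode: str = "greedy"
    gene_extension: int = 500_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_callrate <= 1.0:
            raise ValueError("max_missing_callrate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5 or not 0.0 <= self.reduced_maf <= 0.5:
            raise ValueError("MAF thresholds must be in [0, 0.5]")
        for name in ("min_genotype_depth", "min_q", "min_mac", "min_mean_depth",
                     "thin_distance", "gene_extension"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.thin_mode not in ("greedy", "mutual"):
            raise ValueError("thin_mode must be 'greedy' or 'mutual'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AttritionLog:
    """Ordered record of sites/individuals removed per filter stage."""

    n_input_sites: int = 0
    n_input_individuals: int = 0
    site_stages: list[tuple[str, int]] = field(default_factory=list)
    removed_individuals: list[str] = field(default_factory=list)
    masked_genotypes: int = 0

    def record(self, stage: str, removed: int) -> None:
        self.site_stages.append((stage, removed))

    @property
    def n_output_sites(self) -> int:
        return self.n_input_sites - sum(r for _, r in self.site_stages)

    def to_table(self):
        import pandas as pd

        rows = [{"stage": s, "removed_sites": r} for s, r in self.site_stages]
        return pd.DataFrame(rows)


def mask_low_depth_genotypes(
    gm: GenotypeMatrix, min_genotype_depth: int = 5
) -> GenotypeMatrix:
    """Set genotype calls with DP below the threshold to missing.

    The threshold is inclusive: DP == min_genotype_depth is retained.  Sites
    themselves are kept.  Raises if any genotype lacks a DP value, naming the
    first offending sample/site.
    """
    out = gm.take_sites(np.arange(gm.n_loci))  # copy
    absent = out.depths < 0
    if absent.any():
        i, j = np.argwhere(absent)[0]
        raise ValueError(
            "DP missing for sample "
            f"{out.individuals[i]} at {out.contigs[j]}:{out.positions[j]}; "
            "per-genotype depth masking requires DP"
        )
    mask = out.depths < min_genotype_depth
    dosages = out.dosages.copy()
    dosages[mask] = MISSING
    out.dosages = dosages
    return out


def remove_poor_individuals(
    gm: GenotypeMatrix, max_individual_missing: float = 0.5
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals whose missing-genotype fraction exceeds the threshold.

    Returns the reduced matrix and the removed individual ids.  Removing every
    individual is an error.
    """
    if gm.n_individuals == 0:
        raise ValueError("no individuals in genotype matrix")
    miss = gm.missing_fraction_per_individual()
    keep = np.where(miss <= max_individual_missing)[0]
    removed = [gm.individuals[i] for i in np.where(miss > max_individual_missing)[0]]
    if len(keep) == 0:
        raise ValueError(
            "individual-missingness filter removed every individual "
            f"(threshold {max_individual_missing})"
        )
    return gm.take_individuals(keep), removed


def apply_site_filters(
    gm: GenotypeMatrix,
    config: FilterConfig = FilterConfig(),
    log: AttritionLog | None = None,
) -> GenotypeMatrix:
    """Apply the site-level hard filters in a fixed, logged order.

    Retains sites satisfying *all* of: QUAL >= min_q, minor allele count over
    called genotypes >= min_mac, call rate >= max_missing_callrate, minor
    allele frequency >= min_maf, and mean DP over all individuals >=
    min_mean_depth.  Attrition is attributed to the first failing filter in
    the order Q -> MAC -> call rate -> MAF -> mean depth.
    """
    keep = np.ones(gm.n_loci, dtype=bool)
    stages = [
        ("site_quality", np.asarray(gm.quals, dtype=float) >= config.min_q),
        ("minor_allele_count", gm.minor_allele_counts() >= config.min_mac),
        ("call_rate", gm.call_rate_per_site() >= config.max_missing_callrate),
        ("minor_allele_frequency",
         np.nan_to_num(gm.minor_allele_frequencies(), nan=-1.0) >= config.min_maf),
        ("mean_depth", gm.mean_depth_per_site() >= config.min_mean_depth),
    ]
    for name, ok in stages:
        newly_removed = int(np.sum(keep & ~ok))
        if log is not None:
            log.record(name, newly_removed)
        keep &= ok
    return gm.take_sites(np.where(keep)[0])


def _merged_windows(
    genes: Sequence[tuple[str, int, int]],
    extension: int,
    contig_lengths: Mapping[str, int],
) -> dict[str, list[tuple[int, int]]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in genes:
        if contig not in contig_lengths:
            raise ValueError(f"gene interval on unknown contig {contig!r}")
        length = contig_lengths[contig]
        if start < 0 or end > length or start >= end:
            raise ValueError(
                f"gene interval [{start},{end}) invalid on contig "
                f"{contig} (length {length})"
            )
        lo = max(0, start - extension)
        hi = min(length, end + extension)
        by_contig.setdefault(contig, []).append((lo, hi))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        acc: list[list[int]] = []
        for s, e in ivs:
            if acc and s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[contig] = [(s, e) for s, e in acc]
    return merged


def intersect_candidate_regions(
    gm: GenotypeMatrix,
    genes: Sequence[tuple[str, int, int]],
    extension: int,
    contig_lengths: Mapping[str, int],
) -> GenotypeMatrix:
    """Keep sites inside candidate-gene windows extended both directions.

    Gene intervals (half-open, 0-based) are widened by ``extension`` bp each
    side, clipped to the contig, and merged; SNPs whose (1-based) position
    falls inside any window are retained.
    """
    windows = _merged_windows(genes, extension, contig_lengths)
    keep = np.zeros(gm.n_loci, dtype=bool)
    contigs = np.asarray(gm.contigs)
    positions = np.asarray(gm.positions)
    for contig, ivs in windows.items():
        on_contig = contigs == contig
        pos0 = positions[on_contig] - 1  # to 0-based
        hit = np.zeros(pos0.shape, dtype=bool)
        for s, e in ivs:
            hit |= (pos0 >= s) & (pos0 < e)
        keep[np.where(on_contig)[0][hit]] = True
    return gm.take_sites(np.where(keep)[0])


def reduce_by_maf(gm: GenotypeMatrix, min_maf: float = 0.35) -> GenotypeMatrix:
    """Stricter MAF cut used to shrink the full set toward a diagnostic panel."""
    maf = np.nan_to_num(gm.minor_allele_frequencies(), nan=-1.0)
    return gm.take_sites(np.where(maf >= min_maf)[0])


def thin_by_distance(
    gm: GenotypeMatrix, thin_distance: int = 1_000_000, mode: str = "greedy"
) -> GenotypeMatrix:
    """Thin SNPs so retained markers are >= ``thin_distance`` bp apart.

    ``greedy`` (default) scans each contig left to right keeping a site iff it
    lies at least ``thin_distance`` from the last *kept* site — deterministic
    and retains more sites.  ``mutual`` keeps a site iff no *other input* site
    lies within ``thin_distance`` — the literal "no neighbour within d"
    criterion.  Unsorted input is sorted internally with a warning.
    """
    if mode not in ("greedy", "mutual"):
        raise ValueError("mode must be 'greedy' or 'mutual'")
    if not gm.is_position_sorted():
        warnings.warn("sites not position-sorted; sorting before thinning", stacklevel=2)
        gm = gm.sort_by_position()
    contigs = np.asarray(gm.contigs)
    positions = np.asarray(gm.positions)
    keep_idx: list[int] = []
    for contig in dict.fromkeys(contigs.tolist()):
        idx = np.where(contigs == contig)[0]
        pos = positions[idx]
        if mode == "greedy":
            last = None
            for i, p in zip(idx, pos):
                if last is None or p - last >= thin_distance:
                    keep_idx.append(int(i))
                    last = p
        else:
            for k, (i, p) in enumerate(zip(idx, pos)):
                left_ok = k == 0 or p - pos[k - 1] >= thin_distance
                right_ok = k == len(pos) - 1 or pos[k + 1] - p >= thin_distance
                if left_ok and right_ok:
                    keep_idx.append(int(i))
    return gm.take_sites(np.array(sorted(keep_idx), dtype=int))


def run_filter_cascade(
    gm: GenotypeMatrix, config: FilterConfig = FilterConfig()
) -> tuple[GenotypeMatrix, AttritionLog]:
    """Full-filter pipeline: depth mask -> individual removal -> site filters.

    Returns the filtered matrix and an attrition log.  Panel reduction
    (``reduce_by_maf`` + ``thin_by_distance``) is a separate, subsequent step.
    """
    log = AttritionLog(
        n_input_sites=gm.n_loci, n_input_individuals=gm.n_individuals
    )
    pre_missing = int(np.sum(gm.dosages == MISSING))
    gm = mask_low_depth_genotypes(gm, config.min_genotype_depth)
    log.masked_genotypes = int(np.sum(gm.dosages == MISSING)) - pre_missing
    gm, removed = remove_poor_individuals(gm, config.max_individual_missing)
    log.removed_individuals = removed
    gm = apply_site_filters(gm, config, log=log)
    return gm, log
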