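"""Classify panel SNPs by proximity to genes and LTR retroelements.

Each SNP receives exactly one category from {gene, gene_flank, LTR,
LTR_flank, intergenic}: "gene"/"LTR" when the position lies inside a feature
interval, the "_flank" variants when it lies within a fixed distance of the
nearest feature edge (6 kb for genes, 3 kb for LTR retroelements by default,
inclusive at the limit), and "intergenic" otherwise.  Overlaps between
categories are resolved by an explicit precedence order (gene classes first
by default).  Summaries report per-category counts plus the two composite
fractions of interest: gene-associated (gene + gene_flank) and
LTR-associated (LTR + LTR_flank).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "Feature",
    "FeatureSet",
    "SnpAnnotation",
    "CategorySummary",
    "classify_snp",
    "annotate_snps",
    "summarize_categories",
    "read_features",
]

CATEGORIES = ("gene", "gene_flank", "LTR", "LTR_flank", "intergenic")
DEFAULT_PRECEDENCE = ("gene", "gene_flank", "LTR", "LTR_flank")

# GFF3 type terms accepted for each feature class
GFF_TYPE_MAP = {
    "gene": "gene",
    "protein_coding_gene": "gene",
    "LTR_retrotransposon": "LTR",
    "long_terminal_repeat": "LTR",
    "LTR": "LTR",
    "repeat_region": "LTR",
}


@dataclass(frozen=True)
class Feature:
    """A genomic feature: half-open interval with a class in {gene, LTR}."""

    contig: str
    start: int
    end: int
    ftype: str
    feature_id: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in ("gene", "LTR"):
            raise ValueError(f"feature type must be 'gene' or 'LTR', got {self.ftype!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start},{self.end})")


class FeatureSet:
    """Per-contig interval indexes over gene and LTR features."""

    def __init__(self, features: Iterable[Feature]):
        self.features = list(features)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for f in self.features:
            key = (f.ftype, f.contig)
            self._trees.setdefault(key, IntervalTree()).addi(f.start, f.end, f)

    def contigs(self, ftype: str) -> set[str]:
        return {c for (t, c) in self._trees if t == ftype}

    def distance_to_nearest(self, ftype: str, contig: str, pos0: int) -> float | None:
        """Distance in bp from a 0-based position to the nearest feature edge.

        0 when the position lies inside a feature; None when the contig has no
        features of this type.
        """
        tree = self._trees.get((ftype, contig))
        if tree is None or len(tree) == 0:
            return None
        if tree.overlap(pos0, pos0 + 1):
            return 0
        best = np.inf
        for iv in tree:
            if pos0 < iv.begin:
                d = iv.begin - pos0
            elif pos0 >= iv.end:
                d = pos0 - (iv.end - 1)
            else:
                d = 0
            best = min(best, d)
        return float(best)


@dataclass(frozen=True)
class SnpAnnotation:
    """Category assignment plus per-class distances for one SNP."""

    snp_id: str
    contig: str
    position: int  # 1-based, VCF style
    category: str
    gene_distance: float | None
    ltr_distance: float | None


@dataclass
class CategorySummary:
    """Per-category counts and the composite association percentages."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float] = field(init=False)
    gene_associated_pct: float = field(init=False)
    ltr_associated_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.percentages = {
            c: round(100.0 * self.counts.get(c, 0) / self.total, 1) if self.total else 0.0
            for c in CATEGORIES
        }
        gene_n = self.counts.get("gene", 0) + self.counts.get("gene_flank", 0)
        ltr_n = self.counts.get("LTR", 0) + self.counts.get("LTR_flank", 0)
        self.gene_associated_pct = round(100.0 * gene_n / self.total, 1) if self.total else 0.0
        self.ltr_associated_pct = round(100.0 * ltr_n / self.total, 1) if self.total else 0.0

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total": self.total,
            "percentages": dict(self.percentages),
            "gene_associated_pct": self.gene_associated_pct,
            "ltr_associated_pct": self.ltr_associated_pct,
        }


def classify_snp(
    contig: str,
    position: int,
    features: FeatureSet,
    gene_flank: int = 6_000,
    ltr_flank: int = 3_000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    snp_id: str | None = None,
) -> SnpAnnotation:
    """Assign one SNP (1-based position) a single proximity category.

    Flank membership is inclusive at the flank limit.  When a SNP satisfies
    several categories (e.g. inside a gene that overlaps an LTR), the first
    match in ``precedence`` wins; SNPs matching none are intergenic.
    """
    pos0 = position - 1
    d_gene = features.distance_to_nearest("gene", contig, pos0)
    d_ltr = features.distance_to_nearest("LTR", contig, pos0)
    membership = {
        "gene": d_gene is not None and d_gene == 0,
        "gene_flank": d_gene is not None and 0 < d_gene <= gene_flank,
        "LTR": d_ltr is not None and d_ltr == 0,
        "LTR_flank": d_ltr is not None and 0 < d_ltr <= ltr_flank,
    }
    category = "intergenic"
    for cat in precedence:
        if membership.get(cat):
            category = cat
            break
    return SnpAnnotation(
        snp_id=snp_id or f"{contig}:{position}",
        contig=contig,
        position=position,
        category=category,
        gene_distance=d_gene,
        ltr_distance=d_ltr,
    )


def annotate_snps(
    snps: Iterable[tuple[str, int]],
    features: FeatureSet,
    gene_flank: int = 6_000,
    ltr_flank: int = 3_000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[SnpAnnotation]:
    """Classify an iterable of (contig, 1-based position) SNPs."""
    return [
        classify_snp(c, p, features, gene_flank, ltr_flank, precedence)
        for c, p in snps
    ]


def summarize_categories(annotations: Sequence[SnpAnnotation]) -> CategorySummary:
    """Tally category counts and composite association percentages."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    counts: dict[str, int] = {c: 0 for c in CATEGORIES}
    for ann in annotations:
        counts[ann.category] += 1
    return CategorySummary(counts=counts, total=len(annotations))


def read_features(path: str | Path) -> FeatureSet:
    """Read gene/LTR features from GFF3 or BED (type in column 4 or 7).

    GFF3: the ``type`` column is mapped through a small Sequence-Ontology
    synonym table (gene, LTR_retrotransposon, ...); unrecognised types are
    ignored.  BED: expects a 4th column naming the class (gene/LTR).
    """
    path = Path(path)
    features: list[Feature] = []
    is_gff = path.suffix.lower() in (".gff", ".gff3") or _sniff_gff(path)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if is_gff:
                if len(parts) < 9:
                    continue
                ftype = GFF_TYPE_MAP.get(parts[2])
                if ftype is None:
                    continue
                fid = ""
                for kv in parts[8].split(";"):
                    if kv.startswith("ID="):
                        fid = kv[3:]
                        break
                features.append(
                    Feature(parts[0], int(parts[3]) - 1, int(parts[4]), ftype, fid)
                )
            else:
                if len(parts) < 4:
                    raise ValueError(
                        f"BED feature file {path} needs a 4th column with the "
                        "feature class (gene/LTR)"
                    )
                ftype = GFF_TYPE_MAP.get(parts[3], parts[3])
                features.append(
                    Feature(parts[0], int(parts[1]), int(parts[2]), ftype,
                            parts[3] if len(parts) < 5 else parts[4])
                )
    return FeatureSet(features)


def _sniff_gff(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if not line.startswith("#"):
                return len(line.split("\t")) >= 9
    return False


def annotations_to_table(annotations: Sequence[SnpAnnotation]):
    import pandas as pd

    return pd.DataFrame(
        {
            "snp_id": [a.snp_id for a in annotations],
            "contig": [a.contig for a in annotations],
            "position": [a.position for a in annotations],
            "category": [a.category for a in annotations],
            "gene_distance": [a.gene_distance for a in annotations],
            "ltr_distance": [a.ltr_distance for a in annotations],
        }
    )
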