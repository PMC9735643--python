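"""Fragment-size profiles, smear summaries, and on/off-target accounting.

A digested genome is summarised as a linear-axis size histogram carrying both
a fragment *count* per bin (molar proxy) and a fragment *mass* per bin (summed
lengths, proportional to DNA mass at one genome copy).  A Savitzky-Golay
filter smooths the mass track into an electropherogram-like profile; a LOWESS
mode is available as an alternative smoother.  "Smear" summaries report count
and mass inside an inclusive size window (the 100-300 bp window is the usual
short-read target range).  Size-selected fragments can be exported as target
regions together with their genomic complement, against which aligned-read
intervals are scored for on/off-target enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.signal import savgol_filter

from .digest import Fragment

__all__ = [
    "SizeProfile",
    "SmearSummary",
    "TargetRegions",
    "EnrichmentReport",
    "size_histogram",
    "smooth_profile",
    "smear_summary",
    "make_target_bed",
    "on_off_target",
    "read_bed",
    "write_bed",
]


@dataclass
class SizeProfile:
    """Binned fragment-size distribution (count and mass per bin).

    ``bin_edges`` has one more element than the per-bin arrays; bin *i* covers
    lengths ``[bin_edges[i], bin_edges[i+1])`` except the last bin, which is
    closed on the right so that the configured range is inclusive on both
    ends.
    """

    bin_edges: np.ndarray
    count_per_bin: np.ndarray
    mass_per_bin: np.ndarray
    smoothed_mass: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.count_per_bin)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_table(self):
        import pandas as pd

        cols = {
            "bin_start": self.bin_edges[:-1],
            "bin_end": self.bin_edges[1:],
            "count": self.count_per_bin,
            "mass": self.mass_per_bin,
        }
        if self.smoothed_mass is not None:
            cols["smoothed_mass"] = self.smoothed_mass
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class SmearSummary:
    """Count and mass of fragments inside an inclusive length window."""

    lo: int
    hi: float
    fragment_count: int
    fragment_mass: int
    label: str | None = None


@dataclass
class TargetRegions:
    """Size-selected fragment intervals plus the genomic complement.

    Target and complement are disjoint and together tile the genome exactly.
    """

    target: list[tuple[str, int, int]]
    complement: list[tuple[str, int, int]]
    contig_lengths: dict[str, int]

    def target_bp(self) -> int:
        return sum(e - s for _, s, e in self.target)

    def complement_bp(self) -> int:
        return sum(e - s for _, s, e in self.complement)


@dataclass(frozen=True)
class EnrichmentReport:
    """Per-sample on/off-target read accounting.

    ``density_ratio`` is (on-reads / target bp) / (off-reads / complement bp);
    None when undefined (no reads, or an empty compartment).
    """

    on_target: int
    off_target: int
    unassigned: int
    on_target_fraction: float | None
    density_ratio: float | None

    @property
    def total(self) -> int:
        return self.on_target + self.off_target + self.unassigned


def size_histogram(
    fragments: Sequence[Fragment],
    size_range: tuple[int, int],
    bin_width: int = 1,
) -> SizeProfile:
    """Histogram fragment lengths over ``size_range`` (inclusive both ends).

    Both the fragment count and the summed fragment length (mass) are
    accumulated per bin on a linear axis.  An empty fragment list gives an
    all-zero profile.
    """
    lo, hi = size_range
    if lo >= hi:
        raise ValueError(f"invalid size range [{lo}, {hi}]")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    # np.histogram closes the last bin on the right, so [lo, hi] is covered
    # inclusively once the final edge reaches hi
    edges = np.arange(lo, hi + bin_width, bin_width, dtype=float)
    lengths = np.array(
        [f.length for f in fragments if lo <= f.length <= hi], dtype=float
    )
    count, _ = np.histogram(lengths, bins=edges)
    mass, _ = np.histogram(lengths, bins=edges, weights=lengths)
    return SizeProfile(
        bin_edges=edges,
        count_per_bin=count.astype(int),
        mass_per_bin=mass,
        metadata={"range": (lo, hi), "bin_width": bin_width},
    )


def smooth_profile(
    profile: SizeProfile,
    window_bins: int = 51,
    polyorder: int = 3,
    method: str = "savgol",
) -> SizeProfile:
    """Smooth the mass track of a profile.

    ``method="savgol"`` (default) applies a Savitzky-Golay filter with the
    given odd window length in bins and polynomial order; ``method="lowess"``
    applies locally weighted regression with a bandwidth fraction equivalent
    to ``window_bins / n_bins``.  Raw count and mass tracks are retained.
    """
    n = profile.n_bins
    if method == "savgol":
        if window_bins % 2 == 0:
            raise ValueError("window_bins must be odd")
        if window_bins <= polyorder:
            raise ValueError("window_bins must exceed polyorder")
        if window_bins > n:
            raise ValueError(
                f"smoothing window ({window_bins} bins) exceeds the profile "
                f"({n} bins); reduce the window to at most {n if n % 2 else n - 1}"
            )
        smoothed = savgol_filter(profile.mass_per_bin, window_bins, polyorder)
    elif method == "lowess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        frac = min(1.0, max(window_bins / max(n, 1), 2.0 / max(n, 1)))
        smoothed = lowess(
            profile.mass_per_bin,
            np.arange(n),
            frac=frac,
            return_sorted=False,
        )
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return SizeProfile(
        bin_edges=profile.bin_edges,
        count_per_bin=profile.count_per_bin,
        mass_per_bin=profile.mass_per_bin,
        smoothed_mass=np.asarray(smoothed, dtype=float),
        metadata={
            **profile.metadata,
            "smoothing": {"method": method, "window_bins": window_bins, "polyorder": polyorder},
        },
    )


def smear_summary(
    fragments: Sequence[Fragment],
    window: tuple[int, float],
    label: str | None = None,
) -> SmearSummary:
    """Count and mass of fragments with lengths inside the inclusive window.

    The fragment count is the molar proxy used to rank enzyme combinations;
    only rank order is comparable with instrument-reported molarities.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"invalid window [{lo}, {hi}]")
    in_window = [f.length for f in fragments if lo <= f.length <= hi]
    return SmearSummary(
        lo=lo,
        hi=hi,
        fragment_count=len(in_window),
        fragment_mass=int(sum(in_window)),
        label=label,
    )


def make_target_bed(
    fragments: Sequence[Fragment],
    window: tuple[int, float],
    contig_lengths: Mapping[str, int],
) -> TargetRegions:
    """Split the genome into size-selected target intervals and the rest.

    Fragments whose length falls in ``window`` (inclusive) become target
    intervals; the complement is the remainder of every contig, so target and
    complement always partition the genome.
    """
    lo, hi = window
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for frag in fragments:
        if frag.contig not in contig_lengths:
            raise ValueError(f"fragment contig {frag.contig!r} not in contig_lengths")
        if frag.end > contig_lengths[frag.contig]:
            raise ValueError(
                f"fragment [{frag.start},{frag.end}) exceeds contig "
                f"{frag.contig} length {contig_lengths[frag.contig]}"
            )
        if lo <= frag.length <= hi:
            by_contig[frag.contig].append((frag.start, frag.end))

    target: list[tuple[str, int, int]] = []
    complement: list[tuple[str, int, int]] = []
    for contig, length in contig_lengths.items():
        ivs = sorted(by_contig[contig])
        # merge adjacent/overlapping target intervals
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        for s, e in merged:
            if s > cursor:
                complement.append((contig, cursor, s))
            target.append((contig, s, e))
            cursor = e
        if cursor < length:
            complement.append((contig, cursor, length))
    return TargetRegions(
        target=target, complement=complement, contig_lengths=dict(contig_lengths)
    )


def on_off_target(
    reads: Iterable[tuple[str, int, int]],
    regions: TargetRegions,
    min_overlap: int = 1,
) -> EnrichmentReport:
    """Classify aligned-read intervals against target regions.

    A read is on-target when it overlaps the target by at least
    ``min_overlap`` bp (default: any overlap).  Reads on contigs absent from
    the region set are counted as unassigned with a warning.  The density
    ratio compares read density per target bp with density per complement bp;
    it is reported as None when undefined.
    """
    trees: dict[str, IntervalTree] = {}
    for contig, s, e in regions.target:
        trees.setdefault(contig, IntervalTree()).addi(s, e)

    on = off = unassigned = 0
    unknown_contigs: set[str] = set()
    for contig, start, end in reads:
        if contig not in regions.contig_lengths:
            unknown_contigs.add(contig)
            unassigned += 1
            continue
        tree = trees.get(contig)
        overlap = 0
        if tree is not None:
            for iv in tree.overlap(start, end):
                overlap += min(end, iv.end) - max(start, iv.begin)
        if overlap >= min_overlap:
            on += 1
        else:
            off += 1
    if unknown_contigs:
        warnings.warn(
            f"{unassigned} read(s) on contigs absent from the target genome "
            f"({', '.join(sorted(unknown_contigs))}); counted as unassigned",
            stacklevel=2,
        )

    assigned = on + off
    fraction = on / assigned if assigned else None
    target_bp = regions.target_bp()
    comp_bp = regions.complement_bp()
    if assigned and target_bp and comp_bp and off:
        density_ratio = (on / target_bp) / (off / comp_bp)
    elif assigned and target_bp and comp_bp and on:
        density_ratio = float("inf")
    else:
        density_ratio = None
    return EnrichmentReport(
        on_target=on,
        off_target=off,
        unassigned=unassigned,
        on_target_fraction=fraction,
        density_ratio=density_ratio,
    )


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three columns of a BED file."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return intervals


def write_bed(
    intervals: Iterable[tuple[str, int, int]], path: str | Path, name: str | None = None
) -> None:
    with open(path, "w") as fh:
        for contig, s, e in intervals:
            if name is None:
                fh.write(f"{contig}\t{s}\t{e}\n")
            else:
                fh.write(f"{contig}\t{s}\t{e}\t{name}\n")
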