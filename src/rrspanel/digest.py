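"""In-silico restriction digestion of genome assemblies.

Enumerates every occurrence of each enzyme's recognition sequence on a set of
contigs (overlapping occurrences included), converts occurrences to cut
coordinates, and tiles each contig into restriction fragments.  Contigs are
treated as linear molecules; for non-palindromic recognition sequences the
reverse strand is also scanned and cut positions are mapped back to top-strand
coordinates.

Coordinates are 0-based half-open throughout (BED convention).  A cut at
position ``p`` separates base ``p-1`` from base ``p``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .enzymes import Enzyme, get_enzyme, reverse_complement

__all__ = [
    "CutSite",
    "Fragment",
    "read_fasta",
    "find_cut_sites",
    "digest",
    "combine_digests",
    "enzyme_combination_label",
    "all_enzyme_combinations",
    "fragments_to_bed",
    "cut_sites_to_tsv",
    "write_fragment_fasta",
]


@dataclass(frozen=True)
class CutSite:
    """A cleavage point: the phosphodiester bond before base ``position``."""

    contig: str
    position: int
    enzyme: str


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment as a half-open interval on one contig."""

    contig: str
    start: int
    end: int
    sequence: str | None = field(default=None, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an upper-cased per-contig sequence dict."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def _occurrences(haystack: str, needle: str) -> Iterable[int]:
    """Yield all (overlapping) start indices of needle in haystack."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def find_cut_sites(
    genome: Mapping[str, str], enzymes: Sequence[Enzyme | str]
) -> list[CutSite]:
    """Locate every cut produced by ``enzymes`` on ``genome``.

    Every occurrence of a recognition sequence yields a cut at
    ``occurrence_start + cut_offset``; overlapping occurrences all count.  For
    non-palindromic enzymes the bottom strand is scanned as well, with the cut
    reported in top-strand coordinates.  Cuts at a contig boundary (position 0
    or the contig length) would not separate anything and are dropped.  The
    result is sorted by (contig, position) and deduplicated on coordinates,
    keeping the first contributing enzyme name.
    """
    if not genome:
        raise ValueError("empty genome: no contigs to digest")
    resolved = [get_enzyme(e) for e in enzymes]
    if not resolved:
        raise ValueError("no enzymes supplied")

    sites: list[CutSite] = []
    for contig in genome:
        seq = genome[contig].upper()
        length = len(seq)
        seen: dict[int, str] = {}
        for enz in resolved:
            positions = [
                start + enz.cut_offset
                for start in _occurrences(seq, enz.recognition)
            ]
            if not enz.is_palindromic:
                # bottom-strand occurrence at top-strand index s corresponds to
                # a recognition site read 3'->5'; its cut sits cut_offset bases
                # from the site's right edge in top-strand coordinates
                rc = reverse_complement(enz.recognition)
                site_len = len(enz.recognition)
                positions.extend(
                    start + site_len - enz.cut_offset
                    for start in _occurrences(seq, rc)
                )
            for pos in positions:
                if 0 < pos < length and pos not in seen:
                    seen[pos] = enz.name
        sites.extend(
            CutSite(contig, pos, seen[pos]) for pos in sorted(seen)
        )
    return sites


def digest(
    genome: Mapping[str, str],
    enzymes: Sequence[Enzyme | str],
    with_sequence: bool = False,
) -> list[Fragment]:
    """Digest ``genome`` with the union of ``enzymes``.

    Per contig, fragments are the intervals between consecutive elements of
    ``{0} | cut positions | {contig length}``; a contig with no cuts yields a
    single full-length fragment.  Fragments tile each contig exactly.
    """
    sites = find_cut_sites(genome, enzymes)
    cuts_by_contig: dict[str, list[int]] = {}
    for site in sites:
        cuts_by_contig.setdefault(site.contig, []).append(site.position)

    fragments: list[Fragment] = []
    for contig, seq in genome.items():
        bounds = [0, *cuts_by_contig.get(contig, []), len(seq)]
        for start, end in itertools.pairwise(bounds):
            fragments.append(
                Fragment(
                    contig,
                    start,
                    end,
                    sequence=seq[start:end].upper() if with_sequence else None,
                )
            )
    return fragments


def enzyme_combination_label(enzymes: Sequence[Enzyme | str]) -> str:
    """Canonical label for an enzyme combination, e.g. ``"AluI/EcoRI"``."""
    return "/".join(get_enzyme(e).name for e in enzymes)


def all_enzyme_combinations(
    enzymes: Sequence[Enzyme | str], min_size: int = 2
) -> list[list[Enzyme]]:
    """All subsets of ``enzymes`` of size >= ``min_size``, smallest first."""
    resolved = [get_enzyme(e) for e in enzymes]
    return [
        list(combo)
        for r in range(min_size, len(resolved) + 1)
        for combo in itertools.combinations(resolved, r)
    ]


def combine_digests(
    genome: Mapping[str, str],
    enzyme_sets: Sequence[Sequence[Enzyme | str]],
    with_sequence: bool = False,
) -> dict[str, list[Fragment]]:
    """Digest ``genome`` independently with each enzyme combination.

    Returns fragment lists keyed by combination label.  Duplicate labels are
    rejected rather than silently overwritten.
    """
    if not enzyme_sets:
        raise ValueError("at least one enzyme combination is required")
    out: dict[str, list[Fragment]] = {}
    for combo in enzyme_sets:
        label = enzyme_combination_label(combo)
        if label in out:
            raise ValueError(f"duplicate enzyme combination label {label!r}")
        out[label] = digest(genome, combo, with_sequence=with_sequence)
    return out


def fragments_to_bed(
    fragments: Iterable[Fragment], path: str | Path, name: str = "fragment"
) -> None:
    """Write fragments as BED6 with the fragment length in the score column."""
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(
                f"{frag.contig}\t{frag.start}\t{frag.end}\t{name}\t{frag.length}\t+\n"
            )


def cut_sites_to_tsv(sites: Iterable[CutSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tenzyme\n")
        for site in sites:
            fh.write(f"{site.contig}\t{site.position}\t{site.enzyme}\n")


def write_fragment_fasta(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write fragment sequences (requires digest(with_sequence=True))."""
    with open(path, "w") as fh:
        for frag in fragments:
            if frag.sequence is None:
                raise ValueError("fragments carry no sequence; re-digest with with_sequence=True")
            fh.write(f">{frag.contig}:{frag.start}-{frag.end}\n{frag.sequence}\n")
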