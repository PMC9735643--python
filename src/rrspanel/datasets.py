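"""Bundled example datasets.

Currently one dataset ships with the package: a published pairwise Nei's
(1972) genetic distance matrix across ten Cannabis sativa varieties (four
high-CBD and six high-THC lines, genotyped at ~3600 reduced-representation
SNPs).  It is small, printed to four decimals, and useful as a worked example
for distance summaries and unrooted tree construction: the two near-clonal
variety pairs (CBD1/CBD2 and Mot/BV) give the two smallest distances.
"""

from __future__ import annotations

from importlib import resources

from .distance import DistanceMatrix

__all__ = ["nei_d_10_varieties"]


def nei_d_10_varieties() -> DistanceMatrix:
    """Pairwise Nei's D across ten Cannabis varieties (published matrix)."""
    ref = resources.files("rrspanel").joinpath("data/nei_d_10_varieties.tsv")
    with resources.as_file(ref) as path:
        return DistanceMatrix.from_tsv(
            path, measure="nei_1972", source="bundled example dataset"
        )
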