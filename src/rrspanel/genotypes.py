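"""Genotype matrices and VCF / population-map input-output.

The central container is :class:`GenotypeMatrix`: an individuals x loci array
of alt-allele dosages (0, 1, 2, or -1 for a missing call) together with the
per-genotype read depths, per-site quality scores, locus coordinates, and the
variety (population) label of every individual.  All filtering and population
genetics in this package operates on this container; VCF files are read
through cyvcf2 and written as plain VCF v4.2 text with GT:DP genotype fields.

Sites are restricted to biallelic SNPs on input: multi-allelic records are
split into one biallelic record per alt allele (genotypes carrying other alt
alleles become missing for that record) and indel records are dropped by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["GenotypeMatrix", "read_popmap", "write_popmap"]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci alt-allele dosage matrix.

    Attributes
    ----------
    dosages : (n_individuals, n_loci) int8 array
        Alt-allele dosage per genotype; ``-1`` marks a missing call.
    depths : (n_individuals, n_loci) int32 array
        Per-genotype read depth (DP); ``-1`` when absent.
    quals : (n_loci,) float array of site quality scores.
    contigs, positions : per-locus coordinates (positions 1-based, VCF style).
    ref, alt : per-locus alleles.
    individuals : sample identifiers.
    varieties : per-individual variety / population label ("" if unmapped).
    """

    dosages: np.ndarray
    depths: np.ndarray
    quals: np.ndarray
    contigs: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    individuals: list[str]
    varieties: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        n_ind, n_loci = self.dosages.shape
        if self.depths.shape != (n_ind, n_loci):
            raise ValueError("depths shape does not match dosages")
        for name, arr in (
            ("quals", self.quals),
            ("contigs", self.contigs),
            ("positions", self.positions),
            ("ref", self.ref),
            ("alt", self.alt),
        ):
            if len(arr) != n_loci:
                raise ValueError(f"{name} length {len(arr)} != n_loci {n_loci}")
        if len(self.individuals) != n_ind:
            raise ValueError("individuals length does not match dosage rows")
        if not self.varieties:
            self.varieties = [""] * n_ind
        if len(self.varieties) != n_ind:
            raise ValueError("varieties length does not match individuals")

    # -- basic geometry -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def missing_fraction_per_individual(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_individuals)
        return (self.dosages == MISSING).mean(axis=1)

    def call_rate_per_site(self) -> np.ndarray:
        if self.n_individuals == 0:
            return np.zeros(self.n_loci)
        return (self.dosages != MISSING).mean(axis=0)

    # -- per-site statistics --------------------------------------------

    def alt_allele_counts(self) -> np.ndarray:
        """Alt-allele count per site over called genotypes."""
        d = self.dosages.astype(np.int64)
        return np.where(d == MISSING, 0, d).sum(axis=0)

    def called_allele_totals(self) -> np.ndarray:
        return 2 * (self.dosages != MISSING).sum(axis=0)

    def alt_allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per site; NaN where no genotype is called."""
        totals = self.called_allele_totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.alt_allele_counts() / totals, np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.alt_allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def minor_allele_counts(self) -> np.ndarray:
        ac = self.alt_allele_counts()
        return np.minimum(ac, self.called_allele_totals() - ac)

    def mean_depth_per_site(self) -> np.ndarray:
        """Mean DP per site over all individuals (uncalled included)."""
        d = np.where(self.depths < 0, 0, self.depths)
        return d.mean(axis=0) if self.n_individuals else np.zeros(self.n_loci)

    # -- subsetting ------------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            dosages=self.dosages[:, index],
            depths=self.depths[:, index],
            quals=np.asarray(self.quals)[index],
            contigs=np.asarray(self.contigs)[index],
            positions=np.asarray(self.positions)[index],
            ref=np.asarray(self.ref)[index],
            alt=np.asarray(self.alt)[index],
            individuals=list(self.individuals),
            varieties=list(self.varieties),
        )

    def take_individuals(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return replace(
            self,
            dosages=self.dosages[index, :],
            depths=self.depths[index, :],
            individuals=[self.individuals[i] for i in index],
            varieties=[self.varieties[i] for i in index],
        )

    def with_varieties(self, popmap: dict[str, str]) -> "GenotypeMatrix":
        """Attach variety labels from an individual -> variety mapping."""
        missing = [s for s in self.individuals if s not in popmap]
        if missing:
            raise KeyError(f"individuals absent from population map: {missing[:5]}")
        return replace(self, varieties=[popmap[s] for s in self.individuals])

    def sort_by_position(self) -> "GenotypeMatrix":
        order = np.lexsort((np.asarray(self.positions), np.asarray(self.contigs)))
        return self.take_sites(order)

    def is_position_sorted(self) -> bool:
        contigs = np.asarray(self.contigs)
        positions = np.asarray(self.positions)
        for contig in dict.fromkeys(contigs.tolist()):
            pos = positions[contigs == contig]
            if np.any(np.diff(pos) < 0):
                return False
        return True

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_vcf(
        cls,
        path: str | Path,
        popmap: dict[str, str] | None = None,
        drop_indels: bool = True,
    ) -> "GenotypeMatrix":
        """Load biallelic SNP dosages from a VCF (plain or bgzipped).

        Multi-allelic records are split into one biallelic site per alt
        allele; genotypes carrying a different alt allele at that site are
        set to missing.  Indel alleles are skipped unless ``drop_indels`` is
        False.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=False)
        individuals = list(vcf.samples)
        n = len(individuals)

        dosage_cols: list[np.ndarray] = []
        depth_cols: list[np.ndarray] = []
        quals: list[float] = []
        contigs: list[str] = []
        positions: list[int] = []
        refs: list[str] = []
        alts: list[str] = []

        for rec in vcf:
            try:
                dp = np.asarray(rec.format("DP")).reshape(n).astype(np.int32)
                dp = np.where(dp < 0, -1, dp)
            except (TypeError, ValueError, KeyError):
                dp = np.full(n, -1, dtype=np.int32)
            gts = np.array(rec.genotypes, dtype=np.int32)  # rows: [a1, a2, phased]
            alleles = gts[:, :2]
            for alt_idx, alt_allele in enumerate(rec.ALT, start=1):
                if drop_indels and (
                    len(rec.REF) != 1 or len(alt_allele) != 1 or alt_allele == "*"
                ):
                    continue
                called = np.all(alleles >= 0, axis=1)
                # genotypes containing a third allele are uninformative for
                # this biallelic split
                foreign = np.any((alleles > 0) & (alleles != alt_idx), axis=1)
                dos = (alleles == alt_idx).sum(axis=1).astype(np.int8)
                dos[~called | foreign] = MISSING
                dosage_cols.append(dos)
                depth_cols.append(dp)
                quals.append(rec.QUAL if rec.QUAL is not None else 0.0)
                contigs.append(rec.CHROM)
                positions.append(rec.POS)
                refs.append(rec.REF)
                alts.append(alt_allele)
        vcf.close()

        n_loci = len(dosage_cols)
        gm = cls(
            dosages=(
                np.stack(dosage_cols, axis=1)
                if n_loci
                else np.zeros((n, 0), dtype=np.int8)
            ),
            depths=(
                np.stack(depth_cols, axis=1)
                if n_loci
                else np.zeros((n, 0), dtype=np.int32)
            ),
            quals=np.array(quals, dtype=float),
            contigs=np.array(contigs, dtype=object),
            positions=np.array(positions, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            alt=np.array(alts, dtype=object),
            individuals=individuals,
        )
        if popmap is not None:
            gm = gm.with_varieties(popmap)
        return gm

    def to_vcf(self, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
        """Write the matrix as sorted plain-text VCF v4.2 with GT:DP fields."""
        order = np.lexsort((np.asarray(self.positions), np.asarray(self.contigs)))
        gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=rrspanel\n")
            seen: list[str] = []
            for c in np.asarray(self.contigs)[order]:
                if c not in seen:
                    seen.append(c)
            for c in seen:
                if contig_lengths and c in contig_lengths:
                    fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
                else:
                    fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.individuals)
                + "\n"
            )
            for j in order:
                fields = [
                    str(self.contigs[j]),
                    str(int(self.positions[j])),
                    ".",
                    str(self.ref[j]),
                    str(self.alt[j]),
                    f"{float(self.quals[j]):g}",
                    "PASS",
                    ".",
                    "GT:DP",
                ]
                for i in range(self.n_individuals):
                    dp = int(self.depths[i, j])
                    dp_str = "." if dp < 0 else str(dp)
                    fields.append(f"{gt_strings[int(self.dosages[i, j])]}:{dp_str}")
                fh.write("\t".join(fields) + "\n")


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column (individual, variety) TSV into a dict."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ind, variety = line.split("\t")[:2]
            if ind in ("individual", "sample"):  # tolerate a header row
                continue
            popmap[ind] = variety
    return popmap


def write_popmap(popmap: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = popmap.items() if isinstance(popmap, dict) else popmap
    with open(path, "w") as fh:
        fh.write("individual\tvariety\n")
        for ind, variety in items:
            fh.write(f"{ind}\t{variety}\n")
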