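"""Seeded synthetic-data generators for every fixture the pipeline needs.

Three generators are provided, each fully deterministic under a fixed seed:

* :func:`make_genome` — a random-background genome with restriction-enzyme
  recognition sites planted at known positions (and, in exclusive mode, a
  background guaranteed free of accidental occurrences), so the digest engine
  can be checked against an exhaustive truth table;
* :func:`simulate_population` — a multi-variety diploid SNP population with
  the structure the classification workflow is designed to resolve: clonal
  varieties copied from Balding-Nichols-diverged founders, one seed-derived
  (sibling-family) variety with elevated within-variety diversity, two
  variety pairs sharing a founder (so 10 labels collapse to 8 genetic
  clusters), planted high-missingness individuals to exercise cohort
  clean-up, and per-genotype Poisson read depths straddling the depth
  filters;
* :func:`make_annotation_fixture` — features and SNP positions laid out so
  the proximity classifier yields exactly a requested category census.

The population generator draws an ancestral allele frequency per locus from
Beta(a, b), then founder frequencies from the Balding-Nichols distribution
Beta(p(1-F)/F, (1-p)(1-F)/F); F controls founder divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import Feature
from .enzymes import Enzyme, get_enzyme
from .genotypes import GenotypeMatrix

__all__ = [
    "SyntheticGenomeConfig",
    "VarietyConfig",
    "SyntheticPopulationConfig",
    "PopulationTruth",
    "make_genome",
    "simulate_population",
    "make_annotation_fixture",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    """Layout of a genome with planted recognition sites.

    ``planted`` maps enzyme (name or Enzyme) to either an integer spacing
    (one site every ``spacing`` bp per contig) or an explicit mapping of
    contig -> list of site start positions.  With ``exclusive`` set, the
    random background is scrubbed of accidental occurrences of every planted
    enzyme's recognition sequence, so the truth table is exhaustive.
    """

    contig_lengths: Mapping[str, int]
    planted: Mapping[str, int | Mapping[str, Sequence[int]]] = field(
        default_factory=dict
    )
    gc_content: float = 0.41
    exclusive: bool = True
    seed: int = 0


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _scrub(seq: np.ndarray, motifs: list[str], rng: np.random.Generator,
           protected: np.ndarray) -> None:
    """Destroy unprotected occurrences of each motif by point mutation."""
    text = "".join(_BASES[seq])
    for motif in motifs:
        start = text.find(motif)
        while start != -1:
            span = np.arange(start, start + len(motif))
            if not protected[span].any():
                # mutate the middle base to something else
                mid = start + len(motif) // 2
                current = seq[mid]
                choices = [b for b in range(4) if b != current]
                seq[mid] = rng.choice(choices)
                text = "".join(_BASES[seq])
                start = text.find(motif, start)
            else:
                start = text.find(motif, start + 1)


def make_genome(
    config: SyntheticGenomeConfig,
) -> tuple[dict[str, str], list[tuple[str, int, str]]]:
    """Generate a genome and the truth table of planted sites.

    Returns the per-contig sequences and a list of (contig, site_start,
    enzyme_name) truth records.  Spacing smaller than the recognition length
    is rejected; planted sites never overlap one another.
    """
    rng = np.random.default_rng(config.seed)
    enzymes: dict[str, Enzyme] = {}
    for key in config.planted:
        enz = get_enzyme(key)
        enzymes[enz.name] = enz

    genome: dict[str, str] = {}
    truth: list[tuple[str, int, str]] = []
    for contig, length in config.contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig} has non-positive length")
        seq = _random_background(rng, length, config.gc_content)
        protected = np.zeros(length, dtype=bool)

        plan: list[tuple[int, Enzyme]] = []
        for key, spec in config.planted.items():
            enz = enzymes[get_enzyme(key).name]
            site_len = len(enz.recognition)
            if isinstance(spec, int):
                if spec < site_len:
                    raise ValueError(
                        f"spacing {spec} smaller than recognition length "
                        f"{site_len} for {enz.name}"
                    )
                starts = list(range(spec, length - site_len, spec))
            else:
                starts = [int(p) for p in spec.get(contig, [])]
            for s in starts:
                if s < 0 or s + site_len > length:
                    raise ValueError(f"planted site at {s} outside contig {contig}")
                plan.append((s, enz))

        plan.sort(key=lambda t: t[0])
        occupied_end = -1
        for s, enz in plan:
            if s <= occupied_end:
                raise ValueError(
                    f"planted sites overlap at {contig}:{s}; adjust spacing"
                )
            site_idx = np.array(
                ["ACGT".index(b) for b in enz.recognition], dtype=seq.dtype
            )
            seq[s : s + len(site_idx)] = site_idx
            protected[s : s + len(site_idx)] = True
            occupied_end = s + len(site_idx) - 1
            truth.append((contig, s, enz.name))

        if config.exclusive and enzymes:
            # scrub accidental occurrences (including ones created by
            # planting); repeat until clean since a fix can create a new hit
            motifs = [e.recognition for e in enzymes.values()]
            for _ in range(50):
                text = "".join(_BASES[seq])
                dirty = False
                for motif in motifs:
                    start = text.find(motif)
                    while start != -1:
                        if not protected[start : start + len(motif)].any():
                            dirty = True
                            break
                        start = text.find(motif, start + 1)
                    if dirty:
                        break
                if not dirty:
                    break
                _scrub(seq, motifs, rng, protected)
        genome[contig] = "".join(_BASES[seq])
    return genome, truth


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarietyConfig:
    """One labelled variety: size, founder identity, and propagation mode."""

    name: str
    n_individuals: int
    founder_id: str
    propagation: str = "clonal"  # or "seed"

    def __post_init__(self) -> None:
        if self.propagation not in ("clonal", "seed"):
            raise ValueError("propagation must be 'clonal' or 'seed'")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def default_varieties() -> list[VarietyConfig]:
    """The default 10-variety, 87-plant cohort.

    Six high-THC varieties (5 x 10 plants + THC1 x 5), four high-CBD
    varieties (Bu x 5, SDA x 17 seed-derived, CBD1/CBD2 x 5 each).  CBD1/CBD2
    and Mot/BV share founders, so the 10 labels carry 8 genetic clusters.
    """
    return [
        VarietyConfig("AK", 10, "F_AK"),
        VarietyConfig("BV", 10, "F_BV_Mot"),
        VarietyConfig("CJ", 10, "F_CJ"),
        VarietyConfig("MB", 10, "F_MB"),
        VarietyConfig("Mot", 10, "F_BV_Mot"),
        VarietyConfig("THC1", 5, "F_THC1"),
        VarietyConfig("Bu", 5, "F_Bu"),
        VarietyConfig("SDA", 17, "F_SDA", propagation="seed"),
        VarietyConfig("CBD1", 5, "F_CBD"),
        VarietyConfig("CBD2", 5, "F_CBD"),
    ]


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    """Parameters of the multi-variety genotype simulator.

    ``divergence_f`` is the Balding-Nichols F separating founders from the
    ancestral pool; ``clonal_error`` the per-genotype probability that a
    clone's call is re-drawn rather than copied; ``missing_rate`` the
    background no-call rate; ``n_poor_individuals`` individuals (spread
    across varieties) receive ``poor_missing_rate`` no-calls to exercise
    cohort clean-up; DP is Poisson(``mean_depth``).
    """

    varieties: tuple[VarietyConfig, ...] = field(
        default_factory=lambda: tuple(default_varieties())
    )
    n_loci: int = 3600
    n_contigs: int = 10
    contig_length: int = 90_000_000
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    divergence_f: float = 0.15
    clonal_error: float = 0.005
    missing_rate: float = 0.10
    n_poor_individuals: int = 4
    poor_missing_rate: float = 0.70
    mean_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 < self.divergence_f < 1:
            raise ValueError("divergence_f must be in (0, 1)")
        for name in ("clonal_error", "missing_rate", "poor_missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PopulationTruth:
    """Ground truth carried alongside a simulated population."""

    founder_frequencies: dict[str, np.ndarray]
    founder_of_variety: dict[str, str]
    true_cluster: dict[str, int]  # individual -> cluster id (1..k)
    n_true_clusters: int
    poor_individuals: list[str]

    def write_tsvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "truth_clusters.tsv", "w") as fh:
            fh.write("individual\ttrue_cluster\n")
            for ind, c in self.true_cluster.items():
                fh.write(f"{ind}\t{c}\n")
        with open(outdir / "truth_poor_individuals.tsv", "w") as fh:
            fh.write("individual\n")
            for ind in self.poor_individuals:
                fh.write(f"{ind}\n")


def simulate_population(
    config: SyntheticPopulationConfig = SyntheticPopulationConfig(),
) -> tuple[GenotypeMatrix, PopulationTruth]:
    """Simulate the multi-variety diploid SNP cohort.

    Loci are guaranteed segregating across the cohort (monomorphic draws are
    resampled), positions are sorted within ``n_contigs`` equally sized
    contigs, and the returned matrix carries variety labels.  Ground truth
    (founder frequencies, true cluster ids, planted poor individuals) is
    returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    varieties = list(config.varieties)
    founder_ids = list(dict.fromkeys(v.founder_id for v in varieties))
    a, b = config.ancestral_beta
    f = config.divergence_f

    individuals: list[str] = []
    labels: list[str] = []
    for v in varieties:
        for i in range(v.n_individuals):
            individuals.append(f"{v.name}_{i + 1:02d}")
            labels.append(v.name)
    n_ind = len(individuals)

    # draw loci in batches, keeping only cohort-segregating ones
    founder_freqs: dict[str, list[np.ndarray]] = {fid: [] for fid in founder_ids}
    dosage_cols: list[np.ndarray] = []
    target = config.n_loci
    while len(dosage_cols) < target:
        batch = max(64, int((target - len(dosage_cols)) * 1.3))
        p0 = rng.beta(a, b, size=batch)
        p0 = np.clip(p0, 1e-3, 1 - 1e-3)
        pf = {
            fid: np.clip(
                rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f), 0.0, 1.0
            )
            for fid in founder_ids
        }
        # one founder genotype per founder id: varieties sharing a founder are
        # clones of the same plant, which is what makes their labels
        # genetically unresolvable
        founder_gt_of = {
            fid: rng.binomial(2, pf[fid]).astype(np.int8) for fid in founder_ids
        }
        batch_dosages = np.zeros((n_ind, batch), dtype=np.int8)
        row = 0
        for v in varieties:
            freqs = pf[v.founder_id]
            if v.propagation == "clonal":
                founder_gt = founder_gt_of[v.founder_id]
                for _ in range(v.n_individuals):
                    gt = founder_gt.copy()
                    if config.clonal_error > 0:
                        err = rng.random(batch) < config.clonal_error
                        gt[err] = rng.binomial(2, freqs[err]).astype(np.int8)
                    batch_dosages[row] = gt
                    row += 1
            else:  # seed: full-sib family from two parents of the founder pool
                mother = rng.binomial(2, freqs).astype(np.int8)
                father = rng.binomial(2, freqs).astype(np.int8)
                for _ in range(v.n_individuals):
                    allele_m = rng.binomial(1, mother / 2.0)
                    allele_f = rng.binomial(1, father / 2.0)
                    batch_dosages[row] = (allele_m + allele_f).astype(np.int8)
                    row += 1
        segregating = ~np.all(batch_dosages == batch_dosages[0, :], axis=0)
        keep = np.where(segregating)[0][: target - len(dosage_cols)]
        for j in keep:
            dosage_cols.append(batch_dosages[:, j].copy())
            for fid in founder_ids:
                founder_freqs[fid].append(pf[fid][j])

    dosages = np.stack(dosage_cols, axis=1)
    n_loci = dosages.shape[1]

    # genomic coordinates: n_contigs contigs, loci split evenly, sorted
    per_contig = np.full(config.n_contigs, n_loci // config.n_contigs)
    per_contig[: n_loci % config.n_contigs] += 1
    contigs_arr: list[str] = []
    positions: list[int] = []
    for ci, count in enumerate(per_contig):
        # rejection-free unique draw: oversample, dedupe, top up
        pos = np.unique(
            rng.integers(1, config.contig_length, size=int(count * 1.2) + 8)
        )
        while len(pos) < count:
            extra = rng.integers(1, config.contig_length, size=count)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.permutation(pos)[:count])
        contigs_arr.extend([f"chr{ci + 1}"] * count)
        positions.extend(int(p) for p in pos)

    # missingness: background rate everywhere, elevated on planted individuals
    missing = rng.random(dosages.shape) < config.missing_rate
    poor: list[str] = []
    if config.n_poor_individuals > 0:
        # spread the poor individuals across distinct varieties: the last
        # member of every i-th variety until the quota is filled
        starts = np.cumsum([0] + [v.n_individuals for v in varieties])
        candidate_rows = [int(starts[i + 1] - 1) for i in range(len(varieties))]
        chosen = candidate_rows[: config.n_poor_individuals]
        for r in chosen:
            missing[r] = rng.random(n_loci) < config.poor_missing_rate
            poor.append(individuals[r])
    dosages = dosages.copy()
    dosages[missing] = -1

    depths = rng.poisson(config.mean_depth, size=dosages.shape).astype(np.int32)
    quals = rng.uniform(50.0, 1500.0, size=n_loci)

    ref = np.array(["A"] * n_loci, dtype=object)
    alt = np.array(["G"] * n_loci, dtype=object)

    gm = GenotypeMatrix(
        dosages=dosages,
        depths=depths,
        quals=quals,
        contigs=np.array(contigs_arr, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        individuals=individuals,
        varieties=labels,
    )

    cluster_of_founder = {fid: i + 1 for i, fid in enumerate(founder_ids)}
    founder_of_variety = {v.name: v.founder_id for v in varieties}
    true_cluster = {
        ind: cluster_of_founder[founder_of_variety[lab]]
        for ind, lab in zip(individuals, labels)
    }
    truth = PopulationTruth(
        founder_frequencies={
            fid: np.array(vals) for fid, vals in founder_freqs.items()
        },
        founder_of_variety=founder_of_variety,
        true_cluster=true_cluster,
        n_true_clusters=len(founder_ids),
        poor_individuals=poor,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# annotation fixture
# ---------------------------------------------------------------------------


def make_annotation_fixture(
    counts: Mapping[str, int],
    gene_flank: int = 6_000,
    ltr_flank: int = 3_000,
    feature_length: int = 1_000,
    block_gap: int = 25_000,
    contig: str = "chr1",
    flank_offset: int = 100,
) -> tuple[list[Feature], list[tuple[str, int]]]:
    """Lay out features and SNPs so classification hits a requested census.

    ``counts`` maps categories (gene, gene_flank, LTR, LTR_flank, intergenic)
    to requested SNP counts.  Each SNP gets its own feature block, blocks are
    separated by ``block_gap`` which must exceed both flank sizes so blocks
    cannot interfere.  Returns features and (contig, 1-based position) SNPs.
    """
    for cat, n in counts.items():
        if cat not in ("gene", "gene_flank", "LTR", "LTR_flank", "intergenic"):
            raise ValueError(f"unknown category {cat!r}")
        if n < 0:
            raise ValueError(f"negative count for {cat}")
    if block_gap <= max(gene_flank, ltr_flank) + feature_length:
        raise ValueError(
            "block_gap must exceed the larger flank plus the feature length"
        )
    if not 0 < flank_offset <= min(gene_flank, ltr_flank):
        raise ValueError("flank_offset must lie inside both flank sizes")

    features: list[Feature] = []
    snps: list[tuple[str, int]] = []
    cursor = block_gap
    fid = 0

    def next_block() -> int:
        nonlocal cursor
        start = cursor
        cursor += block_gap
        return start

    for _ in range(counts.get("gene", 0)):
        s = next_block()
        fid += 1
        features.append(Feature(contig, s, s + feature_length, "gene", f"gene{fid}"))
        snps.append((contig, s + feature_length // 2 + 1))  # 1-based, inside
    for _ in range(counts.get("gene_flank", 0)):
        s = next_block()
        fid += 1
        features.append(Feature(contig, s, s + feature_length, "gene", f"gene{fid}"))
        snps.append((contig, s + feature_length + flank_offset))
    for _ in range(counts.get("LTR", 0)):
        s = next_block()
        fid += 1
        features.append(Feature(contig, s, s + feature_length, "LTR", f"ltr{fid}"))
        snps.append((contig, s + feature_length // 2 + 1))
    for _ in range(counts.get("LTR_flank", 0)):
        s = next_block()
        fid += 1
        features.append(Feature(contig, s, s + feature_length, "LTR", f"ltr{fid}"))
        snps.append((contig, s + feature_length + flank_offset))
    for _ in range(counts.get("intergenic", 0)):
        s = next_block()
        snps.append((contig, s + 1))
    return features, snps


def features_to_gff3(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as GFF3 (gene / LTR_retrotransposon types)."""
    type_of = {"gene": "gene", "LTR": "LTR_retrotransposon"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\trrspanel\t{type_of[f.ftype]}\t{f.start + 1}\t{f.end}"
                f"\t.\t+\t.\tID={f.feature_id or 'feat'}\n"
            )
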