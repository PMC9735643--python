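# Methods

This note documents the models, conventions, and numerical choices behind
`rrspanel`, in the order the pipeline runs.

## In-silico digestion

A restriction enzyme is a recognition sequence over {A,C,G,T} plus a
top-strand cut offset (AluI = AGCT/2, EcoRI = GAATTC/1, PstI = CTGCAG/5).
Digestion enumerates every occurrence of the recognition sequence —
overlapping occurrences included, matching an exhaustive window scan — and
cuts at `occurrence_start + offset`. Conventions, chosen where a real
instrument or protocol is silent:

- Bases outside {A,C,G,T} (N runs, IUPAC ambiguity codes) never match. On
  draft assemblies this under-predicts fragments rather than inventing cut
  sites inside gap fill.
- Contigs are linear; no circular topology (plant nuclear assemblies).
- For non-palindromic recognition sequences the reverse complement is also
  scanned, with bottom-strand cuts mapped to top-strand coordinate
  `site_start + site_length − offset`. The three built-ins are palindromic,
  so this path matters only for user-supplied enzymes.
- Coordinates are 0-based half-open (BED-compatible) throughout; fragments
  per contig tile it exactly, so fragment lengths always sum to contig
  length.

## Fragment profiles and smear analysis

Fragment-size histograms carry two tracks per bin: fragment **count** (molar
proxy — each fragment is one molecule) and fragment **mass** (summed length,
proportional to DNA mass at one genome copy). Both are reported because
electrophoretic traces weight by mass while molarity drives library yield;
only the *rank order* of enzyme combinations is comparable with
instrument-reported nmol/L.

Defaults: 1 bp bins, Savitzky–Golay smoothing with a 51-bin window and cubic
polynomial applied to the mass track (raw tracks always retained; parameters
recorded in profile metadata). A LOWESS mode is provided as an alternative
smoother with an equivalent bandwidth fraction. Size windows are inclusive
on both ends ("100 to 300 bp" includes both 100 and 300).

Target regions are the size-selected fragment intervals; the complement is
the remainder of the genome, so the two always partition it. A read is
on-target when it overlaps the target by ≥ 1 bp (a configurable minimum
overlap is available); enrichment is the density ratio
(on-reads/target-bp)/(off-reads/complement-bp), reported as missing when a
compartment is empty.

## Variant filter cascade

Stage order is fixed and logged: per-genotype depth mask (DP < 5 → missing
call) → removal of individuals with > 50% missing calls → site filters
(QUAL ≥ 30, MAC ≥ 3 over called genotypes, call rate ≥ 0.80, MAF ≥ 0.05,
mean DP over **all** individuals ≥ 25). The order matters because MAC/MAF
are computed on post-mask called genotypes; the attrition log attributes
each removed site to the first failing filter so input = output + Σ removed.
All thresholds are inclusive, matching VCFtools `--minDP` / `--min-meanDP` /
`--mac` / `--max-missing` / `--maf` semantics. The per-individual
missingness criterion (default 0.5) is this package's explicit replacement
for ad-hoc "error count" scripts; it is configurable and reported with the
removed IDs.

Panel reduction is a separate step: a stricter MAF cut (default 0.35 —
variants near 50/50 across a variety panel are the most diagnostic),
followed by positional thinning (default order: MAF then thinning, both
logged). Thinning modes:

- **greedy** (default): left-to-right scan keeping a site iff it is ≥ 1 Mb
  from the last kept site. Deterministic, keeps more sites.
- **mutual**: keep a site iff no other input site lies within 1 Mb — the
  literal "no neighbour within d" criterion; strictly sparser.

Multi-allelic records are split into biallelic sites on VCF input (genotypes
carrying a third allele become missing for that split); indels are dropped
by default.

## Proximity annotation

Each panel SNP receives exactly one category. Inside a feature → `gene` or
`LTR`; within 6 kb of a gene edge → `gene_flank`; within 3 kb of an LTR
retroelement edge → `LTR_flank`; otherwise `intergenic`. Flank limits are
inclusive (exactly 3000 bp away is still flank; 3001 is not). Overlapping
memberships are resolved by a configurable precedence, default
gene > gene_flank > LTR > LTR_flank — gene context is the more interpretable
annotation when both apply, and the choice is explicit because no standard
dictates it. Composite summaries report gene-associated (gene + gene_flank)
and LTR-associated (LTR + LTR_flank) percentages rounded to one decimal.

## Nei's distance and trees

Nei's (1972) standard distance uses arithmetic means of the identity
components over loci (the StAMPP convention): Jx, Jy, Jxy averaged over loci
defined in both populations (pairwise deletion), I = Jxy/√(JxJy),
D = −ln I. Frequencies are plain genotype-count estimates. Floating-point
can push I marginally above 1 for identical inputs; I is clamped to 1 so
D = 0 exactly. Reported matrices are rounded to 4 decimals; full precision
is kept internally.

Individual-level distances (for trees over plants rather than varieties):
`allele_mismatch` = mean |dosage difference|/2 over jointly called loci, or
Euclidean distance on locus-mean-imputed dosages.

Trees are built with neighbor joining (scikit-bio), negative branch lengths
clamped to zero. NJ is a documented choice — unrooted variety trees of this
kind rarely state their algorithm — and only topology claims (cherry
recovery for clone pairs, exact recovery on additive matrices) are asserted
by the tests, not branch lengths.

## PCA, cluster selection, DAPC

- PCA: missing dosages imputed with the locus mean, columns centered, no
  scaling by default (a flag enables it), decomposition by SVD. With all
  components retained, scores·loadingsᵀ reproduces the centered imputed
  matrix to 1e−8. 80% cumulative variance is the default retention for
  exploratory reporting.
- Cluster search: k-means (10 random starts, seed recorded) for each
  candidate k, scored by BIC(k) = n·ln(WSS/n) + k·ln(n). **The scan runs on
  the full PC score matrix**, not the 80%-truncated one: truncation loses
  nothing for clustering, and when tight clonal clusters leave almost no
  within-cluster variance in the top PCs this BIC variant degenerates
  (every split removes a large fraction of a near-zero WSS, so the argmin
  slides to k_max). In the full space, residual high-dimensional noise makes
  the criterion consistent; the same effect is why the unit tests exercise
  it with high-dimensional Gaussian clusters. The full BIC curve is always
  returned so an elbow can be read off when the minimum is shallow.
- DAPC: LDA on the PCs retaining ~40% of variance (at least k−1 PCs, and
  never more than exist) with the k-means clusters as classes; all k−1
  discriminants kept; posteriors from the shared-within-class-covariance
  Gaussian model, rows summing to 1 within 1e−9.

## Synthetic data generator

The generator exists so every pipeline stage can be tested against known
truth; its defaults are the study conditions the classification workflow is
designed for.

**Genomes.** Random background at 41% GC with recognition sites planted at
known positions; in exclusive mode accidental occurrences are scrubbed by
point mutation (iterated until clean), so the truth table is exhaustive and
digest output is exactly predictable.

**Populations.** Default cohort: 10 varieties, 87 plants
(10/10/10/10/10/5/5/17/5/5). Per locus, an ancestral frequency is drawn from
Beta(0.8, 0.8) and founder frequencies from Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.15 — a standard minimal-parameter
population-divergence model. One founder **genotype** is drawn per founder
id; two variety pairs (CBD1/CBD2 and Mot/BV analogues) share founders, so 10
labels carry 8 genetic clusters. Clonal varieties copy their founder
genotype with a 0.005 per-genotype re-draw (genotyping error / somatic
variation proxy); the one seed-derived variety (SDA, 17 plants) is a
full-sib family from two parents drawn at the founder's frequencies, giving
the elevated within-variety diversity a seed line shows. Loci are guaranteed
segregating (monomorphic draws resampled) and placed on 10 chromosomes of
90 Mb. Background missingness is 10% — typical of RRS/RADseq call sets and
comfortably inside the cascade's 0.80 call-rate filter — and 4 designated
individuals get 70% missingness to exercise cohort clean-up (87 → 83).
Depths are Poisson(30) so the DP ≥ 5 and mean-DP ≥ 25 filters see values on
both sides; site qualities are uniform on [50, 1500].

What the generator does **not** emulate: linkage disequilibrium between
loci, allele-frequency correlation between founders beyond the shared
ancestral draw, admixed individuals, depth-dependent genotype error, or
batch structure in missingness. Passing tests therefore show the pipeline's
statistics behave correctly under idealised population structure, not that
real cohorts will be as cleanly separable.

**Annotation fixtures.** Features and SNPs are laid out in isolated blocks
(25 kb apart, farther than any flank) so a requested per-category census is
achieved exactly; infeasible geometries are rejected.

## Problem sizes and determinism

Tests and the acceptance script run the default cohort (87 × 3600) and
20-replicate scans, completing in seconds on one core. All randomness flows
from explicit seeds (numpy `default_rng`; k-means seeds recorded in output);
the demo is byte-reproducible for a fixed seed.

## Known limitations

- The digest model ignores methylation sensitivity, star activity, and
  partial digestion; fragment profiles are linear-axis idealisations of
  electrophoretic traces (no gel-mobility nonlinearity or fluorescence
  calibration).
- The BIC cluster criterion over-splits low-dimensional, near-degenerate
  cluster configurations (see above); inspect the returned curve when in
  doubt.
- Nei's D assumes frequency estimates from moderate per-variety sample
  sizes; 5-plant clonal varieties make D between clone pairs an estimate of
  genotyping error more than of divergence.
- The dDocent-style "poorly sequenced individual" criterion is a simple
  missingness fraction; cohorts with depth-correlated missingness may need a
  different threshold.
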