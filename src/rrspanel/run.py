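"""End-to-end demo pipeline on synthetic data.

Stages: synthetic genome -> digest + fragment profile + smear ranking ->
synthetic population -> filter cascade -> Nei's distance + NJ tree -> panel
reduction (MAF + thinning) -> proximity annotation on a census fixture ->
PCA / BIC cluster scan / DAPC.  All randomness flows from the single seed.
A failure at any stage raises :class:`StageError` naming the stage; on
success a JSON report aggregating attrition counts, distance summaries, the
selected cluster number, and the posterior table is written to the output
directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .annotate import annotate_snps, annotations_to_table, summarize_categories, FeatureSet
from .cluster import assignplot_table, dapc_fit, genotype_pca, kmeans_bic_scan
from .digest import digest, enzyme_combination_label
from .distance import distance_summary, nei_distance_matrix, nj_tree
from .filters import FilterConfig, reduce_by_maf, run_filter_cascade, thin_by_distance
from .genotypes import write_popmap
from .profile import size_histogram, smear_summary, smooth_profile
from .synth import (
    SyntheticGenomeConfig,
    SyntheticPopulationConfig,
    features_to_gff3,
    make_annotation_fixture,
    make_genome,
    simulate_population,
    write_fasta,
)

__all__ = ["StageError", "run_demo"]


class StageError(RuntimeError):
    """Pipeline failure wrapper naming the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_demo(seed: int = 7, outdir: Path | str = "demo_out") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "stages": {}, "summary": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - named re-raise
                raise StageError(name, exc) from exc

        return wrap

    # --- digest route ------------------------------------------------
    def _genome():
        config = SyntheticGenomeConfig(
            contig_lengths={"contig1": 60_000},
            # EcoRI offset by 70 bp so sites never collide with the AluI grid
            planted={"AluI": 150, "EcoRI": {"contig1": list(range(970, 59_000, 1000))}},
            seed=seed,
        )
        genome, truth = make_genome(config)
        write_fasta(genome, outdir / "genome.fa")
        return genome, truth

    genome, truth_sites = stage("synth_genome")(_genome)

    def _digest():
        combos = [["AluI"], ["EcoRI"], ["AluI", "EcoRI"]]
        out = {}
        for combo in combos:
            label = enzyme_combination_label(combo)
            frags = digest(genome, combo)
            prof = smooth_profile(
                size_histogram(frags, (100, 1000), 1), 51, 3
            )
            smear = smear_summary(frags, (100, 300), label=label)
            out[label] = {
                "n_fragments": len(frags),
                "smear_count_100_300": smear.fragment_count,
                "smear_mass_100_300": smear.fragment_mass,
            }
            prof.to_table().to_csv(
                outdir / f"profile_{label.replace('/', '-')}.tsv",
                sep="\t", index=False,
            )
        return out

    report["stages"]["digest"] = stage("digest_profile")(_digest)

    # --- population route --------------------------------------------
    def _population():
        config = SyntheticPopulationConfig(seed=seed)
        gm, truth = simulate_population(config)
        gm.to_vcf(outdir / "population.vcf")
        write_popmap(dict(zip(gm.individuals, gm.varieties)), outdir / "popmap.tsv")
        truth.write_tsvs(outdir)
        return gm, truth

    gm, pop_truth = stage("synth_population")(_population)

    def _filter():
        filtered, logbook = run_filter_cascade(gm, FilterConfig())
        filtered.to_vcf(outdir / "filtered.vcf")
        logbook.to_table().to_csv(outdir / "attrition.tsv", sep="\t", index=False)
        report["stages"]["filter"] = {
            "input_sites": logbook.n_input_sites,
            "output_sites": filtered.n_loci,
            "removed_individuals": logbook.removed_individuals,
            "site_attrition": dict(logbook.site_stages),
        }
        return filtered

    filtered = stage("filter_cascade")(_filter)

    def _distance():
        dm = nei_distance_matrix(filtered)
        dm.to_tsv(outdir / "nei_d.tsv")
        summary = distance_summary(dm)
        (outdir / "tree.nwk").write_text(nj_tree(dm) + "\n")
        report["stages"]["distance"] = {
            "min_pair": list(summary["min_pair"]),
            "min_value": round(summary["min_value"], 4),
            "row_means": {k: round(v, 4) for k, v in summary["row_means"].items()},
        }

    stage("nei_distance_tree")(_distance)

    def _reduce():
        panel = thin_by_distance(reduce_by_maf(filtered, 0.35), 1_000_000, "greedy")
        panel.to_vcf(outdir / "panel.vcf")
        report["stages"]["reduce"] = {
            "full_sites": filtered.n_loci,
            "panel_sites": panel.n_loci,
        }
        return panel

    stage("panel_reduction")(_reduce)

    def _annotate():
        census = {"gene": 7, "gene_flank": 7, "LTR": 121, "LTR_flank": 37}
        features, snps = make_annotation_fixture(census)
        features_to_gff3(features, outdir / "features.gff3")
        anns = annotate_snps(snps, FeatureSet(features))
        annotations_to_table(anns).to_csv(
            outdir / "annotation.tsv", sep="\t", index=False
        )
        summary = summarize_categories(anns)
        report["stages"]["annotate"] = summary.to_dict()

    stage("proximity_annotation")(_annotate)

    def _dapc():
        pca = genotype_pca(filtered, retain_variance=0.80)
        scan = kmeans_bic_scan(pca.scores, range(1, 16), n_starts=10, seed=seed)
        fit = dapc_fit(pca, scan.selected_labels, retain_variance=0.40)
        scan.summary().to_csv(outdir / "bic_curve.tsv", sep="\t", index=False)
        assignplot_table(fit, filtered.varieties).to_csv(
            outdir / "dapc_posteriors.tsv", sep="\t", index=False
        )
        high = int((fit.posterior.max(axis=1) > 0.99).sum())
        report["stages"]["dapc"] = {
            "selected_k": scan.selected_k,
            "n_pcs_dapc": fit.n_pcs,
            "high_certainty_individuals": high,
            "n_individuals": filtered.n_individuals,
        }

    stage("pca_dapc")(_dapc)

    report["summary"] = {
        "individuals_after_filtering": filtered.n_individuals,
        "sites_after_filtering": filtered.n_loci,
        "selected_k": report["stages"]["dapc"]["selected_k"],
        "high_certainty_individuals": report["stages"]["dapc"][
            "high_certainty_individuals"
        ],
        "closest_pair": report["stages"]["distance"]["min_pair"],
        "ltr_associated_pct": report["stages"]["annotate"]["ltr_associated_pct"],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
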