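"""End-to-end orchestration: simulate -> call-sfp -> call-segments ->
enrich -> associate -> sweep-scan -> report.

Each stage reads its inputs from and writes its outputs to a run
directory as plain TSV/GFF3, so stages can be re-run individually from
the CLI. A manifest records parameters, derived per-stage seeds and
per-output row counts; re-running with an identical config reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import enrichment as enr
from . import io
from . import segments as seg
from . import sfp
from . import sweep as swp
from . import synthetic as syn
from .config import RunConfig, SimConfig, SweepSpec
from .types import DataError


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the global
    seed and the stage name."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return int((seed * 2654435761 + h) % (2**31 - 1))


def desk_run_config(seed: int = 0) -> RunConfig:
    """Desk-scale study configuration.

    Genome and window parameters are scaled together so the sweep scan
    retains its geometry: ~14000 probes with a sweep occupying a few
    percent of them (pairwise-sharing moments are genome-wide, so a sweep
    that dominates the genome would standardise itself away), windows of
    100 SFPs advancing by 5, and outliers at the top 10% (the published
    1000/50/0.5% values assume ~600k sites; a 0.5% outlier budget at desk
    scale could never fill 45% of a window, so the quantile scales with
    the window).
    """
    sim = SimConfig(
        seed=seed,
        probes_per_chromosome=7000,
        sweep_spec=SweepSpec(chrom=0, start_probe=1000, n_probes=220,
                             carrier_fraction=0.45, marker_rate=0.6),
    )
    return RunConfig(seed=seed, sim=sim, window=100, offset=5,
                     outlier_quantile=0.10, n_shuffles=200)


class PipelineError(RuntimeError):
    """A stage's upstream outputs are missing."""


def _need(outdir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise PipelineError(
            f"stage {stage!r} requires missing upstream outputs: {missing}")


def run_simulate(config: RunConfig, outdir: Path) -> dict:
    sim = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
    probes = syn.generate_probe_map(sim)
    annotation = syn.generate_annotation(sim)
    pop, qmatrix, geo = syn.generate_population(sim)
    truth = syn.plant_variants(pop, sim, probes, annotation)
    intensities = syn.simulate_intensities(truth, probes, sim)
    phenotypes = syn.simulate_phenotypes(truth, qmatrix, sim)
    metabolic_genes = sorted(set(
        annotation.loc[annotation["pathway"] != "", "gene_id"]))
    network = syn.generate_metabolic_network(sim, genes=metabolic_genes or None)
    # networks annotate genes with the pathway the annotation declares
    ann_pwy = (annotation[annotation["pathway"] != ""]
               .drop_duplicates("gene_id").set_index("gene_id")["pathway"])
    for g in network.gene_pathway:
        if g in ann_pwy.index:
            network.gene_pathway[g] = str(ann_pwy[g])
    gmap_table = syn.generate_genetic_map_table(sim)

    io.write_probe_map(probes, outdir / "probe_map.tsv")
    io.write_gff3(annotation, outdir / "annotation.gff3")
    io.write_intensities(intensities, outdir / "intensities.tsv",
                         outdir / "arrays.tsv")
    io.write_qmatrix(qmatrix, outdir / "qmatrix.tsv")
    io.write_table(geo, outdir / "geo.tsv")
    io.write_table(phenotypes, outdir / "phenotypes.tsv")
    io.write_network(network, outdir / "network.tsv")
    io.write_table(gmap_table, outdir / "genetic_map.tsv")
    truth_geno = truth.genotype_truth(probes)
    io.write_genotypes(truth_geno, outdir / "truth_genotypes.tsv")
    io.write_table(truth.segments, outdir / "truth_segments.tsv")
    io.write_table(pd.DataFrame({"accession": list(truth.sweep_carriers)}),
                   outdir / "truth_sweep_carriers.tsv")
    io.write_table(pd.DataFrame(
        [{"trait": t, "probe_idx": i,
          "probe_id": probes.df["probe_id"].iloc[i]}
         for t, i in truth.causal_markers.items()]),
        outdir / "truth_causal_markers.tsv")
    return {"probes": probes.n_probes, "accessions": len(truth.accessions),
            "snp_events": len(truth.snp_probe),
            "truth_sites": len(truth_geno),
            "sweep_carriers": len(truth.sweep_carriers)}


def run_call_sfp(config: RunConfig, outdir: Path) -> dict:
    _need(outdir, "call-sfp", "intensities.tsv", "arrays.tsv", "probe_map.tsv")
    probes = io.read_probe_map(outdir / "probe_map.tsv")
    raw = io.read_intensities(outdir / "intensities.tsv", outdir / "arrays.tsv")
    norm = sfp.normalize_arrays(raw)
    fc = sfp.log2fc_matrix(norm)
    fc = fc.drop(columns=[norm.reference])
    calls = sfp.call_sfps(fc, probes, threshold=config.sfp_threshold)
    io.write_table(sfp.calls_to_bed(calls), outdir / "calls.tsv")
    geno = calls.genotype_matrix()
    geno.insert(0, norm.reference, 0)  # the reference is allele 0 everywhere
    io.write_genotypes(geno, outdir / "genotypes.tsv")
    fc.to_csv(outdir / "log2fc.tsv", sep="\t", index_label="probe_id")
    result = {"sfp_sites": int(calls.called.any(axis=1).sum()),
              "total_calls": int(calls.called.to_numpy().sum()),
              "mean_calls_per_accession": float(calls.n_calls().mean())}
    if (outdir / "truth_genotypes.tsv").exists():
        truth = io.read_genotypes(outdir / "truth_genotypes.tsv").astype(bool)
        truth_full = truth.reindex(fc.index, fill_value=False)
        report = sfp.calibrate_threshold(fc, truth_full, probes)
        io.write_table(report.roc, outdir / "calibration.tsv")
        at = report.roc.loc[(report.roc["threshold"] - config.sfp_threshold)
                            .abs().idxmin()]
        result.update(fdr_at_threshold=float(at["fdr"]),
                      fnr_at_threshold=float(at["fnr"]))
    return result


def run_call_segments(config: RunConfig, outdir: Path) -> dict:
    _need(outdir, "call-segments", "log2fc.tsv", "calls.tsv", "probe_map.tsv")
    probes = io.read_probe_map(outdir / "probe_map.tsv")
    fc = pd.read_csv(outdir / "log2fc.tsv", sep="\t", index_col="probe_id")
    calls = sfp.call_sfps(fc, probes, threshold=config.sfp_threshold)
    dels = seg.call_deletions(calls, probes, min_run=config.min_run)
    dups = seg.call_duplications(fc, probes, min_run=config.min_run,
                                 min_log2fc=config.dup_min_log2fc)
    summary = seg.summarize_segments(dels + dups)
    io.write_table(summary["segments"], outdir / "segments.tsv")
    io.write_table(summary["per_accession"], outdir / "segments_per_accession.tsv")
    io.write_table(summary["overall"], outdir / "segments_summary.tsv")
    return {"deletions": len(dels), "duplications": len(dups)}


def _feature_index(outdir: Path) -> tuple[enr.FeatureIndex, "pd.DataFrame"]:
    annotation = io.read_gff3(outdir / "annotation.gff3")
    probes = io.read_probe_map(outdir / "probe_map.tsv")
    chrom_bp = {c: int(sub["start"].max() + sub["length"].iloc[0])
                for c, sub in probes.df.groupby("chrom")}
    return enr.FeatureIndex.build(annotation, chrom_bp), probes.df


def run_enrich(config: RunConfig, outdir: Path) -> dict:
    _need(outdir, "enrich", "genotypes.tsv", "annotation.gff3",
          "probe_map.tsv", "segments.tsv")
    index, probe_df = _feature_index(outdir)
    geno = io.read_genotypes(outdir / "genotypes.tsv")
    pm = probe_df.set_index("probe_id")
    sites = pd.DataFrame({
        "chrom": pm.loc[geno.index, "chrom"].to_numpy(),
        "pos": pm.loc[geno.index, "start"].to_numpy()
        + pm.loc[geno.index, "length"].to_numpy() // 2})
    hits = enr.map_sites_to_features(sites, index)
    classes = enr.class_enrichment_table(hits, index)
    segments = io.read_table(outdir / "segments.tsv")
    families = enr.gene_family_report(hits, index, segments)
    io.write_table(classes, outdir / "enrichment_classes.tsv")
    io.write_table(families, outdir / "enrichment_families.tsv")
    io.write_table(hits, outdir / "site_features.tsv")
    return {"classes_tested": len(classes),
            "families_tested": len(families),
            "classes_significant": int((classes["p"] < 0.05).sum())}


def run_associate(config: RunConfig, outdir: Path) -> dict:
    _need(outdir, "associate", "genotypes.tsv", "phenotypes.tsv",
          "qmatrix.tsv", "network.tsv", "site_features.tsv")
    geno = io.read_genotypes(outdir / "genotypes.tsv")
    phen = io.read_table(outdir / "phenotypes.tsv")
    q = io.read_qmatrix(outdir / "qmatrix.tsv")
    fits = assoc.association_scan(geno, phen, q, min_maf=config.min_maf)
    if fits.empty:
        raise DataError("association scan produced no testable sites")
    n_sites = fits["site"].nunique()
    n_traits = fits["trait"].nunique()
    n_sig = int((fits["empirical_p"] <= config.alpha).sum())
    fdr = (assoc.estimate_fdr(n_sites, n_traits, config.alpha, n_sig)
           if n_sig else float("nan"))
    network = io.read_network(outdir / "network.tsv")
    hits = io.read_table(outdir / "site_features.tsv",
                         keep_default_na=False)
    site_ids = geno.index.to_numpy()
    hit_sites = site_ids[hits["site_idx"].to_numpy()]
    gene_hits = hits.assign(site=hit_sites)
    metabolic = gene_hits[gene_hits["gene_id"].isin(network.gene_pathway)]
    site_genes = (metabolic.drop_duplicates("site")
                  .set_index("site")["gene_id"])
    pathways = sorted({p for p in network.gene_pathway.values() if p})
    pwy = assoc.pathway_overrepresentation(fits, site_genes, network,
                                           pathways, alpha=config.pathway_alpha)
    in_met = fits["site"].isin(site_genes.index).to_numpy()
    shift_p = (assoc.geneset_score_shift(fits, in_met)
               if in_met.any() and not in_met.all() else float("nan"))
    io.write_table(fits, outdir / "associations.tsv")
    io.write_table(pwy, outdir / "pathway_enrichment.tsv")
    return {"sites_tested": int(n_sites), "traits": int(n_traits),
            "significant": n_sig, "fdr_percent": float(fdr),
            "metabolic_sites": int(site_genes.size),
            "metabolic_shift_p": float(shift_p),
            "pathways_significant": int(pwy["significant"].sum())
            if len(pwy) else 0}


def run_sweep_scan(config: RunConfig, outdir: Path) -> dict:
    _need(outdir, "sweep-scan", "genotypes.tsv", "genetic_map.tsv",
          "probe_map.tsv", "geo.tsv")
    geno = io.read_genotypes(outdir / "genotypes.tsv")
    probes = io.read_probe_map(outdir / "probe_map.tsv")
    markers = io.read_table(outdir / "genetic_map.tsv")
    geo = io.read_table(outdir / "geo.tsv")
    gmap = swp.fit_genetic_map(markers, degree=config.map_degree)
    geno = assoc.maf_filter(geno, config.min_maf)
    sites = swp.sites_from_probes(geno, probes)
    data = swp.compute_sharing(geno, gmap, sites)
    raw = swp.phs_scan(data, min_maf=config.min_maf)
    scored = swp.standardize_scores(raw)
    per_site = swp.site_scores(scored)
    pruned = swp.ld_prune(per_site, geno)
    regions = swp.window_scan(pruned, window=config.window,
                              offset=config.offset,
                              outlier_quantile=config.outlier_quantile,
                              min_proportion=config.min_proportion)
    regions = [swp.avg_sharing_interval(r, data) for r in regions]
    io.write_table(scored, outdir / "phs_scores.tsv")
    io.write_table(swp.regions_to_frame(regions), outdir / "sweep_regions.tsv")
    geo_rows = []
    for r in regions:
        g = geno.loc[r.focal_site]
        carriers = [a for a in geno.columns if g[a] == r.selected_allele]
        p = swp.geographic_clustering(
            carriers, geo, n_shuffles=config.n_shuffles,
            seed=stage_seed(config.seed, f"geo-{r.name}"))
        geo_rows.append({"region": r.name, "n_carriers": len(carriers),
                         "p": p})
    io.write_table(pd.DataFrame(geo_rows, columns=["region", "n_carriers", "p"]),
                   outdir / "sweep_geography.tsv")
    result = {"sites_scanned": len(pruned), "regions": len(regions)}
    if (outdir / "associations.tsv").exists() and regions:
        fits = io.read_table(outdir / "associations.tsv")
        scan_fits = fits.merge(
            pruned[["site", "chrom", "pos"]], on="site", how="inner")
        phen = io.read_table(outdir / "phenotypes.tsv")
        q = io.read_qmatrix(outdir / "qmatrix.tsv")
        out = swp.sweep_trait_association(regions, geno, phen, q, scan_fits)
        io.write_table(out["table"], outdir / "sweep_associations.tsv")
        result["sweep_shift_p"] = float(out["shift_p"])
    return result


def run_report(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    lines = ["tilingsweep run report", "=" * 24, ""]
    stats = manifest.get("stages", {})
    if "call-sfp" in stats:
        s = stats["call-sfp"]
        lines += [f"SFP sites: {s['sfp_sites']}",
                  f"mean SFP calls per accession: "
                  f"{s['mean_calls_per_accession']:.1f}"]
        if "fdr_at_threshold" in s:
            lines += [f"calling FDR at {config.sfp_threshold}: "
                      f"{100 * s['fdr_at_threshold']:.1f}%",
                      f"calling FNR at {config.sfp_threshold}: "
                      f"{100 * s['fnr_at_threshold']:.1f}%"]
    if "call-segments" in stats:
        s = stats["call-segments"]
        lines += [f"deletions: {s['deletions']}",
                  f"duplications: {s['duplications']}"]
    if "associate" in stats:
        s = stats["associate"]
        n = s["significant"]
        lines.append(f"{n} significant association(s)" if n
                     else "0 significant associations")
        if n:
            lines.append(f"estimated FDR: {s['fdr_percent']:.0f}%")
    if (outdir / "sweep_regions.tsv").exists():
        regions = io.read_table(outdir / "sweep_regions.tsv")
        if regions.empty:
            lines += ["", "0 sweep candidate regions"]
            regions = None
    else:
        regions = None
    if regions is not None:
        lines += ["", "sweep candidate regions "
                  "(name, chr, focal position, from, to, "
                  "length of avg haplotype sharing):"]
        cols = ["name", "chr", "focal_position", "from", "to",
                "length_avg_haplotype_sharing"]
        lines.append(regions[cols].to_string(index=False))
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return {"lines": len(lines)}


_STAGES = {
    "simulate": run_simulate,
    "call-sfp": run_call_sfp,
    "call-segments": run_call_segments,
    "enrich": run_enrich,
    "associate": run_associate,
    "sweep-scan": run_sweep_scan,
}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; returns and writes
    the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "sfp_threshold": config.sfp_threshold,
            "min_run": config.min_run,
            "dup_min_log2fc": config.dup_min_log2fc,
            "min_maf": config.min_maf,
            "alpha": config.alpha,
            "window": config.window,
            "offset": config.offset,
            "outlier_quantile": config.outlier_quantile,
            "min_proportion": config.min_proportion,
            "n_shuffles": config.n_shuffles,
        },
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "stages": {},
        "outputs": [],
    }
    for stage in config.stages:
        if stage == "report":
            manifest["stages"]["report"] = run_report(config, outdir, manifest)
        else:
            manifest["stages"][stage] = _STAGES[stage](config, outdir)
    manifest["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.name != "manifest.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
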