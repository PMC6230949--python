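"""End-to-end driver: simulate -> call markers -> map -> anchor -> landscape
-> summary report.

Each stage is wrapped so failures abort with a stage-named error while
earlier outputs stay on disk.  With a fixed seed the whole run, including
the JSON report, is byte-identical across re-runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from radmap import anchor as anchor_mod
from radmap import landscape as landscape_mod
from radmap import linkage, markers, sim
from radmap import io as rio
from radmap.anchor import MAP_COLUMNS
from radmap.config import RunConfig

__all__ = ["StageError", "run_pipeline", "map_table_from", "lift_genes"]

log = logging.getLogger("radmap")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def map_table_from(gm: markers.GenotypeMatrix, lmap: linkage.LinkageMap) -> pd.DataFrame:
    """Flatten a linkage map into the map-table interchange format."""
    recs = []
    for group in lmap.groups:
        for idx, cm in zip(group.markers, group.positions_cm):
            m = gm.markers[idx]
            recs.append((group.name, m.marker_id, m.scaffold, m.pos, float(cm)))
    return pd.DataFrame(recs, columns=MAP_COLUMNS)


def lift_genes(
    genes: list[rio.Gene],
    scaffolds: list[sim.ScaffoldTruth],
    assembly: anchor_mod.AnchoredAssembly,
) -> list[rio.Gene]:
    """Move genes from true-chromosome coordinates onto pseudomolecules.

    A gene follows the scaffold containing its start; genes on unplaced
    scaffolds are dropped.
    """
    index = assembly.placement_index()
    by_chrom: dict[str, list[sim.ScaffoldTruth]] = {}
    for s in scaffolds:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.start)
    out: list[rio.Gene] = []
    for g in genes:
        lst = by_chrom.get(g.chrom)
        if not lst:
            continue
        starts = [s.start for s in lst]
        i = int(np.searchsorted(starts, g.start, side="right")) - 1
        s = lst[i]
        local = g.start - s.start if s.orientation == "+" else s.end - 1 - g.start
        info = index.get(s.scaffold_id)
        if info is None:
            continue
        chrom, offset, orientation, length = info
        pos = offset + (length - 1 - local) if orientation == "-" else offset + local
        out.append(rio.Gene(chrom, int(pos), int(pos) + (g.end - g.start), g.gene_id, g.strand))
    return out


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc

        return inner

    return wrap


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run the full synthetic-data pipeline and write all artefacts.

    Returns the report dict (also written to ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict()}

    # ------------------------------------------------------------------ simulate
    @_stage("simulate")
    def do_simulate():
        genome = sim.simulate_genome(
            cfg.n_chrom,
            cfg.n_chrom * cfg.chrom_len,
            gene_density_profile=cfg.gene_density_profile,
            mean_gene_density=cfg.mean_gene_density_per_100kb / 1e5,
            gc=cfg.gc,
            seed=cfg.seed,
        )
        land = sim.plant_landscape(
            genome,
            cfg.background_rate,
            [tuple(h) for h in cfg.hotspots],
            [tuple(c) for c in cfg.coldspots],
        )
        scaffolds = sim.fragment_scaffolds(genome, cfg.scaffold_mean_len, seed=cfg.seed + 1)
        design = sim.CrossDesign(
            n_progeny=cfg.n_progeny,
            error_rate=cfg.error_rate,
            missing_rate=cfg.missing_rate,
            mean_depth=cfg.mean_depth,
            seed=cfg.seed + 2,
        )
        gm_sim, pileup, truth = sim.simulate_cross(
            genome, land, cfg.markers_per_mb, design,
            scaffolds=scaffolds, decoys_per_mb=cfg.decoys_per_mb,
        )
        rio.write_gff3_genes(outdir / "genes.gff3", genome.genes)
        markers.write_pileup_tsv(outdir / "pileup.tsv", pileup)
        markers.write_genotype_tsv(outdir / "genotypes_simulated.tsv", gm_sim)
        rio.write_json(outdir / "truth.json", truth.summary())
        scaffold_seqs = None
        if cfg.emit_sequences:
            chrom_seqs, scaffold_seqs = sim.emit_sequences(genome, scaffolds, seed=cfg.seed + 3)
            rio.write_fasta(outdir / "genome.fasta", sorted(chrom_seqs.items()))
            rio.write_fasta(outdir / "scaffolds.fasta", sorted(scaffold_seqs.items()))
        return genome, land, scaffolds, pileup, truth, scaffold_seqs

    genome, land, scaffolds, pileup, truth, scaffold_seqs = do_simulate()
    report["simulate"] = truth.summary()

    # ------------------------------------------------------------------ markers
    @_stage("markers")
    def do_markers():
        defs = markers.define_markers(
            pileup, sim.PARENT_A, sim.PARENT_B,
            min_parent_depth=cfg.min_parent_depth,
            het_min_minor_frac=cfg.het_min_minor_frac,
        )
        gm = markers.call_genotypes(
            pileup, defs, min_depth=cfg.min_depth,
            exclude=(sim.PARENT_A, sim.PARENT_B), depth_rule=cfg.depth_rule,
        )
        gm, removal_log = markers.filter_individuals(
            gm, max_missing=cfg.max_missing,
            dup_identity=cfg.dup_identity, min_shared=cfg.min_shared,
        )
        markers.write_genotype_tsv(outdir / "genotypes_called.tsv", gm)
        rio.write_bed(
            outdir / "markers.bed",
            [(m.scaffold, m.pos, m.pos + 1, m.marker_id) for m in gm.markers],
        )
        rio.write_json(outdir / "individual_filter_log.json", removal_log)
        return gm, removal_log

    gm, removal_log = do_markers()
    report["markers"] = {
        "n_markers": gm.n_markers,
        "n_individuals": gm.n_individuals,
        "n_removed": len(removal_log),
    }

    # ------------------------------------------------------------------ map
    @_stage("map")
    def do_map():
        lmap, pairs, groups, singletons, n_masked = linkage.construct_map(
            gm.calls, cfg.max_rf, cfg.min_lod
        )
        table = map_table_from(gm, lmap)
        table.to_csv(outdir / "map.tsv", sep="\t", index=False)
        return pairs, lmap, table, singletons, n_masked

    pairs, lmap, map_table, singletons, n_masked = do_map()
    report["map"] = {
        "n_groups": len(lmap.groups),
        "n_mapped_markers": lmap.n_markers,
        "n_singletons": len(singletons),
        "n_masked_calls": n_masked,
        "total_cm": round(lmap.total_cm, 3),
        "group_cm": {g.name: round(g.length_cm, 3) for g in lmap.groups},
    }

    # ------------------------------------------------------------------ anchor
    @_stage("anchor")
    def do_anchor():
        scaffold_lengths = {s.scaffold_id: s.length for s in scaffolds}
        placements = anchor_mod.assign_scaffolds(map_table)
        assembly = anchor_mod.order_and_orient(placements, map_table, scaffold_lengths, gap=cfg.gap)
        rio.write_agp(outdir / "pseudomolecules.agp", assembly.agp_rows())
        assembly.placement_frame().to_csv(outdir / "placements.tsv", sep="\t", index=False)
        unplaced_report = [
            {"scaffold": p.scaffold, "chimera": p.chimera, "n_markers": p.n_markers}
            for p in assembly.unplaced
        ] + [
            {"scaffold": s.scaffold_id, "chimera": False, "n_markers": 0}
            for s in scaffolds
            if s.scaffold_id not in {p.scaffold for p in placements}
        ]
        rio.write_json(outdir / "unplaced.json", unplaced_report)
        if scaffold_seqs is not None:
            records, _ = anchor_mod.emit_pseudomolecules(assembly, scaffold_seqs)
            rio.write_fasta(outdir / "pseudomolecules.fasta", records)
        return assembly, placements

    assembly, placements = do_anchor()
    input_stats = anchor_mod.assembly_stats([s.length for s in scaffolds])
    pseudo_stats = (
        anchor_mod.assembly_stats([c.length for c in assembly.chromosomes])
        if assembly.chromosomes
        else None
    )
    report["anchor"] = {
        "n_scaffolds": len(scaffolds),
        "n_anchored": sum(len(c.components) for c in assembly.chromosomes),
        "n_chimera": sum(1 for p in assembly.unplaced if p.chimera),
        "n_chromosomes": len(assembly.chromosomes),
        "input_stats": input_stats,
        "pseudomolecule_stats": pseudo_stats,
    }

    # ------------------------------------------------------------------ landscape
    @_stage("landscape")
    def do_landscape():
        profile = landscape_mod.marey_profile(map_table, assembly)
        avg = landscape_mod.genome_average_rate(profile)
        # a zero average (no observed recombination) leaves hotspots undefined
        hotspots = (
            landscape_mod.call_hotspots(profile, avg, fold=cfg.hotspot_fold) if avg > 0 else []
        )
        coldspots = landscape_mod.call_coldspots(profile, min_span_mb=cfg.min_coldspot_mb)
        genes = lift_genes(genome.genes, scaffolds, assembly)
        genome_density = len(genome.genes) / (genome.total_length / 1e5)
        assoc = landscape_mod.associate(
            hotspots, coldspots, genes,
            density_threshold=cfg.density_threshold,
            genome_avg_density=genome_density,
        )
        iv = profile.all_intervals()
        rio.write_bedgraph(
            outdir / "rate.bedgraph",
            [(r.chrom, int(r.start), int(r.end), float(r.rate)) for r in iv.itertuples()],
        )
        pd.DataFrame(
            [
                {"chrom": h.chrom, "start": h.start, "end": h.end,
                 "rate": h.rate, "fold": h.fold, "gene_density": h.gene_density,
                 "genes": ",".join(h.genes)}
                for h in hotspots
            ]
        ).to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"chrom": c.chrom, "start": c.start, "end": c.end,
                 "span_mb": c.span_mb, "gene_density": c.gene_density}
                for c in coldspots
            ]
        ).to_csv(outdir / "coldspots.tsv", sep="\t", index=False)
        rio.write_json(outdir / "association.json", assoc)
        return profile, avg, hotspots, coldspots, assoc

    profile, avg, hotspots, coldspots, assoc = do_landscape()
    report["landscape"] = {
        "genome_average_rate_cm_per_mb": round(avg, 4),
        "n_hotspots": len(hotspots),
        "n_coldspots": len(coldspots),
        "association": assoc,
    }

    rio.write_json(outdir / "report.json", report)
    return report
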