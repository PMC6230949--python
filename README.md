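# radmap

Pseudo-testcross linkage mapping, scaffold anchoring and recombination-
landscape analysis — with a self-contained synthetic-cross generator so the
whole pipeline is buildable and testable without any external data.

The package implements the computational chain used to turn RAD-seq
genotypes of an F1 orchid cross into chromosome pseudomolecules:

1. **`radmap.sim`** — simulate a multi-chromosome genome, fragment it into
   scaffolds, plant a crossover landscape (background rate plus hotspots
   > 10x background and zero-rate coldspots), and draw F1 genotypes from
   Poisson (interference-free) meioses with configurable error, missingness
   and read depth.  Ground truth is retained for recovery tests.
2. **`radmap.markers`** — define pseudo-testcross markers from per-site
   allele counts (seed parent heterozygous, pollen parent homozygous for a
   shared allele), call 0/1/missing genotypes at minimum depth 3, and
   filter duplicated or over-missing individuals.
3. **`radmap.linkage`** — two-point recombination fractions with phase
   inference, base-10 LOD scores, single-linkage grouping (rf < 0.4,
   LOD > 10), greedy + 2-opt/Or-opt marker ordering with double-crossover
   masking, and cumulative map positions via Haldane's mapping function.
4. **`radmap.anchor`** — assign scaffolds to linkage groups by marker
   majority (chimera flagging), order by mean cM, orient by the bp-vs-cM
   Kendall sign, and emit AGP v2.1 + pseudomolecule FASTA; N50/N90 stats.
5. **`radmap.landscape`** — Marey profiles on inter-marker intervals,
   length-weighted genome-average rate, hotspot calls (> 10x average,
   merged), coldspot calls (0 cM over > 1 Mb), and gene-density association.
6. **`radmap.stats`** — exact summary arithmetic (flow-cytometry genome
   size, mean lengths, densities, percentages, marker spacing) with
   half-away-from-zero rounding.
7. **`radmap.pipeline` / `radmap.cli`** — the end-to-end driver and a
   `radmap` executable with one subcommand per stage.

## CLI

```sh
radmap simulate --config cfg.yaml --seed 1 --outdir out/      # synthetic cross
radmap callmarkers --pileup out/pileup.tsv --parent-a PA --parent-b PB \
       --min-depth 3 --out-prefix out/mk
radmap map --genotypes out/mk.genotypes.tsv --max-rf 0.4 --min-lod 10 \
       --out out/map.tsv
radmap anchor --map out/map.tsv --fasta out/scaffolds.fasta --gap 100 \
       --out-prefix out/anchored
radmap landscape --map out/map.tsv --agp out/anchored.agp \
       --gff out/genes.gff3 --fold 10 --min-coldspot-mb 1 --out-prefix out/land
radmap stats size-from-2c 2.445
radmap run --config cfg.yaml --seed 1 --outdir out/            # everything
```

`cfg.yaml` holds a `radmap.config.RunConfig` mapping; unknown keys are
rejected and all defaults mirror the study parameters (184 progeny, depth 3,
rf < 0.4, LOD > 10, 10x hotspot fold, 1 Mb coldspot span, 3 genes/100 kb).

## Conventions

- Coordinates are 0-based half-open in memory and in TSV/BED outputs;
  GFF3 and AGP are written 1-based inclusive as those formats require.
- Orientation vocabulary is `+`, `-`, `?` everywhere; `?` scaffolds are
  emitted as forward sequence but keep `?` in the AGP.
- All randomness flows from explicit seeds; fixed seeds give byte-identical
  outputs, including the pipeline's `report.json`.
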