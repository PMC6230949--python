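"""Canonical worked-example inputs for the summary-arithmetic utilities.

These are the printed summary numbers of the chromosome-scale orchid genome
project this pipeline models; they serve as fixed regression inputs for the
exact arithmetic in :mod:`radmap.stats` and are not recomputed from raw
data here.
"""

#: flow cytometry: 2C nuclear DNA mass in picograms
FLOW_CYTOMETRY_2C_PG = 2.445

#: assembly and annotation totals
ASSEMBLY_TOTAL_MB = 1025.1
N_GENES = 28_902
TOTAL_GENE_LENGTH_MB = 333.45
TOTAL_CDS_LENGTH_MB = 31.19

#: transcript-to-assembly mapping counts
N_TRANSCRIPTS = 190_065
N_TRANSCRIPTS_ALIGNED = 173_500

#: linkage map summary
MAP_TOTAL_CM = 3075.8
N_MAP_MARKERS = 2905
N_LINKAGE_GROUPS = 22
N_ANCHORED_SCAFFOLDS = 522

#: recombination landscape summary
AVG_RECOMBINATION_RATE = 5.5      # cM/Mb
ARABIDOPSIS_AVG_RATE = 4.6        # cM/Mb, comparison value
N_HOTSPOTS = 74
N_HOTSPOTS_GENE_DENSE = 60        # hotspots in regions > 3 genes / 100 kb
GENE_DENSITY_PER_100KB = 2.82
TOMATO_GENE_DENSITY_PER_100KB = 4.0

#: assembly contiguity (kb) before/after map integration — context only;
#: these depend on the raw study data and are not reproduced by this package
SCAFFOLD_N50_KB = 946.4
FINAL_SCAFFOLD_N50_KB = 19_680.0
N_CHROMOSOMES = 19
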