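"""Synthetic pseudo-testcross data with known ground truth.

Generates a multi-chromosome genome with an inhomogeneous gene landscape,
fragments it into scaffolds, plants a crossover-rate step landscape
(background plus hotspots and coldspots), and simulates RAD-style genotype
evidence for an F1 cross: markers heterozygous in the seed parent and
homozygous in the pollen parent, Poisson crossovers without interference
(hence exactly Haldane-consistent), per-call error and missingness, and
per-site read depths.

Every operation is driven by an explicit seed and is byte-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radmap.io import Gene
from radmap.linkage import MISSING
from radmap.markers import ALLELES, GenotypeMatrix, MarkerDefinition, PILEUP_COLUMNS

__all__ = [
    "SimGenome",
    "Landscape",
    "ScaffoldTruth",
    "CrossDesign",
    "TruthSet",
    "simulate_genome",
    "plant_landscape",
    "fragment_scaffolds",
    "simulate_cross",
    "emit_sequences",
    "hotspots_at_density_extremes",
]

#: whole-genome GC fraction used for sequence emission by default
DEFAULT_GC = 0.344

#: mean gene density in genes per bp (2.82 genes per 100 kb)
DEFAULT_GENE_DENSITY = 2.82e-5

_MIN_SCAFFOLD_LEN = 1_000


# ---------------------------------------------------------------------------
# Types


@dataclass
class SimGenome:
    chromosomes: list[tuple[str, int]]
    genes: list[Gene]
    gc: dict[str, float]

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids must be unique")
        for g in self.genes:
            if g.chrom not in lengths or g.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} outside its chromosome")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]


@dataclass
class Landscape:
    """Per-chromosome crossover intensity as a step function in cM/Mb."""

    steps: dict[str, np.ndarray]  # (n, 3) arrays of (start bp, end bp, rate cM/Mb)
    hotspots: list[tuple[str, int, int, float]] = field(default_factory=list)
    coldspots: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for chrom, arr in self.steps.items():
            arr = np.asarray(arr, dtype=float)
            if (arr[:, 2] < 0).any():
                raise ValueError(f"{chrom}: negative rate in landscape")
            if not np.all(arr[1:, 0] == arr[:-1, 1]):
                raise ValueError(f"{chrom}: landscape intervals must tile without gaps")
            self.steps[chrom] = arr

    def total_cm(self, chrom: str) -> float:
        arr = self.steps[chrom]
        return float(np.sum(arr[:, 2] * (arr[:, 1] - arr[:, 0]) / 1e6))

    def genome_average_rate(self) -> float:
        """Length-weighted mean rate in cM/Mb over the whole genome."""
        total_cm = sum(self.total_cm(c) for c in self.steps)
        total_mb = sum(self.steps[c][-1, 1] / 1e6 for c in self.steps)
        return total_cm / total_mb

    def cum_cm(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """Genetic position in cM at physical positions ``bp``."""
        arr = self.steps[chrom]
        edges = np.concatenate([[arr[0, 0]], arr[:, 1]])
        seg_cm = arr[:, 2] * (arr[:, 1] - arr[:, 0]) / 1e6
        cum = np.concatenate([[0.0], np.cumsum(seg_cm)])
        bp = np.asarray(bp, dtype=float)
        seg = np.clip(np.searchsorted(edges, bp, side="right") - 1, 0, len(arr) - 1)
        return cum[seg] + arr[seg, 2] * (bp - edges[seg]) / 1e6

    def bp_at_cm(self, chrom: str, cm: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`cum_cm`; zero-rate segments map to their start."""
        arr = self.steps[chrom]
        seg_cm = arr[:, 2] * (arr[:, 1] - arr[:, 0]) / 1e6
        cum = np.concatenate([[0.0], np.cumsum(seg_cm)])
        cm = np.asarray(cm, dtype=float)
        seg = np.clip(np.searchsorted(cum, cm, side="right") - 1, 0, len(arr) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(seg_cm[seg] > 0, (cm - cum[seg]) / seg_cm[seg], 0.0)
        return arr[seg, 0] + frac * (arr[seg, 1] - arr[seg, 0])


@dataclass
class ScaffoldTruth:
    scaffold_id: str
    chrom: str
    start: int  # 0-based half-open on source chromosome
    end: int
    orientation: str  # "+" or "-"
    sequence: str | None = None

    def __post_init__(self):
        if self.end - self.start < _MIN_SCAFFOLD_LEN:
            raise ValueError(f"{self.scaffold_id}: scaffolds must be >= {_MIN_SCAFFOLD_LEN} bp")
        if self.orientation not in "+-":
            raise ValueError(f"{self.scaffold_id}: orientation must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CrossDesign:
    """Parameters of the simulated F1 cross; the seed fixes everything."""

    n_progeny: int = 184
    error_rate: float = 0.005
    missing_rate: float = 0.15
    mean_depth: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_progeny < 1:
            raise ValueError("need at least one progeny")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")


@dataclass
class TruthSet:
    """Ground truth for recovery tests."""

    genome: SimGenome
    landscape: Landscape
    scaffolds: list[ScaffoldTruth]
    markers: pd.DataFrame  # marker_id, chrom, chrom_pos, scaffold, scaffold_pos, cm
    true_calls: np.ndarray  # int8, markers x progeny, no error/missingness
    genome_avg_rate: float

    def scaffold_of(self, scaffold_id: str) -> ScaffoldTruth:
        return next(s for s in self.scaffolds if s.scaffold_id == scaffold_id)

    def summary(self) -> dict:
        return {
            "n_chromosomes": len(self.genome.chromosomes),
            "genome_length": self.genome.total_length,
            "n_genes": len(self.genome.genes),
            "n_scaffolds": len(self.scaffolds),
            "n_markers": int(len(self.markers)),
            "genome_avg_rate_cm_per_mb": self.genome_avg_rate,
            "hotspots": [list(h) for h in self.landscape.hotspots],
            "coldspots": [list(c) for c in self.landscape.coldspots],
            "chromosome_cm": {c: self.landscape.total_cm(c) for c, _ in self.genome.chromosomes},
        }


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(
    n_chrom: int,
    total_len: int,
    gene_density_profile: str = "sinusoidal",
    mean_gene_density: float = DEFAULT_GENE_DENSITY,
    gc: float = DEFAULT_GC,
    seed: int = 0,
) -> SimGenome:
    """Equal-length chromosomes with genes from an inhomogeneous point process.

    ``gene_density_profile`` is ``"constant"`` or ``"sinusoidal"``; the
    sinusoidal profile modulates the local intensity between 0.2x and 1.8x
    the mean so windowed gene density varies several-fold along each
    chromosome (phase drawn per chromosome).
    """
    if n_chrom < 1:
        raise ValueError(f"need at least one chromosome, got {n_chrom}")
    if total_len < n_chrom * 10_000:
        raise ValueError(f"total length {total_len} too small for {n_chrom} chromosomes")
    if gene_density_profile not in ("constant", "sinusoidal"):
        raise ValueError(f"unknown gene density profile {gene_density_profile!r}")
    if mean_gene_density < 0:
        raise ValueError("gene density must be non-negative")

    rng = np.random.default_rng(seed)
    chrom_len = total_len // n_chrom
    chromosomes = [(f"chr{i + 1:02d}", chrom_len) for i in range(n_chrom)]

    genes: list[Gene] = []
    for ci, (chrom, length) in enumerate(chromosomes):
        n_genes = rng.poisson(mean_gene_density * length)
        if n_genes == 0:
            continue
        if gene_density_profile == "constant":
            starts = rng.integers(0, length, n_genes)
        else:
            phase = rng.uniform(0, 2 * math.pi)
            # rejection sampling against lambda(x) = 1 + 0.8 sin(6 pi x/L + phase)
            starts_list: list[int] = []
            while len(starts_list) < n_genes:
                cand = rng.integers(0, length, 2 * (n_genes - len(starts_list)) + 8)
                lam = 1.0 + 0.8 * np.sin(6 * math.pi * cand / length + phase)
                acc = cand[rng.uniform(0, 1.8, len(cand)) < lam]
                starts_list.extend(int(x) for x in acc)
            starts = np.array(starts_list[:n_genes])
        lengths = np.maximum(rng.gamma(2.0, 1200.0, n_genes).astype(int), 200)
        for gi, (s, gl) in enumerate(sorted(zip(starts.tolist(), lengths.tolist()))):
            end = min(s + gl, length)
            if end <= s:
                continue
            genes.append(Gene(chrom, s, end, f"g{ci + 1:02d}_{gi + 1:05d}"))
    return SimGenome(chromosomes, genes, {c: gc for c, _ in chromosomes})


# ---------------------------------------------------------------------------
# Landscape


def plant_landscape(
    genome: SimGenome,
    background: float,
    hotspots: list[tuple[str, int, int, float]] | None = None,
    coldspots: list[tuple[str, int, int]] | None = None,
) -> Landscape:
    """Step-function crossover landscape with planted hotspots and coldspots.

    Hotspot rates must exceed 10x the background; planted intervals may not
    overlap each other.
    """
    if background < 0:
        raise ValueError("background rate must be non-negative")
    hotspots = list(hotspots or [])
    coldspots = list(coldspots or [])
    for chrom, start, end, rate in hotspots:
        if rate <= 10 * background:
            raise ValueError(
                f"hotspot rate {rate} on {chrom} must exceed 10x background ({10 * background})"
            )
    chrom_lens = dict(genome.chromosomes)
    planted: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_lens}
    for chrom, start, end, rate in hotspots:
        planted[chrom].append((start, end, rate))
    for chrom, start, end in coldspots:
        planted[chrom].append((start, end, 0.0))

    steps: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        ivs = sorted(planted[chrom])
        for (s, e, _), (s2, e2, _) in zip(ivs, ivs[1:]):
            if s2 < e:
                raise ValueError(f"planted intervals overlap on {chrom}: [{s},{e}) and [{s2},{e2})")
        for s, e, _ in ivs:
            if not (0 <= s < e <= length):
                raise ValueError(f"planted interval [{s},{e}) outside {chrom}")
        rows = []
        cursor = 0
        for s, e, rate in ivs:
            if s > cursor:
                rows.append((cursor, s, background))
            rows.append((s, e, rate))
            cursor = e
        if cursor < length:
            rows.append((cursor, length, background))
        steps[chrom] = np.array(rows, dtype=float)
    return Landscape(steps, hotspots, coldspots)


def hotspots_at_density_extremes(
    genome: SimGenome,
    n_hot: int,
    width: int,
    rate: float,
    n_cold: int = 0,
    cold_width: int = 2_000_000,
) -> tuple[list[tuple[str, int, int, float]], list[tuple[str, int, int]]]:
    """Place hotspots in the gene-densest windows and coldspots in the sparsest.

    Utility for experiments coupling crossover intensity to gene density.
    Windows are non-overlapping and at most one hotspot and one coldspot is
    taken per chromosome to keep intervals disjoint.
    """
    dens: list[tuple[float, str, int]] = []
    starts_by_chrom: dict[str, list[int]] = {c: [] for c, _ in genome.chromosomes}
    for g in genome.genes:
        starts_by_chrom[g.chrom].append(g.start)
    for chrom, length in genome.chromosomes:
        starts = np.array(sorted(starts_by_chrom[chrom]))
        for w0 in range(0, length - width + 1, width):
            count = np.searchsorted(starts, w0 + width) - np.searchsorted(starts, w0)
            dens.append((float(count), chrom, w0))
    dens.sort(key=lambda t: (-t[0], t[1], t[2]))
    hot: list[tuple[str, int, int, float]] = []
    used: set[str] = set()
    for count, chrom, w0 in dens:
        if len(hot) == n_hot:
            break
        if chrom in used:
            continue
        hot.append((chrom, w0, w0 + width, rate))
        used.add(chrom)
    cold: list[tuple[str, int, int]] = []
    used_cold: set[str] = set()
    for count, chrom, w0 in reversed(dens):
        if len(cold) == n_cold:
            break
        if chrom in used or chrom in used_cold:
            continue
        end = min(w0 + cold_width, genome.length_of(chrom))
        if end - w0 < cold_width:
            continue
        cold.append((chrom, w0, end))
        used_cold.add(chrom)
    return hot, cold


# ---------------------------------------------------------------------------
# Scaffolds


def fragment_scaffolds(genome: SimGenome, mean_len: int, seed: int = 0) -> list[ScaffoldTruth]:
    """Fragment chromosomes at Poisson-process breakpoints.

    Pieces shorter than 1 kb are merged into their left neighbour so every
    scaffold satisfies the minimum length; the union of scaffolds
    reconstructs each chromosome exactly.  Scaffold ids are shuffled so the
    id order carries no positional information.
    """
    if mean_len < 2_000:
        raise ValueError(f"mean scaffold length must be >= 2 kb, got {mean_len}")
    rng = np.random.default_rng(seed)
    pieces: list[tuple[str, int, int, str]] = []
    for chrom, length in genome.chromosomes:
        cuts = [0]
        pos = 0.0
        while True:
            pos += rng.exponential(mean_len)
            if pos >= length:
                break
            cuts.append(int(pos))
        cuts.append(length)
        cuts = sorted(set(cuts))
        merged: list[list[int]] = []
        for s, e in zip(cuts, cuts[1:]):
            if merged and e - s < _MIN_SCAFFOLD_LEN:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        if len(merged) > 1 and merged[0][1] - merged[0][0] < _MIN_SCAFFOLD_LEN:
            merged[1][0] = merged[0][0]
            merged.pop(0)
        for s, e in merged:
            orient = "+" if rng.random() < 0.5 else "-"
            pieces.append((chrom, s, e, orient))
    ids = [f"scf{i + 1:05d}" for i in range(len(pieces))]
    rng.shuffle(ids)
    return [
        ScaffoldTruth(sid, chrom, s, e, orient)
        for sid, (chrom, s, e, orient) in zip(ids, pieces)
    ]


def emit_sequences(
    genome: SimGenome, scaffolds: list[ScaffoldTruth], seed: int = 0
) -> tuple[dict[str, str], dict[str, str]]:
    """Emit i.i.d. chromosome sequences at each chromosome's GC fraction and
    slice out scaffold sequences (reverse-complemented for '-' scaffolds).

    Returns ``(chromosome_seqs, scaffold_seqs)`` and stores each scaffold's
    sequence on its :class:`ScaffoldTruth`.
    """
    from radmap.io import revcomp

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    chrom_seqs: dict[str, str] = {}
    for chrom, length in genome.chromosomes:
        gc = genome.gc[chrom]
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        chrom_seqs[chrom] = rng.choice(bases, size=length, p=p).tobytes().decode()
    scaffold_seqs: dict[str, str] = {}
    for s in scaffolds:
        seq = chrom_seqs[s.chrom][s.start : s.end]
        if s.orientation == "-":
            seq = revcomp(seq)
        s.sequence = seq
        scaffold_seqs[s.scaffold_id] = seq
    return chrom_seqs, scaffold_seqs


# ---------------------------------------------------------------------------
# The cross


def _marker_positions(length: int, markers_per_mb: float, rng: np.random.Generator) -> np.ndarray:
    """Stratified marker placement: one uniform draw per equal-width stratum.

    Keeps the long-run density at ``markers_per_mb`` while avoiding the long
    empty gaps of a purely uniform draw, which would starve short planted
    features of flanking markers.
    """
    n = max(2, int(round(length / 1e6 * markers_per_mb)))
    edges = np.linspace(0, length, n + 1)
    pos = edges[:-1] + rng.uniform(0, 1, n) * np.diff(edges)
    return np.unique(pos.astype(np.int64))


def simulate_cross(
    genome: SimGenome,
    landscape: Landscape,
    markers_per_mb: float,
    design: CrossDesign,
    scaffolds: list[ScaffoldTruth] | None = None,
    decoys_per_mb: float = 0.0,
    with_pileup: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame | None, TruthSet]:
    """Simulate the seed-parent side of a pseudo-testcross F1.

    Each maternal meiosis draws a Poisson number of crossovers with
    positions proportional to the landscape intensity (a Poisson process in
    genetic-distance space), so pairwise recombination fractions follow
    Haldane's map function exactly.  Calls are flipped with probability
    ``design.error_rate`` and dropped with probability
    ``design.missing_rate``; the returned pileup has per-site Poisson read
    depths consistent with the (post-error) calls.
    """
    if markers_per_mb <= 0:
        raise ValueError("marker density must be positive")
    if not landscape.steps:
        raise ValueError("empty landscape")
    rng = np.random.default_rng(design.seed)
    n = design.n_progeny

    # -- marker truth per chromosome
    records = []
    true_cols: list[np.ndarray] = []
    for chrom, length in genome.chromosomes:
        pos = _marker_positions(length, markers_per_mb, rng)
        cm = landscape.cum_cm(chrom, pos)
        total_cm = landscape.total_cm(chrom)
        # meioses: crossover count ~ Poisson(total cM / 100), positions
        # uniform in cM space (i.e. proportional to intensity)
        geno = np.empty((len(pos), n), dtype=np.int8)
        phase0 = rng.integers(0, 2, n).astype(np.int8)
        n_xo = rng.poisson(total_cm / 100.0, n)
        for k in range(n):
            if n_xo[k] == 0:
                geno[:, k] = phase0[k]
                continue
            xo_cm = np.sort(rng.uniform(0.0, total_cm, n_xo[k]))
            flips = np.searchsorted(xo_cm, cm, side="right") % 2
            geno[:, k] = phase0[k] ^ flips.astype(np.int8)
        for p, c in zip(pos.tolist(), cm.tolist()):
            records.append((chrom, p, c))
        true_cols.append(geno)
    true_calls_chromwise = np.vstack(true_cols)

    truth = pd.DataFrame(records, columns=["chrom", "chrom_pos", "cm"])

    # -- scaffold coordinates
    if scaffolds is not None:
        by_chrom: dict[str, list[ScaffoldTruth]] = {}
        for s in scaffolds:
            by_chrom.setdefault(s.chrom, []).append(s)
        for lst in by_chrom.values():
            lst.sort(key=lambda s: s.start)
        scf_ids, scf_pos = [], []
        for chrom, p in zip(truth["chrom"], truth["chrom_pos"]):
            lst = by_chrom[chrom]
            starts = [s.start for s in lst]
            i = np.searchsorted(starts, p, side="right") - 1
            s = lst[i]
            local = p - s.start if s.orientation == "+" else s.end - 1 - p
            scf_ids.append(s.scaffold_id)
            scf_pos.append(int(local))
        truth["scaffold"] = scf_ids
        truth["scaffold_pos"] = scf_pos
    else:
        truth["scaffold"] = truth["chrom"]
        truth["scaffold_pos"] = truth["chrom_pos"]

    # -- marker ids in (scaffold, scaffold_pos) order; reorder everything
    order = np.lexsort((truth["scaffold_pos"].to_numpy(), truth["scaffold"].to_numpy()))
    truth = truth.iloc[order].reset_index(drop=True)
    true_calls = true_calls_chromwise[order]
    truth.insert(0, "marker_id", [f"UM{i + 1:06d}" for i in range(len(truth))])

    # -- alleles
    k = len(truth)
    het_idx = rng.integers(0, 4, k)
    hom_off = rng.integers(1, 4, k)
    hom_idx = (het_idx + hom_off) % 4
    defs = [
        MarkerDefinition(
            truth["marker_id"][i],
            truth["scaffold"][i],
            int(truth["scaffold_pos"][i]),
            ALLELES[het_idx[i]],
            ALLELES[hom_idx[i]],
        )
        for i in range(k)
    ]

    # -- observed calls: error flips then missingness
    observed = true_calls.copy()
    if design.error_rate > 0:
        flips = rng.random((k, n)) < design.error_rate
        observed = np.where(flips, 1 - observed, observed).astype(np.int8)
    if design.missing_rate > 0:
        miss = rng.random((k, n)) < design.missing_rate
        observed[miss] = MISSING

    progeny = [f"F1_{i + 1:03d}" for i in range(n)]
    gm = GenotypeMatrix(defs, progeny, observed)

    pileup = (
        _build_pileup(truth, defs, observed, progeny, design, rng, genome, decoys_per_mb)
        if with_pileup
        else None
    )

    truth_set = TruthSet(
        genome=genome,
        landscape=landscape,
        scaffolds=scaffolds or [],
        markers=truth,
        true_calls=true_calls,
        genome_avg_rate=landscape.genome_average_rate(),
    )
    return gm, pileup, truth_set


PARENT_A = "PA"  # seed parent (heterozygous at every marker)
PARENT_B = "PB"  # pollen parent (homozygous at every marker)


def _build_pileup(
    truth: pd.DataFrame,
    defs: list[MarkerDefinition],
    observed: np.ndarray,
    progeny: list[str],
    design: CrossDesign,
    rng: np.random.Generator,
    genome: SimGenome,
    decoys_per_mb: float,
) -> pd.DataFrame:
    """Per-site allele depths consistent with the observed calls.

    Parents are modelled as deeply sequenced (depth floored well above the
    marker-definition thresholds) so every planted site is recoverable.
    Heterozygous progeny calls always show both alleles when total depth
    allows, so depth >= min_depth implies the call is recovered exactly.
    """
    k, n = observed.shape
    lam = design.mean_depth
    frames = []

    scaffold = truth["scaffold"].to_numpy()
    pos = truth["scaffold_pos"].to_numpy()
    het = np.array([ALLELES.index(d.allele_het) for d in defs])
    hom = np.array([ALLELES.index(d.allele_hom) for d in defs])

    def depth_frame(scf, p, sample, allele_idx_a, depth_a, allele_idx_b=None, depth_b=None):
        m = len(scf)
        depths = np.zeros((m, 4), dtype=np.int64)
        depths[np.arange(m), allele_idx_a] = depth_a
        if allele_idx_b is not None:
            depths[np.arange(m), allele_idx_b] += depth_b
        df = pd.DataFrame({"scaffold": scf, "pos": p, "sample": sample})
        for ai, a in enumerate(ALLELES):
            df[a] = depths[:, ai]
        return df

    # parents: depth floored at 17 reads, allele split kept within [0.3, 0.7]
    d_pa = np.maximum(rng.poisson(2 * lam, k), 17)
    minor = rng.binomial(d_pa, 0.5)
    lo = np.ceil(0.3 * d_pa).astype(np.int64)
    hi = np.floor(0.7 * d_pa).astype(np.int64)
    minor = np.clip(minor, lo, hi)
    frames.append(depth_frame(scaffold, pos, PARENT_A, het, minor, hom, d_pa - minor))
    d_pb = np.maximum(rng.poisson(2 * lam, k), 5)
    frames.append(depth_frame(scaffold, pos, PARENT_B, hom, d_pb))

    # progeny, one frame per individual (missing calls emit no record)
    for j, name in enumerate(progeny):
        calls = observed[:, j]
        present = calls != MISSING
        idx = np.flatnonzero(present)
        if idx.size == 0:
            continue
        d = rng.poisson(lam, idx.size)
        is_het = calls[idx] == 1
        d_nonb = np.zeros(idx.size, dtype=np.int64)
        splittable = is_het & (d >= 2)
        d_nonb[splittable] = np.clip(
            rng.binomial(d[splittable], 0.5), 1, d[splittable] - 1
        )
        single = is_het & (d == 1)
        d_nonb[single] = rng.integers(0, 2, int(single.sum()))
        keep = d > 0
        idx, d, d_nonb = idx[keep], d[keep], d_nonb[keep]
        frames.append(
            depth_frame(scaffold[idx], pos[idx], name, het[idx], d_nonb, hom[idx], d - d_nonb)
        )

    # decoy sites: monomorphic in the seed parent, must never become markers
    if decoys_per_mb > 0:
        n_decoy = int(round(genome.total_length / 1e6 * decoys_per_mb))
        if n_decoy > 0:
            scf_choices = np.sort(np.unique(scaffold))
            d_scf = rng.choice(scf_choices, n_decoy)
            d_pos = rng.integers(0, 10_000_000, n_decoy) + 100_000_000  # clear of marker sites
            d_allele = rng.integers(0, 4, n_decoy)
            for sample in (PARENT_A, PARENT_B):
                dd = np.maximum(rng.poisson(2 * lam, n_decoy), 5)
                frames.append(depth_frame(d_scf, d_pos, sample, d_allele, dd))

    pileup = pd.concat(frames, ignore_index=True)
    pileup = pileup.sort_values(["scaffold", "pos", "sample"], kind="mergesort").reset_index(drop=True)
    return pileup[PILEUP_COLUMNS]
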