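"""Marey-map recombination landscape: per-interval cM/Mb rates along
pseudomolecules, hotspot and coldspot calling, and gene-density association.

Rates are computed on inter-marker intervals rather than fixed windows, so
very short intervals can show extreme rates, as observed on real maps.
Discordant markers are repaired by keeping the longest non-decreasing
subsequence of cM values along the physical axis.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from radmap.anchor import AnchoredAssembly
from radmap.io import Gene

__all__ = [
    "MareyProfile",
    "HotspotCall",
    "ColdspotCall",
    "marey_profile",
    "genome_average_rate",
    "call_hotspots",
    "call_coldspots",
    "gene_density",
    "associate",
]


@dataclass
class ChromProfile:
    chrom: str
    anchors: pd.DataFrame    # marker_id, bp, cm; bp strictly increasing, cm non-decreasing
    intervals: pd.DataFrame  # start, end, dcm, rate


@dataclass
class MareyProfile:
    chromosomes: dict[str, ChromProfile] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def all_intervals(self) -> pd.DataFrame:
        frames = [
            cp.intervals.assign(chrom=cp.chrom)
            for cp in self.chromosomes.values()
            if len(cp.intervals)
        ]
        if not frames:
            return pd.DataFrame(columns=["start", "end", "dcm", "rate", "chrom"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class HotspotCall:
    chrom: str
    start: int
    end: int
    rate: float
    fold: float
    gene_density: float | None = None
    genes: list[str] = field(default_factory=list)


@dataclass
class ColdspotCall:
    chrom: str
    start: int
    end: int
    gene_density: float | None = None

    @property
    def span_mb(self) -> float:
        return (self.end - self.start) / 1e6


# ---------------------------------------------------------------------------
# Profile construction


def _lnds_keep(values: np.ndarray) -> np.ndarray:
    """Indices of a longest non-decreasing subsequence (ties kept).

    Patience algorithm with predecessor links; deterministic (keeps the
    earliest optimal subsequence).
    """
    n = len(values)
    tails: list[float] = []      # last value of best subsequence per length
    tails_idx: list[int] = []
    prev = np.full(n, -1, dtype=int)
    for i, v in enumerate(values):
        j = bisect.bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1]
    while i != -1:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1], dtype=int)


def marey_profile(map_table: pd.DataFrame, assembly: AnchoredAssembly) -> MareyProfile:
    """Lift mapped markers onto pseudomolecules and form rate intervals.

    Per chromosome: markers are lifted through the scaffold placements,
    the map direction is flipped if cM runs against physical position
    (whole-group reversal is unidentifiable from linkage alone), then
    non-monotone anchors are dropped by longest non-decreasing subsequence
    on cM.  Chromosomes with fewer than two surviving anchors are skipped.
    """
    index = assembly.placement_index()
    recs = []
    for row in map_table.itertuples():
        info = index.get(row.scaffold)
        if info is None:
            continue
        chrom, offset, orientation, length = info
        bp = offset + (length - 1 - row.pos) if orientation == "-" else offset + row.pos
        recs.append((chrom, row.marker_id, int(bp), float(row.cm)))
    lifted = pd.DataFrame(recs, columns=["chrom", "marker_id", "bp", "cm"])

    profile = MareyProfile()
    for chrom in sorted({c.name for c in assembly.chromosomes}):
        sub = lifted[lifted["chrom"] == chrom].sort_values(["bp", "marker_id"]).reset_index(drop=True)
        if len(sub) < 2:
            profile.skipped.append(chrom)
            continue
        tau = kendalltau(sub["bp"], sub["cm"]).statistic
        if np.isfinite(tau) and tau < 0:
            sub["cm"] = float(sub["cm"].max()) - sub["cm"]
        keep = _lnds_keep(sub["cm"].to_numpy())
        sub = sub.iloc[keep].reset_index(drop=True)
        # collapse duplicate physical positions (cannot form an interval)
        sub = sub.drop_duplicates(subset="bp", keep="first").reset_index(drop=True)
        if len(sub) < 2:
            profile.skipped.append(chrom)
            continue
        bp = sub["bp"].to_numpy()
        cm = sub["cm"].to_numpy()
        dcm = np.diff(cm)
        dbp = np.diff(bp)
        intervals = pd.DataFrame(
            {
                "start": bp[:-1],
                "end": bp[1:],
                "dcm": dcm,
                "rate": dcm / (dbp / 1e6),
            }
        )
        profile.chromosomes[chrom] = ChromProfile(chrom, sub, intervals)
    return profile


def genome_average_rate(profile: MareyProfile) -> float:
    """Length-weighted average rate: total cM over total Mb across intervals."""
    iv = profile.all_intervals()
    if not len(iv):
        raise ValueError("profile has no intervals")
    span_mb = float((iv["end"] - iv["start"]).sum()) / 1e6
    if span_mb <= 0:
        raise ValueError("profile has zero physical span")
    return float(iv["dcm"].sum()) / span_mb


# ---------------------------------------------------------------------------
# Hotspots / coldspots


def call_hotspots(profile: MareyProfile, avg: float, fold: float = 10.0) -> list[HotspotCall]:
    """Intervals with rate strictly above ``fold * avg``; adjacent qualifying
    intervals are merged and the merged rate recomputed over the joint span.
    """
    if avg <= 0:
        raise ValueError(f"average rate must be positive, got {avg}")
    threshold = fold * avg
    calls: list[HotspotCall] = []
    for chrom, cp in sorted(profile.chromosomes.items()):
        iv = cp.intervals
        hot = (iv["rate"] > threshold).to_numpy()
        i = 0
        while i < len(iv):
            if not hot[i]:
                i += 1
                continue
            j = i
            # merge runs of adjacent qualifying intervals (physically contiguous)
            while (
                j + 1 < len(iv)
                and hot[j + 1]
                and iv["start"].iat[j + 1] == iv["end"].iat[j]
            ):
                j += 1
            start = int(iv["start"].iat[i])
            end = int(iv["end"].iat[j])
            dcm = float(iv["dcm"].iloc[i : j + 1].sum())
            rate = dcm / ((end - start) / 1e6)
            calls.append(HotspotCall(chrom, start, end, rate, rate / avg))
            i = j + 1
    return calls


def call_coldspots(profile: MareyProfile, min_span_mb: float = 1.0) -> list[ColdspotCall]:
    """Maximal runs of contiguous intervals with zero cM spanning more than
    ``min_span_mb`` megabases."""
    calls: list[ColdspotCall] = []
    for chrom, cp in sorted(profile.chromosomes.items()):
        iv = cp.intervals
        cold = (iv["dcm"] == 0).to_numpy()
        i = 0
        while i < len(iv):
            if not cold[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < len(iv)
                and cold[j + 1]
                and iv["start"].iat[j + 1] == iv["end"].iat[j]
            ):
                j += 1
            start = int(iv["start"].iat[i])
            end = int(iv["end"].iat[j])
            if (end - start) / 1e6 > min_span_mb:
                calls.append(ColdspotCall(chrom, start, end))
            i = j + 1
    return calls


# ---------------------------------------------------------------------------
# Gene density and association


def gene_density(genes: list[Gene], chrom: str, start: int, end: int) -> float:
    """Genes per 100 kb: count of gene starts inside [start, end)."""
    if end <= start:
        raise ValueError(f"empty region [{start}, {end})")
    count = sum(1 for g in genes if g.chrom == chrom and start <= g.start < end)
    return count / ((end - start) / 1e5)


def _genes_in(genes: list[Gene], chrom: str, start: int, end: int) -> list[str]:
    return [g.gene_id for g in genes if g.chrom == chrom and start <= g.start < end]


def associate(
    hotspots: list[HotspotCall],
    coldspots: list[ColdspotCall],
    genes: list[Gene],
    density_threshold: float = 3.0,
    genome_avg_density: float | None = None,
) -> dict:
    """Annotate calls with gene density/content and summarize.

    Returns the fraction of hotspots whose local gene density exceeds
    ``density_threshold`` (genes per 100 kb) and the fraction of coldspots
    below the genome-average density.  Percentages are ``None`` when the
    corresponding call list is empty.
    """
    for h in hotspots:
        h.gene_density = gene_density(genes, h.chrom, h.start, h.end)
        h.genes = _genes_in(genes, h.chrom, h.start, h.end)
    for c in coldspots:
        c.gene_density = gene_density(genes, c.chrom, c.start, c.end)

    n_hot = len(hotspots)
    n_dense = sum(1 for h in hotspots if h.gene_density > density_threshold)
    report = {
        "n_hotspots": n_hot,
        "n_hotspots_gene_dense": n_dense,
        "pct_hotspots_gene_dense": (100.0 * n_dense / n_hot) if n_hot else None,
        "n_hotspot_genes": sum(len(h.genes) for h in hotspots),
        "n_coldspots": len(coldspots),
    }
    if genome_avg_density is not None:
        n_sparse = sum(1 for c in coldspots if c.gene_density < genome_avg_density)
        report["n_coldspots_gene_sparse"] = n_sparse
        report["pct_coldspots_gene_sparse"] = (
            100.0 * n_sparse / len(coldspots) if coldspots else None
        )
    return report
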