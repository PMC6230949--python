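"""Anchor scaffolds to linkage groups, order and orient them, and build
chromosome pseudomolecules (AGP v2.1 + FASTA).

The interface is the map table: one row per mapped marker with columns
``group, marker_id, scaffold, pos, cm``.  Assignment is by majority vote of
a scaffold's markers; scaffolds with two or more markers on each of two or
more groups are flagged as putative chimeras and left unplaced.  Ordering
within a group is by mean marker cM, orientation by the sign of the Kendall
correlation between within-scaffold physical position and cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from radmap.io import AgpRow, revcomp

__all__ = [
    "ScaffoldPlacement",
    "AnchoredAssembly",
    "assign_scaffolds",
    "order_and_orient",
    "emit_pseudomolecules",
    "assembly_stats",
]

MAP_COLUMNS = ["group", "marker_id", "scaffold", "pos", "cm"]


@dataclass
class ScaffoldPlacement:
    scaffold: str
    group: str | None          # None when unplaced
    rank: int | None = None    # order within group, 0-based
    orientation: str = "?"     # "+", "-", "?"
    n_markers: int = 0
    mean_cm: float | None = None
    chimera: bool = False


@dataclass
class Chromosome:
    name: str
    group: str
    components: list[ScaffoldPlacement]
    # per component: (start, end) offsets on the pseudomolecule, 0-based half-open
    spans: list[tuple[int, int]]
    length: int


@dataclass
class AnchoredAssembly:
    chromosomes: list[Chromosome]
    unplaced: list[ScaffoldPlacement]
    gap: int
    scaffold_lengths: dict[str, int]

    def placement_index(self) -> dict[str, tuple[str, int, str, int]]:
        """scaffold -> (chromosome, offset, orientation, scaffold length)."""
        out = {}
        for chrom in self.chromosomes:
            for placement, (start, _end) in zip(chrom.components, chrom.spans):
                out[placement.scaffold] = (
                    chrom.name,
                    start,
                    placement.orientation,
                    self.scaffold_lengths[placement.scaffold],
                )
        return out

    def lift(self, scaffold: str, pos: int) -> tuple[str, int] | None:
        """Map a scaffold coordinate onto its pseudomolecule, or None."""
        info = self.placement_index().get(scaffold)
        if info is None:
            return None
        chrom, offset, orientation, length = info
        if orientation == "-":
            return chrom, offset + (length - 1 - pos)
        return chrom, offset + pos

    def agp_rows(self) -> list[AgpRow]:
        rows: list[AgpRow] = []
        for chrom in self.chromosomes:
            part = 1
            prev_end = None
            for placement, (start, end) in zip(chrom.components, chrom.spans):
                if prev_end is not None and start > prev_end:
                    rows.append(AgpRow(chrom.name, prev_end, start, part, "U", str(start - prev_end), 0, start - prev_end, "na"))
                    part += 1
                length = self.scaffold_lengths[placement.scaffold]
                rows.append(
                    AgpRow(chrom.name, start, end, part, "W", placement.scaffold, 0, length, placement.orientation)
                )
                part += 1
                prev_end = end
        return rows

    def placement_frame(self) -> pd.DataFrame:
        recs = []
        for chrom in self.chromosomes:
            for placement, (start, end) in zip(chrom.components, chrom.spans):
                recs.append(
                    {
                        "scaffold": placement.scaffold,
                        "chromosome": chrom.name,
                        "group": chrom.group,
                        "rank": placement.rank,
                        "start": start,
                        "end": end,
                        "orientation": placement.orientation,
                        "n_markers": placement.n_markers,
                        "mean_cm": placement.mean_cm,
                    }
                )
        return pd.DataFrame(recs)


def _validate_map_table(map_table: pd.DataFrame) -> None:
    missing = [c for c in MAP_COLUMNS if c not in map_table.columns]
    if missing:
        raise ValueError(f"map table is missing columns {missing}")


def assign_scaffolds(
    map_table: pd.DataFrame, chimera_min_markers: int = 2
) -> list[ScaffoldPlacement]:
    """Assign each scaffold to a linkage group by marker majority.

    A scaffold carrying at least ``chimera_min_markers`` markers on each of
    two or more groups is flagged as a putative chimera and left unplaced.
    The mean cM is computed over the markers supporting the winning group.
    """
    _validate_map_table(map_table)
    placements: list[ScaffoldPlacement] = []
    for scaffold, sub in map_table.groupby("scaffold", sort=True):
        counts = sub.groupby("group").size().sort_values(ascending=False)
        strong = counts[counts >= chimera_min_markers]
        if len(strong) >= 2:
            placements.append(
                ScaffoldPlacement(scaffold, None, n_markers=int(counts.sum()), chimera=True)
            )
            continue
        # deterministic winner: highest count, ties by group name
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        support = sub[sub["group"] == best]
        placements.append(
            ScaffoldPlacement(
                scaffold,
                best,
                n_markers=int(len(support)),
                mean_cm=float(support["cm"].mean()),
            )
        )
    return placements


def _orient(sub: pd.DataFrame) -> str:
    """Orientation from the bp-vs-cM Kendall correlation; '?' if undecidable."""
    if sub["cm"].nunique() < 2 or sub["pos"].nunique() < 2:
        return "?"
    tau = kendalltau(sub["pos"], sub["cm"]).statistic
    if not np.isfinite(tau) or tau == 0:
        return "?"
    return "+" if tau > 0 else "-"


def order_and_orient(
    placements: list[ScaffoldPlacement],
    map_table: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    gap: int = 100,
    rename: dict[str, str] | None = None,
) -> AnchoredAssembly:
    """Order scaffolds within each group by mean cM and orient them.

    Pseudomolecules are named ``Chr1..ChrK`` by descending length unless a
    ``rename`` table (group -> chromosome name) is given.  Scaffolds with
    fewer than two distinct informative cM positions keep orientation ``?``
    (treated as ``+`` when sequence is emitted).
    """
    _validate_map_table(map_table)
    for p in placements:
        if p.group is not None and p.scaffold not in scaffold_lengths:
            raise ValueError(f"no length known for scaffold {p.scaffold}")

    unplaced = [p for p in placements if p.group is None]
    by_group: dict[str, list[ScaffoldPlacement]] = {}
    for p in placements:
        if p.group is not None:
            by_group.setdefault(p.group, []).append(p)

    chroms: list[Chromosome] = []
    for group in sorted(by_group):
        members = sorted(by_group[group], key=lambda p: (p.mean_cm, p.scaffold))
        spans: list[tuple[int, int]] = []
        cursor = 0
        for rank, p in enumerate(members):
            p.rank = rank
            sub = map_table[(map_table["scaffold"] == p.scaffold) & (map_table["group"] == group)]
            p.orientation = _orient(sub)
            if rank > 0:
                cursor += gap
            length = scaffold_lengths[p.scaffold]
            spans.append((cursor, cursor + length))
            cursor += length
        chroms.append(Chromosome("", group, members, spans, cursor))

    if rename:
        for c in chroms:
            c.name = rename.get(c.group, c.group)
        chroms.sort(key=lambda c: c.name)
    else:
        chroms.sort(key=lambda c: (-c.length, c.group))
        for i, c in enumerate(chroms):
            c.name = f"Chr{i + 1}"
    return AnchoredAssembly(chroms, unplaced, gap, dict(scaffold_lengths))


def emit_pseudomolecules(
    assembly: AnchoredAssembly, scaffold_seqs: dict[str, str]
) -> tuple[list[tuple[str, str]], list[AgpRow]]:
    """Build pseudomolecule sequences consistent with the AGP.

    '-' scaffolds are reverse-complemented; '?' is treated as '+'.  Gaps are
    runs of N of the assembly's gap size.
    """
    records: list[tuple[str, str]] = []
    for chrom in assembly.chromosomes:
        parts: list[str] = []
        for placement in chrom.components:
            seq = scaffold_seqs.get(placement.scaffold)
            if seq is None:
                raise ValueError(f"no sequence provided for scaffold {placement.scaffold}")
            if len(seq) != assembly.scaffold_lengths[placement.scaffold]:
                raise ValueError(
                    f"sequence length mismatch for scaffold {placement.scaffold}: "
                    f"{len(seq)} vs {assembly.scaffold_lengths[placement.scaffold]}"
                )
            if parts:
                parts.append("N" * assembly.gap)
            parts.append(revcomp(seq) if placement.orientation == "-" else seq)
        records.append((chrom.name, "".join(parts)))
    return records, assembly.agp_rows()


def assembly_from_agp(rows: list[AgpRow], gap: int = 100) -> AnchoredAssembly:
    """Reconstruct a minimal :class:`AnchoredAssembly` from parsed AGP rows.

    Enough for coordinate lifting and landscape analysis; marker support
    counts and chimera flags are not recoverable from AGP.
    """
    by_obj: dict[str, list[AgpRow]] = {}
    for r in rows:
        by_obj.setdefault(r.obj, []).append(r)
    chroms: list[Chromosome] = []
    scaffold_lengths: dict[str, int] = {}
    for obj in by_obj:
        comps: list[ScaffoldPlacement] = []
        spans: list[tuple[int, int]] = []
        length = 0
        for rank, r in enumerate(sorted(by_obj[obj], key=lambda r: r.part_number)):
            length = max(length, r.obj_end)
            if r.is_gap:
                continue
            comps.append(ScaffoldPlacement(r.component_id, obj, rank=len(comps), orientation=r.orientation))
            spans.append((r.obj_start, r.obj_end))
            scaffold_lengths[r.component_id] = r.comp_end - r.comp_start
        chroms.append(Chromosome(obj, obj, comps, spans, length))
    chroms.sort(key=lambda c: c.name)
    return AnchoredAssembly(chroms, [], gap, scaffold_lengths)


def assembly_stats(lengths: list[int]) -> dict:
    """N50/N90 and basic size statistics of a set of sequence lengths.

    N50 is the length of the sequence at which the cumulative sum of the
    descending-sorted lengths first reaches half the total; N90 analogous.
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    out = {"total": total, "max": srt[0], "n": len(srt)}
    for frac, key in ((0.5, "N50"), (0.9, "N90")):
        cum = 0
        for l in srt:
            cum += l
            if cum >= frac * total:
                out[key] = l
                break
    return out
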