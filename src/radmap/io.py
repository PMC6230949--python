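"""Text-format readers and writers shared by the pipeline stages.

Coordinate convention: everything held in memory is 0-based half-open.
GFF3 and AGP are written 1-based inclusive, as those formats require;
the conversion happens in this module and nowhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "FormatError",
    "Gene",
    "AgpRow",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_agp",
    "write_agp",
    "write_bed",
    "write_bedgraph",
    "write_json",
]


class FormatError(ValueError):
    """Raised when an input file violates its format; carries the line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


@dataclass(frozen=True)
class Gene:
    """A gene interval, 0-based half-open on its sequence."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval {self.gene_id}: [{self.start}, {self.end})")


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 line (component or gap), 0-based half-open in memory."""

    obj: str
    obj_start: int
    obj_end: int
    part_number: int
    component_type: str  # "W" or "U"
    component_id: str    # scaffold id, or gap length as str for gaps
    comp_start: int      # 0 for gaps
    comp_end: int
    orientation: str     # "+", "-", "?" for W; linkage evidence fields for U

    @property
    def is_gap(self) -> bool:
        return self.component_type == "U"


# ---------------------------------------------------------------------------
# FASTA

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3_genes(path, genes: Iterable[Gene]) -> None:
    """Write gene features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tradmap\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3_genes(path) -> list[Gene]:
    """Parse gene features from a GFF3 file.

    Only ``gene`` rows are kept.  Raises :class:`FormatError` with the
    offending line number on malformed input.
    """
    genes: list[Gene] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(path, line_no, f"expected 9 tab-separated fields, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(path, line_no, f"non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start1 < 1 or end1 < start1:
                raise FormatError(path, line_no, f"bad coordinate range {start1}-{end1}")
            gene_id = _attr(attrs, "ID") or f"gene_at_{seqid}_{start1}"
            genes.append(Gene(seqid, start1 - 1, end1, gene_id, strand if strand in "+-" else "+"))
    return genes


def _attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


# ---------------------------------------------------------------------------
# AGP v2.1


def write_agp(path, rows: Iterable[AgpRow]) -> None:
    """Write AGP v2.1 with 1-based inclusive coordinates.

    Gap rows are emitted as ``U`` components with gap type ``contig``,
    linkage ``yes`` and evidence ``map``.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in rows:
            if r.is_gap:
                gap_len = r.obj_end - r.obj_start
                fh.write(
                    f"{r.obj}\t{r.obj_start + 1}\t{r.obj_end}\t{r.part_number}\tU\t"
                    f"{gap_len}\tcontig\tyes\tmap\n"
                )
            else:
                fh.write(
                    f"{r.obj}\t{r.obj_start + 1}\t{r.obj_end}\t{r.part_number}\tW\t"
                    f"{r.component_id}\t{r.comp_start + 1}\t{r.comp_end}\t{r.orientation}\n"
                )


def read_agp(path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(path, line_no, f"expected 9 fields, got {len(fields)}")
            obj, ob, oe, pn, ctype = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                ob_i, oe_i, pn_i = int(ob) - 1, int(oe), int(pn)
            except ValueError:
                raise FormatError(path, line_no, "non-integer object coordinates") from None
            if ctype == "U" or ctype == "N":
                rows.append(AgpRow(obj, ob_i, oe_i, pn_i, "U", fields[5], 0, oe_i - ob_i, "na"))
            elif ctype == "W":
                try:
                    cs, ce = int(fields[6]) - 1, int(fields[7])
                except ValueError:
                    raise FormatError(path, line_no, "non-integer component coordinates") from None
                rows.append(AgpRow(obj, ob_i, oe_i, pn_i, "W", fields[5], cs, ce, fields[8]))
            else:
                raise FormatError(path, line_no, f"unsupported component type {ctype!r}")
    return rows


# ---------------------------------------------------------------------------
# BED / BEDGRAPH / JSON


def write_bed(path, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    """Write (chrom, start, end, name) as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_bedgraph(path, intervals: Iterable[tuple[str, int, int, float]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def write_json(path, obj) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
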