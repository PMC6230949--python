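"""Pseudo-testcross marker definition and F1 genotype calling.

A site is a usable marker when the seed parent is heterozygous (two alleles,
both well supported) and the pollen parent is homozygous for one of those
two alleles.  Progeny then segregate 1:1 between the homozygote (call 0) and
the heterozygote (call 1); calls below the minimum read depth are missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from radmap.linkage import MISSING

__all__ = [
    "PILEUP_COLUMNS",
    "MarkerDefinition",
    "GenotypeMatrix",
    "validate_pileup",
    "define_markers",
    "call_genotypes",
    "filter_individuals",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "read_genotype_tsv",
    "write_genotype_tsv",
]

PILEUP_COLUMNS = ["scaffold", "pos", "sample", "A", "C", "G", "T"]
ALLELES = ("A", "C", "G", "T")

_MARKER_ID_RE = re.compile(r"^UM\d{6}$")


@dataclass(frozen=True)
class MarkerDefinition:
    """One pseudo-testcross marker site.

    ``allele_het`` is the seed-parent-specific allele (its presence in a
    progeny makes the call 1); ``allele_hom`` is the allele shared with the
    homozygous pollen parent.
    """

    marker_id: str
    scaffold: str
    pos: int  # 0-based
    allele_het: str
    allele_hom: str

    def __post_init__(self):
        if not _MARKER_ID_RE.match(self.marker_id):
            raise ValueError(f"marker id must match UM followed by six digits, got {self.marker_id!r}")
        if self.allele_het == self.allele_hom:
            raise ValueError(f"{self.marker_id}: parent alleles must differ")
        for a in (self.allele_het, self.allele_hom):
            if a not in ALLELES:
                raise ValueError(f"{self.marker_id}: bad allele {a!r}")


@dataclass
class GenotypeMatrix:
    """Markers x individuals call matrix with values {0, 1, MISSING}."""

    markers: list[MarkerDefinition]
    individuals: list[str]
    calls: np.ndarray  # int8, shape (n_markers, n_individuals)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1 or missing")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing calls."""
        if self.n_markers == 0:
            return np.zeros(self.n_individuals)
        return (self.calls == MISSING).mean(axis=0)

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": [m.marker_id for m in self.markers],
                "scaffold": [m.scaffold for m in self.markers],
                "pos": [m.pos for m in self.markers],
                "allele_het": [m.allele_het for m in self.markers],
                "allele_hom": [m.allele_hom for m in self.markers],
            }
        )


def validate_pileup(pileup: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in PILEUP_COLUMNS if c not in pileup.columns]
    if missing_cols:
        raise ValueError(f"pileup is missing columns {missing_cols}")
    depths = pileup[list(ALLELES)].to_numpy()
    if (depths < 0).any():
        raise ValueError("pileup depths must be non-negative")
    if pileup.duplicated(subset=["scaffold", "pos", "sample"]).any():
        raise ValueError("pileup has duplicate (scaffold, pos, sample) records")
    return pileup


# ---------------------------------------------------------------------------
# Marker definition


def define_markers(
    pileup: pd.DataFrame,
    parent_a: str,
    parent_b: str,
    min_parent_depth: int = 5,
    het_min_minor_frac: float = 0.25,
) -> list[MarkerDefinition]:
    """Select pseudo-testcross marker sites from parental pileup evidence.

    A site qualifies iff parent A shows exactly two alleles, each with depth
    >= ``min_parent_depth`` and minor-allele fraction >= ``het_min_minor_frac``,
    and parent B shows exactly one allele (depth >= ``min_parent_depth``)
    that equals one of the two parent-A alleles.  Marker ids are assigned
    ``UM000001`` onward in (scaffold, position) lexicographic order, so they
    are stable across re-runs.
    """
    validate_pileup(pileup)
    samples = set(pileup["sample"].unique())
    for parent in (parent_a, parent_b):
        if parent not in samples:
            raise ValueError(f"parent sample {parent!r} not present in pileup")

    pa = pileup[pileup["sample"] == parent_a].set_index(["scaffold", "pos"])
    pb = pileup[pileup["sample"] == parent_b].set_index(["scaffold", "pos"])
    shared = pa.index.intersection(pb.index)

    defs: list[MarkerDefinition] = []
    pa_d = pa.loc[shared, list(ALLELES)].to_numpy()
    pb_d = pb.loc[shared, list(ALLELES)].to_numpy()
    for row_a, row_b, (scaffold, pos) in zip(pa_d, pb_d, shared):
        present_a = [k for k in range(4) if row_a[k] > 0]
        if len(present_a) != 2:
            continue
        d1, d2 = row_a[present_a[0]], row_a[present_a[1]]
        if min(d1, d2) < min_parent_depth:
            continue
        if min(d1, d2) / (d1 + d2) < het_min_minor_frac:
            continue
        present_b = [k for k in range(4) if row_b[k] > 0]
        if len(present_b) != 1:
            continue  # pollen parent polymorphic or uncovered
        if row_b[present_b[0]] < min_parent_depth:
            continue
        if present_b[0] not in present_a:
            continue
        hom = ALLELES[present_b[0]]
        het = ALLELES[present_a[0] if present_a[1] == present_b[0] else present_a[1]]
        defs.append((scaffold, int(pos), het, hom))

    defs.sort(key=lambda t: (t[0], t[1]))
    return [
        MarkerDefinition(f"UM{i + 1:06d}", scaffold, pos, het, hom)
        for i, (scaffold, pos, het, hom) in enumerate(defs)
    ]


# ---------------------------------------------------------------------------
# Genotype calling


def call_genotypes(
    pileup: pd.DataFrame,
    defs: list[MarkerDefinition],
    min_depth: int = 3,
    exclude: tuple[str, ...] = (),
    depth_rule: str = "site",
) -> GenotypeMatrix:
    """Call {0, 1, missing} genotypes at the defined markers.

    ``depth_rule='site'`` (default): the summed depth over the two marker
    alleles must reach ``min_depth``; any read of the het-specific allele
    then gives call 1, otherwise call 0.  ``depth_rule='allele'``: call 1
    needs the het-specific allele itself at ``min_depth``, call 0 needs the
    shared allele at ``min_depth``, anything else is missing.  Sites with no
    pileup record are missing.
    """
    if not defs:
        raise ValueError("no marker definitions supplied")
    if depth_rule not in ("site", "allele"):
        raise ValueError(f"depth_rule must be 'site' or 'allele', got {depth_rule!r}")
    validate_pileup(pileup)

    individuals = sorted(s for s in pileup["sample"].unique() if s not in exclude)
    ind_idx = {s: i for i, s in enumerate(individuals)}
    site_idx = {(m.scaffold, m.pos): k for k, m in enumerate(defs)}

    allele_col = {a: i for i, a in enumerate(ALLELES)}
    het_col = np.array([allele_col[m.allele_het] for m in defs])
    hom_col = np.array([allele_col[m.allele_hom] for m in defs])

    rows = pileup[pileup["sample"].isin(ind_idx)]
    keys = list(zip(rows["scaffold"], rows["pos"]))
    marker_of_row = np.array([site_idx.get(key, -1) for key in keys])
    keep = marker_of_row >= 0
    rows = rows.loc[keep]
    marker_of_row = marker_of_row[keep]
    sample_of_row = rows["sample"].map(ind_idx).to_numpy()
    depths = rows[list(ALLELES)].to_numpy()
    r = np.arange(len(rows))
    d_het = depths[r, het_col[marker_of_row]]
    d_hom = depths[r, hom_col[marker_of_row]]

    calls = np.full((len(defs), len(individuals)), MISSING, dtype=np.int8)
    if depth_rule == "site":
        covered = (d_het + d_hom) >= min_depth
        value = np.where(d_het > 0, 1, 0).astype(np.int8)
    else:
        covered = (d_het >= min_depth) | (d_hom >= min_depth)
        value = np.where(d_het >= min_depth, 1, 0).astype(np.int8)
    calls[marker_of_row[covered], sample_of_row[covered]] = value[covered]
    return GenotypeMatrix(list(defs), individuals, calls)


# ---------------------------------------------------------------------------
# Individual filtering


def filter_individuals(
    gm: GenotypeMatrix,
    max_missing: float = 0.5,
    dup_identity: float = 0.95,
    min_shared: int = 100,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Drop over-missing individuals and collapse duplicated ones.

    Individuals whose missing fraction exceeds ``max_missing`` are removed
    first.  Then for every pair sharing at least ``min_shared`` co-called
    markers with genotype identity >= ``dup_identity``, only the member with
    the fewest missing calls survives (ties broken by individual id).
    Returns the filtered matrix and a removal log.
    """
    if not 0 < max_missing <= 1:
        raise ValueError(f"max_missing must be in (0, 1], got {max_missing}")
    log: list[dict] = []
    miss = gm.missing_fraction()
    keep = miss <= max_missing
    for i in np.flatnonzero(~keep):
        log.append(
            {"individual": gm.individuals[i], "reason": "missing", "missing_fraction": float(miss[i])}
        )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("all individuals removed by the missing-data filter")

    calls = gm.calls[:, idx]
    V = (calls != MISSING).astype(np.float64)
    A = (calls == 1).astype(np.float64)
    B = V - A
    shared = V.T @ V
    matches = A.T @ A + B.T @ B
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(shared > 0, matches / shared, 0.0)

    m = idx.size
    dup = (shared >= min_shared) & (identity >= dup_identity)
    np.fill_diagonal(dup, False)

    # connected components of the duplicate graph; keep best per component
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(csr_matrix(dup), directed=False)
    drop_local: set[int] = set()
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if members.size < 2:
            continue
        ranked = sorted(members, key=lambda i: (miss[idx[i]], gm.individuals[idx[i]]))
        best = ranked[0]
        for other in ranked[1:]:
            drop_local.add(int(other))
            log.append(
                {
                    "individual": gm.individuals[idx[other]],
                    "reason": "duplicate",
                    "kept": gm.individuals[idx[best]],
                    "identity": float(identity[best, other]),
                    "shared": int(shared[best, other]),
                }
            )

    keep_local = [i for i in range(m) if i not in drop_local]
    if not keep_local:
        raise ValueError("all individuals removed")
    final_idx = idx[keep_local]
    out = GenotypeMatrix(
        gm.markers,
        [gm.individuals[i] for i in final_idx],
        gm.calls[:, final_idx],
    )
    return out, log


# ---------------------------------------------------------------------------
# TSV round trips (0-based positions; missing written as "-")


def write_pileup_tsv(path, pileup: pd.DataFrame) -> None:
    pileup.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileup_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "sample": str})
    return validate_pileup(df)


def write_genotype_tsv(path, gm: GenotypeMatrix) -> None:
    sym = np.empty(gm.calls.shape, dtype=object)
    sym[gm.calls == 0] = "0"
    sym[gm.calls == 1] = "1"
    sym[gm.calls == MISSING] = "-"
    df = pd.concat(
        [gm.marker_frame(), pd.DataFrame(sym, columns=gm.individuals)], axis=1
    )
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["marker_id", "scaffold", "pos", "allele_het", "allele_hom"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"genotype TSV is missing column {c!r}")
    individuals = [c for c in df.columns if c not in meta_cols]
    markers = [
        MarkerDefinition(r.marker_id, r.scaffold, int(r.pos), r.allele_het, r.allele_hom)
        for r in df.itertuples()
    ]
    sym = df[individuals].to_numpy()
    calls = np.full(sym.shape, MISSING, dtype=np.int8)
    calls[sym == "0"] = 0
    calls[sym == "1"] = 1
    return GenotypeMatrix(markers, individuals, calls)
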