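"""Two-point linkage analysis for a pseudo-testcross F1 design.

Markers segregate 1:1 (het x hom), so with unknown phase each co-called
individual pair of markers is either a match or a mismatch.  Under coupling
the mismatch count M out of n informative meioses is Binomial(n, r); under
repulsion it is Binomial(n, 1-r).  The phase is chosen to make the
recombinant count R = min(M, n-M), giving the maximum-likelihood estimate
r_hat = R/n and the base-10 LOD

    LOD = R*log10(2*r_hat) + (n-R)*log10(2*(1-r_hat))

i.e. the likelihood ratio against r = 0.5.  Genetic distances use Haldane's
map function (no crossover interference): d = -50*ln(1-2r) cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "haldane_cm",
    "haldane_r",
    "PairwiseLinkage",
    "PairwiseTable",
    "pairwise_linkage",
    "pairwise_all",
    "group_markers",
    "order_markers",
    "mask_isolated_flips",
    "construct_map",
    "build_map",
    "LinkageGroup",
    "LinkageMap",
]

MISSING = -1  # genotype call sentinel in int8 call matrices

# distance assigned to marker pairs with no informative meioses; far larger
# than any observable Haldane distance so ordering keeps them apart
_UNLINKED_CM = 1e6


# ---------------------------------------------------------------------------
# Haldane map function


def haldane_cm(r: float) -> float:
    """Haldane genetic distance in cM for recombination fraction ``r``.

    ``d = -50 * ln(1 - 2r)``; valid for ``0 <= r < 0.5``.
    """
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return -50.0 * np.log1p(-2.0 * r)


def haldane_r(d_cm: float) -> float:
    """Inverse Haldane: recombination fraction for a distance in cM."""
    if d_cm < 0:
        raise ValueError(f"distance must be non-negative, got {d_cm}")
    return 0.5 * -np.expm1(-d_cm / 50.0)


# ---------------------------------------------------------------------------
# Pairwise two-point statistics


@dataclass(frozen=True)
class PairwiseLinkage:
    """Two-point linkage summary for one marker pair."""

    i: int
    j: int
    n: int              # informative (co-called) meioses
    mismatches: int     # raw mismatch count M
    phase: str          # "coupling" if M <= n - M else "repulsion"
    rf: float           # min(M, n-M)/n clamped to [1/(2n), 0.5]
    lod: float

    @property
    def defined(self) -> bool:
        return self.n > 0


def _lod_from_counts(R: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized clamped rf and LOD from recombinant counts.

    Returns (rf_clamped, lod); entries with n == 0 get rf = nan, lod = nan.
    """
    n = np.asarray(n, dtype=float)
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, R / n, np.nan)
        lo = np.where(n > 0, 1.0 / (2.0 * n), np.nan)
        rf = np.clip(rf, lo, 0.5)
        lod = R * np.log10(2.0 * rf) + (n - R) * np.log10(2.0 * (1.0 - rf))
    lod = np.where(n > 0, lod, np.nan)
    return rf, lod


def pairwise_linkage(calls: np.ndarray, i: int, j: int) -> PairwiseLinkage:
    """Two-point linkage between markers ``i`` and ``j``.

    ``calls`` is the (markers x individuals) int8 matrix with values
    {0, 1, MISSING}.
    """
    a, b = calls[i], calls[j]
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        return PairwiseLinkage(i, j, 0, 0, "undefined", float("nan"), float("nan"))
    M = int((a[both] != b[both]).sum())
    phase = "coupling" if M <= n - M else "repulsion"
    R = min(M, n - M)
    rf, lod = _lod_from_counts(np.array([R]), np.array([n]))
    return PairwiseLinkage(i, j, n, M, phase, float(rf[0]), float(lod[0]))


@dataclass
class PairwiseTable:
    """Dense all-pairs two-point statistics for a marker set.

    Attributes are (k x k) symmetric arrays; ``rf`` is clamped to
    ``[1/(2n), 0.5]`` (NaN where n = 0), ``rf_raw`` is the unclamped
    ``min(M, n-M)/n`` used for genetic distances so that identical markers
    sit at distance zero.
    """

    n: np.ndarray
    mismatches: np.ndarray
    rf: np.ndarray
    rf_raw: np.ndarray
    lod: np.ndarray

    @property
    def k(self) -> int:
        return self.n.shape[0]

    def pair(self, i: int, j: int) -> PairwiseLinkage:
        n = int(self.n[i, j])
        if n == 0:
            return PairwiseLinkage(i, j, 0, 0, "undefined", float("nan"), float("nan"))
        M = int(self.mismatches[i, j])
        phase = "coupling" if M <= n - M else "repulsion"
        return PairwiseLinkage(i, j, n, M, phase, float(self.rf[i, j]), float(self.lod[i, j]))

    def distance_cm(self) -> np.ndarray:
        """Haldane distance matrix from raw rf, capped below 0.5.

        Pairs with rf_raw >= 0.5 or n = 0 get a large sentinel distance.
        """
        r = np.minimum(np.nan_to_num(self.rf_raw, nan=0.5), 0.49)
        d = -50.0 * np.log1p(-2.0 * r)
        bad = ~np.isfinite(self.rf_raw) | (self.rf_raw >= 0.5)
        d[bad] = _UNLINKED_CM
        np.fill_diagonal(d, 0.0)
        return d


def pairwise_all(calls: np.ndarray) -> PairwiseTable:
    """All-pairs two-point statistics via three matrix products.

    For 0/1 calls with missing entries, the co-called count is V@V.T with V
    the validity mask, and the mismatch count is A@B.T + B@A.T with A the
    one-calls and B the zero-calls.
    """
    V = (calls != MISSING).astype(np.float64)
    A = (calls == 1).astype(np.float64)
    B = V - A
    n = V @ V.T
    M = A @ B.T + B @ A.T
    R = np.minimum(M, n - M)
    rf, lod = _lod_from_counts(R, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        rf_raw = np.where(n > 0, R / n, np.nan)
    return PairwiseTable(
        n=n.astype(np.int64),
        mismatches=M.astype(np.int64),
        rf=rf,
        rf_raw=rf_raw,
        lod=lod,
    )


# ---------------------------------------------------------------------------
# Grouping


def group_markers(
    pairs: PairwiseTable, max_rf: float = 0.4, min_lod: float = 10.0
) -> tuple[list[list[int]], list[int]]:
    """Partition markers by single-linkage on the (rf < max_rf, LOD > min_lod) graph.

    Returns ``(groups, singletons)``: groups of size >= 2 sorted by size
    (descending, ties by smallest member index), and unplaced singletons.
    """
    with np.errstate(invalid="ignore"):
        adj = (pairs.rf < max_rf) & (pairs.lod > min_lod) & (pairs.n >= 1)
    np.fill_diagonal(adj, False)
    graph = csr_matrix(adj)
    n_comp, labels = connected_components(graph, directed=False)
    comps: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(idx)
    groups = [sorted(c) for c in comps.values() if len(c) >= 2]
    singletons = sorted(idx for c in comps.values() if len(c) == 1 for idx in c)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, singletons


# ---------------------------------------------------------------------------
# Ordering


def _bin_identical(group: list[int], pairs: PairwiseTable) -> tuple[list[int], dict[int, list[int]]]:
    """Collapse markers with zero observed mismatches into bins.

    Returns (representatives, {representative: members}); the representative
    is the smallest index of each bin and members are listed in index order.
    Binning uses connected components of the zero-mismatch graph so it is
    stable under missing-data quirks.
    """
    idx = np.array(group)
    sub_m = pairs.mismatches[np.ix_(idx, idx)]
    sub_n = pairs.n[np.ix_(idx, idx)]
    same = (sub_m == 0) & (sub_n > 0)
    n_comp, labels = connected_components(csr_matrix(same), directed=False)
    bins: dict[int, list[int]] = {}
    for local, lab in enumerate(labels):
        bins.setdefault(int(lab), []).append(int(idx[local]))
    reps = sorted(min(members) for members in bins.values())
    by_rep = {min(members): sorted(members) for members in bins.values()}
    return reps, by_rep


def _greedy_chain(d: np.ndarray, lod: np.ndarray) -> list[int]:
    """Initial path: seed with the largest-span pair, grow at nearest end."""
    k = d.shape[0]
    if k == 1:
        return [0]
    # seed: largest finite distance (break ties by higher LOD, then indices)
    finite = d < _UNLINKED_CM
    np.fill_diagonal(finite, False)
    if finite.any():
        span = np.where(finite, d, -1.0)
        best = np.argwhere(span == span.max())
        # deterministic tie-break: highest LOD then lowest (i, j)
        best_sorted = sorted(
            (tuple(ij) for ij in best),
            key=lambda ij: (-np.nan_to_num(lod[ij[0], ij[1]], nan=-1.0), ij[0], ij[1]),
        )
        a, b = best_sorted[0]
    else:
        a, b = 0, 1
    path = [int(a), int(b)]
    placed = set(path)
    while len(path) < k:
        head, tail = path[0], path[-1]
        rest = [m for m in range(k) if m not in placed]
        cand = min(rest, key=lambda m: (min(d[head, m], d[tail, m]), m))
        if d[head, cand] < d[tail, cand]:
            path.insert(0, cand)
        else:
            path.append(cand)
        placed.add(cand)
    return path


def _path_cost(path: list[int], d: np.ndarray) -> float:
    return float(sum(d[path[i], path[i + 1]] for i in range(len(path) - 1)))


def _two_opt(path: list[int], d: np.ndarray) -> list[int]:
    """2-opt plus Or-opt (segment relocation, length 1-3) to a local optimum."""
    k = len(path)
    improved = True
    while improved:
        improved = False
        # 2-opt: reverse path[i:j]
        for i in range(k - 1):
            for j in range(i + 2, k + 1):
                if i == 0 and j == k:
                    continue
                before = 0.0
                after = 0.0
                if i > 0:
                    before += d[path[i - 1], path[i]]
                    after += d[path[i - 1], path[j - 1]]
                if j < k:
                    before += d[path[j - 1], path[j]]
                    after += d[path[i], path[j]]
                if after < before - 1e-12:
                    path[i:j] = path[i:j][::-1]
                    improved = True
        # Or-opt: relocate a short segment (either orientation)
        for seg_len in (1, 2, 3):
            i = 0
            while i + seg_len <= len(path):
                seg = path[i : i + seg_len]
                trial = path[:i] + path[i + seg_len :]
                base = _path_cost(trial, d)
                best_cost = _path_cost(path, d)
                best = None
                for pos in range(len(trial) + 1):
                    gap = d[trial[pos - 1], trial[pos]] if 0 < pos < len(trial) else 0.0
                    for cand in (seg, seg[::-1]) if seg_len > 1 else (seg,):
                        cost = base - gap
                        if pos > 0:
                            cost += d[trial[pos - 1], cand[0]]
                        if pos < len(trial):
                            cost += d[cand[-1], trial[pos]]
                        cost += sum(d[a, b] for a, b in zip(cand, cand[1:]))
                        if cost < best_cost - 1e-12:
                            best_cost = cost
                            best = (pos, list(cand))
                if best is not None:
                    pos, cand = best
                    path[:] = trial[:pos] + cand + trial[pos:]
                    improved = True
                else:
                    i += 1
    return path


def order_markers(group: list[int], pairs: PairwiseTable) -> list[int]:
    """Order the markers of one linkage group.

    Identical markers (zero observed mismatches) are binned and ordered as a
    unit; bins are chained greedily from the widest well-supported pair and
    refined by 2-opt/or-opt minimizing the sum of adjacent Haldane distances.
    The result is canonicalized so the first marker index is smaller than
    the last, making reversal-equivalent orders unique.
    """
    if len(group) < 2:
        return list(group)
    reps, by_rep = _bin_identical(group, pairs)
    if len(reps) == 1:
        return by_rep[reps[0]]
    sub = np.ix_(reps, reps)
    d_full = pairs.distance_cm()
    d = d_full[sub]
    lod = pairs.lod[sub]
    # reject orderings of disconnected groups: every bin must reach another
    if len(reps) > 1 and np.all(d[~np.eye(len(reps), dtype=bool)] >= _UNLINKED_CM):
        raise ValueError("cannot order a group with no informative marker pairs")
    path = _greedy_chain(d, lod)
    path = _two_opt(path, d)
    ordered_reps = [reps[p] for p in path]
    order = [m for rep in ordered_reps for m in by_rep[rep]]
    if order[0] > order[-1]:
        order.reverse()
    return order


# ---------------------------------------------------------------------------
# Singleton (isolated double-crossover) masking


def mask_isolated_flips(
    calls: np.ndarray,
    order: list[int],
    pairs: PairwiseTable,
    max_span_cm: float = 2.0,
) -> tuple[np.ndarray, int]:
    """Mask tight double-crossover runs along an ordered group.

    For each individual, a maximal run of genotypes that disagrees with the
    nearest called neighbours on both sides (which agree with each other)
    and whose flanks lie within ``max_span_cm`` of genetic distance is
    either a genotyping error or a tight double crossover.  Such runs carry
    no reliable ordering information (they make physically distant markers
    look identical), so standard map QC sets them missing.  Operates on a
    copy; returns ``(masked_calls, n_masked_cells)``.
    """
    reps, by_rep = _bin_identical(order, pairs)
    rep_set = set(reps)
    rep_seq = [m for m in order if m in rep_set]
    masked = calls.copy()
    n_masked = 0
    k = len(rep_seq)
    if k < 3:
        return masked, 0
    d = pairs.distance_cm()
    bin_calls = masked[rep_seq]
    n = bin_calls.shape[1]
    for ind in range(n):
        col = bin_calls[:, ind]
        called = np.flatnonzero(col != MISSING)
        if called.size < 3:
            continue
        vals = col[called]
        # maximal runs of constant value strictly inside the called sequence
        change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(vals)]])
        for s, e in zip(starts, ends):
            if s == 0 or e == len(vals):
                continue  # runs touching the ends are not bracketed
            if vals[s - 1] != vals[e]:
                continue  # flanks disagree: a genuine single crossover nearby
            left, right = called[s - 1], called[e]
            # direct flank-to-flank distance: unlike the path through the
            # run it is not inflated by the run's own mismatches
            if d[rep_seq[left], rep_seq[right]] > max_span_cm:
                continue
            for local in range(s, e):
                rep = rep_seq[called[local]]
                for member in by_rep[rep]:
                    if masked[member, ind] != MISSING:
                        masked[member, ind] = MISSING
                        n_masked += 1
    return masked, n_masked


def construct_map(
    calls: np.ndarray,
    max_rf: float = 0.4,
    min_lod: float = 10.0,
    mask_singletons: bool = True,
) -> tuple["LinkageMap", PairwiseTable, list[list[int]], list[int], int]:
    """Full map construction: pairwise, group, order, QC-mask, re-order, place.

    Returns ``(map, pairs, groups, singletons, n_masked)`` where ``pairs``
    are the statistics used for the final distances (post-masking when
    ``mask_singletons`` is set).
    """
    pairs = pairwise_all(calls)
    groups, singletons = group_markers(pairs, max_rf, min_lod)
    orders = [order_markers(g, pairs) for g in groups]
    n_masked = 0
    if mask_singletons and groups:
        work = calls
        for _ in range(3):  # masking can expose further runs after re-binning
            round_masked = 0
            for order in orders:
                work, masked = mask_isolated_flips(work, order, pairs)
                round_masked += masked
            if round_masked == 0:
                break
            n_masked += round_masked
            pairs = pairwise_all(work)
            orders = [order_markers(g, pairs) for g in groups]
    lmap = build_map(pairs, orders)
    return lmap, pairs, groups, singletons, n_masked


# ---------------------------------------------------------------------------
# Map construction


@dataclass
class LinkageGroup:
    name: str
    markers: list[int]            # ordered marker indices
    positions_cm: np.ndarray      # cumulative Haldane positions, same order

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.positions_cm) else 0.0


@dataclass
class LinkageMap:
    groups: list[LinkageGroup] = field(default_factory=list)

    @property
    def total_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)


def build_map(pairs: PairwiseTable, orders: list[list[int]], names: list[str] | None = None) -> LinkageMap:
    """Cumulative Haldane positions from adjacent-pair recombination fractions.

    Adjacent identical markers (raw rf 0) sit at the same position; other
    adjacent distances are Haldane transforms of the raw rf estimate.
    """
    d_full = pairs.distance_cm()
    groups = []
    for g_idx, order in enumerate(orders):
        name = names[g_idx] if names else f"LG{g_idx + 1}"
        pos = np.zeros(len(order))
        for a in range(1, len(order)):
            i, j = order[a - 1], order[a]
            # identical markers: zero distance even when rf is clamped
            step = 0.0 if (pairs.mismatches[i, j] == 0 and pairs.n[i, j] > 0) else d_full[i, j]
            if step >= _UNLINKED_CM:
                step = 0.0  # uninformative adjacency contributes no length
            pos[a] = pos[a - 1] + step
        groups.append(LinkageGroup(name, list(order), pos))
    return LinkageMap(groups)
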