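"""Bounded single-linkage clustering of barcode sequences.

Reimplementation of the nucleotide-sequence clusterizer at the heart of the
counting scheme: starting from singleton clusters, any two sequences that
differ at no more than *Distance* of the compared positions have their
clusters merged, and merging continues to the transitive closure.  With
Distance = 0 the cluster count equals the number of distinct barcode strings,
i.e. the classical unique-barcode count.

The scalable implementation deduplicates barcode strings and generates
candidate pairs by pigeonhole partitioning: the compared positions are split
into Distance+1 contiguous segments, and any pair within the bound must agree
exactly on at least one segment.  Candidates sharing a segment are verified
with an explicit mismatch count, so the partition is exact, not heuristic.
A naive all-pairs union-find oracle is retained for testing.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import BarcodeDesign, Cluster, ReadObservation


@dataclass(frozen=True)
class ClusteringParams:
    """Parameters of barcode clustering.

    ``distance`` is the merge bound (maximum mismatches between two barcodes
    for their clusters to merge).  Compared positions default to every random
    position of the design; ``n_random_bases`` truncates to the first k random
    positions (5' first), and ``positions`` overrides with an explicit 1-based
    subset of barcode positions.
    """

    distance: int = 2
    n_random_bases: int | None = None
    positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.n_random_bases is not None and self.n_random_bases < 1:
            raise ValueError("n_random_bases must be >= 1")
        if self.positions is not None and len(self.positions) == 0:
            raise ValueError("positions must be non-empty")

    def resolve_positions(self, design: BarcodeDesign) -> tuple[int, ...]:
        """Concrete compared positions for one design."""
        if self.positions is not None:
            return self.positions
        randoms = tuple(sorted(design.random_positions))
        if self.n_random_bases is None:
            return randoms
        if self.n_random_bases > len(randoms):
            raise ValueError(
                f"design {design.name} has only {len(randoms)} random bases"
            )
        return randoms[: self.n_random_bases]


def masked_hamming(b1: str, b2: str, positions: Sequence[int] | None = None) -> int:
    """Number of compared positions at which two barcodes differ.

    ``positions`` are 1-based barcode positions; by default all positions are
    compared.  Both barcodes must cover every compared position.
    """
    if positions is None:
        if len(b1) != len(b2):
            raise ValueError("barcodes of unequal length need explicit positions")
        return sum(a != b for a, b in zip(b1, b2))
    top = max(positions)
    if len(b1) < top or len(b2) < top:
        raise ValueError("barcode does not cover all compared positions")
    return sum(b1[p - 1] != b2[p - 1] for p in positions)


def comparison_key(barcode: str, design: BarcodeDesign, params: ClusteringParams) -> str:
    """Project a barcode onto the compared positions, as a string key.

    Keys from different designs are comparable whenever the same number of
    random bases is selected, which is how reads of different templates are
    clustered together for contamination/misidentification resolution.
    """
    return "".join(barcode[p - 1] for p in params.resolve_positions(design))


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.rank[ri] < self.rank[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        if self.rank[ri] == self.rank[rj]:
            self.rank[ri] += 1


def _segments(length: int, n_segments: int) -> list[tuple[int, int]]:
    """Split ``range(length)`` into ``n_segments`` near-equal contiguous slices."""
    bounds = [round(i * length / n_segments) for i in range(n_segments + 1)]
    return [(bounds[i], bounds[i + 1]) for i in range(n_segments)]


def cluster_keys(keys: Sequence[str], distance: int) -> list[list[int]]:
    """Partition key strings under the bounded single-linkage relation.

    Returns member index lists, one per cluster, each sorted ascending, with
    clusters ordered by their lexicographically smallest key.  Two keys share
    a cluster iff they are connected by a chain of pairwise mismatch counts
    <= ``distance``; the result is therefore invariant to input order.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    n = len(keys)
    if n == 0:
        return []
    lengths = {len(k) for k in keys}
    if len(lengths) > 1:
        raise ValueError("all keys must have equal length")
    (length,) = lengths

    # Deduplicate: identical keys always co-cluster, and multiplicities are
    # reattached afterwards, so the pairwise search runs on distinct keys only.
    first_of: dict[str, int] = {}
    members: dict[int, list[int]] = defaultdict(list)
    distinct: list[str] = []
    for i, key in enumerate(keys):
        slot = first_of.setdefault(key, len(distinct))
        if slot == len(distinct):
            distinct.append(key)
        members[slot].append(i)

    m = len(distinct)
    uf = _UnionFind(m)
    if distance >= length:
        for i in range(1, m):
            uf.union(0, i)
    elif distance > 0:
        for lo, hi in _segments(length, distance + 1):
            buckets: dict[str, list[int]] = defaultdict(list)
            for i, key in enumerate(distinct):
                buckets[key[lo:hi]].append(i)
            for bucket in buckets.values():
                if len(bucket) < 2:
                    continue
                for a in range(len(bucket) - 1):
                    i = bucket[a]
                    ki = distinct[i]
                    for b in range(a + 1, len(bucket)):
                        j = bucket[b]
                        if uf.find(i) == uf.find(j):
                            continue
                        d = 0
                        for x, y in zip(ki, distinct[j]):
                            if x != y:
                                d += 1
                                if d > distance:
                                    break
                        if d <= distance:
                            uf.union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for slot in range(m):
        groups[uf.find(slot)].extend(members[slot])
    result = [sorted(g) for g in groups.values()]
    result.sort(key=lambda g: min(keys[i] for i in g))
    return result


def naive_cluster_keys(keys: Sequence[str], distance: int) -> list[list[int]]:
    """O(n^2) all-pairs union-find reference implementation (testing oracle)."""
    n = len(keys)
    if n == 0:
        return []
    if len({len(k) for k in keys}) > 1:
        raise ValueError("all keys must have equal length")
    uf = _UnionFind(n)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if sum(a != b for a, b in zip(keys[i], keys[j])) <= distance:
                uf.union(i, j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[uf.find(i)].append(i)
    result = [sorted(g) for g in groups.values()]
    result.sort(key=lambda g: min(keys[i] for i in g))
    return result


def count_unique(barcodes: Iterable[str]) -> int:
    """Number of distinct barcode strings (= cluster count at Distance 0)."""
    return len(set(barcodes))


def cluster_observations(
    observations: Sequence[ReadObservation], params: ClusteringParams
) -> list[Cluster]:
    """Cluster reads by barcode key and tally members per index and category.

    Each observation must carry an extracted barcode and its design.  The
    cluster id is the lexicographically smallest member key; multi-mapped
    reads contribute fractional weight 1/k to each of their k templates'
    ``(template, index)`` tallies.
    """
    keys = [comparison_key(obs.barcode, obs.design, params) for obs in observations]
    clusters = []
    for group in cluster_keys(keys, params.distance):
        cl = Cluster(cluster_id=min(keys[i] for i in group))
        for i in group:
            obs = observations[i]
            cl.members.append(obs)
            cl.reads_by_index[obs.sample_index] = (
                cl.reads_by_index.get(obs.sample_index, 0) + 1
            )
            if obs.templates:
                w = 1.0 / len(obs.templates)
                for tid in obs.templates:
                    cat = (tid, obs.sample_index)
                    cl.reads_by_category[cat] = cl.reads_by_category.get(cat, 0.0) + w
        clusters.append(cl)
    return clusters
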