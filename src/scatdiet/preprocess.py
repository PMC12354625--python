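"""Read-to-cluster preprocessing.

Four stages turn raw per-sample reads into a clean set of unique sequences
with abundances:

1. exact dereplication — collapse reads identical in sequence and length,
   pooled across samples while tracking per-sample membership counts;
2. minimum-cluster-size filter — drop clusters carried by fewer than three
   reads (singletons and doubletons are overwhelmingly sequencing error);
3. denoising — greedy centroid pass in decreasing-abundance order merging
   low-abundance error variants into nearby centroids using the abundance-skew
   rule beta(d) = 1 / 2**(alpha*d + 1): a cluster may be absorbed by a centroid
   at edit distance d only if its size is at most beta(d) times the centroid's.
   All cluster sizes are retained (no minimum size inside this step);
4. de-novo chimera screening — a cluster is flagged bimeric when two parents,
   each at least ``min_parent_skew`` times more abundant, reconstruct it
   exactly via a single crossover.

Ties are broken everywhere by decreasing size then lexicographic centroid, so
every stage is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import edlib

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass
class SeqCluster:
    """A unique sequence with its pooled abundance and per-sample counts."""

    cluster_id: str
    centroid: str
    size: int
    sample_counts: dict[str, int] = field(default_factory=dict)

    def copy(self) -> "SeqCluster":
        return SeqCluster(self.cluster_id, self.centroid, self.size, dict(self.sample_counts))


@dataclass
class DenoiseParams:
    """UNOISE-style skew rule: beta(d) = 1 / 2**(alpha*d + 1)."""

    alpha: float = 2.0
    max_distance: int | None = None  # optional cap on the merge distance

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def beta(self, d: int) -> float:
        return 1.0 / 2.0 ** (self.alpha * d + 1.0)


@dataclass
class ChimeraParams:
    """Exact two-parent bimera model: both parents must be at least
    ``min_parent_skew`` times more abundant than the query."""

    min_parent_skew: float = 16.0

    def __post_init__(self) -> None:
        if self.min_parent_skew < 1:
            raise ValueError("min_parent_skew must be >= 1")


ReadsInput = Union[Mapping[str, Iterable[str]], Iterable[tuple[str, Iterable[str]]]]


def dereplicate(reads_by_sample: ReadsInput) -> list[SeqCluster]:
    """Collapse identical reads (same sequence, hence same length) into
    clusters, pooled across samples.

    Accepts a mapping ``sample_id -> reads`` or an iterable of
    ``(sample_id, reads)`` pairs (the latter allows streaming generation).
    Reads containing characters outside A/C/G/T are rejected per read, with
    the rejected count logged. Output is ordered by decreasing size, ties
    broken lexicographically by sequence.
    """
    if isinstance(reads_by_sample, Mapping):
        pairs: Iterable[tuple[str, Iterable[str]]] = reads_by_sample.items()
    else:
        pairs = reads_by_sample

    counts: dict[str, dict[str, int]] = {}
    rejected = 0
    for sample_id, reads in pairs:
        for read in reads:
            if not read or not _VALID.issuperset(read):
                rejected += 1
                continue
            per_sample = counts.setdefault(read, {})
            per_sample[sample_id] = per_sample.get(sample_id, 0) + 1
    if rejected:
        logger.warning("dereplicate: rejected %d reads with non-ACGT characters", rejected)

    ordered = sorted(
        counts.items(), key=lambda kv: (-sum(kv[1].values()), kv[0])
    )
    return [
        SeqCluster(f"c{i:06d}", seq, sum(per_sample.values()), dict(per_sample))
        for i, (seq, per_sample) in enumerate(ordered)
    ]


def filter_small_clusters(clusters: list[SeqCluster], min_size: int = 3) -> list[SeqCluster]:
    """Retain clusters with size >= min_size, preserving input order."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [c for c in clusters if c.size >= min_size]
    logger.info("filter_small_clusters: kept %d of %d clusters (min_size=%d)",
                len(kept), len(clusters), min_size)
    return kept


def denoise(clusters: list[SeqCluster], params: DenoiseParams | None = None) -> list[SeqCluster]:
    """Merge likely error variants into more abundant centroids.

    Greedy single pass in decreasing-size order: each cluster merges into the
    first already-accepted centroid within the skew rule; otherwise it becomes
    a centroid itself. Merging adds sizes and per-sample counts, so total read
    count is conserved. Distances are Levenshtein (edlib), tolerating both
    substitutions and length slippage.
    """
    params = params or DenoiseParams()
    order = sorted(clusters, key=lambda c: (-c.size, c.centroid))
    accepted: list[SeqCluster] = []
    for cand in order:
        target = None
        for cen in accepted:
            if cand.size * 2.0 ** (params.alpha + 1.0) > cen.size:
                continue  # even d=1 cannot satisfy the skew rule
            # largest d for which beta(d) * centroid size >= candidate size
            d_allow = math.floor((math.log2(cen.size / cand.size) - 1.0) / params.alpha + 1e-9)
            if params.max_distance is not None:
                d_allow = min(d_allow, params.max_distance)
            if d_allow < 1:
                continue
            d = edlib.align(cand.centroid, cen.centroid, mode="NW", task="distance",
                            k=d_allow)["editDistance"]
            if d >= 1 and cand.size <= cen.size * params.beta(d):
                target = cen
                break
        if target is None:
            accepted.append(cand.copy())
        else:
            target.size += cand.size
            for s, n in cand.sample_counts.items():
                target.sample_counts[s] = target.sample_counts.get(s, 0) + n
    accepted.sort(key=lambda c: (-c.size, c.centroid))
    logger.info("denoise: %d clusters -> %d centroids", len(clusters), len(accepted))
    return accepted


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def remove_chimeras(clusters: list[SeqCluster], params: ChimeraParams | None = None) -> list[SeqCluster]:
    """Drop clusters explainable as exact two-parent bimeras.

    A cluster Q is flagged iff two distinct clusters P1 != P2, each with size
    >= min_parent_skew * size(Q), reconstruct Q as P1[:k] + P2[k:] for some
    crossover 1 <= k < len(Q). Non-flagged clusters pass through unchanged,
    in input order.
    """
    params = params or ChimeraParams()
    kept: list[SeqCluster] = []
    flagged = 0
    by_size = sorted(clusters, key=lambda c: -c.size)
    neg_sizes = [-c.size for c in by_size]
    import bisect

    for q in clusters:
        # candidates form a prefix of the size-sorted list
        cut = bisect.bisect_right(neg_sizes, -params.min_parent_skew * q.size)
        parents = [p for p in by_size[:cut] if p is not q]
        if len(parents) >= 2 and _is_bimera(q.centroid, parents):
            flagged += 1
            logger.debug("remove_chimeras: flagged %s (size %d)", q.cluster_id, q.size)
            continue
        kept.append(q)
    if flagged:
        logger.info("remove_chimeras: removed %d of %d clusters", flagged, len(clusters))
    return kept


def _is_bimera(q: str, parents: list[SeqCluster]) -> bool:
    L = len(q)
    # best and second-best prefix/suffix matches, with owners, so the two
    # parents can be required to be distinct clusters
    best_pre: list[tuple[int, int]] = []  # (length, parent index)
    best_suf: list[tuple[int, int]] = []
    for idx, p in enumerate(parents):
        pre = _common_prefix(q, p.centroid)
        if pre >= 1:
            best_pre.append((pre, idx))
        if len(p.centroid) == L:
            suf = _common_suffix(q, p.centroid)
            if suf >= 1 and suf < L:
                best_suf.append((suf, idx))
    best_pre.sort(reverse=True)
    best_suf.sort(reverse=True)
    for pre, i1 in best_pre[:2]:
        for suf, i2 in best_suf[:2]:
            if i1 != i2 and pre + suf >= L:
                return True
    return False
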