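"""Alignment-hit filtering and majority lowest-common-ancestor assignment.

Each query (a denoised cluster) carries a set of alignment hits against the
reference database. Hits are first filtered to the top 2% bit-score window of
the query's best hit, with at least 90% query coverage and at least 98%
identity (all thresholds inclusive). The surviving hits are deduplicated to
their unique taxonomic lineages and a consensus walk descends the seven ranks:
at each rank the modal taxon among lineages consistent with the accepted
prefix is adopted if it captures at least 80% of all unique lineages; the walk
stops at the first rank that fails, at a modal tie, and the assignment is the
deepest accepted prefix. A single unique lineage is assigned in full.
Assignments that resolve only above order are reported as unassigned.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import edlib
import pandas as pd

from .errors import ConsistencyError, HitParseError
from .preprocess import SeqCluster
from .synthetic import HIT_COLUMNS, ReferenceDatabase
from .taxonomy import RANKS, Lineage, Taxonomy

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-reference match."""

    query_id: str
    taxon_id: str
    lineage: Lineage
    bit_score: float
    percent_identity: float
    percent_coverage: float

    def __post_init__(self) -> None:
        if self.bit_score <= 0:
            raise ValueError("bit_score must be > 0")
        for v in (self.percent_identity, self.percent_coverage):
            if not 0.0 <= v <= 100.0:
                raise ValueError("identity/coverage must be in [0, 100]")


@dataclass
class AssignmentParams:
    bitscore_window: float = 0.02
    min_coverage: float = 90.0
    min_identity: float = 98.0
    agreement: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.bitscore_window < 1.0:
            raise ValueError("bitscore_window must be in (0,1)")
        if not 0.0 < self.agreement <= 1.0:
            raise ValueError("agreement must be in (0,1]")


def parse_hits(path, taxonomy: Taxonomy) -> list[AlignmentHit]:
    """Read a tab-separated hit file in the documented dialect (outfmt-6 plus
    an appended percent-query-coverage column).

    Rows referencing taxon_ids absent from the lineage table are rejected with
    a logged count; malformed rows raise :class:`HitParseError` naming the
    line number.
    """
    hits: list[AlignmentHit] = []
    unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                raise HitParseError(
                    f"{path}: line {lineno}: expected {len(HIT_COLUMNS)} fields, got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                bitscore = float(fields[11])
                qcovs = float(fields[12])
            except ValueError as exc:
                raise HitParseError(f"{path}: line {lineno}: {exc}") from None
            if sid not in taxonomy:
                unknown += 1
                continue
            hits.append(
                AlignmentHit(qid, sid, taxonomy.lineage(sid), bitscore, pident, qcovs)
            )
    if unknown:
        logger.warning("parse_hits: rejected %d rows with unknown taxon_ids", unknown)
    return hits


def hits_from_frame(frame: pd.DataFrame, taxonomy: Taxonomy) -> list[AlignmentHit]:
    """Build hits from an in-memory table in the documented dialect."""
    hits = []
    unknown = 0
    for row in frame.itertuples(index=False):
        sid = row.sseqid
        if sid not in taxonomy:
            unknown += 1
            continue
        hits.append(
            AlignmentHit(row.qseqid, sid, taxonomy.lineage(sid),
                         float(row.bitscore), float(row.pident), float(row.qcovs))
        )
    if unknown:
        logger.warning("hits_from_frame: rejected %d rows with unknown taxon_ids", unknown)
    return hits


def filter_hits(hits: Sequence[AlignmentHit], params: AssignmentParams | None = None) -> list[AlignmentHit]:
    """Apply the per-query retention rule: bit-score within the top window of
    the query's best hit, coverage and identity at or above their minima.
    All thresholds are inclusive."""
    params = params or AssignmentParams()
    if not hits:
        return []
    cutoff = (1.0 - params.bitscore_window) * max(h.bit_score for h in hits)
    return [
        h for h in hits
        if h.bit_score >= cutoff
        and h.percent_coverage >= params.min_coverage
        and h.percent_identity >= params.min_identity
    ]


def mlca(hits: Sequence[AlignmentHit], params: AssignmentParams | None = None) -> Optional[Lineage]:
    """Majority lowest-common-ancestor consensus over filtered hits.

    Returns the assigned lineage (possibly truncated) or None (unassigned).
    The vote at each rank counts unique lineages, restricted to those
    consistent with the already-accepted prefix; the modal share is taken over
    ALL unique lineages. A tie for the modal taxon stops the walk.
    """
    params = params or AssignmentParams()
    unique = sorted({h.lineage.names for h in hits})
    if not unique:
        return None
    if len(unique) == 1:
        lin = Lineage(unique[0])
        return lin if lin.is_assignable else None

    total = len(unique)
    consistent = unique
    depth = 0
    for r in range(len(RANKS)):
        votes = Counter(names[r] for names in consistent if names[r] != "")
        if not votes:
            break
        ranked = votes.most_common(2)
        if len(ranked) == 2 and ranked[0][1] == ranked[1][1]:
            break  # modal tie: stop at the previous rank
        name, count = ranked[0]
        if count / total < params.agreement:
            break
        consistent = [names for names in consistent if names[r] == name]
        depth = r + 1
    if depth == 0:
        return None
    lin = Lineage(consistent[0][:depth] + ("",) * (len(RANKS) - depth))
    return lin if lin.is_assignable else None


def assign_queries(
    hits: Iterable[AlignmentHit],
    query_ids: Iterable[str],
    params: AssignmentParams | None = None,
) -> dict[str, Optional[Lineage]]:
    """Filter and assign every query; queries without hits map to None."""
    params = params or AssignmentParams()
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    return {
        qid: mlca(filter_hits(by_query.get(qid, []), params), params)
        for qid in query_ids
    }


CountsInput = Union[Sequence[SeqCluster], Mapping[str, Mapping[str, int]]]


def assign_counts(
    assignments: Mapping[str, Optional[Lineage]],
    cluster_counts: CountsInput,
) -> pd.DataFrame:
    """Propagate per-sample cluster read counts onto assigned taxa.

    ``cluster_counts`` is either a list of SeqCluster (cluster_id = query_id)
    or a mapping query_id -> {sample_id: reads}. Returns a long table with
    columns sample_id, taxon, rank, reads; unassigned queries accumulate under
    the explicit 'unassigned' taxon. Counts for queries assigned to the same
    taxonomic identity are summed per sample.
    """
    if not isinstance(cluster_counts, Mapping):
        cluster_counts = {c.cluster_id: c.sample_counts for c in cluster_counts}
    missing = [q for q in assignments if q not in cluster_counts]
    if missing:
        raise ConsistencyError(f"queries with no cluster record: {missing[:5]}")

    acc: dict[tuple[str, str, str], int] = {}
    for qid, lineage in assignments.items():
        if lineage is None:
            taxon, rank = UNASSIGNED, UNASSIGNED
        else:
            taxon, rank = lineage.deepest_name, lineage.deepest_rank
        for sample_id, n in cluster_counts[qid].items():
            key = (sample_id, taxon, rank)
            acc[key] = acc.get(key, 0) + int(n)

    rows = [
        dict(sample_id=s, taxon=t, rank=r, reads=n)
        for (s, t, r), n in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["sample_id", "taxon", "rank", "reads"])


def align_clusters(
    clusters: Sequence[SeqCluster],
    db: ReferenceDatabase,
    *,
    max_edit_fraction: float = 0.05,
) -> list[AlignmentHit]:
    """Minimal built-in pairwise scorer so end-to-end runs need no external
    aligner; real BLAST tabular output is the primary input path.

    Each centroid is globally aligned (edlib, Levenshtein) against every
    reference; matches within ``max_edit_fraction`` edits are reported with
    identity = matches / alignment-span, full query coverage, and a surrogate
    bit-score of 2 x matches (monotone in alignment quality). References
    further away than the cap yield no hit — they could never pass the
    identity filter downstream.
    """
    hits: list[AlignmentHit] = []
    refs = [(tid, db.sequence(tid), db[tid].lineage) for tid in db.ids]
    for c in clusters:
        qlen = len(c.centroid)
        for tid, rseq, lineage in refs:
            span = max(qlen, len(rseq))
            k = max(1, int(span * max_edit_fraction) + 1)
            d = edlib.align(c.centroid, rseq, mode="NW", task="distance", k=k)["editDistance"]
            if d < 0:
                continue
            matches = span - d
            hits.append(
                AlignmentHit(
                    query_id=c.cluster_id,
                    taxon_id=tid,
                    lineage=lineage,
                    bit_score=2.0 * matches,
                    percent_identity=100.0 * matches / span,
                    percent_coverage=100.0,
                )
            )
    return hits
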