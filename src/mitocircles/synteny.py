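"""MEM-anchored whole-genome comparison into local collinear blocks.

The comparison follows the classic nucmer/delta-filter recipe: find all
maximal exact matches (MEMs) of at least ``min_anchor`` bp on both
strands, chain co-diagonal same-strand anchors whose gaps stay below
``max_gap``, score each chain's gaps by alignment, and keep chains
passing the minimum length and identity thresholds as local collinear
blocks (LCBs).  Coverage and breakpoint statistics over the signed
permutation of LCB order quantify rearrangement between genomes; the
breakpoint count is reported as a lower bound on rearrangement events,
which is how whole-genome dot plots are normally read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .io import SeqRecord, revcomp

__all__ = [
    "Anchor",
    "LCB",
    "SyntenyConfig",
    "find_anchors",
    "chain_to_lcbs",
    "coverage_and_rearrangements",
    "dotplot_table",
]


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match.  1-based starts; ``query_start`` is on the
    forward query strand regardless of anchor strand."""

    ref_start: int
    query_start: int
    length: int
    strand: str  # "+" | "-"
    query_id: str = ""

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length - 1

    @property
    def query_end(self) -> int:
        return self.query_start + self.length - 1


@dataclass
class LCB:
    ref_start: int
    ref_end: int
    query_id: str
    query_start: int
    query_end: int
    strand: str
    identity: float
    length: int


@dataclass
class SyntenyConfig:
    min_anchor: int = 20
    max_gap: int = 1000
    min_len: int = 100
    min_identity: float = 0.80

    def __post_init__(self) -> None:
        if self.min_len < self.min_anchor:
            raise ValueError("min_len must be >= min_anchor")


def _mem_runs(ref: str, query: str, k: int):
    """Maximal exact matches >= k between ref and (forward) query via
    shared-k-mer runs on each diagonal.  Yields (ref0, query0, length),
    0-based."""
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i : i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for j in range(len(query) - k + 1):
        for i in index.get(query[j : j + k], ()):
            by_diag.setdefault(i - j, []).append(j)
    for d, qs in sorted(by_diag.items()):
        qs.sort()
        run_start = qs[0]
        prev = qs[0]
        for q in qs[1:] + [None]:
            if q is not None and q == prev + 1:
                prev = q
                continue
            yield run_start + d, run_start, (prev - run_start) + k
            if q is not None:
                run_start = prev = q


def find_anchors(
    ref: SeqRecord, query: SeqRecord, cfg: SyntenyConfig | None = None
) -> list[Anchor]:
    """All maximal exact matches >= ``min_anchor`` bp, both strands.

    Left/right maximality holds by construction: a co-diagonal k-mer run
    ends exactly where the flanking bases disagree.
    """
    cfg = cfg or SyntenyConfig()
    k = cfg.min_anchor
    anchors: list[Anchor] = []
    for r0, q0, length in _mem_runs(ref.sequence, query.sequence, k):
        anchors.append(Anchor(r0 + 1, q0 + 1, length, "+", query.id))
    rc = revcomp(query.sequence)
    n = len(query.sequence)
    for r0, q0, length in _mem_runs(ref.sequence, rc, k):
        fwd_start = n - (q0 + length)  # leftmost coordinate on forward strand
        anchors.append(Anchor(r0 + 1, fwd_start + 1, length, "-", query.id))
    anchors.sort(key=lambda a: (a.ref_start, a.query_start, a.strand))
    return anchors


def chain_to_lcbs(
    anchors: list[Anchor],
    cfg: SyntenyConfig | None = None,
    ref: SeqRecord | None = None,
    query: SeqRecord | None = None,
) -> list[LCB]:
    """Chain consistent anchors into LCBs and filter by length/identity.

    Same-strand anchors are chained greedily in reference order when both
    the reference and query gaps to the chain tail are at most
    ``max_gap`` and the query side advances in the strand's direction.
    When sequences are supplied, each chain's inter-anchor gaps are
    aligned (edit distance over the gap region) and block identity is
    ``1 - edits / block_length``; without sequences the anchor coverage
    of the block serves as a lower bound on identity.
    """
    cfg = cfg or SyntenyConfig()
    chains: list[list[Anchor]] = []
    open_chains: list[list[Anchor]] = []
    for anchor in sorted(anchors, key=lambda a: (a.ref_start, a.query_start)):
        best = None
        for chain in open_chains:
            tail = chain[-1]
            if tail.strand != anchor.strand or tail.query_id != anchor.query_id:
                continue
            ref_gap = anchor.ref_start - tail.ref_end - 1
            if ref_gap < -tail.length or ref_gap > cfg.max_gap:
                continue
            if anchor.strand == "+":
                q_gap = anchor.query_start - tail.query_end - 1
            else:
                q_gap = tail.query_start - anchor.query_end - 1
            if q_gap < -tail.length or q_gap > cfg.max_gap:
                continue
            best = chain
            break
        if best is None:
            open_chains.append([anchor])
        else:
            best.append(anchor)
    chains = open_chains

    lcbs: list[LCB] = []
    for chain in chains:
        ref_start = min(a.ref_start for a in chain)
        ref_end = max(a.ref_end for a in chain)
        q_start = min(a.query_start for a in chain)
        q_end = max(a.query_end for a in chain)
        length = ref_end - ref_start + 1
        if length < cfg.min_len:
            continue
        identity = _chain_identity(chain, ref, query, length)
        if identity < cfg.min_identity:
            continue
        lcbs.append(
            LCB(
                ref_start=ref_start,
                ref_end=ref_end,
                query_id=chain[0].query_id,
                query_start=q_start,
                query_end=q_end,
                strand=chain[0].strand,
                identity=round(identity, 4),
                length=length,
            )
        )
    lcbs.sort(key=lambda b: (b.ref_start, b.query_id, b.query_start))
    return lcbs


def _chain_identity(
    chain: list[Anchor], ref: SeqRecord | None, query: SeqRecord | None, length: int
) -> float:
    matched = 0
    prev_ref_end = None
    for a in chain:
        start = a.ref_start if prev_ref_end is None else max(a.ref_start, prev_ref_end + 1)
        matched += max(0, a.ref_end - start + 1)
        prev_ref_end = max(prev_ref_end or 0, a.ref_end)
    if ref is None or query is None:
        return matched / length
    edits = 0
    strand = chain[0].strand
    qseq = query.sequence if strand == "+" else revcomp(query.sequence)
    n = len(query.sequence)

    def q_fwd_to_oriented(pos_1based: int) -> int:  # 0-based in oriented seq
        return pos_1based - 1 if strand == "+" else n - pos_1based

    for prev, nxt in zip(chain, chain[1:]):
        r_gap = ref.sequence[prev.ref_end : nxt.ref_start - 1]
        if strand == "+":
            qa = q_fwd_to_oriented(prev.query_end) + 1
            qb = q_fwd_to_oriented(nxt.query_start)
        else:
            qa = q_fwd_to_oriented(prev.query_start) + 1
            qb = q_fwd_to_oriented(nxt.query_end)
        q_gap = qseq[qa:qb] if qb > qa else ""
        if not r_gap and not q_gap:
            continue
        if not r_gap or not q_gap:
            edits += max(len(r_gap), len(q_gap))
            continue
        edits += edlib.align(r_gap, q_gap, mode="NW")["editDistance"]
    return max(0.0, 1.0 - edits / length)


def coverage_and_rearrangements(
    lcbs: list[LCB], query_lengths: dict[str, int]
) -> dict[str, float | int]:
    """Coverage of the query by LCBs and breakpoint-based rearrangement
    statistics.

    Coverage is the union of query bases inside LCBs over the total query
    length.  Breakpoints are counted on the signed permutation of LCB
    order: a consecutive reference pair is preserved only when it stays
    adjacent, co-oriented and on one query chromosome.  Each reversal or
    translocation disturbs at most two adjacencies, so
    ``ceil(breakpoints / 2)`` is reported as the "at least N" bound.
    """
    total = sum(query_lengths.values())
    per_query: dict[str, list[tuple[int, int]]] = {}
    for b in lcbs:
        per_query.setdefault(b.query_id, []).append((b.query_start, b.query_end))
    covered = 0
    for ivals in per_query.values():
        ivals.sort()
        cur_a, cur_b = ivals[0]
        for a, bb in ivals[1:]:
            if a > cur_b + 1:
                covered += cur_b - cur_a + 1
                cur_a, cur_b = a, bb
            else:
                cur_b = max(cur_b, bb)
        covered += cur_b - cur_a + 1

    by_ref = sorted(lcbs, key=lambda b: b.ref_start)
    by_query = sorted(lcbs, key=lambda b: (b.query_id, b.query_start))
    rank = {id(b): i for i, b in enumerate(by_query)}
    breakpoints = 0
    for prev, nxt in zip(by_ref, by_ref[1:]):
        if prev.query_id != nxt.query_id or prev.strand != nxt.strand:
            breakpoints += 1
        elif prev.strand == "+" and rank[id(nxt)] != rank[id(prev)] + 1:
            breakpoints += 1
        elif prev.strand == "-" and rank[id(nxt)] != rank[id(prev)] - 1:
            breakpoints += 1
    return {
        "n_lcbs": len(lcbs),
        "covered_bp": covered,
        "coverage": covered / total if total else 0.0,
        "breakpoints": breakpoints,
        "min_rearrangements": math.ceil(breakpoints / 2),
    }


def dotplot_table(segments: list[Anchor] | list[LCB]) -> pd.DataFrame:
    """Segment table for dot-plotting: one row per anchor or LCB, with
    query_start > query_end on the minus strand."""
    rows = []
    for seg in segments:
        if isinstance(seg, Anchor):
            qs, qe, ident, qid = seg.query_start, seg.query_end, 1.0, seg.query_id
            rs, re_ = seg.ref_start, seg.ref_end
            strand = seg.strand
        else:
            qs, qe, ident, qid = seg.query_start, seg.query_end, seg.identity, seg.query_id
            rs, re_ = seg.ref_start, seg.ref_end
            strand = seg.strand
        if strand == "-":
            qs, qe = qe, qs
        rows.append(
            {
                "ref_start": rs,
                "ref_end": re_,
                "query_id": qid,
                "query_start": qs,
                "query_end": qe,
                "strand": strand,
                "identity": ident,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ref_start",
            "ref_end",
            "query_id",
            "query_start",
            "query_end",
            "strand",
            "identity",
        ],
    )
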