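"""Contig connection graph: pruning, multiplicity, circular resolution.

The assembly graph is modelled the way overlap assemblers emit it: each
contig has two physical ends -- ``b`` (5', begin) and ``e`` (3', end) --
and junction links join specific ends.  A chromosome is then an
alternating circuit of contig traversals and junction links; a contig
entered at ``b`` is read forward (``+``), entered at ``e`` it is read
reverse-complemented (``-``).

Resolution proceeds in three stages mirroring how a curator works over a
depth-annotated graph:

1. :func:`prune_graph` drops non-mitochondrial nodes and resolves forks
   by read-depth consistency (every removal is logged, and explicit
   keep/drop lists allow manual override of the automatic rules);
2. :func:`assign_multiplicities` converts depth ratios into contig copy
   numbers, resolving ambiguous ratios by decomposition feasibility;
3. :func:`resolve_circles` decomposes the pruned graph into edge-disjoint
   circular walks using each contig exactly its copy number of times,
   with deterministic canonical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .io import SeqRecord, revcomp

__all__ = [
    "ConnectionGraph",
    "ChromosomePath",
    "Multiplicities",
    "ResolutionError",
    "StitchError",
    "prune_graph",
    "assign_multiplicities",
    "resolve_circles",
    "stitch_sequences",
]

End = tuple[str, str]  # (contig id, "b" | "e")


class ResolutionError(RuntimeError):
    """The pruned graph does not decompose into circular chromosomes."""


class StitchError(RuntimeError):
    """Declared junction overlaps disagree with the contig sequences."""


@dataclass
class _Node:
    length: int = 0
    depth: float = 0.0
    n_reads: int = 0
    sequence: str | None = None
    label: str | None = None


class ConnectionGraph:
    """Undirected multigraph over contig ends.

    Links are stored canonically (endpoint pair sorted) so that the edge
    set is order-independent; self-links (both endpoints on one contig)
    represent single-contig circles.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, _Node] = {}
        self._links: list[tuple[End, End, int]] = []

    # -- construction ------------------------------------------------------

    def add_contig(
        self,
        cid: str,
        length: int = 0,
        depth: float = 0.0,
        n_reads: int = 0,
        sequence: str | None = None,
        label: str | None = None,
    ) -> None:
        if sequence is not None and length == 0:
            length = len(sequence)
        self.nodes[cid] = _Node(length, depth, n_reads, sequence, label)

    def add_link(self, a: str, ea: str, b: str, eb: str, support: int = 0) -> None:
        for cid in (a, b):
            if cid not in self.nodes:
                raise KeyError(f"link references unknown contig {cid!r}")
        p, q = sorted([(a, ea), (b, eb)])
        self._links.append((p, q, support))

    # -- queries -----------------------------------------------------------

    def iter_links(self):
        return iter(sorted(self._links))

    @property
    def n_links(self) -> int:
        return len(self._links)

    def links_at(self, end: End) -> list[tuple[End, End, int]]:
        return [l for l in self._links if end in (l[0], l[1])]

    def link_set(self) -> set[tuple[End, End]]:
        return {(p, q) for p, q, _ in self._links}

    def copy(self) -> "ConnectionGraph":
        g = ConnectionGraph()
        for cid, node in self.nodes.items():
            g.nodes[cid] = _Node(
                node.length, node.depth, node.n_reads, node.sequence, node.label
            )
        g._links = list(self._links)
        return g

    # -- mutation ----------------------------------------------------------

    def remove_contig(self, cid: str) -> None:
        self.nodes.pop(cid, None)
        self._links = [
            (p, q, s) for p, q, s in self._links if p[0] != cid and q[0] != cid
        ]

    def remove_link(self, p: End, q: End) -> None:
        p, q = sorted([p, q])
        for i, (a, b, _) in enumerate(self._links):
            if (a, b) == (p, q):
                del self._links[i]
                return
        raise KeyError(f"no link {p}-{q}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectionGraph):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and sorted(self._links) == sorted(other._links)
        )


@dataclass
class ChromosomePath:
    """A circular (or open) ordered walk of oriented contigs."""

    members: list[tuple[str, str]]  # (contig id, "+" | "-")
    circular: bool = True
    total_length: int = 0

    def __iter__(self):
        return iter(self.members)


# ---------------------------------------------------------------------------
# Pruning


def prune_graph(graph: ConnectionGraph, labels: dict[str, str], model,
                keep: frozenset[str] | set[str] = frozenset(),
                drop: frozenset[str] | set[str] = frozenset(),
                log: list[str] | None = None) -> ConnectionGraph:
    """Remove non-mitochondrial nodes and depth-inconsistent fork edges.

    ``labels`` comes from contig screening; nodes labelled ``cp_derived``
    or ``non_organellar`` are dropped unless listed in ``keep`` (a
    chloroplast-derived contig that genuinely sits in the mitogenome, as
    depth-screened MTPTs sometimes do, is kept by explicit override).
    At a fork -- a contig end with more incident links than the contig's
    provisional copy number -- the links with the smallest depth
    difference between the joined contigs are retained.

    Every removal appends a reason line to ``log``.  Idempotent.
    """
    if log is None:
        log = []
    g = graph.copy()
    for cid in sorted(list(g.nodes)):
        if cid in drop and cid in g.nodes:
            g.remove_contig(cid)
            log.append(f"drop-list removal: {cid}")
            continue
        label = labels.get(cid, "mt")
        if label in ("cp_derived", "non_organellar") and cid not in keep:
            g.remove_contig(cid)
            log.append(f"removed {cid}: labelled {label}")
        else:
            g.nodes[cid].label = label

    modal = getattr(model, "modal_depth", None) or 1.0
    anomaly = getattr(model, "anomaly_factor", 3.0)

    def provisional_copies(cid: str) -> int:
        depth = g.nodes[cid].depth
        if not depth or depth > anomaly * modal:
            return 1  # plastid-level depth is not traversal multiplicity
        return max(1, round(depth / modal))

    allowed = {cid: provisional_copies(cid) for cid in g.nodes}

    def depth_diff(link) -> float:
        (a, _), (b, _), _ = link
        return abs(g.nodes[a].depth - g.nodes[b].depth)

    support = {}
    for p, q, s in g._links:
        support[(p, q)] = max(support.get((p, q), 0), s)

    # Preferred resolution is global: keep a link subset giving every
    # contig end exactly its provisional copy number of junctions (the
    # degree condition a circular decomposition needs), preferring links
    # with the most spanning-read support and, at equal support, the
    # smallest depth difference.  A spurious link cannot enter such a
    # selection without starving the true junction of some end.
    if any(
        len(g.links_at((cid, e))) > allowed[cid]
        for cid in g.nodes
        for e in ("b", "e")
    ):
        order = sorted(
            {(p, q) for p, q, _ in g._links},
            key=lambda l: (-support[l], depth_diff((l[0], l[1], 0)), l),
        )
        usage = _select_link_usage(g, allowed, link_order=order, prefer_keep=True)
        if usage is not None:
            for link, used in usage.items():
                if used == 0:
                    g.remove_link(link[0], link[1])
                    log.append(
                        f"fork resolution: dropped link "
                        f"{link[0][0]}:{link[0][1]}-{link[1][0]}:{link[1][1]} "
                        f"(|depth diff| {depth_diff((link[0], link[1], 0)):.1f}, "
                        "no exact-degree selection keeps it)"
                    )
            return g

    # Fallback, deterministic order over ends (used when the graph has
    # no exact-degree selection, e.g. dangling ends from removed nodes).
    # Links with the largest depth difference are dropped first; a link
    # whose removal would leave its other endpoint without enough links
    # is spared unless the fork cannot be resolved otherwise.
    ends = sorted((cid, e) for cid in g.nodes for e in ("b", "e"))
    for end in ends:
        cap = allowed[end[0]]

        def other_endpoint(link):
            p, q, _ = link
            return q if p == end else p

        for guard in (True, False):
            while len(g.links_at(end)) > cap:
                ranked = sorted(
                    g.links_at(end),
                    key=lambda l: (support[(l[0], l[1])], -depth_diff(l), l),
                )
                dropped = False
                for link in ranked:
                    if len(g.links_at(end)) <= cap:
                        break
                    other = other_endpoint(link)
                    if (
                        guard
                        and other != end
                        and len(g.links_at(other)) - 1 < allowed[other[0]]
                    ):
                        continue
                    g.remove_link(link[0], link[1])
                    log.append(
                        f"fork at {end[0]}:{end[1]}: dropped link "
                        f"{link[0][0]}:{link[0][1]}-{link[1][0]}:{link[1][1]} "
                        f"(|depth diff| {depth_diff(link):.1f})"
                    )
                    dropped = True
                if not dropped:
                    break
            if len(g.links_at(end)) <= cap:
                break
    return g


# ---------------------------------------------------------------------------
# Multiplicities


@dataclass
class Multiplicities:
    copy_number: dict[str, int] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    def __getitem__(self, cid: str) -> int:
        return self.copy_number[cid]


def assign_multiplicities(graph: ConnectionGraph, model) -> Multiplicities:
    """Copy number per contig from its depth / modal-depth ratio.

    ``round(depth / modal)`` clamped to >= 1; ratios whose fractional
    part falls in [0.4, 0.6] are flagged ambiguous and resolved to the
    smallest copy number that still admits a full circular decomposition
    of the graph (a partially collapsed dispersed repeat inflates depth
    without necessarily demanding a second traversal).
    """
    modal = model.modal_depth
    anomaly = getattr(model, "anomaly_factor", 3.0)
    result = Multiplicities()
    for cid in sorted(graph.nodes):
        node = graph.nodes[cid]
        ratio = node.depth / modal if modal else 1.0
        frac = ratio - int(ratio)
        m = max(1, round(ratio))
        if ratio > anomaly or node.label == "cp_derived":
            # plastid-level coverage comes from plastid reads, not from
            # extra mitochondrial traversals: start from a single copy
            result.ambiguous.add(cid)
            m = 1
        elif 0.4 <= frac <= 0.6 and ratio >= 1.0:
            result.ambiguous.add(cid)
            m = max(1, int(ratio))  # provisional: smallest candidate
        result.copy_number[cid] = m

    for cid in sorted(result.ambiguous):
        for candidate in (result.copy_number[cid], result.copy_number[cid] + 1):
            trial = dict(result.copy_number)
            trial[cid] = candidate
            if _select_link_usage(graph, trial) is not None:
                result.copy_number[cid] = candidate
                break
    return result


# ---------------------------------------------------------------------------
# Circular resolution


def _select_link_usage(
    graph: ConnectionGraph,
    copy_number: dict[str, int],
    link_order: list[tuple[End, End]] | None = None,
    prefer_keep: bool = False,
) -> dict[tuple[End, End], int] | None:
    """Pick how many times each junction link is traversed.

    Each traversal of contig ``c`` consumes one junction-stub at each of
    its two ends, so a valid usage gives every end-node junction degree
    exactly ``copy_number[c]``.  Links are usable up to
    ``min(copy_number of both contigs)`` times.  Deterministic
    backtracking returns the first feasible usage vector in
    ``link_order`` (lexicographic by default); with ``prefer_keep`` the
    earliest links in the order are kept at the highest multiplicity
    possible.  Returns None when the graph has dangling ends.
    """
    links = link_order or sorted({(p, q) for p, q, _ in graph._links})
    need = {
        (cid, e): copy_number.get(cid, 1)
        for cid in graph.nodes
        for e in ("b", "e")
    }

    def cap(link):
        (a, _), (b, _) = link
        return min(copy_number.get(a, 1), copy_number.get(b, 1))

    remaining_cap: dict[End, int] = {end: 0 for end in need}
    for link in links:
        p, q = link
        c = cap(link)
        if p == q:
            remaining_cap[p] += 2 * c
        else:
            remaining_cap[p] += c
            remaining_cap[q] += c

    usage: dict[tuple[End, End], int] = {}
    deficit = dict(need)

    def feasible() -> bool:
        return all(deficit[end] <= remaining_cap[end] for end in deficit)

    def backtrack(i: int) -> bool:
        if i == len(links):
            return all(v == 0 for v in deficit.values())
        link = links[i]
        p, q = link
        c = cap(link)
        if p == q:
            remaining_cap[p] -= 2 * c
        else:
            remaining_cap[p] -= c
            remaining_cap[q] -= c
        values = range(c, -1, -1) if prefer_keep else range(0, c + 1)
        for use in values:
            if p == q:
                if deficit[p] < 2 * use:
                    continue
                deficit[p] -= 2 * use
            else:
                if deficit[p] < use or deficit[q] < use:
                    continue
                deficit[p] -= use
                deficit[q] -= use
            if feasible() and backtrack(i + 1):
                usage[link] = use
                return True
            if p == q:
                deficit[p] += 2 * use
            else:
                deficit[p] += use
                deficit[q] += use
        if p == q:
            remaining_cap[p] += 2 * c
        else:
            remaining_cap[p] += c
            remaining_cap[q] += c
        return False

    if not backtrack(0):
        return None
    return {link: usage.get(link, 0) for link in links}


def resolve_circles(
    graph: ConnectionGraph, multiplicities: Multiplicities | dict[str, int] | None = None
) -> list[ChromosomePath]:
    """Decompose the pruned graph into circular chromosome paths.

    Each contig is used exactly its copy number of times, each junction
    link at most once per available multiplicity.  Output is canonical:
    every circle is rotated to start at its lexicographically smallest
    contig id in ``+`` orientation, and circles are sorted by descending
    total length.  Raises :class:`ResolutionError` (naming the offending
    contig ends) when no decomposition exists.
    """
    if not graph.nodes:
        return []
    if multiplicities is None:
        copy_number = {cid: 1 for cid in graph.nodes}
    elif isinstance(multiplicities, Multiplicities):
        copy_number = dict(multiplicities.copy_number)
    else:
        copy_number = dict(multiplicities)

    usage = _select_link_usage(graph, copy_number)
    if usage is None:
        dangling = _dangling_ends(graph, copy_number)
        raise ResolutionError(
            "graph does not decompose into circles; offending contig ends: "
            + ", ".join(f"{c}:{e}" for c, e in dangling)
        )

    # Junction stubs per end-node, lexicographically ordered by peer.
    junction_stubs: dict[End, list[tuple[End, int]]] = {
        (cid, e): [] for cid in graph.nodes for e in ("b", "e")
    }
    for (p, q), count in sorted(usage.items()):
        for k in range(count):
            if p == q:
                junction_stubs[p].append((q, 2 * k))
                junction_stubs[p].append((q, 2 * k + 1))
            else:
                junction_stubs[p].append((q, k))
                junction_stubs[q].append((p, k))

    # Contig-traversal stubs: (cid, copy index) at both ends.
    contig_stubs: dict[End, list[int]] = {
        end: list(range(copy_number[end[0]])) for end in junction_stubs
    }

    # Perfect matching per node: i-th contig stub <-> i-th junction stub.
    match_c2j: dict[tuple[str, int, str], tuple[End, End, int]] = {}
    match_j2c: dict[tuple[End, End, int], tuple[str, int, str]] = {}
    for end, stubs in sorted(junction_stubs.items()):
        cid, e = end
        for i, (peer, k) in enumerate(stubs):
            cstub = (cid, contig_stubs[end][i], e)
            jstub = (end, peer, k)
            match_c2j[cstub] = jstub
            match_j2c[jstub] = cstub

    other = {"b": "e", "e": "b"}
    unused = sorted(match_c2j)
    used: set[tuple[str, int, str]] = set()
    circles: list[list[tuple[str, str]]] = []

    for start in unused:
        if start in used:
            continue
        walk: list[tuple[str, str]] = []
        cstub = start
        while True:
            cid, copy_idx, entry = cstub
            used.add(cstub)
            walk.append((cid, "+" if entry == "b" else "-"))
            exit_stub = (cid, copy_idx, other[entry])
            used.add(exit_stub)
            jstub = match_c2j[exit_stub]
            end, peer, k = jstub
            # a link's two stub indices pair 2k<->2k+1 when both endpoints
            # sit on the same end-node (same-end self-link)
            peer_jstub = (peer, end, k ^ 1) if peer == end else (peer, end, k)
            cstub = match_j2c[peer_jstub]
            if cstub == start:
                break
        circles.append(walk)

    paths = [
        ChromosomePath(
            members=_canonicalize(walk),
            circular=True,
            total_length=sum(graph.nodes[c].length for c, _ in walk),
        )
        for walk in circles
    ]
    paths.sort(key=lambda p: (-p.total_length, p.members))
    return paths


def _dangling_ends(graph: ConnectionGraph, copy_number: dict[str, int]) -> list[End]:
    degree: dict[End, int] = {(c, e): 0 for c in graph.nodes for e in ("b", "e")}
    for p, q, _ in graph._links:
        degree[p] += 1
        degree[q] += 1
    return sorted(end for end, d in degree.items() if d < copy_number[end[0]])


def _flip(walk: list[tuple[str, str]]) -> list[tuple[str, str]]:
    return [(c, "+" if o == "-" else "-") for c, o in reversed(walk)]


def _canonicalize(walk: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Smallest rotation starting at the minimal contig id in + orientation,
    considering both traversal directions of the circle."""
    candidates = []
    for variant in (walk, _flip(walk)):
        n = len(variant)
        for r in range(n):
            rot = variant[r:] + variant[:r]
            candidates.append(rot)
    key = lambda w: [(c, 0 if o == "+" else 1) for c, o in w]
    return min(candidates, key=key)


# ---------------------------------------------------------------------------
# Stitching


def stitch_sequences(
    paths: list[ChromosomePath],
    sequences: dict[str, str] | dict[str, SeqRecord],
    overlaps: dict[tuple[End, End], int] | int = 0,
    name_prefix: str = "mtChr",
) -> list[SeqRecord]:
    """Concatenate each path's oriented member sequences into a circle.

    ``overlaps`` declares how many bases adjacent contigs share at each
    junction (0 for Newbler-style non-overlapping contigs); shared bases
    are verified and trimmed once.  A mismatch within a declared overlap
    raises :class:`StitchError`.
    """

    def seq_of(cid: str) -> str:
        s = sequences[cid]
        return s.sequence if isinstance(s, SeqRecord) else s

    def overlap_for(a: tuple[str, str], b: tuple[str, str]) -> int:
        if isinstance(overlaps, int):
            return overlaps
        ea = "e" if a[1] == "+" else "b"
        eb = "b" if b[1] == "+" else "e"
        p, q = sorted([(a[0], ea), (b[0], eb)])
        return overlaps.get((p, q), 0)

    records: list[SeqRecord] = []
    for idx, path in enumerate(paths, 1):
        oriented = [
            seq_of(c) if o == "+" else revcomp(seq_of(c)) for c, o in path.members
        ]
        seq = oriented[0]
        for prev, nxt, piece in zip(path.members, path.members[1:], oriented[1:]):
            ov = overlap_for(prev, nxt)
            if ov:
                if seq[-ov:] != piece[:ov]:
                    raise StitchError(
                        f"overlap mismatch at junction {prev[0]}-{nxt[0]} ({ov} bp)"
                    )
                seq += piece[ov:]
            else:
                seq += piece
        if path.circular and len(path.members) >= 1:
            ov = overlap_for(path.members[-1], path.members[0])
            if ov:
                if seq[-ov:] != seq[:ov]:
                    raise StitchError(
                        f"wrap-around overlap mismatch on circle {idx} ({ov} bp)"
                    )
                seq = seq[:-ov]
        records.append(SeqRecord(f"{name_prefix}{idx}", seq, topology="circular"))
    return records
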