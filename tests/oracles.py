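"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a detector's answer from first principles with a
different algorithmic formulation than the implementation under test:
explicit per-position scans, exhaustive diagonal enumeration, and
exhaustive circuit-decomposition search on tiny graphs.
"""

from __future__ import annotations

import itertools

import numpy as np

from mitocircles.io import revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# SSRs: explicit per-(start, unit) maximal-run scan


def ssr_oracle(seq: str, thresholds=None) -> set[tuple[str, int, int, int, int]]:
    thresholds = thresholds or {1: 8, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}
    n = len(seq)
    out = set()
    for u in range(1, 7):
        for i in range(n - u):
            # run start: cannot extend left by one period
            if i > 0 and i - 1 + u < n and seq[i - 1] == seq[i - 1 + u]:
                continue
            j = i
            while j + u < n and seq[j] == seq[j + u]:
                j += 1
            run = (j - i) + u
            copies = run // u
            motif = seq[i : i + u]
            primitive = all(
                not (u % d == 0 and motif == motif[:d] * (u // d))
                for d in range(1, u)
            )
            if copies >= thresholds[u] and primitive:
                out.add((motif, u, copies, i + 1, i + copies * u))
    return out


# ---------------------------------------------------------------------------
# Dispersed repeats: exhaustive diagonal enumeration with searchsorted
# window bounds (a different formulation than the detector's seeded scan)


def dispersed_oracle(records, min_len=30, max_mm=3) -> set:
    out = set()
    recs = [(r.id, r.sequence) for r in records]
    for i, (id1, s1) in enumerate(recs):
        a1 = np.frombuffer(s1.encode(), dtype="S1")
        for id2, s2 in recs[i:]:
            for orient in ("direct", "palindromic"):
                t2 = s2 if orient == "direct" else revcomp(s2)
                b2 = np.frombuffer(t2.encode(), dtype="S1")
                n1, n2 = len(s1), len(t2)
                for d in range(-(n2 - 1), n1):
                    lo1, lo2 = max(0, d), max(0, d) - d
                    span = min(n1 - lo1, n2 - lo2)
                    if span < min_len:
                        continue
                    mm = (a1[lo1 : lo1 + span] != b2[lo2 : lo2 + span]).astype(int)
                    cum = np.concatenate([[0], np.cumsum(mm)])
                    for a in range(span):
                        bmax = int(np.searchsorted(cum, cum[a] + max_mm + 1)) - 1
                        if bmax - a < min_len:
                            continue
                        c = int(cum[bmax] - cum[a])
                        if a > 0 and not (mm[a - 1] and c == max_mm):
                            continue
                        p1, p2, L = lo1 + a, lo2 + a, bmax - a
                        q2 = p2 if orient == "direct" else n2 - (p2 + L)
                        inst1, inst2 = (id1, p1 + 1), (id2, q2 + 1)
                        if orient == "direct" and id1 == id2:
                            if p1 == q2 or abs(p1 - q2) < min_len:
                                continue
                        if inst2 < inst1:
                            inst1, inst2 = inst2, inst1
                        out.add((inst1, inst2, L, orient, c))
    return out


# ---------------------------------------------------------------------------
# Maximal exact matches: naive per-diagonal run enumeration


def mem_oracle(ref: str, query: str, k: int) -> set[tuple[int, int, int, str]]:
    """(ref_start, query_start, length, strand), 1-based, query_start on
    the forward query strand."""
    out = set()
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        n1, n2 = len(ref), len(q)
        for d in range(-(n2 - 1), n1):
            lo1, lo2 = max(0, d), max(0, d) - d
            span = min(n1 - lo1, n2 - lo2)
            x = 0
            while x < span:
                if ref[lo1 + x] != q[lo2 + x]:
                    x += 1
                    continue
                y = x
                while y < span and ref[lo1 + y] == q[lo2 + y]:
                    y += 1
                if y - x >= k:
                    qs = lo2 + x if strand == "+" else n2 - (lo2 + y)
                    out.add((lo1 + x + 1, qs + 1, y - x, strand))
                x = y
    return out


# ---------------------------------------------------------------------------
# Circular decompositions: exhaustive enumeration on tiny graphs


def _canon_circle(walk):
    def flip(w):
        return [(c, "+" if o == "-" else "-") for c, o in reversed(w)]

    cands = []
    for v in (walk, flip(walk)):
        for r in range(len(v)):
            cands.append(tuple(v[r:] + v[:r]))
    return min(cands, key=lambda w: [(c, o != "+") for c, o in w])


def enumerate_decompositions(graph, copy_number) -> set:
    """All decompositions into circular walks using each contig exactly
    its copy number of times and each link at most min(copy numbers)
    times.  Returns a set of frozen multisets of canonical circles.
    Exponential; only for graphs with a handful of nodes."""
    links = sorted({(p, q) for p, q, _ in graph.iter_links()})
    caps = [min(copy_number[p[0]], copy_number[q[0]]) for p, q in links]
    results = set()

    stub_target = {
        (cid, e): copy_number[cid] for cid in graph.nodes for e in ("b", "e")
    }

    for usage in itertools.product(*(range(c + 1) for c in caps)):
        degree = {end: 0 for end in stub_target}
        for (p, q), u in zip(links, usage):
            if p == q:
                degree[p] += 2 * u
            else:
                degree[p] += u
                degree[q] += u
        if degree != stub_target:
            continue
        # expand stubs and try all pairings at each end-node
        jstubs = {end: [] for end in stub_target}
        for li, ((p, q), u) in enumerate(zip(links, usage)):
            for c in range(u):
                if p == q:
                    jstubs[p].append((li, 2 * c))
                    jstubs[p].append((li, 2 * c + 1))
                else:
                    jstubs[p].append((li, c))
                    jstubs[q].append((li, c))
        ends = sorted(stub_target)
        perms_per_end = [
            list(itertools.permutations(range(len(jstubs[e])))) for e in ends
        ]
        for choice in itertools.product(*perms_per_end):
            pairing = {}
            ok = True
            for e, perm in zip(ends, choice):
                for ci, ji in enumerate(perm):
                    pairing[(e, ci)] = jstubs[e][ji]
            circles = _trace(graph, copy_number, links, usage, pairing)
            if circles is not None:
                results.add(circles)
    return results


def _trace(graph, copy_number, links, usage, pairing):
    other = {"b": "e", "e": "b"}
    # contig stubs: (cid, copy index, end)
    cstubs = sorted(
        (cid, c, e)
        for cid in graph.nodes
        for c in range(copy_number[cid])
        for e in ("b", "e")
    )
    # pairing maps ((end), contig-stub-ordinal) -> junction stub (link, copy)
    # build forward/backward maps between contig stubs and junction stubs
    ordinal = {}
    per_end_count = {}
    for cid, c, e in cstubs:
        end = (cid, e)
        ordinal[(cid, c, e)] = per_end_count.get(end, 0)
        per_end_count[end] = per_end_count.get(end, 0) + 1
    c2j, j2c = {}, {}
    for (cid, c, e) in cstubs:
        end = (cid, e)
        key = (end, ordinal[(cid, c, e)])
        if key not in pairing:
            return None
        li, k = pairing[key]
        c2j[(cid, c, e)] = (end, li, k)
        j2c[(end, li, k)] = (cid, c, e)
    used = set()
    circles = []
    for start in cstubs:
        if start in used:
            continue
        walk = []
        stub = start
        for _ in range(10 * len(cstubs)):
            cid, c, entry = stub
            used.add(stub)
            walk.append((cid, "+" if entry == "b" else "-"))
            exit_stub = (cid, c, other[entry])
            used.add(exit_stub)
            end, li, k = c2j[exit_stub]
            p, q = links[li]
            peer = q if end == p else p
            peer_key = (peer, li, k ^ 1) if peer == end else (peer, li, k)
            if peer_key not in j2c:
                return None
            stub = j2c[peer_key]
            if stub == start:
                break
        else:
            return None
        circles.append(_canon_circle(walk))
    return frozenset((c, circles.count(c)) for c in circles)
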