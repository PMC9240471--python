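"""SSR, tandem and dispersed repeat detection at microsatellite-tool
conventions.

Three detector families, matching how plant organelle papers profile
repeats:

* :func:`find_ssrs` -- perfect microsatellites with 1-6 bp units at the
  MISA-style per-unit copy thresholds (8/4/4/3/3/3 by default);
* :func:`find_tandem_repeats` -- minisatellites with unit >= 7 bp and a
  mismatch allowance, via a periodicity scan with consensus voting (a
  deliberately simple scorer, not a probabilistic-alignment model);
* :func:`find_dispersed_repeats` -- maximal repeated pairs, direct and
  palindromic, of length >= 30 bp within a Hamming-mismatch budget
  (REPuter-style pair semantics).

Coordinates in all records are 1-based inclusive.  Sequences are scanned
linearly by default; ``circular=True`` extends the scan across the
origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SeqRecord, revcomp

__all__ = [
    "SSRConfig",
    "SSRRecord",
    "TandemRepeat",
    "DispersedRepeatPair",
    "find_ssrs",
    "find_tandem_repeats",
    "find_dispersed_repeats",
    "repeat_summary_table",
    "SIZE_BINS",
]

DEFAULT_MIN_REPEATS = {1: 8, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}

#: dispersed-repeat length bins used in comparative tables
SIZE_BINS = [(30, 49), (50, 69), (70, 99), (100, 149), (150, 199), (200, 499), (500, None)]


@dataclass
class SSRConfig:
    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("min_repeats must have keys 1..6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("copy thresholds must be >= 2")


@dataclass(frozen=True)
class SSRRecord:
    chromosome: str
    motif: str
    unit_length: int
    copies: int
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        assert self.end - self.start + 1 == self.unit_length * self.copies


@dataclass(frozen=True)
class TandemRepeat:
    chromosome: str
    period: int
    copies: float
    start: int
    end: int
    consensus: str


@dataclass(frozen=True)
class DispersedRepeatPair:
    chrom1: str
    start1: int  # 1-based
    chrom2: str
    start2: int
    length: int
    mismatches: int
    orientation: str  # "direct" | "palindromic"


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs(record: SeqRecord, cfg: SSRConfig | None = None) -> list[SSRRecord]:
    """All maximal perfect microsatellite runs meeting the copy thresholds.

    Only primitive motifs are reported (an ``A`` x8 run is a mono-SSR,
    never ``(AA)`` x4), each qualifying run once, trimmed to whole unit
    copies, leftmost start.
    """
    cfg = cfg or SSRConfig()
    seq = record.sequence
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out: list[SSRRecord] = []
    for u in range(1, 7):
        if n < 2 * u:
            continue
        thr = cfg.min_repeats[u]
        match = arr[u:] == arr[:-u]  # match[i]: seq[i+u] == seq[i]
        i = 0
        m = len(match)
        while i < m:
            if not match[i]:
                i += 1
                continue
            j = i
            while j < m and match[j]:
                j += 1
            run_len = (j - i) + u  # total repeated region length
            copies = run_len // u
            motif = seq[i : i + u]
            if copies >= thr and _is_primitive(motif):
                out.append(
                    SSRRecord(
                        chromosome=record.id,
                        motif=motif,
                        unit_length=u,
                        copies=copies,
                        start=i + 1,
                        end=i + copies * u,
                    )
                )
            i = j + 1
    out.sort(key=lambda r: (r.start, r.unit_length))
    return out


def find_tandem_repeats(
    record: SeqRecord,
    min_period: int = 7,
    min_copies: float = 2.0,
    max_mismatch_fraction: float = 0.1,
    max_period: int = 60,
) -> list[TandemRepeat]:
    """Minisatellite detection by per-period self-match scanning.

    For each candidate period ``p`` the sequence is compared against
    itself shifted by ``p``; maximal segments whose shifted-mismatch
    fraction stays within budget and that cover at least
    ``min_copies * p * 0.9`` bases are reported with a majority-vote
    consensus unit.  Overlapping calls at different periods collapse to
    the highest-copy (smallest-period) call.
    """
    seq = record.sequence
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    candidates: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        mism = arr[p:] != arr[:-p]
        m = len(mism)
        i = 0
        while i < m:
            if mism[i]:
                i += 1
                continue
            # greedy extension with proportional mismatch budget
            j = i
            bad = 0
            best_j = i
            while j < m:
                if mism[j]:
                    if (bad + 1) > max_mismatch_fraction * ((j + 1 - i) + p):
                        break
                    bad += 1
                else:
                    best_j = j
                j += 1
            span = (best_j + 1 - i) + p  # region [i, i + span)
            copies = span / p
            if span >= min_copies * p * 0.9 and copies >= min_copies * 0.9:
                unit = _consensus_unit(seq[i : i + span], p)
                candidates.append(
                    TandemRepeat(
                        chromosome=record.id,
                        period=p,
                        copies=round(copies, 1),
                        start=i + 1,
                        end=i + span,
                        consensus=unit,
                    )
                )
                i = best_j + 1
            else:
                i += 1
    return _merge_tandem(candidates)


def _consensus_unit(region: str, p: int) -> str:
    cols: list[dict[str, int]] = [{} for _ in range(p)]
    for i, base in enumerate(region):
        d = cols[i % p]
        d[base] = d.get(base, 0) + 1
    return "".join(max(sorted(d), key=lambda b: d[b]) for d in cols)


def _merge_tandem(candidates: list[TandemRepeat]) -> list[TandemRepeat]:
    candidates.sort(key=lambda t: (-t.copies, t.period, t.start))
    kept: list[TandemRepeat] = []
    for cand in candidates:
        overlaps = any(
            k.chromosome == cand.chromosome
            and not (cand.end < k.start or cand.start > k.end)
            for k in kept
        )
        if not overlaps:
            kept.append(cand)
    kept.sort(key=lambda t: (t.chromosome, t.start))
    return kept


# ---------------------------------------------------------------------------
# Dispersed repeats


def _maximal_windows(mism: np.ndarray, max_mm: int, min_len: int):
    """All maximal windows with <= max_mm mismatches along one diagonal.

    A window is maximal when extension on either side would exceed the
    budget or run off the sequence.  Yields (start, length, n_mismatch).
    """
    span = len(mism)
    if span == 0:
        return
    M = np.flatnonzero(mism)
    nm = len(M)
    if nm == 0:
        if span >= min_len:
            yield 0, span, 0
        return
    # A left-maximal window starts at 0 or just after the i-th mismatch
    # (a start > 0 is only maximal when the budget is fully spent,
    # otherwise the window could absorb the preceding mismatch), and runs
    # to just before the (max_mm+1)-th mismatch after its start.
    i = np.arange(nm + 1)
    a = np.concatenate([[0], M + 1])
    blocker = i + max_mm
    b = np.where(blocker < nm, M[np.minimum(blocker, max(nm - 1, 0))], span)
    count = np.minimum(nm - i, max_mm)
    valid = (b - a >= min_len) & ((i == 0) | (count == max_mm))
    for idx in np.flatnonzero(valid):
        yield int(a[idx]), int(b[idx] - a[idx]), int(count[idx])


def find_dispersed_repeats(
    records: list[SeqRecord],
    min_len: int = 30,
    max_mismatch: int = 3,
    modes: tuple[str, ...] = ("direct", "palindromic"),
) -> list[DispersedRepeatPair]:
    """All maximal repeated pairs under a Hamming budget.

    Pairs are sought within and across sequences, in direct and
    palindromic (reverse-complement) orientation.  The trivial self-pair
    of a region with itself is excluded, as are direct pairs offset by
    less than ``min_len`` on one sequence (those are tandem-adjacent,
    not dispersed).  Seeding uses exact shared ``k``-mers with
    ``k = ceil((min_len - max_mismatch) / (max_mismatch + 1))``, which by
    pigeonhole cannot miss a qualifying pair.
    """
    k = max(2, -(-(min_len - max_mismatch) // (max_mismatch + 1)))
    seen: set[tuple] = set()
    out: list[DispersedRepeatPair] = []

    arrays = {
        r.id: np.frombuffer(r.sequence.encode(), dtype="S1") for r in records
    }
    ids = [r.id for r in records]
    seqs = {r.id: r.sequence for r in records}

    def scan_pair(id1: str, id2: str, orientation: str) -> None:
        s1 = seqs[id1]
        s2 = seqs[id2] if orientation == "direct" else revcomp(seqs[id2])
        a1 = arrays[id1]
        a2 = (
            arrays[id2]
            if orientation == "direct"
            else np.frombuffer(s2.encode(), dtype="S1")
        )
        n1, n2 = len(s1), len(s2)
        if n1 < k or n2 < k:
            return
        index: dict[str, list[int]] = {}
        for i in range(n1 - k + 1):
            index.setdefault(s1[i : i + k], []).append(i)
        diagonals: set[int] = set()
        for j in range(n2 - k + 1):
            for i in index.get(s2[j : j + k], ()):  # diagonal d = i - j
                diagonals.add(i - j)
        for d in sorted(diagonals):
            lo1 = max(0, d)
            lo2 = lo1 - d
            span = min(n1 - lo1, n2 - lo2)
            if span < min_len:
                continue
            mism = a1[lo1 : lo1 + span] != a2[lo2 : lo2 + span]
            for w_start, w_len, w_mm in _maximal_windows(mism, max_mismatch, min_len):
                p1 = lo1 + w_start  # 0-based in s1
                p2 = lo2 + w_start  # 0-based in oriented s2
                if orientation == "direct":
                    q2 = p2
                else:
                    q2 = n2 - (p2 + w_len)  # back to original coordinates
                if id1 == id2 and orientation == "direct":
                    if p1 == q2:
                        continue  # region vs itself
                    if abs(p1 - q2) < min_len:
                        continue  # tandem-adjacent, not dispersed
                inst1 = (id1, p1)
                inst2 = (id2, q2)
                if inst2 < inst1:
                    inst1, inst2 = inst2, inst1
                key = (inst1, inst2, w_len, orientation)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    DispersedRepeatPair(
                        chrom1=inst1[0],
                        start1=inst1[1] + 1,
                        chrom2=inst2[0],
                        start2=inst2[1] + 1,
                        length=w_len,
                        mismatches=w_mm,
                        orientation=orientation,
                    )
                )

    for i, id1 in enumerate(ids):
        for id2 in ids[i:]:
            if "direct" in modes:
                scan_pair(id1, id2, "direct")
            if "palindromic" in modes:
                scan_pair(id1, id2, "palindromic")

    out.sort(
        key=lambda p: (p.chrom1, p.start1, p.chrom2, p.start2, p.length, p.orientation)
    )
    return out


# ---------------------------------------------------------------------------
# Comparative table


def repeat_summary_table(
    per_genome: dict[str, tuple[list[DispersedRepeatPair], int]]
) -> pd.DataFrame:
    """Comparative dispersed-repeat table across genomes.

    One row per genome: pair counts per size bin, the longest repeat,
    the total repeat length -- the union of bases covered by at least
    one repeat instance, the only definition guaranteed not to exceed
    the genome length -- and that union as a percentage of the genome
    (two decimals).
    """
    rows = []
    for name, (pairs, genome_len) in per_genome.items():
        row: dict[str, object] = {"genome": name}
        for lo, hi in SIZE_BINS:
            label = f"{lo}-{hi}" if hi else f">{lo}"
            row[label] = sum(
                1
                for p in pairs
                if p.length >= lo and (hi is None or p.length <= hi)
            )
        row["n_repeats"] = sum(
            1 for p in pairs if p.length >= SIZE_BINS[0][0]
        )
        row["longest"] = max((p.length for p in pairs), default=0)
        union = _union_length(pairs)
        row["total_repeat_length"] = union
        row["proportion_pct"] = round(100.0 * union / genome_len, 2) if genome_len else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome")


def _union_length(pairs: list[DispersedRepeatPair]) -> int:
    intervals: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        intervals.setdefault(p.chrom1, []).append((p.start1, p.start1 + p.length - 1))
        intervals.setdefault(p.chrom2, []).append((p.start2, p.start2 + p.length - 1))
    total = 0
    for chrom, ivals in intervals.items():
        ivals.sort()
        cur_a, cur_b = ivals[0]
        for a, b in ivals[1:]:
            if a > cur_b + 1:
                total += cur_b - cur_a + 1
                cur_a, cur_b = a, b
            else:
                cur_b = max(cur_b, b)
        total += cur_b - cur_a + 1
    return total
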