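"""Ground-truthed synthetic multi-circular mitogenomes.

The generator emulates the data regime of a PacBio-assembled poplar
mitogenome: a few circular chromosomes of a few hundred kilobases,
mitochondrial read depth around 70x with a short chloroplast-derived
insert at plastid depth (~1000x), error-corrected long reads with a mean
length around 12.5 kb and a low residual substitution rate, planted
microsatellites / tandem / dispersed repeats, and a single-circle
"ancestral" reference from which the target genome differs by fission.
Every downstream stage of the pipeline can therefore be tested against
recorded truth without any external download.

All randomness flows from ``SynthConfig.seed``; identical configs give
byte-identical outputs.  Reads wrap the circular origin.  The error
model is substitution-only (reads stand for post-correction data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import SeqRecord, revcomp

__all__ = [
    "SynthConfig",
    "TruthSet",
    "ConfigError",
    "PlantedSSR",
    "PlantedTandem",
    "PlantedDispersed",
    "generate_genome",
    "fragment_to_contigs",
    "simulate_reads",
    "scaled_study_config",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Invalid synthetic-genome configuration."""


@dataclass(frozen=True)
class PlantedSSR:
    motif: str  # primitive unit, 1-6 bp
    copies: int


@dataclass(frozen=True)
class PlantedTandem:
    unit: str  # >= 7 bp
    copies: float


@dataclass(frozen=True)
class PlantedDispersed:
    length: int
    orientation: str = "direct"  # "direct" | "palindromic"
    mismatches: int = 0


@dataclass
class SynthConfig:
    """Study conditions for the synthetic mitogenome.

    Defaults reproduce the regime of the *Populus simonii* dataset this
    pipeline was designed around: three circular chromosomes (312.5, 283
    and 186 kb), mitochondrial depth 70x, a 291-bp chloroplast-derived
    insert at ~1000x, corrected long reads of mean length 12,589 bp, and
    contig fragmentation into 1 / 7 / 6 pieces.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_lengths: tuple[int, ...] = (312510, 282934, 186034)
    gc_target: float = 0.4478
    n_breaks_per_chromosome: tuple[int, ...] | int = (1, 7, 6)
    mt_depth: float = 70.0
    cp_insert_length: int = 291
    cp_depth: float = 1000.0
    read_length_mean: float = 12589.0
    read_length_sd: float = 2500.0
    read_error_rate: float = 0.01
    planted_ssrs: tuple[PlantedSSR, ...] = ()
    planted_tandems: tuple[PlantedTandem, ...] = ()
    planted_dispersed: tuple[PlantedDispersed, ...] = ()
    fission_plan: str = "all"  # reference adjacencies absent in the target:
    # "all" = every inter-chromosome boundary of the concatenated ancestral
    # circle is a fission point; "none" = no ancestral reference is built.
    depth_jitter: float = 0.03  # relative sd of bookkeeping depth per contig

    def __post_init__(self) -> None:
        if isinstance(self.n_breaks_per_chromosome, int):
            self.n_breaks_per_chromosome = (
                self.n_breaks_per_chromosome,
            ) * self.n_chromosomes
        self.chromosome_lengths = tuple(self.chromosome_lengths)
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ConfigError("one length per chromosome required")
        if len(self.n_breaks_per_chromosome) != self.n_chromosomes:
            raise ConfigError("one break count per chromosome required")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ConfigError("chromosome lengths must be positive")
        if self.mt_depth <= 0 or self.cp_depth <= 0:
            raise ConfigError("depths must be positive")
        if not 0 <= self.read_error_rate <= 0.2:
            raise ConfigError("read_error_rate must be in [0, 0.2]")
        if not 0 <= self.gc_target <= 1:
            raise ConfigError("gc_target must be in [0, 1]")
        if self.cp_insert_length < 0:
            raise ConfigError("cp_insert_length must be >= 0")


@dataclass
class TruthSet:
    """Everything the generator knows about the genome it made."""

    config: SynthConfig
    chromosomes: list[SeqRecord]
    reference: SeqRecord | None
    # 1-based reference positions that are fission points (absent
    # adjacencies in the target genome) and intact control positions.
    false_junctions: list[int] = field(default_factory=list)
    true_junctions: list[int] = field(default_factory=list)
    # contig truth, filled by fragment_to_contigs
    contig_assignments: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    expected_depth: dict[str, float] = field(default_factory=dict)
    break_positions: list[list[int]] = field(default_factory=list)
    # planted features, 1-based inclusive coordinates
    planted_ssrs: list[tuple[str, int, int, str, int]] = field(default_factory=list)
    planted_tandems: list[tuple[str, int, int, str, float]] = field(default_factory=list)
    planted_dispersed: list[tuple[str, int, str, int, int, str]] = field(
        default_factory=list
    )  # (chrom1, start1, chrom2, start2, length, orientation)
    cp_insert: tuple[str, int, int] | None = None

    def adjacency_set(self) -> set[tuple[tuple[str, str], tuple[str, str]]]:
        """True contig-end adjacencies, canonically ordered pairs."""
        by_chrom: dict[int, list[tuple[int, str]]] = {}
        for cid, (chrom, order, _) in self.contig_assignments.items():
            by_chrom.setdefault(chrom, []).append((order, cid))
        out: set[tuple[tuple[str, str], tuple[str, str]]] = set()
        for chrom, members in by_chrom.items():
            members.sort()
            ids = [cid for _, cid in members]
            for i, cid in enumerate(ids):
                nxt = ids[(i + 1) % len(ids)]
                p, q = sorted([(cid, "e"), (nxt, "b")])
                out.add((p, q))
        return out


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    chrom_len: int,
    feat_len: int,
) -> int:
    """Random 0-based start for a feature avoiding occupied intervals."""
    for _ in range(200):
        start = int(rng.integers(0, chrom_len - feat_len))
        if all(start + feat_len + 5 <= a or start >= b + 5 for a, b in occupied):
            occupied.append((start, start + feat_len))
            return start
    raise ConfigError("could not place planted feature without overlap")


def generate_genome(config: SynthConfig) -> TruthSet:
    """Generate circular chromosomes with planted, recorded features.

    Planted repeats are distributed round-robin over chromosomes; the
    chloroplast-derived insert goes on the chromosome with the most
    planned breaks so fragmentation can isolate it as its own contig.
    Raises :class:`ConfigError` when a planted feature cannot fit.
    """
    rng = np.random.default_rng(config.seed)
    chroms: list[np.ndarray] = []
    occupied: list[list[tuple[int, int]]] = []
    for i, length in enumerate(config.chromosome_lengths):
        chroms.append(_random_seq(rng, length, config.gc_target))
        occupied.append([])

    truth = TruthSet(config=config, chromosomes=[], reference=None)

    def chrom_id(i: int) -> str:
        return f"mtChr{i + 1}"

    # plant SSRs / tandems / dispersed repeats round-robin
    for j, ssr in enumerate(config.planted_ssrs):
        ci = j % config.n_chromosomes
        unit = ssr.motif.upper()
        run = unit * ssr.copies
        if len(run) >= config.chromosome_lengths[ci]:
            raise ConfigError(f"planted SSR longer than chromosome {ci + 1}")
        start = _place(rng, occupied[ci], len(chroms[ci]), len(run))
        chroms[ci][start : start + len(run)] = np.frombuffer(
            run.encode(), dtype="S1"
        )
        # guard flanks so the planted run is maximal
        _break_flank(chroms[ci], start - 1, unit[-1])
        _break_flank(chroms[ci], start + len(run), unit[len(run) % len(unit)])
        truth.planted_ssrs.append(
            (chrom_id(ci), start + 1, start + len(run), unit, ssr.copies)
        )

    for j, tr in enumerate(config.planted_tandems):
        ci = j % config.n_chromosomes
        unit = tr.unit.upper()
        total = int(round(len(unit) * tr.copies))
        run = (unit * (total // len(unit) + 2))[:total]
        if total >= config.chromosome_lengths[ci]:
            raise ConfigError(f"planted tandem longer than chromosome {ci + 1}")
        start = _place(rng, occupied[ci], len(chroms[ci]), total)
        chroms[ci][start : start + total] = np.frombuffer(run.encode(), dtype="S1")
        _break_flank(chroms[ci], start - 1, run[-1])
        _break_flank(chroms[ci], start + total, run[total % len(unit)])
        truth.planted_tandems.append(
            (chrom_id(ci), start + 1, start + total, unit, tr.copies)
        )

    for j, dr in enumerate(config.planted_dispersed):
        ci = j % config.n_chromosomes
        cj = (j + 1) % config.n_chromosomes if config.n_chromosomes > 1 else ci
        if dr.length >= min(
            config.chromosome_lengths[ci], config.chromosome_lengths[cj]
        ):
            raise ConfigError("planted dispersed repeat longer than its chromosome")
        block = _random_seq(rng, dr.length, config.gc_target)
        s1 = _place(rng, occupied[ci], len(chroms[ci]), dr.length)
        chroms[ci][s1 : s1 + dr.length] = block
        copy = block.copy()
        if dr.mismatches:
            pos = rng.choice(dr.length, size=dr.mismatches, replace=False)
            for p in pos:
                alternatives = _BASES[_BASES != copy[p]]
                copy[p] = rng.choice(alternatives)
        if dr.orientation == "palindromic":
            copy = np.frombuffer(
                revcomp(copy.tobytes().decode()).encode(), dtype="S1"
            )
        s2 = _place(rng, occupied[cj], len(chroms[cj]), dr.length)
        chroms[cj][s2 : s2 + dr.length] = copy
        truth.planted_dispersed.append(
            (chrom_id(ci), s1 + 1, chrom_id(cj), s2 + 1, dr.length, dr.orientation)
        )

    # chloroplast-derived insert
    if config.cp_insert_length > 0:
        breaks = config.n_breaks_per_chromosome
        host = int(np.argmax(breaks))
        if config.cp_insert_length >= config.chromosome_lengths[host]:
            raise ConfigError("cp insert longer than its host chromosome")
        start = _place(
            rng, occupied[host], len(chroms[host]), config.cp_insert_length
        )
        truth.cp_insert = (
            chrom_id(host),
            start + 1,
            start + config.cp_insert_length,
        )

    truth.chromosomes = [
        SeqRecord(chrom_id(i), arr.tobytes().decode(), topology="circular")
        for i, arr in enumerate(chroms)
    ]

    # ancestral single-circle reference: concatenation of the chromosomes;
    # the junctions between them are the fission points of the target.
    if config.fission_plan != "none" and config.n_chromosomes > 1:
        ref_seq = "".join(r.sequence for r in truth.chromosomes)
        truth.reference = SeqRecord("ancestral", ref_seq, topology="circular")
        pos = 0
        for r in truth.chromosomes:
            pos += len(r)
            # junction after 1-based position `pos`; the last one wraps the
            # circular origin (the ancestral circle is cut there too)
            truth.false_junctions.append(pos)
        # intact control positions: chromosome midpoints in reference coords
        offset = 0
        for r in truth.chromosomes:
            truth.true_junctions.append(offset + len(r) // 2)
            offset += len(r)
    return truth


def _break_flank(arr: np.ndarray, pos: int, continuing_base: str) -> None:
    """Ensure the base at ``pos`` differs from ``continuing_base`` so a
    planted repeat run does not extend by accident."""
    if 0 <= pos < len(arr) and arr[pos] == continuing_base.encode():
        alternatives = _BASES[_BASES != arr[pos]]
        arr[pos] = alternatives[0]


# ---------------------------------------------------------------------------
# Fragmentation


def fragment_to_contigs(
    truth: TruthSet,
    n_spurious_links: int = 0,
):
    """Cut each circle at its planned break positions into contigs.

    A circle with ``k`` breaks yields ``k`` contigs (one self-adjacent
    contig when ``k`` is 0); graph links encode the true adjacencies.
    ``n_spurious_links`` injects that many reproducible false links
    between non-adjacent contig ends (cross-circle where possible) for
    pruning tests; injection is explicit, never on by default.

    Returns ``(contigs, graph)`` where contigs is a list of
    :class:`~mitocircles.screen.Contig` with sequences and bookkeeping
    depths, and graph is a :class:`~mitocircles.graph.ConnectionGraph`.
    Fills the contig truth fields of ``truth`` in place.
    """
    from .graph import ConnectionGraph
    from .screen import Contig

    config = truth.config
    rng = np.random.default_rng(config.seed + 1)
    contigs: list[Contig] = []
    graph = ConnectionGraph()
    truth.break_positions = []
    truth.contig_assignments = {}
    truth.expected_depth = {}

    for ci, record in enumerate(truth.chromosomes):
        L = len(record)
        k = config.n_breaks_per_chromosome[ci]
        cuts: list[int]
        if k == 0:
            cuts = [0]
        else:
            forced: list[int] = []
            if truth.cp_insert and truth.cp_insert[0] == record.id and k >= 2:
                forced = [truth.cp_insert[1] - 1, truth.cp_insert[2]]
            n_random = max(k - len(forced), 0)
            candidates = set(forced)
            while len(candidates) < len(forced) + n_random:
                candidates.add(int(rng.integers(0, L)))
            cuts = sorted(candidates)
        truth.break_positions.append(cuts)

        n_segments = len(cuts)
        ids = []
        for si in range(n_segments):
            a = cuts[si]
            b = cuts[(si + 1) % n_segments]
            if n_segments == 1:
                seq = record.sequence[a:] + record.sequence[:a]
            elif b > a:
                seq = record.sequence[a:b]
            else:
                seq = record.sequence[a:] + record.sequence[:b]
            cid = f"ctg{ci + 1:d}_{si:02d}"
            ids.append(cid)
            is_cp = (
                truth.cp_insert is not None
                and truth.cp_insert[0] == record.id
                and a == truth.cp_insert[1] - 1
                and b == truth.cp_insert[2]
            )
            expected = config.cp_depth + config.mt_depth if is_cp else config.mt_depth
            depth = round(
                float(expected * (1 + config.depth_jitter * rng.standard_normal())), 1
            )
            n_reads = int(round(depth * len(seq) / config.read_length_mean)) or 1
            contigs.append(
                Contig(cid, len(seq), depth, n_reads=n_reads, sequence=seq)
            )
            graph.add_contig(
                cid, length=len(seq), depth=depth, n_reads=n_reads, sequence=seq
            )
            truth.contig_assignments[cid] = (ci, si, "+")
            truth.expected_depth[cid] = float(expected)

        for si in range(n_segments):
            # junction support: reads spanning the junction, roughly half
            # a read length of coverage on each side
            support = max(1, int(round(config.mt_depth / 2)))
            graph.add_link(
                ids[si], "e", ids[(si + 1) % n_segments], "b", support=support
            )

    if n_spurious_links:
        true_adj = truth.adjacency_set()
        all_ends = sorted((c.id, e) for c in contigs for e in ("b", "e"))
        added = 0
        attempts = 0
        while added < n_spurious_links and attempts < 1000:
            attempts += 1
            i, j = rng.choice(len(all_ends), size=2, replace=False)
            p, q = sorted([all_ends[int(i)], all_ends[int(j)]])
            if (p, q) in true_adj or p == q:
                continue
            # prefer cross-circle links (the realistic failure mode:
            # shared plastid/HGT sequence joining different molecules)
            ci = truth.contig_assignments[p[0]][0]
            cj = truth.contig_assignments[q[0]][0]
            if ci == cj and truth.config.n_chromosomes > 1 and attempts < 500:
                continue
            if (p, q) in graph.link_set():
                continue
            # chance-homology links carry almost no spanning-read support
            graph.add_link(p[0], p[1], q[0], q[1], support=int(rng.integers(0, 3)))
            added += 1
        if added < n_spurious_links:
            raise ConfigError("could not inject requested spurious links")
    return contigs, graph


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(truth: TruthSet, config: SynthConfig | None = None):
    """Draw substitution-noised long reads from the circular chromosomes.

    Read count per chromosome follows the Lander-Waterman expectation
    ``depth * L / mean_read_length``; start positions are uniform on the
    circle and reads wrap the origin.  The chloroplast-derived insert,
    when present, additionally receives reads from its source plastid
    molecule (modelled as the insert sequence circularised) to plastid
    depth.  Returns ``(reads, provenance)`` where provenance maps read id
    to ``(molecule id, 0-based start, length)``.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 2)
    reads: list[SeqRecord] = []
    provenance: dict[str, tuple[str, int, int]] = {}

    def emit(name: str, template: str, mol: str, start: int, length: int) -> None:
        L = len(template)
        end = start + length
        seq = (
            template[start:end]
            if end <= L
            else template[start:] + template[: end - L]
        )
        if config.read_error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            n_err = rng.binomial(length, config.read_error_rate)
            if n_err:
                pos = rng.choice(length, size=n_err, replace=False)
                for p in pos:
                    alternatives = _BASES[_BASES != arr[p]]
                    arr[p] = rng.choice(alternatives)
            seq = arr.tobytes().decode()
        reads.append(SeqRecord(name, seq))
        provenance[name] = (mol, start, length)

    for ci, record in enumerate(truth.chromosomes):
        L = len(record)
        if config.read_length_mean > L:
            raise ConfigError(
                f"read length mean {config.read_length_mean:.0f} exceeds "
                f"chromosome {record.id} length {L}"
            )
        n = int(round(config.mt_depth * L / config.read_length_mean))
        lengths = np.clip(
            rng.normal(config.read_length_mean, config.read_length_sd, size=n),
            max(50, config.read_length_mean * 0.2),
            None,
        ).astype(int)
        lengths = np.minimum(lengths, L)
        starts = rng.integers(0, L, size=n)
        for i in range(n):
            emit(
                f"r{ci + 1}_{i:05d}",
                record.sequence,
                record.id,
                int(starts[i]),
                int(lengths[i]),
            )

    if truth.cp_insert is not None:
        chrom_id, s, e = truth.cp_insert
        insert = next(
            r for r in truth.chromosomes if r.id == chrom_id
        ).sequence[s - 1 : e]
        L = len(insert)
        rl = int(min(config.read_length_mean, L))
        n = int(round(config.cp_depth * L / rl))
        starts = rng.integers(0, L, size=n)
        for i in range(n):
            emit(f"cp_{i:05d}", insert, "cp_insert", int(starts[i]), rl)

    return reads, provenance


def scaled_study_config(factor: float = 0.05, seed: int = 0, **overrides) -> SynthConfig:
    """The default study conditions with genome and read lengths scaled
    down by ``factor`` (depths, error rate, break counts and the depth
    regime unchanged), for desk-scale runs."""
    base = SynthConfig()
    cfg = replace(
        base,
        seed=seed,
        chromosome_lengths=tuple(
            max(2000, int(l * factor)) for l in base.chromosome_lengths
        ),
        read_length_mean=max(500.0, base.read_length_mean * factor),
        read_length_sd=max(100.0, base.read_length_sd * factor),
        cp_insert_length=base.cp_insert_length,
        **overrides,
    )
    return cfg
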