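# Methods

`mitocircles` re-implements, as a tested library, the analysis chain by
which a multi-circular plant mitochondrial genome is resolved from a
depth-annotated contig assembly graph and then characterised: contig
screening by homology and read depth, graph pruning and circular
resolution, spanning-read validation of claimed fission points, repeat
profiling, collinear-block synteny, and genome feature bookkeeping. The
design target is the *Populus simonii* mitogenome — three
circular-mapping molecules (312.5, 283.0 and 186.0 kb, 781.5 kb total)
assembled from corrected PacBio reads at ~70× mitochondrial depth with a
291-bp chloroplast-derived contig at ~1000× — but every stage is generic
over its inputs.

## Depth-screened contig classification

Organelle assemblies from whole-genome reads mix genuine mitochondrial
contigs, plastid-derived contigs at roughly an order of magnitude higher
depth, and nuclear background. Screening combines:

* **Homology** — the fraction of a contig covered by exact shared
  substrings (≥ 20 bp, either strand) with a reference mitogenome.
  This replaces a BLAST screen: with congeneric references at organelle
  scale, exact 20-mer coverage is a deterministic and near-equivalent
  criterion, and it makes the screen reproducible bit for bit.
  Default acceptance is ≥ 0.5 of the contig covered.
* **Depth** — the modal mitochondrial depth is the *length-weighted
  median* of contig depths, computed after excluding contigs above
  `anomaly_factor` (default 3.0) times the unweighted median. Two
  passes are needed because a single plastid-depth contig can shift a
  plain median of a small contig set. On the published *P. simonii*
  contig table this gives 72.6×.

Contigs within ±35% of the modal depth with mitochondrial homology are
`mt`; plastid-level depth plus chloroplast homology marks `cp_derived`;
mitochondrial homology with out-of-band depth marks
`depth_anomalous_mt` (partially collapsed dispersed repeats inflate
depth this way); everything else is `non_organellar`. The ±35% default
makes the published 61.1–88.1× range normal and 113.7× anomalous; both
bounds are configuration.

## Graph pruning and circular resolution

The connection graph is a multigraph over *contig ends* (`b`/`e`); a
chromosome is an alternating circuit of contig traversals and junction
links. Resolution:

1. **Label pruning.** `cp_derived` and `non_organellar` nodes are
   removed with their links. Explicit keep/drop lists override the
   automatic labels — mirroring the manual curation step such analyses
   include, and needed for genuine mitochondrial plastid-derived tracts
   (MTPTs) that belong in a circle despite plastid depth.
2. **Fork resolution.** Provisional copy numbers come from depth
   ratios. Where an end has more links than its copy number, the
   preferred resolution is *global*: choose a link subset giving every
   end exactly its copy number of junctions — the degree condition any
   circular decomposition must satisfy — preferring links with the most
   spanning-read support and, at equal support, the smallest depth
   difference between the joined contigs. A spurious link cannot enter
   such a selection without starving a true junction somewhere. Depth
   difference alone is *not* sufficient: two mitochondrial contigs on
   different circles sit at statistically identical depth, so a chance
   link between them ties with the true links; junction read support is
   the discriminating evidence an assembler actually records. When no
   exact-degree selection exists (dangling ends), a local per-fork
   fallback drops the lowest-support, largest-depth-difference links,
   sparing a link whose removal would leave its partner end dangling
   unless the fork cannot otherwise be resolved. Every removal is
   logged with its reason.
3. **Copy numbers.** `round(depth / modal)`, clamped to ≥ 1. Two
   exceptions: ratios with fractional part in [0.4, 0.6] are flagged
   ambiguous and resolved to the smallest copy number that still admits
   a full circular decomposition; and contigs at anomalously high depth
   (> 3× modal, e.g. kept MTPTs) default to one copy, because
   plastid-level coverage reflects plastid reads, not extra
   mitochondrial traversals — the published 1036× contig is used once
   in its circle.
4. **Decomposition.** Link usage is selected by deterministic
   backtracking (exact per-end degrees, each link usable up to the
   smaller copy number of its two contigs), junction stubs are matched
   to traversal stubs in lexicographic order, and circuits are traced.
   Any such pairing closes into alternating circuits, so the search
   only has to satisfy the degree condition. Output is canonical: each
   circle rotated to its lexicographically smallest contig in `+`
   orientation (considering both traversal directions), circles sorted
   by descending length. The deposited rotations of real records are
   arbitrary; canonical form makes outputs byte-stable.

Stitching concatenates oriented member sequences, verifying and
trimming declared junction overlaps (default 0, the non-overlapping
contig convention). On the published 14-contig table this reproduces
draft lengths 312,303 / 282,737 / 185,980 bp and the 781,020 bp total.

## Spanning-read junction validation

Candidate break sites are reference positions where blocks adjacent on
a close single-circle reference map to different assembly chromosomes
or to non-adjacent loci (adjacency on circular molecules is evaluated
modulo the molecule length, so arbitrary assembly rotations do not
create artifactual sites). For each site, a window of 500 bp per flank
is cut from the reference and every corrected long read is aligned to
it: reads are located by shared 13-mer diagonal voting, clipped to the
overlapping segment (the full window and each flank separately, so a
read matching only one flank of a real fission point is reported as a
one-sided match instead of being rejected), and scored by unit-cost
alignment; identity counts gap columns. Acceptance follows long-read
practice: identity ≥ 0.95 over ≥ 450 columns. A read *spans* the
junction only when its accepted alignment covers ≥ 60% of the window
*and* crosses the midpoint — coverage of 60% of one flank alone must
not count. A junction is supported (i.e. the flanks are physically
contiguous) at ≥ 3 spanning reads; a true fission point shows matched
but essentially no spanning reads. The thresholds are printed as strict
inequalities in the source tables; they are implemented as ≥ on the
printed values.

## Repeat profiling

* **SSRs** — maximal perfect runs of primitive 1–6 bp units at the
  MISA-style thresholds 8/4/4/3/3/3 copies; a run is reported once,
  trimmed to whole copies, leftmost start (an A×8 run is a mono-SSR,
  never (AA)×4). Compound SSRs are not modelled.
* **Tandem repeats** — units ≥ 7 bp, ≥ 2 copies, ≤ 10% mismatch, via a
  per-period self-comparison scan with majority-vote consensus;
  overlapping calls collapse to the highest-copy period. This is a
  deliberately simple periodicity scorer, not a probabilistic-alignment
  model, so its counts on real data are indicative rather than
  tool-comparable.
* **Dispersed repeats** — all maximal pairs ≥ 30 bp within a Hamming
  budget of 3, direct and palindromic, within and across chromosomes,
  REPuter-style: pairs are seeded by exact 7-mers (pigeonhole-complete
  for the default thresholds) and enumerated per diagonal as maximal
  mismatch-budget windows; the trivial self-pair and direct pairs
  offset by < 30 bp (tandem-adjacent) are excluded. A repeat family of
  k copies counts as its C(k,2) pairs, REPuter's convention.
  Chromosomes are scanned per molecule by default; repeats are not
  chased across the circular origin by default, matching how
  linear-input tools are run on deposited records.

The comparative table bins pair counts at 30–49/50–69/70–99/100–149/
150–199/200–499/>500 bp. **Total repeat length is the union of bases
covered by at least one repeat instance** — the only definition under
which the total is guaranteed not to exceed the genome (the published
32,635 bp / 4.18% row is consistent with it).

## Collinear blocks and rearrangements

Anchors are all maximal exact matches ≥ 20 bp on both strands, found by
co-diagonal k-mer run merging (a run is maximal exactly where its
flanking bases disagree). Same-strand anchors whose reference and query
gaps are ≤ 1 kb are chained greedily in reference order; each chain's
inter-anchor gaps are aligned at unit edit costs and block identity is
`1 − edits / block_length`. Chains below 100 bp or 80% identity are
dropped — the standard delta-filter thresholds. Coverage is the union
of query bases in blocks. Rearrangements are counted as breakpoints of
the signed permutation of block order (adjacency preserved only with
equal molecule, equal orientation and consecutive signed rank);
`ceil(breakpoints / 2)` is reported as the "at least N" event bound,
since one reversal or translocation disturbs at most two adjacencies.
Exact block counts of alignment tools are parameterisation-dependent
and are not treated as comparable targets.

## Genome feature bookkeeping

GC content is (G+C)/(A+C+G+T)×100 with Ns excluded. The genome
partitions exactly into *gene territory* (the union of cis-connected
exon runs, introns included) and intergenic sequence; overlapping genes
count once. A junction between consecutive exons is **cis**-spliced
only when the exons share chromosome and strand and the genomic gap is
positive and ≤ 50 kb; different molecules, strand changes, or distant
same-molecule segments are **trans**-spliced junctions. The 50 kb bound
separates real plant mitochondrial cis introns (≤ a few kb) from
trans-spliced gene segments, which lie tens to hundreds of kb apart
even when they share a molecule (as parts of nad1 do). Start/stop
codons are read off the stitched coding sequence in annotation
orientation and reported as annotated — undetermined starts are never
"corrected", and CDS lengths not divisible by three are flagged, not
fatal, since organelle annotations may rely on RNA editing.

## Synthetic data

The generator emulates the study conditions: 3 circular chromosomes of
312,510 / 282,934 / 186,034 bp at GC 0.4478, fragmented into 1/7/6
contigs, mitochondrial depth 70×, a 291-bp chloroplast-derived insert
at 1000× (isolated as its own contig by forcing cuts at its
boundaries), corrected reads of mean 12,589 bp (sd 2,500 bp, a free
choice), and a single-circle "ancestral" reference whose junctions
between chromosome blocks are the planted fission points. Reads wrap
the circular origin; read counts follow the Lander–Waterman
expectation. The error model is substitution-only at a default 1% —
corrected long reads carry low residual error whose exact rate the
source data do not state; indels are deliberately out of scope, which
is why the junction aligner's seeded-diagonal clipping is exact on this
data. Bookkeeping depths carry 3% relative jitter; true junction links
get support ≈ depth/2, injected spurious links 0–2 reads. Spurious
links are injected only on explicit request, never by default, and
prefer cross-circle ends (the realistic failure mode).

What passing tests on this generator do *not* show: robustness to
indel-rich or chimeric reads, to assembler-specific graph artifacts
beyond simple false links, to diverged (rather than jittered) depth
profiles, or to repeat structures long enough to create isomeric
conformations — the study system has none longer than ~300 bp, and the
generator does not model them.

## Problem sizes and tolerances

Tests and the acceptance script run the synthetic study at 2–5% of the
real genome scale (chromosomes of ~6–16 kb, reads of ~0.5–1.3 kb,
depths unchanged), sizes chosen so the full statistical behaviour —
depth contrast, fragmentation profile, junction read support — is
preserved while whole-pipeline runs stay interactive. Structure
recovery is checked over 20 independent seeds; detector correctness is
checked by exact equality against exhaustive brute-force oracles on
500-bp instances; published-table arithmetic is checked exactly.
Verifying the deposited chromosome statistics (total 781,478 bp, GC
44.78%, SSR total at the MISA thresholds) additionally requires
downloading the GenBank records; the same statistics code paths are
oracle-checked on synthetic assemblies instead.

## Known limitations

* The Newbler "454ContigGraph" dialect here is a documented minimal
  stand-in (the original format is proprietary); GFA1 input covers
  modern assemblers.
* The tandem detector is not a TRF re-implementation; period calls on
  highly diverged minisatellites may differ from TRF's.
* Greedy anchor chaining can merge blocks that an optimal chainer would
  split when large repeats create crossing anchor sets; adequate at
  organelle scale, not for repeat-rich nuclear genomes.
* Rearrangement counts are breakpoint lower bounds, not a
  sorting-by-reversals distance.
* `parse_location` covers the location grammar subset used by organelle
  feature tables (ranges, join, complement, nesting); fuzzy positions
  (`<`, `>`) are rejected rather than interpreted.
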