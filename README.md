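# mitocircles

Resolving and characterising **multi-circular plant mitochondrial
genomes** from depth-annotated contig assembly graphs.

Plant mitogenomes are conventionally drawn as one master circle, but a
growing number of species carry their mitochondrial genome as several
independent circular-mapping molecules. Demonstrating such a structure
from whole-genome long-read data takes more than an assembler run: the
candidate mitochondrial contigs must be separated from plastid-derived
and nuclear contigs by read depth, the contig connection graph must be
pruned of false links and resolved into edge-disjoint circular walks,
and — crucially — every point where the assembly breaks the adjacency
of a close single-circle reference must be tested against the raw long
reads: if the molecule were really contiguous there, reads would span
the junction. `mitocircles` packages that whole chain for organelle
genomicists, together with repeat profiling (microsatellites, tandem
and dispersed repeats), collinear-block synteny with rearrangement
counts, genome feature bookkeeping, and a ground-truthed synthetic-data
generator so the entire pipeline is testable offline.

The design case is the *Populus simonii* mitogenome (GenBank
MZ905370–MZ905372): three circles of 312.5 / 283.0 / 186.0 kb assembled
from 14 contigs at ~70× mitochondrial depth, with one 291-bp
chloroplast-derived contig at ~1000×.

## The core computation

A contig connection graph is a multigraph over contig *ends*; a
chromosome is an alternating circuit of contig traversals and junction
links. With modal mitochondrial depth *m* (the length-weighted median
of contig depths after excluding >3 *m* outliers), each contig gets copy
number ≈ `round(depth/m)`, and resolution selects junction-link usage
so that every contig end carries exactly its copy number of junctions —
the degree condition a decomposition into circles requires — preferring
links with the most spanning-read support and the smallest depth
difference. Hierholzer-style tracing with lexicographic tie-breaks then
yields canonical circular paths. Junction validation cuts 500 bp flanks
around each candidate break site of a reference genome and counts reads
whose alignments (identity ≥ 0.95, length ≥ 450 bp) cover ≥ 60% of the
window *and* its midpoint: supported means physically contiguous, so a
real fission point shows matched but no spanning reads.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

Resolve the published *P. simonii* contig table (bundled in
`mitocircles.datasets`; sequences are synthetic stand-ins of the
printed lengths) into its three circles:

```python
from mitocircles.datasets import table1_contigs, table1_graph, CP_DERIVED_CONTIG
from mitocircles.screen import estimate_modal_depth
from mitocircles.graph import (
    prune_graph, assign_multiplicities, resolve_circles, stitch_sequences,
)

contigs = table1_contigs(with_sequences=True)
model = estimate_modal_depth(contigs)
print(f"modal mitochondrial depth: {model.modal_depth:.1f}x")

graph = table1_graph(contigs)
labels = {c.id: "mt" for c in contigs} | {CP_DERIVED_CONTIG: "cp_derived"}
pruned = prune_graph(graph, labels, model, keep={CP_DERIVED_CONTIG})
paths = resolve_circles(pruned, assign_multiplicities(pruned, model))
chromosomes = stitch_sequences(
    paths, {c: n.sequence for c, n in pruned.nodes.items()}
)
for rec, path in zip(chromosomes, paths):
    print(f"{rec.id}: {len(rec.sequence):,} bp from {len(path.members)} contig(s)")
```

Output:

```
modal mitochondrial depth: 72.6x
mtChr1: 312,303 bp from 1 contig(s)
mtChr2: 282,737 bp from 7 contig(s)
mtChr3: 185,980 bp from 6 contig(s)
```

The modal depth is the robust typical coverage of genuine mitochondrial
contigs; the chloroplast-derived contig (1036×) is kept by explicit
override — it is a genuine plastid-derived tract inside the second
circle — but contributes a single traversal, because plastid-level
depth comes from plastid reads, not extra mitochondrial copies. The
three stitched lengths are the draft chromosome sizes implied by the
printed per-contig lengths.

The same stages are available from the shell:

```sh
mitocircles simulate --seed 4 --scale 0.02 --out-prefix sim --spurious-links 2
mitocircles screen   --contigs sim.contigs.fasta --graph sim.graph.tsv \
                     --mt-ref sim.genome.fasta --out screen.tsv
mitocircles resolve  --graph sim.graph.tsv --contigs sim.contigs.fasta \
                     --screen-tsv screen.tsv --out-prefix res
mitocircles validate --chromosomes res.chromosomes.fasta \
                     --reference sim.reference.fasta --reads sim.reads.fasta \
                     --out junctions.tsv
mitocircles repeats ssr --in res.chromosomes.fasta --out ssr.tsv
mitocircles synteny  --ref sim.reference.fasta --query res.chromosomes.fasta \
                     --out-prefix syn
mitocircles run      --config pipeline.yaml        # all stages + manifest
```

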