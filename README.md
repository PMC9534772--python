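# fishprobes

Design pipeline for **sequential single-molecule FISH** (smFISH/seqFISH-style)
probe sets: from gene models to ordered, synthesis-ready 141-nt primary
probes and fluorophore-bearing readout probes, with every filter and
assembly rule explicit, seeded, and testable on a synthetic transcriptome.

## What it does

For each target gene, the pipeline designs a set of **primary probes**. Each
primary probe carries a 35-nt *binding site* complementary to the target
mRNA, flanked by six *readout sites* that a short fluorophore-conjugated
**readout probe** hybridizes to during imaging. Genes are read out one per
(round, channel) cell over sequential hybridization rounds.

The design procedure, per gene:

1. **Target regions** — binding sites are tiled over the *isoform-consensus*
   exonic sequence: the per-base intersection of the exon coverage of every
   annotated splice isoform, so each probe detects all isoforms. Target
   sequences are held mRNA-sense.
2. **Composition filters** — every 35-nt window must have GC ∈ [45, 75]%,
   no homopolymer run of 5 or more identical bases, and no N/soft-masked
   (lowercase) bases.
3. **Off-target screen** — a k-mer index (k = 15) over all spliced mRNAs
   plus reversed introns; a candidate sharing any exact ≥15-nt match, in
   either orientation, with a sequence of a *different* gene is dropped.
   (Sharing a 15-mer is exactly equivalent to a contiguous exact match of
   at least 15 nt, so the word length *is* the match cutoff.)
4. **Selection** — overlapping survivors are resolved greedily in favour of
   GC closest to 55%; genes that fail to yield more than 40 probes from
   consensus exons are expanded into introns and annotated 5′UTRs; the
   final set is trimmed to at most 40 probes by removing those farthest
   from 55% GC.
5. **Readouts** — 20-nt sequences drawn uniformly at random (seeded),
   kept iff GC ∈ [45, 60]% and no contiguous transcriptome homology longer
   than 14 nt in either orientation.
6. **Assembly** — each primary probe is

   `[R']-AA-[R']-AA-[R']-TAAT-[binding site]-TAAT-[R']-AA-[R']-AA-[R']`

   where each `R'` is the reverse complement of a 15-nt readout site, for a
   total of 6·15 + 16 + 35 = **141 nt**. A gene→readout codebook and a
   round/channel schedule (⌈genes/channels⌉ rounds over AF647/AF488/AF546)
   complete the design.

A seeded synthetic-transcriptome generator (`fishprobes.simulate`) builds
toy genomes with known isoform structure and *planted* features — shared
substrings between genes, homopolymers, soft-masked stretches, GC-extreme
exons — and an independent brute-force oracle (`fishprobes.oracle`)
recomputes expected per-gene probe counts from the raw FASTA/GTF for
end-to-end verification.

## Worked example

```bash
fishprobes simulate --seed 3 --n-genes 2 --out tx
fishprobes design --genome tx/genome.fa --annotation tx/annotation.gtf --out run --seed 3
```

prints

```
G01	29 probes
G02	32 probes
total primary probes: 61
hybridization rounds: 1
```

i.e. the two synthetic genes yielded 29 and 32 filter-passing,
non-overlapping binding sites (both under the 40-probe cap, so both genes
were also expanded into their introns), and both fit in one hybridization
round across the three channels. The run directory contains the probe
FASTA, an order sheet (with 5′-phosphate notes for primaries and
5′-fluorophore labels for readouts), the codebook, the schedule, a full
config snapshot, and a per-stage log. Each emitted record parses back
through the assembly grammar:

```
>G01|1|10|exon_consensus
GAGAAGAATCTCAAG...AAGAGAAGAATCTCAAG   # 141 nt
```

`fishprobes validate --run-dir run` re-checks every invariant of the
emitted files (`OK: 61 primary probes validated`).

Library use mirrors the CLI: `run_pipeline(DesignConfig(seed=3), genome,
gtf, out_dir)` returns per-gene probe sets, readouts, codebook and
schedule as Python objects.

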