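# Methods

## Design model

A sequential smFISH experiment images one gene per fluorophore channel per
hybridization round. Each target mRNA is decorated with up to 40 primary
probes; each primary probe presents six copies of a readout-binding site,
and the fluorophore-bearing readout oligo that hybridizes to those sites is
exchanged between rounds. The design problem is therefore: (a) find up to
40 specific, well-behaved 35-nt binding sites per gene; (b) find mutually
usable 20-nt readout sequences orthogonal to the transcriptome; (c) fuse
them into orderable oligos and a round/channel schedule.

## Target-region model

Probes are tiled over the **isoform consensus**: the per-base intersection
of exon coverage across all annotated isoforms of the gene, reported as
maximal disjoint intervals. Intersection is the strictest reading of a
"consensus" and guarantees every probe binds every isoform; a
majority-coverage rule would admit probes invisible to some isoforms.
Internally all coordinates are 0-based half-open (GTF input is converted
at the I/O boundary), and every target sequence is stored mRNA-sense so
windowing is strand-agnostic. When a gene's consensus yields 40 or fewer
probes after all filters, the target space is expanded with intron
sequence (union across isoforms of inter-exon gaps) and annotated 5′UTR
features; 5′UTRs are used only when the annotation provides
`five_prime_utr` lines, since they are not inferable from exon records.

## Filters

| parameter | default | meaning |
|---|---|---|
| `window` | 35 nt | binding-site length |
| `gc_min..gc_max` | 45–75 % | inclusive GC band for binding sites |
| `max_homopolymer_run` | 4 | a run of 5 identical bases disqualifies |
| `offtarget_k` | 15 nt | exact-match word length = off-target cutoff |
| `expansion_threshold` | 40 | expand unless a gene yields **more than** 40 probes |
| `max_probes` | 40 | per-gene probe cap |
| `gc_target` | 55 % | GC value preferred in selection and trimming |
| `readout_length` | 20 nt | readout probe length |
| `readout_gc` | 45–60 % | inclusive readout GC band |
| `readout_max_homology` | 14 nt | longest tolerated transcriptome homology |
| `readout_site_len` | 15 nt | readout prefix embedded in primary probes |
| `channels` | AF647, AF488, AF546 | fluorophore channels |

GC bounds are inclusive at both ends (the conventional reading of a
percentage range). GC is computed case-insensitively over the full window;
windows containing N, lowercase (soft-masked) or ambiguity bases are
rejected outright — masking is enforced at the candidate level rather than
by hard-masking the input, so the emitted target sequences still show what
was masked. The homopolymer rule reads "five repeating bases of the same
kind" as: a run of length ≥ 5 disqualifies; 4 is allowed.

## Off-target screening

The screening database contains every spliced mRNA of every gene plus
every intron **reversed** — literal string reversal by default, matching
the conventional construction of a reversed-intron decoy set;
`intron_reversal_mode: revcomp` switches to reverse-complement since the
wording of such pipelines is often ambiguous. Screening is exact k-mer
sharing with k equal to the match cutoff (15): for exact matches the two
criteria coincide, so no alignment heuristic is needed and the screen is
fully deterministic. Both orientations of the query are checked (as an
aligner searching both strands would). Matches to the candidate's own gene
— any isoform — are exempt; readout screening has no exemption. Gapped or
mismatch-tolerant near-matches below 100% identity are out of scope.

## Selection rules

Candidates tile at step 1, so survivors overlap heavily. Overlap
resolution is greedy: repeatedly accept the candidate minimizing
|GC − 55|, discarding everything overlapping it within the same target
region. Ties are broken by the region's genomic start, then the offset
within the region, then the window string — the spec of "smaller start"
alone is not total when two regions have candidates at equal offsets, so
the region start is included to make the order deterministic and
reproducible by an independent implementation. Trimming removes the probe
maximizing |GC − 55| until 40 remain; ties remove the 3′-most probe
(larger region start, then larger offset) so 5′ probes are preserved.
Exonic probes are never displaced by expansion probes: expansion only
appends, and trimming is applied last, to the merged set.

## Readout generation

Rejection sampling from a seeded `numpy` Generator: uniform draws over
{A,C,G,T}^20 are accepted iff the GC band and the transcriptome-homology
screen pass. A hard attempt cap (10 000 draws per requested readout)
converts a hopeless configuration into an informative error reporting the
acceptance rate rather than an infinite loop. Mutual readout-to-readout
orthogonality (no shared 12-mer, either orientation) is available behind
`cross_check` but off by default, as it is an extension of the published
procedure rather than part of it.

## Assembly arithmetic

The grammar `R'-AA-R'-AA-R'-TAAT-B-TAAT-R'-AA-R'-AA-R'` gives
`6·site_len + 16 + |B|` nt. With full 20-nt readouts as sites this is
171 nt, which contradicts the published total of 141 nt; with 15-nt sites
it is exactly 141. This package therefore embeds the 5′ 15-nt prefix of
each readout as the site (`readout_site_len = 15`, configurable), which
reconciles the arithmetic while keeping full-length readouts for the
order sheet. In sequential mode all six slots carry the same readout —
one gene, one readout identity, six-fold signal amplification; per-slot
mixing is supported by the assembler but not used by the default pipeline.

## Synthetic data and the oracle

The generator emulates only what the pipeline consumes: multi-isoform
genes (isoforms differ by skipped *internal* exons, so the consensus is
known by construction), tunable base GC, alternating strands, and planted
features recorded with exact coordinates in a manifest — shared
substrings between gene pairs (flank bases decorrelated so the exact
match has exactly the requested length), homopolymers (flanks forced
different so the run length is exact), soft-masked stretches, and
GC-extreme exons built by tiling a 35-nt motif with no two equal adjacent
bases, which makes every window's composition identical and survivor
counts analytic. Default scale is 10 genes of roughly 1–2 kb; tests use
2–5 genes so a full pipeline + oracle comparison takes a few seconds, and
the end-to-end agreement check runs 20 seeded transcriptomes.

It does **not** emulate repeat families, codon structure, alternative
transcription starts/ends, expression levels, or realistic intergenic
sequence, so passing tests demonstrate the correctness of the design
*rules*, not probe performance on a real genome; on real annotation the
same rules apply unchanged but yields will differ.

The oracle (`expected_survivors`) recomputes final per-gene counts by
brute force — Biopython FASTA reading, hand-split GTF lines, per-base
boolean masks for consensus/introns, full window enumeration with inline
checks, `str.find` substring search for off-target matches, and literal
simulation of the greedy/expansion/trim rules — sharing no code with the
pipeline, so exact agreement is meaningful evidence of correctness.

## Numerical and degenerate-input choices

* GC comparisons use plain floating point; both sides derive from
  `100*count/length` with identical arithmetic, so boundary candidates are
  classified consistently.
* Regions shorter than the window yield zero candidates (not an error);
  an empty isoform-consensus is an empty region list; an empty final probe
  set is written as a valid empty FASTA with a warning in the run log.
* k-mers containing non-ACGT characters are never indexed; queries skip
  them implicitly because a window containing them was already rejected by
  the mask filter (readout draws are ACGT by construction).
* `ceil(genes/channels)` rounds; a fluorophore-constrained placement that
  cannot fit in that many rounds is a hard error naming the gene.

## Known limitations

No melting-temperature or secondary-structure model (the procedure this
implements uses none); no gapped/mismatched off-target detection; no
genome-wide (non-transcriptomic) screening; no combinatorial
(error-correcting) codebooks — one readout identity per gene only.
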