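"""Gene models and target-region extraction.

Reads a GTF subset (exon features, optional five_prime_utr features) plus an
indexed genome FASTA into :class:`GeneModel` objects, and derives the
sequences probes are designed against:

* **isoform-consensus exonic regions** — the per-base intersection of the
  exon coverage of every annotated isoform, so a probe placed there detects
  all splice isoforms;
* **expansion regions** — introns (union across isoforms) and annotated
  5′UTRs, used only for genes whose consensus regions do not yield enough
  probes.

Coordinates are 0-based half-open internally; GTF input is 1-based closed.
All target sequences are stored mRNA-sense (reverse complement of the
reference slice for minus-strand genes) so downstream windowing is
strand-agnostic.  Soft-masked (lowercase) and N bases are preserved here and
rejected later at candidate filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from pyfaidx import Fasta

from fishprobes._seq import reverse_complement

Interval = tuple[int, int]


class GeneModelError(ValueError):
    """Raised for malformed or inconsistent gene models."""


@dataclass(frozen=True)
class Isoform:
    transcript_id: str
    exons: tuple[Interval, ...]  # sorted, non-overlapping, 0-based half-open


@dataclass
class GeneModel:
    gene_id: str
    strand: str  # '+' or '-'
    reference_name: str
    isoforms: list[Isoform]
    utr5: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.isoforms:
            raise GeneModelError(f"{self.gene_id}: gene has no isoforms")
        for iso in self.isoforms:
            if not iso.exons:
                raise GeneModelError(
                    f"{self.gene_id}/{iso.transcript_id}: transcript has zero exons"
                )
            for start, end in iso.exons:
                if start >= end:
                    raise GeneModelError(
                        f"{self.gene_id}/{iso.transcript_id}: empty exon [{start},{end})"
                    )
            for (s0, e0), (s1, e1) in zip(iso.exons, iso.exons[1:]):
                if s1 < e0:
                    raise GeneModelError(
                        f"{self.gene_id}/{iso.transcript_id}: exons overlap or unsorted"
                    )

    @property
    def span(self) -> Interval:
        starts = [iv[0] for iso in self.isoforms for iv in iso.exons]
        ends = [iv[1] for iso in self.isoforms for iv in iso.exons]
        return min(starts), max(ends)


@dataclass
class TargetRegion:
    """A contiguous stretch of target-sense sequence for one gene."""

    gene_id: str
    start: int  # reference coordinates, 0-based half-open
    end: int
    sequence: str  # mRNA sense; length == end - start
    source: str  # exon_consensus | intron | utr5

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise GeneModelError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# interval arithmetic (0-based half-open)


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as maximal disjoint sorted intervals."""
    if not intervals:
        return []
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Intersection of two disjoint sorted interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


# ---------------------------------------------------------------------------
# I/O


def open_genome(genome_path) -> Fasta:
    """Open an indexed FASTA; lowercase soft-masking is preserved on fetch."""
    return Fasta(str(genome_path))


def _fetch(genome: Fasta, reference: str, start: int, end: int) -> str:
    return str(genome[reference][start:end])


def read_gene_models(annotation_path, genome_path) -> list[GeneModel]:
    """Read a GTF subset into GeneModels, validated against the genome.

    Exon features must carry ``gene_id`` and ``transcript_id`` attributes.
    GTF 1-based closed coordinates are converted to 0-based half-open.
    Genes are returned sorted by gene_id; isoforms sorted by transcript_id.
    """
    genome = open_genome(genome_path)
    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, dict[str, list[Interval]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene_id -> (reference, strand)
    utr5: dict[str, list[Interval]] = {}

    for feat in db.all_features():
        if feat.featuretype not in ("exon", "five_prime_utr"):
            continue
        gene_id = feat.attributes["gene_id"][0]
        if feat.seqid not in genome:
            raise GeneModelError(
                f"reference sequence {feat.seqid!r} (gene {gene_id}) "
                "not present in the genome FASTA"
            )
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> half-open
        ref_len = len(genome[feat.seqid])
        if iv[0] < 0 or iv[1] > ref_len:
            raise GeneModelError(
                f"{gene_id}: feature [{feat.start},{feat.end}] outside "
                f"{feat.seqid} (length {ref_len})"
            )
        prev = meta.setdefault(gene_id, (feat.seqid, feat.strand))
        if prev != (feat.seqid, feat.strand):
            raise GeneModelError(f"{gene_id}: inconsistent reference/strand across features")
        if feat.featuretype == "exon":
            tid = feat.attributes["transcript_id"][0]
            exons.setdefault(gene_id, {}).setdefault(tid, []).append(iv)
        else:
            utr5.setdefault(gene_id, []).append(iv)

    genes: list[GeneModel] = []
    for gene_id in sorted(meta):
        reference, strand = meta[gene_id]
        if gene_id not in exons:
            raise GeneModelError(f"{gene_id}: no exon features (zero-exon gene)")
        isoforms = [
            Isoform(tid, tuple(sorted(ivs)))
            for tid, ivs in sorted(exons[gene_id].items())
        ]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                strand=strand,
                reference_name=reference,
                isoforms=isoforms,
                utr5=merge_intervals(utr5.get(gene_id, [])),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# target regions


def _region(gene: GeneModel, genome: Fasta, iv: Interval, source: str) -> TargetRegion:
    seq = _fetch(genome, gene.reference_name, iv[0], iv[1])
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return TargetRegion(gene.gene_id, iv[0], iv[1], seq, source)


def consensus_exonic_regions(gene: GeneModel, genome: Fasta) -> list[TargetRegion]:
    """Exonic intervals covered by *every* isoform, as maximal disjoint regions.

    A single-isoform gene returns its own exons; disjoint isoforms give an
    empty list.  Regions are sorted by reference coordinate.
    """
    consensus = merge_intervals(list(gene.isoforms[0].exons))
    for iso in gene.isoforms[1:]:
        consensus = intersect_intervals(consensus, merge_intervals(list(iso.exons)))
    return [_region(gene, genome, iv, "exon_consensus") for iv in consensus]


def intron_intervals(gene: GeneModel) -> list[Interval]:
    """Union across isoforms of the gaps between consecutive exons."""
    gaps: list[Interval] = []
    for iso in gene.isoforms:
        for (_, e0), (s1, _) in zip(iso.exons, iso.exons[1:]):
            if e0 < s1:
                gaps.append((e0, s1))
    return merge_intervals(gaps)


def expansion_regions(gene: GeneModel, genome: Fasta) -> list[TargetRegion]:
    """Intron and annotated 5′UTR target regions, used when the consensus
    regions do not yield enough probes."""
    regions = [_region(gene, genome, iv, "intron") for iv in intron_intervals(gene)]
    regions += [_region(gene, genome, iv, "utr5") for iv in gene.utr5]
    return regions
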