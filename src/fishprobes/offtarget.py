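"""Off-target screening against the transcriptome.

The off-target database holds every spliced mRNA (all isoforms of all
genes) plus every intron sequence *reversed* (literal string reversal by
default; reverse-complement available via ``intron_mode``).  Screening uses
exact k-mer sharing with k equal to the match-length cutoff (default 15):
a candidate shares a k-mer with a database sequence iff the two share a
contiguous exact match of at least k nt, so the k-mer criterion and the
match-length criterion coincide exactly.  Both orientations of the query
are screened.

Primary-probe candidates are exempt from matches to their own gene (all of
its isoforms); readout probes get no exemption — they must be orthogonal to
the entire transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyfaidx import Fasta

from fishprobes._seq import reverse_complement
from fishprobes.config import ConfigError
from fishprobes.gene_models import GeneModel, intron_intervals
from fishprobes.candidates import ProbeCandidate


@dataclass
class OffTargetIndex:
    k: int
    kmer_map: dict[str, set[str]] = field(default_factory=dict)
    owner: dict[str, str] = field(default_factory=dict)  # sequence id -> gene_id
    db_composition: list[tuple[str, str, int]] = field(default_factory=list)
    # (sequence id, kind in {mrna, reversed_intron}, length)

    def add_sequence(self, seq_id: str, gene_id: str, kind: str, seq: str) -> None:
        seq = seq.upper()
        self.owner[seq_id] = gene_id
        self.db_composition.append((seq_id, kind, len(seq)))
        k = self.k
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if all(b in "ACGT" for b in kmer):
                self.kmer_map.setdefault(kmer, set()).add(seq_id)

    def lookup(self, kmer: str) -> set[str]:
        return self.kmer_map.get(kmer, set())


@dataclass(frozen=True)
class OffTargetHit:
    candidate_gene_id: str
    hit_sequence_id: str
    hit_gene_id: str
    kmer: str
    orientation: str  # same | revcomp


def _spliced_mrna(gene: GeneModel, genome: Fasta, exons) -> str:
    parts = [str(genome[gene.reference_name][s:e]) for s, e in exons]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


def build_offtarget_index(
    genes: list[GeneModel],
    genome: Fasta,
    k: int = 15,
    intron_mode: str = "reverse",
) -> OffTargetIndex:
    """Index all spliced mRNAs and all reversed introns.

    ``intron_mode``: ``reverse`` (literal reversal, default) or ``revcomp``.
    Sequences are uppercased; k-mers containing non-ACGT bases are skipped.
    """
    if k < 1:
        raise ConfigError(f"offtarget k must be >= 1, got {k}")
    if intron_mode not in ("reverse", "revcomp"):
        raise ConfigError(f"intron_mode must be 'reverse' or 'revcomp', got {intron_mode!r}")
    idx = OffTargetIndex(k=k)
    for gene in genes:
        for iso in gene.isoforms:
            idx.add_sequence(
                f"{gene.gene_id}|{iso.transcript_id}|mrna",
                gene.gene_id,
                "mrna",
                _spliced_mrna(gene, genome, iso.exons),
            )
        for i, (s, e) in enumerate(intron_intervals(gene), start=1):
            intron = str(genome[gene.reference_name][s:e])
            if gene.strand == "-":
                intron = reverse_complement(intron)  # transcript-sense intron
            if intron_mode == "reverse":
                intron = intron[::-1]
            else:
                intron = reverse_complement(intron)
            idx.add_sequence(
                f"{gene.gene_id}|intron{i}|rev",
                gene.gene_id,
                "reversed_intron",
                intron,
            )
    return idx


def _query_hits(seq: str, idx: OffTargetIndex, own_gene: str | None):
    """All index hits of seq's k-mers in both orientations, excluding own_gene."""
    k = idx.k
    hits: list[OffTargetHit] = []
    for orientation, q in (("same", seq.upper()), ("revcomp", reverse_complement(seq.upper()))):
        for i in range(len(q) - k + 1):
            kmer = q[i : i + k]
            for seq_id in sorted(idx.lookup(kmer)):
                gene_id = idx.owner[seq_id]
                if own_gene is not None and gene_id == own_gene:
                    continue
                hits.append(
                    OffTargetHit(
                        candidate_gene_id=own_gene if own_gene is not None else "",
                        hit_sequence_id=seq_id,
                        hit_gene_id=gene_id,
                        kmer=kmer,
                        orientation=orientation,
                    )
                )
    return hits


def screen_candidate(
    c: ProbeCandidate, idx: OffTargetIndex, match_length: int = 15
) -> tuple[bool, list[OffTargetHit]]:
    """Fail iff the candidate window (either orientation) shares a k-mer with
    a sequence owned by a different gene.  Records ``offtarget`` in the
    candidate's filter_status."""
    if idx.k != match_length:
        raise ConfigError(
            f"index k={idx.k} does not match configured match length {match_length}"
        )
    hits = _query_hits(c.target_window, idx, own_gene=c.gene_id)
    ok = not hits
    c.filter_status["offtarget"] = ok
    return ok, hits


def screen_readout(seq: str, idx: OffTargetIndex, max_homology: int = 14) -> bool:
    """Fail iff the sequence (either orientation) shares any contiguous match
    longer than max_homology nt with ANY indexed sequence."""
    if idx.k != max_homology + 1:
        raise ConfigError(
            f"index k={idx.k} does not match max_homology+1={max_homology + 1}"
        )
    return not _query_hits(seq, idx, own_gene=None)
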