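"""Brute-force expected-survivor oracle.

Recomputes the final per-gene probe count from the raw FASTA + GTF with
none of the pipeline's machinery: Biopython FASTA reading, hand-split GTF
lines, per-base numpy coverage masks for the isoform consensus and intron
union, full window enumeration with inline composition checks, exact
substring search (``str.find`` over concatenated database text) for
off-target matches, and a literal simulation of the greedy overlap /
expansion / trimming rules.  Deliberately shares no code path with the
pipeline modules so agreement between the two is meaningful evidence.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from fishprobes.config import DesignConfig


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _parse_gtf(path):
    """gene_id -> (seqid, strand, {transcript_id: [(start0, end)]}, utr5 list)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seqid, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if ftype not in ("exon", "five_prime_utr"):
                continue
            fields = {}
            for chunk in attrs.strip().split(";"):
                chunk = chunk.strip()
                if chunk:
                    key, _, val = chunk.partition(" ")
                    fields[key] = val.strip('"')
            gid = fields["gene_id"]
            rec = genes.setdefault(
                gid, {"seqid": seqid, "strand": strand, "tx": {}, "utr5": []}
            )
            iv = (int(start) - 1, int(end))
            if ftype == "exon":
                rec["tx"].setdefault(fields["transcript_id"], []).append(iv)
            else:
                rec["utr5"].append(iv)
    for rec in genes.values():
        for ivs in rec["tx"].values():
            ivs.sort()
    return genes


def _runs(mask: np.ndarray, offset: int) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as genomic intervals."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((offset + i, offset + j))
            i = j
        else:
            i += 1
    return out


def _gene_regions(rec) -> tuple[list, list]:
    """(consensus intervals, intron-union intervals) via per-base masks."""
    all_iv = [iv for ivs in rec["tx"].values() for iv in ivs]
    lo = min(s for s, _ in all_iv)
    hi = max(e for _, e in all_iv)
    consensus = np.ones(hi - lo, dtype=bool)
    intron = np.zeros(hi - lo, dtype=bool)
    for ivs in rec["tx"].values():
        cover = np.zeros(hi - lo, dtype=bool)
        for s, e in ivs:
            cover[s - lo : e - lo] = True
        consensus &= cover
        first, last = ivs[0][0], ivs[-1][1]
        gaps = np.zeros(hi - lo, dtype=bool)
        gaps[first - lo : last - lo] = True
        for s, e in ivs:
            gaps[s - lo : e - lo] = False
        intron |= gaps
    return _runs(consensus, lo), _runs(intron, lo)


def _region_seq(chrom: str, iv, strand: str) -> str:
    s = chrom[iv[0] : iv[1]]
    return _revcomp(s) if strand == "-" else s


def _db_text(genes, chroms, intron_mode: str) -> dict[str, str]:
    """Per gene: all database sequences (mRNAs + reversed introns) joined
    with '#' separators (never matched by an ACGT k-mer)."""
    texts = {}
    for gid, rec in genes.items():
        chrom = chroms[rec["seqid"]]
        parts = []
        for ivs in rec["tx"].values():
            mrna = "".join(chrom[s:e] for s, e in ivs)
            if rec["strand"] == "-":
                mrna = _revcomp(mrna)
            parts.append(mrna.upper())
        _, introns = _gene_regions(rec)
        for iv in introns:
            intr = _region_seq(chrom, iv, rec["strand"]).upper()
            parts.append(intr[::-1] if intron_mode == "reverse" else _revcomp(intr))
        texts[gid] = "#".join(parts)
    return texts


def _offtarget_hit(window: str, other_text: str, k: int) -> bool:
    w = window.upper()
    for q in (w, _revcomp(w)):
        for i in range(len(q) - k + 1):
            if q[i : i + k] in other_text:
                return True
    return False


def _survivor_windows(regions, chrom, strand, gid, other_text, cfg: DesignConfig):
    """(source, region_start, offset, window, gc) for every passing window."""
    out = []
    for source, iv in regions:
        seq = _region_seq(chrom, iv, strand)
        W = cfg.window
        for s in range(0, len(seq) - W + 1, cfg.step):
            w = seq[s : s + W]
            if any(b not in "ACGT" for b in w):
                continue
            gc = 100.0 * (w.count("G") + w.count("C")) / W
            if not (cfg.gc_min <= gc <= cfg.gc_max):
                continue
            run = best = 1
            for a, b in zip(w, w[1:]):
                run = run + 1 if a == b else 1
                best = max(best, run)
            if best > cfg.max_homopolymer_run:
                continue
            if _offtarget_hit(w, other_text, cfg.offtarget_k):
                continue
            out.append((source, iv[0], s, w, gc))
    return out


def _greedy(windows, cfg: DesignConfig):
    """Literal greedy overlap resolution on (source, region_start, offset, window, gc)."""
    remaining = sorted(
        windows, key=lambda t: (abs(t[4] - cfg.gc_target), t[1], t[2], t[3])
    )
    accepted = []
    for t in remaining:
        if any(
            a[0] == t[0] and a[1] == t[1]
            and t[2] < a[2] + cfg.window and a[2] < t[2] + cfg.window
            for a in accepted
        ):
            continue
        accepted.append(t)
    return accepted


def _trim(probes, cfg: DesignConfig):
    probes = list(probes)
    while len(probes) > cfg.max_probes:
        victim = max(probes, key=lambda t: (abs(t[4] - cfg.gc_target), t[1], t[2]))
        probes.remove(victim)
    return probes


def expected_survivors(
    genome_path, annotation_path, config: DesignConfig | None = None
) -> dict[str, int]:
    """Brute-force final probe count per gene (the end-to-end oracle)."""
    cfg = (config or DesignConfig()).validate()
    chroms = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome_path), "fasta")}
    genes = _parse_gtf(annotation_path)
    db = _db_text(genes, chroms, cfg.intron_reversal_mode)

    counts: dict[str, int] = {}
    for gid in sorted(genes):
        rec = genes[gid]
        chrom = chroms[rec["seqid"]]
        other_text = "#".join(db[g] for g in sorted(db) if g != gid)
        consensus, introns = _gene_regions(rec)
        exonic = _survivor_windows(
            [("exon_consensus", iv) for iv in consensus],
            chrom, rec["strand"], gid, other_text, cfg,
        )
        resolved = _greedy(exonic, cfg)
        if len(resolved) <= cfg.expansion_threshold:
            utr5 = []
            for s, e in sorted(rec["utr5"]):
                if utr5 and s <= utr5[-1][1]:
                    utr5[-1] = (utr5[-1][0], max(utr5[-1][1], e))
                else:
                    utr5.append((s, e))
            expansion = [("intron", iv) for iv in introns]
            expansion += [("utr5", iv) for iv in utr5]
            extra = _survivor_windows(
                expansion, chrom, rec["strand"], gid, other_text, cfg
            )
            resolved = resolved + _greedy(extra, cfg)
        counts[gid] = len(_trim(resolved, cfg))
    return counts
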