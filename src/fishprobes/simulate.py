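"""Seeded synthetic transcriptomes with planted ground truth.

Generates a toy genome FASTA + GTF + manifest JSON whose every feature is
analytically known, so pipeline behaviour can be checked against an
independent brute-force oracle.  Genes alternate strand, have 1..k
isoforms built by skipping internal exons (so the isoform consensus is the
set of exons present in every isoform, computable by inspection), and can
carry planted features:

* ``SharedSubstring`` — an identical random substring embedded in the
  exons (or introns) of two genes, to trigger off-target rejection; flank
  bases are decorrelated so the exact shared match has exactly the
  requested length.
* ``HomopolymerPlant`` — a run of one base, flanks forced different so the
  run has exactly the requested length.
* ``SoftMaskPlant`` — a lowercase (soft-masked) stretch.
* ``GCExtremePlant`` — replaces the gene's first consensus exon with a
  tiling of a 35-nt motif at the requested GC with no base repeated twice
  in a row; every 35-nt window of such an exon has identical composition,
  so survivor counts are exact arithmetic.  (Two genes planted at the same
  GC would share 15-mers; use one per transcriptome.)

Everything is drawn from one ``numpy`` generator seeded by the spec, so
identical specs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fishprobes._seq import DNA_BASES, reverse_complement


class PlantError(ValueError):
    """An infeasible planted feature (e.g. longer than its exon)."""


@dataclass(frozen=True)
class SharedSubstring:
    gene_a: str
    gene_b: str
    length: int
    compartment: str = "exon"  # exon | intron


@dataclass(frozen=True)
class HomopolymerPlant:
    gene: str
    base: str
    run_length: int


@dataclass(frozen=True)
class SoftMaskPlant:
    gene: str
    length: int


@dataclass(frozen=True)
class GCExtremePlant:
    gene: str
    region_gc: float  # percent


@dataclass
class SyntheticSpec:
    seed: int
    n_genes: int = 10
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (200, 400)
    intron_length: tuple[int, int] = (80, 200)
    base_gc: float = 50.0
    plants: list = field(default_factory=list)
    chrom: str = "chrS"
    spacer: int = 100

    def gene_ids(self) -> list[str]:
        width = max(2, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    g = gc / 100.0
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]  # A C G T
    return "".join(np.array(list(DNA_BASES))[rng.choice(4, size=length, p=p)])


def gc_motif(gc: float, length: int = 35) -> str:
    """A motif of the given length and GC with no two equal adjacent bases.

    Interleaves an alternating G/C stream with an alternating A/T stream
    (Bresenham spacing), so any tiling of the motif has max homopolymer
    run 1 and every window of the motif's tiling has identical GC.
    """
    n_gc = int(round(length * gc / 100.0))
    if not 0 <= n_gc <= length:
        raise PlantError(f"region_gc {gc} infeasible for length {length}")
    gc_stream = ["G" if i % 2 == 0 else "C" for i in range(n_gc)]
    at_stream = ["A" if i % 2 == 0 else "T" for i in range(length - n_gc)]
    big, small = (gc_stream, at_stream) if len(gc_stream) >= len(at_stream) else (at_stream, gc_stream)
    out: list[str] = []
    err = 0
    bi = si = 0
    for _ in range(length):
        err += len(small)
        if err >= len(big) and si < len(small):
            out.append(small[si])
            si += 1
            err -= len(big)
        else:
            out.append(big[bi])
            bi += 1
    return "".join(out)


class _GeneDraft:
    """Mutable per-gene state during generation (target-sense segments)."""

    def __init__(self, gene_id, strand, exon_seqs, intron_seqs, isoform_exons, consensus_idx):
        self.gene_id = gene_id
        self.strand = strand
        self.exons = list(exon_seqs)  # target-sense
        self.introns = list(intron_seqs)
        self.isoform_exons = isoform_exons  # transcript_id -> list of exon indices
        self.consensus_idx = consensus_idx  # exon indices in every isoform
        self.cursors = {}  # (compartment, seg_index) -> next free offset
        self.plant_records = []

    def _segment(self, compartment: str):
        if compartment == "exon":
            if not self.consensus_idx:
                raise PlantError(f"{self.gene_id}: no consensus exon to plant into")
            i = self.consensus_idx[0]
            return "exon", i, self.exons
        if compartment == "intron":
            if not self.introns:
                raise PlantError(f"{self.gene_id}: no intron to plant into")
            return "intron", 0, self.introns
        raise PlantError(f"unknown compartment {compartment!r}")

    def paste(self, compartment: str, payload: str, record: dict) -> tuple[int, int]:
        """Paste payload at the segment's cursor; returns (segment_index, offset)."""
        kind, i, store = self._segment(compartment)
        cur = self.cursors.get((kind, i), 5)
        seq = store[i]
        if cur + len(payload) + 5 > len(seq):
            raise PlantError(
                f"{self.gene_id}: plant of length {len(payload)} does not fit in "
                f"{kind} {i} (length {len(seq)}, cursor {cur})"
            )
        store[i] = seq[:cur] + payload + seq[cur + len(payload):]
        self.cursors[(kind, i)] = cur + len(payload) + 7
        record.update(
            {"compartment": kind, "segment_index": i, "offset": cur, "length": len(payload)}
        )
        self.plant_records.append(record)
        return i, cur

    def set_base(self, compartment_kind: str, seg: int, pos: int, base: str) -> None:
        store = self.exons if compartment_kind == "exon" else self.introns
        s = store[seg]
        if 0 <= pos < len(s):
            store[seg] = s[:pos] + base + s[pos + 1:]

    def get_base(self, compartment_kind: str, seg: int, pos: int) -> str | None:
        store = self.exons if compartment_kind == "exon" else self.introns
        s = store[seg]
        return s[pos] if 0 <= pos < len(s) else None


def _different_base(*avoid: str | None) -> str:
    av = {a.upper() for a in avoid if a}
    return next(b for b in DNA_BASES if b not in av)


def _apply_plants(spec: SyntheticSpec, drafts: dict[str, _GeneDraft]) -> None:
    # GC-extreme first: it replaces a whole exon, other plants then paste into it
    for plant in spec.plants:
        if isinstance(plant, GCExtremePlant):
            d = drafts[plant.gene]
            if not d.consensus_idx:
                raise PlantError(f"{plant.gene}: no consensus exon for gc_extreme")
            i = d.consensus_idx[0]
            motif = gc_motif(plant.region_gc)
            tiled = (motif * (len(d.exons[i]) // len(motif) + 1))[: len(d.exons[i])]
            d.exons[i] = tiled
            d.plant_records.append(
                {
                    "kind": "gc_extreme",
                    "compartment": "exon",
                    "segment_index": i,
                    "region_gc": plant.region_gc,
                    "motif": motif,
                }
            )
    for plant in spec.plants:
        if isinstance(plant, SharedSubstring):
            _plant_shared(spec, drafts, plant)
        elif isinstance(plant, HomopolymerPlant):
            d = drafts[plant.gene]
            base = plant.base.upper()
            if base not in DNA_BASES:
                raise PlantError(f"homopolymer base {plant.base!r} not A/C/G/T")
            i, off = d.paste(
                "exon",
                base * plant.run_length,
                {"kind": "homopolymer", "base": base, "run_length": plant.run_length},
            )
            # flanks must not extend the run
            d.set_base("exon", i, off - 1, _different_base(base))
            d.set_base("exon", i, off + plant.run_length, _different_base(base))
        elif isinstance(plant, SoftMaskPlant):
            d = drafts[plant.gene]
            kind, seg, store = d._segment("exon")
            cur = d.cursors.get((kind, seg), 5)
            seq = store[seg]
            if cur + plant.length + 5 > len(seq):
                raise PlantError(
                    f"{plant.gene}: softmask of length {plant.length} does not fit"
                )
            store[seg] = (
                seq[:cur] + seq[cur : cur + plant.length].lower() + seq[cur + plant.length:]
            )
            d.cursors[(kind, seg)] = cur + plant.length + 7
            d.plant_records.append(
                {
                    "kind": "softmask",
                    "compartment": kind,
                    "segment_index": seg,
                    "offset": cur,
                    "length": plant.length,
                }
            )
        elif isinstance(plant, GCExtremePlant):
            pass
        else:
            raise PlantError(f"unknown plant {plant!r}")


def _plant_shared(spec, drafts, plant: SharedSubstring) -> None:
    tag = sum(plant.gene_a.encode()) * 31 + sum(plant.gene_b.encode())
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 7919, plant.length, tag % (2**31)])
    )
    payload = "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=plant.length))
    da, db = drafts[plant.gene_a], drafts[plant.gene_b]
    rec_a = {"kind": "shared_substring", "partner": plant.gene_b, "sequence": payload}
    rec_b = {"kind": "shared_substring", "partner": plant.gene_a, "sequence": payload}
    ia, offa = da.paste(plant.compartment, payload, rec_a)
    ib, offb = db.paste(plant.compartment, payload, rec_b)
    kind = plant.compartment
    # decorrelate flanks so the exact shared match is exactly `length` long
    la, lb = da.get_base(kind, ia, offa - 1), db.get_base(kind, ib, offb - 1)
    if la is not None and lb is not None and la.upper() == lb.upper():
        db.set_base(kind, ib, offb - 1, _different_base(lb))
    ra = da.get_base(kind, ia, offa + plant.length)
    rb = db.get_base(kind, ib, offb + plant.length)
    if ra is not None and rb is not None and ra.upper() == rb.upper():
        db.set_base(kind, ib, offb + plant.length, _different_base(rb))


# ---------------------------------------------------------------------------


def _make_drafts(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, _GeneDraft]:
    drafts: dict[str, _GeneDraft] = {}
    for gi, gene_id in enumerate(spec.gene_ids()):
        strand = "+" if gi % 2 == 0 else "-"
        n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, size=n_ex)
        intron_lens = rng.integers(
            spec.intron_length[0], spec.intron_length[1] + 1, size=max(0, n_ex - 1)
        )
        exon_seqs = [_random_seq(rng, int(L), spec.base_gc) for L in exon_lens]
        intron_seqs = [_random_seq(rng, int(L), spec.base_gc) for L in intron_lens]

        n_iso = int(rng.integers(spec.isoforms_per_gene[0], spec.isoforms_per_gene[1] + 1))
        isoform_exons: dict[str, list[int]] = {f"{gene_id}.T1": list(range(n_ex))}
        for j in range(2, n_iso + 1):
            internal = list(range(1, n_ex - 1))
            if internal:
                n_skip = int(rng.integers(1, len(internal) + 1))
                skipped = set(rng.choice(internal, size=n_skip, replace=False).tolist())
            else:
                skipped = set()
            isoform_exons[f"{gene_id}.T{j}"] = [e for e in range(n_ex) if e not in skipped]
        consensus = sorted(set.intersection(*(set(v) for v in isoform_exons.values())))
        drafts[gene_id] = _GeneDraft(
            gene_id, strand, exon_seqs, intron_seqs, isoform_exons, consensus
        )
    return drafts


def _sense_layout(d: _GeneDraft) -> tuple[list[tuple[int, int]], list[tuple[int, int]], int]:
    """Target-sense offsets of exons and introns within the gene region."""
    exon_iv, intron_iv = [], []
    pos = 0
    for i, ex in enumerate(d.exons):
        exon_iv.append((pos, pos + len(ex)))
        pos += len(ex)
        if i < len(d.introns):
            intron_iv.append((pos, pos + len(d.introns[i])))
            pos += len(d.introns[i])
    return exon_iv, intron_iv, pos


def _sense_to_genomic(iv: tuple[int, int], g0: int, L: int, strand: str) -> tuple[int, int]:
    a, b = iv
    if strand == "+":
        return g0 + a, g0 + b
    return g0 + L - b, g0 + L - a


def generate_transcriptome(spec: SyntheticSpec, out_dir) -> dict[str, Path]:
    """Write genome.fa, annotation.gtf and manifest.json; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    drafts = _make_drafts(spec, rng)
    _apply_plants(spec, drafts)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    chrom_parts: list[str] = []
    gtf_lines: list[str] = []
    manifest: dict = {"seed": spec.seed, "chrom": spec.chrom, "genes": {}}
    pos = 0
    for gene_id in spec.gene_ids():
        d = drafts[gene_id]
        spacer = _random_seq(rng, spec.spacer, spec.base_gc)
        chrom_parts.append(spacer)
        pos += spec.spacer
        g0 = pos
        exon_iv, intron_iv, L = _sense_layout(d)
        sense_seq = "".join(
            seg
            for pair in zip(d.exons, d.introns + [""])
            for seg in pair
        )
        genomic_seq = sense_seq if d.strand == "+" else reverse_complement(sense_seq)
        chrom_parts.append(genomic_seq)
        pos += L

        gene_manifest = {
            "strand": d.strand,
            "start": g0,
            "length": L,
            "exon_sense_intervals": [list(iv) for iv in exon_iv],
            "intron_sense_intervals": [list(iv) for iv in intron_iv],
            "exon_genomic_intervals": [
                list(_sense_to_genomic(iv, g0, L, d.strand)) for iv in exon_iv
            ],
            "isoforms": d.isoform_exons,
            "consensus_exon_indices": d.consensus_idx,
            "plants": [],
        }
        for rec in d.plant_records:
            rec = dict(rec)
            if "offset" in rec:
                seg_iv = (exon_iv if rec["compartment"] == "exon" else intron_iv)[
                    rec["segment_index"]
                ]
                sense = (seg_iv[0] + rec["offset"], seg_iv[0] + rec["offset"] + rec["length"])
                rec["sense_interval"] = list(sense)
                rec["genomic_interval"] = list(_sense_to_genomic(sense, g0, L, d.strand))
            gene_manifest["plants"].append(rec)
        manifest["genes"][gene_id] = gene_manifest

        for tid in sorted(d.isoform_exons):
            for ei in d.isoform_exons[tid]:
                gs, ge = _sense_to_genomic(exon_iv[ei], g0, L, d.strand)
                gtf_lines.append(
                    f"{spec.chrom}\tsynth\texon\t{gs + 1}\t{ge}\t.\t{d.strand}\t.\t"
                    f'gene_id "{gene_id}"; transcript_id "{tid}";'
                )
    chrom_parts.append(_random_seq(rng, spec.spacer, spec.base_gc))
    chrom_seq = "".join(chrom_parts)

    genome_path = out / "genome.fa"
    with genome_path.open("w") as fh:
        fh.write(f">{spec.chrom}\n")
        for i in range(0, len(chrom_seq), 60):
            fh.write(chrom_seq[i : i + 60] + "\n")
    gtf_path = out / "annotation.gtf"
    gtf_path.write_text("".join(line + "\n" for line in sorted(gtf_lines)))
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"genome": genome_path, "annotation": gtf_path, "manifest": manifest_path}
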