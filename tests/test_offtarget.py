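"""Off-target index construction and k-mer screening."""

import numpy as np
import pytest

from fishprobes._seq import reverse_complement
from fishprobes.config import ConfigError
from fishprobes.offtarget import (
    OffTargetIndex,
    build_offtarget_index,
    screen_candidate,
    screen_readout,
)

from conftest import make_gene
from test_candidates import candidate_of


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def longest_shared(a: str, b: str) -> int:
    """Brute-force longest common substring length (one orientation)."""
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best


class TestIndexConstruction:
    def test_single_50nt_transcript_indexes_36_kmers(self):
        seq = random_dna(50, seed=3)  # distinct 15-mers w.h.p. at this seed
        genome = {"chr1": seq}
        gene = make_gene(isoforms={"t1": [(0, 50)]})
        idx = build_offtarget_index([gene], genome, k=15)
        assert len(idx.kmer_map) == 50 - 15 + 1

    def test_intron_indexed_as_literal_reversal(self):
        genome = {"chr1": "AAAAA" + "ACGTT" + "CCCCC"}
        gene = make_gene(isoforms={"t1": [(0, 5), (10, 15)]})
        idx = build_offtarget_index([gene], genome, k=3)
        reversed_intron = "ACGTT"[::-1]
        for i in range(3):
            assert any(
                "reversed_intron" in kind
                for sid in idx.lookup(reversed_intron[i : i + 3])
                for s, kind, _ in idx.db_composition
                if s == sid
            )

    def test_revcomp_intron_mode(self):
        genome = {"chr1": "AAAAA" + "ACGTT" + "CCCCC"}
        gene = make_gene(isoforms={"t1": [(0, 5), (10, 15)]})
        idx = build_offtarget_index([gene], genome, k=5, intron_mode="revcomp")
        assert idx.lookup(reverse_complement("ACGTT"))

    def test_planted_20mer_shared_between_genes_maps_to_both(self):
        shared = random_dna(20, seed=5)
        a = random_dna(40, seed=6) + shared + random_dna(40, seed=7)
        b = random_dna(40, seed=8) + shared + random_dna(40, seed=9)
        genome = {"chr1": a + b}
        genes = [
            make_gene("geneA", isoforms={"t1": [(0, 100)]}),
            make_gene("geneB", isoforms={"t1": [(100, 200)]}),
        ]
        idx = build_offtarget_index(genes, genome, k=15)
        kmers = {shared[i : i + 15] for i in range(6)}
        assert len(kmers) == 6
        for kmer in kmers:
            owners = {idx.owner[sid] for sid in idx.lookup(kmer)}
            assert owners == {"geneA", "geneB"}

    def test_n_containing_kmers_never_indexed(self):
        genome = {"chr1": "ACGTN" * 10}
        gene = make_gene(isoforms={"t1": [(0, 50)]})
        idx = build_offtarget_index([gene], genome, k=4)
        assert all("N" not in k for k in idx.kmer_map)


def two_gene_setup(plant_len, seed=11):
    """Two single-exon genes sharing a planted substring of plant_len.

    Flank bases are forced to differ between the genes so the exact shared
    match has exactly plant_len nucleotides.
    """
    shared = random_dna(plant_len, seed=seed + 90)
    a_left, a_right = random_dna(60, seed=seed), random_dna(60, seed=seed + 1)
    b_left, b_right = random_dna(60, seed=seed + 2), random_dna(60, seed=seed + 3)
    if b_left[-1] == a_left[-1]:
        b_left = b_left[:-1] + ("A" if a_left[-1] != "A" else "C")
    if b_right[0] == a_right[0]:
        b_right = ("A" if a_right[0] != "A" else "C") + b_right[1:]
    a = a_left + shared + a_right
    b = b_left + shared + b_right
    la, lb = len(a), len(b)
    genome = {"chr1": a + b}
    genes = [
        make_gene("geneA", isoforms={"t1": [(0, la)]}),
        make_gene("geneB", isoforms={"t1": [(la, la + lb)]}),
    ]
    return genome, genes, a, b


def cand_a(window):
    c = candidate_of(window)
    c.gene_id = "geneA"
    return c


class TestScreenCandidate:
    def test_planted_15mer_is_rejected(self):
        genome, genes, a, b = two_gene_setup(15)
        idx = build_offtarget_index(genes, genome, k=15)
        window = a[55:90]  # covers the plant at 60..75
        ok, hits = screen_candidate(cand_a(window), idx)
        assert not ok
        assert all(h.hit_gene_id == "geneB" for h in hits)

    def test_14nt_shared_substring_passes(self):
        genome, genes, a, b = two_gene_setup(14)
        idx = build_offtarget_index(genes, genome, k=15)
        window = a[55:90]
        # brute-force longest-common-substring oracle, both orientations
        lcs = max(longest_shared(window, b), longest_shared(reverse_complement(window), b))
        assert lcs == 14
        ok, hits = screen_candidate(cand_a(window), idx)
        assert ok and hits == []

    def test_own_gene_matches_are_exempt(self):
        genome, genes, a, b = two_gene_setup(14)
        idx = build_offtarget_index(genes, genome, k=15)
        ok, _ = screen_candidate(cand_a(a[10:45]), idx)
        assert ok

    def test_revcomp_orientation_is_screened(self):
        genome, genes, a, b = two_gene_setup(20)
        idx = build_offtarget_index(genes, genome, k=15)
        window = reverse_complement(a[55:90])
        ok, hits = screen_candidate(cand_a(window), idx)
        assert not ok
        assert {h.orientation for h in hits} == {"revcomp"}

    def test_k_mismatch_is_a_configuration_error(self):
        idx = OffTargetIndex(k=13)
        with pytest.raises(ConfigError, match="13"):
            screen_candidate(candidate_of("ACGT" * 9), idx, match_length=15)

    def test_fail_matches_brute_force_over_small_transcriptome(self):
        genome, genes, a, b = two_gene_setup(15, seed=21)
        idx = build_offtarget_index(genes, genome, k=15)
        for start in range(0, len(a) - 35 + 1, 7):
            window = a[start : start + 35]
            expected_fail = (
                max(longest_shared(window, b), longest_shared(reverse_complement(window), b))
                >= 15
            )
            ok, _ = screen_candidate(cand_a(window), idx)
            assert ok is (not expected_fail)

    def test_adding_sequences_is_monotone(self):
        genome, genes, a, b = two_gene_setup(15)
        idx = build_offtarget_index(genes[:1], genome, k=15)  # geneA only
        window = a[55:90]
        ok_before, _ = screen_candidate(cand_a(window), idx)
        assert ok_before  # no other gene indexed yet
        idx.add_sequence("geneB|t1|mrna", "geneB", "mrna", b)
        ok_after, _ = screen_candidate(cand_a(window), idx)
        assert not ok_after


class TestScreenReadout:
    def test_empty_index_accepts_everything(self):
        idx = OffTargetIndex(k=15)
        assert screen_readout(random_dna(20, seed=1), idx)

    def test_planted_15mer_homology_rejected_no_own_gene_exemption(self):
        readout = random_dna(20, seed=33)
        idx = OffTargetIndex(k=15)
        idx.add_sequence("x|t|mrna", "anyGene", "mrna", random_dna(30, 34) + readout[:15])
        assert not screen_readout(readout, idx)

    def test_14nt_homology_accepted(self):
        readout = random_dna(20, seed=33)
        flank = random_dna(30, 34)
        host = flank + readout[:14] + ("A" if readout[14] != "A" else "C")
        idx = OffTargetIndex(k=15)
        idx.add_sequence("x|t|mrna", "anyGene", "mrna", host)
        lcs = max(
            longest_shared(readout, host),
            longest_shared(reverse_complement(readout), host),
        )
        assert lcs <= 14
        assert screen_readout(readout, idx)
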