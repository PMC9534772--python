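"""Synthetic transcriptome generator: determinism, plants, oracle agreement."""

import json

import pytest

from fishprobes.candidates import extract_candidates, homopolymer_filter, mask_filter
from fishprobes.config import DesignConfig
from fishprobes.gene_models import consensus_exonic_regions, open_genome, read_gene_models
from fishprobes.offtarget import build_offtarget_index, screen_candidate
from fishprobes.oracle import expected_survivors
from fishprobes.pipeline import run_pipeline
from fishprobes.simulate import (
    GCExtremePlant,
    HomopolymerPlant,
    PlantError,
    SharedSubstring,
    SoftMaskPlant,
    SyntheticSpec,
    generate_transcriptome,
)
from fishprobes._seq import gc_percent


def gen(tmp_path, spec, name="tx"):
    return generate_transcriptome(spec, tmp_path / name)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        spec = SyntheticSpec(seed=11, n_genes=3, plants=[HomopolymerPlant("G01", "A", 5)])
        a = gen(tmp_path, spec, "a")
        b = gen(tmp_path, spec, "b")
        for key in ("genome", "annotation", "manifest"):
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = gen(tmp_path, SyntheticSpec(seed=1, n_genes=2), "a")
        b = gen(tmp_path, SyntheticSpec(seed=2, n_genes=2), "b")
        assert a["genome"].read_bytes() != b["genome"].read_bytes()


class TestStatisticalSanity:
    def test_mean_gc_within_3_points_of_base_gc(self, tmp_path):
        for base_gc in (40.0, 50.0, 60.0):
            spec = SyntheticSpec(
                seed=4, n_genes=8, exon_length=(400, 600), base_gc=base_gc
            )
            paths = gen(tmp_path, spec, f"gc{int(base_gc)}")
            seq = "".join(
                line.strip()
                for line in paths["genome"].read_text().splitlines()
                if not line.startswith(">")
            )
            assert len(seq) >= 10_000
            assert abs(gc_percent(seq) - base_gc) <= 3.0


class TestPlants:
    def test_planted_homopolymer_fails_every_covering_window(self, tmp_path):
        spec = SyntheticSpec(seed=7, n_genes=1, plants=[HomopolymerPlant("G01", "A", 5)])
        paths = gen(tmp_path, spec)
        manifest = json.loads(paths["manifest"].read_text())
        (plant,) = manifest["genes"]["G01"]["plants"]
        genes = read_gene_models(paths["annotation"], paths["genome"])
        genome = open_genome(paths["genome"])
        region = next(
            r
            for r in consensus_exonic_regions(genes[0], genome)
            if r.sequence.upper().count("A" * 5)
        )
        # sense offset of the plant within this region
        covered = [
            c
            for c in extract_candidates(region)
            if "A" * 5 in c.target_window.upper()
        ]
        assert covered
        assert all(not homopolymer_filter(c) for c in covered)

    def test_planted_softmask_fails_mask_filter(self, tmp_path):
        spec = SyntheticSpec(seed=8, n_genes=1, plants=[SoftMaskPlant("G01", 40)])
        paths = gen(tmp_path, spec)
        genes = read_gene_models(paths["annotation"], paths["genome"])
        genome = open_genome(paths["genome"])
        regions = consensus_exonic_regions(genes[0], genome)
        masked = [
            c
            for r in regions
            for c in extract_candidates(r)
            if any(b.islower() for b in c.target_window)
        ]
        assert masked
        assert all(not mask_filter(c) for c in masked)

    def test_planted_shared_substring_triggers_offtarget_hit(self, tmp_path):
        spec = SyntheticSpec(
            seed=9, n_genes=2, plants=[SharedSubstring("G01", "G02", 18)]
        )
        paths = gen(tmp_path, spec)
        manifest = json.loads(paths["manifest"].read_text())
        payload = manifest["genes"]["G01"]["plants"][0]["sequence"]
        genes = read_gene_models(paths["annotation"], paths["genome"])
        genome = open_genome(paths["genome"])
        idx = build_offtarget_index(genes, genome, k=15)
        g1 = next(g for g in genes if g.gene_id == "G01")
        covering = [
            c
            for r in consensus_exonic_regions(g1, genome)
            for c in extract_candidates(r)
            if payload in c.target_window or payload in c.target_window
        ]
        hits = []
        rejected = 0
        for c in covering:
            ok, h = screen_candidate(c, idx)
            if not ok:
                rejected += 1
                hits.extend(h)
        assert covering and rejected == len(covering)
        assert {h.hit_gene_id for h in hits} == {"G02"}

    def test_manifest_genomic_interval_matches_genome_sequence(self, tmp_path):
        spec = SyntheticSpec(
            seed=10, n_genes=2, plants=[SharedSubstring("G01", "G02", 16)]
        )
        paths = gen(tmp_path, spec)
        manifest = json.loads(paths["manifest"].read_text())
        genome = open_genome(paths["genome"])
        from fishprobes._seq import reverse_complement

        for gid in ("G01", "G02"):
            info = manifest["genes"][gid]
            (plant,) = info["plants"]
            s, e = plant["genomic_interval"]
            raw = str(genome[manifest["chrom"]][s:e])
            if info["strand"] == "-":
                raw = reverse_complement(raw)
            assert raw.upper() == plant["sequence"]

    def test_gc_extreme_exon_has_uniform_window_composition(self, tmp_path):
        spec = SyntheticSpec(
            seed=12,
            n_genes=1,
            exons_per_gene=(1, 1),
            isoforms_per_gene=(1, 1),
            plants=[GCExtremePlant("G01", 20.0)],
        )
        paths = gen(tmp_path, spec)
        genes = read_gene_models(paths["annotation"], paths["genome"])
        genome = open_genome(paths["genome"])
        (region,) = consensus_exonic_regions(genes[0], genome)
        gcs = {round(c.gc_percent, 6) for c in extract_candidates(region)}
        assert len(gcs) == 1
        assert abs(gcs.pop() - 20.0) < 3.0  # nearest achievable count out of 35

    def test_infeasible_plant_raises(self, tmp_path):
        spec = SyntheticSpec(
            seed=13, n_genes=1, exon_length=(40, 40),
            plants=[HomopolymerPlant("G01", "A", 200)],
        )
        with pytest.raises(PlantError, match="does not fit"):
            gen(tmp_path, spec)


class TestOracleAgreement:
    def test_pipeline_counts_match_brute_force_on_plant_rich_spec(self, tmp_path):
        spec = SyntheticSpec(
            seed=20,
            n_genes=3,
            plants=[
                SharedSubstring("G01", "G02", 17),
                HomopolymerPlant("G03", "T", 6),
                SoftMaskPlant("G02", 50),
            ],
        )
        paths = gen(tmp_path, spec)
        cfg = DesignConfig(seed=20)
        summary = run_pipeline(cfg, paths["genome"], paths["annotation"], tmp_path / "run")
        assert summary["final_counts"] == expected_survivors(
            paths["genome"], paths["annotation"], cfg
        )
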