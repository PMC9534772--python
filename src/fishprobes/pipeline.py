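"""End-to-end design pipeline.

gene models -> candidate windows -> composition filters -> off-target
screen -> overlap resolution / expansion / trimming -> readout generation
-> codebook + hybridization schedule -> assembled primary probes -> files.
"""

from __future__ import annotations

from pathlib import Path

from fishprobes.assembly import (
    assemble_primary_probe,
    build_codebook,
    schedule_hybridizations,
    write_outputs,
)
from fishprobes.config import DesignConfig
from fishprobes.gene_models import open_genome, read_gene_models
from fishprobes.offtarget import build_offtarget_index
from fishprobes.readouts import assign_fluorophores, generate_readouts
from fishprobes.selection import design_probe_set


def run_pipeline(
    config: DesignConfig,
    genome_path,
    annotation_path,
    out_dir,
    n_readouts: int | None = None,
) -> dict:
    """Run the full design and write outputs; returns a summary dict.

    Deterministic: identical (config, inputs) give byte-identical outputs.
    """
    config.validate()
    genes = read_gene_models(annotation_path, genome_path)
    genome = open_genome(genome_path)
    idx = build_offtarget_index(
        genes, genome, k=config.offtarget_k, intron_mode=config.intron_reversal_mode
    )
    log: list[str] = [
        f"genes: {len(genes)}",
        f"offtarget index: {len(idx.db_composition)} sequences, "
        f"{len(idx.kmer_map)} distinct {idx.k}-mers",
    ]

    probe_sets = {}
    stage_counts = {}
    for gene in genes:
        ps, counts = design_probe_set(gene, genome, idx, config)
        probe_sets[gene.gene_id] = ps
        stage_counts[gene.gene_id] = counts
        log.append(
            f"{gene.gene_id}: extracted={counts.get('extracted', 0)} "
            f"composition={counts.get('composition_passed', 0)} "
            f"offtarget={counts.get('offtarget_passed', 0)} "
            f"resolved={counts.get('overlap_resolved', 0)} "
            f"expanded={bool(counts.get('expanded'))} final={counts['final']}"
        )

    # readout screening needs word length max_homology+1; reuse the index when equal
    ro_idx = idx
    if config.readout_max_homology + 1 != config.offtarget_k:
        ro_idx = build_offtarget_index(
            genes,
            genome,
            k=config.readout_max_homology + 1,
            intron_mode=config.intron_reversal_mode,
        )
    readouts = generate_readouts(
        n=n_readouts or max(1, len(genes)),
        idx=ro_idx,
        seed=config.seed,
        length=config.readout_length,
        gc_min=config.readout_gc_min,
        gc_max=config.readout_gc_max,
        max_homology=config.readout_max_homology,
        site_len=config.readout_site_len,
        cross_check=config.cross_check,
        ortho_k=config.ortho_k,
    )
    assign_fluorophores(readouts, config.channels)
    codebook = build_codebook([g.gene_id for g in genes], readouts)
    schedule = schedule_hybridizations(codebook, readouts, config.channels)
    log.append(f"readouts: {len(readouts)}; rounds: {schedule.n_rounds}")

    by_id = {r.readout_id: r for r in readouts}
    primaries = []
    for gene in genes:
        ro = by_id[codebook[gene.gene_id]]
        for i, cand in enumerate(probe_sets[gene.gene_id].probes, start=1):
            p = assemble_primary_probe(
                cand.binding_site,
                [ro.site_sequence] * 6,
                site_len=config.readout_site_len,
                gene_id=gene.gene_id,
                probe_index=i,
                readout_ids=[ro.readout_id] * 6,
            )
            p.region_source = cand.region_source
            p.region_start = cand.region_start
            p.start = cand.start
            primaries.append(p)
    log.append(f"primary probes assembled: {len(primaries)}")

    files = write_outputs(
        primaries, readouts, schedule, codebook, config.to_dict(), out_dir, log
    )
    table = Path(out_dir) / "probe_sets.tsv"
    with table.open("w") as fh:
        fh.write("gene_id\trank\tregion_start\tstart\tsource\tbinding_site\tgc_percent\n")
        for gene in genes:
            for rank, c in enumerate(probe_sets[gene.gene_id].probes, start=1):
                fh.write(
                    f"{gene.gene_id}\t{rank}\t{c.region_start}\t{c.start}\t"
                    f"{c.region_source}\t{c.binding_site}\t{c.gc_percent:.4f}\n"
                )
    files["probe_sets"] = table
    return {
        "genes": [g.gene_id for g in genes],
        "stage_counts": stage_counts,
        "final_counts": {g: len(ps.probes) for g, ps in probe_sets.items()},
        "n_primary_probes": len(primaries),
        "n_rounds": schedule.n_rounds,
        "files": {k: str(v) for k, v in files.items()},
        "probe_sets": probe_sets,
        "readouts": readouts,
        "codebook": codebook,
        "schedule": schedule,
        "primaries": primaries,
    }
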