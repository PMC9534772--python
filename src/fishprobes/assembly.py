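"""Primary-probe assembly, codebook, hybridization schedule, and outputs.

An assembled primary probe follows the grammar

    R1'-AA-R2'-AA-R3'-TAAT-B-TAAT-R4'-AA-R5'-AA-R6'

where B is the 35-nt binding site and each Ri' is the reverse complement of
a readout *site* (the 5' prefix of a readout sequence, default 15 nt).
Total length is therefore 6*site_len + 16 + len(B); with the defaults that
is 6*15 + 16 + 35 = 141 nt.  In sequential mode (the default) all six
slots carry the same readout, so each gene lights up in exactly one
(round, channel) cell and every bound readout amplifies the same signal.

The codebook assigns one readout identity per gene; the schedule packs
genes round-major into (round, channel) cells, honouring each readout's
fluorophore, with n_rounds = ceil(#genes / #channels).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from fishprobes._seq import is_unmasked_dna, reverse_complement
from fishprobes.readouts import ReadoutProbe

LINKER_AA = "AA"
LINKER_TAAT = "TAAT"


class AssemblyError(ValueError):
    pass


class ScheduleError(ValueError):
    pass


@dataclass
class PrimaryProbe:
    gene_id: str
    probe_index: int
    binding_site: str
    readout_slots: list[str]  # six readout site identifiers
    full_sequence: str
    length: int
    synthesis_notes: str = "5'-phosphate"
    region_source: str = ""
    region_start: int = 0
    start: int = 0


@dataclass
class HybSchedule:
    entries: list[tuple[str, str, int, str]]  # (gene_id, readout_id, round, channel)
    n_rounds: int
    channels: list[str]


def assemble_primary_probe(
    binding_site: str,
    readout_sites: list[str],
    site_len: int = 15,
    gene_id: str = "",
    probe_index: int = 0,
    readout_ids: list[str] | None = None,
) -> PrimaryProbe:
    """Assemble one primary probe from a binding site and six readout sites.

    Each slot carries the reverse complement of its readout site so the
    fluorophore-bearing readout oligo hybridizes to the assembled probe.
    """
    if len(readout_sites) != 6:
        raise AssemblyError(f"expected 6 readout sites, got {len(readout_sites)}")
    for s in readout_sites:
        if len(s) != site_len:
            raise AssemblyError(
                f"readout site length {len(s)} != configured site_len {site_len}"
            )
        if not is_unmasked_dna(s):
            raise AssemblyError(f"readout site {s!r} contains non-ACGT bases")
    if not is_unmasked_dna(binding_site):
        raise AssemblyError("binding site contains non-ACGT bases")

    slots = [reverse_complement(s) for s in readout_sites]
    full = (
        slots[0] + LINKER_AA + slots[1] + LINKER_AA + slots[2]
        + LINKER_TAAT + binding_site + LINKER_TAAT
        + slots[3] + LINKER_AA + slots[4] + LINKER_AA + slots[5]
    )
    assert len(full) == 6 * site_len + 16 + len(binding_site)
    return PrimaryProbe(
        gene_id=gene_id,
        probe_index=probe_index,
        binding_site=binding_site,
        readout_slots=list(readout_ids) if readout_ids is not None else list(readout_sites),
        full_sequence=full,
        length=len(full),
    )


def parse_primary_probe(full_sequence: str, site_len: int = 15) -> tuple[str, list[str]]:
    """Invert the assembly grammar: recover (binding_site, readout_sites).

    Raises AssemblyError if the linkers are not where the grammar puts them.
    """
    n = len(full_sequence)
    binding_len = n - 6 * site_len - 16
    if binding_len < 1:
        raise AssemblyError(f"sequence of length {n} too short for site_len {site_len}")
    pos = 0
    slots = []
    expected_linkers = []

    def take(ln):
        nonlocal pos
        piece = full_sequence[pos : pos + ln]
        pos += ln
        return piece

    slots.append(take(site_len))
    expected_linkers.append(take(2))
    slots.append(take(site_len))
    expected_linkers.append(take(2))
    slots.append(take(site_len))
    expected_linkers.append(take(4))
    binding = take(binding_len)
    expected_linkers.append(take(4))
    slots.append(take(site_len))
    expected_linkers.append(take(2))
    slots.append(take(site_len))
    expected_linkers.append(take(2))
    slots.append(take(site_len))
    if expected_linkers != [LINKER_AA, LINKER_AA, LINKER_TAAT, LINKER_TAAT, LINKER_AA, LINKER_AA]:
        raise AssemblyError("linker bases do not match the assembly grammar")
    return binding, [reverse_complement(s) for s in slots]


def build_codebook(
    genes: list[str],
    readouts: list[ReadoutProbe],
    allow_reuse: bool = False,
) -> dict[str, str]:
    """Injective gene -> readout_id assignment in input order.

    With ``allow_reuse`` readouts are cycled (valid when reused readouts
    land in different hybridization rounds)."""
    if not allow_reuse and len(readouts) < len(genes):
        raise ScheduleError(
            f"{len(genes)} genes but only {len(readouts)} readouts "
            "(readout reuse disabled)"
        )
    return {g: readouts[i % len(readouts)].readout_id for i, g in enumerate(genes)}


def schedule_hybridizations(
    codebook: dict[str, str],
    readouts: list[ReadoutProbe],
    channels: list[str] = ("AF647", "AF488", "AF546"),
) -> HybSchedule:
    """Pack genes round-major into (round, channel) cells.

    Each gene goes to the earliest round where its readout's fluorophore
    channel is free (readouts without an assigned fluorophore take any free
    channel).  n_rounds = ceil(#genes / #channels); a gene that cannot be
    placed within that many rounds is a hard error.
    """
    if not codebook:
        raise ScheduleError("empty codebook")
    channels = list(channels)
    if not channels:
        raise ScheduleError("empty channel list")
    by_id = {r.readout_id: r for r in readouts}
    n_rounds = math.ceil(len(codebook) / len(channels))
    grid: dict[tuple[int, str], str] = {}
    entries = []
    for gene_id, readout_id in codebook.items():
        ro = by_id.get(readout_id)
        if ro is None:
            raise ScheduleError(f"codebook references unknown readout {readout_id}")
        wanted = [ro.fluorophore] if ro.fluorophore else channels
        placed = False
        for rnd in range(1, n_rounds + 1):
            for ch in wanted:
                if ch not in channels:
                    raise ScheduleError(
                        f"readout {readout_id} fluorophore {ch!r} not in channel list"
                    )
                if (rnd, ch) not in grid:
                    grid[(rnd, ch)] = gene_id
                    entries.append((gene_id, readout_id, rnd, ch))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise ScheduleError(
                f"cannot place gene {gene_id} (readout {readout_id}, "
                f"fluorophore {ro.fluorophore}) within {n_rounds} rounds"
            )
    return HybSchedule(entries=entries, n_rounds=n_rounds, channels=channels)


# ---------------------------------------------------------------------------
# outputs


def write_outputs(
    probes: list[PrimaryProbe],
    readouts: list[ReadoutProbe],
    schedule: HybSchedule | None,
    codebook: dict[str, str],
    config_snapshot: dict,
    out_dir,
    log_lines: list[str] | None = None,
) -> dict[str, Path]:
    """Write order-ready outputs; byte-stable for identical inputs.

    Files: primary_probes.fasta, order_sheet.tsv, readout_probes.tsv,
    readouts.fasta, codebook.json, schedule.json, config.json, run_log.txt.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / "primary_probes.fasta"
        with probe.open("w") as fh:
            for p in probes:
                fh.write(
                    f">{p.gene_id}|{p.probe_index}|{p.start}|{p.region_source}\n"
                    f"{p.full_sequence}\n"
                )
        order = out / "order_sheet.tsv"
        with order.open("w") as fh:
            fh.write("name\tsequence\tmodification\n")
            for p in probes:
                fh.write(
                    f"{p.gene_id}_p{p.probe_index}\t{p.full_sequence}\t{p.synthesis_notes}\n"
                )
        ro_tsv = out / "readout_probes.tsv"
        with ro_tsv.open("w") as fh:
            fh.write("readout_id\tsequence\tfluorophore\tmodification\n")
            for r in readouts:
                fluor = r.fluorophore or ""
                fh.write(
                    f"{r.readout_id}\t{r.sequence}\t{fluor}\t5'-{fluor or 'none'}\n"
                )
        ro_fa = out / "readouts.fasta"
        with ro_fa.open("w") as fh:
            for r in readouts:
                fh.write(f">{r.readout_id}\n{r.sequence}\n")
        cell = {}
        if schedule is not None:
            cell = {g: {"round": rnd, "channel": ch} for g, _, rnd, ch in schedule.entries}
        cb = {
            g: {"readout": rid, **cell.get(g, {})} for g, rid in codebook.items()
        }
        (out / "codebook.json").write_text(json.dumps(cb, indent=2, sort_keys=True) + "\n")
        sched = (
            {
                "n_rounds": schedule.n_rounds,
                "channels": schedule.channels,
                "entries": [
                    {"gene_id": g, "readout_id": rid, "round": rnd, "channel": ch}
                    for g, rid, rnd, ch in schedule.entries
                ],
            }
            if schedule is not None
            else {}
        )
        (out / "schedule.json").write_text(json.dumps(sched, indent=2, sort_keys=True) + "\n")
        (out / "config.json").write_text(
            json.dumps(config_snapshot, indent=2, sort_keys=True) + "\n"
        )
        lines = list(log_lines or [])
        if not probes:
            lines.append("WARNING: empty probe set")
        (out / "run_log.txt").write_text("".join(f"{ln}\n" for ln in lines))
    except OSError as exc:
        raise OSError(f"cannot write outputs under {out}: {exc}") from exc
    return {
        "primary_probes": probe,
        "order_sheet": order,
        "readout_probes": ro_tsv,
        "readouts_fasta": ro_fa,
        "codebook": out / "codebook.json",
        "schedule": out / "schedule.json",
        "config": out / "config.json",
        "run_log": out / "run_log.txt",
    }
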