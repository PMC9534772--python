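"""Probe-set selection: overlap resolution, target expansion, trimming.

Filter-passing candidates tile their regions densely, so overlapping
survivors are resolved greedily: repeatedly accept the candidate whose GC
is closest to the 55% target (ties: smaller region start, then smaller
offset, then lexicographic window) and discard everything overlapping it
within the same target region.

A gene whose consensus-exonic regions yield 40 or fewer resolved probes is
expanded: candidates are re-extracted over its introns and annotated 5′UTRs
and the survivors appended (exonic probes are never displaced).  Finally
the set is trimmed to at most 40 probes by repeatedly removing the probe
farthest from 55% GC (ties: the probe further 3′ — larger region start,
then larger offset — is removed first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from fishprobes.candidates import ProbeCandidate, apply_composition_filters, extract_candidates
from fishprobes.config import DesignConfig
from fishprobes.gene_models import GeneModel, consensus_exonic_regions, expansion_regions
from fishprobes.offtarget import OffTargetIndex, screen_candidate


@dataclass
class ProbeSet:
    gene_id: str
    probes: list[ProbeCandidate]
    provenance_counts: dict[str, int] = field(default_factory=dict)
    trimmed: bool = False

    def recount(self) -> None:
        counts: dict[str, int] = {}
        for p in self.probes:
            counts[p.region_source] = counts.get(p.region_source, 0) + 1
        self.provenance_counts = counts


def _position_key(c: ProbeCandidate) -> tuple:
    return (c.region_start, c.region_end, c.region_source, c.start)


def _greedy_key(c: ProbeCandidate, gc_target: float) -> tuple:
    return (abs(c.gc_percent - gc_target), c.region_start, c.start, c.target_window)


def resolve_overlaps(
    candidates: list[ProbeCandidate], gc_target: float = 55.0
) -> list[ProbeCandidate]:
    """Greedy non-overlapping selection preferring GC closest to the target.

    Overlap is assessed within a candidate's own target region (candidates
    from different regions never conflict).  Result is sorted by position.
    """
    accepted: list[ProbeCandidate] = []
    taken: dict[tuple, list[tuple[int, int]]] = {}
    for c in sorted(candidates, key=lambda c: _greedy_key(c, gc_target)):
        spans = taken.setdefault(c.region_key, [])
        if any(c.start < e and s < c.end for s, e in spans):
            continue
        spans.append((c.start, c.end))
        accepted.append(c)
    return sorted(accepted, key=_position_key)


def needs_expansion(candidate_count: int, threshold: int = 40) -> bool:
    """True iff the exonic probe count failed to exceed the threshold
    (a gene must yield strictly more than `threshold` probes to skip
    intron/5′UTR expansion)."""
    return candidate_count <= threshold


def trim_to_max(
    ps: ProbeSet, max_probes: int = 40, gc_target: float = 55.0
) -> ProbeSet:
    """Remove probes farthest from the GC target until at most max_probes
    remain.  Ties remove the 3′-most probe first, preserving 5′ probes.
    Idempotent; sets ``trimmed`` iff any probe was removed."""
    probes = list(ps.probes)
    trimmed = False
    while len(probes) > max_probes:
        victim = max(
            probes,
            key=lambda p: (abs(p.gc_percent - gc_target), p.region_start, p.start),
        )
        probes.remove(victim)
        trimmed = True
    out = ProbeSet(
        gene_id=ps.gene_id,
        probes=sorted(probes, key=_position_key),
        trimmed=ps.trimmed or trimmed,
    )
    out.recount()
    return out


def _design_candidates(regions, idx: OffTargetIndex, config: DesignConfig, counts: dict):
    extracted: list[ProbeCandidate] = []
    for region in regions:
        extracted.extend(extract_candidates(region, config.window, config.step))
    counts["extracted"] = counts.get("extracted", 0) + len(extracted)
    composed = apply_composition_filters(
        extracted, config.gc_min, config.gc_max, config.max_homopolymer_run
    )
    counts["composition_passed"] = counts.get("composition_passed", 0) + len(composed)
    survivors = [c for c in composed if screen_candidate(c, idx, config.offtarget_k)[0]]
    counts["offtarget_passed"] = counts.get("offtarget_passed", 0) + len(survivors)
    return survivors


def design_probe_set(
    gene: GeneModel,
    genome,
    idx: OffTargetIndex,
    config: DesignConfig,
) -> tuple[ProbeSet, dict[str, int]]:
    """Full per-gene selection: consensus-exonic candidates through all
    filters and overlap resolution; intron/5′UTR expansion when the exonic
    yield is insufficient; final trim to the probe cap.

    Returns the final ProbeSet and a dict of per-stage counts.
    """
    counts: dict[str, int] = {}
    exonic = _design_candidates(consensus_exonic_regions(gene, genome), idx, config, counts)
    resolved = resolve_overlaps(exonic, config.gc_target)
    counts["overlap_resolved"] = len(resolved)

    if needs_expansion(len(resolved), config.expansion_threshold):
        counts["expanded"] = 1
        extra = _design_candidates(expansion_regions(gene, genome), idx, config, counts)
        resolved = resolved + resolve_overlaps(extra, config.gc_target)
        resolved.sort(key=_position_key)
    else:
        counts["expanded"] = 0

    ps = ProbeSet(gene_id=gene.gene_id, probes=resolved)
    ps = trim_to_max(ps, config.max_probes, config.gc_target)
    counts["final"] = len(ps.probes)
    return ps, counts
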