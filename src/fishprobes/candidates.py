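"""Sliding-window probe candidates and composition filters.

A candidate is a fixed-length window (default 35 nt) of target-sense
sequence; its binding site is the exact reverse complement.  Composition
filters are independent predicates recorded per candidate:

* ``gc``          — GC content within [gc_min, gc_max] percent, inclusive;
* ``homopolymer`` — no run of more than ``max_run`` identical bases
                    (default: a run of 5 disqualifies, 4 is allowed);
* ``mask``        — no N, soft-masked (lowercase) or ambiguity bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from fishprobes._seq import (
    gc_percent,
    is_unmasked_dna,
    max_homopolymer_run,
    reverse_complement,
)
from fishprobes.gene_models import TargetRegion


@dataclass
class ProbeCandidate:
    gene_id: str
    region_source: str  # exon_consensus | intron | utr5
    region_start: int  # reference coords of the parent TargetRegion
    region_end: int
    start: int  # offset within the parent region's target-sense sequence
    target_window: str  # target (mRNA) sense
    binding_site: str  # probe sense = reverse complement of target_window
    gc_percent: float
    filter_status: dict[str, bool] = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.start + len(self.target_window)

    @property
    def region_key(self) -> tuple[str, int, int]:
        return (self.region_source, self.region_start, self.region_end)

    def passed_all(self) -> bool:
        return all(self.filter_status.values())


def extract_candidates(
    region: TargetRegion, window: int = 35, step: int = 1
) -> list[ProbeCandidate]:
    """All windows at offsets 0, step, 2*step, ... with start+window <= region
    length, unfiltered, ordered by start.  Regions shorter than the window
    yield an empty list."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    out: list[ProbeCandidate] = []
    for start in range(0, len(region) - window + 1, step):
        tw = region.sequence[start : start + window]
        out.append(
            ProbeCandidate(
                gene_id=region.gene_id,
                region_source=region.source,
                region_start=region.start,
                region_end=region.end,
                start=start,
                target_window=tw,
                binding_site=reverse_complement(tw),
                gc_percent=gc_percent(tw),
            )
        )
    return out


def gc_filter(c: ProbeCandidate, gc_min: float = 45.0, gc_max: float = 75.0) -> bool:
    """Pass iff gc_min <= GC% <= gc_max (bounds inclusive)."""
    ok = gc_min <= c.gc_percent <= gc_max
    c.filter_status["gc"] = ok
    return ok


def homopolymer_filter(c: ProbeCandidate, max_run: int = 4) -> bool:
    """Fail iff the window contains a homopolymer run of max_run+1 or more
    identical bases (case-insensitive).  Default: runs of 5 fail."""
    ok = max_homopolymer_run(c.target_window) <= max_run
    c.filter_status["homopolymer"] = ok
    return ok


def mask_filter(c: ProbeCandidate) -> bool:
    """Fail iff the window contains N, lowercase (soft-masked) or ambiguity
    bases; probes must be plain uppercase A/C/G/T."""
    ok = is_unmasked_dna(c.target_window)
    c.filter_status["mask"] = ok
    return ok


def apply_composition_filters(
    candidates: list[ProbeCandidate],
    gc_min: float = 45.0,
    gc_max: float = 75.0,
    max_run: int = 4,
) -> list[ProbeCandidate]:
    """Run all composition filters; return candidates passing every one."""
    out = []
    for c in candidates:
        # evaluate all filters so filter_status is complete, then select
        results = [gc_filter(c, gc_min, gc_max), homopolymer_filter(c, max_run), mask_filter(c)]
        if all(results):
            out.append(c)
    return out
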