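"""Readout probe generation.

Readouts are short (default 20-nt) fluorophore-conjugated oligos generated
by seeded rejection sampling: draws uniform over {A,C,G,T}^length are kept
iff GC is within 45–60% (inclusive) and the sequence shares no contiguous
match longer than 14 nt, in either orientation, with the off-target
database (the transcriptome-orthogonality screen; unlike primary probes,
readouts get no own-gene exemption).  Optional mutual orthogonality between
accepted readouts is available behind ``cross_check``.

Fluorophores are assigned round-robin over the configured channel list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fishprobes._seq import DNA_BASES, gc_percent, reverse_complement
from fishprobes.offtarget import OffTargetIndex, screen_readout


class ReadoutGenerationError(RuntimeError):
    pass


@dataclass
class ReadoutProbe:
    readout_id: str
    sequence: str
    gc_percent: float
    fluorophore: str | None
    site_sequence: str  # 5' prefix embedded (reverse-complemented) in primaries


def _kmers_both(seq: str, k: int) -> set[str]:
    rc = reverse_complement(seq)
    return {seq[i : i + k] for i in range(len(seq) - k + 1)} | {
        rc[i : i + k] for i in range(len(rc) - k + 1)
    }


def generate_readouts(
    n: int,
    idx: OffTargetIndex,
    seed: int,
    length: int = 20,
    gc_min: float = 45.0,
    gc_max: float = 60.0,
    max_homology: int = 14,
    site_len: int = 15,
    cross_check: bool = False,
    ortho_k: int = 12,
    max_attempts: int | None = None,
) -> list[ReadoutProbe]:
    """Generate exactly n readouts from a seeded stream, or raise.

    Deterministic for a fixed (seed, config, index).  ``max_attempts``
    defaults to 10000 draws per requested readout.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if max_attempts is None:
        max_attempts = 10_000 * n
    rng = np.random.default_rng(seed)
    accepted: list[ReadoutProbe] = []
    used_kmers: set[str] = set()
    attempts = 0
    while len(accepted) < n:
        if attempts >= max_attempts:
            rate = len(accepted) / attempts if attempts else 0.0
            raise ReadoutGenerationError(
                f"exhausted {max_attempts} attempts with {len(accepted)}/{n} "
                f"readouts accepted (acceptance rate {rate:.4f})"
            )
        attempts += 1
        seq = "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=length))
        gc = gc_percent(seq)
        if not (gc_min <= gc <= gc_max):
            continue
        if not screen_readout(seq, idx, max_homology):
            continue
        if cross_check and (_kmers_both(seq, ortho_k) & used_kmers):
            continue
        if cross_check:
            used_kmers |= _kmers_both(seq, ortho_k)
        accepted.append(
            ReadoutProbe(
                readout_id=f"RO{len(accepted) + 1:03d}",
                sequence=seq,
                gc_percent=gc,
                fluorophore=None,
                site_sequence=seq[:site_len],
            )
        )
    return accepted


def assign_fluorophores(
    readouts: list[ReadoutProbe],
    channels: list[str] = ("AF647", "AF488", "AF546"),
) -> list[ReadoutProbe]:
    """Round-robin channel assignment: readout i gets channels[i mod C]."""
    if not channels:
        raise ValueError("channel list must be non-empty")
    for i, r in enumerate(readouts):
        r.fluorophore = channels[i % len(channels)]
    return readouts
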