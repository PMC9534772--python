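"""Small shared sequence helpers."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case; only ACGTN (either case) are mapped."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content in percent, case-insensitive, over the full window length."""
    if not seq:
        return 0.0
    up = seq.upper()
    return 100.0 * (up.count("G") + up.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of identical bases, case-insensitive."""
    up = seq.upper()
    best = run = 0
    prev = None
    for base in up:
        run = run + 1 if base == prev else 1
        prev = base
        if run > best:
            best = run
    return best


def is_unmasked_dna(seq: str) -> bool:
    """True iff the sequence is uppercase A/C/G/T only (no N, soft-mask, ambiguity)."""
    return bool(seq) and all(b in "ACGT" for b in seq)
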