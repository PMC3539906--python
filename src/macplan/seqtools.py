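"""Small shared DNA-string helpers."""

from __future__ import annotations

from Bio.Seq import reverse_complement as _bio_revcomp

from .errors import SequenceError


def validate_dna(seq: str, what: str = "sequence") -> None:
    """Raise SequenceError unless ``seq`` is uppercase A/C/G/T only."""
    for off, base in enumerate(seq, start=1):
        if base not in "ACGT":
            raise SequenceError(f"{what}: non-ACGT symbol {base!r} at offset {off}")


def reverse_complement(seq: str) -> str:
    return str(_bio_revcomp(seq))


def is_palindrome(seq: str) -> bool:
    """True iff an even-length ACGT string equals its own reverse complement."""
    validate_dna(seq, what="palindrome test")
    if len(seq) % 2:
        raise SequenceError(f"palindrome test needs even length, got {len(seq)}")
    return seq == reverse_complement(seq)


def occurrences(haystack: str, needle: str) -> list[int]:
    """All 0-based match positions of ``needle``, overlapping matches included."""
    if not needle:
        return []
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
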