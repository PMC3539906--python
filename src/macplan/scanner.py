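"""Sequence cleaning and palindromic/hybrid site mapping.

Input text may be a single FASTA record or pasted plain text copied from a
sequence viewer: digits and whitespace (typical line-numbering artifacts) are
stripped, letters are uppercased, and anything left that is not A/C/G/T is
rejected — this tool is scoped to non-ambiguous hexamer sites, so ambiguity
codes are an error rather than wildcards.

Scanning reports *every* occurrence, overlapping ones included, of every
loaded enzyme site and every hybrid 6-mer on the provided strand.  Because
the hybrid list carries both orientations of each compatible pair and native
sites are palindromic, forward-strand scanning is strand-complete.
Coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .enzymes import EnzymeSet
from .errors import SequenceError
from .hybrids import HybridSite
from .seqtools import is_palindrome, occurrences

PALINDROMIC = "palindromic"
HYBRID = "hybrid"

_STRIP = set("0123456789 \t\r\n\x0b\x0c")


@dataclass(frozen=True)
class CleanSequence:
    """A validated ACGT string plus the FASTA header it came from, if any."""

    residues: str
    source_name: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item):
        return self.residues[item]


@dataclass(frozen=True)
class SiteHit:
    """One site occurrence.

    ``enzymes`` holds enzyme names for a palindromic hit, or ordered
    (left, right) name pairs for a hybrid hit (all pairs that regenerate the
    matched 6-mer upon ligation).
    """

    position: int  # 1-based start of the 6-mer
    sequence: str
    kind: str  # PALINDROMIC or HYBRID
    enzymes: tuple


def clean_sequence(text: str) -> CleanSequence:
    """Normalize raw FASTA or pasted text into a :class:`CleanSequence`."""
    source_name = None
    body_lines = []
    seen_body = False
    for line in text.splitlines():
        if line.startswith(">"):
            if source_name is not None or seen_body:
                raise SequenceError(
                    "multiple FASTA records found; provide one record per run"
                )
            source_name = line[1:].strip()
        else:
            if line.strip():
                seen_body = True
            body_lines.append(line)
    residues = "".join(
        ch for ch in "".join(body_lines) if ch not in _STRIP
    ).upper()
    for off, base in enumerate(residues, start=1):
        if base not in "ACGT":
            raise SequenceError(
                f"non-ACGT symbol {base!r} at offset {off} after cleaning"
            )
    return CleanSequence(residues=residues, source_name=source_name)


def _site_catalog(
    enzymes: EnzymeSet, pairs: Sequence[HybridSite]
) -> dict[str, tuple[str, tuple]]:
    """Map each scannable 6-mer to its (kind, enzymes) annotation."""
    catalog: dict[str, tuple[str, tuple]] = {}
    for enz in enzymes:
        kind = PALINDROMIC if is_palindrome(enz.site) else HYBRID
        prev = catalog.get(enz.site)
        names = prev[1] if prev else ()
        if enz.name not in names:
            catalog[enz.site] = (kind, (*names, enz.name))
    for hyb in pairs:
        if hyb.is_palindromic:
            continue  # identity pairs are native sites, reported above
        prev = catalog.get(hyb.sequence)
        pair_names = (hyb.left.name, hyb.right.name)
        if prev is None:
            catalog[hyb.sequence] = (HYBRID, (pair_names,))
        elif prev[0] == HYBRID and pair_names not in prev[1]:
            catalog[hyb.sequence] = (HYBRID, (*prev[1], pair_names))
    return catalog


def scan_sites(
    seq: CleanSequence | str,
    enzymes: EnzymeSet,
    pairs: Sequence[HybridSite] = (),
) -> list[SiteHit]:
    """Locate every native-site and hybrid-site occurrence in ``seq``.

    Returns hits sorted by position then sequence.  A palindromic site is
    reported once per position with all enzyme names that recognize it; a
    hybrid hit lists all ordered pairs producing that 6-mer.
    """
    residues = seq.residues if isinstance(seq, CleanSequence) else seq
    catalog = _site_catalog(enzymes, pairs)
    hits = []
    for i in range(len(residues) - 5):
        word = residues[i : i + 6]
        entry = catalog.get(word)
        if entry is not None:
            hits.append(
                SiteHit(position=i + 1, sequence=word, kind=entry[0], enzymes=entry[1])
            )
    hits.sort(key=lambda h: (h.position, h.sequence))
    return hits
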