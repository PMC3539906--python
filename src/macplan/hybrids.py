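"""Compatible-overhang classes and hybrid ligation sites.

Two 5'-cutting enzymes whose palindromic hexamer sites share the same central
4-base overhang (isocaudomers, e.g. NcoI ``C^CATGG`` and PciI ``A^CATGT``)
produce ligatable cohesive ends.  Joining a fragment end cut by one to an end
cut by the other regenerates a *hybrid* 6-mer — first base of the left
enzyme's site, the shared overhang, last base of the right enzyme's site
(NcoI + PciI -> ``CCATGT``).  A hybrid formed from two different enzymes is
never a palindrome and is cut by neither parent, which is what makes hybrid
junctions safe anchor points for modular assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .enzymes import FIVE_PRIME, Enzyme, EnzymeSet
from .errors import EligibilityError, IncompatibleEndsError, MacPlanError
from .seqtools import is_palindrome, reverse_complement

__all__ = [
    "CompatClass",
    "HybridSite",
    "compat_classes",
    "hybrid_site",
    "all_hybrid_sites",
    "enumerate_theoretical_sites",
    "is_palindrome",
]


@dataclass(frozen=True)
class CompatClass:
    """All hybrid-eligible enzymes sharing one 4-base 5' overhang."""

    overhang: str
    members: tuple[Enzyme, ...]

    @property
    def n_pairs(self) -> int:
        """Number of unordered pairs of distinct members."""
        n = len(self.members)
        return n * (n - 1) // 2


@dataclass(frozen=True)
class HybridSite:
    """The 6-mer regenerated by ligating ends cut by ``left`` and ``right``."""

    left: Enzyme
    right: Enzyme
    sequence: str
    is_palindromic: bool


def compat_classes(enzymes: EnzymeSet) -> list[CompatClass]:
    """Group hybrid-eligible enzymes into compatibility classes by overhang."""
    by_overhang: dict[str, list[Enzyme]] = {}
    for enz in enzymes.hybrid_eligible():
        by_overhang.setdefault(enz.overhang, []).append(enz)
    return [
        CompatClass(ov, tuple(sorted(members, key=lambda e: e.name)))
        for ov, members in sorted(by_overhang.items())
    ]


def hybrid_site(left: Enzyme, right: Enzyme) -> HybridSite:
    """Construct the ligation product site for an ordered compatible pair.

    The identity pair (A, A) regenerates A's own palindromic site; swapping
    the operands yields the reverse complement of the forward product.
    """
    for enz in (left, right):
        if not enz.hybrid_eligible:
            raise EligibilityError(
                f"{enz.name} is not hybrid-eligible "
                f"({enz.end_type}, {len(enz.overhang)}-base overhang)"
            )
    if left.overhang != right.overhang:
        raise IncompatibleEndsError(
            f"incompatible overhangs {left.overhang} ({left.name}) "
            f"vs {right.overhang} ({right.name})"
        )
    seq = left.site[0] + left.overhang + right.site[5]
    return HybridSite(
        left=left, right=right, sequence=seq, is_palindromic=is_palindrome(seq)
    )


def all_hybrid_sites(enzymes: EnzymeSet) -> list[HybridSite]:
    """Hybrid sites for every ordered pair of distinct compatible enzymes.

    Identity pairs are excluded: (A, A) just restores A's native palindromic
    site and is reported by the scanner as such.  Both orientations of each
    unordered pair are kept, so forward-strand scanning covers both genomic
    strands.
    """
    sites = []
    for cls in compat_classes(enzymes):
        for a, b in product(cls.members, repeat=2):
            if a is not b:
                sites.append(hybrid_site(a, b))
    return sites


def enumerate_theoretical_sites(mode: str) -> tuple[tuple[str, ...], int]:
    """Enumerate a theoretical site space and its cardinality.

    ``palindromes``: all 6-mers equal to their reverse complement (4^3 = 64).
    ``hybrids_incl_palindromes``: all 6-mers whose central 4-mer is a
    palindrome — outer bases free, 16 x 16 = 256; every such 6-mer can arise
    by ligating two (hypothetical) 5'-cutters sharing that overhang.
    ``palindromic_overhangs``: the 16 self-complementary 4-mers.
    """
    if mode == "palindromic_overhangs":
        seqs = tuple(
            s
            for s in ("".join(p) for p in product("ACGT", repeat=4))
            if is_palindrome(s)
        )
        return seqs, len(seqs)
    if mode not in ("palindromes", "hybrids_incl_palindromes"):
        raise MacPlanError(f"unknown enumeration mode {mode!r}")
    seqs = []
    for candidate in ("".join(p) for p in product("ACGT", repeat=6)):
        if mode == "palindromes":
            if is_palindrome(candidate):
                seqs.append(candidate)
        else:
            if is_palindrome(candidate[1:5]):
                seqs.append(candidate)
    return tuple(seqs), len(seqs)
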