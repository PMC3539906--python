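"""Restriction-enzyme table loading, validation and cut-geometry derivation.

The planner works with commercial type II restriction endonucleases that
recognize a non-ambiguous palindromic hexanucleotide and (for hybrid-site
generation) leave a 4-base 5' cohesive end.  Enzymes with 3' overhangs or
blunt ends may be present in a table: they take part in site mapping and in
palindromic junctions, but never in hybrid-site generation.

The on-disk format is delimited text (TSV or CSV) with a header row naming at
least the three mandatory fields: enzyme ``name``, recognition ``site`` and
``cohesive_end`` sequence.  Optional columns ``end_type``, ``dam`` and ``dcm``
override the defaults (5' geometry; methylation-context heuristics).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .errors import EnzymeTableError, UnknownEnzymeError
from .seqtools import is_palindrome, validate_dna

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
BLUNT = "blunt"

_COLUMN_ALIASES = {
    "name": "name",
    "enzyme": "name",
    "enzyme_name": "name",
    "site": "site",
    "recognition_site": "site",
    "cohesive_end": "cohesive_end",
    "cohesive_end_sequence": "cohesive_end",
    "overhang": "cohesive_end",
    "end_type": "end_type",
    "dam": "dam",
    "dcm": "dcm",
}

_END_TYPE_OFFSET = {FIVE_PRIME: 1, THREE_PRIME: 5, BLUNT: 3}

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", "", ".", "na", "none"}


@dataclass(frozen=True)
class Enzyme:
    """One restriction endonuclease with its cut geometry.

    ``cut_offset`` counts the bases before the top-strand cut within the
    recognition site (0..6); the bottom-strand cut mirrors it, so
    ``cut_offset + len(overhang) + bottom_offset == 6``.
    """

    name: str
    site: str
    cut_offset: int
    end_type: str
    overhang: str
    dam_blocked: bool = False
    dcm_blocked: bool = False
    synonyms: tuple[str, ...] = ()

    @property
    def hybrid_eligible(self) -> bool:
        """True for 5'-cutting enzymes leaving a 4-base overhang on a palindrome."""
        return (
            self.end_type == FIVE_PRIME
            and len(self.overhang) == 4
            and is_palindrome(self.site)
        )

    @property
    def all_names(self) -> tuple[str, ...]:
        return (self.name, *self.synonyms)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}({self.site})"


def derive_overhang(site: str, cut_offset: int) -> tuple[str, str]:
    """Derive (overhang, end_type) from a site and its top-strand cut offset.

    The bottom-strand cut mirrors the top-strand cut about the palindrome
    centre, so the overhang is the central segment between the two cuts:
    5' cutters (offset < 3) expose ``site[offset : 6-offset]`` on the top
    strand, 3' cutters (offset > 3) duplicate ``site[6-offset : offset]``,
    and a centred cut (offset 3) is blunt.
    """
    validate_dna(site, what="recognition site")
    if len(site) != 6:
        raise EnzymeTableError(f"recognition site must be 6 bp, got {site!r}")
    if not 0 <= cut_offset <= 6:
        raise EnzymeTableError(f"cut offset {cut_offset} outside 0..6")
    if cut_offset < 3:
        return site[cut_offset : 6 - cut_offset], FIVE_PRIME
    if cut_offset > 3:
        return site[6 - cut_offset : cut_offset], THREE_PRIME
    return "", BLUNT


def methylation_flags(site: str) -> tuple[bool, bool]:
    """Advisory Dam/Dcm sensitivity from sequence context alone.

    Dam methylates GATC; Dcm methylates CCWGG (CCAGG/CCTGG).  An enzyme whose
    recognition site contains one of these contexts may be blocked on DNA
    propagated in dam+/dcm+ E. coli, which makes it inconvenient for cloning.
    Explicit table columns override this heuristic.
    """
    validate_dna(site, what="recognition site")
    dam = "GATC" in site
    dcm = ("CCAGG" in site) or ("CCTGG" in site)
    return dam, dcm


@dataclass(frozen=True)
class EnzymeSet:
    """A deduplicated collection of enzymes indexed by every known name.

    Records are unique by (site, cut_offset, end_type); isoschizomers are
    merged into the first-seen record's ``synonyms``.
    """

    enzymes: tuple[Enzyme, ...]
    skipped: tuple[tuple[int, str], ...] = ()
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        index = {}
        for enz in self.enzymes:
            for nm in enz.all_names:
                index[nm.lower()] = enz
        object.__setattr__(self, "_index", index)

    def __iter__(self) -> Iterator[Enzyme]:
        return iter(self.enzymes)

    def __len__(self) -> int:
        return len(self.enzymes)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._index

    def get(self, name: str) -> Enzyme:
        """Look up an enzyme by canonical name or any synonym."""
        try:
            return self._index[name.lower()]
        except KeyError:
            raise UnknownEnzymeError(f"unknown enzyme {name!r}") from None

    def hybrid_eligible(self) -> tuple[Enzyme, ...]:
        return tuple(e for e in self.enzymes if e.hybrid_eligible)

    def to_tsv(self) -> str:
        """Serialize to the canonical table format (synonyms as extra rows)."""
        out = io.StringIO()
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "site", "cohesive_end", "end_type", "dam", "dcm"])
        for enz in self.enzymes:
            for nm in enz.all_names:
                writer.writerow(
                    [
                        nm,
                        enz.site,
                        enz.overhang,
                        enz.end_type,
                        int(enz.dam_blocked),
                        int(enz.dcm_blocked),
                    ]
                )
        return out.getvalue()


def _parse_bool(raw: str | None, default: bool) -> bool:
    if raw is None:
        return default
    val = raw.strip().lower()
    if val in _TRUTHY:
        return True
    if val in _FALSY:
        return default if val in {"", ".", "na", "none"} else False
    raise EnzymeTableError(f"cannot interpret boolean field {raw!r}")


def parse_enzyme_table(source: str | Iterable[str]) -> EnzymeSet:
    """Parse a delimited enzyme table into a validated :class:`EnzymeSet`.

    ``source`` is the table text (or an iterable of lines).  Rows whose site
    is not a non-ambiguous hexamer are skipped and reported in
    ``EnzymeSet.skipped``; a cohesive-end field inconsistent with the
    geometry derived from the site raises :class:`EnzymeTableError` naming
    the row.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise EnzymeTableError("empty enzyme table")

    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.reader(lines, delimiter=delimiter)
    header = next(reader)
    columns: dict[str, int] = {}
    for i, raw in enumerate(header):
        key = raw.strip().lower().replace(" ", "_")
        if key in _COLUMN_ALIASES:
            columns.setdefault(_COLUMN_ALIASES[key], i)
    for mandatory in ("name", "site", "cohesive_end"):
        if mandatory not in columns:
            raise EnzymeTableError(f"missing mandatory column {mandatory!r}")

    def cell(row: list[str], key: str) -> str | None:
        idx = columns.get(key)
        if idx is None or idx >= len(row):
            return None
        return row[idx].strip()

    records: dict[tuple[str, int, str], Enzyme] = {}
    skipped: list[tuple[int, str]] = []
    for rownum, row in enumerate(reader, start=2):
        name = cell(row, "name") or ""
        site = (cell(row, "site") or "").upper()
        if not name:
            skipped.append((rownum, "missing enzyme name"))
            continue
        if len(site) != 6 or any(b not in "ACGT" for b in site):
            skipped.append((rownum, f"ambiguous/invalid site {site!r}"))
            continue

        end_type_raw = (cell(row, "end_type") or "").lower()
        cohesive = (cell(row, "cohesive_end") or "").upper()
        if end_type_raw:
            if end_type_raw not in _END_TYPE_OFFSET:
                raise EnzymeTableError(
                    f"row {rownum} ({name}): unknown end_type {end_type_raw!r}"
                )
            cut_offset = _END_TYPE_OFFSET[end_type_raw]
        elif not cohesive:
            cut_offset = 3  # no cohesive end declared: blunt centred cut
        else:
            cut_offset = 1  # default convention: 5', 4-base overhang
        overhang, end_type = derive_overhang(site, cut_offset)
        if cohesive and cohesive != overhang:
            raise EnzymeTableError(
                f"row {rownum} ({name}): cohesive end {cohesive!r} inconsistent "
                f"with {overhang!r} derived from site {site} ({end_type})"
            )

        dam_default, dcm_default = methylation_flags(site)
        enzyme = Enzyme(
            name=name,
            site=site,
            cut_offset=cut_offset,
            end_type=end_type,
            overhang=overhang,
            dam_blocked=_parse_bool(cell(row, "dam"), dam_default),
            dcm_blocked=_parse_bool(cell(row, "dcm"), dcm_default),
        )
        key = (site, cut_offset, end_type)
        if key in records:
            prior = records[key]
            if name.lower() not in {n.lower() for n in prior.all_names}:
                records[key] = replace(prior, synonyms=(*prior.synonyms, name))
        else:
            records[key] = enzyme

    return EnzymeSet(enzymes=tuple(records.values()), skipped=tuple(skipped))


def load_enzyme_table(path: str | Path) -> EnzymeSet:
    """Load an enzyme table from a TSV/CSV file."""
    return parse_enzyme_table(Path(path).read_text())


def load_default_enzymes() -> EnzymeSet:
    """Load the bundled 12-enzyme fixture (plus isoschizomer synonyms).

    These are the enzymes used in the worked CHEF1 example: XhoI, XbaI,
    BamHI, SalI, EcoRI, NheI, BclI, SpeI, SacI, AvrII, NcoI and PciI.
    """
    text = resources.files("macplan.data").joinpath("enzymes.tsv").read_text()
    return parse_enzyme_table(text)
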