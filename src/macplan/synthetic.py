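"""Seeded synthetic sequences and the published worked-example fixtures.

Everything here is generated or reconstructed programmatically — no
downloads.  Two kinds of fixture are provided:

* uniform random ACGT sequences, optionally with specific 6-mers planted at
  chosen positions (and, for planner test targets, with all native
  recognition sites of a loaded enzyme set scrubbed from the background so
  that a valid partition is guaranteed to exist);

* *surrogates* for the two published CHEF1 (Chinese hamster elongation
  factor 1 alpha) flanking regions.  The genomic residues of those regions
  are not bundled; only their published module coordinates, flanking enzymes
  and hence junction 6-mers are.  A surrogate is a random background of the
  correct length with each junction's 6-mer planted at its printed position,
  which is sufficient to test junction geometry, classification and assembly
  simulation — never the genomic residues themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .enzymes import EnzymeSet, load_default_enzymes
from .errors import MacPlanError, PlantError
from .hybrids import hybrid_site
from .planner import AssemblyPlan, build_plan_from_flanks
from .scanner import CleanSequence
from .seqtools import occurrences

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Published module tables for the CHEF1 upstream (5') and downstream (3')
# flanking fragments: (start, end, 5'-flanking RE, 3'-flanking RE) per
# module, 1-based inclusive coordinates on the deposited genomic sequence.
# Terminal enzymes (primer-added vector sites, shown in parentheses in the
# published tables) are listed separately.
CHEF1_UPSTREAM_MODULES: tuple[tuple[int, int, str, str], ...] = (
    (8532, 9117, "XhoI", "AvrII"),
    (9114, 9800, "XbaI", "BamHI"),
    (9795, 10573, "BamHI", "AvrII"),
    (10570, 11208, "SpeI", "XhoI"),
    (11205, 12491, "SalI", "NcoI"),
)
CHEF1_UPSTREAM_TERMINALS = ("XhoI", "NcoI")

CHEF1_DOWNSTREAM_MODULES: tuple[tuple[int, int, str, str], ...] = (
    (14545, 15157, "NheI", "XbaI"),
    (15154, 15908, "NheI", "AvrII"),
    (15905, 16644, "NheI", "AvrII"),
    (16639, 17327, "AvrII", "SacI"),
    (17322, 18019, "SacI", "BamHI"),
    (18016, 18794, "BclI", "XhoI"),
)
CHEF1_DOWNSTREAM_TERMINALS = ("NheI", "XhoI")

# Span of the published shotgun-assembly gap over the upstream fragment,
# covered by a single module in the worked example.
CHEF1_SHOTGUN_GAP = (11387, 12196)

_TABLES = {
    "upstream": (CHEF1_UPSTREAM_MODULES, CHEF1_UPSTREAM_TERMINALS),
    "downstream": (CHEF1_DOWNSTREAM_MODULES, CHEF1_DOWNSTREAM_TERMINALS),
}


@dataclass(frozen=True)
class PlantSpec:
    """A 6-mer to embed at a 1-based position."""

    position: int
    sequence: str


def random_sequence(length: int, seed: int) -> CleanSequence:
    """An i.i.d. uniform ACGT sequence; identical output for identical inputs."""
    if length < 0:
        raise MacPlanError(f"length must be >= 0, got {length}")
    rng = np.random.default_rng(seed)
    residues = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    return CleanSequence(residues=residues, source_name=f"random_L{length}_seed{seed}")


def plant_sites(seq: CleanSequence, plants: Sequence[PlantSpec]) -> CleanSequence:
    """Overwrite the sequence with each plant's 6-mer at its position."""
    spans = sorted((p.position, p.position + len(p.sequence) - 1) for p in plants)
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise PlantError(f"planted spans overlap near position {s2}")
    residues = list(seq.residues)
    for plant in plants:
        if plant.position < 1 or plant.position + len(plant.sequence) - 1 > len(residues):
            raise PlantError(f"plant at {plant.position} out of bounds")
        residues[plant.position - 1 : plant.position - 1 + len(plant.sequence)] = (
            plant.sequence
        )
    return CleanSequence(residues="".join(residues), source_name=seq.source_name)


def _scrub(
    residues: str,
    sites: Sequence[str],
    keep_spans: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> str:
    """Mutate single bases until no listed site occurs outside the kept spans."""
    keep = set()
    for s, e in keep_spans:  # 0-based inclusive spans
        keep.update(range(s, e + 1))
    chars = list(residues)
    for _ in range(max_rounds):
        dirty = False
        text = "".join(chars)
        for site in sites:
            for q in occurrences(text, site):
                span = range(q, q + len(site))
                if all(i in keep for i in span):
                    continue  # a deliberately planted site
                editable = [i for i in span if i not in keep]
                i = editable[int(rng.integers(0, len(editable)))]
                choices = [b for b in "ACGT" if b != chars[i]]
                chars[i] = choices[int(rng.integers(0, 3))]
                dirty = True
        if not dirty:
            return "".join(chars)
    raise MacPlanError("could not scrub background sites")  # pragma: no cover


def planted_target(
    length: int,
    seed: int,
    enzymes: EnzymeSet | None = None,
    spacing: int = 750,
    jitter: int = 60,
) -> CleanSequence:
    """A random target guaranteed to admit a clean MAC partition.

    Non-palindromic hybrid 6-mers (cycling through the five compatible pairs
    of the bundled enzyme set) are planted roughly every ``spacing`` bp, and
    every native recognition site of ``enzymes`` is scrubbed from the
    background, so each planted junction passes all cut-safety constraints.
    """
    if enzymes is None:
        enzymes = load_default_enzymes()
    rng = np.random.default_rng(seed)
    base = random_sequence(length, seed)
    pair_names = [
        ("NcoI", "PciI"),
        ("AvrII", "SpeI"),
        ("XhoI", "SalI"),
        ("BamHI", "BclI"),
        ("XbaI", "NheI"),
    ]
    hybrids = [
        hybrid_site(enzymes.get(a), enzymes.get(b)).sequence for a, b in pair_names
    ]
    plants = []
    n_modules = max(1, round(length / spacing))
    for i in range(1, n_modules):
        pos = round(i * length / n_modules) + int(rng.integers(-jitter, jitter + 1))
        plants.append(
            PlantSpec(position=pos, sequence=hybrids[(i - 1) % len(hybrids)])
        )
    planted = plant_sites(base, plants)
    keep = [(p.position - 1, p.position + 4) for p in plants]
    residues = _scrub(planted.residues, sorted({e.site for e in enzymes}), keep, rng)
    return CleanSequence(
        residues=residues, source_name=f"planted_target_L{length}_seed{seed}"
    )


def _junction_plants(
    rows: Sequence[tuple[int, int, str, str]], enzymes: EnzymeSet, origin: int
) -> list[PlantSpec]:
    plants = []
    for (s1, e1, _f1, t1), (s2, _e2, f2, _t2) in zip(rows, rows[1:]):
        overlap = e1 - s2 + 1
        left, right = enzymes.get(t1), enzymes.get(f2)
        if overlap == 6:
            plants.append(PlantSpec(position=s2 - origin + 1, sequence=left.site))
        elif overlap == 4:
            plants.append(
                PlantSpec(
                    position=s2 - 1 - origin + 1,
                    sequence=hybrid_site(left, right).sequence,
                )
            )
        else:  # pragma: no cover - published tables are 4/6 only
            raise MacPlanError(f"unexpected overlap {overlap}")
    return plants


def chef1_surrogate(
    which: str = "upstream",
    seed: int = 2012,
    enzymes: EnzymeSet | None = None,
) -> CleanSequence:
    """Synthetic stand-in for a published CHEF1 flanking region.

    Random background of the region's printed length with every junction
    6-mer planted at its printed position and all other native-site
    occurrences scrubbed; coordinates are shifted so that local position 1
    corresponds to the printed region start.
    """
    if which not in _TABLES:
        raise MacPlanError(f"unknown region {which!r}")
    if enzymes is None:
        enzymes = load_default_enzymes()
    rows, _terms = _TABLES[which]
    origin, end = rows[0][0], rows[-1][1]
    rng = np.random.default_rng(seed)
    base = random_sequence(end - origin + 1, seed)
    plants = _junction_plants(rows, enzymes, origin)
    planted = plant_sites(base, plants)
    keep = [(p.position - 1, p.position + 4) for p in plants]
    residues = _scrub(planted.residues, sorted({e.site for e in enzymes}), keep, rng)
    return CleanSequence(
        residues=residues, source_name=f"CHEF1-{which}-surrogate (synthetic)"
    )


def chef1_published_plan(
    which: str = "upstream", enzymes: EnzymeSet | None = None, local: bool = False
) -> AssemblyPlan:
    """The published MAC partition reconstructed from its printed table.

    With ``local=True`` coordinates are shifted to start at 1, matching
    :func:`chef1_surrogate` output.
    """
    if which not in _TABLES:
        raise MacPlanError(f"unknown region {which!r}")
    if enzymes is None:
        enzymes = load_default_enzymes()
    rows, (t5_name, t3_name) = _TABLES[which]
    if local:
        origin = rows[0][0]
        rows = tuple(
            (s - origin + 1, e - origin + 1, f, t) for s, e, f, t in rows
        )
    return build_plan_from_flanks(
        rows,
        enzymes,
        terminal_5=enzymes.get(t5_name),
        terminal_3=enzymes.get(t3_name),
    )
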