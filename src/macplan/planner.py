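"""Partition a target region into clonable modules joined at safe junctions.

A modular assembly cloning (MAC) plan divides a long target into consecutive
modules, each bounded by either a natural palindromic restriction site (the
6-mer is fully genomic; adjacent modules overlap by 6 bp) or a hybrid site
(two compatible 5'-cutters; adjacent modules share only the 4-base overhang
and each primer supplies the one outer base that completes its module's full
recognition site, so the ligated junction restores the genomic sequence
exactly).

Junction choices must respect cut-safety: an enzyme used to open a junction
must not cut elsewhere in the fragment it is applied to.  In lenient mode the
check covers the two adjacent modules; in strict sequential mode (the
default) the enzyme that re-opens the growing assembly additionally must not
cut anything assembled earlier, including previously formed palindromic
junctions and a primer-added terminal site.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .enzymes import Enzyme, EnzymeSet
from .errors import MacPlanError, NoJunctionFound
from .hybrids import HybridSite, hybrid_site
from .scanner import HYBRID, PALINDROMIC, CleanSequence, scan_sites
from .seqtools import occurrences


@dataclass(frozen=True)
class PlannerConfig:
    """Module size window, terminal enzymes and safety policy.

    Defaults reflect common MAC practice: modules of 500-1300 bp (plans with
    a single oversized module up to ~1.3 kb are acceptable when the sequence
    offers no better junction), aiming for ~750 bp so that an insert can be
    fully read from both vector primers in single sequencing runs.
    """

    min_module: int = 500
    max_module: int = 1300
    ideal_module: int = 750
    terminal_5_enzyme: Optional[Enzyme] = None
    terminal_3_enzyme: Optional[Enzyme] = None
    avoid_methylation: bool = False
    strict_sequential: bool = True

    def __post_init__(self):
        if not 0 < self.min_module <= self.ideal_module <= self.max_module:
            raise MacPlanError(
                "module size window must satisfy 0 < min <= ideal <= max"
            )


@dataclass(frozen=True)
class Junction:
    """Boundary between two adjacent modules."""

    site_position: int  # 1-based start of the 6-mer on the target
    kind: str  # PALINDROMIC or HYBRID
    left_enzyme: Enzyme  # cuts the 3' end of the left module
    right_enzyme: Enzyme  # cuts the 5' end of the right module
    overlap_len: int  # 6 if palindromic, 4 if hybrid
    sequence: str = ""

    @property
    def left_module_end(self) -> int:
        return self.site_position + (5 if self.kind == PALINDROMIC else 4)

    @property
    def right_module_start(self) -> int:
        return self.site_position + (0 if self.kind == PALINDROMIC else 1)


@dataclass(frozen=True)
class ModuleSpec:
    """One PCR-amplified module of the plan (coordinates 1-based inclusive).

    ``left_added``/``right_added`` are the bases the primers append beyond
    the genomic span: the single outer base completing a hybrid junction's
    full recognition site, or a whole terminal enzyme site at the plan ends
    (flagged ``five_paren``/``three_paren``, shown in parentheses in plan
    tables).
    """

    index: int
    start: int
    end: int
    five_re: str
    three_re: str
    left_added: str = ""
    right_added: str = ""
    five_paren: bool = False
    three_paren: bool = False
    undersized: bool = False

    @property
    def length(self) -> int:
        return module_length(self.start, self.end)


@dataclass(frozen=True)
class AssemblyPlan:
    region: tuple[int, int]
    modules: tuple[ModuleSpec, ...]
    junctions: tuple[Junction, ...]
    safety: object = None  # SafetyReport, attached after verification
    terminal_5: Optional[Enzyme] = None
    terminal_3: Optional[Enzyme] = None


def module_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive span."""
    if start > end:
        raise MacPlanError(f"start {start} > end {end}")
    return end - start + 1


def classify_junctions(plan: AssemblyPlan) -> tuple[int, int]:
    """Count (palindromic, hybrid) junctions in a plan."""
    n_pal = sum(1 for j in plan.junctions if j.kind == PALINDROMIC)
    return n_pal, len(plan.junctions) - n_pal


def candidate_junctions(
    seq: CleanSequence | str,
    window: tuple[int, int],
    enzymes: EnzymeSet,
    pairs: Sequence[HybridSite],
) -> list[Junction]:
    """All junction candidates whose 6-mer lies wholly inside ``window``.

    Ranked by distance of the site start from the window midpoint, then
    palindromic before hybrid, then enzyme names.
    """
    lo, hi = window
    mid = (lo + hi) / 2
    candidates: list[Junction] = []
    for hit in scan_sites(seq, enzymes, pairs):
        if hit.position < lo or hit.position + 5 > hi:
            continue
        if hit.kind == PALINDROMIC:
            for name in hit.enzymes:
                enz = enzymes.get(name)
                candidates.append(
                    Junction(hit.position, PALINDROMIC, enz, enz, 6, hit.sequence)
                )
        else:
            for left_name, right_name in hit.enzymes:
                candidates.append(
                    Junction(
                        hit.position,
                        HYBRID,
                        enzymes.get(left_name),
                        enzymes.get(right_name),
                        4,
                        hit.sequence,
                    )
                )
    candidates.sort(
        key=lambda j: (
            abs(j.site_position - mid),
            0 if j.kind == PALINDROMIC else 1,
            j.left_enzyme.name,
            j.right_enzyme.name,
        )
    )
    return candidates


def _interior(haystack: str, site: str) -> list[int]:
    """Occurrences of ``site`` other than at the two termini of ``haystack``."""
    boundary = {0, len(haystack) - 6}
    return [i for i in occurrences(haystack, site) if i not in boundary]


def _junction_additions(junction: Junction) -> tuple[str, str]:
    """Primer bases completing the junction site: (left module's right_added,
    right module's left_added)."""
    if junction.kind == PALINDROMIC:
        return "", ""
    return junction.left_enzyme.site[5], junction.right_enzyme.site[0]


class _Search:
    """Greedy left-to-right junction placement with bounded backtracking."""

    def __init__(self, residues, region, config, enzymes, pairs, budget=5000):
        self.residues = residues
        self.region = region
        self.config = config
        self.enzymes = enzymes
        self.pairs = pairs
        self.budget = budget
        self.last_window = region
        self.t5add = config.terminal_5_enzyme.site if config.terminal_5_enzyme else ""
        self.t3add = config.terminal_3_enzyme.site if config.terminal_3_enzyme else ""

    def span(self, start: int, end: int) -> str:
        return self.residues[start - 1 : end]

    def module_string(self, start, end, left_added, right_added) -> str:
        return left_added + self.span(start, end) + right_added

    def prefix_string(self, end: int, right_added: str) -> str:
        """The assembled product through genomic position ``end``."""
        return self.t5add + self.span(self.region[0], end) + right_added

    def clean_interior(self, string: str, enzyme: Enzyme) -> bool:
        return not _interior(string, enzyme.site)

    def left_boundary_addition(self, prev: Optional[Junction]) -> str:
        if prev is None:
            return self.t5add
        return _junction_additions(prev)[1]

    def left_boundary_enzyme(self, prev: Optional[Junction]) -> Optional[Enzyme]:
        if prev is None:
            return self.config.terminal_5_enzyme
        return prev.right_enzyme

    def close_ok(self, start: int, prev: Optional[Junction], placed: int) -> bool:
        """Can the region be closed with a final module starting at ``start``?"""
        end = self.region[1]
        remaining = end - start + 1
        if remaining > self.config.max_module:
            return False
        if remaining < self.config.min_module and placed > 0:
            return False
        amp = self.module_string(
            start, end, self.left_boundary_addition(prev), self.t3add
        )
        left_enz = self.left_boundary_enzyme(prev)
        if left_enz is not None and not self.clean_interior(amp, left_enz):
            return False
        if self.config.strict_sequential:
            full = self.prefix_string(end, self.t3add)
            for term in (self.config.terminal_5_enzyme, self.config.terminal_3_enzyme):
                if term is None:
                    continue
                occ = occurrences(full, term.site)
                allowed = set()
                if term is self.config.terminal_5_enzyme and self.t5add:
                    allowed.add(0)
                if term is self.config.terminal_3_enzyme and self.t3add:
                    allowed.add(len(full) - 6)
                if any(i not in allowed for i in occ):
                    return False
        return True

    def junction_ok(self, start: int, prev: Optional[Junction], cand: Junction) -> bool:
        cfg = self.config
        if cfg.avoid_methylation and (
            cand.left_enzyme.dam_blocked
            or cand.left_enzyme.dcm_blocked
            or cand.right_enzyme.dam_blocked
            or cand.right_enzyme.dcm_blocked
        ):
            return False
        end = cand.left_module_end
        length = end - start + 1
        if not cfg.min_module <= length <= cfg.max_module:
            return False
        if self.region[1] - cand.right_module_start + 1 < cfg.min_module:
            return False  # would strand the remainder below the minimum
        right_added = _junction_additions(cand)[0]
        amp = self.module_string(
            start, end, self.left_boundary_addition(prev), right_added
        )
        # the enzyme opening this module's left end must not cut inside it
        left_enz = self.left_boundary_enzyme(prev)
        if left_enz is not None and not self.clean_interior(amp, left_enz):
            return False
        # the junction's left enzyme must not cut the fragment it is applied
        # to: the whole growing assembly in strict mode, this module otherwise
        if cfg.strict_sequential:
            prefix = self.prefix_string(end, right_added)
            occ = occurrences(prefix, cand.left_enzyme.site)
            if any(i != len(prefix) - 6 for i in occ):
                return False
        else:
            if not self.clean_interior(amp, cand.left_enzyme):
                return False
        return True

    def solve(self, start: int, prev: Optional[Junction], placed: int):
        if self.budget <= 0:
            raise NoJunctionFound(self.last_window, "search budget exhausted")
        if self.close_ok(start, prev, placed):
            return []
        lo = start + self.config.min_module - 6
        hi = min(self.region[1], start + self.config.max_module)
        self.last_window = (lo, hi)
        for cand in candidate_junctions(
            self.residues, (lo, hi), self.enzymes, self.pairs
        ):
            self.budget -= 1
            if self.budget <= 0:
                break
            if not self.junction_ok(start, prev, cand):
                continue
            rest = self.solve(cand.right_module_start, cand, placed + 1)
            if rest is not None:
                return [cand, *rest]
        return None


def _build_modules(
    region: tuple[int, int],
    junctions: Sequence[Junction],
    config_or_terms,
) -> tuple[ModuleSpec, ...]:
    """Assemble ModuleSpec records from junctions + terminal enzymes."""
    start, end = region
    t5, t3, min_module = config_or_terms
    modules = []
    cur = start
    for i, junction in enumerate(junctions, start=1):
        right_added, next_left_added = _junction_additions(junction)
        left_added = t5.site if (i == 1 and t5) else (
            _junction_additions(junctions[i - 2])[1] if i > 1 else ""
        )
        five_name = (
            junctions[i - 2].right_enzyme.name
            if i > 1
            else (t5.name if t5 else "")
        )
        modules.append(
            ModuleSpec(
                index=i,
                start=cur,
                end=junction.left_module_end,
                five_re=five_name,
                three_re=junction.left_enzyme.name,
                left_added=left_added,
                right_added=right_added,
                five_paren=(i == 1 and t5 is not None),
                three_paren=False,
            )
        )
        cur = junction.right_module_start
    i = len(junctions) + 1
    modules.append(
        ModuleSpec(
            index=i,
            start=cur,
            end=end,
            five_re=(
                junctions[-1].right_enzyme.name
                if junctions
                else (t5.name if t5 else "")
            ),
            three_re=t3.name if t3 else "",
            left_added=(
                _junction_additions(junctions[-1])[1]
                if junctions
                else (t5.site if t5 else "")
            ),
            right_added=t3.site if t3 else "",
            five_paren=(i == 1 and t5 is not None),
            three_paren=t3 is not None,
            undersized=(end - cur + 1) < min_module,
        )
    )
    return tuple(modules)


def plan_partition(
    seq: CleanSequence | str,
    region: tuple[int, int],
    config: PlannerConfig,
    enzymes: EnzymeSet,
    pairs: Sequence[HybridSite],
) -> AssemblyPlan:
    """Find a constraint-satisfying MAC partition of ``region``.

    Junctions are placed left to right, each inside the size window implied
    by the previous module start, preferring sites near the window midpoint
    and palindromic over hybrid junctions (they need no corrective primer
    base).  Backtracking explores alternatives when a later window cannot be
    satisfied.  Raises :class:`NoJunctionFound` when no partition exists.
    """
    residues = seq.residues if isinstance(seq, CleanSequence) else seq
    start, end = region
    if not (1 <= start <= end <= len(residues)):
        raise MacPlanError(f"region {region} outside sequence of {len(residues)} bp")
    for term, label in (
        (config.terminal_5_enzyme, "5'"),
        (config.terminal_3_enzyme, "3'"),
    ):
        if term is not None and occurrences(residues[start - 1 : end], term.site):
            raise MacPlanError(
                f"terminal {label} enzyme {term.name} cuts inside the region"
            )

    search = _Search(residues, region, config, enzymes, pairs)
    junctions = search.solve(start, None, 0)
    if junctions is None:
        raise NoJunctionFound(search.last_window)
    modules = _build_modules(
        region,
        junctions,
        (config.terminal_5_enzyme, config.terminal_3_enzyme, config.min_module),
    )
    plan = AssemblyPlan(
        region=region,
        modules=modules,
        junctions=tuple(junctions),
        terminal_5=config.terminal_5_enzyme,
        terminal_3=config.terminal_3_enzyme,
    )
    from .simulate import assembly_safety_check  # deferred: avoids import cycle

    safety = assembly_safety_check(
        plan, residues, enzymes=enzymes, strict=config.strict_sequential
    )
    return replace(plan, safety=safety)


def primer_termini(module: ModuleSpec, plan: AssemblyPlan) -> tuple[str, str]:
    """Bases the primers add beyond the module's genomic span.

    Hybrid junction: the left module gets its enzyme's final base appended,
    the right module gets its enzyme's first base prepended, completing the
    respective full recognition sites; palindromic junction: nothing added;
    plan termini with configured terminal enzymes: the full 6-mer site.
    """
    if module.index < 1 or module.index > len(plan.modules) or (
        plan.modules[module.index - 1] != module
    ):
        raise MacPlanError("module does not belong to the plan")
    if module.index == 1:
        left = plan.terminal_5.site if plan.terminal_5 else ""
    else:
        left = _junction_additions(plan.junctions[module.index - 2])[1]
    if module.index == len(plan.modules):
        right = plan.terminal_3.site if plan.terminal_3 else ""
    else:
        right = _junction_additions(plan.junctions[module.index - 1])[0]
    return left, right


def module_amplicon(module: ModuleSpec, residues: str) -> str:
    """The PCR amplicon for a module: genomic span plus primer-added bases."""
    return module.left_added + residues[module.start - 1 : module.end] + module.right_added


def build_plan_from_flanks(
    rows: Sequence[tuple],
    enzymes: EnzymeSet,
    terminal_5: Optional[Enzyme] = None,
    terminal_3: Optional[Enzyme] = None,
) -> AssemblyPlan:
    """Reconstruct an AssemblyPlan from printed module coordinates and flanks.

    ``rows`` are ``(start, end, five_re_name, three_re_name)`` per module, in
    order.  Junction kinds are inferred from the coordinate overlap between
    consecutive modules: a 6-bp overlap is a natural palindromic junction, a
    4-bp overlap a hybrid junction.
    """
    junctions = []
    for (s1, e1, _f1, t1), (s2, _e2, f2, _t2) in zip(rows, rows[1:]):
        overlap = e1 - s2 + 1
        left = enzymes.get(t1)
        right = enzymes.get(f2)
        if overlap == 6:
            if left.site != right.site:
                raise MacPlanError(
                    f"6-bp overlap at {s2} but {left.name}/{right.name} differ"
                )
            junctions.append(Junction(s2, PALINDROMIC, left, right, 6, left.site))
        elif overlap == 4:
            junctions.append(
                Junction(s2 - 1, HYBRID, left, right, 4, hybrid_site(left, right).sequence)
            )
        else:
            raise MacPlanError(f"junction overlap {overlap} bp is neither 4 nor 6")
    region = (rows[0][0], rows[-1][1])
    modules = _build_modules(region, junctions, (terminal_5, terminal_3, 1))
    return AssemblyPlan(
        region=region,
        modules=modules,
        junctions=tuple(junctions),
        terminal_5=terminal_5,
        terminal_3=terminal_3,
    )
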