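"""In-silico restriction digestion and sticky-end ligation.

The simulator verifies a plan the way a bench scientist would: build each
module's amplicon (genomic span plus primer-added bases), then repeatedly cut
the growing assembly's right end and the incoming module's left end with the
junction enzymes and ligate the compatible cohesive ends.  A correct plan
reassembles the target region byte-for-byte with no unintended cut at any
step — which is the whole point of hybrid junctions: once ligated they are
non-palindromic 6-mers that no loaded enzyme recognizes.

Duplex representation: a fragment is stored as its top strand between the
two top-strand cuts, with each end annotated by the cohesive-end sequence
and polarity.  For a 5' overhang the single-stranded extension sits on the
top strand at the fragment's *left* end (so the right-end annotation refers
to the bottom-strand extension, written in top-strand coordinates); for a 3'
overhang the roles are mirrored.  With this convention ligation of
compatible ends is exact string concatenation, and digest/ligate round-trips
for both polarities.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

from .enzymes import BLUNT, Enzyme, EnzymeSet
from .errors import IncompatibleEndsError, MacPlanError, SimulationError
from .planner import AssemblyPlan, module_amplicon
from .scanner import HYBRID, CleanSequence
from .seqtools import occurrences, reverse_complement

_BLUNT_END = ("", BLUNT)


@dataclass(frozen=True)
class SimFragment:
    """A linear duplex with annotated cohesive ends.

    ``offset`` is the 0-based start of ``top`` within the parent sequence a
    digest was applied to (0 for fragments built directly).
    """

    top: str
    left_overhang: tuple[str, str] = _BLUNT_END
    right_overhang: tuple[str, str] = _BLUNT_END
    offset: int = 0

    def __len__(self) -> int:
        return len(self.top)


@dataclass(frozen=True)
class Violation:
    """One unintended cut (or cuttable hybrid junction) found during checking."""

    step: int
    enzyme: str
    position: int  # 1-based target coordinate of the offending site start
    context: str


@dataclass(frozen=True)
class SafetyReport:
    violations: tuple[Violation, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def _site_positions(seq: str, enzyme: Enzyme) -> list[tuple[int, int]]:
    """(site_start, top_cut) pairs for every occurrence on either strand.

    Palindromic sites are counted once per top-strand occurrence; for a
    non-palindromic site the reverse-complement orientation is scanned too,
    with the mirrored cut offset.
    """
    hits = [(p, p + enzyme.cut_offset) for p in occurrences(seq, enzyme.site)]
    rc = reverse_complement(enzyme.site)
    if rc != enzyme.site:
        hits += [(p, p + 6 - enzyme.cut_offset) for p in occurrences(seq, rc)]
    return sorted(set(hits))


def digest(seq: str, enzyme: Enzyme) -> list[SimFragment]:
    """Cut ``seq`` at every recognition site; fragments left to right.

    A sequence without sites comes back as a single blunt-ended fragment.
    """
    sites = _site_positions(seq, enzyme)
    cuts: list[tuple[int, tuple[str, str]]] = []
    for p, top_cut in sites:
        lo = p + min(enzyme.cut_offset, 6 - enzyme.cut_offset)
        hi = p + max(enzyme.cut_offset, 6 - enzyme.cut_offset)
        cuts.append((top_cut, (seq[lo:hi], enzyme.end_type)))
    cuts.sort()
    fragments = []
    prev_cut, prev_end = 0, _BLUNT_END
    for top_cut, end in cuts:
        fragments.append(
            SimFragment(seq[prev_cut:top_cut], prev_end, end, offset=prev_cut)
        )
        prev_cut, prev_end = top_cut, end
    fragments.append(SimFragment(seq[prev_cut:], prev_end, _BLUNT_END, offset=prev_cut))
    return fragments


def ligate(left: SimFragment, right: SimFragment) -> SimFragment:
    """Join two fragments over equal, non-blunt cohesive ends."""
    l_seq, l_pol = left.right_overhang
    r_seq, r_pol = right.left_overhang
    if l_pol == BLUNT or r_pol == BLUNT:
        raise IncompatibleEndsError("blunt-end ligation is not supported")
    if l_pol != r_pol:
        raise IncompatibleEndsError(
            f"overhang polarity mismatch: {l_pol} vs {r_pol}"
        )
    if l_seq != r_seq:
        raise IncompatibleEndsError(
            f"incompatible overhangs {l_seq!r} vs {r_seq!r}"
        )
    return SimFragment(
        top=left.top + right.top,
        left_overhang=left.left_overhang,
        right_overhang=right.right_overhang,
        offset=left.offset,
    )


def _reassemble(fragments: list[SimFragment]) -> SimFragment:
    return reduce(ligate, fragments)


def _residues(target: CleanSequence | str) -> str:
    return target.residues if isinstance(target, CleanSequence) else target


def _junction_uncut_violations(plan, enzymes, step, junction) -> list[Violation]:
    out = []
    if enzymes is None or junction.kind != HYBRID:
        return out
    for enz in enzymes:
        if enz.site in (junction.sequence, reverse_complement(junction.sequence)):
            out.append(
                Violation(step, enz.name, junction.site_position, "junction")
            )
    return out


def _terminal_violations(plan: AssemblyPlan, assembled: str, step: int) -> list[Violation]:
    """Unintended occurrences of the terminal enzymes' sites in the product."""
    out = []
    shift = len(plan.modules[0].left_added)
    for term, intended in (
        (plan.terminal_5, 0 if plan.modules[0].left_added else None),
        (plan.terminal_3, len(assembled) - 6 if plan.modules[-1].right_added else None),
    ):
        if term is None:
            continue
        for p in occurrences(assembled, term.site):
            if p != intended:
                out.append(
                    Violation(
                        step, term.name, plan.region[0] + p - shift, "assembly"
                    )
                )
    return out


def simulate_assembly(
    plan: AssemblyPlan,
    target: CleanSequence | str,
    enzymes: EnzymeSet | None = None,
) -> tuple[str, SafetyReport]:
    """Digest and ligate the plan's modules in sequential order.

    Returns the assembled sequence (primer-added terminal sites stripped, so
    success means byte-equality with the target region) and a
    :class:`SafetyReport` of every unintended cut observed along the way.
    When ``enzymes`` is given, each formed hybrid junction is additionally
    checked to be uncuttable by the whole loaded set.
    """
    residues = _residues(target)
    amplicons = [module_amplicon(m, residues) for m in plan.modules]
    violations: list[Violation] = []
    assembly = SimFragment(top=amplicons[0])
    t5_len = len(plan.modules[0].left_added)
    region_start = plan.region[0]

    for k, junction in enumerate(plan.junctions, start=1):
        e_left, e_right = junction.left_enzyme, junction.right_enzyme
        # --- open the growing assembly's right end
        intended = len(assembly.top) - 6
        if assembly.top[intended:] != e_left.site:
            raise SimulationError(
                f"junction {k}: expected {e_left.name} site at assembly 3' end"
            )
        frags = digest(assembly.top, e_left)
        intended_cut = intended + e_left.cut_offset
        for p, _cut in _site_positions(assembly.top, e_left):
            if p != intended:
                violations.append(
                    Violation(k, e_left.name, region_start + p - t5_len, "assembly")
                )
        boundary = [i for i, f in enumerate(frags) if f.offset == intended_cut]
        if not boundary:
            raise SimulationError(f"junction {k}: no cut at the intended site")
        left_piece = _reassemble(frags[: boundary[0]])

        # --- open the incoming module's left end
        incoming = plan.modules[k]
        amp = amplicons[k]
        if amp[:6] != e_right.site:
            raise SimulationError(
                f"junction {k}: expected {e_right.name} site at module "
                f"{incoming.index} 5' end"
            )
        allowed = {0}
        if amp[-6:] == e_right.site:
            allowed.add(len(amp) - 6)  # the module's own right-boundary site
        frags2 = digest(amp, e_right)
        for p, _cut in _site_positions(amp, e_right):
            if p not in allowed:
                violations.append(
                    Violation(
                        k,
                        e_right.name,
                        incoming.start + p - len(incoming.left_added),
                        f"module {incoming.index}",
                    )
                )
        cut2 = e_right.cut_offset
        start_idx = [i for i, f in enumerate(frags2) if f.offset == cut2]
        if not start_idx:
            raise SimulationError(f"junction {k}: no cut at the incoming module site")
        right_piece = _reassemble(frags2[start_idx[0] :])

        assembly = ligate(left_piece, right_piece)
        violations.extend(_junction_uncut_violations(plan, enzymes, k, junction))

    violations.extend(
        _terminal_violations(plan, assembly.top, len(plan.junctions) + 1)
    )
    right_strip = len(plan.modules[-1].right_added)
    core = assembly.top[t5_len : len(assembly.top) - right_strip or None]
    report = SafetyReport(
        tuple(sorted(violations, key=lambda v: (v.step, v.enzyme, v.position)))
    )
    return core, report


def assembly_safety_check(
    plan: AssemblyPlan,
    target: CleanSequence | str,
    enzymes: EnzymeSet | None = None,
    strict: bool = True,
) -> SafetyReport:
    """Static cut-safety analysis of a plan, without digestion or ligation.

    For every junction: the left enzyme must cut nothing in the assembled
    prefix (strict) or in the left module (lenient) besides the junction
    site; the right enzyme nothing inside the incoming module besides its
    boundary sites; each formed hybrid 6-mer must match no loaded enzyme's
    site on either strand; and terminal enzymes must not cut the product
    internally.  Mirrors the unintended cuts :func:`simulate_assembly`
    records dynamically.
    """
    residues = _residues(target)
    region_start = plan.region[0]
    t5_len = len(plan.modules[0].left_added)
    violations: list[Violation] = []

    for k, junction in enumerate(plan.junctions, start=1):
        e_left, e_right = junction.left_enzyme, junction.right_enzyme
        left_module = plan.modules[k - 1]
        prefix = (
            plan.modules[0].left_added
            + residues[region_start - 1 : left_module.end]
            + left_module.right_added
        )
        if strict:
            for p, _cut in _site_positions(prefix, e_left):
                if p != len(prefix) - 6:
                    violations.append(
                        Violation(k, e_left.name, region_start + p - t5_len, "assembly")
                    )
        else:
            amp = module_amplicon(left_module, residues)
            boundary = {0, len(amp) - 6}
            for p, _cut in _site_positions(amp, e_left):
                if p not in boundary:
                    violations.append(
                        Violation(
                            k,
                            e_left.name,
                            left_module.start + p - len(left_module.left_added),
                            "assembly",
                        )
                    )
        incoming = plan.modules[k]
        amp = module_amplicon(incoming, residues)
        allowed = {0}
        if amp[-6:] == e_right.site:
            allowed.add(len(amp) - 6)
        for p, _cut in _site_positions(amp, e_right):
            if p not in allowed:
                violations.append(
                    Violation(
                        k,
                        e_right.name,
                        incoming.start + p - len(incoming.left_added),
                        f"module {incoming.index}",
                    )
                )
        violations.extend(_junction_uncut_violations(plan, enzymes, k, junction))

    assembled = (
        plan.modules[0].left_added
        + residues[region_start - 1 : plan.region[1]]
        + plan.modules[-1].right_added
    )
    violations.extend(_terminal_violations(plan, assembled, len(plan.junctions) + 1))
    return SafetyReport(
        tuple(sorted(violations, key=lambda v: (v.step, v.enzyme, v.position)))
    )
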