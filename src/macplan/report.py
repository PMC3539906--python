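"""Tabular and human-readable output, and plan-table round-tripping.

All tables are tab-delimited with a header row.  In the human-readable site
report, palindromic restriction sites are suffixed with an asterisk to
distinguish them from hybrid sites, and the report is also persisted to a
text file for further use.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .enzymes import EnzymeSet
from .errors import MacPlanError
from .planner import AssemblyPlan, build_plan_from_flanks
from .scanner import PALINDROMIC, SiteHit


def _hit_enzymes(hit: SiteHit) -> str:
    if hit.kind == PALINDROMIC:
        return ",".join(hit.enzymes)
    return ",".join(f"{left}+{right}" for left, right in hit.enzymes)


def format_site_table(hits: Sequence[SiteHit]) -> str:
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["position", "sequence", "kind", "enzymes"])
    for hit in hits:
        writer.writerow([hit.position, hit.sequence, hit.kind, _hit_enzymes(hit)])
    return out.getvalue()


def format_site_report(hits: Sequence[SiteHit], source_name: str | None = None) -> str:
    """Human-readable site list; palindromic sites are marked by asterisks."""
    lines = []
    if source_name:
        lines.append(f"# {source_name}")
    lines.append(f"# {len(hits)} site occurrence(s)")
    for hit in hits:
        mark = " *" if hit.kind == PALINDROMIC else ""
        lines.append(f"{hit.position}\t{hit.sequence}\t{_hit_enzymes(hit)}{mark}")
    return "\n".join(lines) + "\n"


def _paren(name: str, flag: bool) -> str:
    return f"({name})" if flag and name else name


def format_plan_table(plan: AssemblyPlan) -> str:
    """Module table: number, coordinates, length and flanking enzymes.

    Primer-added terminal enzymes (vector sites, not genomic) appear in
    parentheses.
    """
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["module", "start", "end", "length", "five_re", "three_re"])
    for m in plan.modules:
        writer.writerow(
            [
                m.index,
                m.start,
                m.end,
                m.length,
                _paren(m.five_re, m.five_paren),
                _paren(m.three_re, m.three_paren),
            ]
        )
    return out.getvalue()


def parse_plan_table(text: str, enzymes: EnzymeSet) -> AssemblyPlan:
    """Rebuild an :class:`AssemblyPlan` from its emitted table."""
    reader = csv.reader(text.splitlines(), delimiter="\t")
    header = next(reader)
    if header[:4] != ["module", "start", "end", "length"]:
        raise MacPlanError("not a plan table")
    rows = []
    parens = []
    for rec in reader:
        if not rec:
            continue
        _idx, start, end, _length, five, three = rec[:6]
        parens.append((five.startswith("("), three.startswith("(")))
        rows.append(
            (int(start), int(end), five.strip("()"), three.strip("()"))
        )
    if not rows:
        raise MacPlanError("empty plan table")
    terminal_5 = enzymes.get(rows[0][2]) if parens[0][0] else None
    terminal_3 = enzymes.get(rows[-1][3]) if parens[-1][1] else None
    return build_plan_from_flanks(rows, enzymes, terminal_5, terminal_3)


def format_safety_report(report) -> str:
    if report.ok:
        return "OK: no unintended cuts.\n"
    lines = [f"{len(report.violations)} violation(s):"]
    for v in report.violations:
        lines.append(f"step {v.step}\t{v.enzyme}\tposition {v.position}\t{v.context}")
    return "\n".join(lines) + "\n"


def module_records(plan: AssemblyPlan, residues: str) -> list[SeqRecord]:
    """One record per module amplicon; primer-added bases are lowercase."""
    records = []
    for m in plan.modules:
        core = residues[m.start - 1 : m.end]
        seq = m.left_added.lower() + core + m.right_added.lower()
        records.append(
            SeqRecord(
                Seq(seq),
                id=f"module_{m.index}",
                description=f"{m.start}-{m.end} {m.five_re or '.'}/{m.three_re or '.'}",
            )
        )
    return records


def write_modules_fasta(plan: AssemblyPlan, residues: str, path: str | Path) -> None:
    with open(path, "w") as handle:
        seqio_write(module_records(plan, residues), handle, "fasta")


def write_text(path: str | Path, text: str) -> None:
    Path(path).write_text(text)
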