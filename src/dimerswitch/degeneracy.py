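"""Motif-alignment degeneracy report.

Compares aligned functional-motif sequences of several transporters (or
the two halves of one transporter) against a reference row and flags
degeneracy substitutions.  Column conservation marks follow the usual
multiple-alignment convention: ``*`` for columns identical across all
rows, ``:`` for strong similarity groups, ``.`` for weak groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

# Clustal strong / weak similarity groups
STRONG_GROUPS = ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF",
                 "HY", "FYW")
WEAK_GROUPS = ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
               "NDEQHK", "NEQHRK", "FVLIM", "HFY")


@dataclass
class MotifBlock:
    motif: str
    rows: list[tuple[str, str]]          # (row label, aligned residue string)
    reference: str                       # row label used as reference
    flags: dict[str, list[int]]          # row label -> 0-based flagged positions
    conservation: str                    # one mark per column


@dataclass
class MotifAlignment:
    blocks: list[MotifBlock]

    def block(self, motif: str) -> MotifBlock:
        for b in self.blocks:
            if b.motif == motif:
                return b
        raise KeyError(motif)


def _conservation_mark(column: str,
                       strong: Sequence[str] = STRONG_GROUPS,
                       weak: Sequence[str] = WEAK_GROUPS) -> str:
    residues = set(column)
    if len(residues) == 1 and "-" not in residues:
        return "*"
    if "-" in residues:
        return " "
    if any(residues <= set(g) for g in strong):
        return ":"
    if any(residues <= set(g) for g in weak):
        return "."
    return " "


def degeneracy_report(rows: Sequence[tuple[str, str, str]],
                      reference: Optional[str] = None,
                      strong: Sequence[str] = STRONG_GROUPS,
                      weak: Sequence[str] = WEAK_GROUPS) -> MotifAlignment:
    """Flag degeneracy substitutions in aligned motif blocks.

    ``rows`` is a flat list of ``(motif, row_label, aligned_sequence)``;
    motifs are processed independently.  Within each motif every row is
    compared position-by-position against the reference row (by default
    the first row of the block); differing positions are flagged.  Rows
    of one motif must have equal length.
    """
    by_motif: dict[str, list[tuple[str, str]]] = {}
    for motif, label, seq in rows:
        by_motif.setdefault(motif, []).append((label, seq.upper()))
    blocks = []
    for motif, motif_rows in by_motif.items():
        lengths = {len(seq) for _, seq in motif_rows}
        if len(lengths) != 1:
            raise ValueError(
                f"motif {motif!r}: aligned rows have unequal lengths {sorted(lengths)}")
        labels = [lab for lab, _ in motif_rows]
        ref_label = reference if reference in labels else labels[0]
        ref_seq = dict(motif_rows)[ref_label]
        flags = {}
        for lab, seq in motif_rows:
            flags[lab] = [i for i, (a, b) in enumerate(zip(seq, ref_seq))
                          if a != b]
        n = lengths.pop()
        cons = "".join(
            _conservation_mark("".join(seq[i] for _, seq in motif_rows),
                               strong, weak)
            for i in range(n))
        blocks.append(MotifBlock(motif, motif_rows, ref_label, flags, cons))
    return MotifAlignment(blocks)


def parse_alignment_text(text: str) -> list[tuple[str, str, str]]:
    """Parse a simple block alignment: blocks separated by blank lines,
    each optionally headed by ``# motif: NAME``, with ``label sequence``
    rows."""
    rows: list[tuple[str, str, str]] = []
    motif = "motif_1"
    counter = 1
    fresh = True
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            if not fresh:
                counter += 1
                motif = f"motif_{counter}"
                fresh = True
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("motif:"):
                motif = body.split(":", 1)[1].strip()
                fresh = False
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"cannot parse alignment row: {raw!r}")
        rows.append((motif, parts[0], parts[1]))
        fresh = False
    return rows


def format_report(alignment: MotifAlignment) -> str:
    """Plain-text report: aligned rows, degeneracy markers, conservation."""
    lines = []
    for b in alignment.blocks:
        width = max(len(lab) for lab, _ in b.rows)
        lines.append(f"motif: {b.motif} (reference: {b.reference})")
        for lab, seq in b.rows:
            marked = "".join(
                f"[{c}]" if i in b.flags[lab] else c
                for i, c in enumerate(seq))
            lines.append(f"  {lab:<{width}}  {marked}")
        lines.append(f"  {'':<{width}}  {b.conservation}")
        lines.append("")
    return "\n".join(lines)
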