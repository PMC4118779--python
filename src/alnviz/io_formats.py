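"""Input parsing and validation: aligned FASTA and Newick trees.

Sequence sets must be aligned before loading; this module only checks that
they are (equal lengths, legal residues) and that the optional Newick tree
names exactly the same labels as the alignment.  The Newick dialect accepted
is deliberately minimal: unquoted leaf labels, optional branch lengths, no
square-bracket comments, no internal-node labels.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = "-"

#: Legal residue symbols per alphabet (gap handled separately).  'N' and 'X'
#: are accepted as ambiguity codes and participate in variation detection
#: like any other symbol.
DNA_RESIDUES = frozenset("ACGTN")
PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class Alphabet(str, Enum):
    DNA = "dna"
    PROTEIN = "protein"

    @property
    def residues(self) -> frozenset[str]:
        return DNA_RESIDUES if self is Alphabet.DNA else PROTEIN_RESIDUES


class ParseError(ValueError):
    """Raised on malformed FASTA or Newick input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: label (header token up to first whitespace),
    residues (uppercased, gaps retained), optional free-text description."""

    label: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise ParseError("sequence record has an empty label")
        if not self.residues:
            raise ParseError(f"record '{self.label}' has an empty sequence")


@dataclass(frozen=True)
class AlignmentSet:
    """An ordered, labelled, equal-length set of aligned sequences."""

    records: tuple[SequenceRecord, ...]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.records:
            raise ParseError("alignment contains no sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            first = next(
                r for r in self.records
                if len(r.residues) != len(self.records[0].residues)
            )
            raise ParseError(
                f"ragged alignment: record '{first.label}' has length "
                f"{len(first.residues)}, expected {len(self.records[0].residues)}"
            )
        seen: set[str] = set()
        for r in self.records:
            if r.label in seen:
                raise ParseError(f"duplicate label '{r.label}'")
            seen.add(r.label)

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def sequence(self, label: str) -> str:
        for r in self.records:
            if r.label == label:
                return r.residues
        raise KeyError(label)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TreeNode:
    """A rooted tree node.  Leaves carry a non-empty name; internal nodes
    carry none.  Child order is meaningful (it defines row order)."""

    name: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    message: str
    subject: str = ""


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[Issue, ...]

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(text: str, alphabet: Alphabet) -> AlignmentSet:
    """Parse aligned multi-FASTA text into an :class:`AlignmentSet`.

    Sequences are uppercased; '.' gaps are normalised to '-'.  Raises
    :class:`ParseError` on empty input, duplicate labels, ragged lengths, or
    residues outside the declared alphabet.
    """
    if not text or not text.strip():
        raise ParseError("empty FASTA input")
    records: list[SequenceRecord] = []
    allowed = alphabet.residues | {GAP}
    try:
        parsed = list(SeqIO.parse(io.StringIO(text), "fasta"))
    except ValueError as exc:
        raise ParseError(f"no FASTA records found: {exc}") from exc
    for rec in parsed:
        residues = str(rec.seq).upper().replace(".", GAP)
        for pos, ch in enumerate(residues):
            if ch not in allowed:
                raise ParseError(
                    f"record '{rec.id}': illegal {alphabet.value} residue "
                    f"'{ch}' at position {pos + 1}"
                )
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, residues, desc))
    if not records:
        raise ParseError("no FASTA records found")
    return AlignmentSet(tuple(records), alphabet)


def write_fasta(alignment: AlignmentSet, width: int = 60) -> str:
    """Serialise an alignment as wrapped FASTA (LF line endings)."""
    chunks: list[str] = []
    for r in alignment.records:
        header = r.label if not r.description else f"{r.label} {r.description}"
        chunks.append(f">{header}")
        for i in range(0, len(r.residues), width):
            chunks.append(r.residues[i:i + width])
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# Newick (minimal dialect: unquoted labels, optional branch lengths)

_NAME_FORBIDDEN = set("(),:;[]'\" \t\n\r")


class _NewickCursor:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def error(self, msg: str) -> ParseError:
        return ParseError(f"Newick parse error at offset {self.pos}: {msg}")


def _parse_name(cur: _NewickCursor) -> str:
    if cur.peek() in ("'", '"'):
        raise cur.error("quoted labels are not supported")
    if cur.peek() == "[":
        raise cur.error("square-bracket comments are not supported")
    start = cur.pos
    while cur.peek() and cur.peek() not in _NAME_FORBIDDEN:
        cur.pos += 1
    return cur.text[start:cur.pos]


def _parse_branch_length(cur: _NewickCursor) -> Optional[float]:
    if cur.peek() != ":":
        return None
    cur.pos += 1
    start = cur.pos
    while cur.peek() and (cur.peek().isdigit() or cur.peek() in ".eE+-"):
        cur.pos += 1
    token = cur.text[start:cur.pos]
    try:
        value = float(token)
    except ValueError:
        raise cur.error(f"bad branch length '{token}'") from None
    if value < 0:
        raise cur.error(f"negative branch length {value}")
    return value


def _parse_subtree(cur: _NewickCursor) -> TreeNode:
    cur.skip_ws()
    if cur.peek() == "(":
        cur.pos += 1
        children = [_parse_subtree(cur)]
        cur.skip_ws()
        while cur.peek() == ",":
            cur.pos += 1
            children.append(_parse_subtree(cur))
            cur.skip_ws()
        if cur.peek() != ")":
            raise cur.error("expected ')' or ','")
        cur.pos += 1
        cur.skip_ws()
        label = _parse_name(cur)
        if label:
            raise cur.error(f"internal node label '{label}' is not supported")
        bl = _parse_branch_length(cur)
        return TreeNode(children=children, branch_length=bl)
    name = _parse_name(cur)
    if not name:
        raise cur.error("empty leaf name")
    bl = _parse_branch_length(cur)
    return TreeNode(name=name, branch_length=bl)


def parse_newick(text: str) -> TreeNode:
    """Parse a single rooted Newick statement (terminated by ';').

    Child order is preserved as written; branch lengths are captured when
    present.  Duplicate leaf names are an error.
    """
    if not text or not text.strip():
        raise ParseError("empty Newick input")
    cur = _NewickCursor(text)
    root = _parse_subtree(cur)
    cur.skip_ws()
    if cur.peek() != ";":
        raise cur.error("expected ';'")
    cur.pos += 1
    cur.skip_ws()
    if cur.pos != len(cur.text):
        raise cur.error("trailing characters after ';'")
    names = root.leaf_names()
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ParseError(f"duplicate leaf name '{n}'")
        seen.add(n)
    return root


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree back to Newick; ``parse_newick(write_newick(t))``
    reproduces topology, names and branch lengths exactly."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            core = node.name
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.branch_length is not None:
            core += f":{node.branch_length!r}"
        return core

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# Cross-file validation


def _all_gap_columns(alignment: AlignmentSet) -> list[int]:
    out = []
    for p in range(alignment.length):
        if all(r.residues[p] == GAP for r in alignment.records):
            out.append(p)
    return out


def validate_inputs(
    dna: Optional[AlignmentSet] = None,
    protein: Optional[AlignmentSet] = None,
    tree: Optional[TreeNode] = None,
) -> ValidationReport:
    """Check the cross-file label contract.

    Errors: tree leaves differ from alignment labels; DNA and protein label
    sets differ.  Warnings: all-gap columns.  Findings are collected into
    the report rather than raised.
    """
    if dna is None and protein is None:
        raise ValueError("at least one alignment must be supplied")
    issues: list[Issue] = []
    alignments = [a for a in (dna, protein) if a is not None]
    if dna is not None and protein is not None:
        d, p = set(dna.labels), set(protein.labels)
        for lbl in sorted(d - p):
            issues.append(Issue("error", "label missing from protein set", lbl))
        for lbl in sorted(p - d):
            issues.append(Issue("error", "label missing from DNA set", lbl))
    if tree is not None:
        leaf_set = set(tree.leaf_names())
        label_set = set(alignments[0].labels)
        for lbl in sorted(label_set - leaf_set):
            issues.append(Issue("error", f"tree missing label {lbl}", lbl))
        for lbl in sorted(leaf_set - label_set):
            issues.append(Issue("error", f"tree has extra leaf {lbl}", lbl))
    for aln in alignments:
        for p in _all_gap_columns(aln):
            issues.append(
                Issue("warning", f"{aln.alphabet.value} column {p + 1} is all gaps",
                      str(p + 1))
            )
    report = ValidationReport(tuple(issues))
    if not report.ok:
        logger.info("input validation failed: %d error(s)", len(report.errors))
    return report
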