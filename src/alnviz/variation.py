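"""Per-column variation detection and significance scoring.

A column is *variable* over a set of sequences when it holds at least two
distinct symbols (a gap counts as a symbol).  Significance is alphabet
specific:

* DNA — the column is *silent* if every sequence's frame-0 codon covering it
  translates to the same amino acid, *non-silent* otherwise.  Codons
  containing a gap or ambiguity code translate to UNKNOWN and force
  non-silent (conservative).
* Protein — the sum of BLOSUM80 substitution scores over all unordered
  pairs of sequences at that column; lower sums mean more dissimilar
  columns and are rendered darker.

Intensities are in [0, 1] with 0 = pale and 1 = dark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_formats import GAP, AlignmentSet, Alphabet

logger = logging.getLogger(__name__)

#: Pale shade used for silent DNA variation (the dark shade is 1.0).
DNA_PALE_INTENSITY = 0.35

STOP = "STOP"
UNKNOWN = "UNKNOWN"


class DnaClass(str, Enum):
    SILENT = "SILENT"
    NONSILENT = "NONSILENT"
    NA = "NA"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric amino-acid substitution lookup plus a gap score.

    The gap score — applied to any pair involving a gap — is the minimum
    off-diagonal entry of the matrix over residue letters, i.e. gaps are
    treated as maximally dissimilar.
    """

    name: str
    scores: dict[tuple[str, str], int]
    gap_score: int

    def score(self, a: str, b: str) -> int:
        if a == GAP or b == GAP:
            return self.gap_score
        return self.scores[(a, b)]


def load_blosum80() -> SubstitutionMatrix:
    """Load the bundled NCBI BLOSUM80 matrix."""
    path = resources.files("alnviz.data") / "BLOSUM80.txt"
    with resources.as_file(path) as p:
        arr = substitution_matrices.read(str(p))
    letters = [ch for ch in arr.alphabet if ch != "*"]
    scores = {
        (a, b): int(arr[a][b]) for a in letters for b in letters
    }
    gap_score = min(v for (a, b), v in scores.items() if a != b)
    return SubstitutionMatrix("BLOSUM80", scores, gap_score)


@dataclass(frozen=True)
class PositionAnnotation:
    position: int  # 0-based column
    variable: bool
    dna_class: DnaClass = DnaClass.NA
    blosum_score: Optional[int] = None
    intensity: float = 0.0


@dataclass(frozen=True)
class VariationProfile:
    """Per-column annotations for one alignment over one sequence subset."""

    alphabet: Alphabet
    subset: tuple[str, ...]
    annotations: tuple[PositionAnnotation, ...]

    @property
    def variable_positions(self) -> set[int]:
        return {a.position for a in self.annotations if a.variable}

    def __len__(self) -> int:
        return len(self.annotations)


# ---------------------------------------------------------------------------
# Subset semantics


def effective_subset(alignment: AlignmentSet, highlighted: Iterable[str]) -> list[str]:
    """Resolve a highlight selection to the labels indicators cover.

    Two or more highlighted sequences restrict variation indicators to the
    highlighted subset (returned in alignment order); zero or one highlight
    is a display-only emphasis and indicators still reflect all sequences.
    """
    highlighted = set(highlighted)
    known = set(alignment.labels)
    unknown = highlighted - known
    if unknown:
        raise KeyError(f"unknown highlighted label(s): {sorted(unknown)}")
    if len(highlighted) >= 2:
        return [lbl for lbl in alignment.labels if lbl in highlighted]
    return list(alignment.labels)


# ---------------------------------------------------------------------------
# Variable-column detection


def _subset_array(alignment: AlignmentSet, subset: Sequence[str]) -> np.ndarray:
    rows = [alignment.sequence(lbl) for lbl in subset]
    flat = "".join(rows).encode("ascii")
    return np.frombuffer(flat, dtype="S1").reshape(len(rows), alignment.length)

def variable_positions(alignment: AlignmentSet, subset: Sequence[str]) -> set[int]:
    """Columns whose symbols over ``subset`` are not all identical."""
    if not subset:
        raise ValueError("subset must be non-empty")
    arr = _subset_array(alignment, subset)
    diff = (arr != arr[0]).any(axis=0)
    return set(np.flatnonzero(diff).tolist())


# ---------------------------------------------------------------------------
# DNA: codon translation and silent / non-silent classification

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """Translate a 3-character DNA codon with the standard genetic code.

    Returns the one-letter amino acid, ``STOP``, or ``UNKNOWN`` when the
    codon contains a gap or ambiguity code.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got '{codon}'")
    codon = codon.upper()
    if any(ch not in "ACGT" for ch in codon):
        return UNKNOWN
    if codon in _STANDARD_TABLE.stop_codons:
        return STOP
    return _STANDARD_TABLE.forward_table[codon]


def classify_dna_position(
    alignment: AlignmentSet, position: int, subset: Sequence[str]
) -> DnaClass:
    """Classify a variable DNA column as SILENT or NONSILENT.

    The reading frame is frame 0 on aligned coordinates: the codon covering
    column p spans columns [3*(p//3), 3*(p//3)+3).  SILENT requires every
    subset codon to translate to one identical amino acid (all-STOP also
    counts); any UNKNOWN translation, or a STOP mixed with anything else,
    is NONSILENT.  Columns in a trailing partial codon are NONSILENT.
    """
    if alignment.alphabet is not Alphabet.DNA:
        raise ValueError("silent/non-silent classification requires a DNA alignment")
    if position not in variable_positions(alignment, subset):
        raise ValueError(f"position {position} is not variable over the subset")
    codon_start = 3 * (position // 3)
    if codon_start + 3 > alignment.length:
        logger.warning(
            "variable position %d lies in a trailing partial codon; "
            "classified NONSILENT", position + 1,
        )
        return DnaClass.NONSILENT
    translations = {
        translate_codon(alignment.sequence(lbl)[codon_start:codon_start + 3])
        for lbl in subset
    }
    if UNKNOWN in translations:
        return DnaClass.NONSILENT
    if len(translations) == 1:
        return DnaClass.SILENT  # includes the all-STOP case
    return DnaClass.NONSILENT


# ---------------------------------------------------------------------------
# Protein: BLOSUM80 pair-sum scoring


def position_blosum_score(
    alignment: AlignmentSet,
    position: int,
    subset: Sequence[str],
    matrix: SubstitutionMatrix,
) -> int:
    """Sum of substitution scores over all unordered sequence pairs at a column.

    Every pair of distinct sequences (i < j) contributes once, including
    pairs whose residues happen to be equal; pairs involving a gap score
    ``matrix.gap_score``.  Lower sums indicate more dissimilar columns.
    """
    if alignment.alphabet is not Alphabet.PROTEIN:
        raise ValueError("BLOSUM scoring requires a protein alignment")
    if len(subset) < 2:
        raise ValueError("BLOSUM scoring requires at least two sequences")
    column = [alignment.sequence(lbl)[position] for lbl in subset]
    total = 0
    for i in range(len(column)):
        for j in range(i + 1, len(column)):
            total += matrix.score(column[i], column[j])
    return total


def scale_intensities(scores: dict[int, int]) -> dict[int, float]:
    """Linearly map pair-sum scores to shade intensities in [0, 1].

    The minimum score (most dissimilar column) maps to 1 (dark), the
    maximum to 0 (pale).  When all scores are equal, every position is
    rendered dark (intensity 1).
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    lo, hi = min(scores.values()), max(scores.values())
    if lo == hi:
        return {p: 1.0 for p in scores}
    return {p: (hi - s) / (hi - lo) for p, s in scores.items()}


# ---------------------------------------------------------------------------
# Composition


def build_profile(
    alignment: AlignmentSet,
    highlighted: Iterable[str] = (),
    matrix: Optional[SubstitutionMatrix] = None,
    pale_intensity: float = DNA_PALE_INTENSITY,
) -> VariationProfile:
    """Compute the full per-column variation profile.

    DNA columns receive the discrete pale/dark pair (``pale_intensity`` for
    silent, 1.0 for non-silent); protein columns receive linearly scaled
    BLOSUM80 intensities.  Non-variable columns have intensity 0.
    """
    subset = effective_subset(alignment, highlighted)
    if alignment.alphabet is Alphabet.PROTEIN and matrix is None:
        raise ValueError("a substitution matrix is required for protein alignments")
    var = variable_positions(alignment, subset)
    logger.info(
        "profile: %d sequences (%d considered), %d columns, %d variable",
        len(alignment), len(subset), alignment.length, len(var),
    )

    annotations: list[PositionAnnotation] = [None] * alignment.length  # type: ignore
    for p in range(alignment.length):
        if p not in var:
            annotations[p] = PositionAnnotation(p, False)

    if alignment.alphabet is Alphabet.DNA:
        for p in sorted(var):
            cls = classify_dna_position(alignment, p, subset)
            intensity = 1.0 if cls is DnaClass.NONSILENT else pale_intensity
            annotations[p] = PositionAnnotation(p, True, cls, None, intensity)
    else:
        if len(subset) >= 2:
            scores = {
                p: position_blosum_score(alignment, p, subset, matrix)  # type: ignore[arg-type]
                for p in sorted(var)
            }
        else:
            scores = {}
        intensities = scale_intensities(scores) if scores else {}
        for p in sorted(var):
            annotations[p] = PositionAnnotation(
                p, True, DnaClass.NA, scores[p], intensities[p]
            )

    return VariationProfile(alignment.alphabet, tuple(subset), tuple(annotations))
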