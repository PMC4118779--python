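"""Deterministic synthetic fixtures with planted, known-class variation.

All sequences start as copies of one random base sequence; variation is then
*planted* at chosen columns so the ground truth (which columns vary, and
whether each DNA column is silent or non-silent) is known by construction:

* silent plants mutate the third position of a four-fold degenerate codon
  family (GGN, GCN, ... — any third base encodes the same amino acid) in a
  random non-empty proper subset of sequences;
* non-silent plants substitute a single amino-acid-changing base (DNA) or a
  different residue (protein) in such a subset;
* gap columns place '-' in such a subset (for DNA these classify non-silent,
  since a gapped codon cannot be translated).

This emulates the *shape* of real strain-variation data (mostly identical
sequences with sparse substitutions and indel columns), not an evolutionary
process: there is no substitution model, no rate heterogeneity, and planted
columns are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import GAP, AlignmentSet, Alphabet, SequenceRecord, TreeNode
from .variation import DnaClass, SubstitutionMatrix

#: Four-fold degenerate codon prefixes: any third base gives the same amino acid.
FOURFOLD_PREFIXES = ("GG", "GC", "GT", "CC", "CT", "CG", "AC", "TC")

#: Single-base codon swaps that change the encoded amino acid and avoid
#: stop codons: (codon_a, codon_b, differing position within codon).
NONSILENT_SWAPS = (
    ("GAA", "GGA", 1),  # Glu -> Gly
    ("TTG", "TCG", 1),  # Leu -> Ser
    ("ATG", "ACG", 1),  # Met -> Thr
    ("AAA", "AGA", 1),  # Lys -> Arg
    ("GAT", "GCT", 1),  # Asp -> Ala
    ("CAT", "CGT", 1),  # His -> Arg
    ("TTC", "TTA", 2),  # Phe -> Leu
    ("ATT", "GTT", 0),  # Ile -> Val
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureParams:
    n_sequences: int = 22
    length: int = 1731
    alphabet: Alphabet = Alphabet.DNA
    n_silent: int = 0       # DNA only: planted synonymous codons
    n_nonsilent: int = 0    # DNA: amino-acid-changing codons; protein: columns
    n_gap_columns: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be >= 1")
        if self.alphabet is Alphabet.PROTEIN and self.n_silent:
            raise ValueError("silent plants only apply to DNA fixtures")
        if self.alphabet is Alphabet.DNA and self.n_silent and self.length % 3:
            raise ValueError("silent planting requires length divisible by 3")
        n_plants = self.n_silent + self.n_nonsilent + self.n_gap_columns
        if n_plants and self.n_sequences < 2:
            raise ValueError("planting variation requires >= 2 sequences")


@dataclass(frozen=True)
class GroundTruth:
    variable_positions: frozenset[int]
    dna_class: dict[int, DnaClass] = field(default_factory=dict)
    blosum_score: dict[int, int] = field(default_factory=dict)


def _proper_subset(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random non-empty proper subset of row indices."""
    k = int(rng.integers(1, n))
    return rng.choice(n, size=k, replace=False)


def generate_alignment(
    params: FixtureParams,
    matrix: Optional[SubstitutionMatrix] = None,
) -> tuple[AlignmentSet, GroundTruth]:
    """Generate a seeded alignment and its by-construction ground truth.

    Identical params + seed give byte-identical output.  ``matrix`` is only
    consulted for protein fixtures, to record the expected pair-sum score of
    each planted column (by explicit pair enumeration).
    """
    rng = np.random.default_rng(params.seed)
    n, L = params.n_sequences, params.length
    if params.alphabet is Alphabet.DNA:
        base = rng.choice(list(DNA_BASES), size=L)
    else:
        base = rng.choice(list(AMINO_ACIDS), size=L)
    grid = np.tile(base, (n, 1))

    var_cols: set[int] = set()
    dna_class: dict[int, DnaClass] = {}

    if params.alphabet is Alphabet.DNA:
        n_codons = L // 3
        n_plant = params.n_silent + params.n_nonsilent
        if n_plant > n_codons:
            raise ValueError("requested plants exceed available codons")
        codons = rng.choice(n_codons, size=n_plant, replace=False)
        silent_codons, nonsilent_codons = codons[:params.n_silent], codons[params.n_silent:]

        for c in silent_codons:
            prefix = FOURFOLD_PREFIXES[int(rng.integers(len(FOURFOLD_PREFIXES)))]
            third = DNA_BASES[int(rng.integers(4))]
            alt = DNA_BASES[(DNA_BASES.index(third) + 1 + int(rng.integers(3))) % 4]
            grid[:, 3 * c:3 * c + 2] = list(prefix)
            grid[:, 3 * c + 2] = third
            grid[_proper_subset(rng, n), 3 * c + 2] = alt
            var_cols.add(int(3 * c + 2))
            dna_class[int(3 * c + 2)] = DnaClass.SILENT

        for c in nonsilent_codons:
            codon_a, codon_b, d = NONSILENT_SWAPS[int(rng.integers(len(NONSILENT_SWAPS)))]
            grid[:, 3 * c:3 * c + 3] = list(codon_a)
            rows = _proper_subset(rng, n)
            grid[rows, 3 * c + d] = codon_b[d]
            var_cols.add(int(3 * c + d))
            dna_class[int(3 * c + d)] = DnaClass.NONSILENT

        planted_codon_cols = {int(3 * c + i) for c in codons for i in range(3)}
    else:
        if params.n_nonsilent > L:
            raise ValueError("requested plants exceed available columns")
        cols = rng.choice(L, size=params.n_nonsilent, replace=False)
        for col in cols:
            ref = grid[0, col]
            alt = AMINO_ACIDS[(AMINO_ACIDS.index(ref) + 1
                               + int(rng.integers(len(AMINO_ACIDS) - 1)))
                              % len(AMINO_ACIDS)]
            grid[_proper_subset(rng, n), col] = alt
            var_cols.add(int(col))
        planted_codon_cols = set(var_cols)

    free = np.array(sorted(set(range(L)) - planted_codon_cols))
    if params.n_gap_columns > len(free):
        raise ValueError("requested gap columns exceed available columns")
    gap_cols = rng.choice(free, size=params.n_gap_columns, replace=False)
    for col in gap_cols:
        grid[_proper_subset(rng, n), col] = GAP
        var_cols.add(int(col))
        if params.alphabet is Alphabet.DNA:
            dna_class[int(col)] = DnaClass.NONSILENT

    width = len(str(n))
    records = tuple(
        SequenceRecord(f"s{i + 1:0{width}d}", "".join(grid[i]))
        for i in range(n)
    )
    alignment = AlignmentSet(records, params.alphabet)

    blosum: dict[int, int] = {}
    if params.alphabet is Alphabet.PROTEIN and matrix is not None:
        for col in sorted(var_cols):
            total = 0
            for i in range(n):
                for j in range(i + 1, n):
                    total += matrix.score(grid[i, col], grid[j, col])
            blosum[col] = total

    return alignment, GroundTruth(frozenset(var_cols), dna_class, blosum)


def generate_tree(labels: list[str], seed: int) -> TreeNode:
    """Random binary tree over ``labels`` with branch lengths in (0, 1].

    Deterministic per seed; duplicate labels are rejected.
    """
    if not labels:
        raise ValueError("at least one label required")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    rng = np.random.default_rng(seed)
    order = [labels[i] for i in rng.permutation(len(labels))]

    def bl() -> float:
        # (0, 1], rounded so Newick text is byte-stable
        return round(float(rng.uniform(1e-6, 1.0)), 6)

    def build(names: list[str]) -> TreeNode:
        if len(names) == 1:
            return TreeNode(name=names[0], branch_length=bl())
        k = int(rng.integers(1, len(names)))
        return TreeNode(children=[build(names[:k]), build(names[k:])],
                        branch_length=bl())

    root = build(order)
    return root
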