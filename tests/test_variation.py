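"""Variation detection, silent/non-silent classification, BLOSUM scoring."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from alnviz.io_formats import Alphabet
from alnviz.variation import (
    DNA_PALE_INTENSITY,
    STOP,
    UNKNOWN,
    DnaClass,
    build_profile,
    classify_dna_position,
    effective_subset,
    position_blosum_score,
    scale_intensities,
    translate_codon,
    variable_positions,
)

from conftest import make_alignment


def naive_variable_positions(seqs):
    """Independent oracle: per-column distinct-symbol count."""
    L = len(seqs[0])
    return {p for p in range(L) if len({s[p] for s in seqs}) >= 2}


def random_alignment(rng, n, L, alphabet=Alphabet.DNA, gap_frac=0.05):
    symbols = list("ACGT-") if alphabet is Alphabet.DNA else list("ACDEFGHIKLMNPQRSTVWYX-")
    probs = np.full(len(symbols), (1 - gap_frac) / (len(symbols) - 1))
    probs[-1] = gap_frac
    seqs = ["".join(rng.choice(symbols, size=L, p=probs)) for _ in range(n)]
    return make_alignment(seqs, alphabet)


class TestEffectiveSubset:
    def test_empty_and_singleton_mean_everyone(self):
        aln = make_alignment(["ACGT"] * 5)
        assert effective_subset(aln, set()) == aln.labels
        assert effective_subset(aln, {"s2"}) == aln.labels

    def test_two_or_more_restrict_in_alignment_order(self):
        aln = make_alignment(["ACGT"] * 5)
        assert effective_subset(aln, {"s4", "s1"}) == ["s1", "s4"]

    def test_unknown_label(self):
        aln = make_alignment(["ACGT"] * 2)
        with pytest.raises(KeyError):
            effective_subset(aln, {"nope", "s1"})


class TestVariablePositions:
    def test_identical_sequences_have_none(self):
        aln = make_alignment(["ACGT"] * 3)
        assert variable_positions(aln, aln.labels) == set()

    def test_single_differing_column(self):
        aln = make_alignment(["ACGT", "ACTT"])
        assert variable_positions(aln, aln.labels) == {2}

    def test_gap_counts_as_symbol(self):
        aln = make_alignment(["AC-T", "ACTT", "ACGT"])
        assert 2 in variable_positions(aln, aln.labels)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 20))
        L = int(rng.integers(10, 400))
        aln = random_alignment(rng, n, L)
        seqs = [r.residues for r in aln.records]
        assert variable_positions(aln, aln.labels) == naive_variable_positions(seqs)

    @pytest.mark.parametrize("seed", range(5))
    def test_subset_monotonicity(self, seed):
        rng = np.random.default_rng(100 + seed)
        aln = random_alignment(rng, 10, 200)
        full = variable_positions(aln, aln.labels)
        k = int(rng.integers(2, 9))
        subset = list(rng.choice(aln.labels, size=k, replace=False))
        assert variable_positions(aln, subset) <= full


class TestTranslateCodon:
    @pytest.mark.parametrize("codon,expected", [
        ("ATG", "M"), ("GGA", "G"), ("GGG", "G"), ("TAA", STOP),
        ("TGA", STOP), ("A-G", UNKNOWN), ("ANG", UNKNOWN), ("atg", "M"),
    ])
    def test_standard_code_and_sentinels(self, codon, expected):
        assert translate_codon(codon) == expected

    def test_wrong_length(self):
        with pytest.raises(ValueError):
            translate_codon("AT")


class TestClassifyDna:
    def _aln(self, codons, prefix="ATG"):
        # each sequence = fixed prefix + its codon, so position 3..5 is codon 1
        return make_alignment([prefix + c for c in codons])

    def test_synonymous_third_base_is_silent(self):
        aln = self._aln(["GGA", "GGG"])
        assert classify_dna_position(aln, 5, aln.labels) is DnaClass.SILENT

    def test_amino_acid_change_is_nonsilent(self):
        aln = self._aln(["GAA", "GGA"])
        assert classify_dna_position(aln, 4, aln.labels) is DnaClass.NONSILENT

    def test_gap_in_codon_is_nonsilent(self):
        aln = self._aln(["GG-", "GGG"])
        assert classify_dna_position(aln, 5, aln.labels) is DnaClass.NONSILENT

    def test_all_stop_is_silent_mixed_stop_is_not(self):
        all_stop = self._aln(["TAA", "TGA"])
        assert classify_dna_position(all_stop, 4, all_stop.labels) is DnaClass.SILENT
        mixed = self._aln(["TAT", "TAA"])  # Tyr vs STOP
        assert classify_dna_position(mixed, 5, mixed.labels) is DnaClass.NONSILENT

    def test_trailing_partial_codon_is_nonsilent(self):
        aln = make_alignment(["ATGC", "ATGA"])
        assert classify_dna_position(aln, 3, aln.labels) is DnaClass.NONSILENT

    def test_errors_on_protein_or_invariant_position(self):
        prot = make_alignment(["MK", "ML"], Alphabet.PROTEIN)
        with pytest.raises(ValueError):
            classify_dna_position(prot, 1, prot.labels)
        aln = self._aln(["GGA", "GGG"])
        with pytest.raises(ValueError):
            classify_dna_position(aln, 0, aln.labels)

    @pytest.mark.parametrize("seed", range(6))
    def test_metamorphic_flip(self, seed):
        """A silent column flips to NONSILENT when one codon's amino acid changes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        codons = ["GG" + "ACGT"[int(rng.integers(4))] for _ in range(n)]
        codons[0] = "GGA"
        codons[1] = "GGG"  # guarantee third-base variation
        aln = self._aln(codons)
        assert classify_dna_position(aln, 5, aln.labels) is DnaClass.SILENT
        flipped = codons.copy()
        flipped[int(rng.integers(n))] = "GAA"  # Glu, differs from Gly
        aln2 = self._aln(flipped)
        for p in (4, 5):
            if p in variable_positions(aln2, aln2.labels):
                assert classify_dna_position(aln2, p, aln2.labels) is DnaClass.NONSILENT


class TestBlosumScoring:
    def test_matches_brute_force_pairs(self, blosum80):
        aln = make_alignment(["ML", "MI", "MV"], Alphabet.PROTEIN)
        got = position_blosum_score(aln, 1, aln.labels, blosum80)
        b = substitution_matrices.load("BLOSUM80")  # independent source
        assert got == int(b["L"]["I"] + b["L"]["V"] + b["I"]["V"])

    def test_gap_pairs_use_gap_score(self, blosum80):
        aln = make_alignment(["MW", "M-", "MW"], Alphabet.PROTEIN)
        got = position_blosum_score(aln, 1, aln.labels, blosum80)
        assert got == blosum80.score("W", "W") + 2 * blosum80.gap_score

    def test_gap_score_is_min_offdiagonal(self, blosum80):
        b = substitution_matrices.load("BLOSUM80")
        letters = [ch for ch in b.alphabet if ch != "*"]
        expected = min(
            int(b[x][y]) for x in letters for y in letters if x != y
        )
        assert blosum80.gap_score == expected

    def test_permutation_invariance(self, blosum80):
        aln = make_alignment(["MA", "MC", "MD", "M-"], Alphabet.PROTEIN)
        ref = position_blosum_score(aln, 1, aln.labels, blosum80)
        for perm in (["s3", "s1", "s4", "s2"], ["s4", "s3", "s2", "s1"]):
            assert position_blosum_score(aln, 1, perm, blosum80) == ref

    @pytest.mark.parametrize("seed", range(8))
    def test_random_columns_against_enumeration(self, seed, blosum80):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        aln = random_alignment(rng, n, 30, Alphabet.PROTEIN, gap_frac=0.15)
        cols = [r.residues for r in aln.records]
        for p in variable_positions(aln, aln.labels):
            expected = 0
            for i in range(n):
                for j in range(i + 1, n):
                    expected += blosum80.score(cols[i][p], cols[j][p])
            assert position_blosum_score(aln, p, aln.labels, blosum80) == expected


class TestScaleIntensities:
    def test_endpoints(self):
        out = scale_intensities({1: -6, 2: 4})
        assert out == {1: 1.0, 2: 0.0}

    def test_degenerate_equal_scores_all_dark(self):
        assert scale_intensities({1: 5, 2: 5}) == {1: 1.0, 2: 1.0}

    def test_linear_midpoint(self):
        out = scale_intensities({1: -6, 2: -1, 3: 4})
        assert out[2] == pytest.approx(0.5, abs=1e-12)

    @given(st.lists(st.integers(-60, 60), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=60)
    def test_range_and_monotonicity(self, scores):
        mapping = dict(enumerate(scores))
        out = scale_intensities(mapping)
        assert all(0.0 <= v <= 1.0 for v in out.values())
        for a in mapping:
            for b in mapping:
                if mapping[a] < mapping[b]:
                    assert out[a] > out[b]


class TestBuildProfile:
    def test_identical_sequences_all_invariant(self):
        prof = build_profile(make_alignment(["ACGTAA"] * 4))
        assert all(not a.variable and a.intensity == 0 for a in prof.annotations)

    def test_dna_discrete_intensities(self):
        # codon 0: GGA/GGG silent; codon 1: GAA/GGA nonsilent
        aln = make_alignment(["GGAGAA", "GGGGGA"])
        prof = build_profile(aln)
        assert prof.annotations[2].dna_class is DnaClass.SILENT
        assert prof.annotations[2].intensity == pytest.approx(DNA_PALE_INTENSITY)
        assert prof.annotations[4].dna_class is DnaClass.NONSILENT
        assert prof.annotations[4].intensity == 1.0
        assert prof.annotations[0].blosum_score is None

    def test_protein_intensities_scaled(self, blosum80):
        aln = make_alignment(["MAW", "MCF", "MD-"], Alphabet.PROTEIN)
        prof = build_profile(aln, matrix=blosum80)
        var = [a for a in prof.annotations if a.variable]
        assert len(var) == 2
        assert {a.intensity for a in var} == {0.0, 1.0}
        assert all(a.dna_class is DnaClass.NA for a in prof.annotations)

    def test_protein_requires_matrix(self):
        aln = make_alignment(["MA", "MC"], Alphabet.PROTEIN)
        with pytest.raises(ValueError):
            build_profile(aln)

    def test_highlighted_pair_identical_sees_no_variation(self, blosum80):
        aln = make_alignment(["MAW", "MAW", "MCF"], Alphabet.PROTEIN)
        prof = build_profile(aln, highlighted={"s1", "s2"}, matrix=blosum80)
        assert prof.variable_positions == set()
        full = build_profile(aln, matrix=blosum80)
        assert full.variable_positions == {1, 2}

    def test_empty_highlight_equals_full_highlight(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, 8, 120)
        assert build_profile(aln) == build_profile(aln, highlighted=set(aln.labels))
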