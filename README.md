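# alnviz

Static variation reports for aligned sets of DNA or protein sequences.

Web databases often need to show many versions of the same gene or protein
at once — alleles in a population, the same locus across strains, homologs
across species. `alnviz` is a desk-scale Python reimplementation of the
computation behind that kind of sliding-window alignment viewer: given an
aligned FASTA file (and optionally a Newick tree describing a hierarchical
clustering of the sequences), it computes which alignment columns vary,
how *significant* each variable column is, and the full pixel geometry of
a whole-sequence navigation display — then renders everything to a
self-contained SVG or HTML report, or a machine-readable per-position TSV.

## What it computes

**Variable columns.** Column *p* is variable over a set of sequences *S*
when the multiset {sᵢ[p] : i ∈ S} contains ≥ 2 distinct symbols (a gap `-`
counts as a symbol). Highlighting ≥ 2 sequences restricts *S* to the
highlighted subset; highlighting one sequence is display-only emphasis.

**DNA significance.** Using frame 0 on aligned coordinates (codon *c* =
columns 3c…3c+2) and the standard genetic code, a variable column is
*silent* when every sequence's covering codon encodes the same amino acid,
and *non-silent* otherwise. Codons containing gaps or ambiguity codes are
untranslatable and conservatively classed non-silent. Silent columns render
pale (intensity 0.35), non-silent dark (1.0).

**Protein significance.** For each variable column the BLOSUM80 pair-sum

&nbsp;&nbsp;&nbsp;&nbsp;score(p) = Σ_{i<j} B(sᵢ[p], sⱼ[p])

over all unordered sequence pairs, with gap-containing pairs scoring the
matrix's minimum off-diagonal entry (−8). Scores are linearly rescaled so
the minimum (most dissimilar column) maps to intensity 1 (dark) and the
maximum to 0 (pale).

**Navigation geometry.** The whole alignment is compressed into a
fixed-width bar (default 500 px): each pixel column is a bin over a span of
alignment columns whose bar height is ⌈count/span · 20 px⌉ and whose shade
is the most significant variation in the span; a dashed box marks the
50-column viewing window. When the window's box would fall below 10 px the
plan switches to two nested bars, the inner one covering
⌊window·width/min_box⌋ = 2,500 columns centred on the window.

## Worked example

Generate a deterministic 22 × 1,731 DNA fixture with three planted silent
and two planted non-silent codons plus a matching 22-leaf tree, then render
a report:

```
$ alnviz fixture --seed 7 --n-sequences 22 --length 1731 \
    --n-silent 3 --n-nonsilent 2 --out-fasta demo.fa --out-newick demo.nwk
$ alnviz --dna-fasta demo.fa --newick demo.nwk --out demo.svg --log-level info
INFO alnviz: DNA alignment: 22 sequences x 1731 columns
INFO alnviz.variation: profile: 22 sequences (22 considered), 1731 columns, 5 variable
INFO alnviz.navigation: navigation: 1731 columns -> 1 level(s)
INFO alnviz.rendering: rendered SVG: 664 x 428 px, 22 rows, 1 nav level(s)
```

The five planted columns are recovered with their classes; the TSV export
(`--format tsv`, 1-based positions) shows exactly them:

```
$ alnviz --dna-fasta demo.fa --out demo.tsv --format tsv && grep true demo.tsv
8	true	NONSILENT	NA	1.0000
63	true	SILENT	NA	0.3500
663	true	SILENT	NA	0.3500
954	true	NONSILENT	NA	1.0000
1245	true	SILENT	NA	0.3500
```

At 1,731 columns the dashed window box is ≈14 px wide, so one navigation
bar suffices; rerunning with `--length 14733` produces a two-bar plan
(box would be ≈1.7 px) with a 2,500-column inner region. Passing
`--highlight LABEL` twice or more restricts all variation indicators to
the highlighted sequences and renders those rows colour-inverted.

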