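# Methods

## Scope and model

`alnviz` computes, for a pre-aligned set of labelled DNA or protein
sequences, a per-column *variation profile*, the pixel geometry of a
whole-sequence navigation display, and a dendrogram layout — and renders
them as static documents. It deliberately reproduces what an interactive
sliding-window viewer would show for one fixed window position;
interactivity (dragging, paging, tooltips) is out of scope, as is
performing the alignment or the clustering themselves.

## Variation detection

A column is variable over a sequence subset when it contains at least two
distinct symbols; the gap character `-` is a symbol like any other, so a
gap-versus-base column is variable. Detection is a vectorised
any-row-differs-from-row-0 test over a bytes matrix, which is equivalent to
a distinct-symbol count ≥ 2 and is verified against exactly that naive scan
in the tests.

Highlight semantics: a selection of ≥ 2 labels restricts the subset the
profile is computed over; zero or one selected labels leave the subset at
the full sequence set (a single highlight only affects row styling). From
this it follows that any subset profile's variable set is contained in the
full profile's — a property the tests check on random alignments.

## DNA significance: silent vs. non-silent

The reading frame is frame 0 on *aligned* coordinates: the codon covering
column p spans columns [3⌊p/3⌋, 3⌊p/3⌋+3). Translation uses the standard
genetic code (table 1). A variable column is SILENT when every considered
sequence's codon translates to one identical outcome — including the
all-stop case — and NONSILENT otherwise. Three conservative rules cover
the degenerate cases, all of which darken rather than lighten:

* a codon containing a gap or `N` is untranslatable (UNKNOWN) → NONSILENT;
* a stop codon mixed with any other outcome → NONSILENT;
* a variable column inside a trailing partial codon (alignment length not
  divisible by 3) → NONSILENT, with a logged warning.

These rules assume the alignment is an in-frame coding sequence; for
non-coding DNA the silent/non-silent distinction is not meaningful and
every variable column will simply render in one of the two shades.

## Protein significance: BLOSUM80 pair sums

For a variable column the score is the sum of BLOSUM80 entries over all
unordered pairs of distinct sequences (i < j), each pair counted once.
Pairs whose residues are equal are included — agreement between two
sequences legitimately dilutes the column's dissimilarity. Self-pairs are
excluded. Any pair involving a gap scores the matrix's minimum
off-diagonal entry (−8 for BLOSUM80), i.e. gaps are maximally dissimilar.

The matrix is bundled verbatim as `data/BLOSUM80.txt` in NCBI
whitespace-delimited format and parsed with
`Bio.Align.substitution_matrices.read`; it is the single source of truth
for all scores, and the test suite cross-checks it against an
independently loaded copy.

Scores map to shade intensities linearly: intensity(p) =
(max − score(p)) / (max − min), so the most dissimilar column is darkest
(1) and the least is palest (0). When all variable columns share one score
the map is degenerate and everything renders dark — one significance class
should not disappear into the background. DNA columns use the discrete
pair {0.35 pale, 1.0 dark}; the pale value is a rendering constant exposed
as a parameter of `build_profile`.

## Navigation geometry

Tunable constants (`ViewerConfig`): window_size = 50 columns,
canvas_width_px = 500, max_bar_height_px = 20, min_box_width_px = 10.
The defaults are artifact choices; the mechanism is what matters, and all
are CLI-configurable.

Binning tiles a region of R columns into W pixel bins with pixel k
covering [⌊kR/W⌋, ⌊(k+1)R/W⌋) — exact, gap-free tiling for every R/W
ratio including R < W (some bins empty), R = W (one column per pixel) and
R > W. Bin height is ⌈count/span · max_bar_height⌉ so any non-zero count
is visible at ≥ 1 px; bin shade is the maximum intensity in the span (the
most significant variation wins). Box geometry rounds half-up and floors
the width at 1 px.

Level decision: on a single bar the window box would be
window_size/L · canvas_width_px wide; at or above min_box_width_px one bar
is used, strictly below it two. The inner bar covers
min(L, ⌊window_size · canvas_width_px / min_box_width_px⌋) columns
(2,500 at the defaults), centred on the current window and clamped to the
alignment, recomputed per window position. The switch is exact at the
threshold: L = 2,500 gives one level, L = 2,501 gives two.

## Dendrogram

Row order is the depth-first, child-order-preserving leaf sequence of the
Newick tree and overrides FASTA order; without a tree, FASTA order is used
and the panel is omitted. Leaf i sits at y = i·row_height + row_height/2;
an internal node's y is the mean of its children's. Horizontal placement
is uniform depth scaling by default (root at x = 0, leaves pinned at the
panel edge), matching the usual cladogram aesthetic; an optional
branch-length mode places internal nodes at cumulative distance from the
root normalised to the panel width (leaves stay pinned) and requires every
branch length to be present. Each edge contributes one vertical and one
horizontal segment (right-angle elbows).

## Input handling

FASTA is parsed through Bio.SeqIO (wrapped or unwrapped lines); labels are
the header token up to the first whitespace, sequences are uppercased,
`.` gaps are normalised to `-`, and `N`/`X` ambiguity codes are legal
residues. Ragged lengths, duplicate labels, and out-of-alphabet characters
are hard errors naming the offending record and position.

The Newick dialect is deliberately minimal — unquoted labels, optional
non-negative branch lengths, no comments, no internal-node labels — and is
parsed by a small recursive-descent parser that reports character offsets;
the installed general-purpose parsers accept a wider dialect than the
contract here calls for, so one is used only as an independent round-trip
oracle in the tests. `write_newick` emits `repr`-exact branch lengths, so
parse∘write is an identity on topology, names and lengths.

Cross-file validation collects findings into a report rather than raising:
label-set mismatches between tree and alignment, or between DNA and
protein sets, are errors (CLI exit 2); all-gap columns are warnings.

## Synthetic fixtures

The generator emulates the *shape* of strain-variation data — a set of
near-identical sequences with sparse substitutions and indel columns — at
the documented display scales (the defaults are 22 sequences × 1,731
columns; 14,733 columns exercises the two-bar path). All sequences start
as copies of one uniform-random base sequence; variation is planted so the
ground truth is known by construction:

* silent plants use four-fold degenerate codon families (GGN, GCN, GTN,
  CCN, CTN, CGN, ACN, TCN), mutating the third base in a random non-empty
  proper subset of sequences — synonymy is guaranteed in frame 0;
* non-silent plants draw from a fixed table of single-base,
  amino-acid-changing, stop-free codon swaps;
* gap columns place `-` in a proper subset, away from planted codons so
  classes stay independent.

A single seeded `numpy` generator drives everything; identical parameters
and seed give byte-identical FASTA and Newick output. What passing
recovery tests show is that the pipeline finds exactly the planted columns
with the planted classes; they do not show robustness to properties the
generator lacks (realistic substitution processes, rate variation,
alignment error, overlapping variant columns within one codon).

## Numerical and rendering choices

Coordinates are 0-based half-open internally and 1-based in all
user-facing output (TSV, ruler, CLI `--window-start`). Box rounding is
half-up (`floor(x + 0.5)`), bin tiling is floor-based. The sequence panel
uses a fixed 10 × 16 px glyph cell so element positions are testable;
colours are pure red (navigation bins) and pure blue (column highlights)
with opacity equal to the profile intensity. Rendered documents expose
stable class names (`nav-bar`, `nav-bin`, `window-box`, `seq-row`,
`col-highlight`, `col-indicator`, `dendrogram`) as their machine-readable
surface. The HTML report is a self-contained XHTML5 document; with both a
DNA and a protein alignment present it embeds both SVGs behind anchor-based
(CSS `:target`) toggle links, so no scripting is needed.

## Problem sizes in the verification suite

The test suite and the reproduction script run random-alignment oracle
checks at up to 50 sequences × 2,000 columns (hundreds of draws), 1,000
random BLOSUM columns, 200 random trees, and full renders at the 1,731-
and 14,733-column display scales; these sizes exercise every code path
(including R < W, R = W, R > W binning) while keeping a full run to a few
seconds.

## Known limitations

* Silent/non-silent classification is only meaningful for in-frame coding
  DNA; there is no frame detection or frame option.
* The BLOSUM pair-sum treats every pair equally; no sequence weighting.
* Exactly one or two navigation levels are supported.
* SVG text metrics assume a monospace font at the fixed cell size;
  extremely long labels widen the panel rather than truncate.
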