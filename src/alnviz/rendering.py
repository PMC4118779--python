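"""Static SVG / HTML report assembly and per-position TSV export.

The report reproduces, for one fixed window position, exactly what the
interactive widget would show: navigation bar(s) with red variation bins
and a dashed window box on top; a dendrogram and label column bottom-left;
the windowed sequence panel with blue column highlights bottom-right.
Geometry uses a fixed 10x16 px glyph cell so every element position is
testable.  Element classes (``nav-bar``, ``nav-bin``, ``window-box``,
``seq-row``, ``col-highlight``, ``col-indicator``, ``dendrogram``) are the
stable machine-readable surface of the documents.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import dendrogram as dendro
from .io_formats import AlignmentSet, Alphabet, TreeNode
from .navigation import NavPlan, ViewerConfig, build_nav_plan
from .variation import (
    DnaClass,
    PositionAnnotation,
    SubstitutionMatrix,
    VariationProfile,
    build_profile,
)

logger = logging.getLogger(__name__)

GLYPH_W = 10   # px per sequence character cell
GLYPH_H = 16   # px per sequence row
PAD = 10       # outer margin
RULER_H = 14   # position-ruler strip height
IND_H = 6      # column-indicator block height
DENDRO_W = 100  # dendrogram panel width when a tree is present
RED = "#cc0000"
BLUE = "#3366cc"

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass(frozen=True)
class ReportSpec:
    """Everything needed to render one report."""

    dna: Optional[AlignmentSet] = None
    protein: Optional[AlignmentSet] = None
    tree: Optional[TreeNode] = None
    cfg: ViewerConfig = field(default_factory=ViewerConfig)
    highlighted: frozenset[str] = frozenset()
    active_alphabet: Alphabet = Alphabet.DNA
    window_start: int = 0
    use_branch_lengths: bool = False

    def __post_init__(self) -> None:
        if self.dna is None and self.protein is None:
            raise ValueError("at least one alignment required")
        if self.active(self.active_alphabet) is None:
            raise ValueError(
                f"active alphabet '{self.active_alphabet.value}' has no alignment"
            )

    def active(self, alphabet: Alphabet) -> Optional[AlignmentSet]:
        return self.dna if alphabet is Alphabet.DNA else self.protein


def _svg(tag: str, parent: Optional[ET.Element] = None, **attrs) -> ET.Element:
    el = ET.Element(tag) if parent is None else ET.SubElement(parent, tag)
    for k, v in attrs.items():
        el.set(k.replace("_", "-"), str(v))
    return el


def _fmt_intensity(x: float) -> str:
    return f"{x:.4f}"


# ---------------------------------------------------------------------------
# Sequence panel


def render_sequence_panel(
    alignment: AlignmentSet,
    profile: VariationProfile,
    window_start: int,
    cfg: ViewerConfig,
    highlighted: frozenset[str],
    row_order: Sequence[str],
) -> ET.Element:
    """Windowed sequence panel: 1-based ruler, blue indicator blocks and
    column shading for variable columns, fixed-width glyph rows (rows in
    ``row_order``; highlighted rows colour-inverted)."""
    L = alignment.length
    win_lo = max(0, min(window_start, max(0, L - cfg.window_size)))
    win_hi = min(L, win_lo + cfg.window_size)
    n_cols = win_hi - win_lo
    n_rows = len(row_order)
    rows_y0 = RULER_H + IND_H

    g = _svg("g", **{"class": "sequence-panel"})

    # ruler: 1-based positions every 10 columns
    for p in range(win_lo, win_hi):
        if (p + 1) % 10 == 0 or p == win_lo:
            t = _svg("text", g, x=(p - win_lo) * GLYPH_W, y=RULER_H - 3,
                     font_size=9, **{"class": "ruler-tick"})
            t.text = str(p + 1)

    # column highlights behind rows + indicator blocks above
    for p in range(win_lo, win_hi):
        ann = profile.annotations[p]
        if not ann.variable:
            continue
        x = (p - win_lo) * GLYPH_W
        _svg("rect", g, x=x, y=rows_y0, width=GLYPH_W, height=n_rows * GLYPH_H,
             fill=BLUE, fill_opacity=_fmt_intensity(ann.intensity),
             **{"class": "col-highlight"})
        _svg("rect", g, x=x, y=RULER_H, width=GLYPH_W, height=IND_H,
             fill=BLUE, fill_opacity=_fmt_intensity(max(ann.intensity, 0.2)),
             **{"class": "col-indicator"})

    # sequence rows
    for i, label in enumerate(row_order):
        y = rows_y0 + i * GLYPH_H
        inverted = label in highlighted
        classes = "seq-row highlighted" if inverted else "seq-row"
        row = _svg("g", g, **{"class": classes, "data-label": label})
        if inverted:
            _svg("rect", row, x=0, y=y, width=n_cols * GLYPH_W, height=GLYPH_H,
                 fill="#000000", **{"class": "row-invert"})
        seq = alignment.sequence(label)
        for k in range(n_cols):
            t = _svg("text", row, x=k * GLYPH_W + GLYPH_W // 2,
                     y=y + GLYPH_H - 4, text_anchor="middle",
                     font_family="monospace", font_size=12,
                     fill="#ffffff" if inverted else "#000000")
            t.text = seq[win_lo + k]
    return g


# ---------------------------------------------------------------------------
# Navigation bars


def _render_nav(plan: NavPlan, cfg: ViewerConfig) -> tuple[ET.Element, int]:
    """Render all nav tracks stacked vertically; returns (group, height)."""
    g = _svg("g", **{"class": "nav"})
    bar_h = cfg.max_bar_height_px + 2
    y = 0
    for track in plan.tracks:
        bar = _svg("g", g, **{"class": "nav-bar"})
        _svg("rect", bar, x=0, y=y, width=cfg.canvas_width_px, height=bar_h,
             fill="#f8f8f8", stroke="#999999", **{"class": "nav-frame"})
        baseline = y + bar_h - 1
        for k, b in enumerate(track.bins):
            if b.count == 0:
                continue
            _svg("rect", bar, x=k, y=baseline - b.height_px, width=1,
                 height=b.height_px, fill=RED,
                 fill_opacity=_fmt_intensity(b.intensity),
                 **{"class": "nav-bin"})
        bx, bw = track.box
        _svg("rect", bar, x=bx, y=y, width=bw, height=bar_h, fill="none",
             stroke="#000000", stroke_dasharray="3,2",
             **{"class": "window-box"})
        y += bar_h + 4
    return g, y


# ---------------------------------------------------------------------------
# Whole documents


def _translate(el: ET.Element, dx: float, dy: float) -> ET.Element:
    el.set("transform", f"translate({dx},{dy})")
    return el


def render_svg(spec: ReportSpec) -> str:
    """Render the full report for the active alphabet as an SVG document."""
    alignment = spec.active(spec.active_alphabet)
    assert alignment is not None
    matrix = None
    if spec.active_alphabet is Alphabet.PROTEIN:
        from .variation import load_blosum80
        matrix = load_blosum80()
    profile = build_profile(alignment, spec.highlighted, matrix)
    plan = build_nav_plan(profile, spec.window_start, spec.cfg)

    if spec.tree is not None:
        row_order: Sequence[str] = dendro.leaf_order(spec.tree)
    else:
        row_order = alignment.labels

    label_w = max(len(lbl) for lbl in row_order) * 8 + 10
    left_w = (DENDRO_W if spec.tree is not None else 0) + label_w
    panel_w = min(spec.cfg.window_size, alignment.length) * GLYPH_W
    width = PAD + left_w + PAD + max(panel_w, spec.cfg.canvas_width_px) + PAD

    root = _svg("svg", xmlns=SVG_NS, version="1.1")
    nav_g, nav_h = _render_nav(plan, spec.cfg)
    root.append(_translate(nav_g, PAD + left_w + PAD, PAD))

    body_y = PAD + nav_h + PAD
    n_rows = len(row_order)
    rows_y0 = RULER_H + IND_H

    if spec.tree is not None:
        lay = dendro.layout(spec.tree, GLYPH_H, DENDRO_W,
                            spec.use_branch_lengths)
        dg = _svg("g", **{"class": "dendrogram"})
        for (x1, y1, x2, y2) in lay.segments:
            _svg("line", dg, x1=x1, y1=y1, x2=x2, y2=y2,
                 stroke="#555555", **{"class": "dendro-edge"})
        root.append(_translate(dg, PAD, body_y + rows_y0))

    labels_g = _svg("g", **{"class": "labels"})
    for i, lbl in enumerate(row_order):
        t = _svg("text", labels_g, x=4,
                 y=i * GLYPH_H + GLYPH_H - 4, font_family="monospace",
                 font_size=11, **{"class": "seq-label"})
        t.text = lbl
    root.append(_translate(
        labels_g, PAD + (DENDRO_W if spec.tree is not None else 0),
        body_y + rows_y0))

    panel = render_sequence_panel(alignment, profile, spec.window_start,
                                  spec.cfg, spec.highlighted, row_order)
    root.append(_translate(panel, PAD + left_w + PAD, body_y))

    height = body_y + rows_y0 + n_rows * GLYPH_H + PAD
    root.set("width", str(width))
    root.set("height", str(height))
    logger.info("rendered SVG: %d x %d px, %d rows, %d nav level(s)",
                width, height, n_rows, plan.levels)
    return ET.tostring(root, encoding="unicode")


_HTML_TEMPLATE = """<!DOCTYPE html>
<html xmlns="http://www.w3.org/1999/xhtml" lang="en">
<head>
<meta charset="utf-8"/>
<title>Alignment variation report</title>
<style>
.view {{ display: none; }}
.view:target {{ display: block; }}
{default_css}
nav a {{ margin-right: 1em; }}
</style>
</head>
<body>
{toggle}
{views}
</body>
</html>
"""


def render_html(spec: ReportSpec) -> str:
    """Self-contained XHTML report embedding the SVG(s).

    With both a DNA and a protein alignment present, both SVGs are emitted
    with anchor-based (no-script) toggle links; otherwise a single view
    with no toggle.
    """
    views, names = [], []
    for alphabet in (Alphabet.DNA, Alphabet.PROTEIN):
        if spec.active(alphabet) is None:
            continue
        sub = ReportSpec(
            dna=spec.dna, protein=spec.protein, tree=spec.tree, cfg=spec.cfg,
            highlighted=spec.highlighted, active_alphabet=alphabet,
            window_start=spec.window_start,
            use_branch_lengths=spec.use_branch_lengths,
        )
        views.append(
            f'<div class="view" id="{alphabet.value}">\n{render_svg(sub)}\n</div>'
        )
        names.append(alphabet.value)

    if len(names) > 1:
        toggle = "<nav>" + "".join(
            f'<a href="#{n}">View {n.upper() if n == "dna" else n}</a>'
            for n in names
        ) + "</nav>"
    else:
        toggle = ""
    default_css = (
        f"#{spec.active_alphabet.value}"
        " { display: block; }\n"
        f".view:target ~ #{spec.active_alphabet.value}:not(:target)"
        " { display: none; }"
    )
    return _HTML_TEMPLATE.format(
        toggle=toggle, views="\n".join(views), default_css=default_css
    )


# ---------------------------------------------------------------------------
# TSV export


TSV_HEADER = "position\tvariable\tclass\tscore\tintensity"


def export_profile_tsv(profile: VariationProfile) -> str:
    """Machine-readable per-position table (1-based positions, LF, UTF-8)."""
    lines = [TSV_HEADER]
    for a in profile.annotations:
        cls = a.dna_class.value if a.variable else DnaClass.NA.value
        score = "NA" if a.blosum_score is None else str(a.blosum_score)
        lines.append(
            f"{a.position + 1}\t{'true' if a.variable else 'false'}\t"
            f"{cls}\t{score}\t{a.intensity:.4f}"
        )
    return "\n".join(lines) + "\n"


def profile_from_tsv(
    text: str, alphabet: Alphabet, subset: Sequence[str]
) -> VariationProfile:
    """Reconstruct a profile from :func:`export_profile_tsv` output."""
    lines = text.rstrip("\n").split("\n")
    if lines[0] != TSV_HEADER:
        raise ValueError("unrecognised TSV header")
    annotations = []
    for line in lines[1:]:
        pos_s, var_s, cls_s, score_s, int_s = line.split("\t")
        annotations.append(PositionAnnotation(
            position=int(pos_s) - 1,
            variable=var_s == "true",
            dna_class=DnaClass(cls_s),
            blosum_score=None if score_s == "NA" else int(score_s),
            intensity=float(int_s),
        ))
    return VariationProfile(alphabet, tuple(subset), tuple(annotations))
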