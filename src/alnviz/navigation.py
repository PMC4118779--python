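"""Whole-sequence navigation-bar geometry.

The navigation bar compresses the full alignment into a fixed pixel width:
each pixel column is a bin summarising a span of alignment columns (count of
variable positions -> bar height; most significant variation -> shade), and
a dashed box marks the window currently shown at glyph resolution.  When the
alignment is so long that the window's box would be narrower than a usable
minimum, a second, zoomed-in bar is added: the top bar's box marks the
region the second bar depicts, and the second bar's box marks the window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from .variation import VariationProfile

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class ViewerConfig:
    """Pixel-geometry constants; all configurable, defaults are artifact
    choices (the mechanism, not the numbers, is what matters)."""

    window_size: int = 50          # columns shown at glyph resolution
    canvas_width_px: int = 500     # nav-bar width
    max_bar_height_px: int = 20    # height of a full bin
    min_box_width_px: int = 10     # below this the dashed box is "too narrow"

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.canvas_width_px < 1 or self.max_bar_height_px < 1:
            raise ValueError("pixel dimensions must be positive")
        if not (1 <= self.min_box_width_px <= self.canvas_width_px):
            raise ValueError("min_box_width_px must be in [1, canvas_width_px]")


@dataclass(frozen=True)
class NavBin:
    start: int        # 0-based half-open column span
    end: int
    count: int        # variable positions inside the span
    height_px: int
    intensity: float  # max annotation intensity in the span


@dataclass(frozen=True)
class NavTrack:
    region: tuple[int, int]       # columns this bar depicts, half-open
    bins: tuple[NavBin, ...]      # one per pixel column
    box: tuple[int, int]          # (x_px, width_px) of the dashed box


@dataclass(frozen=True)
class NavPlan:
    tracks: tuple[NavTrack, ...]  # top-level first

    @property
    def levels(self) -> int:
        return len(self.tracks)


def decide_levels(length: int, cfg: ViewerConfig) -> tuple[int, Optional[int]]:
    """Decide one- vs two-level navigation for an alignment of ``length``.

    On a single bar the dashed box would be window_size/length of the
    canvas; if that is at least ``min_box_width_px`` one bar suffices.
    Otherwise a second bar is used over a region of
    ``min(length, floor(window_size * canvas_width_px / min_box_width_px))``
    columns — the largest region that keeps the innermost box usable.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    box_px = cfg.window_size / length * cfg.canvas_width_px
    if box_px >= cfg.min_box_width_px:
        return 1, None
    region = min(
        length, cfg.window_size * cfg.canvas_width_px // cfg.min_box_width_px
    )
    return 2, int(region)


def bin_track(
    profile: VariationProfile, region: tuple[int, int], cfg: ViewerConfig
) -> tuple[NavBin, ...]:
    """Tile ``region`` into one bin per pixel column.

    Pixel k covers columns [start + floor(k*R/W), start + floor((k+1)*R/W))
    (exact tiling for every R/W ratio).  height uses ceil of the variable
    fraction so any non-zero count is visible at >= 1 px; shade is the max
    intensity in the span.
    """
    start, end = region
    if end <= start:
        raise ValueError("empty region")
    R = end - start
    W = cfg.canvas_width_px
    annotations = profile.annotations
    bins: list[NavBin] = []
    for k in range(W):
        lo = start + (k * R) // W
        hi = start + ((k + 1) * R) // W
        span = annotations[lo:hi]
        count = sum(1 for a in span if a.variable)
        if count:
            height = math.ceil(count / (hi - lo) * cfg.max_bar_height_px)
            intensity = max(a.intensity for a in span if a.variable)
        else:
            height, intensity = 0, 0.0
        bins.append(NavBin(lo, hi, count, height, intensity))
    return tuple(bins)


def _span_box(
    region: tuple[int, int], span_start: int, span_len: int, cfg: ViewerConfig
) -> tuple[int, int]:
    start, end = region
    R = end - start
    x = _round_half_up((span_start - start) / R * cfg.canvas_width_px)
    w = max(1, _round_half_up(span_len / R * cfg.canvas_width_px))
    return x, w


def box_geometry(
    region: tuple[int, int], window_start: int, cfg: ViewerConfig
) -> tuple[int, int]:
    """Dashed-box (x_px, width_px) for the viewing window on a bar
    depicting ``region``.  Rounding is half-up; width is at least 1 px."""
    return _span_box(region, window_start, cfg.window_size, cfg)


def _clamp(x: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, x))


def build_nav_plan(
    profile: VariationProfile, window_start: int, cfg: ViewerConfig
) -> NavPlan:
    """Assemble the one- or two-level navigation plan.

    With two levels the inner region is centred on the current window and
    clamped to the alignment; the top bar's box depicts that region while
    the inner bar's box depicts the window itself.
    """
    L = len(profile)
    window_start = _clamp(window_start, 0, max(0, L - cfg.window_size))
    levels, region_size = decide_levels(L, cfg)
    logger.info(
        "navigation: %d columns -> %d level(s)%s", L, levels,
        f", inner region {region_size} columns" if levels == 2 else "",
    )
    full = (0, L)
    if levels == 1:
        track = NavTrack(full, bin_track(profile, full, cfg),
                         box_geometry(full, window_start, cfg))
        return NavPlan((track,))

    assert region_size is not None
    r_start = _clamp(
        window_start + cfg.window_size // 2 - region_size // 2,
        0, L - region_size,
    )
    inner_region = (r_start, r_start + region_size)
    top = NavTrack(
        full, bin_track(profile, full, cfg),
        _span_box(full, r_start, region_size, cfg),
    )
    inner = NavTrack(
        inner_region, bin_track(profile, inner_region, cfg),
        box_geometry(inner_region, window_start, cfg),
    )
    return NavPlan((top, inner))
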