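"""Aggregate loop stacks and pixel-window scores.

Aggregate peak analysis (APA) measures collective loop strength by stacking
local contact-map windows centered on many loop pixels (conventionally
21x21 bins at 10 kb, i.e. a 210 kb x 210 kb neighbourhood) and summarizing
them per pixel.  Orientation contract: row index = 5' (smaller-coordinate)
anchor, column index = 3' anchor, so "lower right" means larger row AND
larger column (toward longer-range pixels away from the diagonal on both
axes) and "top right" means smaller row, larger column.

Scores:
  * apa_score  — center pixel / mean of the 5x5 lower-right corner block
  * meta_score — center pixel / median of the 2x2 top-right corner block
  * corner_categories — per-corner average-signal differences between two
    conditions: top-left (category 1, inside-outside left of the loop),
    bottom-right (category 2, inside-outside right), top-right
    (category 3, crossing over the loop).

The scaled multi-anchor metaplot rescales the inter-anchor span of every
loop to 10 equal bins (length-weighted pixel averaging) with unscaled
flanks, compares two conditions per loop (subtraction or log2 fold change)
and takes the per-pixel median across loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contactio import ContactMatrix, GenomeLayout, Loop

DEFAULT_FLANK = 10       # bins on each side of the loop pixel
CORNER = 5               # corner block side for apa_score / categories
META_CORNER = 2          # corner block side for meta_score
LOG2FC_PSEUDO = 1e-6     # pseudocount applied to non-positive pixels
SCALED_BINS = 10         # inter-anchor span bins in scaled metaplots


@dataclass
class APAStack:
    """Stack of per-loop (2*flank+1)^2 windows with a per-pixel aggregate."""

    windows: np.ndarray        # (n_loops, w, w)
    aggregate: np.ndarray      # (w, w)
    stat: str
    n_loops: int
    n_dropped: int

    @property
    def flank(self) -> int:
        return (self.aggregate.shape[0] - 1) // 2


def _loop_pixels(loops: list[Loop], layout: GenomeLayout) -> np.ndarray:
    return np.array([lp.bins(layout) for lp in loops], dtype=int).reshape(-1, 2)


def build_apa_stack(dense: np.ndarray, loops: list[Loop],
                    layout: GenomeLayout, flank_bins: int = DEFAULT_FLANK,
                    stat: str = "median") -> APAStack:
    """Stack windows of a dense symmetric per-chromosome map around loops.

    ``dense`` is the full symmetric map in whatever normalization the
    caller chose (conventionally VCsqrt O/E).  Loops whose window would
    cross the diagonal or the chromosome edge are dropped and counted.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be median or mean")
    n = dense.shape[0]
    w = 2 * flank_bins + 1
    px = _loop_pixels(loops, layout)
    wins, dropped = [], 0
    for bi, bj in px:
        if (bj - bi) <= 2 * flank_bins or bi < flank_bins or bj >= n - flank_bins:
            dropped += 1
            continue
        wins.append(dense[bi - flank_bins: bi + flank_bins + 1,
                          bj - flank_bins: bj + flank_bins + 1])
    if not wins:
        raise ValueError("no loops retained for APA stack")
    windows = np.stack(wins)
    agg = (np.median(windows, axis=0) if stat == "median"
           else windows.mean(axis=0))
    assert agg.shape == (w, w)
    return APAStack(windows, agg, stat, len(wins), dropped)


def apa_score(stack: APAStack, corner: str = "lower_right") -> float:
    """Center pixel over the mean of the 5x5 corner block.

    The reference corner is the lower-right block (rows/cols 16-20 of a
    21x21 window); ``corner="lower_left"`` selects the alternative
    convention.  Returns NaN when the corner mean is non-positive.
    """
    a = stack.aggregate
    c = a.shape[0] // 2
    if corner == "lower_right":
        block = a[-CORNER:, -CORNER:]
    elif corner == "lower_left":
        block = a[-CORNER:, :CORNER]
    else:
        raise ValueError(f"unknown corner {corner!r}")
    denom = block.mean()
    if denom <= 0:
        return float("nan")
    return float(a[c, c] / denom)


def meta_score(stack: APAStack) -> float:
    """Center pixel over the median of the four top-right corner bins."""
    a = stack.aggregate
    c = a.shape[0] // 2
    denom = float(np.median(a[:META_CORNER, -META_CORNER:]))
    if denom == 0:
        return float("nan")
    return float(a[c, c] / denom)


def corner_categories(stack_a: APAStack, stack_b: APAStack) -> tuple[float, float, float]:
    """Per-corner average-signal differences (b minus a).

    Category 1 = top-left 5x5, category 2 = bottom-right 5x5,
    category 3 = top-right 5x5.
    """
    if stack_a.aggregate.shape != stack_b.aggregate.shape:
        raise ValueError("APA window geometry mismatch")
    diff = stack_b.aggregate - stack_a.aggregate
    cat1 = float(diff[:CORNER, :CORNER].mean())
    cat2 = float(diff[-CORNER:, -CORNER:].mean())
    cat3 = float(diff[:CORNER, -CORNER:].mean())
    return cat1, cat2, cat3


# ---------------------------------------------------------------------------
# Scaled multi-anchor metaplots
# ---------------------------------------------------------------------------

@dataclass
class ScaledLoopMatrix:
    """Median-across-loops comparison matrix on a common scaled grid."""

    summary: np.ndarray     # (grid, grid)
    mode: str
    n_loops: int
    n_dropped: int
    flank_bins: int
    scaled_bins: int


def _scaling_weights(n_source: int, n_target: int) -> np.ndarray:
    """Length-weighted averaging matrix W (n_target x n_source).

    Target bin t covers source coordinate [t*r, (t+1)*r) with
    r = n_source/n_target; each source bin contributes in proportion to its
    overlap with the target bin, and rows are normalized to sum to 1.
    """
    r = n_source / n_target
    W = np.zeros((n_target, n_source))
    for t in range(n_target):
        lo, hi = t * r, (t + 1) * r
        s0, s1 = int(np.floor(lo)), int(np.ceil(hi))
        for s in range(s0, min(s1, n_source)):
            W[t, s] = min(hi, s + 1) - max(lo, s)
    W /= W.sum(axis=1, keepdims=True)
    return W


def rescale_window(window: np.ndarray, span_bins: int, flank_bins: int,
                   scaled_bins: int = SCALED_BINS) -> np.ndarray:
    """Rescale a (flank+span+flank)^2 window to a fixed grid.

    The inter-anchor span axis is compressed/stretched to ``scaled_bins``
    bins by length-weighted averaging on both axes; the flanks map 1:1.
    """
    exp = 2 * flank_bins + span_bins
    if window.shape != (exp, exp):
        raise ValueError("window shape does not match span/flank geometry")
    grid = 2 * flank_bins + scaled_bins
    W = np.zeros((grid, exp))
    W[:flank_bins, :flank_bins] = np.eye(flank_bins)
    W[flank_bins: flank_bins + scaled_bins, flank_bins: flank_bins + span_bins] = \
        _scaling_weights(span_bins, scaled_bins)
    W[flank_bins + scaled_bins:, flank_bins + span_bins:] = np.eye(flank_bins)
    return W @ window @ W.T


def scaled_multi_anchor_metaplot(dense_a: np.ndarray, dense_b: np.ndarray,
                                 loops: list[Loop], layout: GenomeLayout,
                                 mode: str = "subtract",
                                 flank_bins: int = DEFAULT_FLANK,
                                 scaled_bins: int = SCALED_BINS) -> ScaledLoopMatrix:
    """Per-loop scaled comparison of two maps, median-summarized.

    For each loop the local window spanning [anchor1 − flank, anchor2 +
    flank] is extracted from both maps, the inter-anchor span is rescaled
    to ``scaled_bins`` equal bins, the per-loop comparison (subtract or
    log2fc of b over a) is computed, and the per-pixel median across loops
    is returned.  Loops spanning fewer than ``scaled_bins`` source bins are
    dropped and counted.
    """
    if mode not in ("subtract", "log2fc"):
        raise ValueError("mode must be subtract or log2fc")
    if dense_a.shape != dense_b.shape:
        raise ValueError("matrix shape mismatch")
    n = dense_a.shape[0]
    per_loop, dropped = [], 0
    for lp in loops:
        bi, bj = lp.bins(layout)
        span = bj - bi
        if span < scaled_bins or bi - flank_bins < 0 or bj + flank_bins >= n:
            dropped += 1
            continue
        sl = slice(bi - flank_bins, bj + flank_bins + 1)
        # window is (span+2*flank+1)^2; drop the final row/col so the span
        # region covers exactly `span` source bins between the anchors
        wa = dense_a[sl, sl][:-1, :-1]
        wb = dense_b[sl, sl][:-1, :-1]
        ra = rescale_window(wa, span, flank_bins, scaled_bins)
        rb = rescale_window(wb, span, flank_bins, scaled_bins)
        if mode == "subtract":
            per_loop.append(rb - ra)
        else:
            ra = np.where(ra > 0, ra, LOG2FC_PSEUDO)
            rb = np.where(rb > 0, rb, LOG2FC_PSEUDO)
            per_loop.append(np.log2(rb / ra))
    if not per_loop:
        raise ValueError("no loops retained for scaled metaplot")
    summary = np.median(np.stack(per_loop), axis=0)
    return ScaledLoopMatrix(summary, mode, len(per_loop), dropped,
                            flank_bins, scaled_bins)
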