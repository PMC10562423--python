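"""Anchor-level annotation of chromatin loops.

Covers four analyses at the loop-anchor level:

* peak co-occupancy — for each loop, does a factor (CTCF, RAD21, ...) have
  a peak at both, one or neither anchor, using +/- 5 kb padded anchors;
* a shuffle-based overlap significance test — peaks are relocated
  uniformly within their chromosome (lengths preserved) 1000 times and the
  anchor-overlap ratio recomputed, giving an empirical expected ratio and
  p-values;
* the anchor-change taxonomy of newly formed loops against the previous
  stage: both anchors new / extension of one retained anchor to a more
  distal partner / a prior anchor pairing with a new internal anchor that
  splits the region / other;
* ranking of loops by the position of an internal cohesin-loading site
  (NIPBL co-occupied with RAD21 strictly inside the loop span), with the
  site position rescaled to a common [0, 1] coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contactio import GenomeLayout, Loop, PeakSet, interval_overlaps

ANCHOR_PAD = 5_000       # bp added on each side of an anchor
N_SHUFFLES = 1000
MATCH_TOLERANCE = 1      # bins: anchors within this are "the same site"


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------

@dataclass
class AnchorAnnotation:
    """Per-loop occupancy class for one factor plus cohort fractions."""

    factor: str
    classes: np.ndarray         # "both" | "one" | "none" per loop
    anchor_hits: np.ndarray     # (n_loops, 2) bool
    fractions: dict[str, float]


def annotate_occupancy(loops: list[Loop], peaks: PeakSet,
                       anchor_pad: int = ANCHOR_PAD) -> AnchorAnnotation:
    """Classify each loop by peak presence at its padded anchors."""
    n = len(loops)
    hits = np.zeros((n, 2), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, lp in enumerate(loops):
        by_chrom.setdefault(lp.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        s1 = np.array([max(0, loops[i].start1 - anchor_pad) for i in idxs])
        e1 = np.array([loops[i].end1 + anchor_pad for i in idxs])
        s2 = np.array([max(0, loops[i].start2 - anchor_pad) for i in idxs])
        e2 = np.array([loops[i].end2 + anchor_pad for i in idxs])
        hits[idxs, 0] = interval_overlaps(peaks.intervals, chrom, s1, e1)
        hits[idxs, 1] = interval_overlaps(peaks.intervals, chrom, s2, e2)
    n_hit = hits.sum(axis=1)
    classes = np.where(n_hit == 2, "both", np.where(n_hit == 1, "one", "none"))
    fractions = {c: float((classes == c).mean()) if n else 0.0
                 for c in ("both", "one", "none")}
    return AnchorAnnotation(peaks.name, classes, hits, fractions)


# ---------------------------------------------------------------------------
# Shuffle overlap test
# ---------------------------------------------------------------------------

@dataclass
class ShuffleResult:
    observed_ratio: float
    expected_ratio: float       # mean over shuffles
    p_literal: float            # #(observed < shuffled) / n
    p_enrichment: float         # (1 + #(shuffled >= observed)) / (n + 1)
    n_shuffles: int


def _anchor_intervals(loops: list[Loop], anchor_pad: int) -> pd.DataFrame:
    rows = []
    for lp in loops:
        rows.append((lp.chrom, max(0, lp.start1 - anchor_pad), lp.end1 + anchor_pad))
        rows.append((lp.chrom, max(0, lp.start2 - anchor_pad), lp.end2 + anchor_pad))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _overlap_ratio(anchors: pd.DataFrame, peaks: pd.DataFrame) -> float:
    hit = np.zeros(len(anchors), dtype=bool)
    for chrom, sub in anchors.groupby("chrom", sort=False):
        hit[sub.index.to_numpy()] = interval_overlaps(
            peaks, chrom, sub["start"].to_numpy(), sub["end"].to_numpy())
    return float(hit.mean()) if len(anchors) else 0.0


def shuffle_overlap_test(loops: list[Loop], peaks: PeakSet,
                         layout: GenomeLayout, seed: int,
                         n_shuffles: int = N_SHUFFLES,
                         anchor_pad: int = ANCHOR_PAD) -> ShuffleResult:
    """Empirical overlap significance by chromosome-restricted shuffling.

    The observed statistic is the fraction of padded anchors overlapping
    at least one peak.  Each shuffle relocates every peak uniformly within
    its own chromosome, length preserved, no non-overlap constraint.  Two
    p-values are reported: the literal depletion-style count
    #(observed < shuffled)/n, and a +1-corrected enrichment p-value
    (1 + #(shuffled >= observed)) / (n + 1).
    """
    anchors = _anchor_intervals(loops, anchor_pad).reset_index(drop=True)
    pk = peaks.intervals[["chrom", "start", "end"]].reset_index(drop=True)
    lengths = (pk["end"] - pk["start"]).to_numpy()
    chrom_size = pk["chrom"].map(dict(layout.chrom_sizes)).to_numpy()
    if np.any(lengths > chrom_size):
        bad = pk["chrom"][lengths > chrom_size].iloc[0]
        raise ValueError(f"peak longer than chromosome {bad}")
    observed = _overlap_ratio(anchors, pk)
    rng = np.random.default_rng(seed)
    max_start = chrom_size - lengths
    n_ge, n_gt_obs, acc = 0, 0, 0.0
    for _ in range(n_shuffles):
        starts = rng.integers(0, max_start + 1)
        shuf = pd.DataFrame({"chrom": pk["chrom"],
                             "start": starts, "end": starts + lengths})
        r = _overlap_ratio(anchors, shuf)
        acc += r
        if r >= observed:
            n_ge += 1
        if observed < r:
            n_gt_obs += 1
    return ShuffleResult(
        observed_ratio=observed,
        expected_ratio=acc / n_shuffles,
        p_literal=n_gt_obs / n_shuffles,
        p_enrichment=(1 + n_ge) / (n_shuffles + 1),
        n_shuffles=n_shuffles,
    )


# ---------------------------------------------------------------------------
# Anchor-change taxonomy
# ---------------------------------------------------------------------------

CATEGORIES = ("both_anchors_new", "extension_one_anchor",
              "paired_new_anchor_split", "other")


@dataclass
class TaxonomyCall:
    loop: Loop
    category: str
    evidence: dict


def _match(bin_a: int, bin_b: int, tol: int) -> bool:
    return abs(bin_a - bin_b) <= tol


def classify_anchor_change(new_loops: list[Loop], prior_loops: list[Loop],
                           layout: GenomeLayout,
                           match_tolerance: int = MATCH_TOLERANCE
                           ) -> list[TaxonomyCall]:
    """Categorize each new loop by how its anchors relate to prior loops.

    * ``both_anchors_new`` — neither anchor matches any prior loop anchor;
    * ``extension_one_anchor`` — exactly one anchor matches a prior loop
      anchor and the new partner lies strictly outside the prior loop span
      on the far side of the shared anchor (more distal);
    * ``paired_new_anchor_split`` — a prior anchor pairs with a brand-new
      anchor lying strictly inside a prior loop span, splitting it into
      shorter loops sharing an anchor;
    * ``other`` — anything else (e.g. both anchors reused in a new pair,
      or one anchor reused with a shorter span ending at a reused site).
    """
    prior_by_chrom: dict[str, list[tuple[int, int, Loop]]] = {}
    for lp in prior_loops:
        b1, b2 = lp.bins(layout)
        prior_by_chrom.setdefault(lp.chrom, []).append((b1, b2, lp))
    calls = []
    for lp in new_loops:
        b1, b2 = lp.bins(layout)
        priors = prior_by_chrom.get(lp.chrom, [])
        anchor_bins = [b for p1, p2, _ in priors for b in (p1, p2)]
        m1 = any(_match(b1, b, match_tolerance) for b in anchor_bins)
        m2 = any(_match(b2, b, match_tolerance) for b in anchor_bins)
        if not m1 and not m2:
            calls.append(TaxonomyCall(lp, "both_anchors_new", {}))
            continue
        if m1 != m2:
            shared_is_left = m1
            category = "other"
            evidence: dict = {}
            for p1, p2, pl in priors:
                if shared_is_left and _match(b1, p1, match_tolerance):
                    if b2 > p2 + match_tolerance:     # more distal partner
                        category = "extension_one_anchor"
                        evidence = {"prior": pl}
                        break
                if not shared_is_left and _match(b2, p2, match_tolerance):
                    if b1 < p1 - match_tolerance:
                        category = "extension_one_anchor"
                        evidence = {"prior": pl}
                        break
            if category == "other":
                # prior anchor + new anchor strictly inside a prior span
                new_bin = b2 if shared_is_left else b1
                shared_bin = b1 if shared_is_left else b2
                for p1, p2, pl in priors:
                    shares = (_match(shared_bin, p1, match_tolerance)
                              or _match(shared_bin, p2, match_tolerance))
                    inside = p1 + match_tolerance < new_bin < p2 - match_tolerance
                    if shares and inside:
                        category = "paired_new_anchor_split"
                        evidence = {"prior": pl}
                        break
            calls.append(TaxonomyCall(lp, category, evidence))
            continue
        calls.append(TaxonomyCall(lp, "other", {}))
    return calls


def taxonomy_fractions(calls: list[TaxonomyCall]) -> dict[str, float]:
    n = len(calls)
    return {c: (sum(1 for t in calls if t.category == c) / n if n else 0.0)
            for c in CATEGORIES}


# ---------------------------------------------------------------------------
# Internal cohesin-loading-site ranking
# ---------------------------------------------------------------------------

@dataclass
class InternalSiteRanking:
    order: list[int]              # loop indices, nearest site first
    scaled_positions: dict[int, float]
    distances: dict[int, int]     # bp from left anchor midpoint to site
    no_site: list[int]
    multi_site_count: int


def cooccupied_sites(peaks_a: PeakSet, peaks_b: PeakSet) -> pd.DataFrame:
    """Intersection intervals of two peak sets (e.g. NIPBL with RAD21)."""
    rows = []
    for chrom, sub_a in peaks_a.intervals.groupby("chrom", sort=False):
        sub_b = peaks_b.on(chrom)
        if len(sub_b) == 0:
            continue
        for _, ra in sub_a.iterrows():
            ov = sub_b[(sub_b["start"] < ra["end"]) & (sub_b["end"] > ra["start"])]
            for _, rb in ov.iterrows():
                rows.append((chrom, max(ra["start"], rb["start"]),
                             min(ra["end"], rb["end"])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def rank_by_internal_site(loops: list[Loop], sites: pd.DataFrame
                          ) -> InternalSiteRanking:
    """Order loops by the distance from the left anchor to an internal site.

    A site qualifies when its midpoint lies strictly between the two
    anchors (end1 < mid < start2).  With several internal sites the one
    nearest the left anchor is used and counted.  The scaled position is
    (site_mid − anchor1_mid) / (anchor2_mid − anchor1_mid) in (0, 1).
    Loops without an internal site form a trailing "no site" group.
    """
    scaled, dist, no_site = {}, {}, []
    multi = 0
    for i, lp in enumerate(loops):
        sub = sites[sites["chrom"] == lp.chrom] if len(sites) else sites
        if len(sub) == 0:
            no_site.append(i)
            continue
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        internal = mids[(mids > lp.end1) & (mids < lp.start2)]
        if internal.size == 0:
            no_site.append(i)
            continue
        if internal.size > 1:
            multi += 1
        d = internal - lp.mid1
        site_mid = int(internal[np.argmin(np.abs(d))])
        dist[i] = int(site_mid - lp.mid1)
        scaled[i] = (site_mid - lp.mid1) / (lp.mid2 - lp.mid1)
    order = sorted(dist, key=lambda i: (dist[i], i))
    return InternalSiteRanking(order, scaled, dist, no_site, multi)
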