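"""One-dimensional chromatin-track analyses.

ATAC fragment-size partitioning (Tn5 +4/−5 shift, then sub-nucleosomal
"TF" 50–115 bp vs mono-nucleosomal "Nuc" 180–247 bp gates), RPM heatmap /
average-profile matrices around anchors, the enhancer classification rule
(H3K4me1 without H3K4me3, overlapping ATAC-TF peaks, away from TSS;
active when also H3K27ac), differential enhancers, 25-kb H3K9me3 bin
calls (IP/Input >= 4; >= 4-fold change between stages), and per-loop-set
summaries of gene-expression change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contactio import (GenomeLayout, Loop, PeakSet, SignalTrack,
                        interval_overlaps)
from .diffloops import nb_exact_test, _bh_fdr

logger = logging.getLogger("loopshift")

TF_RANGE = (50, 115)       # bp, inclusive
NUC_RANGE = (180, 247)     # bp, inclusive
PLUS_SHIFT = 4
MINUS_SHIFT = -5
TSS_PAD_DEFAULT = 1000     # bp on each side of a TSS
ENH_P_CUT = 0.05
ENH_FC_CUT = 3.0
K9_BIN = 25_000
K9_RATIO = 4.0
K9_PSEUDO = 1.0            # reads per input bin


# ---------------------------------------------------------------------------
# ATAC fragments
# ---------------------------------------------------------------------------

@dataclass
class FragmentTable:
    """Aligned fragments: chrom, start, end, strand (+/-)."""

    frags: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "strand"}
        if not need.issubset(self.frags.columns):
            raise ValueError(f"FragmentTable needs columns {need}")
        if len(self.frags) and (self.frags["start"] >= self.frags["end"]).any():
            raise ValueError("fragment start must precede end")
        bad = ~self.frags["strand"].isin(["+", "-"]) if len(self.frags) else pd.Series([], dtype=bool)
        if len(self.frags) and bad.any():
            raise ValueError("strand must be + or -")

    def __len__(self) -> int:
        return len(self.frags)

    @property
    def lengths(self) -> np.ndarray:
        return (self.frags["end"] - self.frags["start"]).to_numpy()


@dataclass
class AtacPartition:
    tf: FragmentTable
    nuc: FragmentTable
    n_discarded: int


def shift_and_partition_atac(fragments: FragmentTable) -> AtacPartition:
    """Tn5-shift fragment 5' ends and split by insert size.

    Plus-strand fragments have their 5' end (start) moved +4 bp;
    minus-strand fragments have theirs (end) moved −5 bp.  After shifting,
    fragments with length in [50, 115] go to the TF (sub-nucleosomal)
    table, [180, 247] to the Nuc (mono-nucleosomal) table; everything else
    is discarded and counted.  Coordinates that would go negative are
    clipped at 0 with a warning.
    """
    df = fragments.frags.copy()
    plus = (df["strand"] == "+").to_numpy()
    df.loc[plus, "start"] += PLUS_SHIFT
    df.loc[~plus, "end"] += MINUS_SHIFT
    if (df["start"] < 0).any():
        logger.warning("clipping %d negative fragment starts at 0",
                       int((df["start"] < 0).sum()))
        df.loc[df["start"] < 0, "start"] = 0
    df = df[df["start"] < df["end"]]
    lengths = df["end"] - df["start"]
    tf_mask = (lengths >= TF_RANGE[0]) & (lengths <= TF_RANGE[1])
    nuc_mask = (lengths >= NUC_RANGE[0]) & (lengths <= NUC_RANGE[1])
    n_disc = int(len(fragments) - tf_mask.sum() - nuc_mask.sum())
    return AtacPartition(FragmentTable(df[tf_mask].reset_index(drop=True)),
                         FragmentTable(df[nuc_mask].reset_index(drop=True)),
                         n_disc)


# ---------------------------------------------------------------------------
# RPM bin matrices (heatmaps / average profiles)
# ---------------------------------------------------------------------------

@dataclass
class BinMatrix:
    """Anchors x bins matrix of reads-per-million-per-bin values."""

    matrix: np.ndarray          # (n_anchors, n_bins); masked rows are NaN
    flank: int
    bin_width: int
    masked: np.ndarray          # bool per anchor

    def average_profile(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=0)


def rpm_bin_matrix(reads: pd.DataFrame, anchors: pd.DataFrame,
                   layout: GenomeLayout, flank: int, bin_width: int,
                   library_size: float,
                   strand_aware: bool = False) -> BinMatrix:
    """Count reads per bin around anchor centers, scaled to RPM.

    A read is counted in every bin it overlaps (intersect semantics).
    Windows are [center − flank, center + flank) split into
    2*flank/bin_width bins.  Anchors whose window leaves the chromosome
    are masked (NaN rows).  With ``strand_aware`` the row of a minus-strand
    anchor is reversed so bins read 5'→3'.
    """
    if (2 * flank) % bin_width != 0:
        raise ValueError("2*flank must be a multiple of bin_width")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    n_bins = 2 * flank // bin_width
    n = len(anchors)
    mat = np.zeros((n, n_bins))
    masked = np.zeros(n, dtype=bool)
    scale = library_size / 1e6
    anchors = anchors.reset_index(drop=True)
    for chrom, sub in anchors.groupby("chrom", sort=False):
        csize = layout.size_of(chrom)
        rd = reads[reads["chrom"] == chrom]
        rs = rd["start"].to_numpy()
        re_ = rd["end"].to_numpy()
        for i, row in sub.iterrows():
            center = (int(row["start"]) + int(row["end"])) // 2
            w0 = center - flank
            if w0 < 0 or center + flank > csize:
                masked[i] = True
                mat[i] = np.nan
                continue
            # overlap counting per bin
            for b in range(n_bins):
                b0 = w0 + b * bin_width
                b1 = b0 + bin_width
                mat[i, b] = np.count_nonzero((rs < b1) & (re_ > b0))
            if strand_aware and row.get("strand", "+") == "-":
                mat[i] = mat[i, ::-1]
    mat /= scale
    return BinMatrix(mat, flank, bin_width, masked)


# ---------------------------------------------------------------------------
# Enhancer classification
# ---------------------------------------------------------------------------

@dataclass
class EnhancerCall:
    chrom: str
    start: int
    end: int
    active: bool


def classify_enhancers(h3k4me1: PeakSet, h3k4me3: PeakSet,
                       atac_tf_peaks: PeakSet, h3k27ac: PeakSet,
                       tss: PeakSet, tss_pad: int = TSS_PAD_DEFAULT
                       ) -> list[EnhancerCall]:
    """Apply the enhancer rule to per-stage peak sets.

    An enhancer is an H3K4me1 peak with no H3K4me3 overlap, at least one
    ATAC-TF peak overlap, and no overlap with any TSS padded by
    ``tss_pad`` on each side.  Enhancers that also overlap an H3K27ac peak
    are active enhancers.
    """
    tss_padded = tss.intervals.copy()
    tss_padded["start"] = (tss_padded["start"] - tss_pad).clip(lower=0)
    tss_padded["end"] = tss_padded["end"] + tss_pad
    calls = []
    for chrom, sub in h3k4me1.intervals.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        has_me3 = interval_overlaps(h3k4me3.intervals, chrom, s, e)
        has_atac = interval_overlaps(atac_tf_peaks.intervals, chrom, s, e)
        near_tss = interval_overlaps(tss_padded, chrom, s, e)
        is_enh = ~has_me3 & has_atac & ~near_tss
        has_ac = interval_overlaps(h3k27ac.intervals, chrom, s, e)
        for k in np.flatnonzero(is_enh):
            calls.append(EnhancerCall(chrom, int(s[k]), int(e[k]),
                                      bool(has_ac[k])))
    return calls


def differential_enhancers(counts_a: np.ndarray, counts_b: np.ndarray,
                           dispersion: float = 0.0,
                           p_cut: float = ENH_P_CUT,
                           fc_cut: float = ENH_FC_CUT) -> pd.DataFrame:
    """Differential calls on per-enhancer replicate counts for two stages.

    Reuses the exact NB test; an enhancer is differential when p < 0.05
    and the fold change (on 0.5-pseudocounted group means) exceeds 3 in
    either direction.
    """
    counts_a = np.atleast_2d(counts_a)
    counts_b = np.atleast_2d(counts_b)
    if counts_a.shape[0] != counts_b.shape[0]:
        raise ValueError("enhancer count tables differ in length")
    p = np.array([nb_exact_test(counts_a[i], counts_b[i], dispersion)
                  for i in range(counts_a.shape[0])])
    ma = counts_a.mean(axis=1) + 0.5
    mb = counts_b.mean(axis=1) + 0.5
    fc = np.maximum(ma / mb, mb / ma)
    return pd.DataFrame({
        "p": p,
        "fdr": _bh_fdr(p),
        "fc": fc,
        "differential": (p < p_cut) & (fc > fc_cut),
    })


# ---------------------------------------------------------------------------
# H3K9me3 25-kb bin calls
# ---------------------------------------------------------------------------

@dataclass
class K9BinCalls:
    positive: dict[str, np.ndarray]   # bool per 25-kb bin
    ratio: dict[str, np.ndarray]


def h3k9me3_bin_calls(ip: SignalTrack, inp: SignalTrack,
                      ratio_cut: float = K9_RATIO,
                      pseudo: float = K9_PSEUDO,
                      depth_match: bool = True) -> K9BinCalls:
    """Positive H3K9me3 bins: depth-matched IP / Input >= 4 (inclusive).

    Input is scaled to the IP total before the ratio; bins whose scaled
    input falls below one read are floored at the pseudocount so empty
    input never divides by zero while IP = 4x input stays exactly on the
    inclusive boundary.  Bin size is whatever the tracks' shared layout
    uses (conventionally 25 kb).
    """
    if ip.layout.bin_size != inp.layout.bin_size:
        raise ValueError("IP and input tracks must share bin size")
    ip_total, in_total = ip.total(), inp.total()
    scale = ip_total / in_total if (depth_match and in_total > 0) else 1.0
    positive, ratios = {}, {}
    for chrom in ip.layout.chroms:
        a = ip.values[chrom]
        b = inp.values[chrom] * scale
        r = a / np.maximum(b, pseudo)
        ratios[chrom] = r
        positive[chrom] = r >= ratio_cut
    return K9BinCalls(positive, ratios)


def h3k9me3_differential_bins(calls_a: K9BinCalls, calls_b: K9BinCalls,
                              fold_cut: float = K9_RATIO
                              ) -> dict[str, np.ndarray]:
    """Bins whose IP/Input ratio changes at least ``fold_cut``-fold.

    Returns per-chromosome int arrays: +1 gain in b, −1 loss in b, 0 no
    change; symmetric under swapping the two stages (gain <-> loss).
    """
    out = {}
    for chrom, ra in calls_a.ratio.items():
        rb = calls_b.ratio[chrom]
        eps = 1e-12
        gain = rb >= fold_cut * np.maximum(ra, eps)
        loss = ra >= fold_cut * np.maximum(rb, eps)
        out[chrom] = gain.astype(int) - loss.astype(int)
    return out


# ---------------------------------------------------------------------------
# Expression inside loops
# ---------------------------------------------------------------------------

def expression_in_loops(loop_sets: dict[str, list[Loop]],
                        genes: pd.DataFrame,
                        tpm: pd.DataFrame,
                        stage_pairs: dict[str, tuple[str, str]]
                        ) -> dict[str, pd.DataFrame]:
    """Per-loop-set distributions of per-gene expression change.

    ``genes`` has columns (gene, chrom, start, end); ``tpm`` is indexed by
    gene with one TPM column per stage.  A gene belongs to a loop when its
    body midpoint falls inside the loop span (anchor1 start to anchor2
    end).  For each loop set, ``stage_pairs`` names the (previous stage,
    stage) pair and the result holds log2((TPM_stage+1)/(TPM_prev+1)) per
    contained gene; loops containing no genes are excluded and counted in
    the frame attrs.
    """
    mids = ((genes["start"] + genes["end"]) // 2).to_numpy()
    out = {}
    for name, loops in loop_sets.items():
        prev, cur = stage_pairs[name]
        rows = []
        n_empty = 0
        for li, lp in enumerate(loops):
            inside = ((genes["chrom"] == lp.chrom).to_numpy()
                      & (mids >= lp.start1) & (mids < lp.end2))
            ids = genes["gene"][inside]
            if len(ids) == 0:
                n_empty += 1
                continue
            for g in ids:
                lfc = float(np.log2((tpm.loc[g, cur] + 1) / (tpm.loc[g, prev] + 1)))
                rows.append({"loop": li, "gene": g, "log2fc": lfc})
        df = pd.DataFrame(rows, columns=["loop", "gene", "log2fc"])
        df.attrs["n_loops_without_genes"] = n_empty
        df.attrs["quartiles"] = (
            df["log2fc"].quantile([0.25, 0.5, 0.75]).tolist() if len(df) else [])
        out[name] = df
    return out
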