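"""Synthetic multi-stage Hi-C/epigenome generator with planted ground truth.

Emulates the structure the pipeline assumes in real data so that every
stage of the analysis can be exercised offline with a known answer:

* power-law distance decay of cis contacts, mean
  mu(i,j) proportional to (|i-j|+1)^(-alpha);
* an A/B compartment checkerboard, multiplying bin pairs by
  (1 + kappa * v_i * v_j) with v in {+1, -1};
* planted loops whose strength varies by stage, applied as a Gaussian-
  tapered multiplier on the 3x3 neighborhood of the loop pixel (the taper
  is normalized to mean 1 over the footprint so the radius-1 aggregate
  enrichment equals the nominal multiplier);
* Poisson counting noise per replicate, with replicate depths jittered
  +/-10% so dispersion estimation stays exercised;
* peak sets co-located with active loop anchors (CTCF/RAD21, optionally
  pre-bound future anchors), internal NIPBL/RAD21 cohesin-loading sites,
  enhancer-mark combinations with known classes, and H3K9me3 IP/input
  tracks;
* ATAC fragment tables as a mixture of sub-nucleosomal and
  mono-nucleosomal truncated-normal insert-length components.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contactio import ContactMatrix, GenomeLayout, Loop, PeakSet, SignalTrack
from .diffloops import STAGES
from .tracks import FragmentTable

LOOP_TAPER_SIGMA = 0.8      # bins; Gaussian taper over the 3x3 footprint
DEPTH_JITTER = 0.10         # relative replicate depth jitter
PERSIST_FRACTION = 0.35     # residual excess kept outside the peak/dip stage
TF_LEN = (82.0, 15.0, 30.0, 140.0)    # mean, sd, lo, hi of TF inserts
NUC_LEN = (205.0, 20.0, 150.0, 280.0)  # mono-nucleosomal inserts


@dataclass(frozen=True)
class PlantedLoop:
    """A planted loop: anchor bins and a strength multiplier per stage."""

    bin1: int
    bin2: int
    multipliers: tuple[float, ...]    # one per stage, all >= 1
    label: str                        # gained | lost | common
    stage: str                        # assigned stage ("" for common)
    category: str = ""                # taxonomy category, if relevant


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic time course.

    Defaults are one 20-Mb chromosome at 10-kb bins (2000 bins), the five
    differentiation stages with two replicates each, decay exponent 1.0,
    compartment blocks of 1 Mb with checkerboard strength kappa, and about
    two million contacts per replicate.
    """

    chrom: str = "chrSim"
    chrom_size: int = 20_000_000
    bin_size: int = 10_000
    stages: tuple[str, ...] = STAGES
    replicates: int = 2
    alpha: float = 1.0
    kappa: float = 0.3
    block_bins: int = 100             # compartment block length in bins
    depth: int = 2_000_000            # contacts per replicate before jitter
    loops: tuple[PlantedLoop, ...] = ()
    min_loop_distance_bins: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for lp in self.loops:
            if lp.bin2 - lp.bin1 < self.min_loop_distance_bins:
                raise ValueError("planted loop closer than minimum distance")
            if any(m < 1 for m in lp.multipliers):
                raise ValueError("loop strength multipliers must be >= 1")
            if len(lp.multipliers) != len(self.stages):
                raise ValueError("one multiplier per stage required")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_dict({self.chrom: self.chrom_size}, self.bin_size)

    @property
    def n_bins(self) -> int:
        return self.layout.n_bins(self.chrom)


def compartment_signs(config: SimConfig) -> np.ndarray:
    """Planted per-bin compartment sign: +1/-1 alternating blocks."""
    n = config.n_bins
    return np.where((np.arange(n) // config.block_bins) % 2 == 0, 1.0, -1.0)


def truth_table(config: SimConfig) -> pd.DataFrame:
    """Per-loop ground truth (anchors, label, stage, multipliers)."""
    rows = []
    for lp in config.loops:
        rows.append({"bin1": lp.bin1, "bin2": lp.bin2, "label": lp.label,
                     "stage": lp.stage, "category": lp.category,
                     **{f"mult_{s}": m
                        for s, m in zip(config.stages, lp.multipliers)}})
    return pd.DataFrame(rows)


def _taper_weights(sigma: float = LOOP_TAPER_SIGMA) -> np.ndarray:
    """3x3 Gaussian taper normalized to mean 1 over the footprint."""
    off = np.arange(-1, 2)
    g = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / (2 * sigma ** 2))
    return g * g.size / g.sum()


def _base_mean(config: SimConfig) -> np.ndarray:
    """Upper-triangle base contact mean, normalized to sum 1."""
    n = config.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    base = (d + 1.0) ** (-config.alpha)
    v = compartment_signs(config)
    base *= 1.0 + config.kappa * np.outer(v, v)
    base = np.triu(base)
    return base / base.sum()


def _stage_mean(config: SimConfig, base: np.ndarray, stage_idx: int) -> np.ndarray:
    """Apply planted-loop multipliers for one stage to the base mean."""
    mu = base.copy()
    taper = _taper_weights()
    n = config.n_bins
    for lp in config.loops:
        m = lp.multipliers[stage_idx]
        if m == 1.0:
            continue
        i0, j0 = lp.bin1, lp.bin2
        for di in range(-1, 2):
            for dj in range(-1, 2):
                i, j = i0 + di, j0 + dj
                if 0 <= i <= j < n:
                    mu[i, j] *= 1.0 + (m - 1.0) * taper[di + 1, dj + 1]
    return mu


def simulate_stage_hic(config: SimConfig
                       ) -> tuple[dict[tuple[str, int], ContactMatrix], pd.DataFrame]:
    """Poisson-sampled contact matrices per stage x replicate, plus truth.

    Counts at pixel (i, j) are Poisson with mean
    depth_r * base(i, j) * loop_multiplier(i, j, stage), where depth_r is
    the nominal per-replicate depth jittered uniformly by +/-10%.
    Replicate streams are seeded from config.seed.
    """
    rng = np.random.default_rng(config.seed)
    base = _base_mean(config)
    layout = config.layout
    out: dict[tuple[str, int], ContactMatrix] = {}
    for si, stage in enumerate(config.stages):
        mu_stage = _stage_mean(config, base, si)
        for rep in range(config.replicates):
            depth = config.depth * (1.0 + DEPTH_JITTER * rng.uniform(-1, 1))
            counts = rng.poisson(mu_stage * depth)
            m = ContactMatrix.from_dense(layout, config.chrom, counts, "raw")
            if m.total_contacts == 0:
                import logging
                logging.getLogger("loopshift").warning(
                    "simulated depth too low: zero contacts at %s rep %d",
                    stage, rep)
            out[(stage, rep)] = m
    return out, truth_table(config)


# ---------------------------------------------------------------------------
# Loop plans
# ---------------------------------------------------------------------------

def random_loop_plan(config: SimConfig, rng: np.random.Generator,
                     n_common: int = 40, n_gained_per_stage: int = 8,
                     n_lost_per_stage: int = 8,
                     common_mult: float = 3.0,
                     diff_mults: tuple[float, ...] = (5.0, 6.0, 8.0),
                     min_sep_bins: int = 20, max_sep_bins: int = 120,
                     margin_bins: int = 30,
                     diff_stages: tuple[str, ...] | None = None
                     ) -> tuple[PlantedLoop, ...]:
    """Draw a non-colliding set of planted loops with stage-specific truth.

    A loop gained at stage s is absent before s, reaches its full
    multiplier m at s, and persists afterwards at a fraction of the
    excess (PERSIST_FRACTION); a loop lost at s carries m before s,
    bottoms at 1 exactly at s and partially re-strengthens afterwards.
    Common loops carry a constant multiplier at all stages.  Anchor
    pixels are kept at least 3 bins apart so 3x3 footprints never
    overlap.

    These asymmetric profiles make the ground truth well-defined under
    the assignment rule: the stage of maximum (gained) or minimum (lost)
    normalized frequency is unique, and the largest consecutive-stage
    change is the rise into (or drop at) the assigned stage rather than a
    tie between a symmetric rise and fall.  Stage-specific loops are
    planted at ``diff_stages`` (default: every stage after the first); a
    loop peaking at the baseline stage is indistinguishable from a loss
    at the following stage, so no truth label exists for it.
    """
    n = config.n_bins
    n_stage = len(config.stages)
    used: list[tuple[int, int]] = []

    def draw_pixel() -> tuple[int, int]:
        for _ in range(10_000):
            i = int(rng.integers(margin_bins, n - margin_bins - max_sep_bins))
            sep = int(rng.integers(min_sep_bins, max_sep_bins + 1))
            j = i + sep
            if j >= n - margin_bins:
                continue
            if all(abs(i - a) > 3 or abs(j - b) > 3 for a, b in used):
                used.append((i, j))
                return i, j
        raise RuntimeError("could not place loop without collision")

    if diff_stages is None:
        diff_stages = config.stages[1:]
    loops: list[PlantedLoop] = []
    for _ in range(n_common):
        i, j = draw_pixel()
        loops.append(PlantedLoop(i, j, (common_mult,) * n_stage, "common", ""))
    for si, stage in enumerate(config.stages):
        if stage not in diff_stages:
            continue
        for _ in range(n_gained_per_stage):
            i, j = draw_pixel()
            m = float(rng.choice(diff_mults))
            tail = 1.0 + (m - 1.0) * PERSIST_FRACTION
            mult = tuple(1.0 if k < si else (m if k == si else tail)
                         for k in range(n_stage))
            loops.append(PlantedLoop(i, j, mult, "gained", stage))
        for _ in range(n_lost_per_stage):
            i, j = draw_pixel()
            m = float(rng.choice(diff_mults))
            tail = 1.0 + (m - 1.0) * PERSIST_FRACTION
            mult = tuple(m if k < si else (1.0 if k == si else tail)
                         for k in range(n_stage))
            loops.append(PlantedLoop(i, j, mult, "lost", stage))
    return tuple(loops)


def loops_from_truth(config: SimConfig, which: str = "all") -> list[Loop]:
    """Materialize planted loops as Loop records (one bin per anchor)."""
    bs = config.bin_size
    out = []
    for lp in config.loops:
        if which != "all" and lp.label != which:
            continue
        out.append(Loop(config.chrom, lp.bin1 * bs, (lp.bin1 + 1) * bs,
                        lp.bin2 * bs, (lp.bin2 + 1) * bs))
    return out


# ---------------------------------------------------------------------------
# Peaks and 1-D tracks
# ---------------------------------------------------------------------------

@dataclass
class StageAssets:
    """Per-stage peak sets and tracks with their generating truth."""

    peaks: dict[str, dict[str, PeakSet]]          # stage -> factor -> peaks
    internal_sites: pd.DataFrame                  # loop idx, chrom, start, end, frac
    enhancer_truth: pd.DataFrame                  # interval + true class
    k9_tracks: dict[str, tuple[SignalTrack, SignalTrack]]  # stage -> (IP, input)


def _peak_at_bin(chrom: str, b: int, bin_size: int, half_width: int = 500
                 ) -> tuple[str, int, int]:
    center = b * bin_size + bin_size // 2
    return (chrom, center - half_width, center + half_width)


def simulate_peaks_and_tracks(config: SimConfig,
                              internal_site_fracs: dict[int, float] | None = None,
                              prebound_anchors: bool = False,
                              n_enhancer_units: int = 30,
                              k9_domain_bins: tuple[tuple[int, int], ...] = (),
                              seed: int | None = None) -> StageAssets:
    """Peak sets and tracks consistent with the planted loop truth.

    CTCF and RAD21 peaks sit at the anchors of loops active in each stage
    (multiplier > 1, or common loops); ``prebound_anchors`` additionally
    places CTCF at every planted anchor in every stage (pre-bound sites
    not yet looping).  ``internal_site_fracs`` maps planted-loop index to
    a fractional position in (0, 1) where an NIPBL+RAD21 co-occupied site
    is placed.  Enhancer units cycle through the truth classes (active
    enhancer / plain enhancer / rejected by H3K4me3 / rejected by missing
    ATAC / rejected by TSS).  ``k9_domain_bins`` lists 25-kb-scale bin
    ranges given high IP/input ratio in the first stage and background in
    later stages.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    chrom, bs = config.chrom, config.bin_size
    peaks: dict[str, dict[str, PeakSet]] = {}
    for si, stage in enumerate(config.stages):
        active_bins = sorted({b for lp in config.loops
                              if lp.multipliers[si] > 1.0 or lp.label == "common"
                              for b in (lp.bin1, lp.bin2)})
        all_bins = sorted({b for lp in config.loops for b in (lp.bin1, lp.bin2)})
        ctcf_bins = all_bins if prebound_anchors else active_bins
        rows_c = [_peak_at_bin(chrom, b, bs) for b in ctcf_bins]
        rows_r = [_peak_at_bin(chrom, b, bs) for b in active_bins]
        peaks[stage] = {
            "CTCF": PeakSet("CTCF", pd.DataFrame(rows_c, columns=["chrom", "start", "end"])),
            "RAD21": PeakSet("RAD21", pd.DataFrame(rows_r, columns=["chrom", "start", "end"])),
        }
    # internal cohesin loading sites (NIPBL co-occupied with RAD21)
    site_rows = []
    nipbl_rows, rad_extra = [], []
    if internal_site_fracs:
        for li, frac in internal_site_fracs.items():
            lp = config.loops[li]
            m1 = lp.bin1 * bs + bs // 2
            m2 = lp.bin2 * bs + bs // 2
            center = int(m1 + frac * (m2 - m1))
            iv = (chrom, center - 250, center + 250)
            site_rows.append({"loop": li, "chrom": chrom,
                              "start": iv[1], "end": iv[2], "frac": frac})
            nipbl_rows.append(iv)
            rad_extra.append(iv)
    for stage in config.stages:
        nip = pd.DataFrame(nipbl_rows, columns=["chrom", "start", "end"])
        peaks[stage]["NIPBL"] = PeakSet("NIPBL", nip)
        if rad_extra:
            extra = pd.DataFrame(rad_extra, columns=["chrom", "start", "end"])
            merged = pd.concat([peaks[stage]["RAD21"].intervals, extra],
                               ignore_index=True)
            peaks[stage]["RAD21"] = PeakSet("RAD21", merged)
    # enhancer units with known classes, placed on a spaced lattice away
    # from planted anchors (offset half a bin)
    classes = ("active", "enhancer", "rej_k4me3", "rej_no_atac", "rej_tss")
    me1, me3, atac, ac, tss, truth_rows = [], [], [], [], [], []
    pos = 100_000
    step = (config.chrom_size - 200_000) // max(n_enhancer_units, 1)
    for u in range(n_enhancer_units):
        cls = classes[u % len(classes)]
        start = pos + u * step + bs // 3
        iv = (chrom, start, start + 800)
        me1.append(iv)
        if cls in ("active", "enhancer", "rej_k4me3", "rej_tss"):
            atac.append((chrom, start + 100, start + 500))
        if cls == "rej_k4me3":
            me3.append(iv)
        if cls == "active":
            ac.append((chrom, start - 200, start + 1000))
        if cls == "rej_tss":
            tss.append((chrom, start + 300, start + 301))
        truth_rows.append({"chrom": chrom, "start": iv[1], "end": iv[2],
                           "class": cls})
    enhancer_truth = pd.DataFrame(truth_rows)
    for stage in config.stages:
        mk = lambda name, rows: PeakSet(  # noqa: E731
            name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        peaks[stage]["H3K4me1"] = mk("H3K4me1", me1)
        peaks[stage]["H3K4me3"] = mk("H3K4me3", me3)
        peaks[stage]["ATAC_TF"] = mk("ATAC_TF", atac)
        peaks[stage]["H3K27ac"] = mk("H3K27ac", ac)
        peaks[stage]["TSS"] = mk("TSS", tss)
    # H3K9me3 IP/input tracks at 25 kb: domains hot in the first stage only
    k9_layout = config.layout.with_bin_size(25_000)
    nb = k9_layout.n_bins(chrom)
    k9_tracks = {}
    for si, stage in enumerate(config.stages):
        base = rng.poisson(20.0, nb).astype(float)
        ip = base.copy()
        if si == 0:
            for b0, b1 in k9_domain_bins:
                ip[b0:b1] *= 8.0
        inp = rng.poisson(20.0, nb).astype(float)
        k9_tracks[stage] = (
            SignalTrack(k9_layout, {chrom: ip}, library_size=float(ip.sum())),
            SignalTrack(k9_layout, {chrom: inp}, library_size=float(inp.sum())),
        )
    return StageAssets(peaks, pd.DataFrame(site_rows,
                                           columns=["loop", "chrom", "start", "end", "frac"]),
                       enhancer_truth, k9_tracks)


# ---------------------------------------------------------------------------
# ATAC fragments
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def simulate_atac_fragments(config: SimConfig,
                            tf_sites: list[int] | None = None,
                            nuc_sites: list[int] | None = None,
                            rate_per_site: int = 200,
                            seed: int | None = None) -> FragmentTable:
    """Fragment table mixing sub- and mono-nucleosomal insert lengths.

    TF fragments draw insert lengths from N(82, 15) truncated to
    [30, 140] bp; Nuc fragments from N(205, 20) truncated to [150, 280].
    Fragment centers scatter around their site with 50 bp jitter; strands
    are uniform.  Zero sites gives an empty table.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    rows = []
    for sites, (mean, sd, lo, hi) in ((tf_sites or [], TF_LEN),
                                      (nuc_sites or [], NUC_LEN)):
        for site in sites:
            n = rng.poisson(rate_per_site)
            if n == 0:
                continue
            lengths = np.round(_truncnorm(rng, mean, sd, lo, hi, n)).astype(int)
            centers = site + np.round(rng.normal(0, 50, n)).astype(int)
            starts = np.maximum(0, centers - lengths // 2)
            ends = starts + lengths
            strands = np.where(rng.random(n) < 0.5, "+", "-")
            for s, e, st in zip(starts, ends, strands):
                rows.append({"chrom": config.chrom, "start": int(s),
                             "end": int(e), "strand": st})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return FragmentTable(df)
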