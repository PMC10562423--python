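"""Differential and stage-specific loop calling across a time course.

The four-step pipeline applied to a multi-stage panel of contact matrices:

1. candidate loops called per stage are combined into a deduplicated union;
2. contact frequencies are quantified on every union loop in every
   stage/replicate, on matrices subsampled to a common depth;
3. each stage pair is tested per loop with an exact negative-binomial test
   (common dispersion estimated across loops by method of moments;
   dispersion 0 reduces to the conditional binomial / Poisson exact test),
   with Benjamini-Hochberg FDR across loops per pair, and loops passing
   FDR < 0.1, p < 0.05 and fold change >= 4 in any pair are labeled
   differential (all others are common);
4. differential loops are assigned to the stage where their normalized
   contact frequency peaks (gained) or bottoms (lost); gained versus lost
   is decided by the sign of the largest-magnitude consecutive-stage
   change.  Exact ties go to the earliest developmental stage and are
   flagged.

Default stage panel: H9 -> DE -> PGT -> PP -> SC-beta.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .contactio import ContactMatrix, GenomeLayout, Loop

STAGES = ("H9", "DE", "PGT", "PP", "SCb")
FDR_CUT = 0.1
P_CUT = 0.05
FC_CUT = 4.0
FC_PSEUDO = 0.5          # pseudocount added to each group mean
DEFAULT_RADIUS = 1       # loop-pixel neighborhood radius in bins


# ---------------------------------------------------------------------------
# Step 1: loop union
# ---------------------------------------------------------------------------

@dataclass
class LoopUnion:
    loops: list[Loop]
    provenance: list[tuple[str, ...]]  # stages that called each merged loop


def merge_loop_calls(per_stage_loops: dict[str, list[Loop]],
                     layout: GenomeLayout,
                     tolerance_bins: int = 1) -> LoopUnion:
    """Combine per-stage loop calls into a deduplicated union.

    Loops whose anchor-midpoint bins agree within ``tolerance_bins`` in
    both anchors are considered the same loop; connected components of
    this proximity relation are merged to the record from the earliest
    stage (ties broken by input order).
    """
    records = []  # (stage_idx, order, loop, b1, b2)
    stage_names = list(per_stage_loops)
    for si, stage in enumerate(stage_names):
        for oi, lp in enumerate(per_stage_loops[stage]):
            b1, b2 = lp.bins(layout)
            records.append((si, oi, lp, b1, b2))
    m = len(records)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_chrom: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        by_chrom.setdefault(rec[2].chrom, []).append(idx)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda k: records[k][3])
        b1s = [records[k][3] for k in idxs]
        for a_pos, a in enumerate(idxs):
            _, _, _, a1, a2 = records[a]
            for b_pos in range(a_pos + 1, len(idxs)):
                b = idxs[b_pos]
                if b1s[b_pos] - a1 > tolerance_bins:
                    break
                if abs(records[b][4] - a2) <= tolerance_bins:
                    union(a, b)
    groups: dict[int, list[int]] = {}
    for idx in range(m):
        groups.setdefault(find(idx), []).append(idx)
    loops, prov = [], []
    for members in sorted(groups.values(),
                          key=lambda ms: min((records[k][0], records[k][1]) for k in ms)):
        rep = min(members, key=lambda k: (records[k][0], records[k][1]))
        loops.append(records[rep][2])
        prov.append(tuple(sorted({stage_names[records[k][0]] for k in members},
                                 key=stage_names.index)))
    return LoopUnion(loops, prov)


# ---------------------------------------------------------------------------
# Step 2: quantification
# ---------------------------------------------------------------------------

def quantify_loops(union: LoopUnion,
                   matrices: dict[tuple[str, int], ContactMatrix],
                   layout: GenomeLayout,
                   radius: int = DEFAULT_RADIUS,
                   normalized: dict[str, np.ndarray] | None = None
                   ) -> pd.DataFrame:
    """Per-loop raw counts per stage x replicate, plus normalized values.

    Counts are the sum over the (2*radius+1)^2 neighborhood of the loop
    pixel in the (subsampled) raw matrix.  ``normalized`` optionally maps
    stage -> dense normalized (KR + distance-normalized) per-chromosome
    map; per-stage mean normalized pixel values are then added as
    ``norm_<stage>`` columns for fold-change reporting and stage
    assignment.  Loops whose neighborhood leaves the matrix are flagged
    missing (NaN counts).
    """
    dense_cache = {k: m.to_dense() for k, m in matrices.items()}
    rows = []
    for lp in union.loops:
        bi, bj = lp.bins(layout)
        row: dict = {"chrom": lp.chrom, "bin1": bi, "bin2": bj}
        for (stage, rep), d in dense_cache.items():
            n = d.shape[0]
            if bi - radius < 0 or bj + radius >= n:
                row[f"count_{stage}_{rep}"] = np.nan
                continue
            row[f"count_{stage}_{rep}"] = float(
                d[bi - radius: bi + radius + 1, bj - radius: bj + radius + 1].sum())
        if normalized is not None:
            for stage, d in normalized.items():
                row[f"norm_{stage}"] = float(d[bi, bj])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Step 3: exact negative-binomial test
# ---------------------------------------------------------------------------

def estimate_dispersion(counts: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across loops.

    ``counts`` is (n_loops, n_replicates) for one condition or a stack of
    conditions with equal means within rows.  For NB, var = mu + phi*mu^2,
    so phi = sum(var_i - mu_i) / sum(mu_i^2), floored at 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs >=2 replicates per row")
    mu = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    denom = float((mu ** 2).sum())
    if denom == 0:
        return 0.0
    return float(max(0.0, (var - mu).sum() / denom))


def _conditional_pmf(s: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """PMF of the group-A sum given total s under equal per-replicate means.

    With dispersion phi > 0 the replicate counts are NB with size r = 1/phi
    each; conditioned on the total, the group-A sum follows the negative
    hypergeometric (Polya) law with weights C(k+ra-1,k)*C(s-k+rb-1,s-k),
    ra = n_a/phi, rb = n_b/phi.  As phi -> 0 this tends to the binomial
    Bin(s, n_a/(n_a+n_b)), used directly at dispersion 0 (Poisson case).
    """
    k = np.arange(s + 1)
    if dispersion <= 0:
        return sps.binom.pmf(k, s, n_a / (n_a + n_b))
    ra, rb = n_a / dispersion, n_b / dispersion
    logw = (gammaln(k + ra) - gammaln(k + 1) - gammaln(ra)
            + gammaln(s - k + rb) - gammaln(s - k + 1) - gammaln(rb))
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def nb_exact_test(counts_a, counts_b, dispersion: float = 0.0) -> float:
    """Two-sided exact test of equal means for two groups of counts.

    Conditions on the total count; the two-sided p-value doubles the
    smaller tail (including the observed outcome) and is capped at 1.
    Both groups all-zero gives p = 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        return float("nan")
    sa, sb = int(round(a.sum())), int(round(b.sum()))
    s = sa + sb
    if s == 0:
        return 1.0
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    pmf = _conditional_pmf(s, len(a), len(b), dispersion)
    cdf = np.cumsum(pmf)
    lower = cdf[sa]
    upper = pmf[sa:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# Steps 3-4: differential calls and stage assignment
# ---------------------------------------------------------------------------

@dataclass
class DiffResult:
    """Per-loop labels and per-stage-pair statistics."""

    table: pd.DataFrame          # one row per loop: label, stage, flags
    pair_stats: pd.DataFrame     # one row per loop x stage pair: p, fdr, fc
    stages: tuple[str, ...]


def _bh_fdr(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    n = ps.size
    if n == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    out[ok] = q
    return out


def call_differential(count_table: pd.DataFrame,
                      stages: tuple[str, ...] = STAGES,
                      replicates: int = 2,
                      dispersion: float | None = None,
                      fdr_cut: float = FDR_CUT,
                      p_cut: float = P_CUT,
                      fc_cut: float = FC_CUT) -> DiffResult:
    """Label every union loop differential or common.

    A loop is differential when any stage pair passes all three gates
    (FDR < 0.1, p < 0.05, fold change >= 4 in either direction on group
    mean counts with a 0.5 pseudocount); otherwise it is common.  The
    common dispersion is estimated across loops when not supplied (single
    replicate requires a supplied dispersion).
    """
    counts = {
        s: count_table[[f"count_{s}_{r}" for r in range(replicates)]].to_numpy()
        for s in stages
    }
    if dispersion is None:
        if replicates < 2:
            raise ValueError("single replicate: dispersion must be supplied")
        stacked = np.vstack([counts[s] for s in stages])
        dispersion = estimate_dispersion(stacked)
    n_loops = len(count_table)
    pair_rows = []
    any_pass = np.zeros(n_loops, dtype=bool)
    for sa, sb in itertools.combinations(stages, 2):
        ca, cb = counts[sa], counts[sb]
        pvals = np.array([nb_exact_test(ca[i], cb[i], dispersion)
                          for i in range(n_loops)])
        fdr = _bh_fdr(pvals)
        ma = ca.mean(axis=1) + FC_PSEUDO
        mb = cb.mean(axis=1) + FC_PSEUDO
        fc = np.maximum(ma / mb, mb / ma)
        passed = (fdr < fdr_cut) & (pvals < p_cut) & (fc >= fc_cut)
        passed &= ~np.isnan(pvals)
        any_pass |= np.where(np.isnan(pvals), False, passed)
        for i in range(n_loops):
            pair_rows.append({"loop": i, "stage_a": sa, "stage_b": sb,
                              "p": pvals[i], "fdr": fdr[i], "fc": fc[i],
                              "pass": bool(passed[i])})
    table = pd.DataFrame({
        "loop": np.arange(n_loops),
        "label": np.where(any_pass, "differential", "common"),
    })
    return DiffResult(table, pd.DataFrame(pair_rows), tuple(stages))


def assign_stage(diff: DiffResult, norm_freq: pd.DataFrame,
                 stages: tuple[str, ...] = STAGES) -> DiffResult:
    """Assign each differential loop to a stage and a gained/lost direction.

    ``norm_freq`` holds per-loop per-stage mean normalized contact
    frequencies (columns ``norm_<stage>``).  Direction is the sign of the
    largest-magnitude consecutive-stage change; gained loops go to the
    argmax stage, lost loops to the argmin.  Exact cross-stage ties pick
    the earliest stage and set ``tie``.
    """
    prof = norm_freq[[f"norm_{s}" for s in stages]].to_numpy()
    n = len(prof)
    direction = np.full(n, "", dtype=object)
    assigned = np.full(n, "", dtype=object)
    tie = np.zeros(n, dtype=bool)
    is_diff = (diff.table["label"] == "differential").to_numpy()
    for i in range(n):
        if not is_diff[i]:
            continue
        deltas = np.diff(prof[i])
        j = int(np.argmax(np.abs(deltas)))
        gained = deltas[j] > 0
        direction[i] = "gained" if gained else "lost"
        target = prof[i].max() if gained else prof[i].min()
        hits = np.flatnonzero(prof[i] == target)
        assigned[i] = stages[hits[0]]
        tie[i] = len(hits) > 1
    table = diff.table.copy()
    table["direction"] = direction
    table["stage"] = assigned
    table["tie"] = tie
    return DiffResult(table, diff.pair_stats, diff.stages)
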