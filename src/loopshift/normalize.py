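"""Library matching, matrix balancing, expected model, compartments.

Implements the normalization ladder applied before any cross-stage
comparison of contact matrices:

1. random subsampling of contact events so every library has the same
   total as the smallest one (without replacement);
2. matrix balancing — Knight–Ruiz-style doubly-stochastic scaling (KR) for
   Hi-C, vanilla-coverage square root (VCsqrt) for HiChIP;
3. an expected model E(d) = mean contact at each bin separation d, and the
   distance normalization (observed − expected) / (expected + 1);
4. the A/B compartment eigenvector: leading eigenvector of the Pearson
   correlation matrix of the distance-normalized map at 25 kb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contactio import ContactMatrix, SignalTrack

KR_TOL = 1e-6          # relative row-sum spread at convergence
KR_MAX_ITER = 3000
MIN_EIG_BINS = 50      # minimum usable bins for a compartment call


# ---------------------------------------------------------------------------
# Subsampling to common depth
# ---------------------------------------------------------------------------

def subsample_contacts(matrices: list[ContactMatrix], seed: int,
                       target: int | None = None) -> list[ContactMatrix]:
    """Randomly pick contact events so all libraries match the smallest.

    Sampling is without replacement over individual contact events
    (multivariate hypergeometric over pixels), so a matrix already at the
    target is returned unchanged.
    """
    for m in matrices:
        if m.norm_state not in ("raw", "subsampled"):
            raise ValueError("subsampling requires raw integer matrices")
    totals = [int(round(m.total_contacts)) for m in matrices]
    tgt = min(totals) if target is None else int(target)
    if any(t < tgt for t in totals):
        raise ValueError(f"matrix total below subsample target {tgt}")
    rng = np.random.default_rng(seed)
    out = []
    for m, tot in zip(matrices, totals):
        if tot == tgt:
            out.append(m.with_values(m.value, "subsampled"))
            continue
        counts = m.value.astype(np.int64)
        kept = rng.multivariate_hypergeometric(counts, tgt, method="marginals")
        out.append(m.with_values(kept.astype(float), "subsampled"))
    return out


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def _kr_scale(dense: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Symmetric scaling vector v with diag(v) A diag(v) doubly balanced.

    Fixed-point iteration v <- v / sqrt(rowsum / mean-rowsum), the symmetric
    Sinkhorn scheme; on symmetric non-negative matrices with support it
    converges to the same balanced matrix as Knight–Ruiz.
    """
    n = dense.shape[0]
    v = np.ones(n)
    spread_trace = []
    for _ in range(max_iter):
        rs = v * (dense @ v)
        mean = rs.mean()
        if mean <= 0:
            raise RuntimeError("balancing degenerate: zero total")
        spread = (rs.max() - rs.min()) / mean
        spread_trace.append(spread)
        if spread <= tol:
            return v
        v = v / np.sqrt(rs / mean)
    raise RuntimeError(
        f"balancing did not converge in {max_iter} iterations; "
        f"last spreads {spread_trace[-5:]}")


def balance(matrix: ContactMatrix, method: str = "KR",
            tol: float = KR_TOL, max_iter: int = KR_MAX_ITER) -> ContactMatrix:
    """Balance a raw/subsampled matrix with KR or VCsqrt.

    Bins with zero marginal are masked (left zero, excluded from the
    balancing system).  KR output preserves the total contact sum; VCsqrt
    is the plain vanilla-coverage square-root division
    value(i,j) / sqrt(rowsum_i * rowsum_j).
    """
    if method not in ("KR", "VCsqrt"):
        raise ValueError(f"unknown balancing method {method!r}")
    rs = matrix.row_sums()
    mask = rs > 0
    if method == "VCsqrt":
        denom = np.sqrt(rs[matrix.bin1] * rs[matrix.bin2])
        vals = np.divide(matrix.value, denom,
                         out=np.zeros_like(matrix.value, dtype=float),
                         where=denom > 0)
        return matrix.with_values(vals, "VCsqrt")
    # KR on the unmasked submatrix
    dense = matrix.to_dense()
    sub = dense[np.ix_(mask, mask)]
    v_sub = _kr_scale(sub, tol, max_iter)
    # rescale so the balanced matrix keeps the raw total
    bal_sub = sub * np.outer(v_sub, v_sub)
    scale = np.sqrt(dense.sum() / bal_sub.sum())
    v = np.zeros(matrix.n_bins)
    v[mask] = v_sub * scale
    vals = matrix.value * v[matrix.bin1] * v[matrix.bin2]
    out = matrix.with_values(vals, "KR")
    return out


# ---------------------------------------------------------------------------
# Expected model and distance normalization
# ---------------------------------------------------------------------------

@dataclass
class ExpectedModel:
    """Mean contact value per genomic-distance bin, per chromosome.

    ``expected[d]`` is the sum of pixel values at separation d divided by
    the number of valid (unmasked) pixel positions at that separation —
    zero pixels count in the denominator, masked bins do not.
    """

    chrom: str
    expected: np.ndarray  # length n_bins, indexed by |i-j|
    n_valid: np.ndarray

    def at(self, d: np.ndarray | int) -> np.ndarray:
        return self.expected[d]


def expected_by_distance(matrix: ContactMatrix,
                         mask: np.ndarray | None = None) -> ExpectedModel:
    """Per-diagonal mean over valid pixel positions.

    ``mask`` flags usable bins; by default bins with zero marginal in a
    raw/subsampled matrix are excluded, and everything is usable otherwise.
    """
    n = matrix.n_bins
    if mask is None:
        if matrix.norm_state in ("raw", "subsampled"):
            mask = matrix.row_sums() > 0
        else:
            mask = matrix.row_sums() != 0
    d = matrix.bin2 - matrix.bin1
    valid_px = mask[matrix.bin1] & mask[matrix.bin2]
    sums = np.bincount(d[valid_px], weights=matrix.value[valid_px], minlength=n)
    # number of valid (i, i+d) positions: count pairs of usable bins at lag d
    mask_f = mask.astype(float)
    n_valid = np.array([float(mask_f[: n - dd] @ mask_f[dd:]) for dd in range(n)])
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), 0.0)
    return ExpectedModel(matrix.chrom, exp, n_valid)


def distance_normalize(matrix: ContactMatrix,
                       expected: ExpectedModel) -> ContactMatrix:
    """(observed − expected) / (expected + 1), pixel-wise.

    Zero pixels of the sparse matrix have observed 0, hence normalized
    value −E/(E+1); those are implicit, so downstream dense consumers must
    rebuild them (``dense_distance_normalized`` does).
    """
    d = matrix.bin2 - matrix.bin1
    if d.size and d.max() >= len(expected.expected):
        raise ValueError("expected model does not cover all separations")
    e = expected.at(d)
    vals = (matrix.value - e) / (e + 1.0)
    return matrix.with_values(vals, "distance_normalized")


def dense_distance_normalized(matrix: ContactMatrix,
                              expected: ExpectedModel) -> np.ndarray:
    """Dense (observed−expected)/(expected+1) map including zero pixels."""
    n = matrix.n_bins
    dense = matrix.to_dense()
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = expected.expected[d]
    return (dense - e) / (e + 1.0)


def dense_oe(matrix: ContactMatrix, expected: ExpectedModel,
             eps: float = 0.0) -> np.ndarray:
    """Dense observed/expected ratio map; pixels with E=0 are set to 0."""
    n = matrix.n_bins
    dense = matrix.to_dense()
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = expected.expected[d] + eps
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(e > 0, dense / np.where(e > 0, e, 1.0), 0.0)


# ---------------------------------------------------------------------------
# Compartment eigenvector
# ---------------------------------------------------------------------------

@dataclass
class CompartmentCall:
    """Per-bin compartment eigenvector with a usable-bin mask.

    ``eigenvector`` has one entry per bin of the chromosome; masked bins
    are NaN, not zero.  The sign convention is positive = correlated with
    the orientation track (active chromatin) when one is provided.
    """

    chrom: str
    eigenvector: np.ndarray
    mask: np.ndarray  # True = usable


def compartment_eigenvector(matrix: ContactMatrix,
                            orientation_track: SignalTrack | None = None
                            ) -> CompartmentCall:
    """Leading eigenvector of the Pearson correlation of the O/E-style map.

    The matrix (conventionally at 25 kb) is distance normalized, rows with
    zero marginal or zero variance are masked, the Pearson correlation
    matrix of the remaining rows is computed, and its first eigenvector is
    reported.  With an orientation track the global sign is flipped so the
    eigenvector correlates positively with the track.
    """
    n = matrix.n_bins
    marg = matrix.row_sums()
    mask = marg > 0 if matrix.norm_state in ("raw", "subsampled") else marg != 0
    if mask.sum() < MIN_EIG_BINS:
        raise ValueError(f"need >= {MIN_EIG_BINS} usable bins, have {mask.sum()}")
    exp = expected_by_distance(matrix, mask=mask)
    dn = dense_distance_normalized(matrix, exp)
    sub = dn[np.ix_(mask, mask)]
    # drop constant rows (undefined correlation)
    row_sd = sub.std(axis=1)
    keep = row_sd > 0
    full_mask = mask.copy()
    full_mask[np.flatnonzero(mask)[~keep]] = False
    if full_mask.sum() < MIN_EIG_BINS:
        raise ValueError("degenerate correlation matrix: too many constant rows")
    sub = dn[np.ix_(full_mask, full_mask)]
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    w, vecs = np.linalg.eigh(corr)
    ev = vecs[:, -1]  # eigenvalues ascending
    full = np.full(n, np.nan)
    full[full_mask] = ev
    if orientation_track is not None:
        track = orientation_track.values[matrix.chrom][full_mask]
        evu = full[full_mask]
        c = float((evu - evu.mean()) @ (track - track.mean()))
        if c < 0:
            full = -full
    return CompartmentCall(matrix.chrom, full, full_mask)
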