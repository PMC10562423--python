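"""Shared genomic data model and on-disk formats.

Containers for binned sparse contact matrices, chromatin loops, peak sets
and per-bin signal tracks, plus readers/writers for the plain-text formats
the pipeline exchanges: whitespace-separated bin-triplet contact files with
a sidecar layout file, BEDPE loop lists, BED peak files and bedGraph tracks.

All coordinates are 0-based half-open internally.  BED/BEDPE/bedGraph are
already 0-based half-open on disk, so no conversion happens at the boundary.
Contact storage is per-chromosome and intra-chromosomal (cis) only;
inter-chromosomal records are skipped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("loopshift")

NORM_STATES = ("raw", "subsampled", "KR", "VCsqrt", "distance_normalized", "oe")


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, lengths (bp) and a fixed bin size (bp).

    Bin index of a position is ``floor(pos / bin_size)``; a chromosome of
    length L has ``ceil(L / bin_size)`` bins.
    """

    chrom_sizes: tuple[tuple[str, int], ...]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        for name, size in self.chrom_sizes:
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @classmethod
    def from_dict(cls, sizes: dict[str, int], bin_size: int) -> "GenomeLayout":
        return cls(tuple(sizes.items()), bin_size)

    @property
    def chroms(self) -> list[str]:
        return [c for c, _ in self.chrom_sizes]

    def size_of(self, chrom: str) -> int:
        for c, s in self.chrom_sizes:
            if c == chrom:
                return s
        raise KeyError(f"unknown chromosome {chrom!r}")

    def n_bins(self, chrom: str) -> int:
        return -(-self.size_of(chrom) // self.bin_size)

    def bin_of(self, chrom: str, pos: int) -> int:
        if not 0 <= pos <= self.size_of(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return min(pos // self.bin_size, self.n_bins(chrom) - 1)

    def with_bin_size(self, bin_size: int) -> "GenomeLayout":
        return GenomeLayout(self.chrom_sizes, bin_size)


# ---------------------------------------------------------------------------
# Contact matrix
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Per-chromosome symmetric sparse binned contact matrix.

    Only the upper triangle (i <= j) is stored; lower-triangle input is
    mirrored into it at construction.  ``total_contacts`` counts each
    off-diagonal pixel once (the sum of stored values for raw matrices).
    """

    layout: GenomeLayout
    chrom: str
    bin1: np.ndarray
    bin2: np.ndarray
    value: np.ndarray
    norm_state: str = "raw"
    total_contacts: float = field(default=0.0)

    @classmethod
    def from_triplets(cls, layout, chrom, bin1, bin2, value, norm_state="raw"):
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        value = np.asarray(value, dtype=float)
        n = layout.n_bins(chrom)
        if bin1.size and (bin1.min() < 0 or bin2.min() < 0 or
                          bin1.max() >= n or bin2.max() >= n):
            bad = np.flatnonzero((bin1 < 0) | (bin2 < 0) | (bin1 >= n) | (bin2 >= n))[0]
            raise ValueError(
                f"bin coordinate outside layout on {chrom}: "
                f"({bin1[bad]}, {bin2[bad]}) with {n} bins")
        if norm_state in ("raw", "subsampled") and value.size and value.min() < 0:
            raise ValueError("negative raw contact count")
        # mirror lower triangle into upper, merge duplicates
        lo = np.minimum(bin1, bin2)
        hi = np.maximum(bin1, bin2)
        key = lo * n + hi
        order = np.argsort(key, kind="stable")
        key, value = key[order], value[order]
        uniq, start = np.unique(key, return_index=True)
        summed = np.add.reduceat(value, start) if value.size else value
        m = cls(layout, chrom, uniq // n, uniq % n, summed, norm_state)
        m.total_contacts = float(summed.sum())
        return m

    @property
    def n_bins(self) -> int:
        return self.layout.n_bins(self.chrom)

    def to_dense(self) -> np.ndarray:
        """Symmetric dense completion (both triangles filled)."""
        n = self.n_bins
        d = np.zeros((n, n))
        d[self.bin1, self.bin2] = self.value
        d[self.bin2, self.bin1] = self.value
        return d

    @classmethod
    def from_dense(cls, layout, chrom, dense, norm_state="raw"):
        i, j = np.nonzero(np.triu(dense))
        return cls.from_triplets(layout, chrom, i, j, dense[i, j], norm_state)

    def with_values(self, value: np.ndarray, norm_state: str) -> "ContactMatrix":
        out = replace(self, value=np.asarray(value, dtype=float),
                      norm_state=norm_state)
        out.total_contacts = float(out.value.sum())
        return out

    def row_sums(self) -> np.ndarray:
        """Full symmetric row marginals (diagonal counted once)."""
        n = self.n_bins
        s = np.bincount(self.bin1, weights=self.value, minlength=n)
        off = self.bin1 != self.bin2
        s += np.bincount(self.bin2[off], weights=self.value[off], minlength=n)
        return s


def read_contacts(path, layout: GenomeLayout, chrom: str,
                  norm_state: str = "raw") -> ContactMatrix:
    """Read a whitespace-separated ``bin_i bin_j value`` triplet file."""
    b1, b2, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {line!r}")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-numeric field in {line!r}") from e
            b1.append(i)
            b2.append(j)
            vals.append(v)
    return ContactMatrix.from_triplets(layout, chrom, b1, b2, vals, norm_state)


def write_contacts(matrix: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        for i, j, v in zip(matrix.bin1, matrix.bin2, matrix.value):
            if float(v).is_integer():
                fh.write(f"{i}\t{j}\t{int(v)}\n")
            else:
                fh.write(f"{i}\t{j}\t{v!r}\n")


def write_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#bin_size\t{layout.bin_size}\n")
        for c, s in layout.chrom_sizes:
            fh.write(f"{c}\t{s}\n")


def read_layout(path) -> GenomeLayout:
    bin_size = None
    sizes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#bin_size"):
                bin_size = int(line.split("\t")[1])
            else:
                c, s = line.split("\t")
                sizes.append((c, int(s)))
    if bin_size is None:
        raise ValueError(f"{path}: missing #bin_size header")
    return GenomeLayout(tuple(sizes), bin_size)


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------

@dataclass
class Loop:
    """Ordered cis anchor pair with optional quantification and labels.

    ``anchor1`` always precedes ``anchor2`` on the chromosome
    (``end1 <= start2`` for non-overlapping anchors).  ``stats`` carries
    per-stage/replicate quantification, test statistics and classification
    labels as the pipeline fills them in.
    """

    chrom: str
    start1: int
    end1: int
    start2: int
    end2: int
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError("anchor start must precede anchor end")
        if (self.start1, self.end1) > (self.start2, self.end2):
            self.start1, self.start2 = self.start2, self.start1
            self.end1, self.end2 = self.end2, self.end1

    @property
    def mid1(self) -> int:
        return (self.start1 + self.end1) // 2

    @property
    def mid2(self) -> int:
        return (self.start2 + self.end2) // 2

    @property
    def span(self) -> int:
        """Anchor-start distance in bp."""
        return self.start2 - self.start1

    def bins(self, layout: GenomeLayout) -> tuple[int, int]:
        """Bin pair containing the anchor midpoints."""
        return (layout.bin_of(self.chrom, self.mid1),
                layout.bin_of(self.chrom, self.mid2))


def read_bedpe(path, on_trans: str = "skip") -> list[Loop]:
    """Read a BEDPE loop list (>= 6 columns).

    ``on_trans`` controls inter-chromosomal rows: "skip" (warn) or "error".
    """
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >=6 columns")
            c1, s1, e1, c2, s2, e2 = parts[:6]
            try:
                s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from e
            if s1 >= e1 or s2 >= e2:
                raise ValueError(f"{path}:{lineno}: anchor start >= end")
            if c1 != c2:
                if on_trans == "error":
                    raise ValueError(f"{path}:{lineno}: inter-chromosomal loop")
                logger.warning("%s:%d: skipping inter-chromosomal loop", path, lineno)
                continue
            loops.append(Loop(c1, s1, e1, s2, e2))
    return loops


def write_bedpe(loops: list[Loop], path, stat_keys: tuple[str, ...] = ()) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            row = [lp.chrom, lp.start1, lp.end1, lp.chrom, lp.start2, lp.end2]
            row += [lp.stats.get(k, ".") for k in stat_keys]
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Peaks and signal tracks
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Named set of genomic intervals (0-based half-open) with scores."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end [, score, strand]

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.intervals.columns):
            raise ValueError(f"PeakSet needs columns {need}")
        if ((self.intervals["start"] >= self.intervals["end"]).any()):
            raise ValueError("peak start must precede end")

    def __len__(self) -> int:
        return len(self.intervals)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == chrom]


def read_bed(path, name: str | None = None) -> PeakSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 4:
                try:
                    row["score"] = float(parts[4])
                except ValueError:
                    row["score"] = np.nan
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "strand"])
    df = df.dropna(axis=1, how="all")
    return PeakSet(name or str(path), df)


def write_bed(peaks: PeakSet, path, extra_cols: tuple[str, ...] = ()) -> None:
    cols = ["chrom", "start", "end"]
    with open(path, "w") as fh:
        for _, r in peaks.intervals.iterrows():
            row = [r[c] for c in cols] + [r.get(c, ".") for c in extra_cols]
            fh.write("\t".join(str(x) for x in row) + "\n")


@dataclass
class SignalTrack:
    """Per-bin float coverage values per chromosome, with library size."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]
    library_size: float = 0.0

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            if len(arr) != self.layout.n_bins(chrom):
                raise ValueError(f"track length mismatch on {chrom}")
            if np.any(arr < 0):
                raise ValueError("signal values must be non-negative")

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))


def read_bedgraph(path, layout: GenomeLayout) -> SignalTrack:
    """Read a 4-column bedGraph and rebin to layout bins.

    Each interval's value is spread over the bins it covers by
    length-weighted mean: a bin's value is the per-base average of the
    signal over the bases of the bin covered by intervals (uncovered bases
    count as 0).  Overlapping intervals are rejected as ambiguous.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            per_chrom.setdefault(chrom, []).append((start, end, val))
    values = {}
    for chrom in layout.chroms:
        n = layout.n_bins(chrom)
        bs = layout.bin_size
        acc = np.zeros(n)
        ivs = sorted(per_chrom.get(chrom, []))
        prev_end = -1
        for start, end, val in ivs:
            if start < prev_end:
                raise ValueError(f"overlapping bedGraph intervals on {chrom} at {start}")
            prev_end = end
            if end > layout.size_of(chrom):
                raise ValueError(f"bedGraph interval beyond {chrom} end")
            b0, b1 = start // bs, (end - 1) // bs
            for b in range(b0, b1 + 1):
                lo = max(start, b * bs)
                hi = min(end, (b + 1) * bs)
                acc[b] += val * (hi - lo)
        # per-base mean over the (possibly truncated) last bin
        widths = np.full(n, bs, dtype=float)
        widths[-1] = layout.size_of(chrom) - (n - 1) * bs
        values[chrom] = acc / widths
    return SignalTrack(layout, values)


def write_bedgraph(track: SignalTrack, path) -> None:
    bs = track.layout.bin_size
    with open(path, "w") as fh:
        for chrom in track.layout.chroms:
            arr = track.values.get(chrom)
            if arr is None:
                continue
            size = track.layout.size_of(chrom)
            for b, v in enumerate(arr):
                if v != 0:
                    fh.write(f"{chrom}\t{b * bs}\t{min((b + 1) * bs, size)}\t{v!r}\n")


# ---------------------------------------------------------------------------
# Interval overlap helper (shared by anchors/tracks)
# ---------------------------------------------------------------------------

def interval_overlaps(peaks: pd.DataFrame, chrom: str,
                      starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean array: does query interval k overlap any peak on ``chrom``?

    Overlap is strict half-open intersection (shared length > 0).
    Sorted-sweep implementation: O((n+m) log n).
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    sub = peaks[peaks["chrom"] == chrom]
    if len(sub) == 0:
        return np.zeros(len(starts), dtype=bool)
    ps = sub["start"].to_numpy()
    pe = sub["end"].to_numpy()
    order = np.argsort(ps, kind="stable")
    ps, pe = ps[order], pe[order]
    cummax_end = np.maximum.accumulate(pe)
    idx = np.searchsorted(ps, ends, side="left")  # peaks with start < end_k
    hit = np.zeros(len(starts), dtype=bool)
    nz = idx > 0
    hit[nz] = cummax_end[idx[nz] - 1] > starts[nz]
    return hit


def validate_file(path, layout: GenomeLayout | None = None) -> str:
    """Best-effort format sniffing + validation; returns the detected kind."""
    with open(path) as fh:
        first = ""
        for line in fh:
            line = line.strip()
            if line and not line.startswith(("#", "track", "browser")):
                first = line
                break
    if not first:
        return "empty"
    parts = first.split("\t") if "\t" in first else first.split()
    if len(parts) >= 6:
        try:
            int(parts[1]), int(parts[2]), int(parts[4]), int(parts[5])
            read_bedpe(path)
            return "bedpe"
        except (ValueError, IndexError):
            pass
    if len(parts) == 4:
        try:
            int(parts[1]), int(parts[2]), float(parts[3])
            if layout is not None:
                read_bedgraph(path, layout)
            return "bedgraph"
        except ValueError:
            pass
    if len(parts) == 3:
        try:
            int(parts[0]), int(parts[1]), float(parts[2])
            return "contacts"
        except ValueError:
            pass
        try:
            int(parts[1]), int(parts[2])
            read_bed(path)
            return "bed"
        except ValueError:
            pass
    if len(parts) >= 3:
        try:
            int(parts[1]), int(parts[2])
            read_bed(path)
            return "bed"
        except ValueError:
            pass
    raise ValueError(f"{path}: unrecognized format")
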