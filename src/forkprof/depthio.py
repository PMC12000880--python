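"""Depth-track IO, fixed-width binning, and bin masks.

The module consumes the output of an upstream alignment/depth pipeline
(per-base depth as 4-column bedGraph, 0-based half-open) and produces the
package's central container, :class:`BinnedDepth`: mean per-base depth over
contiguous fixed-width bins (100 bp by default) with a boolean validity
mask. Bins overlapping non-uniquely-mappable or deleted sequence are
masked — flagged, not deleted, so bin indices stay stable across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, ParameterError
from .layout import GenomeLayout


@dataclass
class DepthTrack:
    """Per-base depth as disjoint sorted intervals (0-based half-open).

    Uncovered gaps are implicitly depth 0.
    """

    length_bp: int
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def per_base(self) -> np.ndarray:
        """Expand to one value per base. Only for small genomes/tests."""
        out = np.zeros(self.length_bp)
        for s, e, v in zip(self.starts, self.ends, self.values):
            out[s:e] = v
        return out

    def total(self) -> float:
        """Sum of depth over all bases."""
        return float(np.sum(self.values * (self.ends - self.starts)))


@dataclass
class BinnedDepth:
    """Mean per-base depth over contiguous fixed-width bins, with a mask.

    Attributes
    ----------
    length_bp : int
        Chromosome length; the final bin may be partial.
    bin_size : int
        Bin width in bp.
    values : ndarray of float
        Mean per-base depth per bin (finite, >= 0).
    mask : ndarray of bool
        True = bin removed from analysis (carries no information downstream).
    """

    length_bp: int
    bin_size: int
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.n_bins
        if len(self.values) != n or len(self.mask) != n:
            raise ParameterError(
                f"expected {n} bins for length {self.length_bp} at bin_size "
                f"{self.bin_size}, got {len(self.values)} values / {len(self.mask)} mask"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ParameterError("bin values must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.length_bp / self.bin_size)

    @property
    def retained(self) -> np.ndarray:
        return ~self.mask

    def bin_widths(self) -> np.ndarray:
        """Actual width of each bin in bp (last bin may be partial)."""
        w = np.full(self.n_bins, self.bin_size, dtype=float)
        rem = self.length_bp - (self.n_bins - 1) * self.bin_size
        w[-1] = rem
        return w

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size

    def bin_ends(self) -> np.ndarray:
        e = self.bin_starts() + self.bin_size
        e[-1] = self.length_bp
        return e

    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_starts() + self.bin_ends()) / 2.0

    def copy(self) -> "BinnedDepth":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


# ---------------------------------------------------------------------------
# readers


def _read_intervals(path, n_cols_min: int):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < n_cols_min:
                raise FormatError(f"{path}:{ln}: expected >= {n_cols_min} columns")
            rows.append((ln, parts))
    return rows


def read_bedgraph(path, layout: GenomeLayout) -> DepthTrack:
    """Read a 4-column bedGraph (0-based half-open) into a :class:`DepthTrack`.

    Intervals must be sorted, non-overlapping and within the chromosome;
    overlaps are a hard error (the upstream depth tool emits disjoint
    intervals, so an overlap signals a corrupted or doubled file). Gaps are
    interpreted as depth 0.
    """
    rows = _read_intervals(path, 4)
    starts, ends, values = [], [], []
    for ln, parts in rows:
        try:
            s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
        if s < 0 or e > layout.length_bp:
            raise BoundsError(
                f"{path}:{ln}: interval [{s},{e}) outside [0,{layout.length_bp})"
            )
        if e <= s:
            raise FormatError(f"{path}:{ln}: empty or inverted interval [{s},{e})")
        starts.append(s)
        ends.append(e)
        values.append(v)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    order = np.argsort(starts, kind="stable")
    starts, ends, values = starts[order], ends[order], values[order]
    if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
        i = int(np.argmax(starts[1:] < ends[:-1]))
        raise FormatError(
            f"{path}: overlapping intervals around [{starts[i]},{ends[i]}) and "
            f"[{starts[i + 1]},{ends[i + 1]})"
        )
    return DepthTrack(layout.length_bp, starts, ends, values)


def read_bed3(path, layout: GenomeLayout | None = None):
    """Read BED3 intervals (0-based half-open) as an (n, 2) int array."""
    rows = _read_intervals(path, 3)
    out = []
    for ln, parts in rows:
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
        if layout is not None and (s < 0 or e > layout.length_bp):
            raise BoundsError(
                f"{path}:{ln}: interval [{s},{e}) outside [0,{layout.length_bp})"
            )
        out.append((s, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# binning


def bin_depth(track: DepthTrack, bin_size: int) -> BinnedDepth:
    """Average per-base depth over contiguous fixed-width bins.

    ``values[i]`` is the mean depth over bases
    ``[i*bin_size, min((i+1)*bin_size, length_bp))``; the final partial bin
    is averaged over its actual width. Binning conserves mass exactly:
    ``sum(values * widths) == sum of per-base depth``.
    """
    if bin_size <= 0:
        raise ParameterError(f"bin_size must be >= 1, got {bin_size}")
    L = track.length_bp
    n = math.ceil(L / bin_size)
    sums = np.zeros(n)
    ramp = np.zeros(n + 1)  # diff-array for runs of complete interior bins
    for s, e, v in zip(track.starts, track.ends, track.values):
        b0 = s // bin_size
        b1 = (e - 1) // bin_size
        if b0 == b1:
            sums[b0] += v * (e - s)
            continue
        sums[b0] += v * ((b0 + 1) * bin_size - s)
        sums[b1] += v * (e - b1 * bin_size)
        if b1 - b0 > 1:  # fully covered bins b0+1 .. b1-1
            ramp[b0 + 1] += v
            ramp[b1] -= v
    sums += np.cumsum(ramp[:-1]) * bin_size
    widths = np.full(n, bin_size, dtype=float)
    widths[-1] = L - (n - 1) * bin_size
    return BinnedDepth(L, bin_size, sums / widths, np.zeros(n, dtype=bool))


def apply_mask(binned: BinnedDepth, intervals) -> BinnedDepth:
    """Mask every bin overlapping any BED interval by >= 1 bp.

    ``intervals`` is a path to a BED3 file or an (n, 2) array of 0-based
    half-open intervals. Values are preserved; only the mask is set, so the
    operation is idempotent and order-independent. An empty BED is a no-op.
    """
    if not isinstance(intervals, np.ndarray):
        intervals = read_bed3(intervals)
    out = binned.copy()
    b = binned.bin_size
    for s, e in intervals:
        if e <= s:
            continue
        b0 = max(int(s) // b, 0)
        b1 = min((int(e) - 1) // b, binned.n_bins - 1)
        if b1 >= b0:
            out.mask[b0 : b1 + 1] = True
    return out


# ---------------------------------------------------------------------------
# binned-profile TSV

_TSV_COLUMNS = ["bin_index", "start", "end", "depth", "masked"]


def write_binned_tsv(binned: BinnedDepth, path) -> None:
    """Write a binned profile as TSV (round-trips bit-identically)."""
    df = pd.DataFrame(
        {
            "bin_index": np.arange(binned.n_bins),
            "start": binned.bin_starts(),
            "end": binned.bin_ends(),
            "depth": binned.values,
            "masked": binned.mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_binned_tsv(path) -> BinnedDepth:
    # round_trip parsing: the default C float parser can be 1 ulp off,
    # which would break the bit-identical TSV round-trip contract
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.sort_values("bin_index")
    n = len(df)
    if not np.array_equal(df["bin_index"].to_numpy(), np.arange(n)):
        raise FormatError(f"{path}: bin_index is not contiguous 0..{n - 1}")
    starts = df["start"].to_numpy()
    bin_size = int(starts[1] - starts[0]) if n > 1 else int(df["end"].iloc[0])
    length_bp = int(df["end"].iloc[-1])
    return BinnedDepth(
        length_bp,
        bin_size,
        df["depth"].to_numpy(dtype=float),
        df["masked"].to_numpy(dtype=bool),
    )


def write_bedgraph(binned: BinnedDepth, path, chrom: str = "chr") -> None:
    """Write binned values back out as bedGraph (one interval per bin)."""
    starts = binned.bin_starts()
    ends = binned.bin_ends()
    with open(path, "w") as fh:
        for s, e, v, m in zip(starts, ends, binned.values, binned.mask):
            if m:
                continue
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")
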