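"""Opening the circular chromosome at a cut locus.

Replication profiles of a circular chromosome are presented as a line
segment: the circle is opened at the *dif* dimer-resolution site so the
origin lands mid-axis, which permutes the X-axis relative to native
coordinates. For trendline generation the permuted profile is additionally
padded by duplicating the terminal bins onto the reciprocal ends, which
lets a windowed smoother behave as if the data were circular; the padding
is trimmed again after fitting.

All maps here are invertible bookkeeping: no depth value is created or
destroyed, and mask flags travel with their bins (duplicated pad bins keep
the source bin's mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .depthio import BinnedDepth
from .errors import PadRegionError, ParameterError


@dataclass
class LinearizedProfile:
    """A permuted, optionally padded linear view of a :class:`BinnedDepth`.

    Attributes
    ----------
    source : BinnedDepth
    cut_bin : int
        Native bin index that becomes linear index 0.
    order : ndarray of int
        Permutation, ``order[j]`` = native bin shown at linear index ``j``
        (pads excluded).
    pad_bins : int
        Number of duplicated bins on each end.
    x : ndarray
        Monotone bin start positions including pads; the left pad continues
        the bin pitch into negative positions (synthetic coordinates).
    y : ndarray
        Depth values including duplicated pads.
    mask : ndarray of bool
        Removed-bin flags, aligned with ``y``.
    pad_mask : ndarray of bool
        True for pad entries of ``x``/``y``.
    """

    source: BinnedDepth
    cut_bin: int
    order: np.ndarray
    pad_bins: int
    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    pad_mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.order)

    def to_native(self, linear_index: int) -> int:
        """Native bin index shown at a linear (unpadded-range) index."""
        if not 0 <= linear_index < self.n_bins:
            raise PadRegionError(
                f"linear index {linear_index} outside the unpadded range "
                f"[0, {self.n_bins})"
            )
        return int(self.order[linear_index])

    def to_linear(self, native_index: int) -> int:
        """Linear index at which a native bin is shown (inverse of to_native)."""
        n = self.n_bins
        if not 0 <= native_index < n:
            raise ParameterError(f"native index {native_index} outside [0, {n})")
        return int((native_index - self.cut_bin) % n)

    def core(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, mask) with pads stripped."""
        keep = ~self.pad_mask
        return self.x[keep], self.y[keep], self.mask[keep]

    def restore_native(self, linear_values: np.ndarray) -> np.ndarray:
        """Map an unpadded linear-order array back to native bin order."""
        linear_values = np.asarray(linear_values)
        if len(linear_values) != self.n_bins:
            raise ParameterError(
                f"expected {self.n_bins} unpadded values, got {len(linear_values)}"
            )
        out = np.empty_like(linear_values)
        out[self.order] = linear_values
        return out


def linearize(binned: BinnedDepth, cut_pos: int) -> LinearizedProfile:
    """Open the circle so the bin containing ``cut_pos`` (1-based bp) leads.

    Linear index ``j`` holds native bin ``(cut_bin + j) mod n_bins``; masks
    travel with their bins. The permutation conserves the multiset of
    values exactly and is inverted by :meth:`LinearizedProfile.to_native`.
    """
    if not 1 <= cut_pos <= binned.length_bp:
        raise ParameterError(
            f"cut_pos {cut_pos} outside [1, {binned.length_bp}]"
        )
    n = binned.n_bins
    cut_bin = (cut_pos - 1) // binned.bin_size
    order = (cut_bin + np.arange(n)) % n
    x = np.arange(n, dtype=float) * binned.bin_size
    return LinearizedProfile(
        source=binned,
        cut_bin=cut_bin,
        order=order,
        pad_bins=0,
        x=x,
        y=binned.values[order],
        mask=binned.mask[order],
        pad_mask=np.zeros(n, dtype=bool),
    )


def pad(profile: LinearizedProfile, pad_bins: int) -> LinearizedProfile:
    """Duplicate the terminal ``pad_bins`` bins onto the reciprocal ends.

    The last ``pad_bins`` values are prepended before linear position 0 and
    the first ``pad_bins`` appended after the end, with x continuing the
    same bin pitch (negative on the left). Pad bins keep the mask of the
    bins they duplicate. ``pad_bins = 0`` returns the profile unchanged.
    """
    if profile.pad_bins:
        raise ParameterError("profile is already padded")
    n = profile.n_bins
    if pad_bins < 0 or pad_bins >= n:
        raise ParameterError(f"pad_bins must be in [0, {n}), got {pad_bins}")
    if pad_bins == 0:
        return profile
    pitch = profile.source.bin_size
    left_x = profile.x[0] - pitch * np.arange(pad_bins, 0, -1)
    right_x = profile.x[-1] + pitch * np.arange(1, pad_bins + 1)
    x = np.concatenate([left_x, profile.x, right_x])
    y = np.concatenate([profile.y[-pad_bins:], profile.y, profile.y[:pad_bins]])
    mask = np.concatenate(
        [profile.mask[-pad_bins:], profile.mask, profile.mask[:pad_bins]]
    )
    pad_mask = np.zeros(n + 2 * pad_bins, dtype=bool)
    pad_mask[:pad_bins] = True
    pad_mask[n + pad_bins :] = True
    return LinearizedProfile(
        source=profile.source,
        cut_bin=profile.cut_bin,
        order=profile.order,
        pad_bins=pad_bins,
        x=x,
        y=y,
        mask=mask,
        pad_mask=pad_mask,
    )
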