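"""Model-style front end: fit a replication profile, inspect the results.

:class:`ReplicationProfile` bundles one sample's binned depth with its
genome layout; :meth:`ReplicationProfile.fit` runs the standard chain —
percent-mean normalization, linearization at *dif*, padding, robust LOESS
— and returns a :class:`ReplicationProfileResults` carrying the trendline,
the parameters that produced it and the feature-calling / normalization /
plotting methods. The functional modules underneath remain usable on
their own; this class is the convenient surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import depthio, features, profiles
from .circular import linearize, pad
from .errors import ParameterError
from .layout import GenomeLayout
from .loess import LoessParams, Trendline, fit_trendline


class ReplicationProfile:
    """One sample's replication (marker-frequency) profile.

    Parameters
    ----------
    binned : BinnedDepth
        Binned depth track (see :func:`forkprof.depthio.bin_depth`).
    layout : GenomeLayout
        Chromosome annotation; supplies the *dif* cut position and named
        normalization regions.

    Examples
    --------
    >>> model = ReplicationProfile.from_bedgraph("wt.bedgraph", layout,
    ...                                          mask_bed="mask.bed")
    >>> res = model.fit(span=0.025)
    >>> print(res.summary())
    """

    def __init__(self, binned: depthio.BinnedDepth, layout: GenomeLayout):
        if binned.length_bp != layout.length_bp:
            raise ParameterError(
                f"depth track length {binned.length_bp} != layout length "
                f"{layout.length_bp}"
            )
        self.binned = binned
        self.layout = layout

    @classmethod
    def from_bedgraph(
        cls, path, layout: GenomeLayout, bin_size: int = 100, mask_bed=None
    ) -> "ReplicationProfile":
        track = depthio.read_bedgraph(path, layout)
        binned = depthio.bin_depth(track, bin_size)
        if mask_bed is not None:
            binned = depthio.apply_mask(binned, mask_bed)
        return cls(binned, layout)

    @classmethod
    def from_binned_tsv(cls, path, layout: GenomeLayout) -> "ReplicationProfile":
        return cls(depthio.read_binned_tsv(path), layout)

    def fit(
        self,
        span: float = 0.025,
        robust_iterations: int = 8,
        cut_at="dif",
        pad_bins: int = 1000,
        percent_normalize: bool = True,
    ) -> "ReplicationProfileResults":
        """Fit the LOESS trendline.

        ``cut_at`` is ``'dif'``, ``'oriC'`` or a 1-based bp position; the
        chromosome is opened there before padding and fitting. ``pad_bins``
        duplicated terminal bins let the smoother see the circular
        continuation (clipped to below the bin count for small genomes).
        """
        cut_pos = self._resolve_cut(cut_at)
        binned = (
            profiles.percent_mean_normalize(self.binned)
            if percent_normalize
            else self.binned
        )
        pb = min(pad_bins, binned.n_bins - 1)
        prof = pad(linearize(binned, cut_pos), pb)
        params = LoessParams(span=span, robust_iterations=robust_iterations)
        trend = fit_trendline(prof, params)
        return ReplicationProfileResults(
            model=self, trendline=trend, params=params,
            normalized=binned, cut_pos=cut_pos,
        )

    def _resolve_cut(self, cut_at) -> int:
        if cut_at == "dif":
            return self.layout.dif_pos
        if cut_at in ("oriC", "oric"):
            return self.layout.oric_pos
        return int(cut_at)


@dataclass
class ReplicationProfileResults:
    """Fitted replication profile: trendline, provenance, diagnostics."""

    model: ReplicationProfile
    trendline: Trendline
    params: LoessParams
    normalized: depthio.BinnedDepth
    cut_pos: int
    _features: features.FeatureCall = field(default=None, repr=False)

    # -- derived quantities ------------------------------------------------

    def region_mean(self, region) -> float:
        return profiles.region_mean(self.trendline, region, self.model.layout)

    def normalized_to(self, region) -> Trendline:
        """Trendline divided by its mean over a named reference region."""
        return profiles.normalize_to_region(
            self.trendline, region, self.model.layout
        )

    def call_features(self, **kwargs) -> features.FeatureCall:
        """Peaks, troughs, initiation zones, downshifts, associations.

        Extremum positions are refined against the raw (normalized) bins.
        """
        kwargs.setdefault("raw", self.normalized)
        self._features = features.call_features(
            self.trendline, self.model.layout, **kwargs
        )
        return self._features

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        tr = self.trendline
        layout = self.model.layout
        vals = tr.values[tr.retained]
        lines = [
            "Replication profile LOESS fit",
            "=" * 46,
            f"genome            {layout.name} ({layout.length_bp:,} bp)",
            f"bins              {tr.n_bins:,} x {tr.bin_size} bp "
            f"({int(tr.mask.sum()):,} masked)",
            f"cut position      {self.cut_pos:,} bp",
            f"pad bins          {tr.pad_bins}",
            f"span              {tr.params.span} "
            f"(~{tr.effective_window_bp:,} bp window)",
            f"degree            {tr.params.degree}",
            f"robust iterations {tr.params.robust_iterations}",
            f"points fitted     {tr.n_fit:,}",
            f"trendline range   [{np.nanmin(vals):.4g}, {np.nanmax(vals):.4g}]",
            f"trendline median  {np.nanmedian(vals):.4g}",
        ]
        feat = self._features
        if feat is not None:
            lines += [
                f"peaks / troughs   {len(feat.peaks)} / {len(feat.troughs)}",
                f"zones             {len(feat.zones)}",
                f"downshifts        {len(feat.downshifts)}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None, show_raw: bool = True):
        """Raw bins (dots) and trendline (line) in the linearized view."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3.2))
        prof = linearize(self.normalized, self.cut_pos)
        x_mb = prof.x / 1e6
        if show_raw:
            y = np.where(prof.mask, np.nan, prof.y)
            ax.plot(x_mb, y, ".", ms=1, alpha=0.25, color="grey")
        trend_linear = self.trendline.values[prof.order]
        ax.plot(x_mb, trend_linear, lw=1.5, color="saddlebrown")
        ax.set_xlabel(f"Mb from cut at {self.cut_pos:,} bp")
        ax.set_ylabel("copy number (trendline)")
        return ax


def plot_nested_set(nested: profiles.NestedSet, cut_pos: int = None, ax=None):
    """Plot an indexed post-UV time course (one curve per timepoint)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.2))
    for t in nested.timepoints:
        tr = nested.indexed(t)
        if cut_pos is not None:
            order = (
                (cut_pos - 1) // tr.bin_size + np.arange(tr.n_bins)
            ) % tr.n_bins
            y = tr.values[order]
        else:
            y = tr.values
        x = np.arange(tr.n_bins) * tr.bin_size / 1e6
        ax.plot(x, y, lw=1.2, label=f"{t:g} min")
    if nested.log_y:
        ax.set_yscale("log")
    ax.set_xlabel("Mb")
    ax.set_ylabel("indexed copy number")
    ax.legend(frameon=False, fontsize=8)
    return ax
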