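"""Profile normalizations, replicate combination, and nested time-course sets.

Three normalizations recur in marker-frequency analysis of post-UV
recovery:

* **percent-mean** — absolute read depth converted to percent of the mean
  across retained bins, removing sequencing-depth differences between
  samples before replicates are combined;
* **region normalization** — a trendline divided by its mean over a named
  reference region (e.g. the *rrnG* reporter segment or the *terE–terD*
  interval), so trendlines of different samples become comparable at that
  region;
* **indexation** — each region-normalized timepoint multiplied by the
  region's measured absolute DNA *increase factor* (e.g. from agarose-plug
  hybridization), so the curves of a time course nest with heights that
  reflect real locus-specific DNA increases.

The indexed collection for one time course is a :class:`NestedSet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import linearize, pad
from .depthio import BinnedDepth
from .errors import NormalizationError, ParameterError
from .layout import GenomeLayout
from .loess import LoessParams, Trendline, fit_trendline


# ---------------------------------------------------------------------------
# normalizations


def percent_mean_normalize(binned: BinnedDepth) -> BinnedDepth:
    """Convert absolute depth to percent of the mean over retained bins.

    The mean of the retained output bins is exactly 100; the operation is
    idempotent and makes samples with different sequencing depth
    comparable. Masked bins are rescaled with the same factor but carry no
    information downstream.
    """
    out = binned.copy()
    retained = out.values[out.retained]
    if retained.size == 0 or np.all(retained == 0):
        raise NormalizationError("cannot percent-normalize an all-zero track")
    mean = retained.mean()
    out.values = out.values * (100.0 / mean)
    return out


def _region_bin_slice(trend_or_binned, region, layout: GenomeLayout | None):
    if isinstance(region, str):
        if layout is None:
            raise ParameterError(f"region name {region!r} needs a GenomeLayout")
        lo, hi = layout.region_bins(region, trend_or_binned.bin_size)
    else:
        start, end = region
        tmp = GenomeLayout(
            "anon", trend_or_binned.length_bp, 1, 1, regions={"r": (start, end)}
        )
        lo, hi = tmp.region_bins("r", trend_or_binned.bin_size)
    return lo, hi


def region_mean(trend: Trendline, region, layout: GenomeLayout | None = None) -> float:
    """Mean trendline value over retained bins fully inside a region.

    ``region`` is a name (resolved through ``layout``) or a 1-based
    inclusive ``(start, end)`` pair. Bins only partially overlapping the
    region are excluded; masked bins are skipped, not interpolated.
    """
    lo, hi = _region_bin_slice(trend, region, layout)
    vals = trend.values[lo:hi]
    keep = trend.retained[lo:hi] & np.isfinite(vals)
    if not keep.any():
        raise NormalizationError(f"region {region!r} is entirely masked")
    return float(vals[keep].mean())


def normalize_to_region(
    trend: Trendline, region, layout: GenomeLayout | None = None
) -> Trendline:
    """Divide a trendline by its mean over a reference region.

    The region mean of the output is exactly 1; the operation is invariant
    to rescaling of the input.
    """
    m = region_mean(trend, region, layout)
    if m <= 0:
        raise NormalizationError(f"region {region!r} mean is not positive ({m})")
    out = trend.copy()
    out.values = out.values / m
    return out


# ---------------------------------------------------------------------------
# increase factors and nested sets


@dataclass
class IncreaseFactors:
    """Per-timepoint absolute DNA increase of a reporter region.

    Factors are hybridization signals normalized to the t0 signal, so
    ``factor(t0) == 1`` by construction.
    """

    timepoints: list
    factors: list

    def __post_init__(self):
        if len(self.timepoints) != len(self.factors):
            raise ParameterError("timepoints and factors differ in length")
        if any(f <= 0 for f in self.factors):
            raise ParameterError("all increase factors must be positive")
        t0 = min(self.timepoints)
        f0 = self.factors[self.timepoints.index(t0)]
        if abs(f0 - 1.0) > 1e-9:
            raise ParameterError(
                f"factor at the reference timepoint {t0} must be 1, got {f0}"
            )

    def factor(self, t) -> float:
        try:
            return float(self.factors[self.timepoints.index(t)])
        except ValueError:
            raise ParameterError(f"no increase factor for timepoint {t}") from None

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"timepoint_min": self.timepoints, "factor": self.factors}
        ).to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "IncreaseFactors":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df["timepoint_min"]), list(df["factor"]))


def increase_factors(signals: dict) -> IncreaseFactors:
    """Build increase factors from raw hybridization signals.

    ``signals`` maps timepoint (min) to a positive signal; every factor is
    ``signal(t) / signal(t0)`` with t0 the smallest timepoint.
    """
    if not signals:
        raise ParameterError("no signals given")
    t0 = min(signals)
    s0 = signals[t0]
    if s0 <= 0 or any(s <= 0 for s in signals.values()):
        raise ParameterError("signals must be positive")
    ts = sorted(signals)
    return IncreaseFactors(ts, [signals[t] / s0 for t in ts])


@dataclass
class NestedSet:
    """An indexed post-UV time course of trendlines.

    Each timepoint's trendline is normalized to the reference region and
    multiplied by that timepoint's increase factor, so the mean of the
    indexed trendline over the reference region equals the factor exactly.
    ``log_y`` is a presentation flag only; stored values are linear.
    """

    reference_region: object
    timepoints: list
    trendlines: dict
    factors: IncreaseFactors
    log_y: bool = False
    meta: dict = field(default_factory=dict)

    def indexed(self, t) -> Trendline:
        return self.trendlines[t]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.timepoints:
            tr = self.trendlines[t]
            starts = np.arange(tr.n_bins) * tr.bin_size
            rows.append(
                pd.DataFrame(
                    {
                        "timepoint_min": t,
                        "bin_start": starts,
                        "indexed_value": tr.values,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def export(self, tsv_path, json_path=None) -> None:
        """Long-format TSV (masked bins as missing values) + JSON metadata."""
        self.to_long_frame().to_csv(
            tsv_path, sep="\t", index=False, float_format="%.17g", na_rep="NA"
        )
        if json_path is not None:
            any_tr = self.trendlines[self.timepoints[0]]
            meta = {
                "reference_region": (
                    self.reference_region
                    if isinstance(self.reference_region, str)
                    else list(self.reference_region)
                ),
                "timepoints_min": list(self.timepoints),
                "factors": list(self.factors.factors),
                "loess": {
                    "span": any_tr.params.span,
                    "degree": any_tr.params.degree,
                    "robust_iterations": any_tr.params.robust_iterations,
                },
                "log_y": self.log_y,
                **self.meta,
            }
            with open(json_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def build_nested_set(
    trends: dict,
    region,
    factors: IncreaseFactors,
    layout: GenomeLayout | None = None,
    log_y: bool = False,
) -> NestedSet:
    """Normalize each timepoint to the reference region and index by factor.

    ``trends`` maps timepoint (min) to :class:`Trendline`. Every timepoint
    must have a factor; the indexed trendline at timepoint t has reference-
    region mean equal to ``factors.factor(t)`` (to 1e-9).
    """
    indexed = {}
    for t, tr in sorted(trends.items()):
        f = factors.factor(t)  # raises if missing
        normed = normalize_to_region(tr, region, layout)
        normed.values = normed.values * f
        indexed[t] = normed
    return NestedSet(
        reference_region=region,
        timepoints=sorted(trends),
        trendlines=indexed,
        factors=factors,
        log_y=log_y,
    )


# ---------------------------------------------------------------------------
# replicate combination


def average_replicates(
    binned_list,
    cut_pos: int,
    pad_bins: int = 1000,
    params: LoessParams | None = None,
) -> Trendline:
    """Combine replicate samples into one summary trendline.

    Each replicate is percent-mean normalized (removing depth differences),
    linearized at ``cut_pos``, padded, and LOESS-fitted; the resulting
    trendlines are averaged pointwise with equal weights. The result is
    invariant to replicate order and to per-replicate depth scaling.
    Averaging normalized profiles *before* the fit gives virtually the
    same summary trendline (see tests); the trendline-averaging order is
    the default because it keeps per-replicate fits available.
    """
    if len(binned_list) < 1:
        raise ParameterError("need at least one replicate")
    first = binned_list[0]
    for b in binned_list[1:]:
        if b.n_bins != first.n_bins or b.bin_size != first.bin_size:
            raise ParameterError("replicates must share binning")
        if not np.array_equal(b.mask, first.mask):
            raise ParameterError("replicates must share the same mask")
    trends = []
    for b in binned_list:
        prof = pad(linearize(percent_mean_normalize(b), cut_pos), pad_bins)
        trends.append(fit_trendline(prof, params))
    out = trends[0].copy()
    out.values = np.mean([t.values for t in trends], axis=0)
    return out


def locus_ratio_timecourse(a_signals: dict, b_signals: dict) -> dict:
    """Ratio of two locus signals over time, normalized to its t0 value.

    ``r(t) = (a(t)/b(t)) / (a(t0)/b(t0))``; by construction ``r(t0) = 1``.
    Used to confirm copy-number differences between two loci (e.g. the
    mdtP/uvrD ratio during post-UV recovery) independently of sequencing.
    """
    if set(a_signals) != set(b_signals):
        raise ParameterError("the two loci must be measured at the same timepoints")
    t0 = min(a_signals)
    for sig in (a_signals, b_signals):
        if any(v <= 0 for v in sig.values()):
            raise ParameterError("signals must be positive")
    ref = a_signals[t0] / b_signals[t0]
    return {t: (a_signals[t] / b_signals[t]) / ref for t in sorted(a_signals)}
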