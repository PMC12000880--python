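"""Calling features on replication trendlines.

Four related calls:

* **extrema** — local peaks and troughs of the trendline, filtered by a
  prominence threshold expressed as a fraction of the profile median;
* **zones** — broad initiation ("oriK-like") zones: maximal intervals
  between consecutive qualifying troughs whose interior rises above the
  flanking trough level;
* **association** — labelling each trough with the nearest annotated
  locus (*ter* site or *rrn* operon) within a distance cutoff;
* **downshifts** — directional step decreases of the trendline
  (fork-stalling signatures): the mean over an upstream window compared
  with a downstream window across a gap, scanned in the stated fork-travel
  direction.

All calls operate on the smoothed trendline, not raw bins, and treat the
chromosome as circular; positions are native bin midpoints in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError
from .layout import CCW, CW, GenomeLayout
from .loess import Trendline


@dataclass
class FeatureCall:
    """Container for one profile's called features."""

    peaks: pd.DataFrame
    troughs: pd.DataFrame
    zones: pd.DataFrame = None
    downshifts: pd.DataFrame = None
    associations: pd.DataFrame = None
    params: dict = field(default_factory=dict)

    def zones_to_bed(self, path, chrom: str = "chr") -> None:
        """Zones as BED6; score column holds the summit height (scaled)."""
        with open(path, "w") as fh:
            for _, z in self.zones.iterrows():
                score = min(int(round(z["summit_height"] * 100)), 1000)
                fh.write(
                    f"{chrom}\t{int(z['start_bp'])}\t{int(z['end_bp'])}\t"
                    f"{z['name']}\t{score}\t.\n"
                )

    def downshifts_to_tsv(self, path) -> None:
        self.downshifts.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _retained_xy(trend: Trendline):
    keep = trend.retained & np.isfinite(trend.values)
    pos = trend.bin_midpoints()[keep]
    val = trend.values[keep]
    return pos, val


def _refine_kink(pos, val, L, p0, sign, flank_left, flank_right):
    """Refine an extremum by fitting a continuous two-slope kink.

    A replication origin (or stall trough) sits where two near-exponential
    copy-number gradients meet, so the extremum of the noisy trendline is
    a poor position estimate: the apex is flat while the flanks are well
    determined. A continuous piecewise-linear model
    ``log2 y = b + m1*min(x - x0, 0) + m2*max(x - x0, 0)`` is least-squares
    fitted over circular offsets in ``[-flank_left, flank_right]`` bp of
    the raw extremum, scanning the breakpoint ``x0`` on the data grid and
    keeping the RSS minimum. The refinement is kept only when the fitted
    slopes have the expected signs and the breakpoint is not pinned at the
    scan edge; otherwise the raw position is returned.
    """
    off = (pos - p0 + L / 2) % L - L / 2  # signed circular offset
    sel = (off >= -flank_left) & (off <= flank_right)
    if sel.sum() < 20:
        return p0
    x = off[sel]
    y = np.log2(val[sel])
    order = np.argsort(x)
    x, y = x[order], y[order]
    half = min(flank_left, flank_right) / 2.0
    scan = x[(x >= -half) & (x <= half)]
    if len(scan) < 3:
        return p0
    ones = np.ones_like(x)
    lo = np.minimum(x[:, None] - scan[None, :], 0.0)
    hi = np.maximum(x[:, None] - scan[None, :], 0.0)
    best = (np.inf, 0.0, 0.0, 0.0)
    for j, x0 in enumerate(scan):
        X = np.stack([ones, lo[:, j], hi[:, j]], axis=1)
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(res[0]) if len(res) else float(np.sum((X @ beta - y) ** 2))
        if rss < best[0]:
            best = (rss, x0, beta[1], beta[2])
    _, x0, m1, m2 = best
    if not (sign * m1 > 0 and sign * m2 < 0):
        return p0
    if abs(x0) >= half:  # pinned at the scan edge: untrustworthy
        return p0
    return (p0 + x0) % L


def call_extrema(
    trend: Trendline,
    min_prominence: float = 0.05,
    refine_flank_bp: int | None = 60_000,
    raw=None,
):
    """Circular peak/trough detection on the trendline.

    ``min_prominence`` is a fraction of the median retained trendline
    value; extrema with smaller prominence are discarded. By default each
    extremum position is refined by a continuous two-slope kink fit to
    its flanking gradients (see :func:`_refine_kink`); the per-side fit
    window extends to 80% of the distance to the nearest opposite-sign
    extremum, capped at ``refine_flank_bp`` — so the window stays inside
    the extremum's own zone, away from neighbouring troughs/peaks and the
    sharp structure near them. Pass ``refine_flank_bp=None`` for raw
    extremum bins. When ``raw`` (a :class:`~forkprof.depthio.BinnedDepth`
    aligned with the trendline) is supplied, the kink fits use the raw
    bins, whose noise is independent bin to bin, instead of the smoothed
    values, whose noise is correlated over the LOESS window —
    substantially better localization. Returns ``(peaks, troughs)``
    DataFrames with columns position_bp, height (trough depth for
    troughs), prominence. A flat profile yields empty frames.
    """
    pos, val = _retained_xy(trend)
    m = len(val)
    if m < 3:
        raise ParameterError("too few retained bins for extremum calling")
    med = float(np.median(val))
    prom = min_prominence * abs(med)
    L = trend.length_bp
    rpos, rval = pos, val
    if raw is not None:
        ok = raw.retained & np.isfinite(raw.values) & (raw.values > 0)
        rpos, rval = raw.bin_midpoints()[ok], raw.values[ok]
    # tile x3 so circular extrema and their prominences are seen correctly
    v3 = np.concatenate([val, val, val])
    raw_idx = {}
    props_by = {}
    for sign, name in ((1.0, "peaks"), (-1.0, "troughs")):
        idx, props = find_peaks(sign * v3, prominence=prom)
        keep = (idx >= m) & (idx < 2 * m)
        raw_idx[name] = idx[keep] - m
        props_by[name] = props["prominences"][keep]
    out = {}
    for sign, name, other in ((1.0, "peaks", "troughs"),
                              (-1.0, "troughs", "peaks")):
        idx = raw_idx[name]
        p = pos[idx].astype(float)
        bounds = pos[raw_idx[other]].astype(float)
        if refine_flank_bp and np.all(rval > 0):
            refined = []
            for pi in p:
                fl = fr = float(refine_flank_bp)
                if len(bounds):
                    fr = min(fr, 0.8 * ((bounds - pi) % L).min())
                    fl = min(fl, 0.8 * ((pi - bounds) % L).min())
                refined.append(
                    _refine_kink(rpos, rval, L, pi, sign, fl, fr)
                )
            p = np.array(refined)
        out[name] = pd.DataFrame(
            {
                "position_bp": p,
                "height": val[idx],
                "prominence": props_by[name],
            }
        ).sort_values("position_bp", ignore_index=True)
    return out["peaks"], out["troughs"]


def call_zones(
    trend: Trendline, troughs: pd.DataFrame, min_prominence: float = 0.05
) -> pd.DataFrame:
    """Initiation zones: intervals between consecutive troughs with an
    elevated interior.

    Consecutive troughs (circularly) delimit a candidate zone; the zone is
    reported when the interior mean exceeds the higher flanking trough
    level by at least ``min_prominence`` of the profile median. Zones are
    disjoint by construction; a wrap-around zone has ``start_bp > end_bp``.
    Columns: name, start_bp, end_bp, summit_bp, summit_height.
    """
    pos, val = _retained_xy(trend)
    med = float(np.median(val))
    thresh = min_prominence * abs(med)
    L = trend.length_bp
    tpos = np.sort(troughs["position_bp"].to_numpy())
    rows = []
    if len(tpos) == 0:
        return pd.DataFrame(
            columns=["name", "start_bp", "end_bp", "summit_bp", "summit_height"]
        )
    tval = np.interp(tpos, pos, val)  # trendline level at each trough
    nt = len(tpos)
    for i in range(nt):
        a, b = tpos[i], tpos[(i + 1) % nt]
        if a < b:
            inside = (pos > a) & (pos < b)
        else:  # wraps through the origin of coordinates
            inside = (pos > a) | (pos < b)
        if not inside.any():
            continue
        interior = val[inside]
        flank = max(tval[i], tval[(i + 1) % nt])
        if interior.mean() - flank < thresh:
            continue
        ppos = pos[inside]
        s = int(np.argmax(interior))
        rows.append(
            {
                "start_bp": float(a),
                "end_bp": float(b),
                "summit_bp": float(ppos[s]),
                "summit_height": float(interior[s]),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("start_bp", ignore_index=True)
        df.insert(0, "name", [f"zone_{i + 1}" for i in range(len(df))])
    else:
        df = pd.DataFrame(
            columns=["name", "start_bp", "end_bp", "summit_bp", "summit_height"]
        )
    return df


def associate(
    troughs: pd.DataFrame, layout: GenomeLayout, max_dist: int = 20_000
) -> pd.DataFrame:
    """Label each trough with the nearest annotated locus within max_dist.

    Candidates are the layout's *ter* sites (point position) and *rrn*
    operons (midpoint); distances are circular. Troughs with nothing
    within ``max_dist`` are labelled ``unassigned``.
    """
    loci = [(t.name, "ter", t.position) for t in layout.ter_sites]
    loci += [
        (r.name, "rrn", (r.start + r.end) // 2) for r in layout.rrn_operons
    ]
    rows = []
    for _, tr in troughs.iterrows():
        p = tr["position_bp"]
        best = ("unassigned", "none", np.nan)
        best_d = max_dist
        for name, kind, lp in loci:
            d = layout.circular_distance(int(round(p)), lp)
            if d <= best_d:
                best, best_d = (name, kind, d), d
        rows.append(
            {
                "trough_bp": p,
                "locus": best[0],
                "kind": best[1],
                "distance_bp": best[2] if best[0] != "unassigned" else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _rolling_mean_circular(val: np.ndarray, ok: np.ndarray, w: int):
    """Circular rolling mean over windows of w bins, skipping masked bins.

    Returns mean[i] = mean of valid values in bins [i, i+w) (circularly),
    NaN where no valid bin falls in the window.
    """
    n = len(val)
    v = np.where(ok, val, 0.0)
    v3 = np.concatenate([v, v, v])
    c3 = np.concatenate([ok, ok, ok]).astype(float)
    cv = np.concatenate([[0.0], np.cumsum(v3)])
    cc = np.concatenate([[0.0], np.cumsum(c3)])
    i = np.arange(n, 2 * n)
    sums = cv[i + w] - cv[i]
    cnts = cc[i + w] - cc[i]
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan), cnts


def detect_downshifts(
    trend: Trendline,
    direction: str,
    window: int = 50_000,
    gap: int = 10_000,
    min_drop: float = 1.10,
) -> pd.DataFrame:
    """Directional copy-number downshifts (fork-stalling discontinuities).

    Scanning in the fork-travel ``direction`` (CW = increasing native
    coordinate), each candidate position compares the trendline mean over
    the ``window`` bp upstream (already replicated side) against the
    ``window`` bp downstream, the two separated by ``gap`` bp. Local
    maxima of the upstream/downstream ratio reaching ``min_drop`` are
    reported; the step position is the bin of steepest descent within the
    gap. Columns: position_bp, upstream_mean, downstream_mean, drop_ratio,
    direction.
    """
    if direction not in (CW, CCW):
        raise ParameterError(f"direction must be CW or CCW, got {direction!r}")
    if window <= 0 or gap <= 0:
        raise ParameterError("window and gap must be positive")
    b = trend.bin_size
    n = trend.n_bins
    W = max(int(round(window / b)), 1)
    G2 = max(int(round(gap / b / 2)), 1)
    if W >= n // 2:
        raise ParameterError(
            f"window of {W} bins is at least half the chromosome ({n} bins)"
        )

    if direction == CCW:
        # mirror, call the CW scanner, and mirror the calls back
        mirrored = trend.copy()
        mirrored.values = trend.values[::-1].copy()
        mirrored.mask = trend.mask[::-1].copy()
        calls = detect_downshifts(mirrored, CW, window, gap, min_drop)
        mid = trend.bin_midpoints()
        L_axis = mid[0] + mid[-1]  # reflection maps midpoint m -> L_axis - m
        calls["position_bp"] = L_axis - calls["position_bp"]
        calls["direction"] = CCW
        return calls.sort_values("position_bp", ignore_index=True)

    ok = trend.retained & np.isfinite(trend.values)
    val = np.where(ok, trend.values, 0.0)
    up_mean, up_cnt = _rolling_mean_circular(val, ok, W)
    # upstream window [i-G2-W, i-G2): shift so index i refers to candidate bin
    up = np.roll(up_mean, W + G2)
    upc = np.roll(up_cnt, W + G2)
    down = np.roll(up_mean, -G2)
    downc = np.roll(up_cnt, -G2)
    valid = (upc > 0) & (downc > 0) & (down > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, up / down, np.nan)
    r = np.where(np.isfinite(ratio), ratio, 0.0)
    r3 = np.concatenate([r, r, r])
    idx, props = find_peaks(r3, height=min_drop)
    keep = (idx >= n) & (idx < 2 * n)
    idx = idx[keep] - n
    mid = trend.bin_midpoints()
    rows = []
    for i in idx:
        # refine: steepest local descent within +-G2 bins of the candidate
        lo, hi = i - G2, i + G2 + 1
        span_idx = np.arange(lo, hi) % n
        vals = trend.values[span_idx]
        with np.errstate(invalid="ignore"):
            grad = vals[:-1] - vals[1:]  # positive where dropping left->right
        grad = np.where(np.isfinite(grad), grad, -np.inf)
        j = span_idx[int(np.argmax(grad))]
        rows.append(
            {
                "position_bp": float(mid[j]),
                "upstream_mean": float(up[i]),
                "downstream_mean": float(down[i]),
                "drop_ratio": float(ratio[i]),
                "direction": CW,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "position_bp",
            "upstream_mean",
            "downstream_mean",
            "drop_ratio",
            "direction",
        ],
    )
    return df.sort_values("position_bp", ignore_index=True) if len(df) else df


def call_features(
    trend: Trendline,
    layout: GenomeLayout | None = None,
    min_prominence: float = 0.05,
    max_dist: int = 20_000,
    window: int = 50_000,
    gap: int = 10_000,
    min_drop: float = 1.10,
    directions=(CW, CCW),
    raw=None,
) -> FeatureCall:
    """Run the full feature-calling battery on one trendline."""
    peaks, troughs = call_extrema(trend, min_prominence, raw=raw)
    zones = call_zones(trend, troughs, min_prominence)
    shifts = []
    for d in directions:
        shifts.append(detect_downshifts(trend, d, window, gap, min_drop))
    downshifts = pd.concat(shifts, ignore_index=True) if shifts else None
    assoc = associate(troughs, layout, max_dist) if layout is not None else None
    return FeatureCall(
        peaks=peaks,
        troughs=troughs,
        zones=zones,
        downshifts=downshifts,
        associations=assoc,
        params={
            "min_prominence": min_prominence,
            "max_dist": max_dist,
            "window": window,
            "gap": gap,
            "min_drop": min_drop,
        },
    )
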