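"""Robust local polynomial regression (LOESS) for replication profiles.

This is a direct-surface LOESS: at every retained bin the local weighted
least-squares polynomial (degree 2 by default) is solved exactly over the
``k = ceil(span * n)`` nearest retained neighbours, with tricube distance
weights. The "symmetric family" robustness of classic LOESS is applied on
top: after the initial fit, residuals are pooled globally and each point
receives a Tukey-bisquare weight with scale ``6 * median(|residual|)``,
multiplying the tricube weights; fit and reweighting alternate for a
configurable number of iterations (default 8, i.e. 9 fitting passes).

The smoother matrix diagonal is available in closed form at every point
(the fitted value is linear in y for fixed weights), which makes the exact
trace of the hat matrix — and hence GCV and AICc span selection — cheap at
any problem size.

Masked bins are excluded from both fitting and evaluation; no imputation
is performed, and the returned trendline carries NaN there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circular import LinearizedProfile
from .errors import ParameterError

_CHUNK = 2048  # points solved per vectorized block; bounds peak memory


@dataclass(frozen=True)
class LoessParams:
    """LOESS settings.

    Parameters
    ----------
    span : float
        Fraction of retained points in each local neighbourhood, in (0, 1].
        Default 0.025 (~115 kb on a 100-bp-binned 4.6-Mb chromosome).
    degree : int
        Local polynomial degree (0, 1 or 2; default 2).
    robust_iterations : int
        Number of bisquare reweighting rounds after the initial fit
        (default 8).
    """

    span: float = 0.025
    degree: int = 2
    robust_iterations: int = 8

    def __post_init__(self):
        if not 0.0 < self.span <= 1.0:
            raise ParameterError(f"span must be in (0, 1], got {self.span}")
        if self.degree not in (0, 1, 2):
            raise ParameterError(f"degree must be 0, 1 or 2, got {self.degree}")
        if self.robust_iterations < 0:
            raise ParameterError("robust_iterations must be >= 0")


@dataclass
class LoessFit:
    """Result of one LOESS fit on a set of retained points."""

    x: np.ndarray
    fitted: np.ndarray
    params: LoessParams
    k: int
    robust_weights: np.ndarray
    rss: float
    trace_hat: float | None = None


def _neighbor_starts(x: np.ndarray, k: int) -> np.ndarray:
    """Start index of the k-nearest contiguous window for each point.

    Ties in distance are broken toward the lower index (the window is not
    advanced when the incoming and outgoing distances are equal).
    """
    n = len(x)
    starts = np.empty(n, dtype=np.int64)
    s = 0
    for i in range(n):
        xi = x[i]
        while s + k < n and x[s + k] - xi < xi - x[s]:
            s += 1
        starts[i] = s
    return starts


def _solve_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched SPD-ish solve with a pseudoinverse fallback for singular blocks."""
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        out = np.empty_like(b)
        for i in range(len(A)):
            try:
                out[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                out[i] = np.linalg.pinv(A[i], rcond=1e-12) @ b[i]
        return out


def _fit_pass(x, y, starts, k, degree, rw, w0, need_trace):
    """One weighted local-polynomial pass. Returns (fitted, hat_diagonal)."""
    n = len(x)
    p = degree + 1
    fitted = np.empty(n)
    hat = np.empty(n) if need_trace else None
    offsets = np.arange(k)
    for c0 in range(0, n, _CHUNK):
        c1 = min(c0 + _CHUNK, n)
        idx = starts[c0:c1, None] + offsets  # (m, k)
        dx = x[idx] - x[c0:c1, None]
        h = np.maximum(np.abs(dx[:, 0]), np.abs(dx[:, -1]))
        h[h == 0] = 1.0  # k == 1 degenerate window
        u = np.abs(dx) / h[:, None]
        w = (1.0 - u * u * u) ** 3
        np.maximum(w, 0.0, out=w)
        w *= rw[idx]
        if w0 is not None:
            w *= w0[idx]
        t = dx / h[:, None]  # scaled abscissa for conditioning
        yw = y[idx]
        # weighted moment matrices A (m,p,p) and right-hand sides b (m,p)
        powers = [np.ones_like(t)]
        for _ in range(2 * degree):
            powers.append(powers[-1] * t)
        S = [np.einsum("mk,mk->m", w, powers[q]) for q in range(2 * degree + 1)]
        T = [np.einsum("mk,mk,mk->m", w, powers[q], yw) for q in range(p)]
        m = c1 - c0
        A = np.empty((m, p, p))
        for a in range(p):
            for bq in range(p):
                A[:, a, bq] = S[a + bq]
        b = np.stack(T, axis=1)
        if need_trace:
            rhs = np.concatenate([b[:, :, None], np.eye(p)[None, :, :1].repeat(m, 0)], axis=2)
            sol = _solve_batch(A, rhs)
            beta = sol[:, :, 0]
            ainv00 = sol[:, 0, 1]
            own = np.arange(c0, c1) - starts[c0:c1]
            w_self = w[np.arange(m), own]
            hat[c0:c1] = w_self * ainv00
        else:
            beta = _solve_batch(A, b[:, :, None])[:, :, 0]
        fitted[c0:c1] = beta[:, 0]
    return fitted, hat


def loess_fit(
    x,
    y,
    params: LoessParams | None = None,
    weights=None,
    compute_trace: bool = False,
) -> LoessFit:
    """Robust LOESS at every point of ``x`` (direct surface).

    Parameters
    ----------
    x : array
        Strictly increasing abscissae of the retained points.
    y : array
        Values at ``x``.
    params : LoessParams
    weights : array, optional
        Prior per-point weights multiplied into the local kernel weights.
    compute_trace : bool
        Also compute the exact trace of the smoother (hat) matrix, needed
        for GCV/AICc span selection.

    Returns
    -------
    LoessFit
        Fitted values at every ``x``, the final robustness weights, the
        residual sum of squares and (optionally) the hat-matrix trace.
    """
    if params is None:
        params = LoessParams()
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    if len(x) > 1 and np.any(np.diff(x) <= 0):
        raise ParameterError("x must be strictly increasing among retained points")
    n = len(x)
    k = min(math.ceil(params.span * n), n)
    if k < 6:
        raise ParameterError(
            f"local window holds only {k} points (span {params.span}, n {n}); "
            "need at least 6"
        )
    w0 = None if weights is None else np.ascontiguousarray(weights, dtype=float)
    starts = _neighbor_starts(x, k)

    rw = np.ones(n)
    fitted = y.copy()
    hat = None
    n_pass = params.robust_iterations + 1
    for it in range(n_pass):
        last = it == n_pass - 1
        fitted, hat = _fit_pass(
            x, y, starts, k, params.degree, rw, w0, need_trace=(compute_trace and last)
        )
        if last:
            break
        resid = y - fitted
        s = 6.0 * np.median(np.abs(resid))
        # floor: residuals at floating-point noise level mean a perfect fit;
        # reweighting on that noise would amplify it instead of robustifying
        if s <= 1e-9 * max(np.max(np.abs(y)), 1e-300):
            rw = np.ones(n)
            continue
        u = resid / s
        rw = np.clip(1.0 - u * u, 0.0, None) ** 2
    rss = float(np.sum((y - fitted) ** 2))
    return LoessFit(
        x=x,
        fitted=fitted,
        params=params,
        k=k,
        robust_weights=rw,
        rss=rss,
        trace_hat=float(np.sum(hat)) if hat is not None else None,
    )


def effective_window_bp(span: float, n_bins: int, bin_size: int) -> int:
    """Genomic width of the LOESS window: ``round(span * n_bins) * bin_size``.

    On the 100-bp-binned 4,641,652-bp MG1655 chromosome (46,417 bins) this
    gives 116,000 bp at span 0.025 and 232,100 bp at span 0.05.
    """
    if span <= 0 or n_bins <= 0 or bin_size <= 0:
        raise ParameterError("span, n_bins and bin_size must be positive")
    return int(round(span * n_bins)) * bin_size


# ---------------------------------------------------------------------------
# trendlines over linearized profiles


@dataclass
class Trendline:
    """Smoothed copy-number values per native bin.

    ``values`` is NaN at masked bins (no imputation). ``params`` records
    the LOESS settings that produced the fit, for provenance.
    """

    values: np.ndarray
    mask: np.ndarray
    bin_size: int
    length_bp: int
    params: LoessParams
    n_fit: int
    pad_bins: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def retained(self) -> np.ndarray:
        return ~self.mask

    @property
    def effective_window_bp(self) -> int:
        return effective_window_bp(self.params.span, self.n_bins, self.bin_size)

    def bin_midpoints(self) -> np.ndarray:
        mid = np.arange(self.n_bins, dtype=float) * self.bin_size + self.bin_size / 2.0
        mid[-1] = (self.bin_size * (self.n_bins - 1) + self.length_bp) / 2.0
        return mid

    def copy(self) -> "Trendline":
        return Trendline(
            self.values.copy(),
            self.mask.copy(),
            self.bin_size,
            self.length_bp,
            self.params,
            self.n_fit,
            self.pad_bins,
        )


def fit_trendline(
    profile: LinearizedProfile,
    params: LoessParams | None = None,
    weights=None,
) -> Trendline:
    """Fit a LOESS trendline on a (padded) linearized profile.

    Masked bins are excluded from the fit and get no fitted value. Pads
    participate in the fit (that is their purpose: the smoother sees the
    circular continuation) and are trimmed from the result, which is
    returned in native bin order.
    """
    if params is None:
        params = LoessParams()
    retain = ~profile.mask
    fit = loess_fit(profile.x[retain], profile.y[retain], params, weights=weights)
    full = np.full(len(profile.x), np.nan)
    full[retain] = fit.fitted
    core = full[~profile.pad_mask]
    native = profile.restore_native(core)
    native_mask = np.zeros_like(native, dtype=bool)
    native_mask[profile.order] = profile.mask[~profile.pad_mask]
    src = profile.source
    return Trendline(
        values=native,
        mask=native_mask,
        bin_size=src.bin_size,
        length_bp=src.length_bp,
        params=params,
        n_fit=int(retain.sum()),
        pad_bins=profile.pad_bins,
    )


# ---------------------------------------------------------------------------
# span selection


@dataclass
class SpanSelection:
    """Outcome of data-driven span selection."""

    criterion: str
    spans: list = field(default_factory=list)
    scores: list = field(default_factory=list)
    chosen_span: float = float("nan")
    chosen_score: float = float("nan")
    method: str = "golden"


def _criterion_score(x, y, span, criterion, params, weights):
    p = LoessParams(span=span, degree=params.degree,
                    robust_iterations=params.robust_iterations)
    fit = loess_fit(x, y, p, weights=weights, compute_trace=True)
    n = len(x)
    tr = fit.trace_hat
    if criterion == "gcv":
        denom = n - tr
        if denom <= 0:
            raise ParameterError(f"span {span} too small: trace(L)={tr:.1f} >= n={n}")
        return n * fit.rss / denom**2
    if criterion == "aicc":
        if n - tr - 2 <= 0:
            raise ParameterError(
                f"span {span} too small for AICc: n - trace(L) - 2 <= 0"
            )
        sigma2 = fit.rss / n
        with np.errstate(divide="ignore"):
            return float(np.log(sigma2) + 1 + 2 * (tr + 1) / (n - tr - 2))
    raise ParameterError(f"criterion must be 'gcv' or 'aicc', got {criterion!r}")


def select_span(
    x,
    y,
    criterion: str = "gcv",
    interval: tuple[float, float] = (0.01, 0.5),
    params: LoessParams | None = None,
    method: str = "golden",
    grid: int = 20,
    weights=None,
    tol: float = 1e-3,
) -> SpanSelection:
    """Choose the LOESS span minimizing GCV or AICc over an interval.

    ``method='golden'`` runs a coarse scan followed by golden-section
    refinement around the best coarse point; ``method='grid'`` evaluates a
    uniform grid of ``grid`` spans. The criteria assume a linear smoother,
    so by default they are evaluated without robustness iterations; pass
    ``params`` to override.

    Scores within a small tolerance of the minimum are treated as ties and
    resolved toward the *largest* span (prefer more smoothing among
    indistinguishable fits), which makes the zero-residual limit
    well-defined: on noise-free polynomial data the upper search bound is
    chosen.
    """
    if params is None:
        params = LoessParams(span=1.0, robust_iterations=0)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = interval
    if not (0 < lo < hi <= 1):
        raise ParameterError(f"invalid span interval {interval}")

    def score(s):
        try:
            return _criterion_score(x, y, s, criterion, params, weights)
        except ParameterError:
            return float("inf")

    sel = SpanSelection(criterion=criterion, method=method)

    def record(s, v):
        sel.spans.append(float(s))
        sel.scores.append(float(v))
        return v

    # absolute tie tolerance on the criterion scale
    if criterion == "gcv":
        tie = 1e-10 * float(np.var(y)) + 1e-300
    else:
        tie = 1e-9

    if method == "grid":
        cand = np.linspace(lo, hi, grid)
        vals = [record(s, score(s)) for s in cand]
        best = min(vals)
        ties = [s for s, v in zip(cand, vals) if v <= best + tie]
        sel.chosen_span = float(max(ties))
        sel.chosen_score = best
        return sel
    if method != "golden":
        raise ParameterError(f"method must be 'golden' or 'grid', got {method!r}")

    # coarse scan to bracket, then golden-section refinement
    n_coarse = 8
    coarse = np.linspace(lo, hi, n_coarse)
    cvals = [record(s, score(s)) for s in coarse]
    best = min(cvals)
    ties = [i for i, v in enumerate(cvals) if v <= best + tie]
    ib = max(ties)
    a = coarse[max(ib - 1, 0)]
    b = coarse[min(ib + 1, n_coarse - 1)]
    invphi = (math.sqrt(5) - 1) / 2
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = record(c, score(c)), record(d, score(d))
    while b - a > tol:
        # '<=' sends exact ties toward the larger-span side
        if fd <= fc + tie:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = record(d, score(d))
        else:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = record(c, score(c))
    i_best = int(np.argmin(sel.scores))
    best_score = sel.scores[i_best]
    tied = [s for s, v in zip(sel.spans, sel.scores) if v <= best_score + tie]
    sel.chosen_span = float(max(tied))
    sel.chosen_score = best_score
    return sel
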