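"""Forward simulation of replicating bacterial chromosome populations.

The generator produces ground-truthed synthetic datasets for every
downstream stage: steady-state exponential-growth copy-number gradients
(the classic marker-frequency law), multi-origin initiation, polar *ter*
fork traps, localized stall sites (rrn-like slow-down or choke points),
and post-UV recovery time courses, all sampled to binned read depth with
Poisson noise.

Model
-----
Each simulated cell holds one circular chromosome plus the replication
rounds active on it. In steady exponential growth with doubling time tau,
cell ages are drawn from the exponential-growth age distribution with
density ``(2 ln2 / tau) * 2**(-a/tau)`` on [0, tau); rounds initiate every
tau minutes in a lineage, so the round elapsed times of a cell of age
``a`` are ``a, a+tau, a+2tau, ...`` with fully completed rounds removed
(completion doubles every locus once and is cancelled by division). A
locus covered by ``m`` active rounds carries ``2**m`` copies. For a locus
replicated ``t(x)`` minutes after initiation this reproduces the
population law ``M(x) ~ 2**(-t(x)/tau)`` exactly, which is retained as the
closed-form no-barrier oracle (:func:`steady_state_profile`).

Forks advance at ``fork_speed``. A *ter* trap arrests forks traveling in
its blocked direction with probability ``efficiency``; the arrested
region is finished by the converging fork. A stall site either slows
traversal by a factor or blocks with a per-minute passage probability
(waiting time drawn exponentially). Trap and stall outcomes are sampled
once per replication round (per site and direction) and shared by all
forks of the round, so a bin's replication time is exactly the minimum
over origins and directions of the path arrival time.

UV recovery freezes all pre-existing forks at t = 0 and, after a lag,
restarts initiation only at the configured origins (optionally at a
reduced fork speed), re-initiating at a fixed interval; no divisions occur
during recovery, so new rounds only add copies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .depthio import BinnedDepth, write_bedgraph
from .errors import ConfigError, ParameterError
from .layout import CCW, CW, GenomeLayout, TerSite
from .profiles import IncreaseFactors

_DIR_SIGN = {CW: +1, CCW: -1}


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class Origin:
    """A replication origin: scheduled origins fire every round; a
    stochastic-rate origin fires in each round with probability ``weight``."""

    position: int
    mode: str = "scheduled"
    weight: float = 1.0

    def __post_init__(self):
        if self.mode not in ("scheduled", "stochastic-rate"):
            raise ConfigError(f"origin mode {self.mode!r} unknown")
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigError("origin weight must be in [0, 1]")


@dataclass(frozen=True)
class StallSite:
    """A hard-to-replicate interval (1-based inclusive coordinates).

    ``mode='slowdown'`` multiplies traversal time by ``factor``;
    ``mode='block'`` holds the fork at the entry with per-minute passage
    probability ``passage_prob`` (exponential waiting time).
    """

    start: int
    end: int
    mode: str = "slowdown"
    factor: float = 10.0
    passage_prob: float = 0.1

    def __post_init__(self):
        if self.start > self.end:
            raise ConfigError("stall site start > end")
        if self.mode not in ("slowdown", "block"):
            raise ConfigError(f"stall mode {self.mode!r} unknown")
        if self.mode == "slowdown" and self.factor < 1.0:
            raise ConfigError("slowdown factor must be >= 1")
        if self.mode == "block" and not 0.0 < self.passage_prob <= 1.0:
            raise ConfigError("passage_prob must be in (0, 1]")


@dataclass(frozen=True)
class UVRecovery:
    """Post-UV recovery scenario: forks halt at t=0; initiation restarts
    only at ``restart_origins`` after ``lag_min``, then every
    ``reinit_interval_min``; ``fork_speed`` overrides the growth speed."""

    lag_min: float
    restart_origins: tuple
    fork_speed: float | None = None
    reinit_interval_min: float | None = None


@dataclass
class SimConfig:
    """Complete description of one simulation scenario."""

    layout: GenomeLayout
    origins: list
    fork_speed: float  # bp/min
    doubling_time: float  # min
    ter_traps: list = field(default_factory=list)
    stall_sites: list = field(default_factory=list)
    uv: UVRecovery | None = None
    n_cells: int = 8000
    mean_depth: float = 50.0
    bin_size: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.fork_speed <= 0 or self.doubling_time <= 0:
            raise ConfigError("fork_speed and doubling_time must be positive")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.seed is None:
            raise ConfigError("a seed is mandatory for any stochastic path")
        L = self.layout.length_bp
        for o in self.origins:
            if not 1 <= o.position <= L:
                raise ConfigError(f"origin at {o.position} outside chromosome")
            for s in self.stall_sites:
                if s.start <= o.position <= s.end:
                    raise ConfigError("an origin lies inside a stall site")

    @property
    def n_bins(self) -> int:
        return self.layout.n_bins(self.bin_size)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "layout": self.layout.to_dict(),
            "origins": [asdict(o) for o in self.origins],
            "fork_speed": self.fork_speed,
            "doubling_time": self.doubling_time,
            "ter_traps": [asdict(t) for t in self.ter_traps],
            "stall_sites": [asdict(s) for s in self.stall_sites],
            "uv": (
                {**asdict(self.uv), "restart_origins": list(self.uv.restart_origins)}
                if self.uv
                else None
            ),
            "n_cells": self.n_cells,
            "mean_depth": self.mean_depth,
            "bin_size": self.bin_size,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        uv = d.get("uv")
        return cls(
            layout=GenomeLayout.from_dict(d["layout"]),
            origins=[Origin(**o) for o in d["origins"]],
            fork_speed=d["fork_speed"],
            doubling_time=d["doubling_time"],
            ter_traps=[TerSite(**t) for t in d.get("ter_traps", [])],
            stall_sites=[StallSite(**s) for s in d.get("stall_sites", [])],
            uv=UVRecovery(
                lag_min=uv["lag_min"],
                restart_origins=tuple(uv["restart_origins"]),
                fork_speed=uv.get("fork_speed"),
                reinit_interval_min=uv.get("reinit_interval_min"),
            )
            if uv
            else None,
            n_cells=d.get("n_cells", 8000),
            mean_depth=d.get("mean_depth", 50.0),
            bin_size=d.get("bin_size", 100),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# fork-path geometry


def _dist_along(L: float, frm: float, to: float, sign: int) -> float:
    return (to - frm) % L if sign > 0 else (frm - to) % L


class _Path:
    """Static geometry of one fork path (origin, direction).

    Edges partition [0, L] path distance into constant-speed pieces;
    point events (traps, block-mode stalls) sit on edges and contribute a
    per-round delay (infinite for a blocking trap).
    """

    __slots__ = ("edges", "tpb", "events", "sign")

    def __init__(self, config: SimConfig, origin_pos: float, direction: str,
                 fork_speed: float):
        L = float(config.layout.length_bp)
        sign = _DIR_SIGN[direction]
        self.sign = sign
        base_tpb = 1.0 / fork_speed
        cuts = {0.0, L}
        slow = []  # (d_in, d_out, factor)
        self.events = []  # (distance, kind, site_index)
        for i, s in enumerate(config.stall_sites):
            length = float(s.end - s.start + 1)
            entry = s.start - 1 if sign > 0 else s.end
            d_in = _dist_along(L, origin_pos, entry, sign)
            d_out = min(d_in + length, L)
            if s.mode == "slowdown":
                slow.append((d_in, d_out, s.factor))
                cuts.update((d_in, d_out))
            else:
                self.events.append((d_in, "block", i))
                cuts.add(d_in)
        for i, t in enumerate(config.ter_traps):
            if t.blocked_direction != direction or t.efficiency <= 0:
                continue
            d = _dist_along(L, origin_pos, t.position, sign)
            self.events.append((d, "trap", i))
            cuts.add(d)
        self.edges = np.array(sorted(cuts))
        mids = (self.edges[:-1] + self.edges[1:]) / 2.0
        tpb = np.full(len(mids), base_tpb)
        for d_in, d_out, factor in slow:
            inside = (mids > d_in) & (mids < d_out)
            tpb[inside] = base_tpb * factor
        self.tpb = tpb
        self.events.sort()

    def extent(self, elapsed: float, delay_of) -> float:
        """Distance reached after ``elapsed`` minutes.

        ``delay_of(kind, index)`` returns the sampled per-round delay for
        a point event (math.inf = blocking trap).
        """
        t = 0.0
        ev = self.events
        ei = 0
        ne = len(ev)
        edges = self.edges
        tpb = self.tpb
        for p in range(len(tpb)):
            d0, d1 = edges[p], edges[p + 1]
            while ei < ne and ev[ei][0] <= d0:
                dly = delay_of(ev[ei][1], ev[ei][2])
                if t + dly >= elapsed:
                    return d0
                t += dly
                ei += 1
            dt = (d1 - d0) * tpb[p]
            if t + dt >= elapsed:
                return d0 + (elapsed - t) / tpb[p]
            t += dt
        return edges[-1]

    def arrival(self, dists: np.ndarray, delay_of) -> np.ndarray:
        """Arrival time at each path distance (vectorized, inf if blocked)."""
        edges = self.edges
        tpb = self.tpb
        # cumulative time at each edge, inserting point delays
        tcum = np.zeros(len(edges))
        extra = np.zeros(len(edges))
        for d, kind, i in self.events:
            j = int(np.searchsorted(edges, d))
            extra[j] += delay_of(kind, i)
        run = 0.0
        for p in range(len(tpb)):
            run += extra[p]
            tcum[p] = run
            run += (edges[p + 1] - edges[p]) * tpb[p]
        tcum[-1] = run + extra[-1]
        idx = np.clip(np.searchsorted(edges, dists, side="right") - 1, 0,
                      len(tpb) - 1)
        return tcum[idx] + (dists - edges[idx]) * tpb[idx]


def _merge_circle_segments(segs, L):
    """Merge bp segments on the circle; returns (merged list, total length).

    Input segments are (start, length) with start in [0, L); wrapping is
    handled by splitting.
    """
    linear = []
    for start, length in segs:
        if length <= 0:
            continue
        if length >= L:
            return [(0.0, L)], L
        start %= L
        end = start + length
        if end <= L:
            linear.append((start, end))
        else:
            linear.append((start, L))
            linear.append((0.0, end - L))
    if not linear:
        return [], 0.0
    linear.sort()
    merged = [list(linear[0])]
    for s, e in linear[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = sum(e - s for s, e in merged)
    return [tuple(m) for m in merged], total


# ---------------------------------------------------------------------------
# closed-form oracle


def steady_state_profile(config: SimConfig) -> np.ndarray:
    """Closed-form steady-state relative copy number, terminus = 1.

    Valid for a single scheduled origin with no traps or stalls: the
    marker-frequency law ``M(x) = 2**((t_max - t(x)) / tau)`` with
    ``t(x)`` the arrival time of the nearest fork.
    """
    if len(config.origins) != 1 or config.origins[0].mode != "scheduled":
        raise ConfigError("closed form requires a single scheduled origin")
    if config.ter_traps or config.stall_sites:
        raise ConfigError("closed form requires no traps or stall sites")
    L = config.layout.length_bp
    o = config.origins[0].position
    mids = (np.arange(config.n_bins) + 0.5) * config.bin_size
    mids = np.minimum(mids, L - 0.5)
    d = np.abs(mids - o)
    d = np.minimum(d, L - d)
    t = d / config.fork_speed
    return 2.0 ** ((t.max() - t) / config.doubling_time)


def origin_increase(minutes: float, doubling_time: float) -> float:
    """Fold-increase of origin copies over ``minutes`` of unperturbed
    exponential initiation: ``2**(minutes / doubling_time)``.

    At a 25-min doubling time, 60 min gives ~5.3-fold.
    """
    if doubling_time <= 0:
        raise ParameterError("doubling_time must be positive")
    return 2.0 ** (minutes / doubling_time)


# ---------------------------------------------------------------------------
# population ensemble


@dataclass
class SimTruth:
    """Ground truth serialized alongside every emitted dataset."""

    timepoints: list
    expected_profiles: dict  # timepoint -> per-bin expected relative copy
    origins: list  # positions bp
    traps: list  # (name, position, blocked_direction, efficiency)
    stalls: list  # (start, end, mode)
    reporter_region: object
    factors: dict  # timepoint -> expected reporter increase factor
    seed: int
    n_cells: int
    bin_size: int
    length_bp: int

    def increase_factors(self) -> IncreaseFactors:
        ts = sorted(self.factors)
        return IncreaseFactors(ts, [self.factors[t] for t in ts])

    def to_json(self, path) -> None:
        d = {
            "timepoints": list(self.timepoints),
            "expected_profiles": {
                str(t): np.asarray(p).tolist()
                for t, p in self.expected_profiles.items()
            },
            "origins": list(self.origins),
            "traps": [list(t) for t in self.traps],
            "stalls": [list(s) for s in self.stalls],
            "reporter_region": (
                list(self.reporter_region)
                if isinstance(self.reporter_region, (tuple, list))
                else self.reporter_region
            ),
            "factors": {str(t): f for t, f in self.factors.items()},
            "seed": self.seed,
            "n_cells": self.n_cells,
            "bin_size": self.bin_size,
            "length_bp": self.length_bp,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            timepoints=d["timepoints"],
            expected_profiles={
                float(t): np.asarray(p) for t, p in d["expected_profiles"].items()
            },
            origins=d["origins"],
            traps=[tuple(t) for t in d["traps"]],
            stalls=[tuple(s) for s in d["stalls"]],
            reporter_region=(
                tuple(d["reporter_region"])
                if isinstance(d["reporter_region"], list)
                else d["reporter_region"]
            ),
            factors={float(t): f for t, f in d["factors"].items()},
            seed=d["seed"],
            n_cells=d["n_cells"],
            bin_size=d["bin_size"],
            length_bp=d["length_bp"],
        )


def _sample_completion(sampler, rng, t_hi: float) -> float:
    """Completion time of one replication round with sampled outcomes.

    Bisection on the covered length; used to anchor round phases: in
    steady state a cell of age ``a`` was born when a round completed, so
    the active rounds have elapsed times ``a + C0 - i*tau`` (i >= 1) with
    ``C0`` the completed round's own duration. This anchoring is what
    makes the ensemble reproduce the 2^(-t/tau) law for any C/tau.
    """
    fired = []
    for _ in range(200):
        fired = sampler.fired_origins(rng)
        if fired:
            break
    if not fired:
        return 0.0
    blocked, delays = sampler.sample_outcomes(rng)
    L = sampler.L
    lo, hi = 0.0, max(t_hi, 1e-6)
    while sampler.segments(hi, fired, blocked, delays)[1] < L - 1e-6:
        hi *= 2.0
        if hi > 1e9:
            raise ConfigError("replication round cannot complete (unreachable bins)")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if sampler.segments(mid, fired, blocked, delays)[1] >= L - 1e-6:
            hi = mid
        else:
            lo = mid
    return hi


class _RoundSampler:
    """Samples per-round trap/stall outcomes and evaluates fork extents."""

    def __init__(self, config: SimConfig, origin_positions, fork_speed: float):
        self.config = config
        self.origins = list(origin_positions)
        self.paths = {
            (o, d): _Path(config, o, d, fork_speed)
            for o in self.origins
            for d in (CW, CCW)
        }
        self.L = float(config.layout.length_bp)

    def sample_outcomes(self, rng):
        cfg = self.config
        blocked = [
            rng.random() < t.efficiency if t.efficiency < 1.0 else True
            for t in cfg.ter_traps
        ]
        delays = {}
        for i, s in enumerate(cfg.stall_sites):
            if s.mode == "block":
                lam = -math.log(1.0 - s.passage_prob) if s.passage_prob < 1 else None
                for d in (CW, CCW):
                    delays[(i, d)] = (
                        rng.exponential(1.0 / lam) if lam else 0.0
                    )
        return blocked, delays

    def segments(self, elapsed: float, fired, blocked, delays):
        """Merged replicated segments of one round at ``elapsed`` minutes."""
        arcs = []
        for o in fired:
            ext = {}
            for d in (CW, CCW):
                def delay_of(kind, i, _d=d):
                    if kind == "trap":
                        return math.inf if blocked[i] else 0.0
                    return delays.get((i, _d), 0.0)

                ext[d] = self.paths[(o, d)].extent(elapsed, delay_of)
            total = ext[CW] + ext[CCW]
            arcs.append(((o - ext[CCW]) % self.L, min(total, self.L)))
        return _merge_circle_segments(arcs, self.L)

    def fired_origins(self, rng):
        fired = []
        for o in self.config.origins:
            if o.mode == "scheduled" or rng.random() < o.weight:
                fired.append(float(o.position))
        return fired


def _worst_case_completion(config: SimConfig) -> float:
    """Upper bound on a round's completion time: all traps block, block
    delays at their 1e-6 survival quantile. Raises on unreachable bins."""
    sampler = _RoundSampler(
        config, [float(o.position) for o in config.origins], config.fork_speed
    )
    n = config.n_bins
    mids = (np.arange(n) + 0.5) * config.bin_size
    mids = np.minimum(mids, config.layout.length_bp - 0.5)
    worst = np.full(n, np.inf)

    def delay_of(kind, i):
        if kind == "trap":
            return math.inf
        s = config.stall_sites[i]
        lam = -math.log(1.0 - s.passage_prob) if s.passage_prob < 1 else None
        return 13.8 / lam if lam else 0.0

    for (o, d), path in sampler.paths.items():
        dists = _dist_along(config.layout.length_bp, o, mids, path.sign)
        worst = np.minimum(worst, path.arrival(dists, delay_of))
    if not np.all(np.isfinite(worst)):
        raise ConfigError(
            "some bins are unreachable when every trap blocks: steady-state "
            "growth is ill-defined (contradictory traps)"
        )
    return float(worst.max())


def simulate_population(config: SimConfig, timepoints=None):
    """Simulate a cell population; return expected per-bin copy profiles.

    Returns ``(profiles, truth)`` where ``profiles`` maps each timepoint
    (minutes; steady state uses whatever timepoints are requested, all
    identical in expectation but sharing one ensemble) to the ensemble
    mean relative copy number per bin, and ``truth`` is the
    :class:`SimTruth` oracle. Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    recovery = config.uv is not None
    if timepoints is None:
        timepoints = [0.0] if not recovery else [0.0, 60.0, 120.0, 180.0]
    timepoints = [float(t) for t in timepoints]
    if recovery and min(timepoints) != 0.0:
        raise ConfigError("recovery time courses must include timepoint 0")

    L = float(config.layout.length_bp)
    n = config.n_bins
    b = config.bin_size
    tau = config.doubling_time
    growth = _RoundSampler(
        config, [float(o.position) for o in config.origins], config.fork_speed
    )
    t_cap = (_worst_case_completion(config) + 1e-9) if config.origins else 0.0
    # pool of sampled round-completion times used to anchor cell phases
    if config.origins:
        pool_n = min(config.n_cells, 1024)
        completion_pool = np.array(
            [_sample_completion(growth, rng, t_cap) for _ in range(pool_n)]
        )
    else:
        completion_pool = np.array([0.0])
    new_sampler = None
    sched = []
    if recovery:
        uv = config.uv
        speed = uv.fork_speed or config.fork_speed
        new_sampler = _RoundSampler(config, [float(p) for p in uv.restart_origins],
                                    speed)
        interval = uv.reinit_interval_min or tau
        t_last = max(timepoints)
        m = 0
        while uv.lag_min + m * interval < t_last:
            sched.append(uv.lag_min + m * interval)
            m += 1

    lut = 2.0 ** np.arange(64)
    acc = {t: np.zeros(n) for t in timepoints}
    chunk = 512
    n_cells = config.n_cells
    # stratified age sampling: the age quantile grid is covered exactly,
    # which removes the dominant coherent ensemble noise near flat peaks
    u = (rng.permutation(n_cells) + rng.random(n_cells)) / n_cells
    ages = -tau * np.log2(1.0 - u / 2.0)
    pool_pick = rng.permutation(n_cells) % len(completion_pool)

    def add_segments(rows, cols, vals, row, segs):
        for s, e in segs:
            i0 = math.ceil(s / b - 0.5)
            i1 = math.floor(e / b - 0.5)
            if i1 < i0:
                continue
            i0 = max(i0, 0)
            i1 = min(i1, n - 1)
            rows.append(row)
            cols.append(i0)
            vals.append(1.0)
            rows.append(row)
            cols.append(i1 + 1)
            vals.append(-1.0)

    for c0 in range(0, n_cells, chunk):
        m_cells = min(chunk, n_cells - c0)
        data = {t: ([], [], []) for t in timepoints}
        for row in range(m_cells):
            a = ages[c0_cell := (c0 + row)]
            c0_anchor = completion_pool[pool_pick[c0_cell]]
            # steady-state rounds active at t=0 (frozen in recovery mode):
            # phases anchored to the division that completed at this cell's
            # birth, elapsed_i = a + c0 - i*tau while positive
            frozen = []
            i = 1
            while config.origins:
                elapsed = a + c0_anchor - i * tau
                if elapsed <= 0:
                    break
                fired = growth.fired_origins(rng)
                i += 1
                if not fired:
                    continue
                blocked, delays = growth.sample_outcomes(rng)
                segs, total = growth.segments(elapsed, fired, blocked, delays)
                if total >= L - 1e-6:
                    continue  # round already completed: removed by division
                frozen.append(segs)
            new_rounds = []
            if recovery:
                for _ in sched:
                    blocked, delays = new_sampler.sample_outcomes(rng)
                    new_rounds.append((blocked, delays))
            for t in timepoints:
                rows, cols, vals = data[t]
                for segs in frozen:
                    add_segments(rows, cols, vals, row, segs)
                if recovery:
                    for start, (blocked, delays) in zip(sched, new_rounds):
                        if t <= start:
                            continue
                        segs, _tot = new_sampler.segments(
                            t - start, new_sampler.origins, blocked, delays
                        )
                        add_segments(rows, cols, vals, row, segs)
        for t in timepoints:
            rows, cols, vals = data[t]
            incr = np.zeros((m_cells, n + 1))
            if rows:
                np.add.at(incr, (rows, cols), vals)
            cover = np.cumsum(incr[:, :n], axis=1)
            cover = np.rint(cover).astype(np.int64)
            acc[t] += lut[np.clip(cover, 0, 63)].sum(axis=0)

    profiles = {t: acc[t] / n_cells for t in timepoints}

    reporter = (
        "reporter" if "reporter" in config.layout.regions else None
    )
    factors = {}
    if reporter is not None:
        lo, hi = config.layout.region_bins(reporter, b)
        t0 = min(timepoints)
        base = profiles[t0][lo:hi].mean()
        factors = {t: float(profiles[t][lo:hi].mean() / base) for t in timepoints}
    truth = SimTruth(
        timepoints=timepoints,
        expected_profiles=profiles,
        origins=[o.position for o in config.origins],
        traps=[
            (t.name, t.position, t.blocked_direction, t.efficiency)
            for t in config.ter_traps
        ],
        stalls=[(s.start, s.end, s.mode) for s in config.stall_sites],
        reporter_region=reporter,
        factors=factors,
        seed=config.seed,
        n_cells=config.n_cells,
        bin_size=b,
        length_bp=config.layout.length_bp,
    )
    return profiles, truth


def default_mask_intervals(config: SimConfig) -> np.ndarray:
    """Bins to mask in emitted datasets: the stall-site (rrn-like) repeats,
    mirroring the removal of non-uniquely-mappable rrn bins in real data."""
    iv = [(s.start - 1, s.end) for s in config.stall_sites]
    return np.asarray(iv, dtype=np.int64).reshape(-1, 2)


def sample_reads(
    copy_profile: np.ndarray,
    mean_depth: float,
    rng,
    length_bp: int,
    bin_size: int,
    mask: np.ndarray | None = None,
) -> BinnedDepth:
    """Poisson-sample binned read depth around a relative copy profile.

    Bin depth ~ Poisson(mean_depth * relative copy number); masked bins are
    emitted masked with no count. Bit-identical for the same rng state.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    copy_profile = np.asarray(copy_profile, dtype=float)
    counts = rng.poisson(mean_depth * copy_profile).astype(float)
    n = len(copy_profile)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool).copy()
    counts[mask] = 0.0
    return BinnedDepth(length_bp, bin_size, counts, mask)


def mask_from_intervals(intervals: np.ndarray, n_bins: int, bin_size: int):
    mask = np.zeros(n_bins, dtype=bool)
    for s, e in np.asarray(intervals).reshape(-1, 2):
        if e <= s:
            continue
        b0 = max(int(s) // bin_size, 0)
        b1 = min((int(e) - 1) // bin_size, n_bins - 1)
        mask[b0 : b1 + 1] = True
    return mask


def emit_dataset(config: SimConfig, timepoints, outdir) -> dict:
    """Run the simulator and write a complete on-disk fixture.

    Writes per-timepoint bedGraph depth tracks, the mask BED, the layout
    YAML, the true increase-factor TSV and the SimTruth JSON; returns a
    dict of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles, truth = simulate_population(config, timepoints)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mask_iv = default_mask_intervals(config)
    mask = mask_from_intervals(mask_iv, config.n_bins, config.bin_size)
    paths = {}
    for t in sorted(profiles):
        binned = sample_reads(
            profiles[t], config.mean_depth, rng, config.layout.length_bp,
            config.bin_size, mask,
        )
        p = outdir / f"depth_t{int(t)}.bedgraph"
        write_bedgraph(binned, p, chrom=config.layout.name)
        paths[f"depth_t{int(t)}"] = p
    bed = outdir / "mask.bed"
    with open(bed, "w") as fh:
        for s, e in mask_iv:
            fh.write(f"{config.layout.name}\t{s}\t{e}\n")
    paths["mask"] = bed
    ly = outdir / "layout.yaml"
    config.layout.to_yaml(ly)
    paths["layout"] = ly
    ft = outdir / "factors.tsv"
    if truth.factors:
        truth.increase_factors().to_tsv(ft)
        paths["factors"] = ft
    tj = outdir / "truth.json"
    truth.to_json(tj)
    paths["truth"] = tj
    sc = outdir / "scenario.yaml"
    config.to_yaml(sc)
    paths["scenario"] = sc
    return paths


# ---------------------------------------------------------------------------
# canonical scenarios


def default_scenario(seed: int = 0, n_cells: int = 8000) -> SimConfig:
    """The canonical 1-Mb test scenario.

    Three scheduled origins, two polar ter traps (90% efficient), two
    rrn-like slow-down sites, and a post-UV recovery mode restarting only
    at the central origin at reduced fork speed. The reporter region spans
    44 kb around the restart origin, mirroring reporter-segment
    hybridization; timepoints 0/60/120/180 min.
    """
    layout = GenomeLayout(
        name="sim1Mb",
        length_bp=1_000_000,
        dif_pos=975_000,
        oric_pos=500_000,
        ter_sites=[
            TerSite("terL", 900_000, CW, 0.9),
            TerSite("terR", 730_000, CCW, 0.9),
        ],
        rrn_operons=[
            ("rrn1", 340_000, 345_000, "+"),
            ("rrn2", 50_000, 55_000, "+"),
        ],
        regions={"reporter": (478_000, 522_000)},
    )
    return SimConfig(
        layout=layout,
        origins=[Origin(150_000), Origin(500_000), Origin(800_000)],
        fork_speed=20_000.0,
        doubling_time=18.0,
        ter_traps=list(layout.ter_sites),
        stall_sites=[
            StallSite(340_000, 345_000, "slowdown", factor=10.0),
            StallSite(50_000, 55_000, "slowdown", factor=10.0),
        ],
        uv=UVRecovery(
            lag_min=15.0,
            restart_origins=(500_000,),
            fork_speed=3_000.0,
            reinit_interval_min=90.0,
        ),
        n_cells=n_cells,
        mean_depth=50.0,
        bin_size=100,
        seed=seed,
    )


def nine_zone_scenario(seed: int = 0, n_cells: int = 4000) -> SimConfig:
    """Nine origin clusters separated by nine rrn-like stall sites on a
    1.8-Mb circle: the trendline should resolve nine initiation zones."""
    L = 1_800_000
    step = L // 9
    origins = [Origin(int(step * i + step // 2)) for i in range(9)]
    stalls = [
        StallSite(int(step * i) + 1, int(step * i) + 6_000, "slowdown", factor=12.0)
        for i in range(9)
    ]
    layout = GenomeLayout(
        name="sim9zones",
        length_bp=L,
        dif_pos=1,
        oric_pos=origins[0].position,
        rrn_operons=[
            (f"rrn{i + 1}", s.start, s.end, "+") for i, s in enumerate(stalls)
        ],
        regions={"reporter": (origins[0].position - 20_000,
                              origins[0].position + 20_000)},
    )
    return SimConfig(
        layout=layout,
        origins=origins,
        fork_speed=20_000.0,
        doubling_time=12.0,
        stall_sites=stalls,
        n_cells=n_cells,
        mean_depth=50.0,
        bin_size=100,
        seed=seed,
    )
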