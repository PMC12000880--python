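# Methods

`forkprof` turns per-base sequencing depth of a circular bacterial
chromosome into smoothed copy-number trendlines and called replication
features, and ships a forward simulator of replicating chromosome
populations that generates ground-truthed synthetic datasets for every
stage. This note records the models, the parameters that matter, the
numerical choices, and the known limits.

## From depth to trendline

**Binning.** Per-base depth (4-column bedGraph, 0-based half-open,
disjoint intervals; gaps are depth 0) is averaged over contiguous
fixed-width bins, 100 bp by default. The final partial bin is averaged
over its real width so the chromosome end is not discarded. Binning
conserves mass exactly: `sum(values * widths)` equals the per-base total.
Overlapping bedGraph intervals are rejected as a format error rather than
summed — the upstream depth tools emit disjoint intervals, so an overlap
signals a corrupted file.

**Masking.** Bins overlapping non-uniquely-mappable or strain-deleted
sequence are consumed as BED intervals and *flagged*, never deleted, so
bin indices stay stable across samples; a single overlapping base masks
the bin. Masked bins are excluded from every downstream computation (fit,
region means, normalization denominators) and exported as missing values,
never zero. Masks are inputs: mappability computation belongs upstream.

**Linearization and padding.** The circle is opened at the *dif*
dimer-resolution site (the bin containing the cut position becomes linear
index 0), which places the origin mid-axis and permutes the X-axis
relative to native coordinates. For fitting, the terminal 1000 bins are
duplicated onto the reciprocal ends; the left pad continues the 100-bp
pitch into negative x. Pads carry their source bins' mask flags (no
information is laundered through duplication). After fitting, the padding
is trimmed and values returned in native bin order. Padding makes the
windowed smoother behave as if the data were circular: trendlines
computed after opening at two different loci agree within 0.1% relative
at every retained bin (asserted in the tests), so the cut is a
presentation choice, not an analysis choice.

## Robust LOESS

The trendline is a direct-surface LOESS: at every retained bin the
weighted least-squares polynomial of degree 2 over the `k = ceil(span*n)`
nearest retained neighbours, with tricube distance weights normalized to
the window's largest distance. Defaults: `span = 0.025` (a ~116 kb window
on the 100-bp-binned 4.64-Mb *E. coli* chromosome), degree 2, and 8
robustness iterations — one initial fit followed by 8 rounds of global
Tukey-bisquare reweighting with scale `6 * median(|residual|)`,
multiplying the tricube weights (the classic "symmetric family"
schedule). The effective genomic window is `round(span*n_bins)*bin_size`.

Numerical choices:

* neighbourhoods are contiguous windows found by a two-pointer sweep;
  distance ties break toward the lower index;
* the local abscissa is rescaled by the window radius before forming the
  normal equations; singular blocks fall back to a pseudoinverse with
  relative tolerance 1e-12;
* when residuals are at floating-point noise level (scale below `1e-9 *
  max|y|`) the bisquare step is skipped with unit weights — reweighting
  on numerical noise would amplify it instead of robustifying
  (degree-2 LOESS reproduces any global quadratic exactly, so
  zero-residual inputs are a real code path, not a corner case);
* masked bins are excluded from both fitting and evaluation; nothing is
  imputed and the returned trendline is NaN there;
* the fit is vectorized in blocks of 2048 points, bounding peak memory;
  a 46,417-bin genome at span 0.025 fits in well under a minute on one
  CPU.

Correctness is pinned by two oracles in the test suite: exact
reproduction (≤1e-8) of global quadratics at any span with and without
robustness, and equality (≤1e-8 relative) with an independent per-point
weighted-normal-equations solver including the full bisquare schedule.

**Span selection.** GCV `n*RSS/(n - tr L)^2` and AICc
`log(RSS/n) + 1 + 2(tr L + 1)/(n - tr L - 2)` are offered, minimized
either on a uniform grid or by a coarse scan plus golden-section
refinement. Because the fitted value is linear in y for fixed weights,
the hat-matrix diagonal is available in closed form at every point
(`L_ii = w_ii * (A^-1)_00` with the centered local design), so `tr L` is
exact at any problem size — no stochastic trace estimation is needed.
The criteria assume a linear smoother, so they are evaluated without
robustness iterations by default. Scores within a small tolerance of the
minimum are ties resolved toward the *largest* span (prefer smoothing
among indistinguishable fits), which makes the zero-residual limit
well-defined. Statistically optimal spans tend to sit near 0.05 on
replication profiles; the package never silently auto-selects a span —
the analysis default stays 0.025, which preserves narrow biological
features (ter/rrn troughs) that heavier smoothing obscures, and both are
exposed.

## Normalizations and nested sets

* **percent-mean**: each retained bin becomes `100 * value /
  mean(retained)`; the retained mean is exactly 100 and the operation is
  idempotent. Applied before combining replicates so sequencing depth
  cancels.
* **region normalization**: a trendline divided by its mean over a named
  1-based-inclusive region (e.g. a reporter segment around *rrnG*, or the
  *terE–terD* interval). Only bins fully inside the region count, so the
  mean never depends on sequence outside it; masked bins are skipped, not
  interpolated. Output region mean is exactly 1; the operation is
  scale-invariant.
* **indexation**: each region-normalized timepoint is multiplied by that
  timepoint's absolute increase factor — the reporter region's
  hybridization signal relative to t0 (`factor(t0) = 1` by construction).
  The indexed trendline's reference-region mean equals the factor to
  1e-9, which is the defining invariant of a nested set. Log-Y display is
  a rendering flag; stored values are always linear.
* **replicates** are combined with equal weights: percent-mean normalize,
  fit each, average the trendlines pointwise. Averaging the normalized
  tracks *before* one fit gives virtually identical summaries — below 1%
  maximum relative difference on five 50x Poisson replicates of a smooth
  profile. Caveat: at a sharp copy-number step (an efficient fork trap)
  the two orders can disagree by ~1–2% locally, because the bisquare
  scale is smaller for the pre-averaged (less noisy) track and the step
  residuals get rejected as outliers in that order only. This is a real
  property of robust smoothing at discontinuities, worth knowing when
  profiles contain strong traps.

## Feature calling

All calls operate on the trendline (matching how profiles are read by
eye), treat the chromosome as circular, and report native bin-midpoint
positions.

* **Extrema**: `scipy.signal.find_peaks` on the circularly tiled retained
  values, prominence threshold 5% of the profile median by default.
* **Position refinement**: a replication origin sits where two
  near-exponential gradients meet, so the trendline apex is flat and its
  argmax noisy. Each extremum is refined by least-squares fitting a
  continuous two-slope kink to `log2` of the raw bins (independent noise
  per bin, unlike the smoothed values whose noise is correlated over the
  LOESS window) within `min(60 kb, 0.8 x distance to the nearest
  opposite-sign extremum)` per side, scanning the breakpoint on the data
  grid; the refinement is dropped when the fitted slopes have unexpected
  signs or the breakpoint pins at the scan edge. At 50x depth and
  gradients of ~1 log2 unit per 360 kb this estimator's statistical floor
  is about 4–5 kb (Monte-Carlo of the same fit on clean kinks); wider
  windows would lower the variance but pick up curvature and trap-step
  bias, and were measured to be worse.
* **Zones**: consecutive troughs (circularly) delimit a candidate
  initiation zone, reported when the interior mean exceeds the higher
  flanking trough by the prominence threshold. A single trough bounds a
  single wrap-around zone.
* **Association**: each trough is labelled with the nearest *ter* site or
  *rrn* operon (circular distance) within 20 kb, else "unassigned".
* **Downshifts**: scanning in the fork-travel direction (CW = increasing
  coordinate), the trendline mean over a 50-kb upstream window is
  compared with the 50-kb downstream window across a 10-kb gap; local
  maxima of the upstream/downstream ratio at ≥1.10 are reported, with the
  step placed at the steepest descent inside the gap. CCW detection runs
  the CW scanner on the mirrored profile and reflects the calls, which
  makes the reflection-symmetry property exact. Note that a steep
  replication gradient alone (ratio across 110 kb above 1.10) can produce
  calls at curvature maxima; on profiles with strong gradients the drop
  threshold should be read against the local slope. All thresholds are
  explicit parameters, echoed into output metadata.

## The population simulator

Each simulated cell carries one circular chromosome plus its active
replication rounds. In steady exponential growth with doubling time tau,
ages are drawn (stratified, so the quantile grid is covered exactly) from
the exponential-growth age density `(2 ln2/tau) 2^(-a/tau)` on [0, tau).
Rounds initiate every tau minutes in a lineage and a cell divides when a
round completes, so the rounds active in a cell of age `a` have elapsed
times `a + C0 - i*tau` (i ≥ 1), where `C0` is the duration of the round
that completed at the cell's birth — sampled per cell from a pre-computed
pool of round-completion times (bisection on covered length). This
completion-anchored phase structure is what reproduces the
marker-frequency law `M(x) ∝ 2^(-t(x)/tau)` for *any* C/tau; anchoring at
initiation instead is only correct when C is a multiple of tau (the
closed-form oracle caught exactly this during development, and the
20,000-cell no-barrier ensemble now matches the law within a fraction of
a percent at every bin). A locus covered by m active rounds carries `2^m`
copies; a completed round doubles every locus once and is cancelled by
division.

Forks advance at `fork_speed`. Polar *ter* traps arrest forks traveling
in their blocked direction with probability `efficiency`; the arrested
region is finished by the converging fork. Stall sites either multiply
traversal time (`slowdown`) or hold the fork at entry with an
exponential waiting time parameterized by a per-minute passage
probability (`block`). Trap and stall outcomes are sampled once per
round (per site and direction) and shared by all forks of that round;
under that convention a bin's replication time is exactly the minimum
over origins and directions of the piecewise path arrival time, so
coverage needs no event-driven fork merging. Configurations in which
every trap blocking leaves bins unreachable are rejected for steady-state
growth (such cells could never divide).

UV recovery freezes all pre-existing forks at t = 0 and, after a lag,
restarts initiation only at the configured origins (typically one), at a
reduced fork speed, re-initiating at a fixed interval; no divisions occur
during recovery, so profiles nest: later timepoints dominate earlier
ones pointwise. The ground truth (`SimTruth`) stores the ensemble
expected profile per timepoint and defines reporter increase factors as
the exact ratios of expected reporter-region copy numbers — so factors
estimated from sampled reads differ from truth only by Poisson counting
error.

Read sampling is `Poisson(mean_depth * relative copy number)` per bin;
masked bins are emitted masked with no count. Everything is
deterministic given the config seed.

**Canonical scenario** (the default dataset all end-to-end tests use):
a 1-Mb circle, three scheduled origins at 150/500/800 kb, two 90%
ter traps (900 kb blocking CW, 730 kb blocking CCW), two rrn-like
5-kb slow-down sites (340 and 50 kb, 10x slower; these intervals are
also the emitted mask, mirroring the removal of repetitive rrn bins from
real data), fork speed 20 kb/min, doubling time 18 min, 8000 cells, 50x
mean depth. Sizes are scaled so a full simulate–fit–call cycle takes
seconds to tens of seconds; gradients (~1 log2 unit per 360 kb) are a
few-fold steeper than a fast-growing *E. coli* chromosome, which keeps
every planted feature resolvable at desk-scale depth. The recovery mode
restarts only the central origin at 3 kb/min after a 15-min lag,
re-initiating every 90 min, giving reporter increase factors of
(1, 2, 4, 4) at 0/60/120/180 min — the ~4-fold scale observed for
reporter segments in post-UV hybridization experiments. A second
scenario plants nine origin clusters separated by nine stall sites on a
1.8-Mb circle; the pipeline must resolve all nine zones.

**What the simulator does not model:** DNA repair and degradation
(post-UV profiles reflect copy number only), transcription or R-loop
mechanism, sequence-level reads (no FASTA/FASTQ), SOS regulation,
cell-to-cell fork-speed variation, and division during recovery.
Passing tests demonstrate that the analysis recovers what the copy-number
model plants; they do not validate biological claims about real data.

## Reproducibility

Every CLI command writes a `manifest.json` (command, parameters, input
SHA-256 digests, package version, seed, timestamp). All randomness flows
from explicit seeds; reruns of deterministic stages are bit-identical,
which the tests assert on the TSV outputs. The binned-profile TSV
round-trips bit-identically (floats are written with 17 significant
digits and parsed in round-trip mode — the default pandas float parser
can be one ulp off).
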