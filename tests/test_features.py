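"""Feature calling: extrema, zones, association, downshifts."""

import numpy as np
import pytest

import forkprof as fp
from forkprof.layout import CCW, CW
from forkprof.loess import LoessParams, Trendline
from forkprof.simulate import sample_reads


def make_trend(values, mask=None, bin_size=100):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(len(values), bool)
    return Trendline(
        values=np.where(mask, np.nan, values),
        mask=np.asarray(mask, bool),
        bin_size=bin_size,
        length_bp=len(values) * bin_size,
        params=LoessParams(),
        n_fit=int((~np.asarray(mask, bool)).sum()),
    )


def marker_frequency(n_bins, origins_bp, v_tau_bp, bin_size=100):
    """Noise-free multi-origin steady-state profile for synthetic tests."""
    L = n_bins * bin_size
    mids = (np.arange(n_bins) + 0.5) * bin_size
    t = np.full(n_bins, np.inf)
    for o in origins_bp:
        d = np.abs(mids - o)
        d = np.minimum(d, L - d)
        t = np.minimum(t, d)
    return 2.0 ** (-t / v_tau_bp)


class TestCallExtrema:
    def test_single_origin_peak_at_origin(self):
        vals = marker_frequency(5000, [230_000], 200_000)
        peaks, troughs = fp.call_extrema(make_trend(vals))
        assert len(peaks) == 1
        assert abs(peaks.position_bp[0] - 230_000) <= 10_000
        # the trough (terminus) is diametrically opposite
        assert len(troughs) == 1
        d = abs(troughs.position_bp[0] - 480_000)
        assert min(d, 500_000 - d) <= 10_000

    def test_monotone_ramp_has_no_interior_extrema(self):
        vals = np.linspace(1.0, 2.0, 1000)
        peaks, troughs = fp.call_extrema(make_trend(vals),
                                         refine_flank_bp=None)
        # circularly the ramp has one max and one min, both at the wrap
        assert len(peaks) <= 1 and len(troughs) <= 1
        for df, edge in ((peaks, 99_950.0), (troughs, 50.0)):
            for p in df.position_bp:
                assert abs(p - edge) <= 200

    def test_three_origins_recovered(self):
        origins = [100_000, 450_000, 800_000]
        vals = marker_frequency(10_000, origins, 300_000)
        peaks, _ = fp.call_extrema(make_trend(vals))
        assert len(peaks) == 3
        for o in origins:
            assert min(abs(peaks.position_bp - o)) <= 10_000

    def test_flat_profile_yields_nothing(self):
        peaks, troughs = fp.call_extrema(make_trend(np.full(500, 3.0)))
        assert len(peaks) == 0 and len(troughs) == 0


class TestCallZones:
    def test_one_bump_between_two_troughs(self):
        vals = marker_frequency(5000, [250_000], 150_000)
        peaks, troughs = fp.call_extrema(make_trend(vals))
        zones = fp.call_zones(make_trend(vals), troughs)
        assert len(zones) == 1
        assert abs(zones.summit_bp[0] - 250_000) <= 10_000

    def test_below_prominence_no_zones(self):
        rng = np.random.default_rng(0)
        vals = 100.0 + rng.normal(0, 0.1, 3000)
        t = make_trend(vals)
        _, troughs = fp.call_extrema(t, min_prominence=0.0,
                                     refine_flank_bp=None)
        zones = fp.call_zones(t, troughs, min_prominence=0.05)
        assert len(zones) == 0

    def test_nine_zone_scenario_recovers_nine_zones(self):
        """Nine origin clusters separated by stall troughs give 9 zones."""
        cfg = fp.nine_zone_scenario(seed=5, n_cells=4000)
        profiles, truth = fp.simulate_population(cfg, [0.0])
        from forkprof.simulate import default_mask_intervals, mask_from_intervals

        mask = mask_from_intervals(
            default_mask_intervals(cfg), cfg.n_bins, cfg.bin_size
        )
        binned = sample_reads(
            profiles[0.0], cfg.mean_depth, np.random.default_rng(7),
            cfg.layout.length_bp, cfg.bin_size, mask,
        )
        res = fp.ReplicationProfile(binned, cfg.layout).fit()
        calls = res.call_features()
        assert len(calls.zones) == 9
        for o in truth.origins:
            assert min(abs(calls.peaks.position_bp - o)) <= 10_000


class TestAssociate:
    def layout(self):
        return fp.GenomeLayout(
            "a", 1_000_000, 1, 500_000,
            ter_sites=[fp.TerSite("terA", 300_000, CW)],
            rrn_operons=[fp.RrnOperon("rrnZ", 700_000, 705_000)],
        )

    def test_trough_near_ter(self):
        import pandas as pd

        troughs = pd.DataFrame({"position_bp": [303_000.0]})
        out = fp.associate(troughs, self.layout())
        assert out.locus[0] == "terA" and out.kind[0] == "ter"
        assert out.distance_bp[0] == 3_000

    def test_far_trough_unassigned(self):
        import pandas as pd

        troughs = pd.DataFrame({"position_bp": [100_000.0]})
        out = fp.associate(troughs, self.layout(), max_dist=20_000)
        assert out.locus[0] == "unassigned"

    def test_circular_distance_used(self):
        import pandas as pd

        layout = fp.GenomeLayout(
            "b", 1_000_000, 1, 500_000,
            ter_sites=[fp.TerSite("terB", 999_000, CW)],
        )
        troughs = pd.DataFrame({"position_bp": [2_000.0]})
        out = fp.associate(troughs, layout)
        assert out.locus[0] == "terB"
        assert out.distance_bp[0] == 3_000


class TestDetectDownshifts:
    def test_clean_step_called_at_position(self):
        vals = np.where(np.arange(10_000) < 6_000, 1.0, 0.8)
        calls = fp.detect_downshifts(make_trend(vals), CW)
        assert len(calls) == 1
        assert abs(calls.position_bp[0] - 600_000) <= 100
        assert calls.drop_ratio[0] == pytest.approx(1.25, abs=0.01)

    def test_gentle_gradient_not_called(self):
        mids = (np.arange(10_000) + 0.5) * 100
        vals = 2.0 ** (-np.minimum(mids, 1_000_000 - mids) / 2_000_000)
        for d in (CW, CCW):
            assert len(fp.detect_downshifts(make_trend(vals), d)) == 0

    def test_reflection_symmetry(self):
        """Mirroring the profile and reversing the scan direction mirrors
        the calls exactly."""
        rng = np.random.default_rng(1)
        n = 8_000
        vals = np.ones(n)
        vals[3_000:] *= 0.8
        vals[6_000:] *= 0.85
        vals *= 1 + 0.002 * rng.standard_normal(n)
        fwd = fp.detect_downshifts(make_trend(vals), CW)
        mirrored = make_trend(vals[::-1].copy())
        rev = fp.detect_downshifts(mirrored, CCW)
        assert len(fwd) == len(rev) >= 1
        L = n * 100
        mirrored_back = np.sort(L - rev.position_bp.to_numpy())
        assert np.allclose(np.sort(fwd.position_bp.to_numpy()), mirrored_back,
                           atol=1e-6)

    def test_false_positive_rate_on_flat_poisson_noise(self):
        """Poisson noise around a flat 50x mean rarely produces a downshift
        call at default thresholds (<5% of replicates)."""
        hits = 0
        reps = 100
        rng = np.random.default_rng(2)
        for _ in range(reps):
            vals = rng.poisson(50.0, 5_000) / 50.0
            t = make_trend(vals)
            n_calls = len(fp.detect_downshifts(t, CW)) + len(
                fp.detect_downshifts(t, CCW)
            )
            hits += n_calls > 0
        assert hits < 0.05 * reps

    def test_window_larger_than_replichore_errors(self):
        with pytest.raises(fp.ParameterError):
            fp.detect_downshifts(make_trend(np.ones(100)), CW, window=900_000)

    def test_trap_downshift_only_in_blocked_direction(
        self, default_config, default_sim, default_t0_features
    ):
        """Simulated ter traps produce downshifts in the blocked fork
        direction, within 10 kb of the trap."""
        _, truth = default_sim
        _, calls = default_t0_features
        for name, pos, direction, eff in truth.traps:
            same = calls.downshifts[calls.downshifts.direction == direction]
            assert min(abs(same.position_bp - pos)) <= 10_000


class TestCutInvariance:
    def test_feature_positions_do_not_depend_on_cut(self):
        """Peaks/troughs move by at most one bin when the linearization cut
        changes."""
        rng = np.random.default_rng(3)
        vals = marker_frequency(5_000, [120_000, 350_000], 180_000)
        binned = fp.BinnedDepth(
            500_000, 100, rng.poisson(vals * 200.0) / 200.0 * 100,
            np.zeros(5_000, bool),
        )
        layout = fp.GenomeLayout("c", 500_000, 1, 120_000)
        model = fp.ReplicationProfile(binned, layout)
        f1 = model.fit(span=0.05, cut_at=1, pad_bins=500).call_features()
        f2 = model.fit(span=0.05, cut_at=260_001, pad_bins=500).call_features()
        assert len(f1.peaks) == len(f2.peaks)
        p1 = np.sort(f1.peaks.position_bp.to_numpy())
        p2 = np.sort(f2.peaks.position_bp.to_numpy())
        assert np.max(np.abs(p1 - p2)) <= 100
        t1 = np.sort(f1.troughs.position_bp.to_numpy())
        t2 = np.sort(f2.troughs.position_bp.to_numpy())
        assert len(t1) == len(t2)
        assert np.max(np.abs(t1 - t2)) <= 100
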