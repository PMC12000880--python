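"""Normalizations, replicate combination, nested sets, locus ratios."""

import numpy as np
import pytest

import forkprof as fp
from forkprof.loess import LoessParams, Trendline


def make_binned(values, mask=None, bin_size=100):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(len(values), bool)
    return fp.BinnedDepth(len(values) * bin_size, bin_size, values, mask)


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


class TestPercentMeanNormalize:
    def test_simple_example(self):
        out = fp.percent_mean_normalize(make_binned([1, 2, 3]))
        assert out.values.tolist() == [50.0, 100.0, 150.0]

    def test_idempotent_and_mean_exactly_100(self):
        out = fp.percent_mean_normalize(make_binned([3, 7, 11, 19]))
        assert out.values[out.retained].mean() == pytest.approx(100.0, abs=1e-9)
        again = fp.percent_mean_normalize(out)
        assert np.allclose(again.values, out.values, rtol=1e-12)

    def test_masked_bins_excluded_from_mean(self):
        mask = np.array([False, False, True])
        out = fp.percent_mean_normalize(make_binned([1, 3, 100], mask))
        # brute force: mean over retained = 2
        assert out.values[:2].tolist() == [50.0, 150.0]

    def test_all_zero_track_errors(self):
        with pytest.raises(fp.NormalizationError):
            fp.percent_mean_normalize(make_binned([0, 0, 0]))


class TestRegionMean:
    def test_constant_trendline(self):
        t = make_trend(np.full(50, 4.2))
        assert fp.region_mean(t, (101, 2000)) == pytest.approx(4.2)

    def test_whole_genome_on_percent_normalized_input(self):
        rng = np.random.default_rng(0)
        b = fp.percent_mean_normalize(make_binned(rng.uniform(1, 9, 40)))
        t = make_trend(b.values)
        assert fp.region_mean(t, (1, 4000)) == pytest.approx(100.0)

    def test_linear_ramp_matches_direct_summation(self):
        vals = np.arange(30, dtype=float)
        t = make_trend(vals)
        # region covering bins 10..19 fully (1-based 1001..2000)
        assert fp.region_mean(t, (1001, 2000)) == pytest.approx(
            vals[10:20].mean()
        )

    def test_partial_edge_bins_excluded(self):
        vals = np.arange(30, dtype=float)
        t = make_trend(vals)
        # 1-based 1051..1990 -> only bins 11..18 are fully inside
        assert fp.region_mean(t, (1051, 1990)) == pytest.approx(
            vals[11:19].mean()
        )

    def test_fully_masked_region_errors(self):
        mask = np.zeros(30, bool)
        mask[10:20] = True
        t = make_trend(np.arange(30), mask)
        with pytest.raises(fp.NormalizationError):
            fp.region_mean(t, (1001, 2000))


class TestNormalizeToRegion:
    def test_region_mean_becomes_one(self):
        rng = np.random.default_rng(1)
        t = make_trend(rng.uniform(1, 5, 40))
        out = fp.normalize_to_region(t, (501, 1500))
        assert fp.region_mean(out, (501, 1500)) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 5, 40)
        a = fp.normalize_to_region(make_trend(vals), (501, 1500))
        b = fp.normalize_to_region(make_trend(7.0 * vals), (501, 1500))
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_nonpositive_region_errors(self):
        t = make_trend(np.zeros(40))
        with pytest.raises(fp.NormalizationError):
            fp.normalize_to_region(t, (501, 1500))


class TestIncreaseFactors:
    def test_signal_ratios(self):
        f = fp.increase_factors({0: 100.0, 60: 220.0, 180: 400.0})
        assert f.timepoints == [0, 60, 180]
        assert f.factors == pytest.approx([1.0, 2.2, 4.0])

    def test_equal_signals_give_unit_factors(self):
        f = fp.increase_factors({0: 5.0, 60: 5.0, 120: 5.0})
        assert all(v == 1.0 for v in f.factors)

    def test_missing_t0_factor_lookup(self):
        f = fp.increase_factors({0: 1.0, 60: 2.0})
        with pytest.raises(fp.ParameterError):
            f.factor(120)

    def test_nonpositive_signal_errors(self):
        with pytest.raises(fp.ParameterError):
            fp.increase_factors({0: 0.0, 60: 2.0})

    def test_tsv_round_trip(self, tmp_path):
        f = fp.increase_factors({0: 100.0, 60: 220.0})
        p = tmp_path / "f.tsv"
        f.to_tsv(p)
        g = fp.IncreaseFactors.from_tsv(p)
        assert g.factors == pytest.approx(f.factors)


class TestNestedSet:
    def region(self):
        return (501, 1500)

    def trends(self, rng):
        return {t: make_trend(rng.uniform(1, 3, 40)) for t in (0, 60, 120)}

    def test_single_timepoint_factor_one(self):
        rng = np.random.default_rng(3)
        t = make_trend(rng.uniform(1, 3, 40))
        fac = fp.IncreaseFactors([0], [1.0])
        ns = fp.build_nested_set({0: t}, self.region(), fac)
        expect = fp.normalize_to_region(t, self.region())
        assert np.allclose(ns.indexed(0).values, expect.values, rtol=1e-12)

    def test_indexed_region_mean_equals_factor(self):
        rng = np.random.default_rng(4)
        fac = fp.IncreaseFactors([0, 60, 120], [1.0, 2.2, 4.0])
        ns = fp.build_nested_set(self.trends(rng), self.region(), fac)
        for t, f in zip(fac.timepoints, fac.factors):
            assert fp.region_mean(ns.indexed(t), self.region()) == pytest.approx(
                f, abs=1e-9
            )

    def test_missing_factor_errors(self):
        rng = np.random.default_rng(5)
        fac = fp.IncreaseFactors([0, 60], [1.0, 2.0])
        with pytest.raises(fp.ParameterError):
            fp.build_nested_set(self.trends(rng), self.region(), fac)

    def test_monotone_factors_flat_profiles_nest(self):
        flat = {t: make_trend(np.full(40, 2.0)) for t in (0, 60, 120)}
        fac = fp.IncreaseFactors([0, 60, 120], [1.0, 2.0, 3.0])
        ns = fp.build_nested_set(flat, self.region(), fac)
        v0, v1, v2 = (ns.indexed(t).values for t in (0, 60, 120))
        assert np.all(v1 >= v0) and np.all(v2 >= v1)

    def test_export_long_format(self, tmp_path):
        rng = np.random.default_rng(6)
        fac = fp.IncreaseFactors([0, 60, 120], [1.0, 2.0, 3.0])
        ns = fp.build_nested_set(self.trends(rng), self.region(), fac)
        ns.export(tmp_path / "ns.tsv", tmp_path / "ns.json")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "ns.tsv", sep="\t")
        assert set(df.columns) == {"timepoint_min", "bin_start", "indexed_value"}
        assert len(df) == 3 * 40
        meta = json.loads((tmp_path / "ns.json").read_text())
        assert meta["factors"] == [1.0, 2.0, 3.0]
        assert meta["loess"]["degree"] == 2


class TestAverageReplicates:
    def test_identical_replicates_average_to_each(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(10, 30, 400)
        reps = [make_binned(vals) for _ in range(3)]
        avg = fp.average_replicates(reps, cut_pos=1, pad_bins=50,
                                    params=LoessParams(span=0.1))
        single = fp.average_replicates(reps[:1], cut_pos=1, pad_bins=50,
                                       params=LoessParams(span=0.1))
        assert np.allclose(avg.values, single.values, rtol=1e-12)

    def test_depth_scaling_is_removed(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(10, 30, 400)
        a = fp.average_replicates(
            [make_binned(vals), make_binned(2.0 * vals)],
            cut_pos=1, pad_bins=50, params=LoessParams(span=0.1),
        )
        b = fp.average_replicates(
            [make_binned(vals), make_binned(vals)],
            cut_pos=1, pad_bins=50, params=LoessParams(span=0.1),
        )
        assert np.allclose(a.values, b.values, rtol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        reps = [make_binned(rng.uniform(10, 30, 400)) for _ in range(3)]
        a = fp.average_replicates(reps, 1, 50, LoessParams(span=0.1))
        b = fp.average_replicates(reps[::-1], 1, 50, LoessParams(span=0.1))
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_inconsistent_masks_error(self):
        m = np.zeros(400, bool)
        m2 = m.copy()
        m2[5] = True
        with pytest.raises(fp.ParameterError):
            fp.average_replicates(
                [make_binned(np.ones(400), m), make_binned(np.ones(400), m2)],
                1, 50, LoessParams(span=0.1),
            )


class TestLocusRatio:
    def test_proportional_loci_all_ones(self):
        a = {0: 10.0, 60: 20.0, 120: 40.0}
        b = {0: 5.0, 60: 10.0, 120: 20.0}
        r = fp.locus_ratio_timecourse(a, b)
        assert all(v == pytest.approx(1.0) for v in r.values())

    def test_doubling_locus(self):
        r = fp.locus_ratio_timecourse(
            {0: 1.0, 120: 2.0}, {0: 1.0, 120: 1.0}
        )
        assert r[0] == 1.0
        assert r[120] == pytest.approx(2.0)

    def test_simulated_copy_difference_recovered(self):
        """Two loci with a true 1.5x copy difference give r ~ 1.5 within
        Poisson counting error."""
        rng = np.random.default_rng(10)
        n_probe = 50_000  # hybridization counts per probe
        a = {0: float(rng.poisson(n_probe)), 120: float(rng.poisson(1.5 * n_probe))}
        b = {0: float(rng.poisson(n_probe)), 120: float(rng.poisson(n_probe))}
        r = fp.locus_ratio_timecourse(a, b)
        sigma = 1.5 * np.sqrt(4.0 / n_probe)
        assert abs(r[120] - 1.5) < 3 * sigma

    def test_mismatched_timepoints_error(self):
        with pytest.raises(fp.ParameterError):
            fp.locus_ratio_timecourse({0: 1.0}, {0: 1.0, 60: 2.0})
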