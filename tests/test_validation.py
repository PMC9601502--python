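"""LOD/LOQ rules, precision statistics and linearity fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ddquant as dq
from ddquant.rounding import round_half_up
from ddquant.simulate import pork_like_config, simulate_dilution_series


def level(actual, detections, total=3, **kw):
    return dq.DilutionSeriesLevel(
        actual_percent=actual, detections=detections, total_replicates=total, **kw
    )


class TestDetectionRate:
    @pytest.mark.parametrize("d, expected", [(0, 0.0), (1, 100 / 3), (3, 100.0)])
    def test_rates(self, d, expected):
        assert dq.detection_rate(level(0.05, d)) == pytest.approx(expected)

    def test_zero_replicates_rejected(self):
        with pytest.raises(dq.InvalidInputError):
            dq.DilutionSeriesLevel(actual_percent=1.0, detections=0, total_replicates=0)


class TestDetermineLod:
    def test_reference_series_lod(self, pork_dilution, chicken_dilution):
        assert dq.determine_lod(pork_dilution) == 0.1
        assert dq.determine_lod(chicken_dilution) == 0.1

    def test_all_levels_detected_gives_lowest(self):
        series = [level(a, 3) for a in (0.5, 0.1, 1.0)]
        assert dq.determine_lod(series) == 0.1

    def test_no_level_fully_detected_is_undefined(self):
        series = [level(a, 2) for a in (0.1, 1.0)]
        assert dq.determine_lod(series) is None

    def test_stability_requirement_skips_nonmonotone_dip(self):
        # a fully detected low level does not count if a higher level failed
        series = [level(0.1, 3), level(0.5, 2), level(1.0, 3)]
        assert dq.determine_lod(series) == 1.0


class TestDetermineLoq:
    def test_reference_series_loq(self, pork_dilution, chicken_dilution):
        assert dq.determine_loq(pork_dilution) == 1.0
        assert dq.determine_loq(chicken_dilution) == 1.0

    def test_lod_not_above_loq_on_reference_series(self, pork_dilution):
        assert dq.determine_lod(pork_dilution) <= dq.determine_loq(pork_dilution)

    def test_high_rsd_level_fails_until_fully_passing_level(self):
        series = [
            level(0.5, 3, measured_mean=0.5, measured_sd=0.15),  # RSD 30 %
            level(1.0, 3, measured_mean=1.0, measured_sd=0.05),
            level(5.0, 3, measured_mean=5.1, measured_sd=0.2),
        ]
        assert dq.determine_loq(series) == 1.0

    def test_bias_arm_excludes_precise_but_biased_level(self):
        # tight replicates, 60 % bias: RSD alone would admit this level
        series = [
            level(0.1, 3, measured_mean=0.16, measured_sd=0.01),
            level(1.0, 3, measured_mean=1.02, measured_sd=0.02),
        ]
        assert dq.determine_loq(series) == 1.0

    def test_no_level_qualifies_is_undefined(self):
        series = [level(0.1, 2), level(1.0, 3, measured_mean=1.9, measured_sd=0.01)]
        assert dq.determine_loq(series) is None


class TestRsd:
    @pytest.mark.parametrize(
        "values, expected",
        [([1.25, 1.12, 1.11, 1.24, 1.23], 5.79), ([0.36, 0.39, 0.35, 0.41, 0.38], 6.32)],
    )
    def test_reference_values(self, values, expected):
        assert round_half_up(dq.rsd(values)) == expected

    def test_identical_values_zero(self):
        assert dq.rsd([2.0, 2.0, 2.0]) == 0.0

    def test_insufficient_data(self):
        with pytest.raises(dq.InsufficientDataError):
            dq.rsd([1.0])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=10),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, values, c):
        assert dq.rsd([c * v for v in values]) == pytest.approx(dq.rsd(values), rel=1e-6)


class TestRepeatabilityReproducibility:
    def test_identical_runs_give_zero_rsds(self):
        runs = {50.0: {"day1": [50.0, 50.0, 50.0], "day2": [50.0, 50.0, 50.0]}}
        (res,) = dq.repeatability_reproducibility(runs)
        assert all(v == 0.0 for v in res.within_run_rsd.values())
        assert res.between_run_rsd == 0.0
        assert res.acceptable

    def test_known_injected_noise_recovered(self):
        """Runs with 2 % multiplicative noise show ≈2 % repeatability RSD."""
        rng = np.random.default_rng(11)
        within = []
        for _ in range(100):
            runs = {
                50.0: {
                    "day1": list(50.0 * rng.lognormal(0, 0.02, size=3)),
                    "day2": list(50.0 * rng.lognormal(0, 0.02, size=3)),
                }
            }
            (res,) = dq.repeatability_reproducibility(runs)
            within.extend(res.within_run_rsd.values())
        assert np.mean(within) == pytest.approx(2.0, rel=0.15)

    def test_level_above_threshold_flagged(self):
        runs = {10.0: {"day1": [10.0, 16.0, 4.0], "day2": [10.0, 10.5, 9.5]}}
        (res,) = dq.repeatability_reproducibility(runs)
        assert not res.acceptable

    def test_single_replicate_insufficient(self):
        with pytest.raises(dq.InsufficientDataError):
            dq.repeatability_reproducibility({10.0: {"day1": [10.0]}})


class TestFitLinearity:
    def test_perfect_data(self):
        pairs = [(a, a) for a in (1, 5, 10, 50, 90)]
        fit = dq.fit_linearity(pairs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert (fit.range_low, fit.range_high) == (1, 90)

    def test_degenerate_design_raises(self):
        with pytest.raises(dq.SingularFitError):
            dq.fit_linearity([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])


class TestLodScalesWithDropletCount:
    def test_lod_nonincreasing_in_droplet_count(self):
        """More partitions per well means more target copies sampled, so
        the fully-detected level can only move down (or stay)."""
        levels = [0.00005, 0.0001, 0.0002, 0.0005, 0.001, 0.002, 0.005, 0.01]
        lods = []
        for n in (5_000, 20_000, 80_000):
            cfg = pork_like_config(droplets_per_well=n, qc_min_droplets=n // 2)
            per_seed = []
            for seed in (101, 202, 303):
                series = simulate_dilution_series(levels, 20, cfg, np.random.default_rng(seed))
                lod = dq.determine_lod(series)
                per_seed.append(lod if lod is not None else 100.0)
            lods.append(float(np.median(per_seed)))
        assert lods[0] >= lods[1] >= lods[2]
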