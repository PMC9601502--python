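"""Generative model: reproducibility, distributional correctness, and the
noiseless expected-value oracle."""

from dataclasses import replace

import numpy as np
import pytest

import ddquant as dq
from ddquant.simulate import chicken_like_config, pork_like_config


class TestSimulatePartition:
    def test_zero_rate_gives_zero_positives(self):
        part = dq.simulate_partition(0.0, 20_000, seed=3)
        assert part.positives == 0

    def test_binomial_expectation_at_unit_rate(self):
        part = dq.simulate_partition(1.0, 20_000, seed=5)
        p = 1 - np.exp(-1.0)
        sd = np.sqrt(20_000 * p * (1 - p))
        assert abs(part.positives - 20_000 * p) < 3 * sd

    def test_seed_reproducibility(self):
        a = dq.simulate_partition(0.3, 20_000, seed=9)
        b = dq.simulate_partition(0.3, 20_000, seed=9)
        assert a.positives == b.positives

    def test_negative_rate_rejected(self):
        with pytest.raises(dq.InvalidInputError):
            dq.simulate_partition(-0.1, 1000)


class TestSimulateMixtureWell:
    def test_zero_fraction_gives_no_target_signal(self):
        cfg = pork_like_config(replicate_cv=0.0)
        well = dq.simulate_mixture_well(0.0, cfg, "target", seed=1)
        assert well.partition.positives == 0

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(dq.InvalidInputError):
            dq.simulate_mixture_well(1.5, pork_like_config(), "target")

    def test_default_magnitudes_match_reference_regime(self):
        """Pork-like defaults at w=10 % give ≈30 target and ≈320 reference
        copies/μL, the magnitude of real single-copy assay data."""
        cfg = pork_like_config()
        rng = np.random.default_rng(17)
        target, reference = [], []
        for _ in range(50):
            for assay, out in (("target", target), ("reference", reference)):
                well = dq.simulate_mixture_well(0.10, cfg, assay, rng)
                conc = dq.cpd_to_concentration(
                    dq.estimate_cpd(well.partition), cfg.droplet_volume_nl
                )
                out.append(conc)
        assert np.mean(target) == pytest.approx(30.0, rel=0.1)
        assert np.mean(reference) == pytest.approx(321.3, rel=0.1)

    def test_degradation_scales_both_channels(self):
        cfg = pork_like_config(replicate_cv=0.0, degradation_factor=0.5)
        well = dq.simulate_mixture_well(0.5, cfg, "target", seed=2)
        full = dq.simulate_mixture_well(0.5, pork_like_config(replicate_cv=0.0), "target", seed=2)
        assert well.lambda_true == pytest.approx(0.5 * full.lambda_true)


class TestExpectedValueOracle:
    def test_noiseless_calibration_recovers_k_exactly(self):
        for cfg in (pork_like_config(), chicken_like_config()):
            cfg0 = replace(cfg, replicate_cv=0.0, expected_value_mode=True)
            mixtures = dq.simulate_calibration_series([0.1, 0.3, 0.5, 0.7, 0.9], 6, cfg0)
            ks = [dq.k_for_mixture(m) for m in mixtures]
            assert ks == [round(cfg.k_true, 2)] * 5

    def test_noiseless_pipeline_recovers_mass_fraction_exactly(self):
        cfg0 = replace(pork_like_config(), replicate_cv=0.0, expected_value_mode=True)
        mixtures = dq.simulate_calibration_series([0.2, 0.4, 0.6, 0.8], 3, cfg0)
        for m in mixtures:
            fraction = dq.mass_fraction(
                dq.mass_ratio(m.target_conc[0], m.reference_conc[0], cfg0.k_true)
            )
            assert fraction == pytest.approx(100 * m.mass_fraction_target, rel=1e-12)


class TestCalibrationSeries:
    def test_bit_reproducible_under_fixed_seed(self):
        cfg = pork_like_config()
        a = dq.simulate_calibration_series([0.1, 0.5], 3, cfg, seed=21)
        b = dq.simulate_calibration_series([0.1, 0.5], 3, cfg, seed=21)
        assert [m.target_conc for m in a] == [m.target_conc for m in b]

    @pytest.mark.parametrize("k_true", [1.19, 0.38])
    def test_parameter_recovery_within_five_percent(self, k_true):
        cfg = pork_like_config() if k_true > 1 else chicken_like_config()
        assert cfg.k_true == pytest.approx(k_true)
        recovered = []
        for seed in range(20):
            mixtures = dq.simulate_calibration_series(
                [0.1, 0.3, 0.5, 0.7, 0.9], 6, cfg, np.random.default_rng(1000 + seed)
            )
            recovered.append(dq.estimate_k(mixtures).k_mean)
        errors = np.abs(np.array(recovered) / k_true - 1)
        assert np.all(errors < 0.05)


class TestDilutionSeries:
    def test_zero_level_never_detected(self):
        cfg = pork_like_config()
        (lvl,) = dq.simulate_dilution_series([0.0], 20, cfg, seed=4)
        assert lvl.detections == 0

    def test_detection_probability_matches_poisson_theory(self):
        """A level with 0.2 expected target copies per well is detected in
        ≈ 1 - exp(-0.2) ≈ 18 % of replicates."""
        cfg = pork_like_config(replicate_cv=0.0)
        copies_per_well = cfg.c_target * cfg.droplet_volume_nl * 1e-3 * cfg.droplets_per_well
        w = 0.2 / copies_per_well
        (lvl,) = dq.simulate_dilution_series([w], 600, cfg, seed=12)
        expected = 1 - np.exp(-0.2)
        se = np.sqrt(expected * (1 - expected) / 600)
        assert abs(lvl.detections / 600 - expected) < 3 * se

    def test_lod_brackets_three_copy_level(self):
        """The fully-detected threshold sits near the level where the well
        expects ≈3 target copies (detection probability ≈95 %)."""
        cfg = pork_like_config(replicate_cv=0.0)
        copies_per_well = cfg.c_target * cfg.droplet_volume_nl * 1e-3 * cfg.droplets_per_well
        w3 = 3.0 / copies_per_well
        levels = [w3 / 16, w3 / 4, w3, w3 * 4, w3 * 16]
        lods = []
        for seed in (31, 32, 33, 34, 35):
            series = dq.simulate_dilution_series(levels, 10, cfg, np.random.default_rng(seed))
            lod = dq.determine_lod(series)
            assert lod is not None
            lods.append(lod)
        assert min(lods) >= 100 * w3 / 16
        assert max(lods) <= 100 * w3 * 16
        assert any(lod in (100 * w3, 100 * w3 * 4) for lod in lods)


class TestEndToEndBias:
    def test_mass_fraction_bias_below_two_points(self):
        """Estimated fractions at 10/50/90 % are unbiased to <2 pp under
        default noise over 200 seeded runs."""
        cfg = pork_like_config()
        rng = np.random.default_rng(77)
        for w in (0.1, 0.5, 0.9):
            fractions = []
            for _ in range(200):
                qt = _measured(dq.simulate_mixture_well(w, cfg, "target", rng), cfg)
                qr = _measured(dq.simulate_mixture_well(w, cfg, "reference", rng), cfg)
                fractions.append(dq.mass_fraction(dq.mass_ratio(qt, qr, cfg.k_true)))
            assert abs(np.mean(fractions) - 100 * w) < 2.0


def _measured(well, cfg):
    return dq.cpd_to_concentration(dq.estimate_cpd(well.partition), cfg.droplet_volume_nl)
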