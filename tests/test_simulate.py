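import math

import numpy as np
import pytest

import ddplex as dd
from ddplex.clustering import band_of
from ddplex.simulate import theoretical_grid, write_amplitude_csv


class TestLambdaFromCopies:
    def test_hand_computed(self, sim_config):
        assert dd.lambda_from_copies(1000.0, sim_config) == pytest.approx(0.0425)

    def test_zero(self, sim_config):
        assert dd.lambda_from_copies(0.0, sim_config) == 0.0

    def test_round_trip_with_estimator(self, sim_config, quant_config):
        # the concentration from the half-positive well maps back to lambda=ln 2
        r = dd.estimate_target(10000, 20000, quant_config)
        lam = dd.lambda_from_copies(r.copies_per_reaction, sim_config)
        assert lam == pytest.approx(math.log(2), rel=1e-9)


class TestSimulateWell:
    def test_seed_determinism(self, sim_config, layout):
        d1, t1 = dd.simulate_well(sim_config, layout)
        d2, t2 = dd.simulate_well(sim_config, layout)
        assert np.array_equal(d1.ch1, d2.ch1) and np.array_equal(d1.ch2, d2.ch2)
        assert np.array_equal(t1.copies, t2.copies)
        assert np.array_equal(t1.is_rain, t2.is_rain)

    def test_different_seed_differs(self, sim_config, layout):
        from dataclasses import replace

        d1, _ = dd.simulate_well(sim_config, layout)
        d2, _ = dd.simulate_well(replace(sim_config, seed=8), layout)
        assert not np.array_equal(d1.ch1, d2.ch1)

    def test_empty_reaction(self, layout):
        cfg = dd.SimulationConfig(
            copies_per_reaction={t.name: 0.0 for t in layout.targets}, seed=1
        )
        droplets, truth = dd.simulate_well(cfg, layout)
        assert (truth.band_ch1 == 0).all() and (truth.band_ch2 == 0).all()
        model = cfg.channel1
        lo = model.baseline_mean - 6 * model.baseline_sd
        hi = model.baseline_mean + 6 * model.baseline_sd
        assert ((droplets.ch1 > lo) & (droplets.ch1 < hi)).all()

    def test_positive_count_within_binomial_bound(self):
        layout = dd.AssayLayout((dd.Target("t", 1, "low"),), "single")
        cfg = dd.SimulationConfig(
            copies_per_reaction={"t": 1000.0}, n_droplets=20000, seed=42
        )
        _, truth = dd.simulate_well(cfg, layout)
        lam = dd.lambda_from_copies(1000.0, cfg)
        p = 1 - math.exp(-lam)
        expected = 20000 * p
        bound = 3 * math.sqrt(20000 * p * (1 - p))
        assert abs(truth.positive_droplets("t") - expected) <= bound

    def test_true_bands_derive_from_occupancy(self, simulated_well, layout):
        _, truth = simulated_well
        names = truth.target_names
        low = truth.copies[:, names.index("MON863")] > 0  # ch1 low
        high = truth.copies[:, names.index("hmgA")] > 0  # ch1 high
        assert np.array_equal(truth.band_ch1, low * 1 + high * 2)

    def test_mean_positive_fraction_converges(self):
        # law of large numbers across wells, 3-sigma binomial tolerance
        layout = dd.AssayLayout((dd.Target("t", 1, "low"),), "single")
        lam = 0.1
        copies = lam / 0.00085 * 20
        n_wells, n_droplets = 20, 5000
        total_pos = 0
        for seed in range(n_wells):
            cfg = dd.SimulationConfig(
                copies_per_reaction={"t": copies}, n_droplets=n_droplets, seed=seed
            )
            _, truth = dd.simulate_well(cfg, layout)
            total_pos += truth.positive_droplets("t")
        n = n_wells * n_droplets
        p = 1 - math.exp(-lam)
        assert abs(total_pos / n - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_missing_target_in_config_rejected(self, layout):
        cfg = dd.SimulationConfig(copies_per_reaction={"hmgA": 100.0}, seed=1)
        with pytest.raises(ValueError, match="MON863"):
            dd.simulate_well(cfg, layout)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_droplets": 0}, "n_droplets"),
            ({"rain_fraction": 1.0}, "rain_fraction"),
            ({"droplet_volume_nL": 0.0}, "droplet_volume_nL"),
        ],
    )
    def test_config_validation_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            dd.SimulationConfig(copies_per_reaction={"t": 1.0}, **kwargs)


class TestEndToEndRecovery:
    def test_tetraplex_recovery_within_10_percent(self, sim_config, layout):
        droplets, truth = dd.simulate_well(sim_config, layout)
        results = dd.MultiplexModel(droplets, layout).fit()
        for t in layout.targets:
            realized = truth.realized_copies_per_reaction(t.name, sim_config)
            measured = results.target(t.name).copies_per_reaction
            assert abs(measured - realized) / realized <= 0.10

    def test_automatic_grid_matches_ground_truth_bands(self, sim_config, layout):
        droplets, truth = dd.simulate_well(sim_config, layout)
        grid = dd.propose_grid(droplets, layout)
        b1 = band_of(droplets.ch1, grid.ch1_lines)
        b2 = band_of(droplets.ch2, grid.ch2_lines)
        agreement = np.mean((b1 == truth.band_ch1) & (b2 == truth.band_ch2))
        assert agreement >= 0.995


class TestRain:
    def duplex(self):
        return dd.AssayLayout(
            (dd.Target("low_t", 1, "low"), dd.Target("high_t", 1, "high")), "duplex"
        )

    def test_rain_false_positives_are_all_rain_droplets(self):
        layout = self.duplex()
        cfg = dd.SimulationConfig(
            copies_per_reaction={"low_t": 0.0, "high_t": 2000.0},
            rain_fraction=0.02,
            seed=11,
        )
        droplets, truth = dd.simulate_well(cfg, layout)
        grid = theoretical_grid(cfg, layout)
        results = {
            r.target_name: r
            for r in dd.quantify_multiplex(dd.classify(droplets, grid), layout)
        }
        fp = results["low_t"].positives
        assert fp > 0
        rate = dd.false_positive_rate(fp, results["high_t"].positives)
        assert rate > 0
        b1 = band_of(droplets.ch1, grid.ch1_lines)
        fp_idx = np.flatnonzero((b1 == 1) | (b1 == 3))
        assert truth.is_rain[fp_idx].all()

    def test_no_rain_no_false_positives_at_300_copies(self):
        layout = self.duplex()
        cfg = dd.SimulationConfig(
            copies_per_reaction={"low_t": 0.0, "high_t": 300.0},
            rain_fraction=0.0,
            seed=13,
        )
        droplets, _ = dd.simulate_well(cfg, layout)
        grid = theoretical_grid(cfg, layout)
        results = dd.quantify_multiplex(dd.classify(droplets, grid), layout)
        assert results[0].positives == 0


class TestDilutionSeries:
    def test_assigned_level_bookkeeping(self, layout):
        base = dd.SimulationConfig(
            copies_per_reaction={t.name: 1000.0 for t in layout.targets}, seed=2
        )
        series = dd.simulate_dilution_series(
            base, layout, [1, 0.1, 0.01], 2, target="hmgA"
        )
        assert [lv.assigned_copies for lv in series] == [1000.0, 100.0, 10.0]
        assert all(len(lv.replicate_values) == 2 for lv in series)

    def test_low_copy_level_has_negative_replicates(self, layout):
        # at 5 copies/reaction the expected positive count is ~3 droplets,
        # so some of 15 replicates fall under the 3-droplet rule
        base = dd.SimulationConfig(
            copies_per_reaction={t.name: 5.0 for t in layout.targets}, seed=9
        )
        series = dd.simulate_dilution_series(base, layout, [1.0], 15, target="hmgA")
        assert any(d < 3 for d in series[0].replicate_positive_droplets)

    def test_asymmetric_series_keeps_low_target_countable(self):
        layout = dd.example_tetraplex()
        base = dd.SimulationConfig(
            copies_per_reaction={
                "hmgA": 56000.0,
                "MON863": 5000.0,
                "MON810": 5000.0,
                "DP98140": 20.0,
            },
            seed=17,
        )
        series = dd.simulate_dilution_series(
            base, layout, [2.0, 1.0], 3, scale_target="DP98140"
        )
        lo = series["DP98140"]
        assert [lv.assigned_copies for lv in lo] == [40.0, 20.0]
        # the low target's positives are still counted in its cells
        assert all(d > 0 for lv in lo for d in lv.replicate_positive_droplets)
        # the other targets were not scaled
        assert all(lv.assigned_copies == 56000.0 for lv in series["hmgA"])

    def test_series_returns_dict_without_target(self, layout):
        base = dd.SimulationConfig(
            copies_per_reaction={t.name: 500.0 for t in layout.targets}, seed=4
        )
        out = dd.simulate_dilution_series(base, layout, [1.0], 1)
        assert set(out) == {t.name for t in layout.targets}


class TestGroundTruthExport:
    def test_amplitude_csv_round_trip(self, simulated_well, tmp_path):
        droplets, _ = simulated_well
        path = tmp_path / "well.csv"
        with open(path, "w") as sink:
            write_amplitude_csv(droplets, sink)
        back = dd.read_amplitude_export(path, well_id=droplets.well_id)
        assert back.n_accepted == droplets.n_accepted
        np.testing.assert_allclose(back.ch1, droplets.ch1, atol=1e-3)

    def test_ground_truth_table_shape(self, simulated_well, tmp_path):
        from ddplex.simulate import write_ground_truth

        droplets, truth = simulated_well
        path = tmp_path / "truth.tsv"
        with open(path, "w") as sink:
            write_ground_truth(truth, sink)
        lines = path.read_text().splitlines()
        assert len(lines) == droplets.n_accepted + 1
        assert lines[0].split("\t")[:4] == [f"copies_{n}" for n in truth.target_names]
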