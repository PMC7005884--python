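import json
import math

import numpy as np
import pytest
from scipy import stats

from sipcell.population import growth_rate_counts
from sipcell.rates import fit_rate
from sipcell.simulate import (
    IncubationSpec,
    NanoSimsSpec,
    PopulationSpec,
    ScenarioConfig,
    gom_fixture,
    simulate_cell_counts,
    simulate_dataset,
    simulate_incubation_series,
    simulate_nanosims_cells,
)
from sipcell.singlecell import cell_enrichment, growth_rate_from_enrichment


def _one_substrate_cfg(true_rate, noise, seed=0, **inc_kw):
    return ScenarioConfig(
        seed=seed,
        populations=[],
        incubation=IncubationSpec(
            ambient_mol_l={"nitrite": 848e-9},
            true_bulk_rates={"nitrite": true_rate},
            noise_sd_nmol=noise,
            **inc_kw,
        ),
    )


class TestIncubationSeries:
    def test_noiseless_exact_recovery(self):
        cfg = _one_substrate_cfg(564.0, 0.0)
        series = simulate_incubation_series(cfg)["nitrite"]
        est = fit_rate(series)
        assert est.rate == pytest.approx(564.0, rel=1e-9)
        assert est.detected

    def test_replication_structure(self):
        cfg = _one_substrate_cfg(100.0, 1.0)
        series = simulate_incubation_series(cfg)["nitrite"]
        assert len(series.times_h) == 12  # 3 replicates x 4 time points
        assert series.n_timepoints == 4

    def test_mean_recovery_over_simulations(self):
        rates = []
        for seed in range(200):
            cfg = _one_substrate_cfg(564.0, 10.0, seed=seed)
            rates.append(fit_rate(simulate_incubation_series(cfg)["nitrite"]).rate)
        assert np.mean(rates) == pytest.approx(564.0, rel=0.02)

    def test_null_detection_frequency(self):
        detections = 0
        n = 400
        for seed in range(n):
            cfg = _one_substrate_cfg(0.0, 10.0, seed=seed)
            detections += fit_rate(simulate_incubation_series(cfg)["nitrite"]).detected
        # one-sided alpha=0.05; binomial 4-sigma band
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(detections / n - 0.05) < 4 * se


class TestNanoSimsCells:
    def _cfg(self, gr, seed=0, cells=50, counts=2e5):
        pop = PopulationSpec(
            taxon="target_NOB",
            abundance_per_l=1e7,
            shape="capsule",
            length_um=1.4,
            width_um=0.5,
            growth_rates={"ammonium": gr},
        )
        return ScenarioConfig(
            seed=seed,
            populations=[pop],
            incubation=IncubationSpec(
                ambient_mol_l={"ammonium": 320e-9}, true_bulk_rates={}
            ),
            nanosims=NanoSimsSpec(
                cells_per_taxon=cells, mean_total_ion_counts=counts, planes=10
            ),
        )

    def test_unlabeled_cells_center_on_zero(self):
        cells, truth = simulate_nanosims_cells(self._cfg(0.0, seed=3))
        excesses = [cell_enrichment(c).n15_excess for c in cells]
        assert np.mean(excesses) == pytest.approx(0.0, abs=0.01)
        assert truth[0]["true_excess_at_percent"] == 0.0

    def test_growth_rate_recovery(self):
        cfg = self._cfg(0.53, seed=4, cells=100)
        label = cfg.incubation.label_excess("ammonium")
        cells, truth = simulate_nanosims_cells(cfg)
        grs = [
            growth_rate_from_enrichment(cell_enrichment(c).n15_excess, label, 1.0)
            for c in cells
        ]
        # Poisson-limited spread: SE of the mean well under 1%
        assert np.mean(grs) == pytest.approx(0.53, rel=0.01)

    def test_filter_fail_fraction_matches_prediction(self):
        # small count budget: predict the pass probability by enumerating
        # the Poisson count distributions (independent oracle)
        cfg = self._cfg(0.0, seed=5, cells=300, counts=110000.0)
        cells, _ = simulate_nanosims_cells(cfg)
        nat = 0.0037
        lam = 110000.0
        # area spread: pass probability averaged over simulated cell areas
        p_pass = []
        for c in cells:
            lam_cell = lam * c.roi_area_um2 / _mean_area(cfg)
            lam_minor = nat * lam_cell
            lam_major = (1 - nat) * lam_cell
            m = np.arange(0, 2000)
            pm = stats.poisson.pmf(m, lam_minor)
            # major counts are large; approximate by expectation
            with np.errstate(divide="ignore"):
                err = np.sqrt(1.0 / m + 1.0 / lam_major)
            p_pass.append(float(pm[(m > 0) & (err < 0.05)].sum()))
        expected = float(np.mean(p_pass))
        observed = np.mean([cell_enrichment(c).passed_filter_n for c in cells])
        se = math.sqrt(max(expected * (1 - expected), 1e-6) / len(cells))
        assert abs(observed - expected) < 5 * se + 0.02

    def test_ground_truth_attached(self):
        cells, truth = simulate_nanosims_cells(self._cfg(0.2, seed=6, cells=5))
        assert len(cells) == len(truth) == 5
        assert {t["cell_id"] for t in truth} == {c.cell_id for c in cells}


def _mean_area(cfg):
    from sipcell.simulate import _projected_area

    return _projected_area(cfg.populations[0].cell_shape)


class TestCellCounts:
    def _cfg(self, gr, seed=0, effort=1000):
        pop = PopulationSpec(
            taxon="target_NOB",
            abundance_per_l=1e7,
            shape="capsule",
            length_um=1.4,
            width_um=0.5,
            growth_rates={"ammonium": gr},
        )
        return ScenarioConfig(
            seed=seed,
            populations=[pop],
            incubation=IncubationSpec(
                ambient_mol_l={}, true_bulk_rates={}, expected_counted_cells=effort
            ),
        )

    def test_growth_recovery_within_counting_error(self):
        snap = simulate_cell_counts(self._cfg(1.2, seed=7, effort=2000))[0]
        gr = growth_rate_counts(snap.abundance_t0, snap.abundance_t1, snap.t_days)
        se = math.sqrt(1 / snap.counted_t0 + 1 / snap.counted_t1)
        assert abs(gr - 1.2) < 4 * se

    def test_flat_population(self):
        snap = simulate_cell_counts(self._cfg(0.0, seed=8, effort=5000))[0]
        gr = growth_rate_counts(snap.abundance_t0, snap.abundance_t1, snap.t_days)
        se = math.sqrt(1 / snap.counted_t0 + 1 / snap.counted_t1)
        assert abs(gr) < 4 * se

    def test_high_effort_tightens_recovery(self):
        snap = simulate_cell_counts(self._cfg(0.5, seed=9, effort=200000))[0]
        gr = growth_rate_counts(snap.abundance_t0, snap.abundance_t1, snap.t_days)
        assert gr == pytest.approx(0.5, abs=0.02)


class TestGomFixture:
    def test_parameter_values(self):
        cfg = gom_fixture()
        by_taxon = {p.taxon: p for p in cfg.populations}
        assert by_taxon["target_NOB"].abundance_per_l == 1.32e7
        assert by_taxon["target_AOA"].abundance_per_l == 4.15e8
        assert cfg.incubation.true_bulk_rates["nitrite"] == 564.0
        assert cfg.incubation.true_bulk_rates["ammonium"] == 2508.0
        assert cfg.delta_g_kj_mol == {
            "nitrite_oxidation": -65.0,
            "ammonia_oxidation": -262.0,
        }

    def test_volumes_match_quota_calibration(self):
        cfg = gom_fixture()
        by_taxon = {p.taxon: p for p in cfg.populations}
        assert by_taxon["target_NOB"].volume_um3 == pytest.approx(0.25, rel=1e-9)
        assert by_taxon["target_AOA"].volume_um3 == pytest.approx(0.06, rel=1e-9)

    def test_combined_assimilation_truth(self):
        from sipcell.morphology import quota_from_volume

        cfg = gom_fixture()
        nob = next(p for p in cfg.populations if p.taxon == "target_NOB")
        quota = quota_from_volume(0.25)
        combined = sum(gr * quota.nitrogen_fmol for gr in nob.growth_rates.values())
        assert combined == pytest.approx(0.903, abs=1e-9)

    def test_determinism_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        cfg = gom_fixture(seed=11)
        cfg.nanosims.cells_per_taxon = 5
        cfg.nanosims.planes = 5
        simulate_dataset(cfg).write(d1)
        cfg2 = gom_fixture(seed=11)
        cfg2.nanosims.cells_per_taxon = 5
        cfg2.nanosims.planes = 5
        simulate_dataset(cfg2).write(d2)
        for name in ("roi.tsv", "timeseries.csv", "counts.csv", "ground_truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        cfg_a, cfg_b = gom_fixture(seed=1), gom_fixture(seed=2)
        for c in (cfg_a, cfg_b):
            c.nanosims.cells_per_taxon = 3
            c.nanosims.planes = 3
        da = simulate_dataset(cfg_a)
        db = simulate_dataset(cfg_b)
        assert da.series["nitrite"].product_nmol_l != db.series["nitrite"].product_nmol_l

    def test_scaling_invariance_of_yield(self):
        # halving bulk rates and growth rates together leaves yields unchanged
        from sipcell.energetics import biomass_yield, energy_flux
        from sipcell.morphology import quota_from_volume
        from sipcell.population import population_assimilation

        quota = quota_from_volume(0.25)
        for factor in (1.0, 0.5):
            rate = 564.0 * factor
            grs = {
                s: g * factor
                for s, g in gom_fixture().populations[0].growth_rates.items()
            }
            c_per_cell = sum(grs.values()) * quota.nitrogen_fmol * 6.625
            c_assim = population_assimilation(c_per_cell, 1.32e7)
            y = biomass_yield(c_assim, energy_flux(rate, -65.0))
            if factor == 1.0:
                baseline = y
        assert y == pytest.approx(baseline, rel=1e-12)
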