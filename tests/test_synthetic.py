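"""The synthetic-study generator: printing model, virtual tester, fatigue draws."""

import json

import numpy as np
import pytest

from poroendure.fatigue import CENSOR_LIMIT, LoadPlan, fit_sn, observations_to_frame
from poroendure.geometry import (
    UnitCellSpec,
    VoxelGrid,
    threshold_for_porosity,
    voxelize_unit_cell,
)
from poroendure.metrology import records_to_frame
from poroendure.monotonic import (
    OffsetCriterion,
    estimate_stiffness,
    ultimate_load_max,
    ultimate_load_offset,
)
from poroendure.synthetic import (
    FatigueNoiseModel,
    PrintModel,
    VirtualTesterConfig,
    closed_form_offset_load,
    generate_study,
    make_tensile_curve,
    reduced_config,
    sample_fatigue_lifetimes,
    simulate_printing,
    virtual_monotonic_test,
)


def _cell_grid(cell_type="SP", L=0.75, porosity=0.7, n=32):
    cell = UnitCellSpec(cell_type, L, porosity)
    threshold_for_porosity(cell, L / n)
    return VoxelGrid(voxelize_unit_cell(cell, n), L / n)


class TestSimulatePrinting:
    def test_zero_radius_is_identity(self):
        grid = _cell_grid()
        model = PrintModel(radius_voxels=(("SP", 0.0), ("SW", 0.0)), surface_noise=0.0)
        out = simulate_printing(grid, model, "SP", periodic=True)
        assert np.array_equal(out.solid, grid.solid)

    def test_dilation_strictly_reduces_porosity(self):
        grid = _cell_grid()
        out = simulate_printing(grid, PrintModel(surface_noise=0.0), "SP", periodic=True)
        assert (1 - out.solid.mean()) < (1 - grid.solid.mean())

    def test_cell_type_asymmetry(self):
        # with the default radii SP loses clearly fewer porosity points than SW
        drops = {}
        for ct, L in (("SP", 0.75), ("SW", 1.125)):
            grid = _cell_grid(ct, L, 0.7)
            out = simulate_printing(
                grid, PrintModel(surface_noise=0.0), ct, periodic=True
            )
            drops[ct] = (1 - grid.solid.mean()) - (1 - out.solid.mean())
        assert drops["SP"] < drops["SW"]

    def test_oversized_radius_rejected(self):
        grid = _cell_grid(n=16)
        with pytest.raises(ValueError):
            simulate_printing(grid, PrintModel(radius_voxels=(("SP", 99), ("SW", 99))), "SP")


class TestVirtualTester:
    def test_elastic_perfectly_plastic_limit(self):
        cfg = VirtualTesterConfig(hardening_ratio=0.0)
        c = virtual_monotonic_test(0.0, "SP", cfg)
        assert estimate_stiffness(c) == pytest.approx(cfg.k0, rel=1e-9)
        assert c.F.max() == pytest.approx(cfg.F0, rel=1e-9)

    def test_lower_porosity_is_stronger(self):
        cfg = VirtualTesterConfig()
        crit = OffsetCriterion(cfg.failure_offset)
        loads = {
            p: ultimate_load_offset(
                virtual_monotonic_test(p, "SP", cfg), criterion=crit
            ).F_ult
            for p in (0.60, 0.70)
        }
        assert loads[0.60] > loads[0.70]

    def test_offset_load_matches_closed_form(self):
        cfg = VirtualTesterConfig()
        for p, ct in ((0.5, "SP"), (0.65, "SW")):
            c = virtual_monotonic_test(p, ct, cfg)
            k = cfg.stiffness(p, ct)
            F_y = cfg.knee_force(p, ct)
            expected = closed_form_offset_load(k, F_y, cfg.hardening_ratio, 0.07)
            got = ultimate_load_offset(c, k, OffsetCriterion(0.07)).F_ult
            assert got == pytest.approx(expected, rel=1e-9)

    def test_softening_curve_peaks_at_failure_offset(self):
        cfg = VirtualTesterConfig()
        c = virtual_monotonic_test(0.55, "SP", cfg, softening=True)
        k = cfg.stiffness(0.55, "SP")
        F_y = cfg.knee_force(0.55, "SP")
        expected = closed_form_offset_load(k, F_y, cfg.hardening_ratio, cfg.failure_offset)
        assert ultimate_load_max(c).F_ult == pytest.approx(expected, rel=1e-9)


class TestFatigueSampling:
    def test_boundary_load_is_exact_runout(self):
        noise = FatigueNoiseModel(scatter_sd=0.0)
        F_ult = 1000.0
        boundary = noise.a * F_ult * CENSOR_LIMIT**noise.b
        plan = LoadPlan(levels=[(boundary / F_ult, boundary)], replicates_per_level=2)
        obs = sample_fatigue_lifetimes(F_ult, plan, noise, np.random.default_rng(0))
        assert all(o.runout and o.N_f == CENSOR_LIMIT for o in obs)

    def test_ten_percent_level_is_dominated_by_runouts(self):
        noise = FatigueNoiseModel()
        plan = LoadPlan(levels=[(0.10, 100.0)], replicates_per_level=20)
        obs = sample_fatigue_lifetimes(1000.0, plan, noise, np.random.default_rng(1))
        assert np.mean([o.runout for o in obs]) >= 0.9

    def test_lower_level_lives_longer(self):
        noise = FatigueNoiseModel()
        rng = np.random.default_rng(2)
        plan = LoadPlan(
            levels=[(0.5, 500.0), (0.35, 350.0), (0.25, 250.0)],
            replicates_per_level=40,
        )
        obs = sample_fatigue_lifetimes(1000.0, plan, noise, rng)
        med = [
            np.median([o.N_f for o in obs if o.F_cyclic == load])
            for load in (500.0, 350.0, 250.0)
        ]
        assert med[0] < med[1] < med[2]

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            FatigueNoiseModel(b=0.1)


class TestTensileFixture:
    def test_shape_and_peak(self):
        strain, stress, truth = make_tensile_curve()
        assert np.all(np.diff(strain) >= 0)
        i = np.argmax(stress)
        assert stress[i] == truth["uts_mpa"]
        assert strain[i] == pytest.approx(truth["a_percent"] / 100.0)

    def test_inconsistent_fixture_rejected(self):
        with pytest.raises(ValueError):
            make_tensile_curve(proportional_limit=900.0)  # above sigma_y


class TestGenerateStudy:
    def test_roster_and_split(self, study):
        assert sorted(study.designs) == ["50SP", "50SW", "60SP", "60SW", "70SP", "70SW"]
        assert sorted(study.calibration_ids) == ["60SP", "60SW", "70SP", "70SW"]
        assert sorted(study.validation_ids) == ["50SP", "50SW"]

    def test_fatigue_campaign_shape(self, study):
        frame = observations_to_frame(study.observations)
        assert len(frame) == 144
        assert (frame.groupby("design_id").size() == 24).all()

    def test_printing_deficit_structure(self, study):
        for d in study.designs.values():
            assert d.printed_porosity < d.design_porosity
        sp = np.mean(
            [
                d.design_porosity - d.printed_porosity
                for d in study.designs.values()
                if d.cell_type.value == "SP"
            ]
        )
        sw = np.mean(
            [
                d.design_porosity - d.printed_porosity
                for d in study.designs.values()
                if d.cell_type.value == "SW"
            ]
        )
        assert sp < sw

    def test_ultimate_load_porosity_scale(self, study):
        # ~200 N of ultimate load per 10 porosity points (within a factor 2)
        for ct in ("SP", "SW"):
            d60 = study.designs[f"60{ct}"].F_ult_exp
            d70 = study.designs[f"70{ct}"].F_ult_exp
            assert 100.0 <= d60 - d70 <= 400.0

    def test_truth_record_recovers_sn_law(self, study):
        # a and b have strongly correlated single-study scatter, so recovery
        # is judged on the median across study seeds (geometry is cached,
        # only the stochastic stages regenerate)
        truth = study.truth["sn_law"]
        fits = [fit_sn(study.observations)]
        fits += [
            fit_sn(generate_study(seed=s, config=study.config).observations)
            for s in range(1, 9)
        ]
        assert np.median([f.a for f in fits]) == pytest.approx(truth["a"], abs=0.5)
        assert np.median([f.b for f in fits]) == pytest.approx(truth["b"], abs=0.03)
        # the extrapolated endurance fraction is the stable functional
        assert fits[0].endurance_fraction_at_5M == pytest.approx(
            truth["a"] * truth["censor_limit"] ** truth["b"], abs=0.02
        )

    def test_same_seed_is_byte_identical(self):
        cfg = reduced_config()
        s1 = generate_study(seed=5, config=cfg)
        s2 = generate_study(seed=5, config=cfg)
        assert (
            observations_to_frame(s1.observations).to_csv()
            == observations_to_frame(s2.observations).to_csv()
        )
        assert (
            records_to_frame(s1.porosity_records()).to_csv()
            == records_to_frame(s2.porosity_records()).to_csv()
        )
        assert json.dumps(s1.truth, sort_keys=True) == json.dumps(
            s2.truth, sort_keys=True
        )

    def test_save_layout(self, study, tmp_path):
        study.save(tmp_path / "study")
        root = tmp_path / "study"
        assert (root / "fatigue.csv").exists()
        assert (root / "porosity.csv").exists()
        assert (root / "truth.json").exists()
        truth = json.loads((root / "truth.json").read_text())
        assert truth["schema_version"] == 1
        assert len(list((root / "curves").glob("*.csv"))) == 6 * (4 + 2 + 4)
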