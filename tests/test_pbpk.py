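"""Whole-body model: structure, conservation, solver accuracy, readouts."""

import math

import numpy as np
import pytest

from tacpredict.constants import LiteratureConstants, NuclideConstants, DEFAULT_CONSTANTS
from tacpredict.parameters import FitParameters, DEFAULT_PARAMETERS
from tacpredict.pbpk import (
    BINDING_ORGANS,
    LAYOUT,
    N_BASE,
    Trajectory,
    build_model,
    build_ode_system,
    organ_activity,
    simulate,
)
from tacpredict.physiology import ConfigurationError, DoseEvent, DosingSchedule, PatientPhysiology


def _params(**overrides):
    return FitParameters.from_dict({**DEFAULT_PARAMETERS, **overrides})


class TestBuildModel:
    def test_lumped_lesions_use_tumour_mean(self, median_physiology, constants):
        m = build_model(median_physiology, constants, _params(rd_tumour1=28.0, rd_tumour2=59.0))
        assert m.receptor_density("tumour_liver") == pytest.approx(43.5)
        assert m.receptor_density("tumour_rob") == pytest.approx(43.5)

    def test_lumped_lesions_equal_tumours(self, median_physiology, constants):
        m = build_model(median_physiology, constants, _params(rd_tumour1=40.0, rd_tumour2=40.0))
        assert m.receptor_density("tumour_liver") == pytest.approx(40.0)

    def test_six_fitted_densities_and_derived_capacities(self, median_model):
        for organ in ("tumour1", "tumour2", "kidneys", "liver", "spleen", "muscle_fat"):
            expected = DEFAULT_PARAMETERS[f"rd_{organ}"] * median_model.v_int[organ]
            assert median_model.receptor_capacity_nmol[organ] == pytest.approx(expected)

    def test_missing_volume_names_region(self, constants):
        with pytest.raises(ConfigurationError, match="liver"):
            PatientPhysiology(
                weight_kg=76.5, height_cm=176.5, gfr_ml_min_1p73m2=70.0,
                volumes_l={"kidneys": 0.36, "spleen": 0.18, "tumour1": 0.03, "tumour2": 0.03},
            )

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            _params(rd_kidneys=0.0)

    def test_sub_threshold_tumour_rejected(self):
        with pytest.raises(ConfigurationError, match="tumour1"):
            PatientPhysiology(
                weight_kg=76.5, height_cm=176.5, gfr_ml_min_1p73m2=70.0,
                volumes_l={"kidneys": 0.36, "spleen": 0.18, "liver": 1.8,
                           "tumour1": 0.004, "tumour2": 0.03},
            )


class TestSimulate:
    def test_zero_administration_gives_zero_activity(self, median_model):
        dosing = DosingSchedule(events=[DoseEvent(0.0, 0.0, 0.0, 0.0, "ga68")])
        traj = simulate(median_model, dosing, t_end=100.0, grid=np.array([0.0, 50.0, 100.0]))
        assert np.all(traj.states == 0.0)
        assert traj.activity_at("kidneys", 50.0) == 0.0

    def test_mass_conservation_median_patient(self, median_trajectory):
        assert median_trajectory.balance_error_max < 1e-3

    def test_mass_conservation_during_infusion(self, median_model, median_dosing):
        infusion = median_dosing.events[1]
        grid = np.linspace(infusion.start_min, infusion.start_min + infusion.duration_min, 7)
        traj = simulate(median_model, median_dosing, t_end=grid[-1], grid=grid)
        assert traj.balance_error_max < 1e-3

    def test_grid_outside_window_rejected(self, median_model, median_dosing):
        with pytest.raises(ValueError):
            simulate(median_model, median_dosing, t_end=100.0, grid=np.array([150.0]))

    def test_loose_and_tight_tolerances_agree(self, median_model, median_dosing, median_trajectory):
        grid = np.array([63.0, 11520.0, 20160.0])
        loose = simulate(median_model, median_dosing, t_end=20200.0, grid=grid, rtol=1e-6, atol=1e-9)
        for region in ("kidneys", "tumour1", "whole_body"):
            for t in grid:
                a, b = loose.activity_at(region, t), median_trajectory.activity_at(region, t)
                assert a == pytest.approx(b, rel=5e-3, abs=1e-9)


class TestIndependentIntegratorOracle:
    def test_matches_fixed_step_rk4_over_first_200_min(self, median_model):
        """BDF/LSODA solution vs an independently stepped classic RK4."""
        dosing = DosingSchedule(events=[DoseEvent(0.0, 0.0, 1.7e-3, 13.0, "ga68")])
        grid = np.array([50.0, 100.0, 150.0, 200.0])
        traj = simulate(median_model, dosing, t_end=200.0, grid=grid)

        sys_ = build_ode_system(median_model, 1)
        u = np.zeros(sys_.n)
        y = np.zeros(sys_.n)
        y[LAYOUT[("serum", "venous")]] = 13.0 + 1.7e-3
        dt = 0.01
        out = {}
        t = 0.0
        for step in range(int(200.0 / dt)):
            k1 = sys_.rhs(t, y, u)
            k2 = sys_.rhs(t + dt / 2, y + dt / 2 * k1, u)
            k3 = sys_.rhs(t + dt / 2, y + dt / 2 * k2, u)
            k4 = sys_.rhs(t + dt, y + dt * k3, u)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = (step + 1) * dt
            if np.any(np.isclose(t, grid)):
                out[round(t, 6)] = y.copy()

        for i, tg in enumerate(grid):
            ref = out[round(tg, 6)]
            got = traj.states[i]
            scale = np.abs(ref).max()
            assert np.abs(got - ref).max() <= 5e-3 * scale
            for region in ("kidneys", "liver", "whole_body"):
                idx = np.asarray(median_model.regions[region])
                assert got[idx].sum() == pytest.approx(ref[idx].sum(), rel=5e-3)


class TestActivityReadout:
    def test_exact_at_grid_nodes(self, median_trajectory):
        series = median_trajectory.activity_series("kidneys", "ga68")
        i = np.searchsorted(median_trajectory.times, 63.0)
        t_node = median_trajectory.times[i]
        assert organ_activity(median_trajectory, "kidneys", t_node, "ga68") == pytest.approx(
            series[i], rel=1e-12
        )

    def test_unknown_region_raises(self, median_trajectory):
        with pytest.raises(KeyError):
            organ_activity(median_trajectory, "pancreas", 63.0)

    def test_interpolation_matches_exponential_closed_form(self, median_model):
        """Mono-exponential amounts: interpolated activity vs closed form."""
        half_life = 9563.0
        lam_bio = 1.0 / 2000.0
        dosing = DosingSchedule(events=[DoseEvent(0.0, 0.0, 1.0, 0.0, "lu177")])
        times = np.linspace(0.0, 20000.0, 201)
        states = np.zeros((len(times), N_BASE))
        states[:, LAYOUT[("kidneys", "bound")]] = np.exp(-lam_bio * times)
        traj = Trajectory(times=times, states=states, model=median_model, dosing=dosing)
        nuc = median_model.constants.nuclides["lu177"]
        for t in (150.0, 1234.5, 9999.9):
            expected = math.exp(-lam_bio * t) * nuc.mbq_per_nmol * math.exp(
                -nuc.decay_constant_per_min * t
            )
            assert traj.activity_at("kidneys", t, "lu177") == pytest.approx(expected, rel=1e-3)


class TestModelInvariants:
    def test_receptor_occupancy_bounded_by_capacity(self, median_trajectory, median_model):
        n_species = len(median_trajectory.dosing.events)
        for organ in BINDING_ORGANS:
            cap = median_model.receptor_capacity_nmol[organ]
            idx = [LAYOUT[(organ, "bound")] + N_BASE * s for s in range(n_species)]
            bound_total = median_trajectory.states[:, idx].sum(axis=1)
            assert bound_total.max() <= cap * (1 + 1e-6) + 1e-9

    def test_washout_monotone_without_receptors(self, median_physiology, constants):
        tiny = {k: (1e-9 if k.startswith("rd_") else v) for k, v in DEFAULT_PARAMETERS.items()}
        model = build_model(median_physiology, constants, FitParameters.from_dict(tiny))
        dosing = DosingSchedule(events=[DoseEvent(0.0, 0.0, 1.7e-3, 13.0, "ga68")])
        grid = np.linspace(5.0, 3000.0, 40)
        traj = simulate(model, dosing, t_end=3000.0, grid=grid)
        body = traj.species_amount_series("whole_body", 0)
        assert np.all(np.diff(body) <= 1e-9)

    def test_saturation_ordering_between_amounts(self, median_model):
        """Fractional specific uptake falls with the administered amount."""

        def specific_fraction(total_nmol):
            dosing = DosingSchedule(events=[DoseEvent(0.0, 0.0, 0.01, total_nmol - 0.01, "ga68")])
            traj = simulate(median_model, dosing, t_end=63.0, grid=np.array([63.0]))
            out = {}
            for organ in BINDING_ORGANS:
                idx = [LAYOUT[(organ, c)] for c in ("bound", "endosomal", "lysosomal")]
                out[organ] = traj.states[0, idx].sum() / total_nmol
            return out

        diag = specific_fraction(14.9)
        ther = specific_fraction(134.0)
        for organ in BINDING_ORGANS:
            assert ther[organ] <= diag[organ] * (1 + 1e-9)

    def test_decay_constant_only_scales_readout(self, median_physiology, median_dosing):
        """Amounts are decay-independent; activity scales by the decay factor."""
        slow = LiteratureConstants()
        slow.nuclides["ga68"] = NuclideConstants(half_life_min=2 * 67.71)
        m_ref = build_model(median_physiology, DEFAULT_CONSTANTS, FitParameters.default())
        m_slow = build_model(median_physiology, slow, FitParameters.default())
        grid = np.array([30.0, 63.0])
        t_ref = simulate(m_ref, median_dosing, t_end=63.0, grid=grid)
        t_slow = simulate(m_slow, median_dosing, t_end=63.0, grid=grid)
        assert np.allclose(t_ref.states, t_slow.states, rtol=1e-9, atol=1e-12)
        lam_ref = DEFAULT_CONSTANTS.nuclides["ga68"].decay_constant_per_min
        lam_slow = slow.nuclides["ga68"].decay_constant_per_min
        for t in grid:
            a_ref = t_ref.activity_at("kidneys", t, "ga68")
            a_slow = t_slow.activity_at("kidneys", t, "ga68")
            # per-nmol activity scales with lambda; residual decay with exp(-dl t)
            expected = a_ref * (lam_slow / lam_ref) * math.exp((lam_ref - lam_slow) * t)
            assert a_slow == pytest.approx(expected, rel=1e-9)


def test_administered_activity_consistent_with_labelled_amount(constants, median_dosing):
    ther = median_dosing.event_for_nuclide("lu177")
    assert ther.administered_activity_mbq(constants) == pytest.approx(7480.0, rel=0.01)
    diag = median_dosing.event_for_nuclide("ga68")
    assert diag.administered_activity_mbq(constants) == pytest.approx(175.0, rel=0.02)
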