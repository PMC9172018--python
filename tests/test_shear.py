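"""Reduced-order saccadic shear: closed-form rotor relaxation, scaling
properties of the stress model and the qualitative regional orderings."""

import numpy as np
import pandas as pd
import pytest

from tamponade.fluids import FluidProperties
from tamponade.geometry import Variant
from tamponade.kinematics import SaccadeTrajectory, fit_saccade, sample_trajectory
from tamponade.pipeline import SweepConfig, saccade_shear_analysis
from tamponade.shear import (ShearOptions, geometry_factors,
                             relax_fluid_rotation, shear_summary,
                             wall_shear_field)


def _const_omega_traj(omega=300.0, dt=1e-3, t_end=0.3):
    t = np.arange(0.0, t_end, dt)
    return SaccadeTrajectory(t, np.cumsum(np.full_like(t, omega * dt)),
                             np.full_like(t, omega), np.zeros_like(t))


class TestRelaxFluidRotation:
    def test_rest_input_stays_at_rest(self, fluids):
        t = np.arange(0.0, 0.2, 1e-3)
        traj = SaccadeTrajectory(t, np.zeros_like(t), np.zeros_like(t),
                                 np.zeros_like(t))
        om = relax_fluid_rotation(traj, fluids, 12.0)
        assert np.all(om["sio"] == 0.0)
        assert np.all(om["aqueous"] == 0.0)

    def test_step_response_closed_form(self, fluids):
        opts = ShearOptions()
        traj = _const_omega_traj()
        om = relax_fluid_rotation(traj, fluids, 12.0, opts)
        tau_r = (12e-3) ** 2 / (opts.relaxation_constant
                                * fluids.kinematic_viscosity_sio)
        expected = 300.0 * (1.0 - np.exp(-traj.t / tau_r))
        assert np.allclose(om["sio"], expected, atol=0.02 * 300.0)

    def test_oil_relaxes_far_faster_than_aqueous(self, fluids):
        # relaxation time ratio equals the kinematic viscosity ratio (> 100)
        ratio = (fluids.kinematic_viscosity_sio
                 / fluids.kinematic_viscosity_aqueous)
        assert ratio >= 100.0
        traj = _const_omega_traj(t_end=0.1)
        om = relax_fluid_rotation(traj, fluids, 12.0)
        assert om["sio"][-1] > 100.0 * om["aqueous"][-1]


class TestWallShearField:
    def test_geometry_factor_unity_on_emmetropic(self, labelled_variants):
        mesh, _ = labelled_variants[Variant.EMMETROPIC]
        pocket, ridge = geometry_factors(mesh)
        assert np.all(pocket == 0.0)
        assert np.all(ridge == 0.0)

    def test_pocket_and_ridge_localised(self, labelled_variants, params):
        mesh, _ = labelled_variants[Variant.STAPHYLOMA_CERCLAGE]
        pocket, ridge = geometry_factors(mesh)
        psi = mesh.face_psi_deg
        assert ridge[psi < 60].max() < 1e-3   # Gaussian tail only
        assert ridge.max() == pytest.approx(params.cerclage_depth, rel=0.05)
        # the staphyloma pouch is a recess; the band shadow extends it anteriorly
        assert pocket[psi > 170].max() == pytest.approx(
            params.staphyloma_depth, rel=0.05)

    def test_stress_proportional_to_viscosity(self, labelled_variants,
                                              fluids):
        mesh, rmap = labelled_variants[Variant.EMMETROPIC]
        traj = sample_trajectory(fit_saccade())
        zeros = {"sio": np.zeros_like(traj.t), "aqueous": np.zeros_like(traj.t)}
        wet = np.ones(len(mesh.faces), bool)
        tau1 = wall_shear_field(mesh, rmap, wet, traj, zeros, fluids)
        doubled = FluidProperties(viscosity_sio=2 * fluids.viscosity_sio,
                                  density_sio=2 * fluids.density_sio,
                                  density_aqueous=2 * fluids.density_aqueous)
        tau2 = wall_shear_field(mesh, rmap, wet, traj, zeros, doubled)
        assert np.allclose(tau2, 2.0 * tau1, rtol=1e-9)

    def test_stress_proportional_to_axis_distance(self, labelled_variants,
                                                  fluids):
        # tau ~ r_perp within one phase; faces near the axis carry ~no stress
        mesh, rmap = labelled_variants[Variant.EMMETROPIC]
        traj = sample_trajectory(fit_saccade())
        zeros = {"sio": np.zeros_like(traj.t), "aqueous": np.zeros_like(traj.t)}
        wet = np.ones(len(mesh.faces), bool)
        tau = wall_shear_field(mesh, rmap, wet, traj, zeros, fluids)
        cent = mesh.face_centroids
        r = np.hypot(cent[:, 0], cent[:, 2])
        k = 50  # sample instant mid-saccade
        ratio = tau[k] / r
        assert np.ptp(ratio) < 1e-9 * ratio.max()

    def test_zero_omega_means_zero_stress(self, labelled_variants, fluids):
        mesh, rmap = labelled_variants[Variant.STAPHYLOMA_CERCLAGE]
        t = np.arange(0.0, 0.2, 1e-3)
        traj = SaccadeTrajectory(t, np.zeros_like(t), np.zeros_like(t),
                                 np.zeros_like(t))
        om = relax_fluid_rotation(traj, fluids, 12.0)
        wet = np.ones(len(mesh.faces), bool)
        tau = wall_shear_field(mesh, rmap, wet, traj, om, fluids)
        assert np.all(tau == 0.0)


@pytest.fixture(scope="module")
def summaries(params, fluids):
    cfg = SweepConfig(geometry=params, fluids=fluids, resolution=48)
    return {v: saccade_shear_analysis(cfg, v)
            for v in ("emmetropic", "staphyloma", "staphyloma_cerclage")}


class TestShearSummary:
    def test_aggregate_consistent_with_instantaneous(self, summaries):
        s = summaries["emmetropic"]
        for _, row in s.aggregate.iterrows():
            inst = s.instantaneous[
                (s.instantaneous.region == row.region)
                & (s.instantaneous.hemifield == row.hemifield)
                & (s.instantaneous.phase == row.phase)]
            assert row.tau_max_pa == pytest.approx(inst.tau_max_pa.max())
            assert row.tau_max_pa >= inst.tau_max_pa.max() - 1e-12

    def test_band_hosts_global_maximum(self, summaries):
        agg = summaries["staphyloma_cerclage"].aggregate
        peak = agg.loc[agg.tau_max_pa.idxmax()]
        assert peak.region == "cerclage_band"

    def test_staphyloma_shelters_macula(self, summaries):
        def macula_avg(s):
            rows = s.aggregate[s.aggregate.region == "macula"]
            w = rows.tau_time_avg_pa
            return float(w.max())
        assert macula_avg(summaries["staphyloma"]) < macula_avg(
            summaries["emmetropic"])

    def test_band_lowers_pre_equatorial_stress(self, summaries):
        # compared on the superior hemifield, which is fully oil-wetted in
        # both variants (standing, 90 % fill), so the wetted masks agree
        def pre_eq(s):
            rows = s.aggregate[(s.aggregate.region == "pre_equatorial")
                               & (s.aggregate.phase == "sio")
                               & (s.aggregate.hemifield == "superior")]
            return float(rows.tau_time_avg_pa.max())
        assert pre_eq(summaries["staphyloma_cerclage"]) < pre_eq(
            summaries["staphyloma"])

    def test_phases_partition_regions(self, summaries):
        agg = summaries["emmetropic"].aggregate
        assert set(agg.phase) <= {"sio", "aqueous"}
        # a (region, hemifield) wetted by both phases may appear twice, but
        # never twice within one phase
        dup = agg.duplicated(["region", "hemifield", "phase"])
        assert not dup.any()
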