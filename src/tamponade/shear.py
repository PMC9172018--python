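"""Reduced-order wall shear stress during a saccade.

This is an explicit surrogate for the full unsteady two-phase flow: it keeps
the scaling drivers of retinal shear — fluid viscosity, wall slip velocity,
distance from the rotation axis, an unsteady (Stokes) boundary-layer depth —
and the geometric mechanisms of the chamber variants (a concave recess
shelters the wall, a protruding ridge is exposed).  It is intended for
*orderings* between regions and geometries, never for absolute stress values.

Model, per wall face and time sample:

    tau(t) = mu_phase * |omega(t) - Omega_phase(t)| * r_perp / delta(t) * f_geo

* each fluid phase lags the wall as a rigid rotor with relaxation time
  ``tau_r = R^2 / (k nu)`` (k a calibration constant, default 10);
* ``delta(t) = min(sqrt(nu * max(t, t_min)), R)`` is the developing
  boundary-layer depth;
* ``f_geo = exp(-d_pocket / delta) * (1 + p_ridge / delta)`` with
  ``d_pocket`` the face's recess depth (its outward displacement in the
  staphyloma pouch, plus the shadow cast by a nearby taller ridge) and
  ``p_ridge`` its protrusion into the fluid (the cerclage indent).

The saccade rotates about the vertical ``+y`` axis (horizontal saccade);
``r_perp`` is the face-centroid distance from that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluids import FluidProperties
from .geometry import TriMeshSurface
from .kinematics import SaccadeTrajectory
from .segmentation import RegionMap

MM_TO_M = 1e-3
DEG_TO_RAD = np.pi / 180.0


@dataclass(frozen=True)
class ShearOptions:
    relaxation_constant: float = 10.0   # k in tau_r = R^2 / (k nu)
    t_min_s: float = 1e-3               # floor for the boundary-layer clock
    shelter_length_mm: float = 4.0      # decay length of a ridge's shadow


@dataclass
class ShearSummary:
    """Instantaneous and time-aggregated per-region shear statistics."""

    instantaneous: pd.DataFrame  # time, region, hemifield, phase, tau_max, tau_avg
    aggregate: pd.DataFrame      # region, hemifield, phase, tau_max, tau_time_avg


def relax_fluid_rotation(traj: SaccadeTrajectory, fluids: FluidProperties,
                         radius_mm: float,
                         opts: ShearOptions = ShearOptions(),
                         ) -> dict[str, np.ndarray]:
    """Bulk fluid angular velocity Omega(t) (deg/s) for each phase.

    Solves d(Omega)/dt = (omega - Omega) / tau_r with Omega(0) = 0 by the
    exact exponential step on the <= 1 ms sampling grid.
    """
    R_m = radius_mm * MM_TO_M
    out: dict[str, np.ndarray] = {}
    for phase, nu in (("sio", fluids.kinematic_viscosity_sio),
                      ("aqueous", fluids.kinematic_viscosity_aqueous)):
        tau_r = R_m ** 2 / (opts.relaxation_constant * nu)
        omega = traj.omega_deg_s
        Om = np.zeros_like(omega)
        decay = np.exp(-np.diff(traj.t) / tau_r)
        for i in range(1, len(omega)):
            Om[i] = omega[i - 1] + (Om[i - 1] - omega[i - 1]) * decay[i - 1]
        out[phase] = Om
    return out


def geometry_factors(mesh: TriMeshSurface,
                     opts: ShearOptions = ShearOptions(),
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-face recess depth ``d_pocket`` and protrusion ``p_ridge`` (mm).

    Both derive from the recorded radial deformation: outward displacement
    (staphyloma) is a recess of the wall, inward displacement (cerclage) a
    ridge.  A ridge also shadows its meridional neighbourhood: a face lying
    within the decay length of a taller ridge is sheltered by the height
    difference.
    """
    disp = mesh.radial_disp[mesh.faces].mean(axis=1)
    pocket = np.maximum(disp, 0.0)
    ridge = np.maximum(-disp, 0.0)

    # meridional arc coordinate (mm) from the equator, on the reference sphere
    radius = np.linalg.norm(mesh.vertices, axis=1)[mesh.faces].mean(axis=1)
    arc = (np.radians(mesh.face_psi_deg) - np.pi / 2.0)
    arc = arc * np.median(radius[ridge == 0] if (ridge == 0).any() else radius)

    lam = opts.shelter_length_mm
    if ridge.max() > 0 and lam > 0:
        # binned meridional ridge profile -> shadow cast on neighbours
        nbin = 256
        lo, hi = arc.min(), arc.max()
        centers = np.linspace(lo, hi, nbin)
        prof = np.zeros(nbin)
        idx = np.clip(((arc - lo) / (hi - lo) * (nbin - 1)).astype(int), 0, nbin - 1)
        np.maximum.at(prof, idx, ridge)
        shadow_bins = (prof[None, :] *
                       np.exp(-np.abs(centers[:, None] - centers[None, :]) / lam)
                       ).max(axis=1)
        shadow = np.interp(arc, centers, shadow_bins) - ridge
        pocket = pocket + np.maximum(shadow, 0.0)
    return pocket, ridge


def wall_shear_field(mesh: TriMeshSurface, rmap: RegionMap,
                     wetted: np.ndarray, traj: SaccadeTrajectory,
                     omega_fluid: dict[str, np.ndarray],
                     fluids: FluidProperties,
                     opts: ShearOptions = ShearOptions()) -> np.ndarray:
    """Shear stress tau (Pa) per (time sample, face).

    ``wetted`` flags the SiO-wetted faces (from the static equilibrium of
    the scenario under study); other faces see the aqueous phase.
    """
    if len(traj.t) < 2:
        raise ValueError("trajectory must be sampled")
    cent = mesh.face_centroids * MM_TO_M
    r_perp = np.hypot(cent[:, 0], cent[:, 2])
    d_pocket, p_ridge = geometry_factors(mesh, opts)
    d_pocket_m = d_pocket * MM_TO_M
    p_ridge_m = p_ridge * MM_TO_M
    R_m = float(np.linalg.norm(mesh.vertices, axis=1).max()) * MM_TO_M

    tau = np.zeros((len(traj.t), len(mesh.faces)))
    t_eff = np.maximum(traj.t, opts.t_min_s)
    for phase, mu, nu, mask in (
            ("sio", fluids.viscosity_sio, fluids.kinematic_viscosity_sio,
             np.asarray(wetted, bool)),
            ("aqueous", fluids.viscosity_aqueous,
             fluids.kinematic_viscosity_aqueous, ~np.asarray(wetted, bool))):
        if not mask.any():
            continue
        slip = np.abs(traj.omega_deg_s - omega_fluid[phase]) * DEG_TO_RAD
        delta = np.minimum(np.sqrt(nu * t_eff), R_m)
        f_geo = (np.exp(-d_pocket_m[mask][None, :] / delta[:, None])
                 * (1.0 + p_ridge_m[mask][None, :] / delta[:, None]))
        tau[:, mask] = (mu * slip[:, None] * r_perp[mask][None, :]
                        / delta[:, None] * f_geo)
    return tau


def shear_summary(tau: np.ndarray, mesh: TriMeshSurface, rmap: RegionMap,
                  wetted: np.ndarray, traj: SaccadeTrajectory) -> ShearSummary:
    """Per-(region, hemifield, phase) instantaneous max / area-averaged shear
    and their time aggregates."""
    wetted = np.asarray(wetted, bool)
    areas = mesh.face_areas
    phase = np.where(wetted, "sio", "aqueous")
    keys = pd.DataFrame({"region": rmap.face_region,
                         "hemifield": rmap.face_hemifield,
                         "phase": phase})
    groups = keys.groupby(["region", "hemifield", "phase"], sort=True).groups

    inst_rows = []
    agg_rows = []
    for (region, hemi, ph), faces in groups.items():
        f = np.asarray(faces)
        sub = tau[:, f]
        w = areas[f] / areas[f].sum()
        tmax = sub.max(axis=1)
        tavg = sub @ w
        inst_rows.append(pd.DataFrame({
            "time_s": traj.t, "region": region, "hemifield": hemi,
            "phase": ph, "tau_max_pa": tmax, "tau_avg_pa": tavg}))
        agg_rows.append({"region": region, "hemifield": hemi, "phase": ph,
                         "tau_max_pa": float(tmax.max()),
                         "tau_time_avg_pa": float(np.trapezoid(tavg, traj.t)
                                                  / (traj.t[-1] - traj.t[0]))})
    return ShearSummary(pd.concat(inst_rows, ignore_index=True),
                        pd.DataFrame(agg_rows))
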