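"""Sweep orchestration: contact tables over (variant, posture, fill) grids
and the saccadic shear scenario, with tidy CSV outputs.

The pipeline is deterministic: a config fully determines every output byte
(the solvers use fixed iteration orders and no randomness; the ``seed``
field is reserved for future stochastic components).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .equilibrium import (ContactReport, MinimizerOptions, contact_fractions,
                          minimize_capillary_energy, rotation_to_gravity_frame,
                          solve_flat_interface, voxelize_chamber)
from .fluids import FluidProperties, Posture
from .geometry import EyeGeometryParams, Variant, build_eye_surface
from .kinematics import fit_saccade, sample_trajectory
from .segmentation import RegionLabel, label_regions, region_areas
from .shear import (ShearOptions, ShearSummary, relax_fluid_rotation,
                    shear_summary, wall_shear_field)

log = logging.getLogger("tamponade")

DEFAULT_FILLS = (80.0, 85.0, 90.0, 95.0, 100.0)
DEFAULT_POSTURES = ("standing", "tilt45", "supine")
DEFAULT_VARIANTS = ("emmetropic", "staphyloma", "staphyloma_cerclage")


@dataclass
class SweepConfig:
    geometry: EyeGeometryParams = field(default_factory=EyeGeometryParams)
    fluids: FluidProperties = field(default_factory=FluidProperties)
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    postures: tuple[str, ...] = DEFAULT_POSTURES
    fills_pct: tuple[float, ...] = DEFAULT_FILLS
    resolution: int = 96
    minimizer: MinimizerOptions = field(default_factory=MinimizerOptions)
    solver: str = "capillary"        # "capillary" | "flat"
    output_dir: str | None = None
    seed: int | None = None          # reserved; current solvers are deterministic

    def __post_init__(self) -> None:
        if not self.variants or not self.postures:
            raise ValueError("need at least one variant and posture")
        if any(not 0.0 <= f <= 100.0 for f in self.fills_pct):
            raise ValueError("fills must lie in [0, 100] percent")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key, sub in (("geometry", EyeGeometryParams),
                         ("fluids", FluidProperties),
                         ("minimizer", MinimizerOptions)):
            if key in raw:
                params = raw.pop(key)
                if "kernel_anneal" in params:
                    params["kernel_anneal"] = tuple(params["kernel_anneal"])
                kw[key] = sub(**params)
        for key in ("variants", "postures", "fills_pct"):
            if key in raw:
                raw[key] = tuple(raw.pop(key))
        kw.update(raw)
        return cls(**kw)


def _report_rows(rep: ContactReport) -> pd.DataFrame:
    rows = rep.table.copy()
    rows = rows.rename(columns={"area_mm2": "area_mm2"})
    overall = pd.DataFrame([{
        "region": "overall", "hemifield": "both",
        "area_mm2": rows.loc[rows.region != RegionLabel.LENS.value,
                             "area_mm2"].sum(),
        "contact_pct": rep.overall_pct}])
    out = pd.concat([rows, overall], ignore_index=True)
    out.insert(0, "variant", rep.variant)
    out.insert(1, "posture", rep.posture)
    out.insert(2, "fill_pct", rep.fill_pct)
    out["method"] = rep.method
    out["resolution"] = rep.resolution
    out["iterations"] = rep.iterations
    out["converged"] = rep.converged
    return out


def run_case(mesh, rmap, config: SweepConfig, variant: str, posture: Posture,
             fill_pct: float, domain=None) -> ContactReport:
    """Solve a single (variant, posture, fill) case."""
    if config.solver == "flat":
        return solve_flat_interface(mesh, rmap, fill_pct / 100.0, posture,
                                    variant=variant)
    if domain is None:
        domain = voxelize_chamber(mesh, config.resolution,
                                  rotation=rotation_to_gravity_frame(posture))
    phase = minimize_capillary_energy(domain, config.fluids, fill_pct / 100.0,
                                      posture, config.minimizer)
    return contact_fractions(phase, mesh, rmap, variant=variant,
                             posture=posture.name, fill_pct=fill_pct)


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Contact reports for the full (variant x posture x fill) grid.

    Per-case failures are logged and recorded; the sweep continues and a
    ``RuntimeError`` summarising the failures is raised at the end.
    """
    frames: list[pd.DataFrame] = []
    failures: list[str] = []
    for vname in config.variants:
        variant = Variant(vname)
        mesh = build_eye_surface(config.geometry, variant)
        rmap = label_regions(mesh, config.geometry, variant)
        for pname in config.postures:
            posture = Posture.from_name(pname)
            domain = None
            if config.solver == "capillary":
                domain = voxelize_chamber(
                    mesh, config.resolution,
                    rotation=rotation_to_gravity_frame(posture))
            for fill in config.fills_pct:
                label = f"{vname}/{pname}/{fill:g}%"
                try:
                    rep = run_case(mesh, rmap, config, vname, posture, fill,
                                   domain)
                except Exception as exc:  # noqa: BLE001 - sweep must go on
                    log.error("case %s failed: %s", label, exc)
                    failures.append(label)
                    continue
                log.info("case %s: overall contact %.1f%% (%d sweeps, %s)",
                         label, rep.overall_pct, rep.iterations,
                         "converged" if rep.converged else "NOT converged")
                frames.append(_report_rows(rep))
    result = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame())
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_csv(result, outdir / "contact_sweep.csv")
    if failures:
        raise RuntimeError(f"{len(failures)} case(s) failed: {failures}")
    return result


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV output (fixed float formatting)."""
    df.to_csv(path, index=False, float_format="%.6f")


def summarize_figures(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot tables mirroring the published figure panels.

    * ``overall_vs_fill`` — overall contact per posture panel, one curve per
      geometry over the fill grid.
    * ``quadrants_vs_fill`` — superior/inferior pre-/post-equatorial contact.
    * ``regional_at_90`` — per-region bars at the representative 90 % fill.
    """
    out: dict[str, pd.DataFrame] = {}
    overall = results[results.region == "overall"]
    out["overall_vs_fill"] = overall.pivot_table(
        index="fill_pct", columns=["posture", "variant"],
        values="contact_pct", observed=True)
    quad = results[results.region.isin(["pre_equatorial", "post_equatorial"])]
    out["quadrants_vs_fill"] = quad.pivot_table(
        index="fill_pct", columns=["posture", "region", "hemifield", "variant"],
        values="contact_pct", observed=True)
    at90 = results[np.isclose(results.fill_pct, 90.0)
                   & (results.region != "overall")]
    out["regional_at_90"] = at90.pivot_table(
        index=["region", "hemifield"], columns=["posture", "variant"],
        values="contact_pct", observed=True)
    for name, df in out.items():
        if df.isna().any().any():
            log.warning("summary table %s has missing cells", name)
    return out


# ---------------------------------------------------------------------------
# saccadic shear scenario
# ---------------------------------------------------------------------------

def saccade_shear_analysis(config: SweepConfig, variant: str,
                           fill_pct: float = 90.0,
                           posture_name: str = "standing",
                           shear_opts: ShearOptions = ShearOptions(),
                           ) -> ShearSummary:
    """Shear summary for the saccade scenario (default: standing, 90 % fill).

    The SiO-wetted mask is taken from the static equilibrium of the scenario,
    the saccade is the amplitude-exact 50-degree / 0.137 s wave.
    """
    var = Variant(variant)
    mesh = build_eye_surface(config.geometry, var)
    rmap = label_regions(mesh, config.geometry, var)
    posture = Posture.from_name(posture_name)
    rep_domain = voxelize_chamber(mesh, config.resolution,
                                  rotation=rotation_to_gravity_frame(posture))
    phase = minimize_capillary_energy(rep_domain, config.fluids,
                                      fill_pct / 100.0, posture,
                                      config.minimizer)
    from .equilibrium import wetted_faces
    wetted = wetted_faces(phase, mesh)

    params = fit_saccade()
    traj = sample_trajectory(params)
    radius_mm = config.geometry.sphere_radius
    omega_fluid = relax_fluid_rotation(traj, config.fluids, radius_mm,
                                       shear_opts)
    tau = wall_shear_field(mesh, rmap, wetted, traj, omega_fluid,
                           config.fluids, shear_opts)
    return shear_summary(tau, mesh, rmap, wetted, traj)
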