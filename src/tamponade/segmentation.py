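"""Retinal-surface partition of the chamber wall.

Regions follow the standard clinical scheme: lens (planar cap), pars plana,
pre-equatorial retina, post-equatorial retina and macula, the last read as a
20-degree polar cone about the posterior pole.  In the cerclage variant the
faces carrying more than half of the maximum band indent are relabelled as
the band.  Each region is split into superior / inferior hemifields by the
sign of the face-centroid ``y`` (ties count as superior).

Labels are assigned on the pre-deformation polar angle ``psi``, so the same
face has the same label in all three variants (cerclage relabelling aside).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (EyeGeometryParams, TriMeshSurface, Variant,
                       cerclage_displacement)


class RegionLabel(str, enum.Enum):
    LENS = "lens"
    PARS_PLANA = "pars_plana"
    PRE_EQUATORIAL = "pre_equatorial"
    POST_EQUATORIAL = "post_equatorial"
    MACULA = "macula"
    CERCLAGE_BAND = "cerclage_band"


class Hemifield(str, enum.Enum):
    SUPERIOR = "superior"
    INFERIOR = "inferior"


#: polar-angle boundaries (deg from the anterior pole); all configurable
DEFAULT_BOUNDARIES = {
    "pars_plana_posterior": 60.0,   # pars plana: lens rim -> 60 deg
    "equator": 90.0,                # pre-/post-equatorial split
    "macula_extent": 20.0,          # polar cone half-angle about the posterior pole
}


@dataclass
class RegionMap:
    """Per-face region and hemifield labels with area bookkeeping."""

    face_region: np.ndarray      # array of str (RegionLabel values)
    face_hemifield: np.ndarray   # array of str (Hemifield values)
    face_areas: np.ndarray       # mm^2

    def __post_init__(self) -> None:
        if len(self.face_region) != len(self.face_areas):
            raise ValueError("label/area length mismatch")

    @property
    def retina_mask(self) -> np.ndarray:
        """Faces counted in the retinal-surface denominator (everything but lens)."""
        return self.face_region != RegionLabel.LENS.value

    @property
    def retina_area(self) -> float:
        return float(self.face_areas[self.retina_mask].sum())

    def region_area(self, region: RegionLabel | str) -> float:
        region = RegionLabel(region).value
        return float(self.face_areas[self.face_region == region].sum())


def label_regions(mesh: TriMeshSurface, params: EyeGeometryParams,
                  variant: Variant = Variant.EMMETROPIC,
                  boundaries: dict | None = None) -> RegionMap:
    """Assign one region and one hemifield to every face."""
    variant = Variant(variant)
    b = dict(DEFAULT_BOUNDARIES)
    if boundaries:
        b.update(boundaries)
    psi = mesh.face_psi_deg
    macula_onset = 180.0 - b["macula_extent"]

    region = np.empty(len(mesh.faces), dtype=object)
    region[mesh.is_cap] = RegionLabel.LENS.value
    wall = ~mesh.is_cap
    region[wall & (psi < b["pars_plana_posterior"])] = RegionLabel.PARS_PLANA.value
    region[wall & (psi >= b["pars_plana_posterior"])
           & (psi < b["equator"])] = RegionLabel.PRE_EQUATORIAL.value
    region[wall & (psi >= b["equator"])
           & (psi < macula_onset)] = RegionLabel.POST_EQUATORIAL.value
    region[wall & (psi >= macula_onset)] = RegionLabel.MACULA.value

    if variant is Variant.STAPHYLOMA_CERCLAGE:
        indent = cerclage_displacement(psi, params)
        band = wall & (indent > 0.5 * params.cerclage_depth)
        region[band] = RegionLabel.CERCLAGE_BAND.value

    if any(r is None for r in region):
        raise RuntimeError("unlabeled face")

    hemi = np.where(mesh.face_centroids[:, 1] >= 0.0,
                    Hemifield.SUPERIOR.value, Hemifield.INFERIOR.value)
    return RegionMap(region.astype(str), hemi.astype(str), mesh.face_areas)


def region_areas(rmap: RegionMap) -> pd.DataFrame:
    """Tidy (region, hemifield) area table.

    ``share_pct`` is the share of the retinal surface — the denominator
    excludes the lens, whose rows carry NaN shares.
    """
    df = pd.DataFrame({
        "region": rmap.face_region,
        "hemifield": rmap.face_hemifield,
        "area_mm2": rmap.face_areas,
    })
    out = (df.groupby(["region", "hemifield"], sort=True)["area_mm2"]
             .sum().reset_index())
    retina = out.loc[out.region != RegionLabel.LENS.value, "area_mm2"].sum()
    out["share_pct"] = np.where(out.region == RegionLabel.LENS.value, np.nan,
                                100.0 * out.area_mm2 / retina)
    return out
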