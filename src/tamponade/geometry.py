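"""Parametric vitreous-chamber geometry.

The chamber is modelled as a 24 mm sphere truncated anteriorly by the planar
lens indentation, with two optional axisymmetric deformations:

* a posterior **staphyloma** (high-myopia outpouching) — a smooth radial
  bulge of the posterior wall, and
* an encircling **cerclage band** — a Gaussian equatorial indentation
  mimicking a 360-degree scleral buckle.

Coordinates: origin at the undeformed sphere centre, ``+z`` anterior along the
optical axis, ``+y`` anatomical superior.  Every vertex carries the polar
angle ``psi`` (degrees from the anterior pole) it had on the *undeformed*
sphere; both deformations are purely radial, so ``psi`` identifies material
points across all three variants and region labels are deformation-invariant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh


class Variant(str, enum.Enum):
    """The three chamber morphologies."""

    EMMETROPIC = "emmetropic"
    STAPHYLOMA = "staphyloma"
    STAPHYLOMA_CERCLAGE = "staphyloma_cerclage"


@dataclass(frozen=True)
class EyeGeometryParams:
    """Construction parameters (all lengths in mm).

    Defaults: 24 mm globe, 3 mm lens vault, a 3.5 mm deep staphyloma starting
    at psi = 140 deg, and a 1.5 mm deep / 4 mm wide band indent (typical
    240-style encircling band).  The clinical literature gives no canonical
    values for the deformation sizes; these are configurable.
    """

    sphere_radius: float = 12.0
    lens_cap_height: float = 3.0
    staphyloma_depth: float = 3.5
    staphyloma_onset_angle: float = 140.0
    cerclage_depth: float = 1.5
    cerclage_width: float = 4.0
    mesh_subdivision: int = 5

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if not 0 <= self.lens_cap_height < self.sphere_radius:
            raise ValueError("lens_cap_height must lie in [0, sphere_radius)")
        for name in ("staphyloma_depth", "cerclage_depth", "cerclage_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 90.0 < self.staphyloma_onset_angle < 180.0:
            raise ValueError("staphyloma_onset_angle must be in (90, 180) deg")
        if self.mesh_subdivision < 1:
            raise ValueError("mesh_subdivision must be >= 1")
        # band must sit fully anterior to the staphyloma onset: 3 sigma of the
        # Gaussian indent, measured as polar angle from the equator
        sigma_deg = np.degrees(
            (self.cerclage_width / 2.0) / self.sphere_radius)
        if 90.0 + 3.0 * sigma_deg >= self.staphyloma_onset_angle:
            raise ValueError("cerclage band overlaps the staphyloma onset")

    @property
    def lens_plane_z(self) -> float:
        return self.sphere_radius - self.lens_cap_height

    @property
    def lens_rim_angle(self) -> float:
        """Polar angle (deg) of the lens-plane rim on the sphere."""
        return float(np.degrees(np.arccos(self.lens_plane_z / self.sphere_radius)))


@dataclass
class TriMeshSurface:
    """Closed triangulated chamber wall.

    ``psi_deg`` is the per-vertex polar angle recorded on the undeformed
    sphere (cap vertices get the polar angle of their planar position);
    ``radial_disp`` is the accumulated signed radial displacement applied by
    the deformations (positive outward), zero for the emmetropic variant.
    ``is_cap`` flags the faces of the planar lens cap.
    """

    vertices: np.ndarray
    faces: np.ndarray
    psi_deg: np.ndarray
    radial_disp: np.ndarray
    is_cap: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    # -- derived quantities -------------------------------------------------
    def _tri(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    @property
    def face_cross(self) -> np.ndarray:
        a, b, c = self._tri()
        return np.cross(b - a, c - a)

    @property
    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross, axis=1)

    @property
    def face_normals(self) -> np.ndarray:
        cr = self.face_cross
        return cr / np.linalg.norm(cr, axis=1, keepdims=True)

    @property
    def face_centroids(self) -> np.ndarray:
        a, b, c = self._tri()
        return (a + b + c) / 3.0

    @property
    def face_psi_deg(self) -> np.ndarray:
        return self.psi_deg[self.faces].mean(axis=1)

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    def copy(self) -> "TriMeshSurface":
        return TriMeshSurface(self.vertices.copy(), self.faces.copy(),
                              self.psi_deg.copy(), self.radial_disp.copy(),
                              self.is_cap.copy())

    def validate(self) -> None:
        """Hard-fail unless the mesh is watertight, outward and degenerate-free."""
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise ValueError("mesh is not watertight")
        if not tm.is_winding_consistent:
            raise ValueError("mesh winding is inconsistent")
        if tm.volume <= 0:
            raise ValueError("mesh normals are not outward (signed volume <= 0)")
        if np.any(self.face_areas <= 0):
            raise ValueError("mesh contains degenerate faces")

    def export(self, path: str) -> None:
        """Export as STL or OBJ (by extension)."""
        self.as_trimesh().export(path)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _resolution(subdivision: int) -> tuple[int, int]:
    """Number of polar bands / azimuthal segments for a refinement level."""
    n_psi = 5 * 2 ** max(subdivision - 2, 0)
    n_az = int(round(2.6 * n_psi))
    n_az += n_az % 2  # even, so the mesh is symmetric under y -> -y
    return n_psi, n_az


def _truncated_sphere(params: EyeGeometryParams) -> TriMeshSurface:
    """Structured triangulation: spherical wall below the lens plane plus a
    planar cap, sharing the rim ring (hence watertight by construction)."""
    R = params.sphere_radius
    z_cap = params.lens_plane_z
    psi0 = np.radians(params.lens_rim_angle)
    n_psi, n_az = _resolution(params.mesh_subdivision)

    phi = 2.0 * np.pi * np.arange(n_az) / n_az
    cphi, sphi = np.cos(phi), np.sin(phi)

    verts: list[np.ndarray] = []
    psis: list[np.ndarray] = []

    # wall rings from the rim (psi0) towards the posterior pole (pi);
    # snap rings onto the segmentation boundaries (region edges and the
    # band-relabel edges) so no face straddles a label boundary
    uniform = psi0 + (np.pi - psi0) * np.arange(n_psi + 1) / n_psi
    snap = _snap_angles(params)
    keep = np.all(np.abs(uniform[:, None] - snap[None, :])
                  > 0.35 * (np.pi - psi0) / n_psi, axis=1)
    keep[0] = keep[-1] = True
    psi_rings = np.unique(np.concatenate([uniform[keep], snap]))
    psi_rings = psi_rings[(psi_rings >= psi0 - 1e-12)
                          & (psi_rings < np.pi - 1e-9)]
    n_psi = len(psi_rings)
    for psi in psi_rings:
        r = R * np.sin(psi)
        ring = np.column_stack([r * cphi, r * sphi,
                                np.full(n_az, R * np.cos(psi))])
        verts.append(ring)
        psis.append(np.full(n_az, np.degrees(psi)))
    pole_idx = n_psi * n_az
    verts.append(np.array([[0.0, 0.0, -R]]))
    psis.append(np.array([180.0]))

    # cap rings shrink from the rim towards the centre; radial spacing chosen
    # to roughly match the wall band width
    rim_r = R * np.sin(psi0)
    band = R * (np.pi - psi0) / n_psi
    n_cap = max(int(np.ceil(rim_r / band)), 1)
    cap_start = pole_idx + 1
    for j in range(1, n_cap):
        r = rim_r * (1.0 - j / n_cap)
        ring = np.column_stack([r * cphi, r * sphi, np.full(n_az, z_cap)])
        verts.append(ring)
        psis.append(np.degrees(np.arctan2(r, z_cap)) * np.ones(n_az))
    centre_idx = cap_start + (n_cap - 1) * n_az
    verts.append(np.array([[0.0, 0.0, z_cap]]))
    psis.append(np.array([0.0 if z_cap > 0 else 180.0]))

    vertices = np.vstack(verts)
    psi_deg = np.concatenate(psis)

    faces: list[tuple[int, int, int]] = []
    is_cap: list[bool] = []

    def ring_index(base: int, k: int) -> int:
        return base + (k % n_az)

    # wall quads; winding chosen so normals point outward (away from origin)
    for i in range(n_psi - 1):
        a, b = i * n_az, (i + 1) * n_az
        for k in range(n_az):
            a0, a1 = ring_index(a, k), ring_index(a, k + 1)
            b0, b1 = ring_index(b, k), ring_index(b, k + 1)
            faces.append((a0, b0, a1))
            faces.append((a1, b0, b1))
            is_cap += [False, False]
    # posterior pole fan
    a = (n_psi - 1) * n_az
    for k in range(n_az):
        faces.append((ring_index(a, k), pole_idx, ring_index(a, k + 1)))
        is_cap.append(False)

    # cap: rim ring (wall ring 0) -> cap rings -> centre; outward normal is +z
    cap_rings = [0] + [cap_start + (j - 1) * n_az for j in range(1, n_cap)]
    for i in range(len(cap_rings) - 1):
        a, b = cap_rings[i], cap_rings[i + 1]
        for k in range(n_az):
            a0, a1 = ring_index(a, k), ring_index(a, k + 1)
            b0, b1 = ring_index(b, k), ring_index(b, k + 1)
            faces.append((a0, a1, b0))
            faces.append((a1, b1, b0))
            is_cap += [True, True]
    a = cap_rings[-1]
    for k in range(n_az):
        faces.append((ring_index(a, k), ring_index(a, k + 1), centre_idx))
        is_cap.append(True)

    mesh = TriMeshSurface(vertices, np.array(faces, dtype=np.int64), psi_deg,
                          np.zeros(len(vertices)), np.array(is_cap))
    mesh.validate()
    return mesh


def _snap_angles(params: EyeGeometryParams) -> np.ndarray:
    """Polar angles (rad) the wall rings must hit exactly: the standard
    region boundaries and the cerclage relabel edges (half-maximum indent)."""
    angles = [60.0, 90.0, 160.0]
    half_width = np.degrees(
        (params.cerclage_width / 2.0) * np.sqrt(np.log(2.0))
        / params.sphere_radius)
    angles += [90.0 - half_width, 90.0 + half_width]
    out = np.radians(sorted(set(angles)))
    lo = np.radians(params.lens_rim_angle)
    return out[(out > lo + 1e-9) & (out < np.pi - 1e-9)]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def apply_staphyloma(mesh: TriMeshSurface,
                     params: EyeGeometryParams) -> TriMeshSurface:
    """Radially bulge the posterior wall outward.

    Displacement ``d(psi) = depth * smoothstep((psi - onset)/(180 - onset))``
    gives a C1 junction at the onset angle and exactly ``depth`` at the
    posterior pole.
    """
    out = mesh.copy()
    onset = params.staphyloma_onset_angle
    u = (out.psi_deg - onset) / (180.0 - onset)
    d = params.staphyloma_depth * _smoothstep(u)
    rad = np.linalg.norm(out.vertices, axis=1)
    scale = np.where(rad > 0, (rad + d) / np.where(rad > 0, rad, 1.0), 1.0)
    out.vertices = out.vertices * scale[:, None]
    out.radial_disp = out.radial_disp + d
    out.validate()
    return out


def cerclage_displacement(psi_deg: np.ndarray,
                          params: EyeGeometryParams) -> np.ndarray:
    """Inward band indent depth (mm) at polar angle ``psi`` (deg).

    Gaussian in the meridional arc distance from the equator, with
    ``sigma = cerclage_width / 2``.
    """
    arc = params.sphere_radius * np.abs(np.radians(psi_deg) - np.pi / 2.0)
    sigma = params.cerclage_width / 2.0
    return params.cerclage_depth * np.exp(-((arc / sigma) ** 2))


def apply_cerclage(mesh: TriMeshSurface,
                   params: EyeGeometryParams) -> TriMeshSurface:
    """Indent the equatorial band radially inward (rotationally symmetric)."""
    out = mesh.copy()
    d = cerclage_displacement(out.psi_deg, params)
    rad = np.linalg.norm(out.vertices, axis=1)
    if np.any(d >= rad - 1e-9):
        raise ValueError("cerclage_depth reaches the local radius")
    scale = np.where(rad > 0, (rad - d) / np.where(rad > 0, rad, 1.0), 1.0)
    out.vertices = out.vertices * scale[:, None]
    out.radial_disp = out.radial_disp - d
    out.validate()
    return out


def build_eye_surface(params: EyeGeometryParams,
                      variant: Variant = Variant.EMMETROPIC) -> TriMeshSurface:
    """Build the watertight chamber wall for one morphology variant."""
    variant = Variant(variant)
    mesh = _truncated_sphere(params)
    if variant in (Variant.STAPHYLOMA, Variant.STAPHYLOMA_CERCLAGE):
        mesh = apply_staphyloma(mesh, params)
    if variant is Variant.STAPHYLOMA_CERCLAGE:
        mesh = apply_cerclage(mesh, params)
    return mesh


def enclosed_volume(mesh: TriMeshSurface | trimesh.Trimesh) -> float:
    """Signed enclosed volume (mm^3) by the divergence theorem.

    Positive for outward-oriented surfaces; raises on open meshes.
    """
    if isinstance(mesh, TriMeshSurface):
        tm = mesh.as_trimesh()
    else:
        tm = mesh
    if not tm.is_watertight:
        raise ValueError("enclosed_volume requires a watertight mesh")
    v = tm.vertices
    f = tm.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def axial_length(mesh: TriMeshSurface, params: EyeGeometryParams) -> float:
    """Lens plane to posterior pole distance (mm)."""
    return params.lens_plane_z - float(mesh.vertices[:, 2].min())
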