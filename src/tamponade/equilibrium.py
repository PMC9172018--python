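"""Static oil–aqueous equilibrium and per-region contact fractions.

Two solvers are provided:

* :func:`solve_flat_interface` — the zero-capillarity baseline: a horizontal
  interface placed by bisection so the buoyant-oil side holds the prescribed
  volume, with exact triangle–plane clipping of the wall.  It doubles as the
  initial condition and as an analytic oracle for the energy minimizer in the
  zero-surface-tension limit.

* :func:`minimize_capillary_energy` — minimization of the capillary energy

      E[a] = sigma * A(oil–aqueous)  - sigma*cos(theta_oil) * A(oil-wetted wall)
             + (rho_aq - rho_sio) * g * integral_oil (-height) dV

  over a voxelized oil indicator ``a`` under an exact oil-volume constraint,
  by volume-conserving threshold dynamics: each sweep convolves the phase
  field with a Gaussian kernel (wall voxels carry the ghost value
  ``(1 + cos(theta_oil))/2`` which imposes Young's angle), adds the buoyancy
  potential, and rethresholds at the level that keeps the oil voxel count
  fixed.  The fixed point satisfies the Young–Laplace balance
  ``sigma*kappa + delta_rho*g*h = const`` along the interface, i.e. the same
  static state a two-phase volume-of-fluid solver relaxes to.

The solver is fully deterministic: fixed iteration order, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fluids import FluidProperties, Posture
from .geometry import TriMeshSurface, enclosed_volume
from .segmentation import RegionLabel, RegionMap

MM3_TO_M3 = 1e-9
MM_TO_M = 1e-3


# ---------------------------------------------------------------------------
# contact report
# ---------------------------------------------------------------------------

@dataclass
class ContactReport:
    """SiO-wetted area percentages for one (geometry, posture, fill) case."""

    variant: str
    posture: str
    fill_pct: float
    method: str                      # "flat" or "capillary"
    table: pd.DataFrame              # region, hemifield, area_mm2, contact_pct
    overall_pct: float               # area-weighted, lens excluded
    resolution: int | None = None
    converged: bool = True
    iterations: int = 0

    def contact(self, region: str, hemifield: str) -> float:
        sel = self.table[(self.table.region == region)
                         & (self.table.hemifield == hemifield)]
        if sel.empty:
            raise KeyError((region, hemifield))
        return float(sel.contact_pct.iloc[0])

    def region_contact(self, region: str) -> float:
        """Area-weighted contact of one region, both hemifields pooled."""
        sel = self.table[self.table.region == region]
        if sel.empty:
            raise KeyError(region)
        return float((sel.contact_pct * sel.area_mm2).sum() / sel.area_mm2.sum())

    def hemifield_contact(self, hemifield: str) -> float:
        """Area-weighted contact of one hemifield, lens excluded."""
        sel = self.table[(self.table.hemifield == hemifield)
                         & (self.table.region != RegionLabel.LENS.value)]
        return float((sel.contact_pct * sel.area_mm2).sum() / sel.area_mm2.sum())


def _report_from_wetted(mesh: TriMeshSurface, rmap: RegionMap,
                        wetted_area: np.ndarray, **meta) -> ContactReport:
    df = pd.DataFrame({
        "region": rmap.face_region,
        "hemifield": rmap.face_hemifield,
        "area_mm2": rmap.face_areas,
        "wetted_mm2": wetted_area,
    })
    tab = df.groupby(["region", "hemifield"], sort=True).sum().reset_index()
    tab["contact_pct"] = 100.0 * tab.wetted_mm2 / tab.area_mm2
    retina = tab[tab.region != RegionLabel.LENS.value]
    overall = float(100.0 * retina.wetted_mm2.sum() / retina.area_mm2.sum())
    tab = tab.drop(columns="wetted_mm2")
    return ContactReport(table=tab, overall_pct=overall, **meta)


# ---------------------------------------------------------------------------
# flat-interface baseline (exact clipping)
# ---------------------------------------------------------------------------

def _roll_faces(faces: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Cyclically rotate each face's vertex order by a per-face shift."""
    idx = (shift[:, None] + np.arange(3)[None, :]) % 3
    return np.take_along_axis(faces, idx, axis=1)

def _tet_volumes(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                 origin: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", a - origin,
                     np.cross(b - origin, c - origin)) / 6.0

def _tri_areas(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def clip_metrics_above_plane(mesh: TriMeshSurface, up: np.ndarray,
                             offset: float) -> tuple[float, np.ndarray]:
    """Exact volume of the chamber above the plane ``x.up = offset`` and the
    per-face wall area above it (partial faces split at the plane)."""
    up = np.asarray(up, dtype=float)
    verts, faces = mesh.vertices, mesh.faces
    d = verts @ up - offset
    dv = d[faces]
    pos = dv > 0.0
    npos = pos.sum(axis=1)
    origin = offset * up

    area_above = np.zeros(len(faces))
    volume = 0.0

    full = npos == 3
    if full.any():
        f = faces[full]
        a, b, c = verts[f[:, 0]], verts[f[:, 1]], verts[f[:, 2]]
        area_above[full] = _tri_areas(a, b, c)
        volume += _tet_volumes(a, b, c, origin).sum()

    one = npos == 1
    if one.any():
        f = _roll_faces(faces[one], np.argmax(pos[one], axis=1))
        da, db, dc = (d[f[:, k]] for k in range(3))
        A, B, C = verts[f[:, 0]], verts[f[:, 1]], verts[f[:, 2]]
        pab = A + ((da / (da - db))[:, None]) * (B - A)
        pac = A + ((da / (da - dc))[:, None]) * (C - A)
        area_above[one] = _tri_areas(A, pab, pac)
        volume += _tet_volumes(A, pab, pac, origin).sum()

    two = npos == 2
    if two.any():
        # roll so the single below-plane vertex is last (cyclic: orientation kept)
        f = _roll_faces(faces[two], np.argmin(pos[two], axis=1) + 1)
        da, db, dc = (d[f[:, k]] for k in range(3))
        A, B, C = verts[f[:, 0]], verts[f[:, 1]], verts[f[:, 2]]
        pbc = B + ((db / (db - dc))[:, None]) * (C - B)
        pac = A + ((da / (da - dc))[:, None]) * (C - A)
        area_above[two] = _tri_areas(A, B, pbc) + _tri_areas(A, pbc, pac)
        volume += _tet_volumes(A, B, pbc, origin).sum()
        volume += _tet_volumes(A, pbc, pac, origin).sum()

    return float(volume), area_above


def solve_flat_interface(mesh: TriMeshSurface, rmap: RegionMap,
                         fill: float, posture: Posture,
                         variant: str = "", tol_rel: float = 1e-6,
                         ) -> ContactReport:
    """Horizontal-interface oil placement (oil on the anti-gravity side)."""
    if not 0.0 <= fill <= 1.0:
        raise ValueError("fill must lie in [0, 1]")
    if fill in (0.0, 1.0):
        wetted = mesh.face_areas * fill
        return _report_from_wetted(
            mesh, rmap, wetted, variant=variant, posture=posture.name,
            fill_pct=100.0 * fill, method="flat")
    up = posture.up
    vtot = enclosed_volume(mesh)
    target = fill * vtot
    proj = mesh.vertices @ up
    lo, hi = float(proj.min()) - 1e-6, float(proj.max()) + 1e-6
    # volume above the plane decreases monotonically with the offset
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        vol, _ = clip_metrics_above_plane(mesh, up, mid)
        if abs(vol - target) <= tol_rel * vtot:
            break
        if vol > target:
            lo = mid
        else:
            hi = mid
    _, area_above = clip_metrics_above_plane(mesh, up, mid)
    return _report_from_wetted(
        mesh, rmap, area_above, variant=variant, posture=posture.name,
        fill_pct=100.0 * fill, method="flat")


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

@dataclass
class PhaseField:
    """Voxelized oil fraction over the chamber interior.

    The grid may live in a rotated (gravity-aligned) frame: ``rotation`` maps
    eye-frame coordinates into grid-frame coordinates (identity by default).
    """

    origin: np.ndarray           # mm, corner of voxel (0,0,0), grid frame
    pitch: float                 # mm, cubic voxels
    mask: np.ndarray             # bool, inside the chamber
    alpha: np.ndarray            # float32 oil fraction, 0 outside mask
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    converged: bool = True
    sweeps: int = 0
    energy: float = np.nan       # J, discrete capillary energy at return

    @property
    def voxel_volume(self) -> float:
        return self.pitch ** 3

    @property
    def domain_volume(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume

    @property
    def oil_volume(self) -> float:
        return float(self.alpha.sum()) * self.voxel_volume

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.mask.shape
        ax = self.origin[0] + (np.arange(nx) + 0.5) * self.pitch
        ay = self.origin[1] + (np.arange(ny) + 0.5) * self.pitch
        az = self.origin[2] + (np.arange(nz) + 0.5) * self.pitch
        return ax, ay, az

    def to_vtk(self, path: str) -> None:
        """Write the oil fraction as a legacy-VTK structured-points file."""
        nx, ny, nz = self.alpha.shape
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\noil fraction\nASCII\n"
                     "DATASET STRUCTURED_POINTS\n"
                     f"DIMENSIONS {nx} {ny} {nz}\n"
                     f"ORIGIN {self.origin[0]} {self.origin[1]} {self.origin[2]}\n"
                     f"SPACING {self.pitch} {self.pitch} {self.pitch}\n"
                     f"POINT_DATA {nx * ny * nz}\n"
                     "SCALARS alpha float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, self.alpha.reshape(-1, order="F"), fmt="%.4f")

    def interface_area(self) -> float:
        """Oil–aqueous interface area (mm^2) by marching cubes.

        The binary field is pre-smoothed by one voxel: marching cubes on raw
        binary data overestimates areas by ~9 % (staircase facets).
        """
        from skimage import measure
        a = ndimage.gaussian_filter(
            np.ascontiguousarray(self.alpha, dtype=np.float32), 1.0)
        v, f, _, _ = measure.marching_cubes(a, 0.5, spacing=(self.pitch,) * 3)
        return float(measure.mesh_surface_area(v, f))


def rotation_to_gravity_frame(posture: Posture) -> np.ndarray:
    """Rotation matrix mapping eye coordinates to a frame whose ``+y`` axis
    is 'up' (opposite gravity) for the given posture."""
    up = posture.up
    target = np.array([0.0, 1.0, 0.0])
    v = np.cross(up, target)
    c = float(np.dot(up, target))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def voxelize_chamber(mesh: TriMeshSurface, resolution: int = 64,
                     rotation: np.ndarray | None = None) -> PhaseField:
    """Inside/outside mask on a regular grid by vertical-ray parity counting.

    The grid is jittered by an irrational sub-voxel offset so mesh vertices
    and edges never coincide with ray columns (deterministic).  ``rotation``
    optionally voxelizes in a rotated frame (see :class:`PhaseField`).
    """
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    tm = mesh.as_trimesh()
    if len(mesh.faces) == 0 or not tm.is_watertight:
        raise ValueError("voxelize_chamber requires a watertight mesh")
    if rotation is not None:
        mesh = mesh.copy()
        mesh.vertices = mesh.vertices @ np.asarray(rotation).T
    else:
        rotation = np.eye(3)

    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    extent = hi - lo
    pitch = float(extent.max()) / (resolution - 4)
    dims = np.ceil(extent / pitch).astype(int) + 4
    jitter = np.array([0.1237, 0.2719, 0.3361]) * pitch
    origin = lo - 0.5 * (dims * pitch - extent) + jitter

    ax, ay, az = (origin[k] + (np.arange(dims[k]) + 0.5) * pitch
                  for k in range(3))

    verts, faces = mesh.vertices, mesh.faces
    tri = verts[faces]                       # (F, 3, 3)
    # column buckets from the xy bounding box of each triangle
    txy = tri[:, :, :2]
    imin = np.searchsorted(ax, txy[:, :, 0].min(axis=1), side="left")
    imax = np.searchsorted(ax, txy[:, :, 0].max(axis=1), side="right")
    jmin = np.searchsorted(ay, txy[:, :, 1].min(axis=1), side="left")
    jmax = np.searchsorted(ay, txy[:, :, 1].max(axis=1), side="right")
    counts = np.maximum(imax - imin, 0) * np.maximum(jmax - jmin, 0)
    keep = counts > 0
    tri_id = np.repeat(np.nonzero(keep)[0], counts[keep])
    # per (triangle, column) pair indices
    spans_i = imax[tri_id] - imin[tri_id]
    spans_j = jmax[tri_id] - jmin[tri_id]
    local = np.concatenate([np.arange(n) for n in counts[keep]]) \
        if len(tri_id) else np.empty(0, dtype=int)
    ii = imin[tri_id] + local // spans_j
    jj = jmin[tri_id] + local % spans_j

    a, b, c = tri[tri_id, 0], tri[tri_id, 1], tri[tri_id, 2]
    px, py = ax[ii], ay[jj]
    # 2D barycentric point-in-triangle test in the xy plane
    v0 = (b - a)[:, :2]
    v1 = (c - a)[:, :2]
    vp = np.column_stack([px - a[:, 0], py - a[:, 1]])
    den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    ok = np.abs(den) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, den, 1.0), 0.0)
    u = (vp[:, 0] * v1[:, 1] - vp[:, 1] * v1[:, 0]) * inv
    v = (v0[:, 0] * vp[:, 1] - v0[:, 1] * vp[:, 0]) * inv
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
    zc = (a[:, 2] + u * (b[:, 2] - a[:, 2]) + v * (c[:, 2] - a[:, 2]))[hit]
    col = (ii * dims[1] + jj)[hit]

    # parity: voxel (i,j,k) is inside iff an odd number of crossings lie above
    # its centre along +z
    kidx = np.searchsorted(az, zc, side="left")  # crossings above centres < kidx
    above = np.zeros((dims[0] * dims[1], dims[2] + 1), dtype=np.int32)
    np.add.at(above, (col, np.zeros(len(col), dtype=int)), 1)
    np.add.at(above, (col, kidx), -1)
    above = np.cumsum(above, axis=1)[:, :-1]
    mask = (above % 2 == 1).reshape(dims[0], dims[1], dims[2])

    alpha = np.zeros(mask.shape, dtype=np.float32)
    return PhaseField(origin=origin, pitch=pitch, mask=mask, alpha=alpha,
                      rotation=np.asarray(rotation, dtype=float))


# ---------------------------------------------------------------------------
# threshold-dynamics energy minimization
# ---------------------------------------------------------------------------

@dataclass
class MinimizerOptions:
    kernel_width_voxels: float = 1.5   # Gaussian std of the final diffusion kernel
    kernel_anneal: tuple[float, ...] = (6.0, 3.0)  # coarse-to-fine prefix widths
    max_sweeps: int = 2000             # total budget across annealing stages
    conv_window: int = 10              # sweeps over which displacement is summed
    conv_disp_voxels: float = 0.25     # mean interface displacement threshold
    wall_wetting: bool = True          # False -> neutral (90 deg) wall
    move_band_voxels: float | None = None  # flips allowed only this close to
    #   the interface; None disables the restriction (pure variational update)
    interface_topology: str = "graph"  # "graph": the oil-aqueous interface is
    #   a single-valued sheet over the gravity-normal plane (oil above,
    #   aqueous below, per vertical column) — the configuration class a
    #   settled two-phase transport solver reaches from a horizontal initial
    #   interface.  "free": unconstrained minimization, which additionally
    #   admits thin aqueous shells coating wall concavities (lower energy but
    #   unreachable by bulk interface motion on clinical timescales).


def _height_field(phase: PhaseField, up: np.ndarray) -> np.ndarray:
    ax, ay, az = phase.centers()
    return (up[0] * ax[:, None, None] + up[1] * ay[None, :, None]
            + up[2] * az[None, None, :]).astype(np.float32)


def _graph_project(chi_grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Stack the oil of every contiguous vertical fluid segment onto the
    segment's topmost voxels (grid axis 1 = up).

    Hydrostatic stability of the static state: the buoyant oil sits above
    the aqueous in every fluid column, where 'column' is a maximal run of
    chamber voxels not interrupted by wall.  Oil counts are conserved per
    segment, so phase never crosses a solid boundary."""
    nx, ny, nz = mask.shape
    m2 = mask.transpose(0, 2, 1).reshape(-1, ny)
    c2 = chi_grid.transpose(0, 2, 1).reshape(-1, ny)
    mr = m2.ravel()
    cr = c2.ravel()
    start = m2.copy()
    start[:, 1:] &= ~m2[:, :-1]
    sr = start.ravel()
    seg_id = np.cumsum(sr) * mr          # 0 outside, 1..nseg inside
    nseg = int(seg_id.max())
    oil_count = np.bincount(seg_id, weights=cr, minlength=nseg + 1)
    seg_len = np.bincount(seg_id, minlength=nseg + 1)
    # position of each voxel within its segment (segments are contiguous runs)
    idx = np.arange(mr.size)
    seg_start = np.zeros(nseg + 1, dtype=np.int64)
    seg_start[seg_id[sr]] = idx[sr]
    pos = idx - seg_start[seg_id]
    new = mr & (pos >= seg_len[seg_id] - np.rint(oil_count[seg_id]).astype(np.int64))
    return new.reshape(-1, ny).reshape(nx, nz, ny).transpose(0, 2, 1)


def minimize_capillary_energy(domain: PhaseField, fluids: FluidProperties,
                              fill: float, posture: Posture,
                              opts: MinimizerOptions | None = None,
                              init_alpha: np.ndarray | None = None,
                              ) -> PhaseField:
    """Relax the oil phase to the minimum of the capillary energy.

    Initialized from the flat (gravity-only) configuration; the oil voxel
    count is conserved exactly at every sweep by construction of the
    volume-pinned threshold.
    """
    if not 0.0 <= fill <= 1.0:
        raise ValueError("fill must lie in [0, 1]")
    opts = opts or MinimizerOptions()
    mask = domain.mask
    n_dom = int(mask.sum())
    if n_dom == 0:
        raise ValueError("empty voxel domain")
    k_oil = int(round(fill * n_dom))

    pitch_m = domain.pitch * MM_TO_M
    sigma = fluids.interfacial_tension
    up_grid = domain.rotation @ posture.up
    use_graph = opts.interface_topology == "graph"
    if opts.interface_topology not in ("graph", "free"):
        raise ValueError("interface_topology must be 'graph' or 'free'")
    if use_graph and not np.allclose(up_grid, [0.0, 1.0, 0.0], atol=1e-9):
        raise ValueError(
            "graph topology requires a gravity-aligned grid; voxelize with "
            "rotation=rotation_to_gravity_frame(posture)")
    # buoyancy potential per unit volume of oil (J/m^3); h in metres
    h = _height_field(domain, up_grid) * MM_TO_M
    potential = (-fluids.delta_rho * fluids.gravity * h).astype(np.float32)

    w_ghost = 0.5
    if opts.wall_wetting:
        w_ghost = 0.5 * (1.0 + np.cos(np.radians(fluids.contact_angle_sio_deg)))

    if init_alpha is not None:
        chi = init_alpha[mask] >= 0.5
        k_oil = int(chi.sum())   # conserve the supplied oil volume
    else:
        # flat initialization: the k highest voxels hold oil
        hm = h[mask]
        order = np.argsort(hm, kind="stable")
        chi = np.zeros(n_dom, dtype=bool)
        if k_oil > 0:
            chi[order[-k_oil:]] = True

    field = np.full(mask.shape, w_ghost, dtype=np.float32)
    pot_m = potential[mask]
    voxvol_m3 = pitch_m ** 3

    # coarse-to-fine kernel schedule: wide kernels let the interface travel
    # several voxels per sweep (threshold dynamics otherwise pins as soon as
    # the per-sweep displacement falls below the voxel size); the final width
    # sets the resolution of the converged state
    stages = tuple(opts.kernel_anneal) + (opts.kernel_width_voxels,)
    converged = False
    energy = np.nan
    best_energy = np.inf
    best_chi = chi.copy()
    sweep = 0

    for eps_vox in stages:
        gamma = sigma * np.sqrt(2.0 * np.pi) / (eps_vox * pitch_m) if sigma > 0 else 0.0
        flips_hist: list[int] = []
        stage_converged = False
        stage_sweeps = 0
        while sweep < opts.max_sweeps:
            sweep += 1
            stage_sweeps += 1
            field[mask] = chi
            smooth = ndimage.gaussian_filter(field, sigma=eps_vox,
                                             mode="nearest")
            sm = smooth[mask]
            score = 2.0 * gamma * (sm - 0.5) - pot_m
            if k_oil == 0:
                new_chi = np.zeros(n_dom, dtype=bool)
            elif k_oil == n_dom:
                new_chi = np.ones(n_dom, dtype=bool)
            elif opts.move_band_voxels is None:
                part = np.argpartition(score, n_dom - k_oil)
                new_chi = np.zeros(n_dom, dtype=bool)
                new_chi[part[n_dom - k_oil:]] = True
            else:
                # transport locality: only voxels near the current interface
                # may change phase this sweep
                chi_grid = np.zeros(mask.shape, dtype=bool)
                chi_grid[mask] = chi
                dil = ndimage.binary_dilation(
                    chi_grid, iterations=int(np.ceil(opts.move_band_voxels)))
                ero = ndimage.binary_erosion(
                    chi_grid, iterations=int(np.ceil(opts.move_band_voxels)),
                    border_value=1)
                movable = (dil & ~ero)[mask]
                k_mov = k_oil - int((chi & ~movable).sum())
                n_mov = int(movable.sum())
                new_chi = chi.copy()
                if 0 < n_mov:
                    k_mov = min(max(k_mov, 0), n_mov)
                    sc = score[movable]
                    sel = np.zeros(n_mov, dtype=bool)
                    if k_mov > 0:
                        part = np.argpartition(sc, n_mov - k_mov)
                        sel[part[n_mov - k_mov:]] = True
                    new_chi[movable] = sel

            if use_graph:
                chi_grid = np.zeros(mask.shape, dtype=bool)
                chi_grid[mask] = new_chi
                new_chi = _graph_project(chi_grid, mask)[mask]

            if eps_vox == stages[-1]:
                # Lyapunov energy of the current state at the final kernel
                energy = float((gamma * (chi * (1.0 - sm)).sum()
                                + (chi * pot_m).sum()) * voxvol_m3)
                if energy < best_energy:
                    best_energy = energy
                    best_chi = chi.copy()

            flips = int((new_chi ^ chi).sum())
            chi = new_chi
            flips_hist.append(flips)
            if flips == 0:
                stage_converged = True
                break
            if (stage_sweeps % opts.conv_window == 0
                    and stage_sweeps >= opts.conv_window):
                iface = _interface_count(field, mask)
                recent = sum(flips_hist[-opts.conv_window:])
                if iface > 0 and recent / iface < opts.conv_disp_voxels:
                    stage_converged = True
                    break
        converged = stage_converged

    if not converged and np.isfinite(best_energy):
        chi = best_chi
        energy = best_energy

    alpha = np.zeros(mask.shape, dtype=np.float32)
    alpha[mask] = chi.astype(np.float32)
    return PhaseField(origin=domain.origin, pitch=domain.pitch, mask=mask,
                      alpha=alpha, rotation=domain.rotation,
                      converged=converged, sweeps=sweep, energy=energy)


def _interface_count(field: np.ndarray, mask: np.ndarray) -> int:
    """Number of oil voxels with at least one non-oil 6-neighbour."""
    chi = np.zeros(mask.shape, dtype=bool)
    chi[mask] = field[mask] > 0.5
    er = ndimage.binary_erosion(chi)
    return int((chi & ~er).sum())


# ---------------------------------------------------------------------------
# contact measurement
# ---------------------------------------------------------------------------

def wetted_faces(phase: PhaseField, mesh: TriMeshSurface) -> np.ndarray:
    """Boolean per-face SiO-wetted flags from an equilibrated phase field.

    A face is SiO-wetted iff the trilinearly interpolated oil fraction one
    voxel pitch inside the wall (along the inward normal at the centroid) is
    at least 0.5 — the tie counts as wetted.
    """
    pts = mesh.face_centroids - phase.pitch * mesh.face_normals
    pts = pts @ phase.rotation.T   # eye frame -> grid frame
    coords = ((pts - phase.origin) / phase.pitch - 0.5).T
    # extend the oil fraction 2 voxels into the wall so trilinear sampling
    # near the boundary is not biased by outside-domain zeros
    alpha_ext = np.asarray(phase.alpha, dtype=np.float32).copy()
    known = phase.mask.copy()
    for _ in range(2):
        grown = ndimage.binary_dilation(known)
        ring = grown & ~known
        alpha_ext[ring] = ndimage.grey_dilation(alpha_ext, size=3)[ring]
        known = grown
    vals = ndimage.map_coordinates(alpha_ext, coords, order=1,
                                   mode="nearest")
    return vals >= 0.5


def contact_fractions(phase: PhaseField, mesh: TriMeshSurface,
                      rmap: RegionMap, variant: str = "",
                      posture: str = "", fill_pct: float = np.nan,
                      ) -> ContactReport:
    """Per-region SiO contact percentages from an equilibrated phase field."""
    wetted = wetted_faces(phase, mesh)
    wetted_area = mesh.face_areas * wetted
    return _report_from_wetted(
        mesh, rmap, wetted_area, variant=variant, posture=posture,
        fill_pct=fill_pct, method="capillary",
        resolution=max(phase.mask.shape), converged=phase.converged,
        iterations=phase.sweeps)
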