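"""Static two-phase equilibrium: flat-interface closed forms, voxelization
accuracy, and the capillary minimizer's oracle limits and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tamponade.equilibrium import (MinimizerOptions, PhaseField,
                                   clip_metrics_above_plane,
                                   contact_fractions, _graph_project,
                                   minimize_capillary_energy,
                                   rotation_to_gravity_frame,
                                   solve_flat_interface, voxelize_chamber)
from tamponade.fluids import FluidProperties, Posture
from tamponade.geometry import (EyeGeometryParams, Variant, build_eye_surface,
                                enclosed_volume)
from tamponade.segmentation import RegionLabel, label_regions

SPHERE_VOL = 4.0 / 3.0 * np.pi * 12.0 ** 3


# ---------------------------------------------------------------------------
# flat-interface baseline
# ---------------------------------------------------------------------------

class TestFlatInterface:
    def test_half_fill_is_half_contact(self, near_sphere, standing):
        _, mesh, rmap = near_sphere
        rep = solve_flat_interface(mesh, rmap, 0.5, standing)
        assert rep.overall_pct == pytest.approx(50.0, abs=0.2)

    def test_full_fill_is_full_contact(self, near_sphere, standing):
        _, mesh, rmap = near_sphere
        rep = solve_flat_interface(mesh, rmap, 1.0, standing)
        assert rep.overall_pct == pytest.approx(100.0, abs=1e-9)

    def test_95_percent_fill_spherical_cap_root(self, near_sphere, standing):
        # the unwetted polar cap height x = h/R solves x^2 (3 - x) = 0.2;
        # wetted fraction = 1 - x/2 ~ 86.6 %
        _, mesh, rmap = near_sphere
        rep = solve_flat_interface(mesh, rmap, 0.95, standing)
        roots = np.roots([-1.0, 3.0, 0.0, -0.2])
        x = min(r.real for r in roots if 0 < r.real < 1)
        assert rep.overall_pct == pytest.approx(100 * (1 - x / 2), abs=0.5)

    def test_posture_invariance_on_sphere(self, near_sphere):
        _, mesh, rmap = near_sphere
        vals = [solve_flat_interface(mesh, rmap, 0.9,
                                     Posture.from_name(n)).overall_pct
                for n in ("standing", "supine", "tilt45")]
        assert np.ptp(vals) < 0.3

    def test_fill_out_of_range_rejected(self, near_sphere, standing):
        _, mesh, rmap = near_sphere
        with pytest.raises(ValueError):
            solve_flat_interface(mesh, rmap, 1.2, standing)

    @settings(derandomize=True, max_examples=20)
    @given(ux=st.floats(-1, 1), uy=st.floats(-1, 1), uz=st.floats(-1, 1),
           frac=st.floats(0.05, 0.95))
    def test_clip_partitions_volume_and_area(self, near_sphere, ux, uy, uz,
                                             frac):
        _, mesh, _ = near_sphere
        n = np.array([ux, uy, uz])
        if np.linalg.norm(n) < 1e-3:
            return
        n = n / np.linalg.norm(n)
        proj = mesh.vertices @ n
        off = proj.min() + frac * np.ptp(proj)
        v_above, a_above = clip_metrics_above_plane(mesh, n, off)
        v_below, a_below = clip_metrics_above_plane(mesh, -n, -off)
        total = enclosed_volume(mesh)
        assert v_above + v_below == pytest.approx(total, rel=1e-9)
        assert np.all(a_above <= mesh.face_areas * (1 + 1e-12))
        assert a_above + a_below == pytest.approx(mesh.face_areas, rel=1e-9)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

class TestVoxelize:
    def test_sphere_volume_within_2_percent(self, near_sphere):
        _, mesh, _ = near_sphere
        dom = voxelize_chamber(mesh, 64)
        assert dom.domain_volume == pytest.approx(SPHERE_VOL, rel=0.02)

    def test_refinement_reduces_volume_error(self, labelled_variants):
        # reference is the mesh's own enclosed volume: that is the quantity
        # the voxel mask approximates; the grid-aligned lens plane makes the
        # leading error O(pitch), so doubling the resolution halves it
        mesh, _ = labelled_variants[Variant.EMMETROPIC]
        ref = enclosed_volume(mesh)
        errs = [abs(voxelize_chamber(mesh, res).domain_volume - ref) / ref
                for res in (32, 64, 128)]
        assert errs[1] < 0.65 * errs[0]
        assert errs[2] < 0.65 * errs[1]

    @pytest.mark.parametrize("variant", list(Variant))
    def test_variant_volumes_match_mesh(self, variant, labelled_variants):
        mesh, _ = labelled_variants[variant]
        dom = voxelize_chamber(mesh, 64)
        assert dom.domain_volume == pytest.approx(enclosed_volume(mesh),
                                                  rel=0.02)

    def test_open_mesh_rejected(self, near_sphere):
        _, mesh, _ = near_sphere
        broken = mesh.copy()
        broken.faces = broken.faces[:-10]
        with pytest.raises(ValueError):
            voxelize_chamber(broken, 32)


# ---------------------------------------------------------------------------
# capillary energy minimizer
# ---------------------------------------------------------------------------

class TestMinimizer:
    def test_zero_surface_tension_matches_flat_oracle(self, labelled_variants,
                                                      standing):
        """With sigma = 0 the minimizer must reduce to the analytic
        flat-interface solution on every chamber variant."""
        fl0 = FluidProperties(interfacial_tension=0.0)
        for variant, (mesh, rmap) in labelled_variants.items():
            dom = voxelize_chamber(
                mesh, 64, rotation=rotation_to_gravity_frame(standing))
            phase = minimize_capillary_energy(dom, fl0, 0.9, standing)
            rep = contact_fractions(phase, mesh, rmap)
            flat = solve_flat_interface(mesh, rmap, 0.9, standing)
            assert rep.overall_pct == pytest.approx(flat.overall_pct, abs=2.0)
            for region in set(rmap.face_region) - {RegionLabel.LENS.value}:
                assert rep.region_contact(region) == pytest.approx(
                    flat.region_contact(region), abs=3.0)

    def test_oil_volume_conserved_exactly(self, labelled_variants, fluids,
                                          standing):
        mesh, rmap = labelled_variants[Variant.EMMETROPIC]
        dom = voxelize_chamber(mesh, 48,
                               rotation=rotation_to_gravity_frame(standing))
        for fill in (0.8, 0.93):
            phase = minimize_capillary_energy(dom, fluids, fill, standing)
            k = round(fill * dom.mask.sum())
            assert phase.alpha.sum() == k
            assert abs(phase.oil_volume - fill * dom.domain_volume) \
                <= dom.voxel_volume

    def test_zero_gravity_blob_is_spherical(self, fluids, standing,
                                            labelled_variants):
        """Without gravity an interior oil blob relaxes to the minimal
        surface: isoperimetric ratio A^3/(36 pi V^2) near one."""
        mesh, _ = labelled_variants[Variant.EMMETROPIC]
        dom = voxelize_chamber(mesh, 64)
        g0 = FluidProperties(gravity=0.0)
        ax, ay, az = dom.centers()
        side = (0.2 * dom.domain_volume) ** (1 / 3)
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        seed = ((np.abs(X) < side / 2) & (np.abs(Y) < side / 2)
                & (np.abs(Z) < side / 2) & dom.mask).astype(np.float32)
        opts = MinimizerOptions(interface_topology="free", max_sweeps=600)
        phase = minimize_capillary_energy(dom, g0, 0.2, standing, opts,
                                          init_alpha=seed)
        ratio = phase.interface_area() ** 3 / (36 * np.pi
                                               * phase.oil_volume ** 2)
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_extreme_fills(self, labelled_variants, fluids, standing):
        mesh, rmap = labelled_variants[Variant.EMMETROPIC]
        dom = voxelize_chamber(mesh, 48,
                               rotation=rotation_to_gravity_frame(standing))
        full = contact_fractions(
            minimize_capillary_energy(dom, fluids, 1.0, standing), mesh, rmap)
        assert full.table.contact_pct.min() == pytest.approx(100.0, abs=1e-6)
        empty = contact_fractions(
            minimize_capillary_energy(dom, fluids, 0.0, standing), mesh, rmap)
        assert empty.table.contact_pct.max() == 0.0

    def test_supine_hemifield_symmetry(self, labelled_variants, fluids):
        """Supine gravity is axisymmetric for the chamber: superior and
        inferior contact must agree to voxel tolerance."""
        mesh, rmap = labelled_variants[Variant.EMMETROPIC]
        supine = Posture.from_name("supine")
        dom = voxelize_chamber(mesh, 64,
                               rotation=rotation_to_gravity_frame(supine))
        phase = minimize_capillary_energy(dom, fluids, 0.9, supine)
        rep = contact_fractions(phase, mesh, rmap)
        assert rep.hemifield_contact("superior") == pytest.approx(
            rep.hemifield_contact("inferior"), abs=1.5)

    def test_contact_monotone_in_fill(self, labelled_variants, fluids,
                                      standing):
        mesh, rmap = labelled_variants[Variant.STAPHYLOMA]
        dom = voxelize_chamber(mesh, 48,
                               rotation=rotation_to_gravity_frame(standing))
        vals = [contact_fractions(
            minimize_capillary_energy(dom, fluids, f, standing),
            mesh, rmap).overall_pct for f in (0.8, 0.85, 0.9, 0.95, 1.0)]
        assert np.all(np.diff(vals) >= -0.5)   # voxel-level slack
        assert vals[-1] == pytest.approx(100.0, abs=1e-6)

    def test_graph_topology_requires_aligned_grid(self, labelled_variants,
                                                  fluids):
        mesh, _ = labelled_variants[Variant.EMMETROPIC]
        dom = voxelize_chamber(mesh, 32)   # no rotation
        with pytest.raises(ValueError):
            minimize_capillary_energy(dom, fluids, 0.9,
                                      Posture.from_name("supine"))

    def test_deterministic(self, labelled_variants, fluids, standing):
        mesh, _ = labelled_variants[Variant.EMMETROPIC]
        dom = voxelize_chamber(mesh, 48,
                               rotation=rotation_to_gravity_frame(standing))
        a = minimize_capillary_energy(dom, fluids, 0.87, standing)
        b = minimize_capillary_energy(dom, fluids, 0.87, standing)
        assert np.array_equal(a.alpha, b.alpha)


class TestGraphProjection:
    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_conserves_and_stacks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((6, 12, 6)) > 0.3
        chi = mask & (rng.random((6, 12, 6)) > 0.5)
        out = _graph_project(chi, mask)
        assert out.sum() == chi.sum()
        assert not (out & ~mask).any()
        # within every contiguous vertical run, oil occupies the top
        for i in range(6):
            for k in range(6):
                col_m = mask[i, :, k]
                col_o = out[i, :, k]
                runs = np.split(np.arange(12), np.nonzero(np.diff(col_m))[0] + 1)
                for run in runs:
                    if not col_m[run].any():
                        continue
                    vals = col_o[run].astype(int)
                    assert np.all(np.diff(vals) >= 0)   # aqueous below oil

    def test_projection_is_idempotent(self):
        rng = np.random.default_rng(7)
        mask = rng.random((5, 9, 5)) > 0.25
        chi = mask & (rng.random((5, 9, 5)) > 0.5)
        once = _graph_project(chi, mask)
        assert np.array_equal(once, _graph_project(once, mask))


class TestRotationFrame:
    @pytest.mark.parametrize("name", ["standing", "tilt45", "supine"])
    def test_up_maps_to_plus_y(self, name):
        posture = Posture.from_name(name)
        R = rotation_to_gravity_frame(posture)
        assert np.allclose(R @ posture.up, [0, 1, 0], atol=1e-12)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
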