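"""Surface reconstruction, spot detection and signed-distance geometry."""

import numpy as np
import pytest
import trimesh
from trimesh.proximity import closest_point_naive

from conftest import match_spots_to_truth
from glioquant import geometry as geo
from glioquant.synth3d import DepthLaw, ImagingParams, generate_scene, \
    render_stack

VOXEL_DIAG = np.linalg.norm([3.0, 1.2, 1.2])


def ray_parity_inside(points, mesh):
    """Independent inside test: parity of +x ray crossings over all
    triangles (Möller–Trumbore), brute force."""
    tri = mesh.triangles.view(np.ndarray)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = b - a, c - a
    d = np.array([1.0, 0.0, 0.0])
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        h = np.cross(d, e2)
        det = np.einsum("mk,mk->m", e1, h)
        ok = np.abs(det) > 1e-12
        s = p - a
        u = np.einsum("mk,mk->m", s, h) / np.where(ok, det, 1.0)
        q = np.cross(s, e1)
        v = (q @ d) / np.where(ok, det, 1.0)
        t = np.einsum("mk,mk->m", e2, q) / np.where(ok, det, 1.0)
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        out[i] = hit.sum() % 2 == 1
    return out


# --------------------------------------------------------------------------
# padding
# --------------------------------------------------------------------------

class TestPadStack:
    def test_default_padding_gives_135_slices(self, sphere_case):
        # 85 acquired sections + 50 blank slices below
        assert sphere_case["stack"].shape[0] == 135

    def test_zero_padding_is_identity(self):
        scene = generate_scene(30.0, 50, 0, DepthLaw.fixed([]), seed=0)
        stack = render_stack(scene, ImagingParams(n_xy=48, n_slices=10))
        assert geo.pad_stack(stack, 0) is stack

    def test_blank_slices_are_zero_and_positions_preserved(self):
        scene = generate_scene(30.0, 50, 0, DepthLaw.fixed([]), seed=0)
        stack = render_stack(scene, ImagingParams(n_xy=48, n_slices=10,
                                                  background=0.0))
        padded = geo.pad_stack(stack, 5)
        assert padded.shape[0] == 15
        assert padded.nuclear[:5].max() == 0.0
        # a voxel's physical position is unchanged by padding
        p0 = stack.voxel_to_um([[3, 7, 9]])
        p1 = padded.voxel_to_um([[8, 7, 9]])
        assert np.allclose(p0, p1)


# --------------------------------------------------------------------------
# surface reconstruction
# --------------------------------------------------------------------------

class TestReconstructSurface:
    def test_sphere_vertex_radii_match_truth(self, sphere_case):
        scene, mesh1 = sphere_case["scene"], sphere_case["mesh1"]
        radii = np.linalg.norm(mesh1.vertices - scene.organoid_center, axis=1)
        tol = max(VOXEL_DIAG, 25.0 / 2.0)
        assert np.all(np.abs(radii - 100.0) < tol)
        assert abs(radii.mean() - 100.0) < 3.0

    def test_uniform_stack_raises_empty_surface(self):
        from glioquant.synth3d import VoxelStack
        arr = np.full((20, 32, 32), 7.0)
        stack = VoxelStack(nuclear=arr, tumor=arr.copy(),
                           spacing=(3.0, 1.2, 1.2), origin=np.zeros(3))
        with pytest.raises(geo.EmptySurfaceError):
            geo.reconstruct_surface(stack)

    def test_two_disjoint_spheres_keep_larger(self):
        big = generate_scene(60.0, None, 0, DepthLaw.fixed([]), seed=1,
                             center=(-75.0, 0.0, 0.0))
        small = generate_scene(25.0, None, 0, DepthLaw.fixed([]), seed=2,
                               center=(75.0, 0.0, 0.0))
        params = ImagingParams(n_xy=256)
        stack = render_stack(big, params, origin=np.array([-153.6, -153.6,
                                                           -66.0]))
        stack2 = render_stack(small, params, origin=stack.origin)
        stack.nuclear += stack2.nuclear - params.background
        stack = geo.pad_stack(stack, 20)
        mesh = geo.reconstruct_surface(stack)
        vol = geo.mesh_volume(mesh)
        big_vol = 4 / 3 * np.pi * 60.0 ** 3
        assert vol == pytest.approx(big_vol, rel=0.15)
        # every vertex belongs to the big sphere's neighbourhood
        d_big = np.linalg.norm(mesh.vertices - big.organoid_center, axis=1)
        assert d_big.max() < 80.0


class TestOutsideMaskResurface:
    def test_pass2_volume_close_to_pass1(self, sphere_case):
        v1 = geo.mesh_volume(sphere_case["mesh1"])
        v2 = geo.mesh_volume(sphere_case["mesh2"])
        assert abs(v2 - v1) / v1 < 0.05

    def test_fill_value_does_not_move_surface(self, sphere_case):
        stack, mesh1 = sphere_case["stack"], sphere_case["mesh1"]
        m150 = sphere_case["mesh2"]
        m255 = geo.outside_mask_resurface(stack, mesh1, fill_value=255.0)
        # same binary geometry: vertex sets coincide to within a voxel
        d = geo.unsigned_distance(m255.vertices[::50], m150)
        assert np.abs(d).max() < VOXEL_DIAG

    def test_truncated_organoid_pass1_open_pass2_closed(self, truncated_case):
        mesh1, mesh2 = truncated_case["mesh1"], truncated_case["mesh2"]
        stack = truncated_case["stack"]
        assert not mesh1.is_watertight      # open where the organoid crosses
        assert mesh2.is_watertight          # the acquisition top
        z_top = stack.origin[2] + (stack.shape[0] - 1) * stack.spacing[0]
        # the pass-2 closure is displaced above the acquired data, and no
        # flat cap sits on the top image plane
        assert mesh2.vertices[:, 2].max() > z_top + 100.0
        m = mesh2.mesh
        flat = (np.abs(m.face_normals[:, 2]) > 0.95) \
            & (np.abs(m.triangles_center[:, 2] - z_top) < stack.spacing[0])
        assert m.area_faces[flat].sum() < 0.001 * m.area

    def test_pass2_provenance(self, sphere_case):
        assert sphere_case["mesh2"].provenance["pass"] == 2
        assert sphere_case["mesh1"].provenance["pass"] == 1


# --------------------------------------------------------------------------
# spot detection
# --------------------------------------------------------------------------

class TestDetectSpots:
    def test_all_cells_found_within_one_voxel(self, sphere_case):
        scene, spots = sphere_case["scene"], sphere_case["spots"]
        assert len(spots) == len(scene.tumor_positions)
        matched, idx = match_spots_to_truth(spots, scene, max_dist=VOXEL_DIAG)
        assert matched.all()

    def test_blank_channel_yields_no_spots(self):
        scene = generate_scene(40.0, 100, 0, DepthLaw.fixed([]), seed=0)
        stack = render_stack(scene, ImagingParams(n_xy=64, n_slices=30))
        assert len(geo.detect_spots(stack)) == 0

    def test_two_close_cells_deterministic(self):
        # cells 4 um apart (closer than the 10 um spot size): the detector
        # may merge them, but the outcome is fixed for a fixed input
        scene = generate_scene(50.0, 0, 2, DepthLaw.fixed([20.0, 24.0]),
                               seed=6)
        # force both cells onto the same ray 4 um apart
        c = scene.organoid_center
        scene.tumor_positions[0] = c + np.array([30.0, 0, 0])
        scene.tumor_positions[1] = c + np.array([26.0, 0, 0])
        stack = render_stack(scene, ImagingParams(n_xy=96, n_slices=40))
        counts = {len(geo.detect_spots(stack)) for _ in range(3)}
        assert counts <= {1, 2}
        assert len(counts) == 1


# --------------------------------------------------------------------------
# signed distance
# --------------------------------------------------------------------------

class TestSignedDistance:
    def test_sphere_analytic_values(self, icosphere_100):
        # chord error of a subdivision-3 icosphere is < 0.6 um at R=100
        d = geo.signed_distance(
            np.array([[0.0, 0, 0], [120.0, 0, 0], [0, 50.0, 0]]),
            icosphere_100)
        assert d[0] == pytest.approx(100.0, abs=0.6)
        assert d[1] == pytest.approx(-20.0, abs=0.6)
        assert d[2] == pytest.approx(50.0, abs=0.6)

    def test_matches_brute_force_and_external_oracle(self, icosphere_100):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-150, 150, (1000, 3))
        pruned = geo.unsigned_distance(pts, icosphere_100, method="pruned")
        brute = geo.unsigned_distance(pts, icosphere_100, method="brute")
        _, oracle, _ = closest_point_naive(icosphere_100, pts)
        assert np.abs(pruned - brute).max() < 1e-6
        assert np.abs(pruned - oracle).max() < 1e-6

    def test_matches_oracle_on_irregular_mesh(self, sphere_case):
        # reconstructed (non-analytic) mesh with vertex/edge/face cases
        m = sphere_case["mesh2"].mesh
        rng = np.random.default_rng(1)
        pts = rng.uniform(-130, 130, (60, 3))
        mine = geo.unsigned_distance(pts, m, method="pruned")
        _, oracle, _ = closest_point_naive(m, pts)
        assert np.abs(mine - oracle).max() < 1e-6

    def test_winding_number_agrees_with_ray_parity(self, icosphere_100):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-150, 150, (400, 3))
        wn = geo.winding_number(pts, icosphere_100) > 0.5
        rp = ray_parity_inside(pts, icosphere_100)
        assert np.array_equal(wn, rp)

    def test_open_mesh_rejected_with_guidance(self, truncated_case):
        with pytest.raises(geo.OpenMeshError, match="outside_mask_resurface"):
            geo.signed_distance(np.zeros((1, 3)), truncated_case["mesh1"])

    def test_translation_by_lattice_vector_preserves_distances(self):
        scene = generate_scene(70.0, None, 25, DepthLaw.exponential(12.0),
                               seed=13)
        params = ImagingParams(n_xy=160, n_slices=60)

        def measure(origin_shift):
            stack = render_stack(scene, params)
            origin = stack.origin + origin_shift
            stack = render_stack(scene, params, origin=origin)
            stack = geo.pad_stack(stack, 20)
            m1 = geo.reconstruct_surface(stack)
            m2 = geo.outside_mask_resurface(stack, m1)
            spots = geo.detect_spots(stack)
            tab = geo.shortest_distance(spots, m2)
            matched, idx = match_spots_to_truth(spots, scene)
            out = np.full(len(scene.tumor_positions), np.nan)
            out[idx[matched]] = tab["distance_um"].to_numpy()[matched]
            return out

        base = measure(np.zeros(3))
        shifted = measure(np.array([-1.2, -1.2, -3.0]))  # one voxel
        both = ~np.isnan(base) & ~np.isnan(shifted)
        assert both.sum() >= 20
        assert np.abs(base[both] - shifted[both]).max() < VOXEL_DIAG


# --------------------------------------------------------------------------
# mesh measurements
# --------------------------------------------------------------------------

class TestMeshMeasures:
    def test_icosphere_volume_and_area(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=100.0)
        assert geo.mesh_volume(ico) == pytest.approx(4.18879e6, rel=0.01)
        assert geo.mesh_area(ico) == pytest.approx(1.25664e5, rel=0.01)

    def test_unit_cube(self):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        assert geo.mesh_volume(cube) == pytest.approx(1.0)
        assert geo.mesh_area(cube) == pytest.approx(6.0)

    def test_scaling_laws(self, icosphere_100):
        doubled = icosphere_100.copy()
        doubled.apply_scale(2.0)
        assert geo.mesh_volume(doubled) == pytest.approx(
            8 * geo.mesh_volume(icosphere_100), rel=1e-9)
        assert geo.mesh_area(doubled) == pytest.approx(
            4 * geo.mesh_area(icosphere_100), rel=1e-9)

    def test_open_mesh_volume_errors_area_defined(self, truncated_case):
        with pytest.raises(geo.OpenMeshError):
            geo.mesh_volume(truncated_case["mesh1"])
        assert geo.mesh_area(truncated_case["mesh1"]) > 0


class TestEndToEndRecovery:
    def test_depth_rmse_within_tolerance(self, sphere_case):
        scene, spots = sphere_case["scene"], sphere_case["spots"]
        tab = geo.shortest_distance(spots, sphere_case["mesh2"])
        matched, idx = match_spots_to_truth(spots, scene)
        err = tab["distance_um"].to_numpy()[matched] \
            - scene.tumor_true_depth[idx[matched]]
        rmse = float(np.sqrt((err ** 2).mean()))
        assert rmse <= max(VOXEL_DIAG, 12.5)

    def test_volume_area_within_5pct(self, sphere_case):
        mesh2 = sphere_case["mesh2"]
        assert geo.mesh_volume(mesh2) == pytest.approx(
            4 / 3 * np.pi * 100.0 ** 3, rel=0.05)
        assert geo.mesh_area(mesh2) == pytest.approx(
            4 * np.pi * 100.0 ** 2, rel=0.05)
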