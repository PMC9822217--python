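"""Element HU averaging strategies and whole-mesh material mapping."""

import numpy as np
import pytest

import bonemap as bm
from bonemap.errors import MappingError
from bonemap.femesh import points_in_tet
from bonemap.hu_mapping import subdivision_weights
from bonemap.imaging import voxel_to_world

from conftest import affine_hu


def _chain():
    return bm.builtin_chain("bonemat_test_eq11_13")


def _cfg(**kw):
    kw.setdefault("chain", _chain())
    return bm.MappingConfig(**kw)


class TestSubdivisionQuadrature:
    @pytest.mark.parametrize("refinement", [1, 2, 3])
    def test_weights_partition_and_first_moment(self, refinement):
        W = subdivision_weights(refinement)
        assert W.shape == (8**refinement, 4)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)
        # equal-weight sample centroid = element centroid
        assert np.allclose(W.mean(axis=0), 0.25, atol=1e-12)

    def test_children_have_equal_volumes(self):
        W1 = subdivision_weights(1)
        # reconstruct child tets on a random parent and check volumes
        rng = np.random.default_rng(0)
        verts = rng.normal(size=(4, 3))
        parent_vol = abs(np.linalg.det(verts[1:] - verts[0])) / 6
        from bonemap.hu_mapping import _refine_once

        kids = _refine_once(np.eye(4)[None])
        vols = [abs(np.linalg.det((k @ verts)[1:] - (k @ verts)[0])) / 6 for k in kids]
        assert np.allclose(vols, parent_vol / 8, rtol=1e-12)


class TestNodeAverage:
    def test_constant_volume(self, constant_volume, cube_mesh):
        v = bm.element_hu_node_average(cube_mesh, constant_volume, _cfg(), 1)
        assert v == 250.0

    def test_affine_field_gives_centroid_value(self, affine_volume, cube_mesh):
        for eid in cube_mesh.elem_ids:
            v = bm.element_hu_node_average(cube_mesh, affine_volume, _cfg(), int(eid))
            expect = affine_hu(bm.element_centroid(cube_mesh, int(eid)))[0]
            assert v == pytest.approx(expect, rel=1e-12)

    def test_equals_mean_of_four_point_evaluations(self, cube_mesh):
        # quadratic HU field: node average must equal the mean of hu_at calls
        rng = np.random.default_rng(1)
        hu = rng.uniform(0, 1500, size=(14, 14, 14))
        vol = bm.CTVolume(hu=hu, spacing=(1, 1, 1), origin=(0, 0, 0))
        for eid in (1, 3, 6):
            direct = np.mean([bm.hu_at(vol, p) for p in cube_mesh.element_vertices(eid)])
            assert bm.element_hu_node_average(cube_mesh, vol, _cfg(), eid) == pytest.approx(
                direct, rel=1e-14
            )


class TestVoxelAverage:
    def test_constant_volume(self, constant_volume, cube_mesh):
        cfg = _cfg(strategy="voxel_average")
        assert bm.element_hu_voxel_average(cube_mesh, constant_volume, cfg, 1) == 250.0

    def test_matches_exhaustive_voxel_enumeration(self):
        spec = bm.PhantomSpec(kind="two_phase", params={"hu_low": 0.0, "hu_high": 1000.0},
                              dims=(16, 16, 16))
        vol = bm.make_volume(spec)
        mesh = bm.make_box_mesh((9.0, 7.0, 8.0), (1, 1, 1), origin=(1.2, 2.1, 3.3))
        cfg = _cfg(strategy="voxel_average")
        for eid in mesh.elem_ids:
            eid = int(eid)
            # oracle: enumerate every voxel center in the grid, test membership
            idx = np.stack(np.meshgrid(*[np.arange(d) for d in vol.dims],
                                       indexing="ij"), axis=-1).reshape(-1, 3)
            centers = voxel_to_world(vol, idx.astype(float))
            verts = mesh.element_vertices(eid)
            inside = points_in_tet(verts, centers)
            expect = vol.hu.ravel()[inside].mean()
            assert bm.element_hu_voxel_average(mesh, vol, cfg, eid) == pytest.approx(
                expect, rel=1e-12
            )

    def test_subvoxel_element_falls_back_to_integration(self, affine_volume):
        tiny = bm.make_box_mesh((0.4, 0.4, 0.4), (1, 1, 1), origin=(5.3, 5.3, 5.3))
        cfg = _cfg(strategy="voxel_average", voxel_fallback="integration")
        for eid in tiny.elem_ids:
            v = bm.element_hu_voxel_average(tiny, affine_volume, cfg, int(eid))
            ref = bm.element_hu_integration(tiny, affine_volume, cfg, int(eid))
            assert v == pytest.approx(ref, rel=1e-12)

    def test_subvoxel_element_error_mode(self, affine_volume):
        tiny = bm.make_box_mesh((0.4, 0.4, 0.4), (1, 1, 1), origin=(5.3, 5.3, 5.3))
        cfg = _cfg(strategy="voxel_average", voxel_fallback="error")
        with pytest.raises(MappingError, match="no voxel center"):
            bm.element_hu_voxel_average(tiny, affine_volume, cfg, 1)


class TestVolumeIntegration:
    @pytest.mark.parametrize("refinement", [1, 2, 4])
    def test_constant_volume_any_refinement(self, constant_volume, cube_mesh, refinement):
        cfg = _cfg(strategy="volume_integration", refinement=refinement)
        assert bm.element_hu_integration(cube_mesh, constant_volume, cfg, 2) == 250.0

    @pytest.mark.parametrize("refinement", [1, 3])
    def test_affine_field_exact_at_any_refinement(self, affine_volume, cube_mesh, refinement):
        cfg = _cfg(refinement=refinement)
        for eid in cube_mesh.elem_ids:
            v = bm.element_hu_integration(cube_mesh, affine_volume, cfg, int(eid))
            expect = affine_hu(bm.element_centroid(cube_mesh, int(eid)))[0]
            assert v == pytest.approx(expect, rel=1e-9)

    def test_refinements_agree_on_affine_field(self, affine_volume, cube_mesh):
        v1 = bm.element_hu_integration(cube_mesh, affine_volume, _cfg(refinement=1), 1)
        v3 = bm.element_hu_integration(cube_mesh, affine_volume, _cfg(refinement=3), 1)
        assert v1 == pytest.approx(v3, abs=1e-9)

    def test_convergence_on_smooth_nonlinear_field(self):
        x = np.arange(20, dtype=float)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        hu = 800 * np.sin(0.4 * X) * np.cos(0.3 * Y) + 50 * Z
        vol = bm.CTVolume(hu=hu, spacing=(1, 1, 1), origin=(0, 0, 0))
        mesh = bm.make_box_mesh((5.0, 5.0, 5.0), (1, 1, 1), origin=(3.1, 4.2, 5.3))
        ref = bm.element_hu_integration(mesh, vol, _cfg(refinement=6), 1)
        errors = [
            abs(bm.element_hu_integration(mesh, vol, _cfg(refinement=r), 1) - ref)
            for r in (1, 2, 3)
        ]
        assert errors[0] > errors[1] > errors[2]


class TestMapMaterials:
    def test_constant_phantom_uniform_modulus(self, constant_volume, box_mesh):
        chain = bm.builtin_chain("pelvis_uniform_eq1_2")
        a, report = bm.map_materials(box_mesh, constant_volume, _cfg(chain=chain))
        expect = bm.hu_to_modulus(chain, 250.0)
        assert np.allclose(a.young_modulus, expect, rtol=1e-12)
        assert report.n_clamped_samples == 0

    @pytest.mark.parametrize("strategy", ["node_average", "volume_integration"])
    def test_affine_strategies_agree_exactly(self, affine_volume, box_mesh, strategy):
        a, _ = bm.map_materials(box_mesh, affine_volume, _cfg(strategy=strategy))
        expect = affine_hu(box_mesh.centroids())
        assert np.allclose(a.hu_mean, expect, rtol=1e-9)

    def test_hu_mean_bounded_by_volume_range(self, shell_volume, box_mesh):
        a, _ = bm.map_materials(box_mesh, shell_volume, _cfg(strategy="volume_integration"))
        lo, hi = shell_volume.hu_range()
        assert a.hu_mean.min() >= lo - 1e-12
        assert a.hu_mean.max() <= hi + 1e-12

    def test_deterministic_bitwise(self, shell_volume, box_mesh):
        a1, _ = bm.map_materials(box_mesh, shell_volume, _cfg())
        a2, _ = bm.map_materials(box_mesh, shell_volume, _cfg())
        assert np.array_equal(a1.hu_mean, a2.hu_mean)
        assert np.array_equal(a1.young_modulus, a2.young_modulus)

    @pytest.mark.parametrize("strategy", ["node_average", "voxel_average", "volume_integration"])
    def test_frame_invariance_under_shared_rigid_motion(self, strategy, affine_spec):
        vol = bm.make_volume(affine_spec)
        mesh = bm.make_box_mesh((6, 6, 6), (2, 2, 2), origin=(3, 3, 3))
        base, _ = bm.map_materials(mesh, vol, _cfg(strategy=strategy))
        angle = 0.7
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        t = np.array([4.0, -2.0, 1.5])
        moved_vol = bm.CTVolume(hu=vol.hu, spacing=vol.spacing,
                                origin=R @ vol.origin + t, orientation=R @ vol.orientation)
        cfg = _cfg(strategy=strategy,
                   transform=bm.RigidTransform(rotation=R, translation=t))
        moved, _ = bm.map_materials(mesh, moved_vol, cfg)
        assert np.allclose(moved.hu_mean, base.hu_mean, rtol=1e-9, atol=1e-9)
        assert np.allclose(moved.young_modulus, base.young_modulus, rtol=1e-9)

    def test_overhanging_mesh_warns_and_reports(self, constant_volume):
        mesh = bm.make_box_mesh((20, 4, 4), (5, 1, 1), origin=(-10, 1, 1))
        with pytest.warns(UserWarning, match="centroids"):
            a, report = bm.map_materials(mesh, constant_volume, _cfg())
        assert report.centroid_in_hull_fraction < 0.99
        assert report.n_clamped_samples > 0
        assert len(report.out_of_hull_elements) > 0

    def test_empty_mesh_rejected(self, constant_volume, cube_mesh):
        empty = bm.FEMesh(node_ids=cube_mesh.node_ids, coords=cube_mesh.coords,
                          elem_ids=np.array([], dtype=int),
                          conn=np.empty((0, 4), dtype=int))
        with pytest.raises(MappingError, match="no elements"):
            bm.map_materials(empty, constant_volume, _cfg())

    def test_modulus_average_order_differs_on_nonuniform_field(self, shell_volume, box_mesh):
        a_hu, _ = bm.map_materials(box_mesh, shell_volume, _cfg())
        a_mod, _ = bm.map_materials(
            box_mesh, shell_volume, _cfg(conversion_order="modulus_average")
        )
        # Jensen: averaging after the convex power law gives >= the default order
        assert np.all(a_mod.young_modulus >= a_hu.young_modulus - 1e-9)
        assert a_mod.young_modulus.max() > a_hu.young_modulus.max()

    def test_floor_counts_propagate(self, box_mesh):
        air = bm.make_volume(bm.PhantomSpec(kind="constant", params={"hu": -1000.0},
                                            dims=(16, 16, 16)))
        chain = bm.builtin_chain("pelvis_uniform_eq1_2")
        a, report = bm.map_materials(box_mesh, air, _cfg(chain=chain))
        assert np.allclose(a.young_modulus, chain.e_floor)
        assert report.floor_counts.rho_floored == box_mesh.n_elements
        assert report.floor_counts.e_floored == box_mesh.n_elements


class TestShellContrast:
    """Cortical/trabecular contrast on the conforming cubic-shell phantom."""

    @pytest.mark.parametrize("strategy", ["node_average", "voxel_average", "volume_integration"])
    def test_every_shell_element_stiffer_than_every_interior(
        self, conforming_shell_setup, strategy
    ):
        vol, mesh, shell, interior = conforming_shell_setup
        a, _ = bm.map_materials(mesh, vol, _cfg(strategy=strategy, refinement=2))
        E = a.young_modulus
        assert E[shell].min() > E[interior].max()

    def test_spherical_shell_contrast_in_the_bulk(self, shell_volume, shell_spec):
        # away from interfaces the spherical body shows the same contrast
        mesh = bm.make_box_mesh((14, 14, 14), (9, 9, 9), origin=(3, 3, 3))
        cent = mesh.centroids()
        r = np.linalg.norm(cent - shell_spec.params["center"], axis=1)
        margin = 1.0  # one element diameter clear of both interfaces
        shell = (r > shell_spec.params["r_inner"] + margin) & (
            r <= shell_spec.params["r_outer"] - margin
        )
        interior = r <= shell_spec.params["r_inner"] - margin
        a, _ = bm.map_materials(mesh, shell_volume, _cfg())
        assert a.young_modulus[shell].min() > a.young_modulus[interior].max()
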