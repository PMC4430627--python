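import math

import numpy as np
import pytest

from osseoquant import (
    PhantomSpec,
    aliasing_report,
    area_of,
    classify_shell,
    compute_bic3d,
    export_surface,
    extract_boundary_faces,
    generate_phantom,
    interface_faces,
)
from osseoquant.surface_bic import load_surface_area, triangle_count
from osseoquant.volume import BACKGROUND, BONE, IMPLANT, LabelVolume

from conftest import CLEAN, make_cylinder_labels


def _labels(arr, spacing=4.0):
    return LabelVolume(np.asarray(arr, dtype=np.uint8), spacing=spacing)


def brute_force_pair_faces(lab: np.ndarray, a: int, b: int) -> int:
    """Independent oracle: count 6-neighbour transitions a|b by axis diffs."""
    n = 0
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        left, right = lab[tuple(lo)], lab[tuple(hi)]
        n += int(((left == a) & (right == b)).sum())
        n += int(((left == b) & (right == a)).sum())
    return n


class TestBoundaryFaces:
    def test_single_voxel_cube(self):
        lab = np.zeros((3, 3, 3), dtype=np.uint8)
        lab[1, 1, 1] = IMPLANT
        faces = extract_boundary_faces(_labels(lab), IMPLANT)
        assert len(faces) == 6
        assert area_of(faces) == pytest.approx(6 * 16.0)

    def test_two_cubed_block(self):
        lab = np.zeros((4, 4, 4), dtype=np.uint8)
        lab[1:3, 1:3, 1:3] = IMPLANT
        assert len(extract_boundary_faces(_labels(lab), IMPLANT)) == 24

    def test_absent_material_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            extract_boundary_faces(_labels(np.zeros((3, 3, 3))), IMPLANT)

    def test_cylinder_staircase_ratio_approaches_4_over_pi(self):
        lv = make_cylinder_labels(radius=40, height=20, spacing=4.0)
        shell = classify_shell(extract_boundary_faces(lv, IMPLANT), lv)
        analytic = 2 * math.pi * (40 * 4.0) * (20 * 4.0)
        assert area_of(shell) / analytic == pytest.approx(4 / math.pi, abs=0.03)


class TestInterfaceFaces:
    def test_adjacent_pair_single_face(self):
        lab = np.zeros((3, 3, 4), dtype=np.uint8)
        lab[1, 1, 1] = IMPLANT
        lab[1, 1, 2] = BONE
        assert len(interface_faces(_labels(lab), IMPLANT, BONE)) == 1

    def test_separated_materials_empty(self):
        lab = np.zeros((3, 3, 5), dtype=np.uint8)
        lab[1, 1, 1] = IMPLANT
        lab[1, 1, 3] = BONE
        assert len(interface_faces(_labels(lab), IMPLANT, BONE)) == 0

    def test_embedded_implant_set_identity(self):
        """For an implant fully surrounded by bone, implant|bone interface =
        implant boundary (no border faces)."""
        lab = np.ones((6, 6, 6), dtype=np.uint8) * BONE
        lab[2:4, 2:4, 2:4] = IMPLANT
        lv = _labels(lab)
        boundary = extract_boundary_faces(lv, IMPLANT)
        inter = interface_faces(lv, IMPLANT, BONE)
        assert len(inter) == len(boundary) == 24

    def test_face_counts_match_brute_force_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            shape = tuple(rng.integers(4, 9, size=3))
            lab = rng.integers(0, 4, size=shape).astype(np.uint8)
            lv = _labels(lab)
            present = np.unique(lab)
            for a in present:
                for b in present:
                    if a == b:
                        continue
                    got = len(interface_faces(lv, int(a), int(b)))
                    assert got == brute_force_pair_faces(lab, int(a), int(b))


class TestClassifyShell:
    def test_cylinder_loses_exactly_the_end_disks(self):
        lv = make_cylinder_labels(radius=10, height=8, spacing=4.0)
        boundary = extract_boundary_faces(lv, IMPLANT)
        shell = classify_shell(boundary, lv)
        disk_voxels = int((lv.data[0] == IMPLANT).sum())
        assert len(boundary) - len(shell) == 2 * disk_voxels

    def test_sphere_loses_at_most_polar_slices(self):
        n = 25
        z, y, x = np.mgrid[:n, :n, :n]
        c = (n - 1) / 2
        lab = (((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= 10**2).astype(np.uint8) * IMPLANT
        lv = _labels(lab)
        boundary = extract_boundary_faces(lv, IMPLANT)
        shell = classify_shell(boundary, lv)
        zs = np.where((lab == IMPLANT).any(axis=(1, 2)))[0]
        removed = len(boundary) - len(shell)
        # removed faces live only in the 3-slice polar slabs
        polar = (
            (boundary.index[:, 0] <= zs.min() + 2) | (boundary.index[:, 0] >= zs.max() - 2)
        )
        assert 0 < removed <= int(polar.sum())

    def test_cone_shell_area_resolution_stable(self):
        """Retained lateral area / analytic slant area agrees within 2%
        between voxel sizes s and s/2."""
        ratios = []
        for vx in (60.0, 30.0):
            spec = PhantomSpec(contact_mode="full", voxel_size=vx, rng_seed=0, **CLEAN)
            _, labels, _ = generate_phantom(spec)
            r_top = spec.implant_max_diameter / 2
            r_bot = r_top - spec.implant_length * math.tan(math.radians(spec.implant_taper_angle))
            slant = math.hypot(spec.implant_length, r_top - r_bot)
            analytic = math.pi * (r_top + r_bot) * slant
            ratios.append(aliasing_report(labels, analytic))
        assert ratios[0] == pytest.approx(ratios[1], rel=0.02)


class TestAreaAndExport:
    def test_area_arithmetic(self):
        lab = np.zeros((3, 3, 3), dtype=np.uint8)
        lab[1, 1, 1] = IMPLANT
        faces = extract_boundary_faces(_labels(lab, spacing=4.0), IMPLANT)
        assert area_of(faces) == 96.0
        assert triangle_count(faces) == 12

    def test_area_additive_over_disjoint_subsets(self):
        lv = make_cylinder_labels(radius=6, height=5)
        faces = extract_boundary_faces(lv, IMPLANT)
        up = faces.subset(faces.axis == 0)
        rest = faces.subset(faces.axis != 0)
        assert area_of(up) + area_of(rest) == pytest.approx(area_of(faces))

    @pytest.mark.parametrize("ext", ["stl", "ply"])
    def test_export_round_trip(self, tmp_path, ext):
        lab = np.zeros((3, 3, 3), dtype=np.uint8)
        lab[1, 1, 1] = IMPLANT
        faces = extract_boundary_faces(_labels(lab, spacing=4.0), IMPLANT)
        path = tmp_path / f"cube.{ext}"
        export_surface(faces, path)
        n_tri, area = load_surface_area(path)
        assert n_tri == 12
        assert area == pytest.approx(area_of(faces))

    def test_export_empty_set(self, tmp_path):
        lv = make_cylinder_labels(radius=6, height=5)
        faces = extract_boundary_faces(lv, IMPLANT).subset(np.zeros(0, dtype=bool))
        faces = faces.subset(np.zeros(len(faces), dtype=bool))
        path = tmp_path / "empty.ply"
        export_surface(faces, path)
        assert path.exists()


class TestComputeBic3d:
    def test_full_contact_pva_100(self):
        spec = PhantomSpec(contact_mode="full", voxel_size=60.0, rng_seed=0, **CLEAN)
        _, labels, _ = generate_phantom(spec)
        assert compute_bic3d(labels).pVA == 100.0

    def test_no_contact_pva_0(self):
        spec = PhantomSpec(contact_mode="none", voxel_size=60.0, rng_seed=0, **CLEAN)
        _, labels, _ = generate_phantom(spec)
        assert compute_bic3d(labels).pVA == 0.0

    def test_sector_pva_matches_fraction(self, clean_sector_phantom):
        _, labels, true_f = clean_sector_phantom
        res = compute_bic3d(labels)
        assert res.pVA == pytest.approx(100 * true_f, abs=2.0)
        assert res.pVA == pytest.approx(50.0, abs=2.0)

    def test_invariants_on_random_grids(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 10:
            lab = rng.integers(0, 3, size=(6, 6, 6)).astype(np.uint8)
            lv = _labels(lab)
            if not (lab == IMPLANT).any():
                continue
            try:
                res = compute_bic3d(lv)
            except ValueError:
                continue
            assert 0.0 <= res.pVA <= 100.0
            assert res.eBIC_area <= res.pBIC_area
            assert res.triangle_count_eBIC == 2 * round(res.eBIC_area / lv.spacing**2)
            checked += 1

    def test_pva_resolution_invariant_on_clean_sector(self):
        vals = []
        for vx in (60.0, 30.0):
            spec = PhantomSpec(
                contact_mode="sector", contact_fraction=0.5, voxel_size=vx,
                rng_seed=2, **CLEAN
            )
            _, labels, _ = generate_phantom(spec)
            vals.append(compute_bic3d(labels).pVA)
        assert abs(vals[0] - vals[1]) <= 2.0


class TestAliasing:
    def test_flat_slab_ratio_is_one(self):
        lab = np.zeros((10, 8, 8), dtype=np.uint8)
        lab[2:8, 2:6, 2:6] = IMPLANT
        lv = _labels(lab, spacing=4.0)
        # lateral area of the box: perimeter x height
        analytic = (4 + 4 + 4 + 4) * 4.0 * 6 * 4.0
        assert aliasing_report(lv, analytic) == pytest.approx(1.0)

    def test_cone_ratio_matches_independent_face_count(self):
        """45°-half-angle cone: the shell ratio equals an independent direct
        count of 6-neighbour exposed faces, excluding the base plane."""
        n = 41
        z, y, x = np.mgrid[:n, :n, :n]
        c = (n - 1) / 2
        r_at = (n - 3) / 2 - z  # radius shrinks 1 voxel per slice: 45° slope
        cone = (np.hypot(y - c, x - c) <= r_at) & (r_at >= 5)  # truncated tip
        lab = cone.astype(np.uint8) * IMPLANT
        lv = _labels(lab, spacing=2.0)
        shell = classify_shell(extract_boundary_faces(lv, IMPLANT), lv)

        # oracle: direct neighbour count of exposed faces, minus the base cap
        exposed = 0
        padded = np.pad(lab, 1)
        for axis, orient in [(0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)]:
            shifted = np.roll(padded, -orient, axis=axis)[1:-1, 1:-1, 1:-1]
            exposed += int(((lab == IMPLANT) & (shifted != IMPLANT)).sum())
        zs = np.where(cone.any(axis=(1, 2)))[0]
        base_down = int(cone[zs.min()].sum()) + int(
            (cone[zs.min() + 1] & ~cone[zs.min()]).sum()
        )
        top_up = int(cone[zs.max()].sum()) + int(
            (cone[zs.max() - 1] & ~cone[zs.max()]).sum()
        )
        assert len(shell) == exposed - base_down - top_up
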