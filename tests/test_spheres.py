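import math

import numpy as np
import pytest

from hydrabind import (
    AnchorSpec,
    HydrationSphere,
    SoluteAtom,
    enclosed_hydration_energy,
    free_volume,
    place_sphere,
    switching,
)
from hydrabind.spheres import read_spheres_json, write_spheres_json

from conftest import lens_free_volume


def _atoms(*positions, radius=1.7):
    return [
        SoluteAtom(serial=i + 1, element="C", position=tuple(p), radius=radius)
        for i, p in enumerate(positions)
    ]


class TestPlacement:
    def test_centroid(self):
        atoms = _atoms((0, 0, 0), (2, 0, 0), (1, 3, 0))
        anchor = AnchorSpec("center_of_mass", [1, 2, 3])
        assert np.allclose(place_sphere(anchor, atoms), (1, 1, 0))

    def test_polar_hydrogen_collinear(self):
        atoms = _atoms((0, 0, 0), (1, 0, 0))
        anchor = AnchorSpec("polar_hydrogen", [1, 2], {"distance": 1.0})
        assert np.allclose(place_sphere(anchor, atoms), (2, 0, 0))

    def test_carbonyl_lone_pairs_mirror_symmetric(self):
        # C at origin, O along +x, reference atom defining the sp2 plane
        atoms = _atoms((0, 0, 0), (1.23, 0, 0), (-0.8, 1.2, 0))
        d = 2.5
        pos = {}
        for branch in (1, -1):
            anchor = AnchorSpec(
                "backbone_carbonyl", [1, 2, 3],
                {"distance": d, "angle": 120.0, "branch": branch},
            )
            pos[branch] = place_sphere(anchor, atoms)
        # mirror symmetry about the C=O (x) axis
        assert abs(pos[1][1] + pos[-1][1]) < 1e-9
        assert abs(pos[1][0] - pos[-1][0]) < 1e-9
        # C-O-site angle is 120 degrees
        o = np.array([1.23, 0, 0])
        v1 = np.array([0, 0, 0]) - o
        v2 = pos[1] - o
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert math.degrees(math.acos(cosang)) == pytest.approx(120.0, abs=1e-9)
        assert np.linalg.norm(pos[1] - o) == pytest.approx(d)

    def test_carboxylate_sites_on_both_oxygens(self):
        atoms = _atoms((0, 0, 0), (1.0, 0.8, 0), (1.0, -0.8, 0))
        p1 = place_sphere(
            AnchorSpec("sidechain_carboxylate", [1, 2, 3], {"oxygen": 1}), atoms
        )
        p2 = place_sphere(
            AnchorSpec("sidechain_carboxylate", [1, 2, 3], {"oxygen": 2}), atoms
        )
        assert np.allclose(p1[1], -p2[1], atol=1e-9)  # mirror across x axis

    def test_missing_anchor_atom_named_in_error(self):
        atoms = _atoms((0, 0, 0))
        with pytest.raises(KeyError, match="99"):
            place_sphere(AnchorSpec("center_of_mass", [99]), atoms)


class TestSwitching:
    def test_endpoints_and_midpoint(self):
        assert switching(0.1, 0.1, 0.5) == 0.0
        assert switching(0.5, 0.1, 0.5) == 1.0
        assert switching(0.3, 0.1, 0.5) == pytest.approx(0.5)
        assert switching(0.0, 0.1, 0.5) == 0.0
        assert switching(1.0, 0.1, 0.5) == 1.0

    def test_zero_derivative_at_thresholds(self):
        h = 1e-7
        for w0 in (0.1, 0.5):
            d = (switching(w0 + h, 0.1, 0.5) - switching(max(w0 - h, 0), 0.1, 0.5)) / (
                2 * h
            )
            assert abs(d) < 1e-6

    def test_monotone(self):
        ws = np.linspace(0, 1, 200)
        vals = [switching(w, 0.1, 0.5) for w in ws]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            switching(0.5, 0.6, 0.4)


class TestFreeVolume:
    def test_no_occluders_full_volume(self):
        v = free_volume((0, 0, 0), 1.4, [])
        assert v == pytest.approx(4 / 3 * math.pi * 1.4**3)

    def test_total_occlusion(self):
        occ = _atoms((0, 0, 0), radius=1.5)
        assert free_volume((0, 0, 0), 1.4, occ) == 0.0

    def test_partial_overlap_matches_lens_formula(self):
        R, r, d = 1.4, 1.7, 2.0
        occ = _atoms((d, 0, 0), radius=r)
        v = free_volume((0, 0, 0), R, occ, grid_spacing=0.1)
        expected = lens_free_volume(R, r, d)
        assert abs(v - expected) / (4 / 3 * math.pi * R**3) < 0.01

    def test_monotone_under_approach(self):
        R = 1.4
        prev = None
        for d in np.linspace(3.5, 0.0, 15):
            v = free_volume((0, 0, 0), R, _atoms((d, 0, 0)), grid_spacing=0.1)
            if prev is not None:
                assert v <= prev + 1e-9
            prev = v

    def test_probe_offset_shrinks_free_volume(self):
        occ = _atoms((2.5, 0, 0))
        v0 = free_volume((0, 0, 0), 1.4, occ, probe_offset=0.0)
        v1 = free_volume((0, 0, 0), 1.4, occ, probe_offset=0.5)
        assert v1 < v0


class TestEnclosedHydration:
    def test_open_sphere_contributes_full_weight(self):
        sphere = HydrationSphere(sphere_id=0, h_s=2.83, center=(0, 0, 0))
        dg, occ = enclosed_hydration_energy([sphere], [])
        assert dg == pytest.approx(2.83)
        assert occ[0].w_s == pytest.approx(1.0)
        assert occ[0].s_of_w == 1.0

    def test_fully_occluded_sphere_contributes_zero(self):
        sphere = HydrationSphere(sphere_id=0, h_s=2.83, center=(0, 0, 0))
        dg, occ = enclosed_hydration_energy([sphere], _atoms((0, 0, 0), radius=2.0))
        assert dg == 0.0
        assert occ[0].s_of_w == 0.0

    def test_additivity_over_spheres(self):
        s1 = HydrationSphere(sphere_id=0, h_s=1.27, center=(0, 0, 0))
        s2 = HydrationSphere(sphere_id=1, h_s=0.34, center=(10, 0, 0))
        dg_both, _ = enclosed_hydration_energy([s1, s2], [])
        assert dg_both == pytest.approx(1.61)
        ligand = _atoms((0, 0, 0), radius=2.0)
        dg_occ, _ = enclosed_hydration_energy([s1, s2], ligand)
        assert dg_occ == pytest.approx(0.34)
        dg_a, _ = enclosed_hydration_energy([s1], ligand)
        dg_b, _ = enclosed_hydration_energy([s2], ligand)
        assert dg_occ == pytest.approx(dg_a + dg_b)

    def test_anchored_sphere_on_structure(self):
        atoms = _atoms((0, 0, 0), (2, 0, 0), (1, 3, 0))
        sphere = HydrationSphere(
            sphere_id=0, h_s=1.0, anchor=AnchorSpec("center_of_mass", [1, 2, 3])
        )
        dg, occ = enclosed_hydration_energy([sphere], atoms)
        assert 0.0 <= occ[0].w_s <= 1.0

    def test_displacement_never_increases_dg_hs(self, toy_pocket):
        prev = None
        for ligand in toy_pocket.ligand_sets:
            dg, _ = enclosed_hydration_energy(
                toy_pocket.spheres, toy_pocket.pocket_atoms + ligand, grid_spacing=0.2
            )
            if prev is not None:
                assert dg <= prev + 1e-9
            prev = dg


def test_spheres_json_roundtrip(tmp_path):
    spheres = [
        HydrationSphere(sphere_id=0, h_s=2.83, center=(1, 2, 3)),
        HydrationSphere(
            sphere_id=1,
            h_s=1.27,
            anchor=AnchorSpec("polar_hydrogen", [5, 6], {"distance": 1.0}),
        ),
    ]
    path = tmp_path / "spheres.json"
    write_spheres_json(spheres, path)
    loaded = read_spheres_json(path)
    assert loaded[0].center == (1, 2, 3)
    assert loaded[1].anchor.anchoring_type == "polar_hydrogen"
    assert loaded[1].h_s == 1.27
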