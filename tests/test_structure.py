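"""Reference geometry: SES volume, MVEE, ellipsoid-of-revolution reduction."""

import math
import textwrap

import numpy as np
import pytest

from nanopulse.structure import (
    DEFAULT_RADIUS_NM,
    VDW_RADII_NM,
    AtomSet,
    Ellipsoid,
    ellipsoid_of_revolution,
    load_atoms,
    mvee,
    reference_shape_from_atoms,
    ses_volume,
)


def sphere_union_volume(r1, r2, d):
    """Analytic volume of the union of two spheres with center distance d."""
    v1 = 4 / 3 * math.pi * r1**3
    v2 = 4 / 3 * math.pi * r2**3
    if d >= r1 + r2:
        return v1 + v2
    if d <= abs(r1 - r2):
        return max(v1, v2)
    lens = (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )
    return v1 + v2 - lens


class TestSesVolume:
    def test_single_atom_is_a_sphere(self):
        r = 0.5
        atoms = AtomSet(np.zeros((1, 3)), np.array([r]))
        vol, surface = ses_volume(atoms, pitch=0.025)
        assert vol == pytest.approx(4 / 3 * math.pi * r**3, rel=0.03)
        dist = np.linalg.norm(surface, axis=1)
        assert np.all(np.abs(dist - r) < 0.06)

    def test_two_far_atoms_merge_probe_inaccessible_gap(self):
        # two spheres separated by a gap narrower than the probe: the SES
        # volume exceeds the bare union because the probe cannot enter
        r, gap = 0.4, 0.1
        d = 2 * r + gap
        atoms = AtomSet(
            np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), np.array([r, r])
        )
        vol, _ = ses_volume(atoms, probe_diameter=0.28, pitch=0.025)
        assert vol > sphere_union_volume(r, r, d)

    def test_overlapping_atoms_union_oracle(self):
        r, d = 0.5, 0.4
        atoms = AtomSet(
            np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), np.array([r, r])
        )
        # tiny probe: SES converges to the bare van der Waals union
        vol, _ = ses_volume(atoms, probe_diameter=0.01, pitch=0.025)
        assert vol == pytest.approx(sphere_union_volume(r, r, d), rel=0.04)

    def test_internal_cavity_counted(self):
        # shell of atoms around an empty center, with inter-atom gaps that a
        # water-sized probe cannot pass but a tiny probe can: the cavity (and
        # the gaps) belong to the SES solid only for the large probe
        pts = []
        n = 14
        golden = math.pi * (3 - math.sqrt(5))
        for i in range(n):
            z = 1 - 2 * (i + 0.5) / n
            rad = math.sqrt(1 - z * z)
            pts.append([math.cos(golden * i) * rad, math.sin(golden * i) * rad, z])
        shell = AtomSet(0.45 * np.asarray(pts), np.full(n, 0.19))
        vol_water, _ = ses_volume(shell, probe_diameter=0.28, pitch=0.02)
        vol_tiny, _ = ses_volume(shell, probe_diameter=0.02, pitch=0.02)
        cavity = 4 / 3 * math.pi * (0.45 - 0.19) ** 3
        assert vol_water - vol_tiny > 0.8 * cavity

    def test_validation(self):
        with pytest.raises(ValueError):
            AtomSet(np.zeros((0, 3)), np.zeros(0))
        with pytest.raises(ValueError):
            AtomSet(np.zeros((1, 3)), np.array([-1.0]))
        with pytest.raises(ValueError):
            AtomSet(np.zeros((2, 3)), np.array([1.0]))


class TestMvee:
    def test_sphere_recovery(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(500, 3))
        pts = 2.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        ell = mvee(pts, tolerance=1e-6)
        np.testing.assert_allclose(ell.semiaxes, 2.0, rtol=0.02)
        np.testing.assert_allclose(ell.center, 0.0, atol=0.05)

    def test_axis_aligned_ellipsoid(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(2000, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts = pts * np.array([3.0, 1.5, 1.0])
        ell = mvee(pts, tolerance=1e-6)
        np.testing.assert_allclose(ell.semiaxes, [3.0, 1.5, 1.0], rtol=0.03)

    def test_contains_all_points(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(300, 3)) * np.array([2.0, 1.0, 0.5]) + 1.0
        ell = mvee(pts, tolerance=1e-6)
        # Khachiyan is a (1 + eps)-approximation; allow a small margin
        assert np.all(ell.contains(pts, tol=0.02))

    def test_volume_property(self):
        ell = Ellipsoid(np.zeros(3), np.array([3.0, 2.0, 1.0]), np.eye(3))
        assert ell.volume == pytest.approx(4 / 3 * math.pi * 6.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            mvee(np.zeros((3, 3)))
        coplanar = np.column_stack(
            [np.arange(10.0), np.arange(10.0) ** 2, np.zeros(10)]
        )
        with pytest.raises(ValueError):
            mvee(coplanar)


class TestReduction:
    def test_prolate(self):
        m, a_eq = ellipsoid_of_revolution(np.array([4.0, 2.0, 2.0]))
        assert m == pytest.approx(2.0)
        assert a_eq == pytest.approx(2.0)

    def test_oblate(self):
        m, a_eq = ellipsoid_of_revolution(np.array([2.0, 2.0, 1.0]))
        assert m == pytest.approx(0.5)
        assert a_eq == pytest.approx(2.0)

    def test_sphere(self):
        m, _ = ellipsoid_of_revolution(np.array([1.0, 1.0, 1.0]))
        assert m == pytest.approx(1.0)


class TestLoadAtoms:
    PDB = textwrap.dedent(
        """\
        ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
        ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
        ATOM      3  C   ALA A   1      10.751   6.702  -4.093  1.00  0.00           C
        ATOM      4  O   ALA A   1       9.906   7.553  -4.379  1.00  0.00           O
        ATOM      5  SD  MET A   2       8.000   5.000  -3.000  1.00  0.00           S
        END
        """
    )

    def test_parses_and_converts_to_nm(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(self.PDB)
        atoms = load_atoms(str(p))
        assert atoms.centers.shape == (5, 3)
        np.testing.assert_allclose(atoms.centers[0], [1.1104, 0.6134, -0.6504])
        np.testing.assert_allclose(
            atoms.radii,
            [VDW_RADII_NM["N"], VDW_RADII_NM["C"], VDW_RADII_NM["C"],
             VDW_RADII_NM["O"], VDW_RADII_NM["S"]],
        )
        assert DEFAULT_RADIUS_NM == VDW_RADII_NM["C"]


class TestReferenceShape:
    def test_synthetic_prolate_cluster(self):
        # atoms filling a prolate ellipsoid (a, a, b) = (1, 1, 2) nm
        rng = np.random.default_rng(3)
        n = 800
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ball = dirs * rng.uniform(0.0, 1.0, n)[:, None] ** (1.0 / 3.0)
        pts = ball * np.array([1.0, 1.0, 2.0])
        atoms = AtomSet(pts, np.full(n, 0.17))
        m_ref, v_ref, ell = reference_shape_from_atoms(atoms, pitch=0.06)
        assert m_ref == pytest.approx(2.0, rel=0.2)
        # SES volume close to the generating ellipsoid volume
        assert v_ref == pytest.approx(4 / 3 * math.pi * 2.0, rel=0.35)
        assert ell.semiaxes[0] > ell.semiaxes[2]
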