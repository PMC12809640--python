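"""Reference geometry from protein structures.

Pipeline: atomic coordinates (PDB/mmCIF) -> solvent-excluded surface (SES)
volume on a voxel grid -> minimum-volume enclosing ellipsoid (MVEE) of the
surface -> reduction to an ellipsoid of revolution ``(a, a, b)`` giving the
reference axis ratio ``m_ref = b/a`` and volume ``V_ref`` (the SES volume).

The SES is computed by the rolling-probe morphology: voxelize the van der
Waals solid, dilate by the probe radius, flood-fill the exterior so internal
cavities and probe-inaccessible crevices stay solid, then erode by the probe
radius. Distances are computed with Euclidean distance transforms, which is
equivalent to spherical dilation/erosion on the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

# Bondi van der Waals radii, nm
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "F": 0.147,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
    "SE": 0.190,
    "FE": 0.156,
    "ZN": 0.139,
    "MG": 0.173,
    "CA": 0.231,
    "MN": 0.161,
    "CU": 0.140,
    "NA": 0.227,
    "K": 0.275,
}
DEFAULT_RADIUS_NM = 0.170
WATER_PROBE_DIAMETER_NM = 0.28


@dataclass
class AtomSet:
    centers: np.ndarray  # (n, 3) nm
    radii: np.ndarray  # (n,) nm

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if self.centers.shape[0] != self.radii.shape[0]:
            raise ValueError("centers and radii lengths differ")
        if self.centers.shape[0] < 1:
            raise ValueError("at least one atom is required")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")


@dataclass
class Ellipsoid:
    center: np.ndarray  # (3,) nm
    semiaxes: np.ndarray  # (3,) nm, descending
    rotation: np.ndarray  # (3, 3), columns are axis directions

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * float(np.prod(self.semiaxes))

    def contains(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        y = (points - self.center) @ self.rotation
        q = np.sum((y / self.semiaxes) ** 2, axis=1)
        return q <= 1.0 + tol


def ses_volume(
    atoms: AtomSet,
    probe_diameter: float = WATER_PROBE_DIAMETER_NM,
    pitch: float = 0.05,
) -> Tuple[float, np.ndarray]:
    """Solvent-excluded-surface volume (nm^3) and surface point cloud.

    ``pitch`` is the voxel edge in nm (default 0.05). Returns the SES volume
    (voxel count times voxel volume) and the centers of boundary voxels.
    """
    probe_r = probe_diameter / 2.0
    centers, radii = atoms.centers, atoms.radii
    lo = centers.min(axis=0) - radii.max() - probe_r - 2 * pitch
    hi = centers.max(axis=0) + radii.max() + probe_r + 2 * pitch
    shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 3)
    if np.any(shape < 3):
        raise ValueError("degenerate bounding box")

    # occupancy of the van der Waals solid, painted atom by atom over a
    # local sub-box (cheap relative to whole-grid distance fields)
    occ = np.zeros(shape, dtype=bool)
    for c, r in zip(centers, radii):
        ijk_lo = np.maximum(((c - r - lo) / pitch).astype(int), 0)
        ijk_hi = np.minimum(((c + r - lo) / pitch).astype(int) + 2, shape)
        axes = [np.arange(ijk_lo[d], ijk_hi[d]) * pitch + lo[d] - c[d] for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        ball = gx * gx + gy * gy + gz * gz <= r * r
        occ[
            ijk_lo[0] : ijk_hi[0], ijk_lo[1] : ijk_hi[1], ijk_lo[2] : ijk_hi[2]
        ] |= ball

    probe_vox = probe_r / pitch
    # dilate by the probe radius: voxels within probe_r of the vdW solid
    dist_out = ndimage.distance_transform_edt(~occ)
    dilated = dist_out <= probe_vox
    # flood-fill: keep only the exterior connected component of the
    # complement; interior cavities and crevices remain part of the solid
    free = ~dilated
    labels, _ = ndimage.label(free)
    border_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :]))
    border_labels |= set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
    border_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    border_labels.discard(0)
    exterior = np.isin(labels, sorted(border_labels))
    filled = ~exterior
    # erode by the probe radius: final SES solid
    dist_in = ndimage.distance_transform_edt(filled)
    ses = dist_in > probe_vox
    volume = float(np.count_nonzero(ses)) * pitch**3
    # boundary voxels: SES voxels with at least one non-SES 6-neighbour
    eroded = ndimage.binary_erosion(ses)
    boundary = ses & ~eroded
    idx = np.argwhere(boundary)
    surface = idx * pitch + lo
    return volume, surface


def mvee(points: np.ndarray, tolerance: float = 1e-4, max_iter: int = 2000) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid by Khachiyan's algorithm.

    Runs on the convex hull of the cloud (the MVEE depends only on hull
    vertices), so large surface clouds are fine.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points")
    try:
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except Exception as exc:  # coplanar/degenerate clouds
        raise ValueError(f"degenerate point cloud: {exc}") from exc
    n, d = pts.shape
    q = np.column_stack([pts, np.ones(n)]).T  # (4, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x = q @ np.diag(u) @ q.T
        m_vec = np.einsum("ij,ji->i", q.T, np.linalg.solve(x, q))
        j = int(np.argmax(m_vec))
        maximum = m_vec[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tolerance * 1e-3:
            u = new_u
            break
        u = new_u
    center = pts.T @ u
    # ellipsoid matrix: A = (1/d) * inv(P'UP - cc'), E = {x: (x-c)'A(x-c) <= 1}
    scatter = pts.T @ np.diag(u) @ pts - np.outer(center, center)
    a_mat = np.linalg.inv(scatter) / d
    eigval, eigvec = np.linalg.eigh(a_mat)
    semiaxes = 1.0 / np.sqrt(eigval)  # descending since eigval ascending
    order = np.argsort(semiaxes)[::-1]
    return Ellipsoid(center=center, semiaxes=semiaxes[order], rotation=eigvec[:, order])


def load_atoms(path: str) -> AtomSet:
    """Read atoms from a PDB or mmCIF file (first model, highest-occupancy
    altloc; hydrogens included only if present). Coordinates converted to nm."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    model = st[0]
    centers = []
    radii = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                el = atom.element.name.upper()
                centers.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(VDW_RADII_NM.get(el, DEFAULT_RADIUS_NM))
    if not centers:
        raise ValueError(f"no atoms found in {path}")
    return AtomSet(np.asarray(centers) / 10.0, np.asarray(radii))


def ellipsoid_of_revolution(semiaxes: np.ndarray) -> Tuple[float, float]:
    """Reduce general semiaxes (a1 >= a2 >= a3) to (m, equivalent a).

    The axis most distinct from the other two is taken as the polar axis b;
    the equatorial radius is the geometric mean of the remaining pair.
    """
    a1, a2, a3 = [float(v) for v in semiaxes]
    # candidate polar axes: compare separation from the other two
    d1 = abs(math.log(a1 / math.sqrt(a2 * a3)))
    d3 = abs(math.log(a3 / math.sqrt(a1 * a2)))
    if d1 >= d3:
        b, a_eq = a1, math.sqrt(a2 * a3)
    else:
        b, a_eq = a3, math.sqrt(a1 * a2)
    return b / a_eq, a_eq


def reference_shape(
    pdb_path: str,
    probe_diameter: float = WATER_PROBE_DIAMETER_NM,
    pitch: float = 0.05,
) -> Tuple[float, float, Ellipsoid]:
    """(m_ref, V_ref nm^3, MVEE) for a protein structure file."""
    atoms = load_atoms(pdb_path)
    volume, surface = ses_volume(atoms, probe_diameter=probe_diameter, pitch=pitch)
    ell = mvee(surface)
    m_ref, _ = ellipsoid_of_revolution(ell.semiaxes)
    return m_ref, volume, ell


def reference_shape_from_atoms(
    atoms: AtomSet,
    probe_diameter: float = WATER_PROBE_DIAMETER_NM,
    pitch: float = 0.05,
) -> Tuple[float, float, Ellipsoid]:
    volume, surface = ses_volume(atoms, probe_diameter=probe_diameter, pitch=pitch)
    ell = mvee(surface)
    m_ref, _ = ellipsoid_of_revolution(ell.semiaxes)
    return m_ref, volume, ell
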