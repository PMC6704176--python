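"""Low-level 3D geometry: angles, dihedrals, rigid transforms, superposition.

All coordinates are in Angstrom (Å). Rotations are proper (det = +1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex ``b`` of the triangle a-b-c, in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom D given three predecessors (NeRF construction).

    ``bond`` is the C-D distance (Å), ``angle`` the B-C-D angle (deg) and
    ``torsion`` the A-B-C-D dihedral (deg).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 50.0):
    """A uniformly random rotation and a random translation (Å)."""
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-max_translation, max_translation, size=3)
    return rot, trans


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid superposition of a mobile onto a reference set.

    ``transform(x) = x @ rotation.T + translation`` maps mobile coordinates
    onto the reference frame.
    """
    rotation: np.ndarray   # 3x3, det +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float            # Å, after the fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal (Kabsch) superposition of ``mobile`` onto ``reference``.

    Both arrays are (n, 3) with n >= 3 and must not be collinear.
    """
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mob_c = (w[:, None] * mob).sum(axis=0) / wsum
    ref_c = (w[:, None] * ref).sum(axis=0) / wsum
    mob0 = mob - mob_c
    ref0 = ref - ref_c
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    rot, _ = Rotation.align_vectors(ref0, mob0, weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    fitted = mob @ R.T + t
    rmsd = float(np.sqrt((w * ((fitted - ref) ** 2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_raw(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between two matching coordinate sets, no fitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit eigenvector of largest variance of a point cloud."""
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    return axis / np.linalg.norm(axis)
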