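"""Vectorised geometry primitives shared across the package.

All routines broadcast over leading axes so that whole ensembles (or whole
batches of frames) are processed in single numpy calls.  Distances are in
Angstrom, angles in degrees at the API surface (converted internally).
"""
from __future__ import annotations

import numpy as np


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle (degrees, in (-180, 180]) for four points.

    Uses the standard projection formulation; broadcasts over leading axes.
    """
    b0 = np.asarray(p0, float) - p1
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float | np.ndarray, angle_deg: float | np.ndarray,
               torsion_deg: np.ndarray) -> np.ndarray:
    """Place a fourth point from internal coordinates (NeRF construction).

    The new point ``d`` satisfies |c-d| = ``bond``, angle(b,c,d) =
    ``angle_deg`` and torsion(a,b,c,d) = ``torsion_deg``.
    """
    tor = np.radians(np.asarray(torsion_deg, float))
    ang = np.radians(np.broadcast_to(np.asarray(angle_deg, float), tor.shape))
    bln = np.broadcast_to(np.asarray(bond, float), tor.shape)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    local = np.stack([-bln * np.cos(ang),
                      bln * np.sin(ang) * np.cos(tor),
                      bln * np.sin(ang) * np.sin(tor)], axis=-1)
    return c + (local[..., 0:1] * bc + local[..., 1:2] * m
                + local[..., 2:3] * n)


def kabsch_rmsd_one_to_many(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Minimum RMSD of ``x`` (A, 3) against each structure in ``ys`` (n, A, 3)
    after optimal superposition (proper rotations only).

    Batched Kabsch: the optimal rotation is built from the SVD of the
    covariance (with the smallest singular direction flipped when the
    orthogonal optimum would be a reflection) and the deviation is then
    measured explicitly, which keeps rigid-copy RMSDs at machine precision
    instead of suffering the cancellation of the closed-form expression.
    """
    x = np.asarray(x, float)
    ys = np.asarray(ys, float)
    single = ys.ndim == 2
    if single:
        ys = ys[None]
    n_atoms = x.shape[0]
    if n_atoms < 3:
        raise ValueError("superposition requires at least 3 atoms")
    xc = x - x.mean(axis=0)
    yc = ys - ys.mean(axis=1, keepdims=True)
    # covariance per pair: (n, 3, 3), H = Y_c^T X_c
    cov = np.einsum("nai,aj->nij", yc, xc)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    u[:, :, 2] *= d[:, None]
    rot = u @ vt
    aligned = np.einsum("nai,nij->naj", yc, rot)
    diff = aligned - xc
    out = np.sqrt(np.einsum("naj,naj->n", diff, diff) / n_atoms)
    return out[0] if single else out


def pairwise_min_distance(coords: np.ndarray, min_gap: int = 2) -> np.ndarray:
    """Per-frame minimum distance over atom pairs separated by >= min_gap
    positions along the chain.  ``coords``: (frames, atoms, 3)."""
    n = coords.shape[-2]
    iu = np.triu_indices(n, k=min_gap)
    diff = coords[..., iu[0], :] - coords[..., iu[1], :]
    d2 = np.sum(diff * diff, axis=-1)
    return np.sqrt(d2.min(axis=-1))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (3, 3)."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix()
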