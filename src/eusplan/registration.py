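"""Rigid landmark-to-structure registration.

Intra-procedure landmarks are not paired with specific pre-procedure
points — only with a whole structure (an organ surface or a vessel/duct
centreline, both represented as point clouds).  Registration therefore
alternates, as in iterative closest point (ICP), between assigning each
landmark its nearest point *within its own labelled structure* and solving
the closed-form least-squares rigid transform, starting from a stochastic
correspondence (a random structure point per landmark) and keeping the best
of several restarts.  The label constraint on correspondences is what
distinguishes the method from plain ICP.

The inner machinery is batched: many (restart x Monte-Carlo-draw) chains
iterate simultaneously through stacked 3x3 SVDs and shared k-d-tree
queries, which is what makes thousand-draw TRE simulations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import AnatomyModel, Structure


class UnderdeterminedError(ValueError):
    """Fewer than three (or degenerate) landmark correspondences."""


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t (R orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        tr = np.clip((np.trace(self.rotation) - 1) / 2, -1.0, 1.0)
        return float(np.degrees(np.arccos(tr)))


@dataclass(frozen=True)
class LabeledLandmark:
    """An intra-procedure point tagged with its pre-procedure structure."""

    point: np.ndarray
    structure_label: int


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_mm: float
    iterations: int
    converged: bool
    rms_history: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# closed-form rigid least squares (Kabsch / Procrustes via SVD)

def _solve_rigid_batch(moving: np.ndarray, fixed: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transforms for stacked correspondences.

    moving, fixed: (C, L, 3).  Returns R: (C, 3, 3), t: (C, 3) minimising
    sum ||R m + t - f||^2 per chain, reflections excluded.
    """
    cm = moving.mean(axis=1, keepdims=True)
    cf = fixed.mean(axis=1, keepdims=True)
    H = np.einsum("clm,cln->cmn", moving - cm, fixed - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("cmn,cnk->cmk", Vt.transpose(0, 2, 1),
                                        U.transpose(0, 2, 1))))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("cmn,cnk,ckl->cml", Vt.transpose(0, 2, 1), D,
                  U.transpose(0, 2, 1))
    t = cf[:, 0, :] - np.einsum("cmn,cn->cm", R, cm[:, 0, :])
    return R, t


def solve_rigid(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform for paired points.

    Needs at least three non-collinear pairs for a unique six-DOF solution.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("moving and fixed must be matching (N, 3) arrays")
    if len(moving) < 3:
        raise UnderdeterminedError("need at least 3 point pairs")
    centered = moving - moving.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise UnderdeterminedError("points are collinear")
    R, t = _solve_rigid_batch(moving[None], fixed[None])
    return RigidTransform(R[0], t[0])


def closest_point(p: np.ndarray, s: Structure) -> tuple[np.ndarray, float]:
    """Nearest structure point to ``p`` (exhaustive scan; ties broken by the
    lowest point index)."""
    d = np.linalg.norm(s.points - np.asarray(p, dtype=float), axis=1)
    i = int(np.argmin(d))
    return s.points[i], float(d[i])


# ---------------------------------------------------------------------------
# batched label-constrained ICP

def _group_by_label(labels: np.ndarray) -> dict[int, np.ndarray]:
    return {int(lab): np.flatnonzero(labels == lab)
            for lab in np.unique(labels)}


def icp_batch(points: np.ndarray, labels: np.ndarray, anatomy: AnatomyModel,
              rng: np.random.Generator, *, n_starts: int = 10,
              tol: float = 1e-4, max_iter: int = 100
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Run label-constrained ICP for a batch of landmark sets.

    points: (D, L, 3) — D independent landmark sets (Monte-Carlo draws)
    sharing the label vector ``labels`` (L,).  Each draw runs ``n_starts``
    chains from independent random correspondences; the best (lowest final
    RMS) chain per draw wins.

    Returns (R: (D,3,3), t: (D,3), rms: (D,), history: (iters+1, D*n_starts),
    iterations).  ``history`` rows are the per-chain RMS after each rigid
    solve, monotone non-increasing down the rows.
    """
    points = np.asarray(points, dtype=float)
    D, L, _ = points.shape
    if L < 3:
        raise UnderdeterminedError(
            "at least 3 landmarks are required for a 6-DOF rigid transform")
    groups = _group_by_label(np.asarray(labels))
    for lab in groups:
        if lab not in anatomy.structures:
            raise KeyError(f"landmark references unknown structure {lab}")

    C = D * n_starts
    m = np.repeat(points, n_starts, axis=0)            # (C, L, 3)
    fixed = np.empty_like(m)
    for lab, idx in groups.items():
        cloud = anatomy.structures[lab].points
        pick = rng.integers(0, len(cloud), size=(C, len(idx)))
        fixed[:, idx, :] = cloud[pick]

    history = []
    R, t = _solve_rigid_batch(m, fixed)
    it = 0
    prev = None
    for it in range(1, max_iter + 1):
        x = np.einsum("cmn,cln->clm", R, m) + t[:, None, :]
        for lab, idx in groups.items():
            tree = anatomy.kdtree(lab)
            cloud = anatomy.structures[lab].points
            _, nn = tree.query(x[:, idx, :].reshape(-1, 3))
            fixed[:, idx, :] = cloud[nn].reshape(C, len(idx), 3)
        rms = np.sqrt(np.mean(np.sum((x - fixed) ** 2, axis=2), axis=1))
        history.append(rms)
        if prev is not None and np.max(prev - rms) < tol:
            break
        prev = rms
        R, t = _solve_rigid_batch(m, fixed)
    hist = np.array(history)
    final = hist[-1].reshape(D, n_starts)
    best = np.argmin(final, axis=1)
    sel = np.arange(D) * n_starts + best
    return R[sel], t[sel], final[np.arange(D), best], hist, it


def register(landmarks: list[LabeledLandmark], anatomy: AnatomyModel, *,
             n_starts: int = 10, seed: int | np.random.Generator = 0,
             tol: float = 1e-4, max_iter: int = 100) -> RegistrationResult:
    """Register one landmark set to the anatomy (best of ``n_starts``).

    Each restart assigns every landmark a random point of its own structure,
    solves the closed-form rigid transform, then iterates nearest-point
    reassignment (restricted to the landmark's structure) and re-solving
    until the RMS improvement drops below ``tol`` mm.
    """
    if len(landmarks) < 3:
        raise UnderdeterminedError(
            "at least 3 landmarks are required for a 6-DOF rigid transform")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pts = np.array([lm.point for lm in landmarks], dtype=float)[None]
    labels = np.array([lm.structure_label for lm in landmarks])
    R, t, rms, hist, iters = icp_batch(pts, labels, anatomy, rng,
                                       n_starts=n_starts, tol=tol,
                                       max_iter=max_iter)
    best_col = int(np.argmin(hist[-1]))
    return RegistrationResult(
        transform=RigidTransform(R[0], t[0]), rms_mm=float(rms[0]),
        iterations=iters, converged=iters < max_iter,
        rms_history=hist[:, best_col])
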