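"""Rigid superimposition of T1 tooth models onto T0.

Two stages, mirroring how paired surface scans are aligned in practice:
a point-based pre-alignment from a handful of manually matched landmarks
(Kabsch / orthogonal Procrustes, no scaling, no reflection), followed by
a global best-fit refinement with point-to-point ICP using nearest-
neighbour correspondences and robust rejection of outlying matches —
the resorbed apical region behaves as a partial outlier and must not
drag the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import TriangleMesh, ValidationError

__all__ = [
    "RigidTransform",
    "IcpParams",
    "RegistrationReport",
    "RegistrationError",
    "landmark_align",
    "icp_register",
    "apply_transform",
]


class RegistrationError(Exception):
    """ICP could not establish a usable correspondence set."""

    def __init__(self, message: str, report: "RegistrationReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm). det(R) = +1 always."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValidationError(f"rotation not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("reflection is not a rigid motion")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass
class IcpParams:
    """Best-fit refinement settings (defaults give sub-resolution accuracy)."""

    max_iterations: int = 100
    tolerance: float = 1e-5  # mm, RMS-change stopping criterion
    n_samples: int = 5000  # source vertices sampled (all if fewer)
    rejection_ratio: float = 3.0  # reject matches beyond ratio x median
    seed: int = 0


@dataclass
class RegistrationReport:
    initial_rms: float = float("nan")
    final_rms: float = float("nan")
    iterations: int = 0
    converged: bool = False
    rms_history: list = field(default_factory=list)


def landmark_align(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping source landmarks onto target.

    Kabsch/Procrustes solution via SVD with the reflection correction;
    no scaling. Requires at least three non-collinear matched points.
    """
    src = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    dst = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if len(src) != len(dst):
        raise ValidationError("landmark sets must be matched 1:1")
    if len(src) < 3:
        raise ValidationError("at least 3 matched landmarks required")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    s0, d0 = src - sc, dst - dc
    sing = np.linalg.svd(s0, compute_uv=False)
    if sing[1] <= 1e-9 * max(sing[0], 1.0):
        raise ValidationError("landmarks are collinear; rotation undetermined")
    h = s0.T @ d0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, dc - r @ sc)


def apply_transform(obj, t: RigidTransform):
    """Transformed copy of a TriangleMesh or an (n,3) point array."""
    if isinstance(obj, TriangleMesh):
        return TriangleMesh(t.apply(obj.vertices), obj.faces.copy(), obj.provenance)
    return t.apply(obj)


def icp_register(
    source: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform | None = None,
    params: IcpParams | None = None,
) -> tuple[RigidTransform, RegistrationReport]:
    """Point-to-point ICP of ``source`` onto ``target``.

    Correspondences are nearest target vertices via a KD-tree; matches
    farther than ``rejection_ratio`` x the median distance are dropped
    each iteration. Returns the composed transform (init then
    refinement) and a report whose RMS history is non-increasing over
    accepted iterations.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValidationError("both meshes must be non-empty")
    params = params or IcpParams()
    t_total = init or RigidTransform.identity()

    rng = np.random.default_rng(params.seed)
    pts = source.vertices
    if len(pts) > params.n_samples:
        pts = pts[rng.choice(len(pts), params.n_samples, replace=False)]
    tree = cKDTree(target.vertices)

    moved = t_total.apply(pts)
    d, _ = tree.query(moved)
    report = RegistrationReport(initial_rms=float(np.sqrt(np.mean(d**2))))
    rms_prev = report.initial_rms
    report.rms_history.append(rms_prev)

    for it in range(params.max_iterations):
        d, idx = tree.query(moved)
        med = float(np.median(d))
        keep = d <= max(params.rejection_ratio * med, 1e-9)
        if keep.sum() < 3:
            report.final_rms = rms_prev
            report.iterations = it
            raise RegistrationError(
                "fewer than 3 correspondences within the rejection radius", report
            )
        delta = landmark_align(moved[keep], target.vertices[idx[keep]])
        moved_new = delta.apply(moved)
        d_new, _ = tree.query(moved_new)
        rms_new = float(np.sqrt(np.mean(d_new**2)))
        if rms_new > rms_prev + 1e-15:
            # update would worsen the fit; stop at the current optimum
            report.converged = True
            break
        moved = moved_new
        t_total = delta.compose(t_total)
        report.iterations = it + 1
        report.rms_history.append(rms_new)
        if rms_prev - rms_new < params.tolerance:
            report.converged = True
            rms_prev = rms_new
            break
        rms_prev = rms_new

    report.final_rms = rms_prev
    return t_total, report
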