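"""Rigid pose estimation between occlusal records in a shared maxillary frame.

The excursive records and the reference (MIP) record are meshes of one rigid
body — the mandibular arch — expressed in the same coordinate frame anchored
to the fixed maxillary arch.  This module recovers, per record, the rigid
transform carrying the MIP mesh onto that record.

Two routes exist.  When the meshes still share vertex ordering (the usual case
for duplicated scanner projects), the closed-form least-squares fit
(:func:`kabsch`) on the shared vertices is exact.  When correspondence is
broken (remeshed exports), :func:`icp` recovers it iteratively from an
identity initialization, which suffices because excursive movements are
millimetre-scale in the shared frame.

Reflections are never returned: the smallest singular direction is
sign-corrected so every estimated rotation has determinant +1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._quaternion import (
    quat_canonical,
    quat_conjugate,
    quat_from_matrix,
    quat_multiply,
    quat_normalize,
    quat_rotation_angle,
    quat_to_matrix,
)
from .errors import RegistrationError
from .mesh_io import Correspondence, PoseLabel, TriangleMesh, check_correspondence

__all__ = [
    "ICPResult",
    "KabschResult",
    "PoseSet",
    "RigidTransform",
    "estimate_pose_set",
    "icp",
    "kabsch",
    "kabsch_fit",
    "rebase_anchor",
    "rotation_angle_between",
]


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """A proper rigid motion: unit quaternion ``(w, x, y, z)`` plus a
    translation vector in millimetres.

    The quaternion is normalized and sign-canonicalized (``w >= 0``, ties
    broken by the first nonzero component) on construction, so two transforms
    representing the same motion compare equal component-wise.
    """

    quaternion: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        q = quat_canonical(quat_normalize(self.quaternion))
        t = np.asarray(self.translation, dtype=np.float64)
        if t.shape != (3,):
            raise ValueError(f"translation must have shape (3,), got {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("translation has non-finite components")
        q.setflags(write=False)
        t = t.copy()
        t.setflags(write=False)
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(quat_from_matrix(rotation), translation)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (4, 4):
            raise ValueError(f"homogeneous matrix must be 4x4, got {matrix.shape}")
        return cls(quat_from_matrix(matrix[:3, :3]), matrix[:3, 3])

    @property
    def rotation_matrix(self) -> np.ndarray:
        return quat_to_matrix(self.quaternion)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix, row-major, translation in the last column."""
        out = np.eye(4)
        out[:3, :3] = self.rotation_matrix
        out[:3, 3] = self.translation
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation_matrix.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        q = quat_multiply(self.quaternion, other.quaternion)
        t = self.apply(other.translation)
        return RigidTransform(q, t)

    def inverse(self) -> "RigidTransform":
        q_inv = quat_conjugate(self.quaternion)
        t_inv = -(quat_to_matrix(q_inv) @ self.translation)
        return RigidTransform(q_inv, t_inv)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians, in [0, pi]."""
        return quat_rotation_angle(self.quaternion)

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return (
            rotation_angle_between(self, other) <= atol
            and float(np.linalg.norm(self.translation - other.translation)) <= atol
        )


def rotation_angle_between(a: RigidTransform, b: RigidTransform) -> float:
    """Angle in radians of the relative rotation carrying ``a`` onto ``b``."""
    rel = quat_multiply(quat_conjugate(a.quaternion), b.quaternion)
    return quat_rotation_angle(rel)


@dataclass(frozen=True)
class KabschResult:
    transform: RigidTransform
    rms: float
    degenerate: bool  # True when the point cloud is (near-)collinear


@dataclass(frozen=True)
class ICPResult:
    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool


def kabsch_fit(source_points: np.ndarray, target_points: np.ndarray) -> KabschResult:
    """Closed-form least-squares rigid fit of corresponded point sets.

    Centers both sets on their centroids, estimates the rotation by SVD of the
    cross-covariance (flipping the smallest singular direction if needed so the
    determinant is +1 — no reflections), then recovers the translation.

    Near-collinear configurations are solved anyway but flagged ``degenerate``;
    a real dental arch never triggers this.
    """
    src = np.asarray(source_points, dtype=np.float64)
    tgt = np.asarray(target_points, dtype=np.float64)
    if src.ndim != 2 or src.shape[1] != 3 or tgt.shape != src.shape:
        raise RegistrationError(
            f"point sets must both have shape (n, 3); got {src.shape} and {tgt.shape}"
        )
    if len(src) < 3:
        raise RegistrationError(f"need at least 3 point pairs, got {len(src)}")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(tgt))):
        raise RegistrationError("point sets contain non-finite coordinates")
    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    src_c = src - c_src
    tgt_c = tgt - c_tgt
    spread = float(np.linalg.norm(src_c))
    if spread == 0.0:
        raise RegistrationError("source points are all coincident; rotation is undefined")
    h = src_c.T @ tgt_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = c_tgt - rotation @ c_src
    transform = RigidTransform.from_rotation_translation(rotation, translation)
    residuals = transform.apply(src) - tgt
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    # rank < 2 of the centered cloud leaves the rotation about the line free
    degenerate = bool(s[1] <= 1e-9 * max(s[0], 1e-300))
    return KabschResult(transform=transform, rms=rms, degenerate=degenerate)


def kabsch(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``source_points`` onto
    ``target_points`` (corresponded, equal length >= 3).  See :func:`kabsch_fit`
    for the residual and degeneracy flag."""
    return kabsch_fit(source_points, target_points).transform


def icp(
    source: TriangleMesh,
    target: TriangleMesh,
    max_iterations: int = 50,
    convergence_tol: float = 1e-8,
) -> ICPResult:
    """Iterative closest point on mesh vertices, initialized at identity.

    Alternates nearest-neighbour pairing (KD-tree on the target vertices) with
    the closed-form rigid fit until the RMS residual change drops below
    ``convergence_tol`` (mm) or ``max_iterations`` is reached.  Failure to
    converge is reported in the result flag, not raised.
    """
    if max_iterations < 1:
        raise RegistrationError("max_iterations must be >= 1")
    source.require_usable()
    target.require_usable()
    src = source.vertices
    tgt = target.vertices
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(tgt))):
        raise RegistrationError("meshes contain non-finite coordinates")
    tree = cKDTree(tgt)
    transform = RigidTransform.identity()
    prev_rms = np.inf
    rms = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        _, idx = tree.query(transform.apply(src))
        transform = kabsch(src, tgt[idx])
        residuals = transform.apply(src) - tgt[idx]
        rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
        if abs(prev_rms - rms) < convergence_tol:
            converged = True
            break
        prev_rms = rms
    return ICPResult(transform=transform, rms=rms, iterations=iterations, converged=converged)


@dataclass(frozen=True, eq=False)
class PoseSet:
    """The four labelled static records as transforms relative to MIP.

    ``poses[MIP]`` is always the identity; ``provenance`` records how each
    non-reference pose was estimated (``"corresponded"`` or ``"icp"``, plus a
    degeneracy / non-convergence note when applicable).  ``residuals`` carries
    the per-label RMS fit error in millimetres.
    """

    reference_mesh: TriangleMesh
    poses: Mapping[PoseLabel, RigidTransform]
    provenance: Mapping[PoseLabel, str]
    residuals: Mapping[PoseLabel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [label for label in PoseLabel if label not in self.poses]
        if missing:
            raise RegistrationError(
                "pose set missing labels: " + ", ".join(m.value for m in missing)
            )
        mip = self.poses[PoseLabel.MIP]
        if mip.rotation_angle() > 1e-12 or mip.translation_norm() > 1e-12:
            raise RegistrationError("the MIP pose must be the identity transform")


def estimate_pose_set(
    meshes: Mapping[PoseLabel, TriangleMesh],
    *,
    icp_enabled: bool = True,
    icp_max_iterations: int = 50,
    icp_tolerance: float = 1e-8,
    vertex_indices: Sequence[int] | None = None,
) -> PoseSet:
    """Estimate the transform from the MIP record to each excursive record.

    Per non-MIP label the route is chosen by :func:`check_correspondence`: the
    exact corresponded fit on the shared vertices when topology matches, the
    ICP fallback otherwise (or an error if ``icp_enabled`` is False).  All
    shared vertices are used by default; ``vertex_indices`` restricts the
    corresponded fit to a tracked subset.
    """
    missing = [label for label in PoseLabel if label not in meshes]
    if missing:
        raise RegistrationError(
            "missing occlusal record(s): " + ", ".join(m.value for m in missing)
        )
    reference = meshes[PoseLabel.MIP]
    reference.require_usable()
    idx = None
    if vertex_indices is not None:
        idx = np.asarray(vertex_indices, dtype=np.int64)
        if len(idx) < 3:
            raise RegistrationError("vertex_indices must select at least 3 vertices")

    poses: dict[PoseLabel, RigidTransform] = {PoseLabel.MIP: RigidTransform.identity()}
    provenance: dict[PoseLabel, str] = {PoseLabel.MIP: "reference"}
    residuals: dict[PoseLabel, float] = {PoseLabel.MIP: 0.0}
    for label in (
        PoseLabel.PROTRUSIVE,
        PoseLabel.RIGHT_LATEROTRUSIVE,
        PoseLabel.LEFT_LATEROTRUSIVE,
    ):
        mesh = meshes[label]
        mesh.require_usable()
        verdict = check_correspondence(reference, mesh)
        if verdict is Correspondence.CORRESPONDED:
            src = reference.vertices if idx is None else reference.vertices[idx]
            tgt = mesh.vertices if idx is None else mesh.vertices[idx]
            fit = kabsch_fit(src, tgt)
            poses[label] = fit.transform
            residuals[label] = fit.rms
            provenance[label] = "corresponded" + (" (degenerate)" if fit.degenerate else "")
        else:
            if not icp_enabled:
                raise RegistrationError(
                    f"{label.value}: mesh is not corresponded with the MIP record "
                    "and the ICP fallback is disabled"
                )
            result = icp(
                reference,
                mesh,
                max_iterations=icp_max_iterations,
                convergence_tol=icp_tolerance,
            )
            poses[label] = result.transform
            residuals[label] = result.rms
            provenance[label] = "icp" + ("" if result.converged else " (not converged)")
    return PoseSet(
        reference_mesh=reference, poses=poses, provenance=provenance, residuals=residuals
    )


def rebase_anchor(t: RigidTransform) -> RigidTransform:
    """Invert a transform whose anchor is the wrong arch.

    A record captured with the mandible as the registration anchor expresses
    maxillary motion relative to the mandible; the group inverse converts it to
    mandibular motion relative to the fixed maxilla, which is the frame the
    rest of the pipeline assumes.
    """
    return t.inverse()
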