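"""Pose interpolation and trajectory assembly.

Between the reference (MIP) pose and each excursive endpoint the pipeline
inserts a user-defined number of transitional frames — "quantified points" —
at evenly spaced fractions, endpoints excluded: ``n`` intermediate poses sit
at fractions ``k / (n + 1)`` for ``k = 1..n``, and the static records
themselves are emitted separately as keyframes.  Rotation is interpolated by
shortest-arc SLERP (constant angular speed), translation linearly; the two
are deliberately decoupled.

The assembled trajectory is a closed loop through the excursive envelope,
returning to MIP between strokes, with a uniform frame interval.  No easing
or velocity profile is applied; the trajectory is a simplified, piecewise
interpolation between static extremes, not a neuromuscular simulation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mesh_io import PoseLabel, TriangleMesh
from .registration import PoseSet, RigidTransform

__all__ = [
    "DEFAULT_SEQUENCE",
    "MotionTrajectory",
    "TrajectoryFrame",
    "apply_pose",
    "build_trajectory",
    "interpolate_pose",
    "interpolate_segment",
]

#: Default playback order: each excursive stroke leaves from and returns to MIP.
DEFAULT_SEQUENCE: tuple[PoseLabel, ...] = (
    PoseLabel.MIP,
    PoseLabel.PROTRUSIVE,
    PoseLabel.MIP,
    PoseLabel.RIGHT_LATEROTRUSIVE,
    PoseLabel.MIP,
    PoseLabel.LEFT_LATEROTRUSIVE,
    PoseLabel.MIP,
)


@dataclass(frozen=True)
class TrajectoryFrame:
    time: float  # seconds
    pose: RigidTransform
    segment_label: str  # keyframe label, or "A->B" for transitional frames


@dataclass(frozen=True, eq=False)
class MotionTrajectory:
    """An ordered, time-parameterized pose sequence tracing the excursive
    envelope.  ``keyframe_indices`` locate the static records within
    ``frames``; keyframe poses are the stored :class:`PoseSet` transforms,
    not re-derived copies."""

    frames: tuple[TrajectoryFrame, ...]
    keyframe_indices: tuple[int, ...]
    frames_per_segment: int

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        times = np.array([f.time for f in self.frames])
        if not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        for i in self.keyframe_indices:
            if not 0 <= i < len(self.frames):
                raise ValueError(f"keyframe index {i} out of range")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return self.frames[-1].time - self.frames[0].time


def interpolate_pose(a: RigidTransform, b: RigidTransform, t: float) -> RigidTransform:
    """Pose at fraction ``t`` in [0, 1] between ``a`` and ``b``.

    Shortest-arc SLERP for the rotation (the quaternions are sign-aligned so
    their dot product is non-negative) and linear interpolation for the
    translation.  ``t = 0`` and ``t = 1`` return the endpoint values exactly.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"interpolation fraction must be in [0, 1], got {t}")
    if t == 0.0:
        return a
    if t == 1.0:
        return b
    qa = a.quaternion
    qb = b.quaternion
    dot = float(qa @ qb)
    if dot < 0.0:
        qb = -qb
        dot = -dot
    if dot > 1.0 - 1e-12:
        # nearly parallel: fall back to normalized lerp to avoid sin(0)/0
        q = (1.0 - t) * qa + t * qb
    else:
        theta = np.arccos(min(dot, 1.0))
        q = (np.sin((1.0 - t) * theta) * qa + np.sin(t * theta) * qb) / np.sin(theta)
    translation = (1.0 - t) * a.translation + t * b.translation
    return RigidTransform(q, translation)


def interpolate_segment(a: RigidTransform, b: RigidTransform, n: int) -> list[RigidTransform]:
    """Exactly ``n`` strictly intermediate poses between ``a`` and ``b``.

    Poses sit at fractions ``k / (n + 1)``, ``k = 1..n`` — the endpoints are
    excluded here because the trajectory assembler emits them as keyframes.
    """
    if n < 1:
        raise ValueError(f"quantified-point count must be >= 1, got {n}")
    return [interpolate_pose(a, b, k / (n + 1)) for k in range(1, n + 1)]


def build_trajectory(
    poses: PoseSet,
    n_per_segment: int = 100,
    sequence: Sequence[PoseLabel] | None = None,
    frame_interval: float = 0.01,
) -> MotionTrajectory:
    """Assemble keyframes and interpolated segments into a timed trajectory.

    The sequence must start and end at MIP (the loop anchor).  Junction
    keyframes are emitted once, so the total frame count is
    ``len(sequence) + (len(sequence) - 1) * n_per_segment``.
    Times are ``frame index * frame_interval``.
    """
    if sequence is None:
        sequence = DEFAULT_SEQUENCE
    sequence = tuple(sequence)
    if len(sequence) < 2:
        raise ValueError("sequence needs at least two labels")
    if sequence[0] is not PoseLabel.MIP or sequence[-1] is not PoseLabel.MIP:
        raise ValueError("sequence must start and end at MIP")
    unknown = [s for s in sequence if s not in poses.poses]
    if unknown:
        raise ValueError("unknown labels in sequence: " + ", ".join(u.value for u in unknown))
    if n_per_segment < 1:
        raise ValueError(f"frames per segment must be >= 1, got {n_per_segment}")
    if frame_interval <= 0:
        raise ValueError(f"frame interval must be positive, got {frame_interval}")

    frames: list[TrajectoryFrame] = []
    keyframe_indices: list[int] = []
    for i, label in enumerate(sequence):
        keyframe_indices.append(len(frames))
        frames.append(
            TrajectoryFrame(
                time=len(frames) * frame_interval,
                pose=poses.poses[label],
                segment_label=label.value,
            )
        )
        if i + 1 < len(sequence):
            nxt = sequence[i + 1]
            seg_label = f"{label.value}->{nxt.value}"
            for pose in interpolate_segment(poses.poses[label], poses.poses[nxt], n_per_segment):
                frames.append(
                    TrajectoryFrame(
                        time=len(frames) * frame_interval,
                        pose=pose,
                        segment_label=seg_label,
                    )
                )
    return MotionTrajectory(
        frames=tuple(frames),
        keyframe_indices=tuple(keyframe_indices),
        frames_per_segment=n_per_segment,
    )


def apply_pose(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Materialize a pose: rotate-then-translate every vertex, topology untouched."""
    return TriangleMesh(vertices=t.apply(mesh.vertices), facets=mesh.facets)
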