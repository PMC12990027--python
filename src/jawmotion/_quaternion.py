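"""Unit-quaternion helpers (scalar-first ``(w, x, y, z)`` convention).

Internal module: the public surface exposes :class:`~jawmotion.registration.RigidTransform`
instead of raw quaternions.  All functions accept and return plain float64
arrays and assume (but re-normalize against) unit norm.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "quat_canonical",
    "quat_conjugate",
    "quat_from_matrix",
    "quat_multiply",
    "quat_normalize",
    "quat_rotation_angle",
    "quat_to_matrix",
]


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if q.shape != (4,):
        raise ValueError(f"quaternion must have shape (4,), got {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("quaternion has non-finite components")
    norm = float(np.linalg.norm(q))
    if norm == 0.0:
        raise ValueError("zero quaternion cannot be normalized")
    return q / norm


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Fix the double-cover sign: w >= 0, ties broken by the first nonzero
    component being positive."""
    q = np.asarray(q, dtype=np.float64)
    for c in q:
        if c > 0.0:
            return q.copy()
        if c < 0.0:
            return -q
    raise ValueError("zero quaternion has no canonical sign")


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, pv = p[0], p[1:]
    qw, qv = q[0], q[1:]
    w = pw * qw - float(pv @ qv)
    v = pw * qv + qw * pv + np.cross(pv, qv)
    return np.concatenate(([w], v))


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    out = np.asarray(q, dtype=np.float64).copy()
    out[1:] = -out[1:]
    return out


def quat_rotation_angle(q: np.ndarray) -> float:
    """Rotation angle in radians, in [0, pi]."""
    return 2.0 * float(np.arctan2(np.linalg.norm(q[1:]), abs(q[0])))


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = quat_normalize(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ],
        dtype=np.float64,
    )


def quat_from_matrix(m: np.ndarray) -> np.ndarray:
    """Extract a unit quaternion from a proper rotation matrix.

    Uses the numerically stable branch selection on the largest of the trace
    and the diagonal entries (Shepperd's method).
    """
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {m.shape}")
    tr = m[0, 0] + m[1, 1] + m[2, 2]
    if tr > max(m[0, 0], m[1, 1], m[2, 2]):
        s = 2.0 * np.sqrt(1.0 + tr)
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    elif m[0, 0] >= m[1, 1] and m[0, 0] >= m[2, 2]:
        s = 2.0 * np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2])
        q = np.array(
            [(m[2, 1] - m[1, 2]) / s, 0.25 * s, (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
        )
    elif m[1, 1] >= m[2, 2]:
        s = 2.0 * np.sqrt(1.0 - m[0, 0] + m[1, 1] - m[2, 2])
        q = np.array(
            [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s, 0.25 * s, (m[1, 2] + m[2, 1]) / s]
        )
    else:
        s = 2.0 * np.sqrt(1.0 - m[0, 0] - m[1, 1] + m[2, 2])
        q = np.array(
            [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s, (m[1, 2] + m[2, 1]) / s, 0.25 * s]
        )
    return quat_canonical(quat_normalize(q))
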