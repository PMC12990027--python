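"""Parametric mandibular-arch fixtures with ground-truth excursive poses.

Stands in for the clinical scanning steps so the whole pipeline can be tested
with no scan data.  The generated mesh is a horseshoe-shaped band — a
parabolic arch swept with a bumped occlusal profile imitating cusps — which is
non-planar and of full affine rank, so rigid registration on it is well posed.

Axis convention (documented, arbitrary): +x lateral (toward the right record's
working side), +y anterior, +z superior.  Protrusion is modelled as pure
translation (anterior advance plus an inferior drop standing in for incisal
guidance); laterotrusion as pure yaw about a vertical axis through a condyle
proxy point placed posterior to the arch.  The default magnitudes are
clinically plausible placeholders — millimetre translations, single-digit
degree rotations — and are NOT measured values from any source.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh_io import PoseLabel, TriangleMesh
from .registration import RigidTransform

__all__ = [
    "ExcursionParams",
    "break_correspondence",
    "generate_arch_mesh",
    "generate_pose_records",
]

# Arch shape constants (mm): half-width of the parabola, anterior depth,
# band half-width, cusp bump height, posterior hinge depth for the condyle axis.
_ARCH_HALF_WIDTH = 25.0
_ARCH_DEPTH = 42.0
_BAND_HALF_WIDTH = 4.0
_CUSP_HEIGHT = 1.8
_HINGE_Y = -12.0


@dataclass(frozen=True)
class ExcursionParams:
    """Magnitudes of the three simulated excursive movements plus noise/seed.

    ``laterotrusion_angle`` is a yaw in degrees about the vertical axis through
    the working-side condyle proxy at ``(+/- condyle_offset, hinge, 0)``;
    ``condyle_offset`` is half the inter-condylar width.  ``noise_sigma`` is
    per-vertex isotropic Gaussian scan noise in millimetres, applied after the
    rigid transform.
    """

    protrusion_advance: float = 8.0
    protrusion_drop: float = 2.0
    laterotrusion_angle: float = 10.0
    condyle_offset: float = 50.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protrusion_advance < 0:
            raise ValueError("protrusion_advance must be >= 0")
        if not 0 <= self.laterotrusion_angle < 45:
            raise ValueError("laterotrusion_angle must be in [0, 45) degrees")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_arch_mesh(n_vertices: int = 500, seed: int = 0) -> TriangleMesh:
    """Deterministic horseshoe band mesh with at least ``n_vertices`` vertices.

    A parabolic centerline is swept with a 5-row profile whose height carries
    sinusoidal cusp-like bumps; a small seeded jitter decorrelates meshes
    generated with different seeds without disturbing the overall shape.
    """
    if n_vertices < 50:
        raise ValueError(f"n_vertices must be >= 50, got {n_vertices}")
    n_profile = 5
    n_along = math.ceil(n_vertices / n_profile)
    rng = np.random.default_rng(seed)

    u = np.linspace(-1.0, 1.0, n_along)
    # centerline of the arch and its unit normal in the occlusal plane
    cx = _ARCH_HALF_WIDTH * u
    cy = _ARCH_DEPTH * (1.0 - u**2)
    tx = np.full_like(u, _ARCH_HALF_WIDTH)
    ty = -2.0 * _ARCH_DEPTH * u
    tlen = np.hypot(tx, ty)
    nx, ny = -ty / tlen, tx / tlen

    v = np.linspace(-1.0, 1.0, n_profile)
    # vertices[i, j] = centerline(i) offset by v[j] across the band
    x = cx[:, None] + _BAND_HALF_WIDTH * v[None, :] * nx[:, None]
    y = cy[:, None] + _BAND_HALF_WIDTH * v[None, :] * ny[:, None]
    cusp = np.cos(0.5 * np.pi * v[None, :]) ** 2
    z = _CUSP_HEIGHT * cusp * (1.0 + 0.35 * np.sin(9.0 * np.pi * u[:, None]))
    vertices = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    vertices += rng.normal(0.0, 0.01, size=vertices.shape)

    facets = []
    for i in range(n_along - 1):
        for j in range(n_profile - 1):
            a = i * n_profile + j
            b = a + 1
            c = a + n_profile
            d = c + 1
            facets.append((a, c, b))
            facets.append((b, c, d))
    return TriangleMesh(vertices=vertices, facets=np.asarray(facets, dtype=np.int64))


def _yaw_about(pivot: np.ndarray, angle_deg: float) -> RigidTransform:
    """Rotation by ``angle_deg`` about the vertical (+z) axis through ``pivot``."""
    half = math.radians(angle_deg) / 2.0
    q = np.array([math.cos(half), 0.0, 0.0, math.sin(half)])
    rotation = RigidTransform(q, np.zeros(3)).rotation_matrix
    translation = pivot - rotation @ pivot
    return RigidTransform(q, translation)


def ground_truth_poses(params: ExcursionParams) -> dict[PoseLabel, RigidTransform]:
    """The generating transform for each record, relative to MIP."""
    protrusive = RigidTransform(
        np.array([1.0, 0.0, 0.0, 0.0]),
        np.array([0.0, params.protrusion_advance, -params.protrusion_drop]),
    )
    right_pivot = np.array([params.condyle_offset, _HINGE_Y, 0.0])
    left_pivot = np.array([-params.condyle_offset, _HINGE_Y, 0.0])
    return {
        PoseLabel.MIP: RigidTransform.identity(),
        PoseLabel.PROTRUSIVE: protrusive,
        # working-side condyle stays put; the arch swings toward that side
        PoseLabel.RIGHT_LATEROTRUSIVE: _yaw_about(right_pivot, -params.laterotrusion_angle),
        PoseLabel.LEFT_LATEROTRUSIVE: _yaw_about(left_pivot, params.laterotrusion_angle),
    }


def generate_pose_records(
    mesh: TriangleMesh, params: ExcursionParams
) -> tuple[dict[PoseLabel, TriangleMesh], dict[PoseLabel, RigidTransform]]:
    """Emulate the four occlusal records of one rigid arch.

    Each record is the MIP mesh carried by its ground-truth transform, with
    optional per-vertex Gaussian noise added afterwards (independent streams
    per label, all derived from ``params.seed``).  Returns the records and the
    generating transforms side by side.
    """
    truths = ground_truth_poses(params)
    streams = np.random.SeedSequence(params.seed).spawn(len(PoseLabel))
    records: dict[PoseLabel, TriangleMesh] = {}
    for stream, label in zip(streams, PoseLabel):
        vertices = truths[label].apply(mesh.vertices)
        if params.noise_sigma > 0:
            rng = np.random.default_rng(stream)
            vertices = vertices + rng.normal(0.0, params.noise_sigma, size=vertices.shape)
        records[label] = TriangleMesh(vertices=vertices, facets=mesh.facets)
    return records, truths


def break_correspondence(mesh: TriangleMesh, seed: int = 0) -> TriangleMesh:
    """Permute the vertex table (facets re-indexed consistently).

    The mesh is geometrically identical as a point set but no longer shares
    vertex ordering with the original — the input that forces the ICP route.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(mesh.n_vertices)
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(mesh.n_vertices)
    return TriangleMesh(vertices=mesh.vertices[perm], facets=inverse[mesh.facets])
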