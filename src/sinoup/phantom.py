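"""Analytic phantom simulator for parallel-beam CT.

Scenes are built from axis-aligned quadric primitives (ellipsoids, spheres,
finite cylinders, and clipped half-ellipsoids), each carrying an attenuation
density.  Forward projection is exact: the contribution of a primitive to a
ray is its density times the chord length of the ray/primitive intersection,
obtained in closed form from the quadric's quadratic equation.  Projections
are additive over primitives, so the projector is linear in densities and
oracle-checkable.

The default scene emulates an in-situ corrosion experiment: a metal pin
(finite cylinder) topped by a salt-water droplet (half-ellipsoid), gas
bubbles rising inside the droplet (spheres of negative relative density),
and small dense deposits scattered inside the pin (ellipsoids).

Geometry convention: the rotation axis is z (the sample-height axis).  For
projection row ``t`` of ``T`` the beam direction in the x-y plane is
``d = (cos θ, sin θ, 0)`` with ``θ = t·180°/(T−1)``, and detector
coordinate ``s`` offsets the ray along ``n = (−sin θ, cos θ, 0)``, so the
first and last rows form the 0°/180° mirror pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SinogramStack

_BIG = 1.0e9  # stand-in for ±infinity in interval arithmetic
_EPS = 1.0e-12

KINDS = ("ellipsoid", "sphere", "cylinder", "half-ellipsoid")


@dataclass(frozen=True)
class QuadricPrimitive:
    """One axis-aligned quadric with a uniform attenuation density.

    ``semi_axes`` is ``(a, b, c)`` for ellipsoids, ``(r, r, r)`` for spheres
    and ``(r, r, half_height)`` for finite cylinders (axis along z).
    ``clip_plane = (axis, offset, side)`` keeps the half-space
    ``side · (x[axis] − offset) ≥ 0`` (used for the cut-in-half droplet).
    """

    kind: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    density: float
    clip_plane: tuple[int, float, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if not all(a > 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be strictly positive")
        if not np.isfinite(self.density):
            raise ValueError("density must be finite")
        if self.clip_plane is not None:
            axis, _, side = self.clip_plane
            if axis not in (0, 1, 2) or side not in (-1, 1):
                raise ValueError("clip_plane must be (axis in 0..2, offset, side ±1)")


def sphere(center, radius: float, density: float) -> QuadricPrimitive:
    return QuadricPrimitive("sphere", tuple(center), (radius,) * 3, density)


def ellipsoid(center, semi_axes, density: float) -> QuadricPrimitive:
    return QuadricPrimitive("ellipsoid", tuple(center), tuple(semi_axes), density)


def cylinder(center, radius: float, half_height: float, density: float) -> QuadricPrimitive:
    return QuadricPrimitive("cylinder", tuple(center), (radius, radius, half_height), density)


def half_ellipsoid(center, semi_axes, density: float, axis: int = 2,
                   side: int = 1) -> QuadricPrimitive:
    """Ellipsoid cut by the axis-aligned plane through its own center."""
    return QuadricPrimitive("half-ellipsoid", tuple(center), tuple(semi_axes),
                            density, clip_plane=(axis, center[axis], side))


@dataclass(frozen=True)
class PhantomScene:
    """Ordered list of primitives inside a bounding cube of half-width ``extent``."""

    primitives: tuple[QuadricPrimitive, ...]
    extent: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "primitives", tuple(self.primitives))
        if self.extent <= 0:
            raise ValueError("extent must be positive")


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam step-scan geometry over a 180° sweep.

    ``pixel_size`` is scene units per detector pixel; detector row heights
    are centred on ``height_center`` along the rotation axis.
    """

    n_angles: int
    detector_width: int
    n_heights: int
    pixel_size: float
    height_center: float = 0.0
    angle_span: float = field(default=180.0, init=False)

    def __post_init__(self) -> None:
        if self.n_angles < 2:
            raise ValueError("n_angles must be at least 2 (first 0°, last 180°)")
        if self.detector_width < 1 or self.n_heights < 1:
            raise ValueError("detector_width and n_heights must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def angles(self) -> np.ndarray:
        """Row angles in degrees: ``t·180/(T−1)`` for ``t = 0..T−1``."""
        return np.linspace(0.0, self.angle_span, self.n_angles)

    def angle_of_row(self, t: int) -> float:
        return t * self.angle_span / (self.n_angles - 1)

    @property
    def detector_offsets(self) -> np.ndarray:
        """Signed detector-pixel centre offsets in scene units."""
        w = self.detector_width
        return (np.arange(w) - (w - 1) / 2.0) * self.pixel_size

    @property
    def height_offsets(self) -> np.ndarray:
        h = self.n_heights
        return (np.arange(h) - (h - 1) / 2.0) * self.pixel_size + self.height_center


@dataclass(frozen=True)
class NoiseModel:
    """Transmission Poisson counting noise with incident flux ``i0``."""

    i0: float = 1.0e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError("incident flux i0 must be positive")


# ---------------------------------------------------------------------------
# closed-form ray/primitive chords


def _quadratic_interval(A, B, C):
    """Solve A t² + B t + C ≤ 0 for the inside interval; empty → (BIG, −BIG).

    Handles the degenerate A ≈ 0 case (ray parallel to a cylinder axis):
    inside for all t when C ≤ 0, else empty.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    C = np.asarray(C, dtype=np.float64)
    disc = B * B - 4.0 * A * C
    degenerate = np.abs(A) < _EPS
    safe_A = np.where(degenerate, 1.0, A)
    sq = np.sqrt(np.maximum(disc, 0.0))
    lo = (-B - sq) / (2.0 * safe_A)
    hi = (-B + sq) / (2.0 * safe_A)
    empty = (disc < 0.0) & ~degenerate
    lo = np.where(empty, _BIG, lo)
    hi = np.where(empty, -_BIG, hi)
    # degenerate: all-of-line when C <= 0, empty otherwise
    lo = np.where(degenerate, np.where(C <= 0.0, -_BIG, _BIG), lo)
    hi = np.where(degenerate, np.where(C <= 0.0, _BIG, -_BIG), hi)
    return lo, hi


def _slab_interval(o, d, half_width):
    """Interval where |o + t·d| ≤ half_width along one coordinate."""
    o = np.asarray(o, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    parallel = np.abs(d) < _EPS
    safe_d = np.where(parallel, 1.0, d)
    t1 = (-half_width - o) / safe_d
    t2 = (half_width - o) / safe_d
    lo = np.minimum(t1, t2)
    hi = np.maximum(t1, t2)
    inside = np.abs(o) <= half_width
    lo = np.where(parallel, np.where(inside, -_BIG, _BIG), lo)
    hi = np.where(parallel, np.where(inside, _BIG, -_BIG), hi)
    return lo, hi


def _halfspace_interval(o, d, side):
    """Interval where side · (o + t·d) ≥ 0 along one coordinate."""
    o = np.asarray(o, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    parallel = np.abs(d) < _EPS
    safe_d = np.where(parallel, 1.0, d)
    tcut = -o / safe_d
    forward = side * d > 0  # half-space lies at t >= tcut
    lo = np.where(forward, tcut, -_BIG)
    hi = np.where(forward, _BIG, tcut)
    keep = side * o >= 0
    lo = np.where(parallel, np.where(keep, -_BIG, _BIG), lo)
    hi = np.where(parallel, np.where(keep, _BIG, -_BIG), hi)
    return lo, hi


def _chord(prim: QuadricPrimitive, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Chord length of ray(s) ``origin + t·direction`` through ``prim``.

    ``origin`` and ``direction`` broadcast against each other over a
    trailing xyz axis; directions are assumed unit length.
    """
    c = np.asarray(prim.center, dtype=np.float64)
    a = np.asarray(prim.semi_axes, dtype=np.float64)
    o = np.asarray(origin, dtype=np.float64) - c
    d = np.asarray(direction, dtype=np.float64)
    o, d = np.broadcast_arrays(o, d)

    if prim.kind == "cylinder":
        A = (d[..., 0] / a[0]) ** 2 + (d[..., 1] / a[1]) ** 2
        B = 2.0 * (o[..., 0] * d[..., 0] / a[0] ** 2 + o[..., 1] * d[..., 1] / a[1] ** 2)
        C = (o[..., 0] / a[0]) ** 2 + (o[..., 1] / a[1]) ** 2 - 1.0
        lo, hi = _quadratic_interval(A, B, C)
        slo, shi = _slab_interval(o[..., 2], d[..., 2], a[2])
        lo, hi = np.maximum(lo, slo), np.minimum(hi, shi)
    else:  # sphere / ellipsoid / half-ellipsoid
        q0 = o / a
        q1 = d / a
        A = np.sum(q1 * q1, axis=-1)
        B = 2.0 * np.sum(q0 * q1, axis=-1)
        C = np.sum(q0 * q0, axis=-1) - 1.0
        lo, hi = _quadratic_interval(A, B, C)

    if prim.clip_plane is not None:
        axis, offset, side = prim.clip_plane
        clo, chi = _halfspace_interval(o[..., axis] + c[axis] - offset, d[..., axis], side)
        lo, hi = np.maximum(lo, clo), np.minimum(hi, chi)

    return np.maximum(hi - lo, 0.0)


def line_integral(prim: QuadricPrimitive, origin, direction) -> float:
    """Path-weighted density of one ray: density × chord length.

    ``direction`` must be unit length; a zero-length direction is an error.
    Returns 0 when the ray misses the primitive.
    """
    direction = np.asarray(direction, dtype=np.float64)
    norm = float(np.linalg.norm(direction))
    if norm < _EPS:
        raise ValueError("ray direction must be non-degenerate (unit length)")
    if abs(norm - 1.0) > 1.0e-9:
        raise ValueError("ray direction must be unit length")
    return float(prim.density * _chord(prim, np.asarray(origin, dtype=np.float64), direction))


def _height_span(prim: QuadricPrimitive) -> tuple[float, float]:
    """z-interval outside which the primitive cannot intersect any ray."""
    lo = prim.center[2] - prim.semi_axes[2]
    hi = prim.center[2] + prim.semi_axes[2]
    if prim.clip_plane is not None and prim.clip_plane[0] == 2:
        _, offset, side = prim.clip_plane
        if side > 0:
            lo = max(lo, offset)
        else:
            hi = min(hi, offset)
    return lo, hi


def project_scene(scene: PhantomScene, geometry: ProjectionGeometry,
                  angle_chunk: int = 46) -> SinogramStack:
    """Noiseless parallel-beam line integrals of a scene.

    Returns a :class:`SinogramStack` ``(height, angle, width)``; element
    ``(h, t, u)`` sums ``density × chord`` over primitives for the ray at
    height row ``h``, angle row ``t`` and detector column ``u``.  Exactly
    linear in primitive densities.  Each primitive is only evaluated on the
    height rows its z-extent can reach (rays here are horizontal).
    """
    theta = np.deg2rad(geometry.angles)
    dirs = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
    normals = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
    s = geometry.detector_offsets
    z = geometry.height_offsets
    spans = [_height_span(p) for p in scene.primitives]
    h_ranges = [(int(np.searchsorted(z, lo - 1e-12)),
                 int(np.searchsorted(z, hi + 1e-12))) for lo, hi in spans]

    out = np.zeros((geometry.n_heights, geometry.n_angles, geometry.detector_width),
                   dtype=np.float64)
    zhat = np.array([0.0, 0.0, 1.0])
    for k0 in range(0, geometry.n_angles, angle_chunk):
        k1 = min(k0 + angle_chunk, geometry.n_angles)
        n_k = normals[k0:k1]  # (K, 3)
        d_k = dirs[k0:k1][:, None, None, :]  # (K, 1, 1, 3)
        # ray origins: detector offset along the normal plus the height offset
        origins = (s[None, None, :, None] * n_k[:, None, None, :]
                   + z[None, :, None, None] * zhat)
        acc = np.zeros((k1 - k0, geometry.n_heights, geometry.detector_width))
        for prim, (h0, h1) in zip(scene.primitives, h_ranges):
            if h1 <= h0:
                continue
            acc[:, h0:h1] += prim.density * _chord(prim, origins[:, h0:h1], d_k)
        out[:, k0:k1, :] = acc.transpose(1, 0, 2)
    return SinogramStack(out.astype(np.float32), angles=geometry.angles,
                         provenance="noiseless")


def apply_poisson_noise(p: SinogramStack, noise: NoiseModel) -> SinogramStack:
    """Simulate transmission counting statistics on a noiseless stack.

    Counts ``c ~ Poisson(i0 · exp(−p))`` per pixel; the returned stack holds
    ``p̂ = −ln(max(c, 1)/i0)`` (zero counts are clamped to one so the log
    stays finite).  Identical seeds give bit-identical output.
    """
    data = np.asarray(p.data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("sinogram stack must be finite")
    if data.min() < 0:
        raise ValueError("line integrals must be non-negative for Poisson noise")
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(noise.i0 * np.exp(-data))
    p_hat = -np.log(np.maximum(counts, 1) / noise.i0)
    return SinogramStack(p_hat.astype(np.float32), angles=p.angles.copy(),
                         provenance="noisy")


# ---------------------------------------------------------------------------
# the corrosion phantom


@dataclass(frozen=True)
class PhantomConfig:
    """Sizes, counts and densities of the corrosion scene (scene units).

    Densities are attenuation per unit length relative to the beam; the
    bubbles carry a *negative* density because they displace droplet
    material (the additive projector then yields the correct contrast).
    """

    extent: float = 1.0
    n_bubbles: int = 3
    n_deposits: int = 40
    pin_radius: float = 0.28
    pin_bottom: float = -0.95
    pin_top: float = 0.25
    pin_density: float = 1.0
    droplet_semi: tuple[float, float, float] = (0.24, 0.24, 0.30)
    droplet_density: float = 0.55
    bubble_radius: tuple[float, float] = (0.03, 0.07)
    bubble_density: float = -0.35
    deposit_semi: tuple[float, float] = (0.015, 0.045)
    deposit_density: float = 0.5

    def __post_init__(self) -> None:
        if self.n_bubbles < 0 or self.n_deposits < 0:
            raise ValueError("counts must be non-negative")


def build_corrosion_phantom(config: PhantomConfig | None = None,
                            seed: int = 0) -> PhantomScene:
    """Assemble the corrosion scene from a seeded generator.

    The scene is one pin (cylinder), one droplet (half-ellipsoid sitting on
    the pin top), ``n_bubbles`` spheres placed inside the droplet, and
    ``n_deposits`` small ellipsoids whose centres lie inside the pin.
    Placements are uniform within their admissible regions and reproducible
    per seed.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    prims: list[QuadricPrimitive] = []

    pin_center_z = 0.5 * (cfg.pin_top + cfg.pin_bottom)
    pin_half = 0.5 * (cfg.pin_top - cfg.pin_bottom)
    prims.append(cylinder((0.0, 0.0, pin_center_z), cfg.pin_radius, pin_half,
                          cfg.pin_density))

    droplet_center = (0.0, 0.0, cfg.pin_top)
    prims.append(half_ellipsoid(droplet_center, cfg.droplet_semi,
                                cfg.droplet_density, axis=2, side=1))

    dsemi = np.asarray(cfg.droplet_semi)
    for _ in range(cfg.n_bubbles):
        r = rng.uniform(*cfg.bubble_radius)
        # rejection-sample a point in the upper half unit ball, then shrink
        # per-axis so the whole bubble stays inside the kept droplet half
        while True:
            v = rng.uniform(-1.0, 1.0, size=3)
            if np.dot(v, v) > 1.0 or v[2] < 0.0:
                continue
            margin = np.maximum(dsemi - r, 0.0)
            center = np.asarray(droplet_center) + v * margin
            if center[2] - cfg.pin_top >= 1.05 * r:
                break
        prims.append(sphere(tuple(center), r, cfg.bubble_density))

    max_semi = cfg.deposit_semi[1]
    for _ in range(cfg.n_deposits):
        semi = rng.uniform(cfg.deposit_semi[0], cfg.deposit_semi[1], size=3)
        radial = (cfg.pin_radius - max_semi) * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        z = rng.uniform(cfg.pin_bottom + max_semi, cfg.pin_top - max_semi)
        prims.append(ellipsoid((radial * np.cos(phi), radial * np.sin(phi), z),
                               tuple(semi), cfg.deposit_density))

    return PhantomScene(tuple(prims), extent=cfg.extent)


def point_density(prim: QuadricPrimitive, points: np.ndarray) -> np.ndarray:
    """Density of a primitive at point(s) ``(..., 3)`` (0 outside)."""
    pts = np.asarray(points, dtype=np.float64)
    c = np.asarray(prim.center)
    a = np.asarray(prim.semi_axes)
    q = (pts - c) / a
    if prim.kind == "cylinder":
        inside = (q[..., 0] ** 2 + q[..., 1] ** 2 <= 1.0) & (np.abs(q[..., 2]) <= 1.0)
    else:
        inside = np.sum(q * q, axis=-1) <= 1.0
    if prim.clip_plane is not None:
        axis, offset, side = prim.clip_plane
        inside &= side * (pts[..., axis] - offset) >= 0.0
    return np.where(inside, prim.density, 0.0)


def density_slice(scene: PhantomScene, geometry: ProjectionGeometry,
                  height_index: int) -> np.ndarray:
    """Rasterized W×W density map of the scene at one sample height.

    Pixel centres use the detector grid on both in-plane axes, so the map is
    directly comparable with a filtered-back-projection reconstruction.
    """
    s = geometry.detector_offsets
    z = geometry.height_offsets[height_index]
    xx, yy = np.meshgrid(s, s, indexing="xy")
    pts = np.stack([xx, yy, np.full_like(xx, z)], axis=-1)
    out = np.zeros(xx.shape)
    for prim in scene.primitives:
        out += point_density(prim, pts)
    return out
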