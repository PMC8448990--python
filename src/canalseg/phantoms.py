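"""Synthetic CT phantoms of the semicircular canals.

The clinical CT data this package targets is not redistributable, so the
package ships a geometric phantom generator that reproduces the documented
statistics of that data: 512x512x64-voxel volumes at 1 mm isotropic
spacing, containing tubular targets that each follow roughly two-thirds of
a circle of ~6.5 mm diameter and jointly occupy well under 1% of the
volume — the extreme class imbalance that makes the segmentation task hard.

Each phantom side carries ``n_canals`` circular arcs in mutually
near-orthogonal planes (superior / posterior / lateral canal geometry),
rasterised into a binary label grid as tubes of ``tube_radius_mm`` around
the arc polyline.  Intensities are a flat soft-tissue background, a
brighter bone-like shell around each tube, a darker fluid-like lumen inside
it, and additive Gaussian noise.  The model makes no claim about clinical
HU statistics (none are published for this dataset); intensity levels are
free parameters chosen so the target is clearly learnable.

Coordinate convention: voxel index ``(d, h, w)``, 0-based; the physical
position of a voxel centre is ``(index + 0.5) * spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryError", "IntensityParams", "PhantomSpec", "LabeledVolume",
    "DEFAULT_SPEC", "SMALL_SPEC",
    "canal_centerline", "rasterize_tube", "generate_labels",
    "generate_phantom", "generate_dataset",
]


class GeometryError(ValueError):
    """Canal geometry does not fit inside the requested volume."""


@dataclass(frozen=True)
class IntensityParams:
    """CT-like intensity levels (arbitrary units)."""

    background_mean: float = 50.0
    bone_mean: float = 700.0
    lumen_mean: float = -100.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of one synthetic volume.

    Defaults mirror the study conditions: a 512x512x64 grid (stored depth
    first) at 1 mm isotropic spacing, canals spanning two-thirds of a
    6.5 mm-diameter circle, three canals per side, both sides present.
    """

    volume_shape: tuple = (64, 512, 512)        # (D, H, W) voxels
    spacing_mm: tuple = (1.0, 1.0, 1.0)         # per-axis voxel size
    canal_diameter_mm: float = 6.5
    arc_fraction: float = 2.0 / 3.0
    tube_radius_mm: float = 0.75
    shell_thickness_mm: float = 1.0
    n_canals: int = 3
    bilateral: bool = True
    intensity_params: IntensityParams = field(default_factory=IntensityParams)
    noise_sigma: float = 25.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "volume_shape", tuple(int(s) for s in self.volume_shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if any(s < 8 for s in self.volume_shape):
            raise ValueError("all volume_shape entries must be >= 8")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if not (0.0 < self.arc_fraction <= 1.0):
            raise ValueError("arc_fraction must be in (0, 1]")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube_radius_mm must be positive")
        if self.n_canals < 0:
            raise ValueError("n_canals must be >= 0")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.volume_shape) * np.asarray(self.spacing_mm)


DEFAULT_SPEC = PhantomSpec()
#: Reduced spec for CPU tests; full-size grids are unnecessary for correctness.
SMALL_SPEC = PhantomSpec(volume_shape=(48, 96, 96), bilateral=False, seed=0)


@dataclass
class LabeledVolume:
    """An intensity grid with an aligned binary label grid."""

    intensities: np.ndarray                      # float32 (D, H, W)
    labels: np.ndarray                           # uint8 (D, H, W), values {0,1}
    spacing_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.intensities.shape != self.labels.shape:
            raise ValueError(
                f"intensities {self.intensities.shape} and labels "
                f"{self.labels.shape} must have identical shapes")
        vals = np.unique(self.labels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"labels must be binary, found values {vals}")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    @property
    def foreground_fraction(self) -> float:
        return float(self.labels.sum()) / self.labels.size


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

# canonical plane bases for up to three mutually orthogonal canal planes
_PLANES = (((1.0, 0, 0), (0, 1.0, 0)),
           ((0, 1.0, 0), (0, 0, 1.0)),
           ((1.0, 0, 0), (0, 0, 1.0)))


def _small_rotation(rng: np.random.Generator, max_angle_rad: float) -> np.ndarray:
    """Random rotation by small independent angles about the three axes."""
    a, b, c = rng.uniform(-max_angle_rad, max_angle_rad, size=3)
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rx @ ry @ rz


def _safe_center_box(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Range of arc-centre positions such that the circle plus tube margin
    stays inside the volume regardless of plane orientation."""
    margin = spec.canal_diameter_mm / 2.0 + spec.tube_radius_mm + spec.shell_thickness_mm
    lo = np.full(3, margin)
    hi = spec.extent_mm - margin
    if np.any(lo > hi):
        ax = int(np.argmin(spec.extent_mm - 2 * margin))
        raise GeometryError(
            f"a circle of diameter {spec.canal_diameter_mm} mm with tube radius "
            f"{spec.tube_radius_mm} mm (+{spec.shell_thickness_mm} mm shell) needs "
            f"{2 * margin:.2f} mm of clearance but axis {ax} spans only "
            f"{spec.extent_mm[ax]:.2f} mm")
    return lo, hi


def canal_centerline(spec: PhantomSpec, canal_index: int,
                     rng: np.random.Generator,
                     center_mm: np.ndarray | None = None) -> np.ndarray:
    """Ordered points (mm) along one canal's circular arc.

    The arc lies in a plane chosen per ``canal_index`` from a set of
    mutually orthogonal canonical planes, randomly jittered by a small
    rotation; consecutive points are spaced at most ``tube_radius_mm / 2``
    apart so tube rasterisation sees a dense polyline.
    """
    if not (0 <= canal_index < max(spec.n_canals, 1)):
        raise ValueError(f"canal_index {canal_index} outside [0, {spec.n_canals})")
    lo, hi = _safe_center_box(spec)
    if center_mm is None:
        center_mm = rng.uniform(lo, hi)
    center_mm = np.clip(np.asarray(center_mm, dtype=np.float64), lo, hi)

    u0, v0 = (np.asarray(b, dtype=np.float64) for b in _PLANES[canal_index % len(_PLANES)])
    rot = _small_rotation(rng, np.deg2rad(12.0))
    u, v = rot @ u0, rot @ v0

    radius = spec.canal_diameter_mm / 2.0
    arc_len = spec.arc_fraction * 2.0 * np.pi * radius
    step = spec.tube_radius_mm / 2.0
    n_pts = max(int(np.ceil(arc_len / step)) + 1, 2)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    theta = theta0 + np.linspace(0.0, spec.arc_fraction * 2.0 * np.pi, n_pts)
    pts = center_mm + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    return pts


def _segment_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each point to the polyline (exact)."""
    if len(poly) == 1:
        return np.linalg.norm(points - poly[0], axis=1)
    a = poly[:-1]                                  # (S, 3)
    ab = poly[1:] - a                              # (S, 3)
    den = (ab * ab).sum(axis=1)                    # (S,)
    ap = points[:, None, :] - a[None, :, :]        # (M, S, 3)
    t = np.einsum("msk,sk->ms", ap, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, t / den, 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    return np.linalg.norm(points[:, None, :] - closest, axis=2).min(axis=1)


def rasterize_tube(centerline: np.ndarray, tube_radius_mm: float,
                   shape: tuple, spacing_mm: tuple) -> np.ndarray:
    """Binary mask of voxels whose centre lies within ``tube_radius_mm`` of
    the centerline polyline (Euclidean, mm), clipped at the volume boundary."""
    centerline = np.atleast_2d(np.asarray(centerline, dtype=np.float64))
    if centerline.size == 0:
        raise ValueError("rasterize_tube: empty centerline")
    if tube_radius_mm <= 0:
        raise ValueError("rasterize_tube: tube radius must be positive")
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    shape = tuple(int(s) for s in shape)

    lo_mm = centerline.min(axis=0) - tube_radius_mm
    hi_mm = centerline.max(axis=0) + tube_radius_mm
    # voxel centre (i + 0.5) * sp within [lo, hi]
    i_lo = np.maximum(np.floor(lo_mm / spacing - 0.5).astype(int), 0)
    i_hi = np.minimum(np.ceil(hi_mm / spacing - 0.5).astype(int), np.asarray(shape) - 1)
    mask = np.zeros(shape, dtype=bool)
    if np.any(i_lo > i_hi):
        return mask

    grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(i_lo, i_hi)],
                        indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)          # (M, 3)
    centres = (idx + 0.5) * spacing
    # chunk the (M x S) distance matrix to bound memory
    within = np.empty(len(centres), dtype=bool)
    chunk = max(1, 2_000_000 // max(len(centerline), 1))
    for s in range(0, len(centres), chunk):
        d = _segment_distances(centres[s:s + chunk], centerline)
        within[s:s + chunk] = d <= tube_radius_mm
    sel = idx[within]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask


# ---------------------------------------------------------------------------
# Whole-phantom generation
# ---------------------------------------------------------------------------

def _side_boxes(spec: PhantomSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Arc-centre sampling boxes: whole safe box, or left/right halves of it
    (split along the last axis) for bilateral phantoms."""
    lo, hi = _safe_center_box(spec)
    if not spec.bilateral:
        return [(lo, hi)]
    mid = 0.5 * (lo[2] + hi[2])
    left_hi = np.array([hi[0], hi[1], max(mid, lo[2])])
    right_lo = np.array([lo[0], lo[1], min(mid, hi[2])])
    return [(lo, left_hi), (right_lo, hi)]


def _all_centerlines(spec: PhantomSpec, rng: np.random.Generator) -> list[np.ndarray]:
    lines = []
    for box_lo, box_hi in _side_boxes(spec):
        # one cluster centre per side; individual canals jitter around it
        cluster = rng.uniform(box_lo, box_hi)
        for ci in range(spec.n_canals):
            offset = rng.uniform(-1.0, 1.0, size=3)
            lines.append(canal_centerline(spec, ci, rng, center_mm=cluster + offset))
    return lines


def generate_labels(spec: PhantomSpec) -> np.ndarray:
    """Binary label grid only (cheaper than a full phantom)."""
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.volume_shape, dtype=bool)
    for line in _all_centerlines(spec, rng):
        labels |= rasterize_tube(line, spec.tube_radius_mm,
                                 spec.volume_shape, spec.spacing_mm)
    return labels


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Full phantom: labels plus CT-like intensities, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.volume_shape
    labels = np.zeros(shape, dtype=bool)
    shell = np.zeros(shape, dtype=bool)
    for line in _all_centerlines(spec, rng):
        labels |= rasterize_tube(line, spec.tube_radius_mm, shape, spec.spacing_mm)
        shell |= rasterize_tube(line, spec.tube_radius_mm + spec.shell_thickness_mm,
                                shape, spec.spacing_mm)
    shell &= ~labels

    ip = spec.intensity_params
    intensities = np.full(shape, ip.background_mean, dtype=np.float32)
    intensities[shell] = ip.bone_mean
    intensities[labels] = ip.lumen_mean
    if spec.noise_sigma > 0:
        intensities += spec.noise_sigma * rng.standard_normal(shape, dtype=np.float32)
    return LabeledVolume(intensities=intensities,
                         labels=labels.astype(np.uint8),
                         spacing_mm=spec.spacing_mm)


def generate_dataset(spec: PhantomSpec, n_train: int = 26, n_val: int = 7,
                     n_test: int = 6, seed: int | None = None
                     ) -> tuple[list, list, list]:
    """Train/val/test lists of phantoms with disjoint per-volume seeds.

    Default split sizes mirror the study's 26/7/6 case split.  Per-volume
    seeds derive deterministically from the master seed, so the same seed
    always yields the same splits and no volume is shared between them.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be >= 0")
    master = spec.seed if seed is None else seed
    n_total = n_train + n_val + n_test
    children = np.random.SeedSequence(master).spawn(n_total)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    volumes = [generate_phantom(replace(spec, seed=s)) for s in seeds]
    return (volumes[:n_train],
            volumes[n_train:n_train + n_val],
            volumes[n_train + n_val:])
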