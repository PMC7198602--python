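"""Synthetic two-channel 3D-SIM-like scenes with ring-shaped foci.

Forward model used throughout the package's tests and analyses: active rDNA
chromatin units are modelled as thin circular (optionally elliptic) loops of
known midline diameter, random 3D orientation and Gaussian tube cross-section,
placed without overlap inside a nucleolar ellipsoid nested in nucleus and cell
masks.  Rendered intensity is blurred with an anisotropic Gaussian PSF proxy
(axial worse than lateral, as in structured-illumination reconstructions) and
degraded with Poisson photon noise plus Gaussian read noise.  A mixing
parameter controls which fraction of second-channel structures co-occur with
first-channel structures, giving ground truth for colocalization analyses.

All randomness flows through integer seeds (or numpy Generators); identical
seeds give identical scenes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_io import ImageStack, RoiSet

#: Default reconstructed-SIM-like sampling, nm per voxel along (Z, Y, X).
DEFAULT_VOXEL_SIZE = (125.0, 40.0, 40.0)
DEFAULT_CANVAS_SHAPE = (32, 192, 192)

#: Anisotropic PSF proxy, nm (lateral, axial).
DEFAULT_SIGMA_XY = 50.0
DEFAULT_SIGMA_Z = 150.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


@dataclass(frozen=True)
class RingSpec:
    """Ground-truth geometry of one loop-shaped focus.

    center : (z, y, x) position of the ring centre, nm.
    diameter : midline (peak-to-peak) diameter, nm.
    normal : unit normal of the ring plane, (z, y, x) components.
    ellipticity : major/minor axis ratio of the midline, >= 1 (1 = circle);
        the stated diameter is the geometric mean of the two axes.
    amplitude : peak intensity of the tube profile, arbitrary units.
    tube_sigma : Gaussian sigma of the annulus cross-section, nm.
    """

    center: tuple[float, float, float]
    diameter: float
    normal: tuple[float, float, float]
    ellipticity: float = 1.0
    amplitude: float = 100.0
    tube_sigma: float = 40.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.ellipticity < 1:
            raise ValueError("ellipticity is major/minor and must be >= 1")
        if self.tube_sigma <= 0:
            raise ValueError("tube_sigma must be > 0")
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector (within 1e-9)")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "normal", tuple(float(c) for c in n))


def is_clipped(
    spec: RingSpec,
    canvas_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> bool:
    """True if the ring centre sits closer than diameter/2 to a canvas face."""
    margin = spec.diameter / 2.0
    for c, dim, vs in zip(spec.center, canvas_shape, voxel_size):
        if c < margin or c > (dim - 1) * vs - margin:
            return True
    return False


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise proxy: Poisson photons, Gaussian read noise, offset."""

    photon_scale: float = 1.0
    read_sigma: float = 2.0
    background: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be >= 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


@dataclass(frozen=True)
class RoiGeometry:
    """Nested ellipsoidal cell / nucleus / nucleolus geometry, nm.

    Semi-axes are (z, y, x); the three ellipsoids share one centre.
    """

    center: tuple[float, float, float]
    cell_semiaxes: tuple[float, float, float]
    nucleus_semiaxes: tuple[float, float, float]
    nucleolus_semiaxes: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("cell_semiaxes", "nucleus_semiaxes", "nucleolus_semiaxes"):
            if any(a <= 0 for a in getattr(self, name)):
                raise ValueError(f"{name} must be positive")


def default_roi_geometry(
    canvas_shape: tuple[int, int, int] = DEFAULT_CANVAS_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> RoiGeometry:
    """Nested ellipsoids filling a fixed fraction of the canvas."""
    extent = np.array([(d - 1) * v for d, v in zip(canvas_shape, voxel_size)])
    center = extent / 2.0
    return RoiGeometry(
        center=tuple(center),
        cell_semiaxes=tuple(0.46 * extent),
        nucleus_semiaxes=tuple(0.36 * extent),
        nucleolus_semiaxes=tuple(0.22 * extent),
    )


@dataclass
class Scene:
    """A full simulated field: per-channel rings, canvas, ROIs, mixing."""

    rings: dict[str, list[RingSpec]]
    canvas_shape: tuple[int, int, int] = DEFAULT_CANVAS_SHAPE
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    coloc_mixing: float = 1.0
    roi_geometry: RoiGeometry | None = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not 0.0 <= self.coloc_mixing <= 1.0:
            raise ValueError("coloc_mixing must lie in [0, 1]")
        if self.roi_geometry is None:
            self.roi_geometry = default_roi_geometry(self.canvas_shape, self.voxel_size)


# ---------------------------------------------------------------------------
# samplers


def sample_unit_vectors(n: int, seed=0) -> np.ndarray:
    """n orientations uniform on the unit sphere, shape (n, 3)."""
    rng = _as_rng(seed)
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # resample the (measure-zero) degenerate draws
    bad = norms[:, 0] < 1e-12
    while bad.any():
        v[bad] = rng.normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        bad = norms[:, 0] < 1e-12
    return v / norms


def sample_diameters(n: int, mean: float, sd: float, seed=0) -> np.ndarray:
    """Diameters from a normal(mean, sd) truncated at zero, nm."""
    if mean <= 0:
        raise ValueError("diameter mean must be > 0")
    if sd < 0:
        raise ValueError("diameter sd must be >= 0")
    rng = _as_rng(seed)
    if sd == 0:
        return np.full(n, float(mean))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        draw = draw[draw > 0]
        out[filled : filled + draw.size] = draw
        filled += draw.size
    return out


def _uniform_in_ellipsoid(
    rng: np.random.Generator,
    center: np.ndarray,
    semiaxes: np.ndarray,
) -> np.ndarray:
    """One point uniform inside an axis-aligned ellipsoid."""
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    r = rng.uniform() ** (1.0 / 3.0)
    return center + semiaxes * d * r


def sample_ring_population(
    n: int,
    diameter_mean: float,
    diameter_sd: float,
    canvas_shape: tuple[int, int, int] = DEFAULT_CANVAS_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    seed=0,
    roi_geometry: RoiGeometry | None = None,
    amplitude: float = 100.0,
    tube_sigma: float = 40.0,
    ellipticity: float = 1.0,
    max_attempts: int = 10_000,
) -> list[RingSpec]:
    """Draw n ring specs: truncated-normal diameters, orientations uniform on
    the sphere, centres uniform in the nucleolar ellipsoid with a hard
    non-overlap spacing of 1.5 x diameter_mean between centres.

    Raises RuntimeError("scene too crowded") if placement fails within
    ``max_attempts`` candidate draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    geom = roi_geometry or default_roi_geometry(canvas_shape, voxel_size)
    diameters = sample_diameters(n, diameter_mean, diameter_sd, rng)
    normals = sample_unit_vectors(n, rng)

    min_spacing = 1.5 * diameter_mean
    center = np.asarray(geom.center)
    semi = np.asarray(geom.nucleolus_semiaxes)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"scene too crowded: placed {len(centers)}/{n} rings at spacing "
                f"{min_spacing:.0f} nm within {max_attempts} attempts"
            )
        cand = _uniform_in_ellipsoid(rng, center, semi)
        if all(np.linalg.norm(cand - c) >= min_spacing for c in centers):
            centers.append(cand)

    return [
        RingSpec(
            center=tuple(centers[i]),
            diameter=float(diameters[i]),
            normal=tuple(normals[i]),
            ellipticity=ellipticity,
            amplitude=amplitude,
            tube_sigma=tube_sigma,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# rendering


def plane_basis(normal) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal in-plane basis (u, v) for a ring normal."""
    w = _unit(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


def _add_ring(img: np.ndarray, spec: RingSpec, voxel_size) -> None:
    """Accumulate one ring's analytic tube profile into ``img`` in place.

    Each voxel's value is the tube profile averaged over a sub-voxel grid
    fine enough to resolve the tube cross-section; rendering at the voxel
    centres alone would alias the (typically 40 nm) tube on the coarse
    (typically 125 nm) axial pitch and no later blur could remove that.
    """
    vs = np.asarray(voxel_size, dtype=float)
    c = np.asarray(spec.center, dtype=float)
    r = spec.diameter / 2.0
    a = r * math.sqrt(spec.ellipticity)  # semi-major
    b = r / math.sqrt(spec.ellipticity)  # semi-minor
    margin = a + 4.0 * spec.tube_sigma

    lo = np.maximum(np.floor((c - margin) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((c + margin) / vs).astype(int) + 1, np.asarray(img.shape))
    if np.any(hi <= lo):
        return
    step = max(10.0, spec.tube_sigma / 2.0)  # nm between sub-samples
    sub = [max(1, int(math.ceil(vs[i] / step))) for i in range(3)]
    axes = []
    for i in range(3):
        centres = np.arange(lo[i], hi[i]) * vs[i]
        offsets = ((np.arange(sub[i]) + 0.5) / sub[i] - 0.5) * vs[i]
        axes.append((centres[:, None] + offsets[None, :]).ravel() - c[i])
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")

    w = np.asarray(spec.normal)
    u, v = plane_basis(w)
    pu = zz * u[0] + yy * u[1] + xx * u[2]
    pv = zz * v[0] + yy * v[1] + xx * v[2]
    pw = zz * w[0] + yy * w[1] + xx * w[2]

    rip = np.hypot(pu, pv)
    denom = np.sqrt((b * pu) ** 2 + (a * pv) ** 2)
    # radius of the ellipse midline along each voxel's in-plane azimuth;
    # at the centre (rip ~ 0) the nearest midline point is on the minor axis
    rho = np.where(denom > 1e-12, a * b * rip / np.maximum(denom, 1e-12), b)
    d2 = (rip - rho) ** 2 + pw**2
    fine = spec.amplitude * np.exp(-d2 / (2.0 * spec.tube_sigma**2))
    shape6 = (
        hi[0] - lo[0], sub[0],
        hi[1] - lo[1], sub[1],
        hi[2] - lo[2], sub[2],
    )
    coarse = fine.reshape(shape6).mean(axis=(1, 3, 5))
    img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += coarse


def render_rings(
    rings: list[RingSpec],
    canvas_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    channel_name: str = "",
) -> ImageStack:
    """Noise-free, blur-free rendering of a ring list."""
    img = np.zeros(canvas_shape, dtype=np.float64)
    for spec in rings:
        _add_ring(img, spec, voxel_size)
    return ImageStack(data=img, voxel_size=voxel_size, channel_name=channel_name)


def render_scene(scene: Scene) -> dict[str, ImageStack]:
    """Render every channel of a scene (noise-free)."""
    return {
        name: render_rings(rings, scene.canvas_shape, scene.voxel_size, name)
        for name, rings in scene.rings.items()
    }


def apply_blur(stack: ImageStack, sigma_xy: float, sigma_z: float) -> ImageStack:
    """Anisotropic Gaussian blur with physical sigmas (nm) per axis."""
    if sigma_xy < 0 or sigma_z < 0:
        raise ValueError("blur sigmas must be >= 0")
    if sigma_xy == 0 and sigma_z == 0:
        return stack.with_data(stack.data.copy())
    vz, vy, vx = stack.voxel_size
    sig_vox = (sigma_z / vz, sigma_xy / vy, sigma_xy / vx)
    blurred = ndimage.gaussian_filter(
        np.asarray(stack.data, dtype=np.float64), sigma=sig_vox, mode="constant"
    )
    return stack.with_data(blurred)


def add_noise(stack: ImageStack, model: NoiseModel) -> ImageStack:
    """Poisson(photon_scale * value) + N(0, read_sigma) + background.

    Output is in detected counts; identical model (incl. seed) gives a
    bit-identical stack.
    """
    rng = np.random.default_rng(model.seed)
    data = np.clip(np.asarray(stack.data, dtype=np.float64), 0.0, None)
    if model.photon_scale > 0:
        out = rng.poisson(model.photon_scale * data).astype(np.float64)
    else:
        out = np.zeros_like(data)
    if model.read_sigma > 0:
        out += rng.normal(0.0, model.read_sigma, size=out.shape)
    out += model.background
    return stack.with_data(out)


# ---------------------------------------------------------------------------
# two-channel co-occurrence and ROI masks


def make_coloc_pair(
    scene: Scene,
    seed=0,
    jitter_sd: float = 20.0,
) -> tuple[ImageStack, ImageStack, list[dict]]:
    """Build channel 2 from channel 1 with controlled co-occurrence.

    A fraction ``scene.coloc_mixing`` of channel-2 structures are copies of
    randomly chosen channel-1 rings displaced by isotropic Gaussian jitter
    (default SD 20 nm, well below resolution); the remainder are placed
    independently inside the nucleolus.  Returns the two noise-free rendered
    stacks and a per-structure ground-truth record.
    """
    rng = _as_rng(seed)
    rings1 = scene.rings.get("ch1")
    if not rings1:
        raise ValueError("scene must define at least one 'ch1' ring")
    n = len(rings1)
    k = int(round(scene.coloc_mixing * n))
    chosen = sorted(rng.choice(n, size=k, replace=False).tolist())

    rings2: list[RingSpec] = []
    truth: list[dict] = []
    for i in chosen:
        src = rings1[i]
        offset = rng.normal(0.0, jitter_sd, size=3) if jitter_sd > 0 else np.zeros(3)
        moved = RingSpec(
            center=tuple(np.asarray(src.center) + offset),
            diameter=src.diameter,
            normal=src.normal,
            ellipticity=src.ellipticity,
            amplitude=src.amplitude,
            tube_sigma=src.tube_sigma,
        )
        rings2.append(moved)
        truth.append({"colocalized": True, "partner_index": i, "spec": moved})

    n_indep = n - k
    if n_indep > 0:
        diam_pool = np.array([r.diameter for r in rings1])
        indep_diams = rng.choice(diam_pool, size=n_indep, replace=True)
        normals = sample_unit_vectors(n_indep, rng)
        geom = scene.roi_geometry
        center = np.asarray(geom.center)
        semi = np.asarray(geom.nucleolus_semiaxes)
        template = rings1[0]
        for j in range(n_indep):
            pos = _uniform_in_ellipsoid(rng, center, semi)
            spec = RingSpec(
                center=tuple(pos),
                diameter=float(indep_diams[j]),
                normal=tuple(normals[j]),
                ellipticity=template.ellipticity,
                amplitude=template.amplitude,
                tube_sigma=template.tube_sigma,
            )
            rings2.append(spec)
            truth.append({"colocalized": False, "partner_index": None, "spec": spec})

    scene.rings["ch2"] = rings2
    ch1 = render_rings(rings1, scene.canvas_shape, scene.voxel_size, "ch1")
    ch2 = render_rings(rings2, scene.canvas_shape, scene.voxel_size, "ch2")
    return ch1, ch2, truth


def make_roi_masks(scene: Scene) -> RoiSet:
    """Nested ellipsoidal cell / nucleus / nucleolus masks for a scene."""
    geom = scene.roi_geometry
    vs = np.asarray(scene.voxel_size)
    axes = [np.arange(d) * vs[i] - geom.center[i] for i, d in enumerate(scene.canvas_shape)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")

    def ellipsoid(semi):
        return (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2 <= 1.0

    nucleolus = ellipsoid(geom.nucleolus_semiaxes)
    nucleus = ellipsoid(geom.nucleus_semiaxes) | nucleolus
    cell = ellipsoid(geom.cell_semiaxes) | nucleus
    return RoiSet(cell=cell, nucleus=nucleus, nucleolus=nucleolus)


# ---------------------------------------------------------------------------
# ground truth serialization and dataset convenience


def rings_to_json(rings: list[RingSpec], path: str | Path | None = None) -> str:
    """Serialize ring ground truth as JSON (optionally to a file)."""
    payload = json.dumps([asdict(r) for r in rings], indent=2)
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload


def rings_from_json(source: str | Path) -> list[RingSpec]:
    """Inverse of :func:`rings_to_json`; accepts a path or a JSON string."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    records = json.loads(text)
    return [
        RingSpec(
            center=tuple(r["center"]),
            diameter=r["diameter"],
            normal=tuple(r["normal"]),
            ellipticity=r.get("ellipticity", 1.0),
            amplitude=r.get("amplitude", 100.0),
            tube_sigma=r.get("tube_sigma", 40.0),
        )
        for r in records
    ]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFF_FFFF) for s in state]


@dataclass
class SimulatedDataset:
    """Everything one simulated acquisition produces."""

    scene: Scene
    ch1: ImageStack  # noisy, blurred
    ch2: ImageStack
    ch1_clean: ImageStack  # blurred, noise-free
    ch2_clean: ImageStack
    rois: RoiSet
    truth: list[dict]


def simulate_roi_contrast_dataset(
    seed: int = 0,
    n_nucleolar: int = 6,
    n_background: int = 6,
    coloc_mixing: float = 0.9,
    canvas_shape: tuple[int, int, int] = (16, 96, 96),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    sigma_xy: float = DEFAULT_SIGMA_XY,
    sigma_z: float = DEFAULT_SIGMA_Z,
    noise: NoiseModel | None = None,
    amplitude: float = 1000.0,
) -> tuple[ImageStack, ImageStack, RoiSet]:
    """Two channels with co-occurring structures confined to the nucleolus and
    independently placed structures spread over the nucleus — the layout that
    produces nucleolar enrichment of co-occurrence measures.
    """
    s_nuc, s_pair, s_bg1, s_bg2, s_n1, s_n2 = _child_seeds(seed, 6)
    geom = default_roi_geometry(canvas_shape, voxel_size)
    rings1 = sample_ring_population(
        n_nucleolar,
        200.0,
        30.0,
        canvas_shape=canvas_shape,
        voxel_size=voxel_size,
        seed=s_nuc,
        roi_geometry=geom,
        amplitude=amplitude,
    )
    scene = Scene(
        rings={"ch1": rings1},
        canvas_shape=canvas_shape,
        voxel_size=voxel_size,
        coloc_mixing=coloc_mixing,
        roi_geometry=geom,
    )
    ch1, ch2, _ = make_coloc_pair(scene, seed=s_pair)

    # independent background structures per channel, spread over the nucleus
    wide = RoiGeometry(
        center=geom.center,
        cell_semiaxes=geom.cell_semiaxes,
        nucleus_semiaxes=geom.nucleus_semiaxes,
        nucleolus_semiaxes=tuple(0.95 * a for a in geom.nucleus_semiaxes),
    )
    for stack, s_bg in ((ch1, s_bg1), (ch2, s_bg2)):
        bg = sample_ring_population(
            n_background,
            200.0,
            30.0,
            canvas_shape=canvas_shape,
            voxel_size=voxel_size,
            seed=s_bg,
            roi_geometry=wide,
            amplitude=amplitude / 2.0,
        )
        for spec in bg:
            _add_ring(stack.data, spec, voxel_size)

    ch1 = apply_blur(ch1, sigma_xy, sigma_z)
    ch2 = apply_blur(ch2, sigma_xy, sigma_z)
    base = noise or NoiseModel()
    ch1 = add_noise(ch1, NoiseModel(base.photon_scale, base.read_sigma, base.background, s_n1))
    ch2 = add_noise(ch2, NoiseModel(base.photon_scale, base.read_sigma, base.background, s_n2))
    rois = make_roi_masks(scene)
    return ch1, ch2, rois


def simulate_two_channel_dataset(
    n_rings: int = 12,
    diameter_mean: float = 240.0,
    diameter_sd: float = 60.0,
    coloc_mixing: float = 0.9,
    canvas_shape: tuple[int, int, int] = DEFAULT_CANVAS_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    sigma_xy: float = DEFAULT_SIGMA_XY,
    sigma_z: float = DEFAULT_SIGMA_Z,
    noise: NoiseModel | None = None,
    jitter_sd: float = 20.0,
    seed: int = 0,
    amplitude: float = 100.0,
    tube_sigma: float = 40.0,
) -> SimulatedDataset:
    """One full simulated acquisition: place rings, pair channels, blur, noise."""
    s_place, s_pair, s_noise1, s_noise2 = _child_seeds(seed, 4)
    rings1 = sample_ring_population(
        n_rings,
        diameter_mean,
        diameter_sd,
        canvas_shape=canvas_shape,
        voxel_size=voxel_size,
        seed=s_place,
        amplitude=amplitude,
        tube_sigma=tube_sigma,
    )
    scene = Scene(
        rings={"ch1": rings1},
        canvas_shape=canvas_shape,
        voxel_size=voxel_size,
        coloc_mixing=coloc_mixing,
    )
    ch1_raw, ch2_raw, truth = make_coloc_pair(scene, seed=s_pair, jitter_sd=jitter_sd)
    ch1_clean = apply_blur(ch1_raw, sigma_xy, sigma_z)
    ch2_clean = apply_blur(ch2_raw, sigma_xy, sigma_z)
    base = noise or NoiseModel()
    ch1 = add_noise(
        ch1_clean,
        NoiseModel(base.photon_scale, base.read_sigma, base.background, s_noise1),
    )
    ch2 = add_noise(
        ch2_clean,
        NoiseModel(base.photon_scale, base.read_sigma, base.background, s_noise2),
    )
    rois = make_roi_masks(scene)
    return SimulatedDataset(
        scene=scene,
        ch1=ch1,
        ch2=ch2,
        ch1_clean=ch1_clean,
        ch2_clean=ch2_clean,
        rois=rois,
        truth=truth,
    )
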