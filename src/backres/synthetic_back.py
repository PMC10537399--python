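"""Band-limited synthetic back-surface generator.

A human back is, to first order, a smooth surface whose spatial frequency
content sits well below 0.1 mm^-1. The generator emulates that surface class
with a depth field

    z(x, y) = sum_i A_i cos(2 pi fx_i (x - s(y))) cos(2 pi fy_i (y - H/2) + phi_i)
              + Gaussian bumps mirrored about x = s(y)
              + seeded uniform noise,

where s(y) is a lateral symmetry-axis curve (polynomial in normalized
height), so scoliotic lateral asymmetry can be imposed with a known ground
truth. Every cosine term is even in x - s(y) and the bumps are mirrored, so
with s(y) = 0 the surface is exactly left–right symmetric. The sampling grid
is jittered so slice regularization is genuinely exercised.

The generator is its own oracle: each cloud's metadata records the true
symmetry curve, band cap and full parameter set, enabling parameter-recovery
tests of the spectral, degradation and symmetry pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from backres.surface_io import PointCloud

__all__ = [
    "BackModelParams",
    "generate_back",
    "generate_cohort",
    "cohort_manifest",
    "symmetry_offset_curve",
]


def _default_base_components() -> list[tuple[float, float, float, float]]:
    # (amplitude mm, x-frequency mm^-1, y-frequency mm^-1, phase rad)
    # Broad torso rounding plus progressively finer surface relief; all
    # lateral frequencies below the 0.06 mm^-1 band cap.
    return [
        (35.0, 0.0011, 0.0006, 0.0),
        (8.0, 0.008, 0.0025, 0.7),
        (3.0, 0.02, 0.004, 1.3),
        (1.2, 0.04, 0.006, 2.1),
    ]


def _default_bumps() -> list[tuple[float, float, float, float, float]]:
    # (x-offset from axis mm, y-center mm, sigma_x mm, sigma_y mm, amplitude mm)
    # Scapular prominences and paraspinal muscle bulk, mirrored about s(y).
    return [
        (110.0, 390.0, 45.0, 50.0, 6.0),
        (35.0, 250.0, 25.0, 120.0, 3.0),
    ]


@dataclass
class BackModelParams:
    """Parameters of the synthetic back surface.

    ``asymmetry_offset`` holds ascending polynomial coefficients (mm) of the
    lateral symmetry-axis curve s(t) with t = (y - height/2)/(height/2) in
    [-1, 1]; ``(0,)`` means a perfectly symmetric back. ``f_max`` caps all
    component frequencies and the sampling grid must satisfy the sampling
    theorem against it.
    """

    width: float = 454.0
    height: float = 516.0
    base_components: list[tuple[float, float, float, float]] = field(
        default_factory=_default_base_components)
    asymmetry_offset: tuple[float, ...] = (0.0,)
    bump_components: list[tuple[float, float, float, float, float]] = field(
        default_factory=_default_bumps)
    f_max: float = 0.06
    sample_spacing: float = 1.0
    jitter_fraction: float = 0.2
    noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be positive")
        if self.sample_spacing > 1.0 / (2.0 * self.f_max) + 1e-12:
            raise ValueError(
                "sample_spacing violates the sampling theorem for f_max "
                f"({self.sample_spacing} > {1.0 / (2.0 * self.f_max):.3g})")
        for amp, fx, fy, _ in self.base_components:
            if fx > self.f_max + 1e-12 or fy > self.f_max + 1e-12:
                raise ValueError("component frequency exceeds f_max")
        if not 0 <= self.jitter_fraction <= 0.45:
            raise ValueError("jitter_fraction must be in [0, 0.45]")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_components"] = [list(c) for c in self.base_components]
        d["bump_components"] = [list(c) for c in self.bump_components]
        d["asymmetry_offset"] = list(self.asymmetry_offset)
        return d


def symmetry_offset_curve(params: BackModelParams, y: np.ndarray) -> np.ndarray:
    """True lateral symmetry-axis offset s(y) in mm (relative to mid-width)."""
    t = (np.asarray(y, dtype=float) - params.height / 2) / (params.height / 2)
    s = np.zeros_like(t)
    for k, c in enumerate(params.asymmetry_offset):
        s += c * t**k
    return s


def _depth_field(params: BackModelParams, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    s = symmetry_offset_curve(params, y)
    xc = x - (params.width / 2 + s)
    z = np.zeros_like(x, dtype=float)
    for amp, fx, fy, phase in params.base_components:
        z += amp * np.cos(2 * np.pi * fx * xc) * np.cos(
            2 * np.pi * fy * (y - params.height / 2) + phase)
    for x_off, y_c, sx, sy, amp in params.bump_components:
        for sign in (+1.0, -1.0):
            z += amp * np.exp(
                -((xc - sign * x_off) ** 2 / (2 * sx**2)
                  + (y - y_c) ** 2 / (2 * sy**2)))
            if x_off == 0:
                break
    return z


def generate_back(params: BackModelParams | None = None) -> PointCloud:
    """Sample the synthetic surface on a jittered grid into a point cloud.

    Metadata records the full parameter set, the symmetry curve coefficients
    and the band cap for downstream oracle use. Bit-for-bit reproducible
    under a fixed seed.
    """
    params = params or BackModelParams()
    rng = np.random.default_rng(params.seed)
    h = params.sample_spacing
    xs = np.arange(0.0, params.width + 1e-9, h)
    ys = np.arange(0.0, params.height + 1e-9, h)
    gx, gy = np.meshgrid(xs, ys)
    jit = params.jitter_fraction * h
    if jit > 0:
        gx = gx + rng.uniform(-jit, jit, size=gx.shape)
        gy = gy + rng.uniform(-jit, jit, size=gy.shape)
        gx = np.clip(gx, 0.0, params.width)
        gy = np.clip(gy, 0.0, params.height)
    z = _depth_field(params, gx, gy)
    if params.noise_amplitude > 0:
        z = z + rng.uniform(-params.noise_amplitude, params.noise_amplitude,
                            size=z.shape)
    points = np.column_stack([gx.ravel(), gy.ravel(), z.ravel()])
    return PointCloud(
        points=points,
        source_id=f"synthetic-{params.seed}",
        metadata={
            "params": params.to_dict(),
            "asymmetry_offset": list(params.asymmetry_offset),
            "f_max": params.f_max,
        },
    )


#: Ranges the cohort sampler understands: scalar BackModelParams fields plus
#: two convenience multipliers.
_RANGE_KEYS = {
    "width", "height", "noise_amplitude", "sample_spacing",
    "amplitude_scale", "asymmetry_scale",
}

# S-shaped lateral deviation t^3 - t, normalized so its peak is 1, as the
# canonical scoliotic offset shape scaled by "asymmetry_scale" (mm).
_S_SHAPE_PEAK = 2.0 / (3.0 * np.sqrt(3.0))


def generate_cohort(n: int, params_ranges: dict | None = None, seed: int = 0,
                    base: BackModelParams | None = None) -> list[PointCloud]:
    """Generate n synthetic subjects with parameters drawn from ranges.

    ``params_ranges`` maps a parameter name to a (low, high) uniform range.
    Besides scalar :class:`BackModelParams` fields it accepts
    ``amplitude_scale`` (multiplies all base-component amplitudes) and
    ``asymmetry_scale`` (peak lateral deviation, mm, of an S-shaped
    symmetry-axis curve). Each subject gets its own derived seed, so
    degenerate ranges (low = high) still yield distinct jitter/noise draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params_ranges = params_ranges or {}
    unknown = set(params_ranges) - _RANGE_KEYS
    if unknown:
        raise ValueError(f"unknown range keys: {sorted(unknown)}")
    for key, (lo, hi) in params_ranges.items():
        if hi < lo:
            raise ValueError(f"invalid range for {key}: ({lo}, {hi})")
    base = base or BackModelParams()
    rng = np.random.default_rng(seed)
    clouds = []
    for i in range(n):
        draws = {k: float(rng.uniform(lo, hi))
                 for k, (lo, hi) in params_ranges.items()}
        subject_seed = int(rng.integers(0, 2**31 - 1))
        kwargs = base.to_dict()
        kwargs["base_components"] = [tuple(c) for c in kwargs["base_components"]]
        kwargs["bump_components"] = [tuple(c) for c in kwargs["bump_components"]]
        kwargs["asymmetry_offset"] = tuple(kwargs["asymmetry_offset"])
        for k in ("width", "height", "noise_amplitude", "sample_spacing"):
            if k in draws:
                kwargs[k] = draws[k]
        if "amplitude_scale" in draws:
            kwargs["base_components"] = [
                (a * draws["amplitude_scale"], fx, fy, ph)
                for a, fx, fy, ph in kwargs["base_components"]]
        if "asymmetry_scale" in draws:
            a = draws["asymmetry_scale"] / _S_SHAPE_PEAK
            kwargs["asymmetry_offset"] = (0.0, -a, 0.0, a)
        kwargs["seed"] = subject_seed
        params = BackModelParams(**kwargs)
        cloud = generate_back(params)
        cloud.source_id = f"synthetic-{seed}-{i:03d}"
        cloud.metadata["cohort_index"] = i
        clouds.append(cloud)
    return clouds


def cohort_manifest(clouds: list[PointCloud]) -> list[dict]:
    """True parameter sets of a cohort, JSON-serializable."""
    return [
        {"source_id": c.source_id, **c.metadata}
        for c in clouds
    ]
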