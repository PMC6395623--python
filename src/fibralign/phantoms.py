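"""Synthetic fibrous phantoms with known orientation statistics.

The directionality statistics have no deposited reference micrographs, so
validation rests on phantoms: fields of straight, anti-aliased fibre
segments whose orientations are drawn either from a wrapped normal on the
half-turn circle (aligned mats, mean ``mu0`` and dispersion ``sigma0``) or
uniformly on [0, 180) (isotropic controls).  Every generated image carries
its ground truth, making parameter-recovery and monotonicity experiments
possible end to end.

The generator deliberately emulates only the features the spectral
statistics respond to — elongated bright structures on a darker background
with additive sensor noise; it does not model fibre curvature, branching,
SEM speckle or confocal Poisson statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .images import GrayImage

WRAPPED_NORMAL = "wrapped_normal"
UNIFORM = "uniform"

#: grids of the standard benchmark suite
BENCHMARK_SIGMA0_LEVELS: tuple = (5.0, 15.0, 30.0, 60.0, None)  # None = uniform
BENCHMARK_MU0_LEVELS: tuple = (0.0, 30.0, 90.0, 120.0)


@dataclass(frozen=True)
class FiberFieldSpec:
    """Parameters of a synthetic fibre-field image.

    ``orientation_model`` is ``"wrapped_normal"`` (with ``mu0_deg``,
    ``sigma0_deg``) or ``"uniform"``.  Lengths are drawn from a normal with
    the given (mean, sd) in pixels; each fibre is an anti-aliased straight
    segment of ``width_px`` at intensity ``fiber_intensity`` over
    ``background``, with additive Gaussian noise of SD ``noise_sd`` and the
    result clipped to [0, 1].
    """

    image_px: int = 825
    n_fibers: int = 300
    orientation_model: str = WRAPPED_NORMAL
    mu0_deg: float = 0.0
    sigma0_deg: float = 10.0
    length_px: tuple[float, float] = (400.0, 80.0)
    width_px: float = 3.0
    fiber_intensity: float = 0.8
    background: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_px < 3:
            raise ParameterError(f"image_px must be >= 3, got {self.image_px}")
        if self.n_fibers < 0:
            raise ParameterError("n_fibers must be non-negative")
        if self.orientation_model not in (WRAPPED_NORMAL, UNIFORM):
            raise ParameterError(
                f"orientation_model must be {WRAPPED_NORMAL!r} or {UNIFORM!r}, "
                f"got {self.orientation_model!r}")
        if self.orientation_model == WRAPPED_NORMAL and self.sigma0_deg <= 0:
            raise ParameterError(
                f"sigma0_deg must be > 0 for wrapped_normal, got {self.sigma0_deg}")
        if not 0.0 < self.fiber_intensity <= 1.0:
            raise ParameterError("fiber_intensity must be in (0, 1]")
        if not 0.0 <= self.background < 1.0:
            raise ParameterError("background must be in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.background + self.noise_sd >= self.fiber_intensity:
            raise ParameterError(
                "fibers must rise above the noise floor: require "
                "background + noise_sd < fiber_intensity")
        if self.width_px <= 0:
            raise ParameterError("width_px must be positive")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth attached to a rendered phantom."""

    orientations_deg: np.ndarray  # per-fibre orientation, mod 180
    orientation_model: str
    mu0_deg: float | None
    sigma0_deg: float | None
    seed: int

    def __post_init__(self):
        object.__setattr__(
            self, "orientations_deg",
            np.asarray(self.orientations_deg, dtype=float) % 180.0)


def sample_orientations(spec: FiberFieldSpec) -> PhantomTruth:
    """Draw the per-fibre orientations prescribed by ``spec``.

    Wrapped-normal angles are ``(mu0 + sigma0 * z) mod 180`` with standard
    normal ``z``; the uniform model draws directly from [0, 180).  Identical
    specs (including seed) give identical draws.
    """
    rng = np.random.default_rng([spec.seed, 0])
    if spec.orientation_model == UNIFORM:
        angles = rng.uniform(0.0, 180.0, size=spec.n_fibers)
        mu0: float | None = None
        sigma0: float | None = None
    else:
        angles = (spec.mu0_deg
                  + spec.sigma0_deg * rng.standard_normal(spec.n_fibers)) % 180.0
        mu0, sigma0 = spec.mu0_deg, spec.sigma0_deg
    return PhantomTruth(orientations_deg=angles,
                        orientation_model=spec.orientation_model,
                        mu0_deg=mu0, sigma0_deg=sigma0, seed=spec.seed)


def _paint_segment(canvas: np.ndarray, p0, p1, width: float) -> None:
    """Max-accumulate the anti-aliased coverage of one segment onto canvas.

    Coverage follows a 1 px linear ramp around the half-width, giving
    sub-pixel endpoints and no axis locking at grid-aligned angles.
    """
    n_rows, n_cols = canvas.shape
    margin = width / 2.0 + 1.5
    c0 = max(int(np.floor(min(p0[0], p1[0]) - margin)), 0)
    c1 = min(int(np.ceil(max(p0[0], p1[0]) + margin)) + 1, n_cols)
    r0 = max(int(np.floor(min(p0[1], p1[1]) - margin)), 0)
    r1 = min(int(np.ceil(max(p0[1], p1[1]) + margin)) + 1, n_rows)
    if c0 >= c1 or r0 >= r1:
        return
    xs = np.arange(c0, c1, dtype=float)
    ys = np.arange(r0, r1, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    seg_len2 = vx * vx + vy * vy
    if seg_len2 == 0.0:
        dist = np.hypot(X - p0[0], Y - p0[1])
    else:
        t = ((X - p0[0]) * vx + (Y - p0[1]) * vy) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(X - (p0[0] + t * vx), Y - (p0[1] + t * vy))
    cov = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
    np.maximum(canvas[r0:r1, c0:c1], cov, out=canvas[r0:r1, c0:c1])


def render_fiber_image(truth: PhantomTruth, spec: FiberFieldSpec) -> GrayImage:
    """Render the phantom image for a set of sampled orientations.

    Fibre centres are uniform over the image, lengths normal with the spec's
    (mean, sd) floored at 4 px; overlapping fibres occlude (max-composite)
    rather than add, as opaque fibres do in a micrograph.  Background and
    clipped additive Gaussian noise complete the image.  Rendering is fully
    determined by ``truth`` and ``spec``.
    """
    n = spec.image_px
    canvas = np.zeros((n, n), dtype=float)
    rng = np.random.default_rng([spec.seed, 1])
    mean_len, sd_len = spec.length_px
    for theta in truth.orientations_deg:
        length = max(float(rng.normal(mean_len, sd_len)), 4.0)
        cx = float(rng.uniform(0.0, n))
        cy = float(rng.uniform(0.0, n))
        rad = np.radians(theta)
        hx = 0.5 * length * np.cos(rad)
        hy = 0.5 * length * np.sin(rad)
        _paint_segment(canvas, (cx - hx, cy - hy), (cx + hx, cy + hy),
                       spec.width_px)
    img = spec.background + canvas * (spec.fiber_intensity - spec.background)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(n, n))
    img = np.clip(img, 0.0, 1.0)
    tag = (f"{spec.orientation_model}"
           + (f"_mu{spec.mu0_deg:g}_s{spec.sigma0_deg:g}"
              if spec.orientation_model == WRAPPED_NORMAL else "")
           + f"_seed{spec.seed}")
    return GrayImage(pixels=img, source_id=f"phantom_{tag}")


def generate_phantom(spec: FiberFieldSpec) -> tuple[GrayImage, PhantomTruth]:
    """Sample orientations and render in one call."""
    truth = sample_orientations(spec)
    return render_fiber_image(truth, spec), truth


def _child_seed(base_seed: int, index: int) -> int:
    """Deterministic per-image seed below 2**31."""
    state = np.random.SeedSequence([int(base_seed), int(index)])
    return int(state.generate_state(1)[0] % (2**31 - 1))


def make_benchmark_suite(out_dir, seed: int,
                         sigma0_levels=BENCHMARK_SIGMA0_LEVELS,
                         mu0_levels=BENCHMARK_MU0_LEVELS,
                         replicates: int = 3,
                         image_px: int = 825,
                         n_fibers: int = 300,
                         **spec_overrides) -> pd.DataFrame:
    """Write a fixed grid of phantoms plus a ground-truth manifest.

    The default grid crosses dispersion levels sigma0 in {5, 15, 30, 60 deg,
    uniform} with mean directions mu0 in {0, 30, 90, 120 deg} and 3
    replicates: 60 16-bit TIFFs.  The manifest CSV has one row per file with
    columns (file, model, mu0_deg, sigma0_deg, n_fibers, seed); regeneration
    with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    index = 0
    for sigma0 in sigma0_levels:
        for mu0 in mu0_levels:
            for rep in range(replicates):
                child = _child_seed(seed, index)
                index += 1
                if sigma0 is None:
                    model = UNIFORM
                    spec = FiberFieldSpec(image_px=image_px, n_fibers=n_fibers,
                                          orientation_model=UNIFORM,
                                          seed=child, **spec_overrides)
                    name = f"phantom_uniform_mu{int(mu0):03d}_rep{rep}.tif"
                else:
                    model = WRAPPED_NORMAL
                    spec = FiberFieldSpec(image_px=image_px, n_fibers=n_fibers,
                                          orientation_model=WRAPPED_NORMAL,
                                          mu0_deg=float(mu0),
                                          sigma0_deg=float(sigma0),
                                          seed=child, **spec_overrides)
                    name = (f"phantom_wn_mu{int(mu0):03d}"
                            f"_sig{int(sigma0):03d}_rep{rep}.tif")
                img, _ = generate_phantom(spec)
                data16 = np.round(img.pixels * 65535.0).astype(np.uint16)
                tifffile.imwrite(out_dir / name, data16)
                rows.append({"file": name, "model": model,
                             "mu0_deg": "" if sigma0 is None else float(mu0),
                             "sigma0_deg": "" if sigma0 is None else float(sigma0),
                             "n_fibers": n_fibers, "seed": child})
    manifest = pd.DataFrame(rows, columns=["file", "model", "mu0_deg",
                                           "sigma0_deg", "n_fibers", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
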