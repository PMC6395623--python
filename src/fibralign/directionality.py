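"""Fourier-spectrum directionality statistics for fibrous images.

The anisotropy of a fibrous image (electrospun scaffold fibres, immunostained
neurites) is quantified from the modulus of its 2D discrete Fourier
transform.  Elongated structures at spatial orientation theta concentrate
spectral energy along the perpendicular direction theta + 90 deg, so the
shape of the spectral mass encodes how tightly orientations cluster:

* the modulus, recentred so the zero-frequency (DC) term sits at the central
  pixel, is treated as an unnormalised probability mass over frequency
  coordinates;
* high-frequency noise is suppressed by zeroing all values below a cutoff
  estimated from the maxima of 64x64 blocks at the four corners of the
  centred matrix (the most noise-dominated region);
* the three second-order central moments of the surviving mass define an
  equivalent covariance ellipse. Its eccentricity
  ``eps = sqrt(1 - lambda_min/lambda_max)`` tends to 0 for isotropic
  structure and approaches 1 for perfect alignment, and the *short* axis of
  the frequency-domain ellipse points along the prevailing spatial
  direction mu;
* independently, spectral mass is summed into equal-width angular sectors
  over a 180 deg half-turn (antipodal pixels pooled, Hermitian symmetry
  makes them redundant) and the angular standard deviation sigma is the
  square root of the weighted sample variance of that normalised angular
  distribution, computed after recentring at the circular mean.

Orientations are undirected, so every angle here lives on the half-turn
circle: mu in [0, 180) deg, sigma in [0, 90] deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSpectrumError, ImageInputError, ParameterError
from .images import GrayImage

DEFAULT_CORNER_PX = 64
DEFAULT_N_SECTORS = 180

#: eccentricity below which the ellipse is near-circular and its orientation
#: (hence mu) carries no information beyond noise
ORIENTATION_RELIABLE_MIN_ECC = 1e-3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectrumDistribution:
    """Centred FFT-modulus matrix treated as unnormalised probability mass.

    ``modulus`` has the same shape as the source image with the DC term at
    index ``(h//2, w//2)``.  ``cutoff`` records the noise limit already
    applied (0 if none) and ``dc_excluded`` whether the DC pixel was zeroed.
    """

    modulus: np.ndarray
    cutoff: float = 0.0
    dc_excluded: bool = False
    source_id: str = ""

    @property
    def center(self) -> tuple[int, int]:
        h, w = self.modulus.shape
        return h // 2, w // 2

    def centered_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer frequency coordinate grids (u horizontal, v vertical)."""
        h, w = self.modulus.shape
        v = np.arange(h, dtype=float) - h // 2
        u = np.arange(w, dtype=float) - w // 2
        uu, vv = np.meshgrid(u, v)
        return uu, vv

    @property
    def total_mass(self) -> float:
        return float(self.modulus.sum())


@dataclass(frozen=True)
class MomentSummary:
    """Second-order central-moment summary of a spectral mass distribution."""

    total_mass: float
    centroid: tuple[float, float]  # (u_bar, v_bar) in centred frequency coords
    mu20: float
    mu02: float
    mu11: float
    lambda_major: float
    lambda_minor: float


@dataclass(frozen=True)
class AngularDistribution:
    """Normalised distribution of spectral mass over orientation sectors.

    ``bin_centers_deg`` are frequency-domain angles on [0, 180); ``weights``
    sum to 1.  ``fit_mu_deg``/``fit_sigma_deg`` are filled by
    :func:`fit_angular_normal`.
    """

    bin_centers_deg: np.ndarray
    weights: np.ndarray
    fit_mu_deg: float | None = None
    fit_sigma_deg: float | None = None


@dataclass(frozen=True)
class AlignmentResult:
    """Full directionality readout for one image.

    ``mu_deg`` is the prevailing spatial orientation (degrees, [0, 180)),
    ``sigma_deg`` the angular standard deviation of the sector distribution
    and ``eccentricity_eps`` the covariance-ellipse eccentricity in [0, 1].
    Intermediates are retained for audit.
    """

    source_id: str
    eccentricity_eps: float
    mu_deg: float
    sigma_deg: float
    ellipse_angle_freq_deg: float
    moments: MomentSummary
    angular: AngularDistribution
    cutoff: float
    flags: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# spectral operations
# ---------------------------------------------------------------------------

def hann_window_2d(shape: tuple[int, int]) -> np.ndarray:
    """Separable 2D Hann window, used optionally to suppress the axis-aligned
    cross artefact produced by the periodic extension of a rectangular crop."""
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def compute_spectrum(img: GrayImage, window: str = "none") -> SpectrumDistribution:
    """Modulus of the 2D DFT of an image, recentred so DC is the central pixel.

    Parameters
    ----------
    img : GrayImage
        Input intensity grid (finite, non-negative).
    window : {"none", "hann"}
        Optional apodisation applied before the transform. Default "none".
    """
    px = img.pixels
    if not np.all(np.isfinite(px)):
        raise ImageInputError("image contains non-finite pixels")
    if window == "hann":
        px = px * hann_window_2d(px.shape)
    elif window != "none":
        raise ParameterError(f"unknown window {window!r} (expected none|hann)")
    mod = np.abs(np.fft.fftshift(np.fft.fft2(px)))
    return SpectrumDistribution(modulus=mod, cutoff=0.0, dc_excluded=False,
                                source_id=img.source_id)


def estimate_noise_cutoff(spec: SpectrumDistribution,
                          corner_px: int = DEFAULT_CORNER_PX) -> float:
    """Noise limit: the maximum modulus over the four corner blocks.

    The corners of the *centred* spectrum hold the highest spatial
    frequencies, where fibrous structure contributes essentially nothing and
    the modulus is noise-dominated; the single maximum over all four
    ``corner_px`` x ``corner_px`` blocks is the most conservative
    deterministic floor.
    """
    if corner_px < 1:
        raise ParameterError(f"corner_px must be positive, got {corner_px}")
    h, w = spec.modulus.shape
    if corner_px > min(h, w) // 2 - 1:
        raise ParameterError(
            f"corner blocks of {corner_px} px would overlap the centre of a "
            f"{h}x{w} spectrum"
        )
    m = spec.modulus
    c = corner_px
    corners = (m[:c, :c], m[:c, -c:], m[-c:, :c], m[-c:, -c:])
    return float(max(block.max() for block in corners))


def apply_cutoff(spec: SpectrumDistribution, cutoff: float,
                 exclude_dc: bool = True) -> SpectrumDistribution:
    """Zero all modulus values strictly below ``cutoff`` (and the DC pixel).

    The DC term is proportional to mean image brightness and has no defined
    orientation, so it is excluded by default before any moment or sector
    computation.

    Values within one part in 1e9 of the cutoff count as at the cutoff and
    are kept: the pixel that defines a corner-max cutoff has modulus exactly
    equal to it, and without the slack its retention would depend on
    arithmetic rounding order (e.g. flip under a global intensity rescaling
    that perturbs both sides by an ulp).

    Raises
    ------
    DegenerateSpectrumError
        If no mass survives — the image is blank or indistinguishable from
        noise at the estimated floor.
    """
    if cutoff < 0:
        raise ParameterError(f"cutoff must be >= 0, got {cutoff}")
    mod = spec.modulus.copy()
    mod[mod < cutoff * (1.0 - 1e-9)] = 0.0
    if exclude_dc:
        mod[spec.center] = 0.0
    if mod.sum() <= 0.0:
        raise DegenerateSpectrumError(
            f"cutoff {cutoff:g} removed all spectral mass "
            f"(blank or noise-only image)"
        )
    return SpectrumDistribution(modulus=mod, cutoff=float(cutoff),
                                dc_excluded=exclude_dc,
                                source_id=spec.source_id)


def second_order_moments(spec: SpectrumDistribution) -> MomentSummary:
    """Centroid and second-order central moments of the spectral mass.

    The modulus is normalised to a probability mass ``w(u, v)`` over centred
    integer frequency coordinates; ``mu20``, ``mu02``, ``mu11`` are the
    central moments and the covariance eigenvalues are returned sorted
    (major first).
    """
    total = spec.total_mass
    if total <= 0:
        raise DegenerateSpectrumError("spectrum has zero total mass")
    w = spec.modulus / total
    uu, vv = spec.centered_coords()
    u_bar = float((w * uu).sum())
    v_bar = float((w * vv).sum())
    du = uu - u_bar
    dv = vv - v_bar
    mu20 = float((w * du * du).sum())
    mu02 = float((w * dv * dv).sum())
    mu11 = float((w * du * dv).sum())
    # closed-form eigenvalues of [[mu20, mu11], [mu11, mu02]]
    half_trace = 0.5 * (mu20 + mu02)
    disc = np.hypot(0.5 * (mu20 - mu02), mu11)
    lam_major = half_trace + disc
    lam_minor = max(half_trace - disc, 0.0)
    return MomentSummary(total_mass=total, centroid=(u_bar, v_bar),
                         mu20=mu20, mu02=mu02, mu11=mu11,
                         lambda_major=float(lam_major),
                         lambda_minor=float(lam_minor))


def equivalent_ellipse(m: MomentSummary) -> tuple[float, float]:
    """Eccentricity and long-axis orientation of the equivalent ellipse.

    Returns
    -------
    (eccentricity_eps, ellipse_angle_freq_deg)
        ``eps = sqrt(1 - lambda_minor/lambda_major)`` in [0, 1]; the angle of
        the major eigenvector in frequency space, degrees in [0, 180).
    """
    if m.lambda_major <= 0:
        raise DegenerateSpectrumError(
            "all spectral mass concentrated at a single point; "
            "no ellipse is defined"
        )
    ecc = float(np.sqrt(max(0.0, 1.0 - m.lambda_minor / m.lambda_major)))
    angle = 0.5 * np.degrees(np.arctan2(2.0 * m.mu11, m.mu20 - m.mu02))
    return ecc, float(angle % 180.0)


def prevailing_direction(ellipse_angle_freq_deg: float) -> float:
    """Spatial alignment direction mu from the frequency-domain long axis.

    A structure oriented at mu in image space concentrates spectral mass
    perpendicular to itself, so the short frequency-domain axis — i.e. the
    long axis rotated a quarter turn — gives the spatial direction:
    ``mu = (angle + 90) mod 180``.
    """
    if not np.isfinite(ellipse_angle_freq_deg):
        raise ParameterError("ellipse angle must be finite")
    return float((ellipse_angle_freq_deg + 90.0) % 180.0)


def angular_sector_distribution(spec: SpectrumDistribution,
                                n_sectors: int = DEFAULT_N_SECTORS
                                ) -> AngularDistribution:
    """Spectral mass summed into equal-width orientation sectors.

    Each off-centre pixel is assigned the angle ``atan2(v, u)`` folded into
    the [0, 180) half-turn (antipodal pixels pool together — their moduli are
    equal by Hermitian symmetry), and the modulus is summed per sector.  The
    result is normalised to total weight 1.  The DC pixel, whose angle is
    undefined, never contributes.
    """
    if n_sectors < 8:
        raise ParameterError(f"need at least 8 sectors, got {n_sectors}")
    mod = spec.modulus.copy()
    mod[spec.center] = 0.0  # angle undefined at the origin
    total = mod.sum()
    if total <= 0:
        raise DegenerateSpectrumError("no off-centre spectral mass to bin")
    uu, vv = spec.centered_coords()
    ang = np.degrees(np.arctan2(vv, uu)) % 180.0
    width = 180.0 / n_sectors
    idx = np.minimum((ang / width).astype(int), n_sectors - 1)
    sums = np.bincount(idx.ravel(), weights=mod.ravel(), minlength=n_sectors)
    weights = sums / total
    centers = (np.arange(n_sectors) + 0.5) * width
    return AngularDistribution(bin_centers_deg=centers, weights=weights)


def circular_mean_halfturn(angles_deg: np.ndarray,
                           weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of undirected orientations (period 180 deg)."""
    angles = np.asarray(angles_deg, dtype=float)
    if weights is None:
        weights = np.full(angles.shape, 1.0 / angles.size)
    doubled = np.radians(2.0 * angles)
    s = float((weights * np.sin(doubled)).sum())
    c = float((weights * np.cos(doubled)).sum())
    return float((0.5 * np.degrees(np.arctan2(s, c))) % 180.0)


def fit_angular_normal(dist: AngularDistribution) -> tuple[float, float]:
    """Weighted-mean / weighted-variance normal fit on the half-turn circle.

    The sector angles are recentred so the weighted circular mean sits in the
    middle of a (-90, 90] window — unwrapping the half-turn circle without
    wrap bias — and a plain weighted mean and weighted sample variance are
    taken there.  Returns ``(fit_mu_deg, fit_sigma_deg)`` with the mean
    mapped back to [0, 180).
    """
    weights = np.asarray(dist.weights, dtype=float)
    centers = np.asarray(dist.bin_centers_deg, dtype=float)
    if centers.size < 8:
        raise ParameterError(f"need at least 8 sectors, got {centers.size}")
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ParameterError("weights must be normalised to sum 1")
    mu_c = circular_mean_halfturn(centers, weights)
    # deviations on (-90, 90] around the circular mean
    dev = (centers - mu_c + 90.0) % 180.0 - 90.0
    dev_bar = float((weights * dev).sum())
    var = float((weights * (dev - dev_bar) ** 2).sum())
    fit_mu = float((mu_c + dev_bar) % 180.0)
    fit_sigma = float(np.sqrt(max(var, 0.0)))
    return fit_mu, fit_sigma


def log_display_normalize(spec: SpectrumDistribution) -> np.ndarray:
    """Log-scale display normalisation of a spectrum, for visualisation only.

    ``log(1 + modulus)`` linearly rescaled to [0, 1]; a constant (or all-zero)
    spectrum maps to all zeros.  Never used by the statistics.
    """
    logm = np.log1p(spec.modulus)
    lo, hi = float(logm.min()), float(logm.max())
    if hi <= lo:
        return np.zeros_like(logm)
    return (logm - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# pipeline composition
# ---------------------------------------------------------------------------

def analyze(img: GrayImage,
            corner_px: int = DEFAULT_CORNER_PX,
            n_sectors: int = DEFAULT_N_SECTORS,
            window: str = "none",
            exclude_dc: bool = True) -> AlignmentResult:
    """Run the full directionality pipeline on an in-memory image.

    Composes spectrum computation, corner-block noise cutoff, moment /
    equivalent-ellipse analysis and the sector-sum angular distribution; any
    stage failure is re-raised as :class:`~fibralign.errors.StageError` with
    the stage name attached.
    """
    from .errors import StageError

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    spec = _stage("compute_spectrum", compute_spectrum, img, window=window)
    cutoff = _stage("estimate_noise_cutoff", estimate_noise_cutoff, spec,
                    corner_px=corner_px)
    spec = _stage("apply_cutoff", apply_cutoff, spec, cutoff,
                  exclude_dc=exclude_dc)
    moments = _stage("second_order_moments", second_order_moments, spec)
    ecc, freq_angle = _stage("equivalent_ellipse", equivalent_ellipse, moments)
    mu = _stage("prevailing_direction", prevailing_direction, freq_angle)
    dist = _stage("angular_sector_distribution", angular_sector_distribution,
                  spec, n_sectors=n_sectors)
    fit_mu, fit_sigma = _stage("fit_angular_normal", fit_angular_normal, dist)
    dist = AngularDistribution(bin_centers_deg=dist.bin_centers_deg,
                               weights=dist.weights,
                               fit_mu_deg=fit_mu, fit_sigma_deg=fit_sigma)
    flags: list[str] = []
    if ecc < ORIENTATION_RELIABLE_MIN_ECC:
        flags.append("orientation_unreliable")
    return AlignmentResult(source_id=img.source_id,
                           eccentricity_eps=ecc,
                           mu_deg=mu,
                           sigma_deg=fit_sigma,
                           ellipse_angle_freq_deg=freq_angle,
                           moments=moments,
                           angular=dist,
                           cutoff=spec.cutoff,
                           flags=tuple(flags))


def analyze_image(path, config=None) -> AlignmentResult:
    """Load an image file and run :func:`analyze` with the given configuration.

    ``config`` is an :class:`~fibralign.config.AnalysisConfig` (or None for
    defaults).
    """
    from .config import AnalysisConfig
    from .errors import StageError
    from .images import load_and_prepare

    cfg = config if config is not None else AnalysisConfig()
    try:
        img = load_and_prepare(path, crop_px=cfg.crop_px)
    except Exception as exc:
        raise StageError("load_and_prepare", str(exc)) from exc
    return analyze(img, corner_px=cfg.corner_px, n_sectors=cfg.n_sectors,
                   window=cfg.window, exclude_dc=cfg.exclude_dc)
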