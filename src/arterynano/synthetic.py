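"""Synthetic-data generators with known ground truth.

Everything downstream (curve processing, densitometry, co-registration,
statistics) is exercised against data produced here: Hertzian approach
curves with instrument artefacts, polarized-light-like images with known
per-ROI bright-fibre coverage, grid-landmark image pairs related by a
known 2-D transform, and bivariately coupled (log-modulus, density)
cohorts.

Ground-truth group moduli follow a lognormal distribution — the model
observed for arterial nano-indentation data — parameterised analytically
from the group median m and interquartile range IQR:

    mu = ln(m),   sigma = asinh(IQR / (2 m)) / z_0.75

which reproduces the requested quartiles exactly under the lognormal
quantile function.

All generators are deterministic given a seed (or a caller-provided
``numpy.random.Generator``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri
from skimage.draw import line_aa

from .collagen import RoiBox, roi_pixel_slices
from .coreg import LandmarkSet, Transform2D
from .errors import ArteryNanoError
from .force import ForceCurve
from .hertz import TipGeometry
from .stats import CoregPair

_Z75 = float(ndtri(0.75))


def _as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


# ---------------------------------------------------------------------------
# Group parameters and lognormal calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Population ground truth for one histological group."""

    label: str
    median_E_kPa: float
    iqr_E_kPa: float
    n_rois: int
    median_density_pct: float | None = None

    def __post_init__(self) -> None:
        if not self.median_E_kPa > 0:
            raise ValueError(f"{self.label}: median modulus must be positive")
        if self.iqr_E_kPa < 0:
            raise ValueError(f"{self.label}: IQR must be non-negative")
        if self.n_rois < 1:
            raise ValueError(f"{self.label}: n_rois must be >= 1")
        if self.median_density_pct is not None and not 0.0 <= self.median_density_pct <= 100.0:
            raise ValueError(f"{self.label}: density must be in [0, 100]")


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given median and IQR.

    Closed form: the quartiles are exp(mu +/- sigma*z75), so
    IQR = 2 m sinh(sigma z75).
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if iqr < 0:
        raise ValueError("IQR must be non-negative")
    return float(np.log(median)), float(np.arcsinh(iqr / (2.0 * median)) / _Z75)


def sample_group_moduli(
    group: GroupParams,
    rng_or_seed=None,
    n: int | None = None,
    method: str = "stratified",
) -> np.ndarray:
    """Draw per-ROI ground-truth moduli for one group.

    ``method="stratified"`` (default) takes one inverse-CDF draw per
    equal-probability stratum in a random order, so even small cohorts
    embody the calibrated quantiles of the group distribution;
    ``method="iid"`` gives plain independent draws.
    """
    rng = _as_rng(rng_or_seed)
    n = group.n_rois if n is None else n
    mu, sigma = lognormal_from_median_iqr(group.median_E_kPa, group.iqr_E_kPa)
    if sigma == 0.0:
        return np.full(n, group.median_E_kPa)
    if method == "stratified":
        u = (rng.permutation(n) + rng.uniform(size=n)) / n
    elif method == "iid":
        u = rng.uniform(size=n)
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    return np.exp(mu + sigma * ndtri(u))


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Instrument artefacts applied to the force channel.

    ``relative_force_noise`` expresses the additive noise SD as a
    fraction of the curve's own peak Hertz force, matching how noise
    floors are usually quoted relative to the working force range; it
    adds to the absolute ``deflection_noise_sd_nN``.
    """

    deflection_noise_sd_nN: float = 0.0
    baseline_slope_nN_per_um: float = 0.0
    baseline_offset_nN: float = 0.0
    contact_jitter_sd_um: float = 0.0
    relative_force_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.deflection_noise_sd_nN < 0 or self.contact_jitter_sd_um < 0 or self.relative_force_noise < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class RampSpec:
    """Approach ramp: target indentation depth and sampling."""

    depth_um: float = 1.0
    n_samples: int = 200
    pre_contact_um: float = 1.5

    def __post_init__(self) -> None:
        if not self.depth_um > 0:
            raise ValueError("ramp depth must be positive")
        if self.n_samples < 50:
            raise ValueError("need at least 50 samples per curve")
        if not self.pre_contact_um > 0:
            raise ValueError("pre-contact travel must be positive")


def _cantilever_deflection_um(s_um: np.ndarray, modulus_kPa: float, tip: TipGeometry, k_N_per_m: float) -> np.ndarray:
    """Deflection d solving k d = C E (s - d)^2 for tip-sample travel s > 0.

    Uses the cancellation-free root d = 2 a s^2 / ((2 a s + K) +
    sqrt(K^2 + 4 a s K)) with a = C E [nN/um^2], K = 1000 k [nN/um].
    """
    a = tip.prefactor * modulus_kPa
    big_k = 1000.0 * k_N_per_m
    s = np.clip(s_um, 0.0, None)
    return 2.0 * a * s**2 / ((2.0 * a * s + big_k) + np.sqrt(big_k**2 + 4.0 * a * s * big_k))


def generate_force_curve(
    true_E_kPa: float,
    tip: TipGeometry = TipGeometry(),
    ramp: RampSpec = RampSpec(),
    noise: NoiseModel = NoiseModel(),
    rng_or_seed=None,
    spring_constant_N_per_m: float = 0.6,
    section_thickness_um: float = 20.0,
    roi_id: str | None = None,
    position: tuple[int, int] | None = None,
) -> ForceCurve:
    """Forward-simulate one approach curve for a sample of known modulus.

    Before contact the deflection carries only baseline offset/tilt and
    noise; past contact the force follows the pyramidal Hertz law in the
    indentation depth exactly (the static cantilever-sample force
    balance is solved per sample).  The true contact point and modulus
    are stored in ``truth``.
    """
    if not true_E_kPa > 0:
        raise ValueError("true modulus must be positive")
    rng = _as_rng(rng_or_seed)
    k = spring_constant_N_per_m

    z0 = ramp.pre_contact_um + rng.normal(0.0, noise.contact_jitter_sd_um)
    z0 = float(np.clip(z0, 0.3 * ramp.pre_contact_um, ramp.pre_contact_um + 5 * max(noise.contact_jitter_sd_um, 1e-12)))
    # piezo travel needed to reach the target depth: depth + deflection there
    d_full_um = tip.prefactor * true_E_kPa * ramp.depth_um**2 / (1000.0 * k)
    z_max = z0 + ramp.depth_um + d_full_um
    z = np.linspace(0.0, z_max, ramp.n_samples)

    d_um = _cantilever_deflection_um(z - z0, true_E_kPa, tip, k)
    deflection_nm = 1000.0 * d_um
    baseline_nN = noise.baseline_offset_nN + noise.baseline_slope_nN_per_um * z
    deflection_nm = deflection_nm + baseline_nN / k
    peak_force_nN = tip.prefactor * true_E_kPa * ramp.depth_um**2
    noise_sd_nN = noise.deflection_noise_sd_nN + noise.relative_force_noise * peak_force_nN
    if noise_sd_nN > 0:
        deflection_nm = deflection_nm + rng.normal(0.0, noise_sd_nN / k, z.size)

    return ForceCurve(
        piezo_height_um=z,
        deflection_nm=deflection_nm,
        spring_constant_N_per_m=k,
        section_thickness_um=section_thickness_um,
        roi_id=roi_id,
        position=position,
        truth={"true_E_kPa": float(true_E_kPa), "contact_point_um": z0, "peak_force_nN": peak_force_nN},
    )


# ---------------------------------------------------------------------------
# ROI datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiGridSpec:
    """Indentation layout within one square ROI."""

    side_um: float = 50.0
    pitch_um: float = 10.0

    def positions(self) -> np.ndarray:
        """(n, 2) grid of indentation sites (um, ROI-local), centred."""
        k = int(round(self.side_um / self.pitch_um))
        offs = (np.arange(k) + 0.5) * self.pitch_um
        xx, yy = np.meshgrid(offs, offs)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class RoiSample:
    """Ground truth and simulated curves for one indentation ROI."""

    roi_id: str
    label: str
    true_E_kPa: float
    curves: list[ForceCurve]


def generate_roi_dataset(
    groups: list[GroupParams],
    grid: RoiGridSpec = RoiGridSpec(),
    noise: NoiseModel = NoiseModel(),
    rng_or_seed=None,
    tip: TipGeometry = TipGeometry(),
    ramp: RampSpec = RampSpec(),
    spring_constant_N_per_m: float = 0.6,
    section_thickness_um: float = 20.0,
    sampling_method: str = "stratified",
) -> list[RoiSample]:
    """Simulate every ROI of every group: one ground-truth modulus per
    ROI drawn from the group's calibrated lognormal, and one curve per
    grid position (5x5 at the default 50 um side / 10 um pitch)."""
    if not groups:
        raise ArteryNanoError("need at least one group")
    rng = _as_rng(rng_or_seed)
    positions = grid.positions()
    out: list[RoiSample] = []
    for group in groups:
        moduli = sample_group_moduli(group, rng, method=sampling_method)
        for i, true_e in enumerate(moduli):
            roi_id = f"{group.label}_{i:03d}"
            curves = [
                generate_force_curve(
                    float(true_e),
                    tip=tip,
                    ramp=ramp,
                    noise=noise,
                    rng_or_seed=rng,
                    spring_constant_N_per_m=spring_constant_N_per_m,
                    section_thickness_um=section_thickness_um,
                    roi_id=roi_id,
                    position=(j // int(np.sqrt(len(positions))), j % int(np.sqrt(len(positions)))),
                )
                for j in range(len(positions))
            ]
            out.append(RoiSample(roi_id=roi_id, label=group.label, true_E_kPa=float(true_e), curves=curves))
    return out


# ---------------------------------------------------------------------------
# Polarized-light-like images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FibreTexture:
    """Bright straight-segment texture parameters (pixels)."""

    width_px: float = 2.0
    length_px_range: tuple[float, float] = (12.0, 40.0)
    orientation_spread_deg: float = 180.0  # isotropic by default


def _draw_fibre(view: np.ndarray, rng: np.random.Generator, texture: FibreTexture,
                background_level: int, fibre_levels: tuple[int, int]) -> None:
    """Stamp one anti-aliased straight segment into ``view`` (in place)."""
    h, w = view.shape
    r0 = rng.uniform(0, h)
    c0 = rng.uniform(0, w)
    angle = np.radians(rng.uniform(0.0, texture.orientation_spread_deg))
    length = rng.uniform(*texture.length_px_range)
    dr, dc = 0.5 * length * np.sin(angle), 0.5 * length * np.cos(angle)
    # perpendicular unit vector for thickness
    pr, pc = np.cos(angle), -np.sin(angle)
    level = rng.integers(fibre_levels[0], fibre_levels[1] + 1)
    n_strands = max(int(round(texture.width_px)), 1)
    for s in range(n_strands):
        off = s - 0.5 * (n_strands - 1)
        ra, ca = r0 - dr + off * pr, c0 - dc + off * pc
        rb, cb = r0 + dr + off * pr, c0 + dc + off * pc
        rr, cc, val = line_aa(
            int(np.clip(round(ra), 0, h - 1)), int(np.clip(round(ca), 0, w - 1)),
            int(np.clip(round(rb), 0, h - 1)), int(np.clip(round(cb), 0, w - 1)),
        )
        shade = background_level + val * (level - background_level)
        np.maximum.at(view, (rr, cc), shade.astype(view.dtype))


def generate_polarized_image(
    shape_px: tuple[int, int],
    pixel_pitch_um: float,
    rois: list[tuple[RoiBox, float]],
    texture: FibreTexture = FibreTexture(),
    rng_or_seed=None,
    threshold: int = 75,
    background_levels: tuple[int, int] = (5, 55),
    fibre_levels: tuple[int, int] = (150, 255),
) -> tuple[np.ndarray, dict[str, float]]:
    """8-bit greyscale polarized-light-like image with known coverage.

    Dark noisy background (all levels below ``threshold``); per ROI,
    bright fibre segments are placed until the fraction of pixels at or
    above ``threshold`` reaches the requested coverage, then trimmed at
    pixel granularity so the truth coverage is exact to one pixel.
    Returns the image and a map roi_id -> true coverage (percent).
    """
    rng = _as_rng(rng_or_seed)
    if background_levels[1] >= threshold:
        raise ValueError("background levels must stay below the threshold")
    if fibre_levels[0] < threshold:
        raise ValueError("fibre levels must be at or above the threshold")
    image = rng.integers(background_levels[0], background_levels[1] + 1, size=shape_px).astype(np.uint8)
    truth: dict[str, float] = {}
    for box, coverage in rois:
        if not 0.0 <= coverage <= 100.0:
            raise ValueError(f"{box.roi_id}: coverage must be in [0, 100]")
        rows, cols = roi_pixel_slices(box, pixel_pitch_um, image.shape)
        view = image[rows, cols]
        total = view.size
        target = int(round(coverage / 100.0 * total))
        if target == total:
            view[:, :] = rng.integers(fibre_levels[0], fibre_levels[1] + 1, size=view.shape)
        elif target > 0:
            budget = 200 * total  # hard cap on stamped pixels before speckle fill
            stamped = 0
            while int(np.count_nonzero(view >= threshold)) < target and stamped < budget:
                _draw_fibre(view, rng, texture, background_levels[1], fibre_levels)
                stamped += int(texture.width_px * texture.length_px_range[1])
            bright = np.flatnonzero(view >= threshold)
            if bright.size < target:  # dense ROI: fill remainder with speckle
                dark = np.flatnonzero(view < threshold)
                pick = rng.choice(dark, size=target - bright.size, replace=False)
                view[np.unravel_index(pick, view.shape)] = rng.integers(
                    fibre_levels[0], fibre_levels[1] + 1, size=pick.size
                )
            elif bright.size > target:  # trim overshoot back to background
                pick = rng.choice(bright, size=bright.size - target, replace=False)
                view[np.unravel_index(pick, view.shape)] = rng.integers(
                    background_levels[0], background_levels[1] + 1, size=pick.size
                )
        truth[box.roi_id] = 100.0 * target / total
    return image, truth


# ---------------------------------------------------------------------------
# Grid-landmark image pairs
# ---------------------------------------------------------------------------


@dataclass
class GridPair:
    """Two brightfield-like images related by a known transform."""

    image_a: np.ndarray
    image_b: np.ndarray
    landmarks: LandmarkSet
    true_transform: Transform2D
    pixel_pitch_um: float


def _grid_image(shape_px: tuple[int, int], pitch_px: float, bg: int = 230, line: int = 40,
                line_width_px: int = 2) -> np.ndarray:
    img = np.full(shape_px, bg, dtype=np.uint8)
    for r in np.arange(0.0, shape_px[0], pitch_px):
        lo = int(round(r))
        img[max(lo - line_width_px // 2, 0) : lo + (line_width_px + 1) // 2, :] = line
    for c in np.arange(0.0, shape_px[1], pitch_px):
        lo = int(round(c))
        img[:, max(lo - line_width_px // 2, 0) : lo + (line_width_px + 1) // 2] = line
    return img


def generate_grid_pair(
    true_transform: Transform2D,
    image_shape_px: tuple[int, int] = (400, 400),
    pixel_pitch_um: float = 1.0,
    grid_pitch_um: float = 50.0,
    landmark_noise_sd_um: float = 0.0,
    rng_or_seed=None,
) -> GridPair:
    """Grid-stamped image pair plus landmark lists in both frames.

    Landmarks are the grid intersections of frame A; their frame-B
    coordinates are the transform image plus isotropic Gaussian noise.
    Image B is the warp of image A under the true transform.
    """
    rng = _as_rng(rng_or_seed)
    h_um = image_shape_px[0] * pixel_pitch_um
    w_um = image_shape_px[1] * pixel_pitch_um
    xs = np.arange(grid_pitch_um, w_um - 0.5 * grid_pitch_um, grid_pitch_um)
    ys = np.arange(grid_pitch_um, h_um - 0.5 * grid_pitch_um, grid_pitch_um)
    xx, yy = np.meshgrid(xs, ys)
    src = np.column_stack([xx.ravel(), yy.ravel()])
    dst = true_transform.apply(src)
    if landmark_noise_sd_um > 0:
        dst = dst + rng.normal(0.0, landmark_noise_sd_um, dst.shape)

    image_a = _grid_image(image_shape_px, grid_pitch_um / pixel_pitch_um)
    # warp: B(p) = A(T^{-1}(p)); transform matrices act on um, images on px
    from skimage.transform import AffineTransform, warp

    scale_to_um = np.diag([pixel_pitch_um, pixel_pitch_um, 1.0])
    m_px = np.linalg.inv(scale_to_um) @ true_transform.matrix @ scale_to_um
    image_b = warp(image_a, AffineTransform(matrix=np.linalg.inv(m_px)), preserve_range=True, cval=255)
    image_b = np.round(image_b).astype(np.uint8)
    return GridPair(
        image_a=image_a,
        image_b=image_b,
        landmarks=LandmarkSet(src_um=src, dst_um=dst, grid_pitch_um=grid_pitch_um),
        true_transform=true_transform,
        pixel_pitch_um=pixel_pitch_um,
    )


# ---------------------------------------------------------------------------
# Coupled (log-modulus, density) cohorts
# ---------------------------------------------------------------------------


def generate_coregistered_cohort(
    groups: list[GroupParams],
    rho_true: float,
    rng_or_seed=None,
    density_sd_pct: float = 8.0,
    sampling_method: str = "stratified",
) -> list[CoregPair]:
    """Draw (median modulus, collagen density) pairs per group such that
    the population correlation of (log E, density) equals ``rho_true``.

    Densities are the conditional Gaussian given the modulus z-score,
    centred on the group's median density; values are clipped to
    [0, 100] (rare at the defaults).
    """
    if not -1.0 <= rho_true <= 1.0:
        raise ValueError("rho_true must be in [-1, 1]")
    rng = _as_rng(rng_or_seed)
    pairs: list[CoregPair] = []
    for group in groups:
        if group.median_density_pct is None:
            raise ArteryNanoError(f"group {group.label!r} lacks a median density")
        mu, sigma = lognormal_from_median_iqr(group.median_E_kPa, group.iqr_E_kPa)
        moduli = sample_group_moduli(group, rng, method=sampling_method)
        z1 = (np.log(moduli) - mu) / sigma if sigma > 0 else np.zeros(group.n_rois)
        z2 = rng.standard_normal(group.n_rois)
        density = group.median_density_pct + density_sd_pct * (
            rho_true * z1 + np.sqrt(1.0 - rho_true**2) * z2
        )
        density = np.clip(density, 0.0, 100.0)
        for i in range(group.n_rois):
            pairs.append(
                CoregPair(
                    roi_id=f"{group.label}_{i:03d}",
                    label=group.label,
                    median_E_kPa=float(moduli[i]),
                    density_pct=float(density[i]),
                )
            )
    return pairs
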