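"""Force-curve processing: from raw approach curves to QC-filtered moduli.

The chain mirrors standard AFM force-spectroscopy batch processing:
baseline (offset + tilt) removal, contact-point detection, conversion of
piezo travel and cantilever deflection to indentation depth and force,
closed-form Hertz fit, and quality-control filtering.  Per 50x50 um ROI
the median modulus over the accepted fits is the representative value.

Conventions
-----------
* piezo height in um, increasing towards/into the sample over the approach;
* cantilever deflection in nm; force F[nN] = k[N/m] * d[nm]
  (1 N/m == 1 nN/nm);
* indentation depth delta[um] = (z - z0) - d[um], i.e. piezo travel past
  the contact point minus the cantilever deflection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ContactNotFoundError, FitError, FormatError, ProcessingError
from .hertz import TipGeometry

MIN_SAMPLES = 50


@dataclass
class ForceCurve:
    """One approach force-indentation record.

    ``truth`` carries generator ground truth (true modulus, true contact
    point) when the curve is synthetic; it is never consulted by the
    processing chain.
    """

    piezo_height_um: np.ndarray
    deflection_nm: np.ndarray
    spring_constant_N_per_m: float
    section_thickness_um: float = 20.0
    roi_id: str | None = None
    position: tuple[int, int] | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.piezo_height_um, dtype=float)
        d = np.asarray(self.deflection_nm, dtype=float)
        if z.ndim != 1 or d.shape != z.shape:
            raise FormatError("height and deflection must be 1-D arrays of equal length")
        if z.size < MIN_SAMPLES:
            raise FormatError(f"curve has {z.size} samples, need at least {MIN_SAMPLES}")
        dz = np.diff(z)
        if np.all(dz < 0):  # store approach with height ascending
            z, d = z[::-1], d[::-1]
            dz = -dz[::-1]
        if not np.all(dz > 0):
            raise FormatError("non-monotone approach: piezo height must be strictly monotone")
        if not self.spring_constant_N_per_m > 0:
            raise FormatError("spring constant must be positive")
        if not self.section_thickness_um > 0:
            raise FormatError("section thickness must be positive")
        self.piezo_height_um = z
        self.deflection_nm = d

    @property
    def n_samples(self) -> int:
        return int(self.piezo_height_um.size)

    @property
    def force_nN(self) -> np.ndarray:
        return self.spring_constant_N_per_m * self.deflection_nm

    def with_deflection(self, deflection_nm: np.ndarray) -> "ForceCurve":
        return replace(self, deflection_nm=np.asarray(deflection_nm, dtype=float))


@dataclass
class HertzFit:
    """Result of fitting the pyramidal Hertz model to one curve."""

    E_kPa: float
    contact_point_um: float
    max_indentation_um: float
    rms_residual_nN: float
    accepted: bool = True
    reason: str | None = None

    def rejected(self, reason: str) -> "HertzFit":
        return replace(self, accepted=False, reason=reason)


@dataclass
class RoiRecord:
    """Per-ROI aggregate: 25 fits reduced to one representative modulus."""

    roi_id: str
    label: str
    fits: list[HertzFit]
    median_E_kPa: float
    n_accepted: int
    n_rejected: int
    usable: bool


# ---------------------------------------------------------------------------
# I/O: per-curve TSV (piezo_height_um, deflection_nm) + JSON sidecar
# ---------------------------------------------------------------------------

_HEIGHT_COLS = {"piezo_height_um": 1.0, "piezo_height_nm": 1e-3}
_DEFL_COLS = {"deflection_nm": 1.0, "deflection_um": 1e3}


def read_force_curve(path: str | Path) -> ForceCurve:
    """Read one curve from ``<path>`` (TSV) and its ``.json`` sidecar.

    Heights and deflections are normalized to um / nm on read regardless
    of the column units used in the file.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surfaced as a format error
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    height = deflection = None
    for col, fac in _HEIGHT_COLS.items():
        if col in table.columns:
            height = table[col].to_numpy(dtype=float) * fac
    for col, fac in _DEFL_COLS.items():
        if col in table.columns:
            deflection = table[col].to_numpy(dtype=float) * fac
    if height is None or deflection is None:
        raise FormatError(
            f"{path}: missing required columns "
            f"(need one of {sorted(_HEIGHT_COLS)} and one of {sorted(_DEFL_COLS)})"
        )
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    if "spring_constant_N_per_m" not in meta:
        raise FormatError(f"{sidecar}: spring_constant_N_per_m absent")
    position = meta.get("position")
    try:
        return ForceCurve(
            piezo_height_um=height,
            deflection_nm=deflection,
            spring_constant_N_per_m=float(meta["spring_constant_N_per_m"]),
            section_thickness_um=float(meta.get("section_thickness_um", 20.0)),
            roi_id=meta.get("roi_id"),
            position=tuple(position) if position is not None else None,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_force_curve(curve: ForceCurve, path: str | Path) -> Path:
    """Write ``curve`` as TSV + JSON sidecar; returns the TSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "piezo_height_um": curve.piezo_height_um,
            "deflection_nm": curve.deflection_nm,
        }
    ).to_csv(path, sep="\t", index=False)
    meta = {
        "spring_constant_N_per_m": curve.spring_constant_N_per_m,
        "section_thickness_um": curve.section_thickness_um,
        "roi_id": curve.roi_id,
        "position": list(curve.position) if curve.position is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# Processing chain
# ---------------------------------------------------------------------------


def correct_baseline(
    curve: ForceCurve,
    fit_fraction: float = 0.3,
    min_samples: int = 20,
    n_fit: int | None = None,
) -> ForceCurve:
    """Remove constant offset and linear tilt from the pre-contact baseline.

    A straight line is fitted to the leading ``fit_fraction`` of the
    approach (which must lie before contact; ``n_fit`` overrides the
    fraction with an explicit sample count) and subtracted from the
    whole deflection signal, since offset and tilt are instrument
    artefacts affecting the entire channel.
    """
    if n_fit is None:
        n_fit = int(round(fit_fraction * curve.n_samples))
    if n_fit < min_samples:
        raise ProcessingError(
            f"baseline fit needs >= {min_samples} pre-contact samples, window has {n_fit}"
        )
    z = curve.piezo_height_um
    force = curve.force_nN
    slope, intercept = np.polyfit(z[:n_fit], force[:n_fit], 1)
    corrected = force - (slope * z + intercept)
    return curve.with_deflection(corrected / curve.spring_constant_N_per_m)


def _piecewise_rss(z0: float, z: np.ndarray, force: np.ndarray, tip_sample_sep: np.ndarray) -> float:
    """Residual sum of squares of the flat + Hertz-parabola model at contact z0."""
    u = np.clip(tip_sample_sep - z0, 0.0, None) ** 2
    suu = float(u @ u)
    if suu <= 0.0:
        return float(force @ force)
    b = max(float(u @ force) / suu, 0.0)
    resid = force - b * u
    return float(resid @ resid)


def detect_contact_point(
    curve: ForceCurve,
    noise_factor: float = 5.0,
    min_post_samples: int = 10,
    refine_xatol_um: float = 1e-8,
) -> float:
    """Locate the contact point of a baseline-corrected approach curve.

    A change-point scan over sample positions fits the piecewise model
    "zero force before contact, Hertz parabola in the indentation depth
    after contact" and the sample minimising the residual sum of squares
    seeds a bounded continuous refinement (Brent) of z0.  The parabola
    abscissa already uses the true indentation depth
    (z - z0) - deflection, so on clean curves the objective vanishes
    exactly at the true contact point.
    """
    z = curve.piezo_height_um
    force = curve.force_nN
    n = z.size
    lead = force[: max(int(0.3 * n), min(20, n))]
    noise_sd = 1.4826 * np.median(np.abs(lead - np.median(lead)))
    if force.max() <= max(noise_factor * noise_sd, 1e-12):
        raise ContactNotFoundError("no contact: force never rises above the noise floor")

    # tip-sample separation: the candidate-independent part of the depth
    sep = z - force / (1000.0 * curve.spring_constant_N_per_m)
    n_cand = n - min_post_samples
    cand = z[:n_cand]
    u = np.clip(sep[None, :] - cand[:, None], 0.0, None) ** 2  # (n_cand, n)
    suu = np.einsum("ij,ij->i", u, u)
    sfu = u @ force
    b = np.where(suu > 0, sfu / np.where(suu > 0, suu, 1.0), 0.0)
    b = np.clip(b, 0.0, None)
    rss = force @ force - 2.0 * b * sfu + b**2 * suu
    j = int(np.argmin(rss))

    lo = z[max(j - 2, 0)]
    hi = z[min(j + 2, n - 1)]
    if hi <= lo:
        return float(z[j])
    res = minimize_scalar(
        _piecewise_rss,
        bounds=(lo, hi),
        args=(z, force, sep),
        method="bounded",
        options={"xatol": refine_xatol_um},
    )
    z0 = float(res.x)
    if _piecewise_rss(float(z[j]), z, force, sep) < res.fun:
        z0 = float(z[j])
    return z0


def compute_indentation(curve: ForceCurve, z0_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Post-contact (indentation depth um, force nN) series.

    delta = (z - z0) - d, with d the cantilever deflection expressed in
    um; clipped at zero so the series starts at the contact point.
    """
    z = curve.piezo_height_um
    force = curve.force_nN
    mask = z >= z0_um
    d_um = force[mask] / (1000.0 * curve.spring_constant_N_per_m)
    delta = np.clip((z[mask] - z0_um) - d_um, 0.0, None)
    return delta, force[mask]


def fit_hertz(
    delta_um: np.ndarray,
    force_nN: np.ndarray,
    tip: TipGeometry,
    contact_point_um: float = np.nan,
    min_samples: int = 10,
) -> HertzFit:
    """Least-squares Hertz fit, linear in E given delta^2.

    E_hat = sum(F * delta^2) / (C * sum(delta^4)); the RMS of the force
    residuals (nN) quantifies goodness of fit.
    """
    delta = np.asarray(delta_um, dtype=float)
    force = np.asarray(force_nN, dtype=float)
    if int(np.count_nonzero(delta > 0)) < min_samples:
        raise FitError(f"fewer than {min_samples} post-contact samples with positive depth")
    x = delta**2
    denom = float(x @ x)
    if denom <= 0.0:
        raise FitError("all-zero indentation depth")
    prefac = tip.prefactor
    modulus = float(x @ force) / (prefac * denom)
    resid = force - prefac * modulus * x
    fit = HertzFit(
        E_kPa=modulus,
        contact_point_um=float(contact_point_um),
        max_indentation_um=float(delta.max()),
        rms_residual_nN=float(np.sqrt(np.mean(resid**2))),
    )
    if modulus <= 0:
        return fit.rejected("nonphysical")
    return fit


def qc_filter(
    fit: HertzFit,
    curve: ForceCurve,
    max_depth_fraction: float = 0.10,
    max_rms_fraction: float = 0.10,
    modulus_bounds_kPa: tuple[float, float] = (0.01, 1e4),
) -> HertzFit:
    """Quality-control verdict for one fit; always returns a verdict.

    Rejects when the indentation exceeds ``max_depth_fraction`` of the
    section thickness (linear-regime rule), when the RMS residual
    exceeds ``max_rms_fraction`` of the peak force, or when the modulus
    is outside physically plausible bounds.
    """
    if not fit.accepted:
        return fit
    if fit.max_indentation_um > max_depth_fraction * curve.section_thickness_um:
        return fit.rejected("depth_exceeds_thickness_fraction")
    peak = float(np.max(np.abs(curve.force_nN)))
    if peak > 0 and fit.rms_residual_nN > max_rms_fraction * peak:
        return fit.rejected("poor_fit")
    lo, hi = modulus_bounds_kPa
    if not lo <= fit.E_kPa <= hi:
        return fit.rejected("modulus_out_of_bounds")
    return fit


def process_curve(
    curve: ForceCurve,
    tip: TipGeometry,
    baseline_fraction: float = 0.3,
    max_depth_fraction: float = 0.10,
    max_rms_fraction: float = 0.10,
    modulus_bounds_kPa: tuple[float, float] = (0.01, 1e4),
) -> HertzFit:
    """Full chain: baseline -> contact point -> indentation -> fit -> QC.

    Processing failures (no contact, too few samples) become rejected
    fits with a reason code rather than exceptions, so batch runs keep
    full discard accounting.

    The baseline is fitted twice: a conservative leading window locates
    the contact point, after which the line is refitted over the whole
    pre-contact region — a longer lever arm that keeps the extrapolated
    baseline from tilting the post-contact force.
    """
    try:
        corrected = correct_baseline(curve, fit_fraction=baseline_fraction)
        z0 = detect_contact_point(corrected)
        z = curve.piezo_height_um
        spacing = (z[-1] - z[0]) / (z.size - 1)
        n_pre = int(np.searchsorted(z, z0 - 3.0 * spacing))
        if n_pre >= 20:
            corrected = correct_baseline(curve, n_fit=n_pre)
            z0 = detect_contact_point(corrected)
        delta, force = compute_indentation(corrected, z0)
        fit = fit_hertz(delta, force, tip, contact_point_um=z0)
        return qc_filter(
            fit,
            corrected,
            max_depth_fraction=max_depth_fraction,
            max_rms_fraction=max_rms_fraction,
            modulus_bounds_kPa=modulus_bounds_kPa,
        )
    except ContactNotFoundError:
        return HertzFit(np.nan, np.nan, np.nan, np.nan, accepted=False, reason="no_contact")
    except ProcessingError as exc:
        return HertzFit(np.nan, np.nan, np.nan, np.nan, accepted=False, reason=str(exc))


def aggregate_roi(fits: list[HertzFit], label: str, roi_id: str = "") -> RoiRecord:
    """Median modulus over the accepted fits of one ROI.

    Even counts use the mean of the two central order statistics.  With
    zero accepted fits the ROI is flagged unusable (median NaN).
    """
    accepted = [f.E_kPa for f in fits if f.accepted]
    n_acc = len(accepted)
    return RoiRecord(
        roi_id=roi_id,
        label=label,
        fits=list(fits),
        median_E_kPa=float(np.median(accepted)) if n_acc else float("nan"),
        n_accepted=n_acc,
        n_rejected=len(fits) - n_acc,
        usable=n_acc >= 1,
    )
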