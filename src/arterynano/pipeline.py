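"""End-to-end synthetic study: simulate -> fit -> densitometry ->
co-registration -> statistics, with every stage deterministic given the
configured seed.

The default study configuration reproduces the geometry of a two-vessel
comparison: a healthy medial-wall group plus three plaque constituents
(lipid-rich necrotic core, fibrous cap shoulder, mid-cap), each with its
own lognormal modulus distribution and, where histology permits, a
collagen density distribution coupled to the modulus field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import collagen as ci
from . import coreg as cr
from . import force as fp
from . import stats as st
from . import synthetic as syn
from .errors import ConfigError
from .hertz import TipGeometry

OUTPUT_FILES = (
    "fits.csv",
    "density.csv",
    "mapped_rois.csv",
    "pairs.csv",
    "summaries.json",
    "stats.json",
)


@dataclass(frozen=True)
class GroupConfig:
    label: str
    median_E_kPa: float
    iqr_E_kPa: float
    n_rois: int
    n_curves: int | None = None  # trim per-curve tallies to a printed total
    median_density_pct: float | None = None
    n_density_rois: int | None = None  # how many ROIs carry histology

    def as_params(self) -> syn.GroupParams:
        return syn.GroupParams(
            label=self.label,
            median_E_kPa=self.median_E_kPa,
            iqr_E_kPa=self.iqr_E_kPa,
            n_rois=self.n_rois,
            median_density_pct=self.median_density_pct,
        )


@dataclass(frozen=True)
class CoregConfig:
    """Ground-truth transform chain AFM -> stained -> polarized."""

    afm_to_stained: dict = field(
        default_factory=lambda: {"rotation_deg": 3.0, "scale": 1.01, "translation_um": (40.0, -25.0)}
    )
    stained_to_polarized: dict = field(
        default_factory=lambda: {"rotation_deg": -2.0, "scale": 0.99, "translation_um": (15.0, 30.0)}
    )
    landmark_noise_sd_um: float = 0.5
    image_shape_px: tuple[int, int] = (600, 600)
    pixel_pitch_um: float = 1.0
    grid_pitch_um: float = 50.0
    heldout_fraction: float = 0.2


@dataclass(frozen=True)
class PipelineConfig:
    groups: tuple[GroupConfig, ...]
    seed: int = 0
    tip: TipGeometry = TipGeometry()
    ramp: syn.RampSpec = syn.RampSpec()
    noise: syn.NoiseModel = syn.NoiseModel(relative_force_noise=0.05, baseline_offset_nN=0.2,
                                           baseline_slope_nN_per_um=0.05, contact_jitter_sd_um=0.05)
    spring_constant_N_per_m: float = 0.6
    section_thickness_um: float = 20.0
    threshold: int = 75
    bin_size: int = 6
    density_rho: float = 0.6
    density_sd_pct: float = 8.0
    density_pixel_pitch_um: float = 0.5
    comparisons: tuple[tuple[str, str], ...] = ()
    coreg: CoregConfig = CoregConfig()
    sampling_method: str = "stratified"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigError("config needs at least one group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError("group labels must be unique")
        if not 0 <= self.threshold <= 255:
            raise ConfigError("threshold must be in [0, 255]")
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        if not -1.0 <= self.density_rho <= 1.0:
            raise ConfigError("density_rho must be in [-1, 1]")
        for a, b in self.comparisons:
            for lbl in (a, b):
                if lbl not in labels and lbl not in _COMPOSITES:
                    raise ConfigError(f"comparison references unknown group {lbl!r}")


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build and validate a PipelineConfig from plain (YAML-friendly) data."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    try:
        groups = tuple(GroupConfig(**g) for g in raw.get("groups", []))
        kwargs: dict = {"groups": groups}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "tip" in raw:
            kwargs["tip"] = TipGeometry(**raw["tip"])
        if "ramp" in raw:
            kwargs["ramp"] = syn.RampSpec(**raw["ramp"])
        if "noise" in raw:
            kwargs["noise"] = syn.NoiseModel(**raw["noise"])
        if "coreg" in raw:
            cfg = dict(raw["coreg"])
            if "image_shape_px" in cfg:
                cfg["image_shape_px"] = tuple(cfg["image_shape_px"])
            kwargs["coreg"] = CoregConfig(**cfg)
        if "comparisons" in raw:
            kwargs["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        for key in (
            "spring_constant_N_per_m",
            "section_thickness_um",
            "threshold",
            "bin_size",
            "density_rho",
            "density_sd_pct",
            "density_pixel_pitch_um",
            "sampling_method",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_study_config(seed: int = 0) -> PipelineConfig:
    """Study conditions: per-group medians/IQRs, densities and sample
    sizes of the healthy/plaque coronary cohort this package analyses."""
    return PipelineConfig(
        seed=seed,
        groups=(
            GroupConfig("healthy_wall", 11.0, 8.6, n_rois=67, n_curves=1379,
                        median_density_pct=32.4, n_density_rois=67),
            GroupConfig("lipid_core", 2.2, 1.7, n_rois=16, n_curves=392,
                        median_density_pct=2.7, n_density_rois=7),
            GroupConfig("fibrous_cap_shoulder", 4.8, 3.4, n_rois=26, n_curves=638,
                        median_density_pct=17.8, n_density_rois=14),
            GroupConfig("fibrous_cap_mid", 5.1, 2.8, n_rois=35, n_curves=868,
                        median_density_pct=14.7, n_density_rois=10),
        ),
        comparisons=(
            ("healthy_wall", "plaque"),
            ("lipid_core", "fibrous_cap"),
            ("fibrous_cap_shoulder", "fibrous_cap_mid"),
        ),
    )


_COMPOSITES = {
    "plaque": ("lipid_core", "fibrous_cap_shoulder", "fibrous_cap_mid"),
    "fibrous_cap": ("fibrous_cap_shoulder", "fibrous_cap_mid"),
}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def simulate_cohort(config: PipelineConfig, rng: np.random.Generator) -> list[syn.RoiSample]:
    return syn.generate_roi_dataset(
        [g.as_params() for g in config.groups],
        noise=config.noise,
        rng_or_seed=rng,
        tip=config.tip,
        ramp=config.ramp,
        spring_constant_N_per_m=config.spring_constant_N_per_m,
        section_thickness_um=config.section_thickness_um,
        sampling_method=config.sampling_method,
    )


def fit_cohort(
    roi_samples: list[syn.RoiSample], config: PipelineConfig
) -> tuple[pd.DataFrame, list[fp.RoiRecord]]:
    """Run the full force-processing chain over every simulated curve."""
    rows = []
    records: list[fp.RoiRecord] = []
    for roi in roi_samples:
        fits = [fp.process_curve(c, config.tip) for c in roi.curves]
        records.append(fp.aggregate_roi(fits, roi.label, roi_id=roi.roi_id))
        for j, (curve, fit) in enumerate(zip(roi.curves, fits)):
            rows.append(
                {
                    "roi_id": roi.roi_id,
                    "label": roi.label,
                    "position": j,
                    "E_kPa": fit.E_kPa,
                    "z0_um": fit.contact_point_um,
                    "delta_max_um": fit.max_indentation_um,
                    "rms_nN": fit.rms_residual_nN,
                    "accepted": fit.accepted,
                    "reason": fit.reason or "",
                    "true_E_kPa": curve.truth.get("true_E_kPa"),
                }
            )
    return pd.DataFrame(rows), records


def _density_targets(
    config: PipelineConfig, roi_samples: list[syn.RoiSample], rng: np.random.Generator
) -> dict[str, float]:
    """Ground-truth coverage per density-carrying ROI, coupled to the
    ROI's modulus z-score with correlation ``density_rho``."""
    targets: dict[str, float] = {}
    rho = config.density_rho
    for g in config.groups:
        if g.median_density_pct is None:
            continue
        n_d = g.n_density_rois if g.n_density_rois is not None else g.n_rois
        mu, sigma = syn.lognormal_from_median_iqr(g.median_E_kPa, g.iqr_E_kPa)
        rois = [r for r in roi_samples if r.label == g.label][:n_d]
        for roi in rois:
            z1 = (np.log(roi.true_E_kPa) - mu) / sigma if sigma > 0 else 0.0
            cov = g.median_density_pct + config.density_sd_pct * (
                rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal()
            )
            targets[roi.roi_id] = float(np.clip(cov, 0.5, 99.5))
    return targets


def measure_collagen(
    config: PipelineConfig, roi_samples: list[syn.RoiSample], rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Render per-group polarized-light tiles at the coupled coverages
    and measure them back through the thresholding chain."""
    targets = _density_targets(config, roi_samples, rng)
    pitch = config.density_pixel_pitch_um
    side = 50.0
    tile_px = int(round(side / pitch)) + 8  # 4-px gutter around each ROI
    rows = []
    images: dict[str, np.ndarray] = {}
    for g in config.groups:
        ids = [r.roi_id for r in roi_samples if r.label == g.label and r.roi_id in targets]
        if not ids:
            continue
        n_cols = int(np.ceil(np.sqrt(len(ids))))
        n_rows = int(np.ceil(len(ids) / n_cols))
        shape = (n_rows * tile_px, n_cols * tile_px)
        boxes = []
        for i, roi_id in enumerate(ids):
            r, c = divmod(i, n_cols)
            boxes.append(
                ci.RoiBox(roi_id, x_um=(c * tile_px + 4) * pitch, y_um=(r * tile_px + 4) * pitch, side_um=side)
            )
        image, truth = syn.generate_polarized_image(
            shape, pitch, [(b, targets[b.roi_id]) for b in boxes],
            rng_or_seed=rng, threshold=config.threshold,
        )
        images[g.label] = image
        measured = ci.measure_rois(image, boxes, pitch, threshold=config.threshold)
        for meas, box in zip(measured, boxes):
            rows.append(
                {
                    "roi_id": meas.roi_id,
                    "label": g.label,
                    "density_pct": meas.density_pct,
                    "true_coverage_pct": truth[box.roi_id],
                    "threshold": config.threshold,
                }
            )
    return pd.DataFrame(rows), images


def _transform_from(params: dict) -> cr.Transform2D:
    return cr.Transform2D.similarity(
        rotation_deg=params.get("rotation_deg", 0.0),
        scale=params.get("scale", 1.0),
        translation_um=tuple(params.get("translation_um", (0.0, 0.0))),
    )


def coregister_stage(
    config: PipelineConfig, roi_samples: list[syn.RoiSample], rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Estimate the AFM->stained and stained->polarized legs from noisy
    grid landmarks, compose them, map the ROI boxes and score the chain
    on held-out landmarks."""
    cc = config.coreg
    t_ab = _transform_from(cc.afm_to_stained)
    t_bc = _transform_from(cc.stained_to_polarized)
    pair_ab = syn.generate_grid_pair(
        t_ab, cc.image_shape_px, cc.pixel_pitch_um, cc.grid_pitch_um, cc.landmark_noise_sd_um, rng
    )
    pair_bc = syn.generate_grid_pair(
        t_bc, cc.image_shape_px, cc.pixel_pitch_um, cc.grid_pitch_um, cc.landmark_noise_sd_um, rng
    )

    def split(lms: cr.LandmarkSet) -> tuple[cr.LandmarkSet, cr.LandmarkSet]:
        n = len(lms)
        n_hold = max(int(round(cc.heldout_fraction * n)), 1)
        idx = rng.permutation(n)
        hold, fit = idx[:n_hold], idx[n_hold:]
        return (
            cr.LandmarkSet(lms.src_um[fit], lms.dst_um[fit], lms.grid_pitch_um),
            cr.LandmarkSet(lms.src_um[hold], lms.dst_um[hold], lms.grid_pitch_um),
        )

    fit_ab, hold_ab = split(pair_ab.landmarks)
    fit_bc, hold_bc = split(pair_bc.landmarks)
    est_ab = cr.estimate_transform(fit_ab, "similarity")
    est_bc = cr.estimate_transform(fit_bc, "similarity")
    chain = cr.compose(est_ab.transform, est_bc.transform)
    true_chain = cr.compose(t_ab, t_bc)

    # held-out chain landmarks: true chain images of held-out AFM points + noise
    chain_hold = cr.LandmarkSet(
        hold_ab.src_um,
        true_chain.apply(hold_ab.src_um)
        + rng.normal(0.0, cc.landmark_noise_sd_um, hold_ab.src_um.shape),
        cc.grid_pitch_um,
    )
    err = cr.coregistration_error(chain, chain_hold)

    # lay the indentation ROIs out on a grid in the AFM frame and map them
    h_um = cc.image_shape_px[0] * cc.pixel_pitch_um
    w_um = cc.image_shape_px[1] * cc.pixel_pitch_um
    rows = []
    spacing = 70.0
    per_row = max(int((w_um - 100.0) // spacing), 1)
    for i, roi in enumerate(roi_samples):
        r, c = divmod(i, per_row)
        box = ci.RoiBox(roi.roi_id, 50.0 + c * spacing, 50.0 + (r % per_row) * spacing)
        mapped = cr.map_roi(box, chain)
        rows.append(
            {
                "roi_id": roi.roi_id,
                "label": roi.label,
                "x_src_um": box.x_um,
                "y_src_um": box.y_um,
                "x_dst_um": mapped.corners_um[0, 0],
                "y_dst_um": mapped.corners_um[0, 1],
                "side_dst_um": mapped.side_um,
                "in_bounds": mapped.in_bounds(w_um, h_um),
            }
        )
    report = {
        "error_percent_of_pitch": err.percent_of_pitch,
        "mean_displacement_um": err.mean_displacement_um,
        "per_landmark_percent": err.per_landmark_percent.tolist(),
        "leg_residual_um": {"afm_to_stained": est_ab.rms_residual_um, "stained_to_polarized": est_bc.rms_residual_um},
        "n_heldout": len(chain_hold),
    }
    del hold_bc  # held-out pairs of the second leg are folded into the chain test
    return pd.DataFrame(rows), report


def statistics_stage(
    fits: pd.DataFrame,
    records: list[fp.RoiRecord],
    density: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[dict, dict, pd.DataFrame]:
    """Group summaries, lognormality, binned correlation and Wilcoxon
    comparisons; returns (summaries, stats, pairs table)."""
    accepted = fits[fits["accepted"]]
    curves_by_label = {
        g.label: _trim(accepted.loc[accepted["label"] == g.label, "E_kPa"].to_numpy(), g.n_curves)
        for g in config.groups
    }
    density_by_roi = dict(zip(density.get("roi_id", []), density.get("density_pct", [])))

    summaries = {}
    for g in config.groups:
        dens = density.loc[density["label"] == g.label, "density_pct"].to_numpy() if len(density) else np.array([])
        s = st.summarize_group(curves_by_label[g.label], g.label, densities_pct=dens if dens.size else None,
                               n_rois=g.n_rois)
        summaries[g.label] = asdict(s)
    for comp_label, members in _COMPOSITES.items():
        present = [curves_by_label[m] for m in members if m in curves_by_label]
        vals = np.concatenate(present) if present else np.array([])
        if vals.size:
            summaries[comp_label] = asdict(st.summarize_group(vals, comp_label))

    pairs = []
    for rec in records:
        if rec.usable and rec.roi_id in density_by_roi:
            pairs.append(
                st.CoregPair(rec.roi_id, rec.label, rec.median_E_kPa, float(density_by_roi[rec.roi_id]))
            )
    pairs_df = st.pairs_frame(pairs)

    stats: dict = {"comparisons": {}, "metadata": {
        "quartiles": "linear interpolation", "log_base": "e",
        "multiple_testing": "none (raw p values)",
        "threshold": config.threshold, "bin_size": config.bin_size,
    }}

    healthy_pairs = [p for p in pairs if p.label == "healthy_wall"]
    if len(healthy_pairs) >= max(config.bin_size, 5):
        e_vals = np.array([p.median_E_kPa for p in healthy_pairs])
        ks = st.ks_lognormal_test(e_vals, seed=config.seed)
        stats["ks_lognormal_healthy"] = {"statistic": ks.statistic, "p_value": ks.p_value,
                                         "lognormal": ks.lognormal, "n_boot": ks.n_boot}
        binned = st.bin_pairs(healthy_pairs, config.bin_size)
        if binned.n_bins >= 3:
            corr = st.pearson_binned(binned)
            stats["pearson_binned_healthy"] = {"rho": corr.rho, "p_value": corr.p_value,
                                               "n_bins": corr.n_bins, "n_pairs": len(healthy_pairs)}
    cap_pairs = [p for p in pairs if p.label in _COMPOSITES["fibrous_cap"]]
    pooled = healthy_pairs + cap_pairs
    if cap_pairs and len(pooled) >= 3 * config.bin_size:
        binned = st.bin_pairs(pooled, config.bin_size)
        corr = st.pearson_binned(binned)
        stats["pearson_binned_healthy_plus_cap"] = {"rho": corr.rho, "p_value": corr.p_value,
                                                    "n_bins": corr.n_bins, "n_pairs": len(pooled)}

    def group_values(label: str) -> np.ndarray:
        if label in _COMPOSITES:
            return np.concatenate([curves_by_label[m] for m in _COMPOSITES[label] if m in curves_by_label])
        return curves_by_label[label]

    for a, b in config.comparisons:
        comp = st.compare_groups(group_values(a), group_values(b))
        stats["comparisons"][f"{a}_vs_{b}"] = {"statistic": comp.statistic, "p_value": comp.p_value,
                                               "method": comp.method}
    return summaries, stats, pairs_df


def _trim(values: np.ndarray, n: int | None) -> np.ndarray:
    return values if n is None else values[:n]


# ---------------------------------------------------------------------------
# Parameter-recovery experiments (single-group, used for validation)
# ---------------------------------------------------------------------------


def recover_group_median(
    group: syn.GroupParams,
    n_curves: int,
    noise: syn.NoiseModel,
    seed: int,
    tip: TipGeometry = TipGeometry(),
) -> dict:
    """Simulate a cohort at the group's distribution parameters, run the
    full force-processing chain and report the median fitted modulus.

    The cohort is ROI-structured (25 curves per ROI); enough ROIs are
    simulated to cover ``n_curves`` and the per-curve tally is trimmed
    to exactly that size.
    """
    n_rois = int(np.ceil(n_curves / 25))
    sized = syn.GroupParams(group.label, group.median_E_kPa, group.iqr_E_kPa, n_rois,
                            group.median_density_pct)
    rois = syn.generate_roi_dataset([sized], noise=noise, rng_or_seed=np.random.default_rng(seed), tip=tip)
    moduli = []
    n_rejected = 0
    for roi in rois:
        for curve in roi.curves:
            fit = fp.process_curve(curve, tip)
            if fit.accepted:
                moduli.append(fit.E_kPa)
            else:
                n_rejected += 1
    moduli = np.array(moduli[:n_curves])
    return {
        "label": group.label,
        "median_E_kPa": float(np.median(moduli)),
        "n_curves": int(moduli.size),
        "n_rejected": n_rejected,
    }


def recover_density_median(
    median_density_pct: float,
    n_rois: int,
    seed: int,
    density_sd_pct: float = 8.0,
    threshold: int = 75,
    pixel_pitch_um: float = 0.5,
) -> dict:
    """Render synthetic polarized-light ROIs whose ground-truth coverage
    distribution is centred on ``median_density_pct``, push them through
    greyscale conversion, binarization and per-ROI densitometry, and
    report the median measured density."""
    rng = np.random.default_rng(seed)
    from scipy.special import ndtri

    u = (rng.permutation(n_rois) + rng.uniform(size=n_rois)) / n_rois
    coverages = np.clip(median_density_pct + density_sd_pct * ndtri(u), 0.5, 99.5)
    side = 50.0
    tile_px = int(round(side / pixel_pitch_um)) + 8
    n_cols = int(np.ceil(np.sqrt(n_rois)))
    n_rows = int(np.ceil(n_rois / n_cols))
    boxes = []
    for i in range(n_rois):
        r, c = divmod(i, n_cols)
        boxes.append(ci.RoiBox(f"roi_{i:03d}", (c * tile_px + 4) * pixel_pitch_um,
                               (r * tile_px + 4) * pixel_pitch_um, side))
    image, _ = syn.generate_polarized_image(
        (n_rows * tile_px, n_cols * tile_px), pixel_pitch_um,
        list(zip(boxes, coverages)), rng_or_seed=rng, threshold=threshold,
    )
    measured = ci.measure_rois(image, boxes, pixel_pitch_um, threshold=threshold)
    densities = np.array([m.density_pct for m in measured])
    return {
        "median_density_pct": float(np.median(densities)),
        "n_rois": int(densities.size),
        "true_median_coverage_pct": float(np.median(coverages)),
    }


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the six result files to ``outdir``.

    Returns a dict with the in-memory results and output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    rng_sim, rng_img, rng_coreg = (np.random.default_rng(s) for s in master.spawn(3))

    roi_samples = simulate_cohort(config, rng_sim)
    fits, records = fit_cohort(roi_samples, config)
    density, _ = measure_collagen(config, roi_samples, rng_img)
    mapped, coreg_report = coregister_stage(config, roi_samples, rng_coreg)
    summaries, stats, pairs_df = statistics_stage(fits, records, density, config)
    stats["coregistration"] = coreg_report

    fits.to_csv(outdir / "fits.csv", index=False)
    density.to_csv(outdir / "density.csv", index=False)
    mapped.to_csv(outdir / "mapped_rois.csv", index=False)
    pairs_df.to_csv(outdir / "pairs.csv", index=False)
    (outdir / "summaries.json").write_text(json.dumps(summaries, indent=1, default=_json_default))
    (outdir / "stats.json").write_text(json.dumps(stats, indent=1, default=_json_default))

    n_total = len(fits)
    n_rej = int((~fits["accepted"]).sum())
    return {
        "outdir": outdir,
        "fits": fits,
        "records": records,
        "density": density,
        "mapped_rois": mapped,
        "pairs": pairs_df,
        "summaries": summaries,
        "stats": stats,
        "discard_rate": n_rej / n_total if n_total else float("nan"),
    }


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
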