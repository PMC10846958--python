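"""Statistical layer: group summaries, lognormality testing, the
sort-and-bin pairing of stiffness with collagen density, correlations and
nonparametric group comparisons.

Young's modulus values are summarised by median and interquartile range
(Q3 - Q1, linear-interpolation quantiles) because their distribution is
right-skewed (approximately lognormal).  Co-registered (modulus, density)
pairs are reduced by sorting on density and replacing consecutive chunks
of six pairs by their coordinate-wise medians before computing Pearson's
correlation on the binned pairs; the final short chunk is kept as its own
bin.  No multiple-testing correction is applied; all p values reported by
this module are raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr

from .errors import ArteryNanoError


@dataclass(frozen=True)
class CoregPair:
    """One co-registered (median modulus, collagen density) data point."""

    roi_id: str
    label: str
    median_E_kPa: float
    density_pct: float

    def __post_init__(self) -> None:
        if not self.median_E_kPa > 0:
            raise ValueError(f"{self.roi_id}: modulus must be positive")
        if not 0.0 <= self.density_pct <= 100.0:
            raise ValueError(f"{self.roi_id}: density must be in [0, 100]")

    @property
    def log_E(self) -> float:
        """Natural log of the median modulus (any base gives the same rho)."""
        return math.log(self.median_E_kPa)


def pairs_frame(pairs: list[CoregPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi_id": [p.roi_id for p in pairs],
            "label": [p.label for p in pairs],
            "median_E_kPa": [p.median_E_kPa for p in pairs],
            "density_pct": [p.density_pct for p in pairs],
            "log_E": [p.log_E for p in pairs],
        }
    )


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n_curves: int
    median_E_kPa: float
    iqr_E_kPa: float
    median_density_pct: float | None = None
    n_rois: int | None = None


def summarize_group(
    e_values_kPa,
    label: str,
    densities_pct=None,
    n_rois: int | None = None,
) -> GroupSummary:
    """Median/IQR summary of per-curve moduli (and optionally densities).

    Quartiles use linear interpolation between order statistics.
    """
    values = np.asarray(e_values_kPa, dtype=float)
    if values.size == 0:
        raise ArteryNanoError(f"empty group {label!r}")
    q1, q3 = np.percentile(values, [25, 75])
    med_density = None
    if densities_pct is not None:
        densities = np.asarray(densities_pct, dtype=float)
        if densities.size:
            med_density = float(np.median(densities))
            if n_rois is None:
                n_rois = int(densities.size)
    return GroupSummary(
        label=label,
        n_curves=int(values.size),
        median_E_kPa=float(np.median(values)),
        iqr_E_kPa=float(q3 - q1),
        median_density_pct=med_density,
        n_rois=n_rois,
    )


# ---------------------------------------------------------------------------
# Lognormality: Lilliefors-style KS test with parametric bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    lognormal: bool | None  # verdict at alpha; None when degenerate
    n_boot: int
    degenerate: bool = False


def _lilliefors_statistic(z_sorted: np.ndarray) -> float:
    n = z_sorted.size
    u = ndtr(z_sorted)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))


def ks_lognormal_test(
    values,
    n_boot: int = 1999,
    seed: int = 0,
    alpha: float = 0.05,
) -> KSResult:
    """Kolmogorov-Smirnov test of lognormality with estimated parameters.

    The log-transformed sample is compared with a normal law whose mean
    and SD are estimated from the data.  Because estimating parameters
    makes the naive KS p value anti-conservative, the p value is
    computed by parametric bootstrap (Lilliefors): ``n_boot`` normal
    samples of the same size are drawn, re-standardised with their own
    estimates, and p = (1 + #{D_b >= D}) / (n_boot + 1).  The null
    distribution of D is parameter-free for a location-scale family, so
    this bootstrap is exact up to Monte Carlo error.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ArteryNanoError("lognormality test needs n >= 5")
    if np.any(v <= 0):
        raise ArteryNanoError("lognormality test requires strictly positive values")
    x = np.log(v)
    sd = float(x.std(ddof=1))
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        return KSResult(float("nan"), float("nan"), None, 0, degenerate=True)
    z = np.sort((x - x.mean()) / sd)
    d_obs = _lilliefors_statistic(z)

    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_boot, v.size))
    sims = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    sims.sort(axis=1)
    n = v.size
    u = ndtr(sims)
    i = np.arange(1, n + 1)
    d_boot = np.max(np.maximum(i / n - u, u - (i - 1) / n), axis=1)
    p = (1.0 + float(np.sum(d_boot >= d_obs - 1e-12))) / (n_boot + 1.0)
    return KSResult(d_obs, p, lognormal=p > alpha, n_boot=n_boot)


# ---------------------------------------------------------------------------
# Sort-and-bin pairing and binned correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinnedPairs:
    """Density-sorted pairs reduced to per-bin medians."""

    bins: pd.DataFrame  # columns: density_pct, log_E, n
    bin_size: int

    @property
    def n_bins(self) -> int:
        return int(len(self.bins))


def bin_pairs(pairs, bin_size: int = 6) -> BinnedPairs:
    """Sort pairs by density ascending and replace each consecutive chunk
    of ``bin_size`` pairs by its (median density, median log-modulus).

    The final chunk may be smaller and is kept as its own bin, so
    n_bins = ceil(n_pairs / bin_size).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = pairs_frame(pairs) if not isinstance(pairs, pd.DataFrame) else pairs.copy()
    if not {"density_pct", "log_E"}.issubset(df.columns):
        raise ArteryNanoError("pairs need 'density_pct' and 'log_E' columns")
    n = len(df)
    if n < bin_size:
        raise ArteryNanoError(f"need at least bin_size={bin_size} pairs, got {n}")
    df = df.sort_values("density_pct", kind="stable").reset_index(drop=True)
    rows = []
    for start in range(0, n, bin_size):
        chunk = df.iloc[start : start + bin_size]
        rows.append(
            {
                "density_pct": float(chunk["density_pct"].median()),
                "log_E": float(chunk["log_E"].median()),
                "n": int(len(chunk)),
            }
        )
    return BinnedPairs(bins=pd.DataFrame(rows), bin_size=bin_size)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_bins: int
    valid: bool = True


def pearson_binned(binned: BinnedPairs) -> CorrelationResult:
    """Pearson correlation of the bin medians (density vs log-modulus),
    two-sided t-based p on n_bins - 2 degrees of freedom."""
    if binned.n_bins < 3:
        raise ArteryNanoError(f"insufficient bins: need >= 3, got {binned.n_bins}")
    x = binned.bins["density_pct"].to_numpy()
    y = binned.bins["log_E"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), binned.n_bins, valid=False)
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), binned.n_bins)


# ---------------------------------------------------------------------------
# Wilcoxon comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    method: str


_EXACT_MAX_N = 25


def compare_groups(a, b, paired: bool = False) -> GroupComparison:
    """Two-sided Wilcoxon comparison of two samples.

    Unpaired data use the rank-sum (Mann-Whitney) test, paired data the
    signed-rank test.  The exact null distribution is used for small
    tie-free samples, otherwise the normal approximation with tie
    correction; the choice is recorded in ``method``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ArteryNanoError("each group needs at least 3 values")
    if paired:
        if a.size != b.size:
            raise ArteryNanoError("paired comparison requires equal-length samples")
        diffs = a - b
        ties = np.unique(np.abs(diffs[diffs != 0])).size < np.count_nonzero(diffs)
        exact = not ties and a.size <= _EXACT_MAX_N and np.any(diffs != 0)
        res = sps.wilcoxon(a, b, alternative="two-sided", method="exact" if exact else "approx")
        name = "wilcoxon_signed_rank"
    else:
        pooled = np.concatenate([a, b])
        ties = np.unique(pooled).size < pooled.size
        exact = not ties and max(a.size, b.size) <= _EXACT_MAX_N
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic")
        name = "wilcoxon_rank_sum"
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"{name}_{'exact' if exact else 'normal_approx_tie_corrected'}",
    )
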