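"""Sensitivity-corrected ratio of regional sSNV counts with a mixing null.

Mosaic-variant discovery is less sensitive at low alternate-allele fractions
(AAFs), so raw per-region variant counts are not comparable.  This module
estimates the ratio of detectable sSNVs in one region versus another inside
AAF bins: a detection threshold is simulated per bin (minimum binomial read
count over bin members at 250 reads), each variant-region is re-simulated
and retained against that threshold, and every retained variant contributes
the reciprocal of the discovery sensitivity at its AAF.  Repeating the whole
simulation gives a Monte-Carlo interval for the ratio; the null model
replaces each variant's regional AAFs by its cross-region mean ("uniformly
mixed"), and an empirical p-value compares the observed ratio to the null
ratio distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "DEFAULT_AAF_BINS",
    "SensitivityCurve",
    "RatioEstimate",
    "bin_and_threshold",
    "project_counts",
    "ratio_distribution",
    "estimate_ratio_ci",
]

#: The seven AAF bins used throughout: 1-2, 2-3, 3-4, 4-5, 5-10, 10-20, 20-50%.
DEFAULT_AAF_BINS: list[tuple[float, float]] = [
    (0.01, 0.02),
    (0.02, 0.03),
    (0.03, 0.04),
    (0.04, 0.05),
    (0.05, 0.10),
    (0.10, 0.20),
    (0.20, 0.50),
]

READ_MODEL_N = 250  # reads in the binomial detection model (kept as printed)


class SensitivityCurve:
    """Detection sensitivity as a monotone function of AAF.

    Built from (AAF, sensitivity) support points: isotonic regression
    enforces monotonicity, then a monotone (PCHIP) spline smooths between
    points.  The packaged default is a logistic in log-AAF anchored so
    sensitivity is ~1 above 10% AAF — a stand-in shape, NOT the published
    caller-specific sensitivity values, which must be supplied by the user
    for canonical analyses.
    """

    def __init__(self, aaf: np.ndarray, sensitivity: np.ndarray):
        aaf = np.asarray(aaf, dtype=float)
        sens = np.asarray(sensitivity, dtype=float)
        if np.any((sens < 0) | (sens > 1)):
            raise ValueError("sensitivities must lie in [0, 1]")
        order = np.argsort(aaf)
        aaf, sens = aaf[order], sens[order]
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
        smoothed = iso.fit_transform(aaf, sens)
        # PCHIP needs strictly increasing x; merge ties
        xs, idx = np.unique(aaf, return_index=True)
        ys = np.array([smoothed[aaf == x].mean() for x in xs])
        ys = np.maximum.accumulate(ys)
        if xs.size == 1:  # degenerate support: constant curve
            xs = np.array([xs[0], xs[0] + 1e-6])
            ys = np.array([ys[0], ys[0]])
        self._spline = PchipInterpolator(xs, ys, extrapolate=False)
        self._lo, self._hi = xs[0], xs[-1]
        self._ylo, self._yhi = ys[0], ys[-1]

    def __call__(self, aaf) -> np.ndarray:
        aaf = np.asarray(aaf, dtype=float)
        out = self._spline(np.clip(aaf, self._lo, self._hi))
        out = np.where(aaf <= self._lo, self._ylo, out)
        out = np.where(aaf >= self._hi, self._yhi, out)
        return out

    @classmethod
    def constant(cls, value: float) -> "SensitivityCurve":
        return cls(np.array([1e-4, 0.5]), np.array([value, value]))

    @classmethod
    def default(cls) -> "SensitivityCurve":
        """Logistic in log10(AAF), midpoint 2% AAF, ~1 above 10% AAF."""
        aaf = np.logspace(-3, np.log10(0.5), 40)
        sens = 1.0 / (1.0 + np.exp(-6.0 * (np.log10(aaf) - np.log10(0.02))))
        return cls(aaf, np.clip(sens, 1e-4, 1.0))


@dataclass
class RatioEstimate:
    """Observed and null (uniform-mixing) ratio of projected sSNV counts."""

    region_a: str
    region_b: str
    bin_label: str
    observed: float
    observed_ci: tuple[float, float]
    expected: float
    expected_ci: tuple[float, float]
    p_value: float
    significant: bool
    n_iter: int
    ci_level: float
    n_undefined_observed: int
    n_undefined_null: int


def _binning_aaf(aafs: np.ndarray) -> np.ndarray:
    """Per-variant AAF used for bin assignment and thresholds: the mean AAF
    over the regions where the variant was actually detected (AAF > 0)."""
    pos = aafs > 0
    with np.errstate(invalid="ignore"):
        out = np.where(
            pos.any(axis=1), (aafs * pos).sum(axis=1) / np.maximum(pos.sum(axis=1), 1), 0.0
        )
    return out


def _bin_index(values: np.ndarray, bins: list[tuple[float, float]]) -> np.ndarray:
    """Bin id per variant; -1 when outside every bin. Bins are (lo, hi]."""
    idx = np.full(values.shape, -1, dtype=int)
    for b, (lo, hi) in enumerate(bins):
        idx[(values > lo) & (values <= hi)] = b
    return idx


def _pivot(variants: pd.DataFrame) -> pd.DataFrame:
    wide = variants.pivot_table(
        index="variant", columns="region", values="aaf", fill_value=0.0
    )
    return wide


def bin_and_threshold(
    variants: pd.DataFrame,
    bins: list[tuple[float, float]] | None = None,
    read_model_n: int = READ_MODEL_N,
    seed: int | None = None,
) -> dict[tuple[float, float], int]:
    """Simulate the per-bin minimum detectable read count.

    For each bin, each member variant draws reads ~ Binomial(read_model_n,
    AAF); the bin's threshold is the minimum draw.  Empty bins are omitted
    from the result (flagged by absence).
    """
    bins = bins or DEFAULT_AAF_BINS
    rng = np.random.default_rng(seed)
    wide = _pivot(variants)
    baafs = _binning_aaf(wide.values)
    bidx = _bin_index(baafs, bins)
    out: dict[tuple[float, float], int] = {}
    for b, bin_ in enumerate(bins):
        members = baafs[bidx == b]
        if members.size == 0:
            continue
        draws = rng.binomial(read_model_n, members)
        out[bin_] = int(draws.min())
    return out


def project_counts(
    variants: pd.DataFrame,
    region: str,
    thresholds: dict[tuple[float, float], int],
    curve: SensitivityCurve,
    bins: list[tuple[float, float]] | None = None,
    read_model_n: int = READ_MODEL_N,
    seed: int | None = None,
) -> float:
    """Sensitivity-corrected projected variant count for one region.

    Per variant: reads ~ Binomial(read_model_n, regional AAF); variants with
    reads >= their bin's threshold each contribute 1/sensitivity(AAF).
    """
    bins = bins or DEFAULT_AAF_BINS
    rng = np.random.default_rng(seed)
    wide = _pivot(variants)
    if region not in wide.columns:
        raise KeyError(f"region {region!r} not present")
    baafs = _binning_aaf(wide.values)
    bidx = _bin_index(baafs, bins)
    aaf_r = wide[region].values
    total = 0.0
    for v in range(len(wide)):
        b = bidx[v]
        if b < 0 or bins[b] not in thresholds or aaf_r[v] <= 0:
            continue
        reads = rng.binomial(read_model_n, aaf_r[v])
        if reads >= thresholds[bins[b]]:
            s = float(curve(aaf_r[v]))
            if s <= 0:
                raise ValueError(
                    f"sensitivity is not positive at AAF {aaf_r[v]:.4g} "
                    f"(variant {wide.index[v]})"
                )
            total += 1.0 / s
    return total


def ratio_distribution(
    variants: pd.DataFrame,
    region_a: str,
    region_b: str,
    curve: SensitivityCurve,
    n_iter: int = 1000,
    bins: list[tuple[float, float]] | None = None,
    read_model_n: int = READ_MODEL_N,
    null: bool = False,
    aaf_filter: tuple[float, float] | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, int]:
    """Monte-Carlo distribution of projected-count ratios A/B.

    Thresholds are recomputed every iteration.  Under ``null=True`` each
    variant's regional AAFs are replaced by the cross-region mean before
    simulating.  Iterations with a zero projected count in the denominator
    are dropped; their number is returned alongside the ratios.
    """
    bins = bins or DEFAULT_AAF_BINS
    rng = np.random.default_rng(seed)
    wide = _pivot(variants)
    for r in (region_a, region_b):
        if r not in wide.columns:
            raise KeyError(f"region {r!r} not present")
    aafs = wide.values
    baafs = _binning_aaf(aafs)
    if null:
        # uniformly-mixed null: each region sees the cross-region mean AAF
        # (zeros in tested-but-undetected regions included in the mean)
        aafs = np.tile(aafs.mean(axis=1)[:, None], (1, aafs.shape[1]))
    bidx = _bin_index(baafs, bins)
    if aaf_filter is not None:
        lo, hi = aaf_filter
        keep = (baafs > lo) & (baafs <= hi)
    else:
        keep = bidx >= 0
    sel = np.flatnonzero(keep)
    if sel.size == 0:
        raise ValueError("no variants fall inside the requested AAF range")
    baafs_s = baafs[sel]
    bidx_s = bidx[sel]
    a_idx = wide.columns.get_loc(region_a)
    b_idx = wide.columns.get_loc(region_b)
    aaf_a = aafs[sel, a_idx]
    aaf_b = aafs[sel, b_idx]
    sens_a = np.asarray(curve(aaf_a), dtype=float)
    sens_b = np.asarray(curve(aaf_b), dtype=float)
    for aaf_r, sens_r in ((aaf_a, sens_a), (aaf_b, sens_b)):
        bad = (aaf_r > 0) & (sens_r <= 0)
        if np.any(bad):
            v = wide.index[sel[np.flatnonzero(bad)[0]]]
            raise ValueError(f"sensitivity is not positive for variant {v}")
    # a variant absent from a region (AAF 0) cannot be detected there and
    # contributes nothing, whatever the simulated read count
    inv_a = np.where(aaf_a > 0, 1.0 / np.maximum(sens_a, 1e-300), 0.0)
    inv_b = np.where(aaf_b > 0, 1.0 / np.maximum(sens_b, 1e-300), 0.0)

    nv = sel.size
    thr_draws = rng.binomial(read_model_n, baafs_s, size=(n_iter, nv))
    # per-iteration, per-bin minimum over members
    n_bins = len(bins)
    thr = np.full((n_iter, n_bins), np.iinfo(np.int64).max, dtype=np.int64)
    for b in range(n_bins):
        cols = bidx_s == b
        if cols.any():
            thr[:, b] = thr_draws[:, cols].min(axis=1)
    thr_v = thr[:, bidx_s]  # (n_iter, nv)
    reads_a = rng.binomial(read_model_n, aaf_a, size=(n_iter, nv))
    reads_b = rng.binomial(read_model_n, aaf_b, size=(n_iter, nv))
    proj_a = ((reads_a >= thr_v) * inv_a).sum(axis=1)
    proj_b = ((reads_b >= thr_v) * inv_b).sum(axis=1)
    ok = proj_b > 0
    ratios = proj_a[ok] / proj_b[ok]
    return ratios, int((~ok).sum())


def estimate_ratio_ci(
    variants: pd.DataFrame,
    region_a: str,
    region_b: str,
    curve: SensitivityCurve | None = None,
    n_iter: int = 1000,
    ci_level: float = 0.95,
    alpha: float = 0.05,
    bins: list[tuple[float, float]] | None = None,
    read_model_n: int = READ_MODEL_N,
    aaf_filter: tuple[float, float] | None = None,
    seed: int | None = None,
) -> RatioEstimate:
    """Observed vs uniform-mixing-null ratio with percentile CIs.

    The point estimate is the median of iteration ratios; the empirical
    p-value is the two-sided tail probability of the observed point under
    the null ratio distribution (with a +1 finite-sample correction);
    ``significant`` is ``p < alpha``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    curve = curve or SensitivityCurve.default()
    rng = np.random.default_rng(seed)
    s_obs, s_null = rng.integers(2**31, size=2)
    obs, n_und_obs = ratio_distribution(
        variants, region_a, region_b, curve, n_iter, bins, read_model_n,
        null=False, aaf_filter=aaf_filter, seed=int(s_obs),
    )
    nul, n_und_nul = ratio_distribution(
        variants, region_a, region_b, curve, n_iter, bins, read_model_n,
        null=True, aaf_filter=aaf_filter, seed=int(s_null),
    )
    q = (1.0 - ci_level) / 2.0
    point = float(np.median(obs))
    null_point = float(np.median(nul))
    lo_p = (1 + np.sum(nul <= point)) / (len(nul) + 1)
    hi_p = (1 + np.sum(nul >= point)) / (len(nul) + 1)
    p = float(min(1.0, 2.0 * min(lo_p, hi_p)))
    if aaf_filter is not None:
        label = f"{aaf_filter[0]:g}-{aaf_filter[1]:g}"
    else:
        label = "all"
    return RatioEstimate(
        region_a=region_a,
        region_b=region_b,
        bin_label=label,
        observed=point,
        observed_ci=(float(np.quantile(obs, q)), float(np.quantile(obs, 1 - q))),
        expected=null_point,
        expected_ci=(float(np.quantile(nul, q)), float(np.quantile(nul, 1 - q))),
        p_value=p,
        significant=p < alpha,
        n_iter=n_iter,
        ci_level=ci_level,
        n_undefined_observed=n_und_obs,
        n_undefined_null=n_und_nul,
    )
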