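"""Deep-amplicon (MIPP-seq-style) mosaic-fraction analysis.

Ultra-deep replicate-primer amplicon sequencing re-genotypes candidate sSNVs
across many tissue samples.  This module turns per-primer read tallies into
mosaic-fraction (MF) estimates with flanking-sequence background error,
applies the detection rule (>=10,000 reads, matching alternate allele,
MF >= 0.1%), buckets variants into mosaicism categories, and tests regional
restriction against a uniform-mixing null: simulate how many regions a
variant at its cortex-wide average MF would be detected in, then score the
observed region count with a lower-tail Poisson p-value and
Benjamini-Hochberg correction across the variant family.

Conventions: MF (percent) = 2 x AAF (percent); a read samples alleles, so a
variant at MF m occupies a fraction m/2 of reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mf_from_aaf",
    "cells_from_dna_input",
    "estimate_mf_and_error",
    "classify_detection",
    "classify_category",
    "expected_regions_null",
    "region_restriction_test",
    "restriction_tests",
    "flag_outliers",
]

MIN_READS = 10_000  # below this a site is inconclusive
MF_FLOOR_PCT = 0.1  # detection floor, percent MF (= 0.05% AAF)


def mf_from_aaf(aaf_percent: float) -> float:
    """Mosaic fraction (percent) from alternate allele fraction (percent)."""
    return 2.0 * aaf_percent


def cells_from_dna_input(nanograms: float, pg_per_cell: float) -> int:
    """Number of diploid cells represented by a DNA input mass.

    50 ng at 6 pg/cell -> 8,333 cells; at 7 pg/cell -> 7,142 cells.
    """
    if nanograms <= 0 or pg_per_cell <= 0:
        raise ValueError("mass and per-cell content must be positive")
    return int(nanograms * 1000.0 / pg_per_cell)


def estimate_mf_and_error(readouts: pd.DataFrame) -> pd.DataFrame:
    """Per variant/region MF (percent) and background error from amplicons.

    MF = 2 x mean per-primer AAF; background error = mean flanking AAF
    across replicate primers (reported both as AAF fraction and on the
    percent-MF scale for direct comparison with MF).  Zero-read primers are
    excluded with a warning.
    """
    df = readouts.copy()
    zero = df["depth"] <= 0
    if zero.any():
        warn(f"excluding {int(zero.sum())} primer measurements with zero reads")
        df = df[~zero]
    df["aaf"] = df["alt_reads"] / df["depth"]
    has_flank = "flank_error" in df.columns
    rows = []
    for (variant, region), grp in df.groupby(["variant", "region"], sort=True):
        mean_aaf = grp["aaf"].mean()
        bg_aaf = float(grp["flank_error"].mean()) if has_flank else 0.0
        rows.append(
            {
                "variant": variant,
                "region": region,
                "mf_pct": 200.0 * mean_aaf,
                "mean_aaf_pct": 100.0 * mean_aaf,
                "primer_aafs": tuple(round(a, 10) for a in grp["aaf"]),
                "background_error_aaf": bg_aaf,
                "background_error_mf_pct": 200.0 * bg_aaf,
                "n_primers": len(grp),
                "total_reads": int(grp["depth"].sum()),
            }
        )
    return pd.DataFrame(rows)


def classify_detection(
    estimate: pd.Series | dict,
    expected_alt: str | None = None,
    observed_alt: str | None = None,
) -> str:
    """Detection status: 'detected', 'absent' or 'inconclusive'.

    Inconclusive below 10,000 total reads; detected requires MF >= 0.1%
    and (when allele information is given) the primary alternate allele
    observed during discovery; otherwise absent.
    """
    reads = int(estimate["total_reads"])
    if reads < MIN_READS:
        return "inconclusive"
    allele_ok = (
        expected_alt is None or observed_alt is None or expected_alt == observed_alt
    )
    if estimate["mf_pct"] >= MF_FLOOR_PCT and allele_ok:
        return "detected"
    return "absent"


def classify_category(mean_mf_pct: float, mean_aaf_pct: float | None = None) -> str:
    """Mosaicism category from the cross-sample average.

    germline: average AAF >= 45%; ultra-low: MF <= 2%; low: 2-10%;
    higher: 10-90% (boundaries closed on the lower category).
    """
    if mean_aaf_pct is None:
        mean_aaf_pct = mean_mf_pct / 2.0
    if mean_mf_pct < 0 or mean_aaf_pct < 0:
        raise ValueError("mosaic and allele fractions must be non-negative")
    if not (math.isfinite(mean_mf_pct) and math.isfinite(mean_aaf_pct)):
        raise ValueError("inputs must be finite")
    if mean_aaf_pct >= 45.0:
        return "germline"
    if mean_mf_pct <= 2.0:
        return "ultra-low"
    if mean_mf_pct <= 10.0:
        return "low"
    return "higher"


def expected_regions_null(
    variant_mean_mf: float,
    mean_error_rate: float,
    n_regions: int,
    n_reps: int = 1000,
    seed: int | None = None,
    depth: int = 10_000,
    floor_scale: str = "mf",
) -> tuple[float, tuple[int, int], np.ndarray]:
    """Uniform-mixing null: regions in which a variant would be detected.

    Per replicate and region, mutant reads ~ Binomial(depth, MF/2) and error
    reads ~ Binomial(depth, error/2) (rates given in percent on the MF
    scale; a read carries the mutant allele with probability MF/2).  A
    region counts as detected when mutant reads exceed error reads and the
    mutant-read fraction clears the 0.1%-MF floor (i.e. >0.05% of reads when
    ``floor_scale='mf'``; set ``floor_scale='aaf'`` to read the printed
    0.1% as a raw read fraction).

    Returns (mean detected-region count, (min, max) envelope, per-replicate
    counts).
    """
    if not 0.0 <= variant_mean_mf <= 100.0:
        raise ValueError("MF must be a percentage in [0, 100]")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    p_mut = variant_mean_mf / 200.0
    p_err = mean_error_rate / 200.0
    mut = rng.binomial(depth, p_mut, size=(n_reps, n_regions))
    err = rng.binomial(depth, p_err, size=(n_reps, n_regions))
    floor_frac = (MF_FLOOR_PCT / 100.0) / (2.0 if floor_scale == "mf" else 1.0)
    detected = (mut > err) & (mut / depth > floor_frac)
    counts = detected.sum(axis=1)
    return float(counts.mean()), (int(counts.min()), int(counts.max())), counts


def region_restriction_test(
    observed_count: int, null_counts: np.ndarray, n_regions: int | None = None
) -> float:
    """Lower-tail Poisson p-value for seeing this few regions.

    The Poisson rate is the mean of the simulated null region counts;
    observed == expected == 0 gives p = 1 by convention.
    """
    null_counts = np.asarray(null_counts)
    expected = float(null_counts.mean())
    if n_regions is not None and observed_count > n_regions:
        raise ValueError("observed count exceeds the number of regions")
    if expected == 0.0:
        return 1.0
    return float(stats.poisson.cdf(observed_count, expected))


def restriction_tests(
    table: pd.DataFrame,
    n_regions: int,
    n_reps: int = 1000,
    seed: int | None = None,
    depth: int = 10_000,
) -> pd.DataFrame:
    """Family-wise restriction tests with Benjamini-Hochberg q-values.

    ``table`` needs one row per variant with columns variant, mean_mf_pct,
    mean_error_pct, observed_regions.  The family is corrected together
    (one-sided: fewer regions than expected).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in table.iterrows():
        exp_mean, (lo, hi), counts = expected_regions_null(
            r["mean_mf_pct"],
            r["mean_error_pct"],
            n_regions,
            n_reps=n_reps,
            seed=int(rng.integers(2**31)),
            depth=depth,
        )
        p = region_restriction_test(int(r["observed_regions"]), counts, n_regions)
        rows.append(
            {
                "variant": r["variant"],
                "observed_regions": int(r["observed_regions"]),
                "expected_regions": exp_mean,
                "expected_min": lo,
                "expected_max": hi,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


def flag_outliers(values) -> list[str]:
    """Tukey fences: 'mild' beyond 1.5x IQR, 'extreme' beyond 3x IQR.

    Quartiles use the linear-interpolation convention; comparisons are
    strict, so values exactly on a fence are not flagged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 values to define quartiles")
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    iqr = q3 - q1
    flags = []
    for x in arr:
        if x < q1 - 3.0 * iqr or x > q3 + 3.0 * iqr:
            flags.append("extreme")
        elif x < q1 - 1.5 * iqr or x > q3 + 1.5 * iqr:
            flags.append("mild")
        else:
            flags.append("none")
    return flags
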