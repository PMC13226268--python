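"""Masked-region spectral statistics and paired shift assessment.

For each region of each image the module computes the coefficient of
variation CoV = 100*sigma/mu, Shannon entropy H' = -sum p_i ln p_i over
intensity bins, Rao's quadratic entropy Q = sum_ij d_ij p_i p_j, and —
between the bush region and its background — the Bhattacharyya distance
B and the Jeffries-Matusita separability JM = 2(1 - exp(-B)), a bounded
[0, 2) score where values above 1.9 conventionally read as excellent
class separability.

Paired assessment reports, per scene pair, the percent shift of each
metric from the original image to the reconstructed one, and aggregates
the shifts per class and globally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .imaging import RasterImage, RegionMask, ScenePair, complement_mask

DEFAULT_BINS = 256

#: Separability grades.  The "excellent" cutpoint (JM > 1.9) is the
#: conventional remote-sensing reading; the lower cutpoints are this
#: package's own convention, flagged as such in output metadata.
GRADE_CUTPOINTS = {"excellent": 1.9, "good": 1.7, "moderate": 1.0}


@dataclass(frozen=True)
class RegionHistogram:
    """Equal-width intensity histogram of a masked region on [0, 1]."""

    proportions: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=np.float64)
        e = np.asarray(self.bin_edges, dtype=np.float64)
        if p.size < 2:
            raise ValueError("histogram needs at least 2 bins")
        if e.size != p.size + 1:
            raise ValueError("bin_edges must have one more entry than proportions")
        if p.min() < 0:
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        object.__setattr__(self, "proportions", p)
        object.__setattr__(self, "bin_edges", e)

    @property
    def bin_count(self) -> int:
        return self.proportions.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class RegionSpectralSummary:
    """First- and second-order spectral statistics of one masked region."""

    mean: float
    std: float  # population (weight-normalized)
    cov_percent: Optional[float]  # None when mean == 0 (undefined)
    entropy_nats: float
    raos_q: float
    histogram: RegionHistogram
    pixel_count: float  # effective (weight-summed)


class SeparabilityGrade(str, Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


@dataclass(frozen=True)
class SeparabilityResult:
    bhattacharyya: float
    jm: float
    grade: SeparabilityGrade


@dataclass(frozen=True)
class PairShiftRecord:
    """Percent shifts of the region metrics across one original/reconstructed pair.

    Each delta is 100 * (reconstructed - original) / original; a delta is
    None (and excluded from aggregation) when the original metric is 0.
    """

    pair_id: str
    class_label: str
    delta_cov_bg: Optional[float]
    delta_entropy_bg: Optional[float]
    delta_cov_bush: Optional[float]
    delta_jm: Optional[float]
    jm_original: float
    jm_reconstructed: float
    summary_bush_orig: RegionSpectralSummary
    summary_bg_orig: RegionSpectralSummary
    summary_bush_recon: RegionSpectralSummary
    summary_bg_recon: RegionSpectralSummary
    warnings: tuple[str, ...] = ()

    def deltas(self) -> dict[str, Optional[float]]:
        return {
            "dCoV_Bg_pct": self.delta_cov_bg,
            "dH_Bg_pct": self.delta_entropy_bg,
            "dCoV_Bush_pct": self.delta_cov_bush,
            "dJM_pct": self.delta_jm,
        }


DELTA_COLUMNS = ("dCoV_Bg_pct", "dH_Bg_pct", "dCoV_Bush_pct", "dJM_pct")


@dataclass(frozen=True)
class ShiftTable:
    """Per-class and global mean percent shifts (one row per class + Global).

    ``frame`` has columns Class, n, dCoV_Bg_pct, dH_Bg_pct,
    dCoV_Bush_pct, dJM_pct; the Global row pools all pairs (it is the
    mean over pairs, not the mean of class means).
    """

    frame: pd.DataFrame
    n_undefined: int = 0

    @property
    def global_row(self) -> pd.Series:
        return self.frame[self.frame["Class"] == "Global"].iloc[0]


# ---------------------------------------------------------------------------
# region statistics


def _region_values(image: RasterImage, mask: RegionMask,
                   channel: Literal["luminance", "mean"] = "luminance",
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Intensity samples and weights of a masked region.

    RGBA alpha acts as a validity channel: alpha-0 pixels are dropped.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask dims differ")
    intens = image.luminance() if channel == "luminance" else image.rgb().mean(axis=2)
    valid = image.validity()
    w = np.where(valid, mask.weights, 0.0)
    sel = w > 0
    return intens[sel], w[sel]


def region_histogram(image: RasterImage, mask: RegionMask, bins: int = DEFAULT_BINS,
                     channel: Literal["luminance", "mean"] = "luminance",
                     ) -> RegionHistogram:
    """Weighted intensity histogram over [0, 1] with equal-width bins."""
    vals, w = _region_values(image, mask, channel)
    if w.sum() <= 0:
        raise ValueError("region is empty")
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0), weights=w)
    return RegionHistogram(counts / counts.sum(), edges)


def coefficient_of_variation(image: RasterImage, mask: RegionMask,
                             channel: Literal["luminance", "mean"] = "luminance",
                             ) -> float:
    """CoV = 100 * sigma / mu of the region intensities, in percent.

    sigma is the population (weight-normalized) standard deviation.
    Raises when the region mean is 0, where the ratio is undefined.
    """
    vals, w = _region_values(image, mask, channel)
    if w.sum() <= 0:
        raise ValueError("region is empty")
    mu = float(np.average(vals, weights=w))
    if mu == 0:
        raise ValueError("CoV undefined: region mean is 0")
    sigma = math.sqrt(float(np.average((vals - mu) ** 2, weights=w)))
    return 100.0 * sigma / mu


def shannon_entropy(hist: RegionHistogram) -> float:
    """H' = -sum p_i ln p_i in nats (0 ln 0 := 0)."""
    p = hist.proportions[hist.proportions > 0]
    return float(-(p * np.log(p)).sum())


def raos_q(hist: RegionHistogram) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.

    d_ij is the absolute bin-center difference on the normalized [0, 1]
    intensity axis, so Q is dimensionless and bounded by 1.
    """
    c = hist.bin_centers
    p = hist.proportions
    d = np.abs(c[:, None] - c[None, :])
    return float(p @ d @ p)


def summarize_region(image: RasterImage, mask: RegionMask, bins: int = DEFAULT_BINS,
                     channel: Literal["luminance", "mean"] = "luminance",
                     ) -> RegionSpectralSummary:
    """Bundle mu, sigma, CoV, H', Q and the histogram for one region."""
    vals, w = _region_values(image, mask, channel)
    total = w.sum()
    if total <= 0:
        raise ValueError("region is empty")
    mu = float(np.average(vals, weights=w))
    sigma = math.sqrt(float(np.average((vals - mu) ** 2, weights=w)))
    hist = region_histogram(image, mask, bins, channel)
    return RegionSpectralSummary(
        mean=mu,
        std=sigma,
        cov_percent=(100.0 * sigma / mu) if mu > 0 else None,
        entropy_nats=shannon_entropy(hist),
        raos_q=raos_q(hist),
        histogram=hist,
        pixel_count=float(total),
    )


# ---------------------------------------------------------------------------
# separability


def bhattacharyya_gaussian(summary_a: RegionSpectralSummary,
                           summary_b: RegionSpectralSummary) -> float:
    """Bhattacharyya distance under a univariate-Gaussian model of each region.

    B = (mu_a - mu_b)^2 / (8 * s) + 0.5 * ln(s / (sigma_a * sigma_b))
    with s = (sigma_a^2 + sigma_b^2) / 2.  Requires positive variance in
    both regions.
    """
    sa, sb = summary_a.std, summary_b.std
    if sa <= 0 or sb <= 0:
        raise ValueError("Bhattacharyya distance needs positive variance in both regions")
    s = (sa**2 + sb**2) / 2.0
    return ((summary_a.mean - summary_b.mean) ** 2 / (8.0 * s)
            + 0.5 * math.log(s / (sa * sb)))


def bhattacharyya_histogram(hist_a: RegionHistogram, hist_b: RegionHistogram) -> float:
    """Nonparametric estimator B = -ln sum_i sqrt(p_i q_i) from histograms."""
    if hist_a.bin_count != hist_b.bin_count:
        raise ValueError("histograms must share binning")
    bc = float(np.sqrt(hist_a.proportions * hist_b.proportions).sum())
    bc = min(bc, 1.0)
    if bc == 0:
        return math.inf
    return -math.log(bc)


def jm_distance(B: float) -> SeparabilityResult:
    """Jeffries-Matusita separability JM = 2(1 - exp(-B)) in [0, 2)."""
    if B < 0:
        raise ValueError("Bhattacharyya distance must be non-negative")
    jm = 2.0 * (1.0 - math.exp(-B))
    if jm > GRADE_CUTPOINTS["excellent"]:
        grade = SeparabilityGrade.EXCELLENT
    elif jm > GRADE_CUTPOINTS["good"]:
        grade = SeparabilityGrade.GOOD
    elif jm > GRADE_CUTPOINTS["moderate"]:
        grade = SeparabilityGrade.MODERATE
    else:
        grade = SeparabilityGrade.POOR
    return SeparabilityResult(bhattacharyya=B, jm=jm, grade=grade)


def region_separability(image: RasterImage, bush: RegionMask,
                        bins: int = DEFAULT_BINS,
                        estimator: Literal["gaussian", "histogram"] = "gaussian",
                        channel: Literal["luminance", "mean"] = "luminance",
                        ) -> SeparabilityResult:
    """JM separability between the bush region and its background."""
    bg = complement_mask(bush)
    sum_bush = summarize_region(image, bush, bins, channel)
    sum_bg = summarize_region(image, bg, bins, channel)
    if estimator == "gaussian":
        B = bhattacharyya_gaussian(sum_bush, sum_bg)
    else:
        B = bhattacharyya_histogram(sum_bush.histogram, sum_bg.histogram)
    return jm_distance(B)


# ---------------------------------------------------------------------------
# paired shifts


def _percent_shift(orig: Optional[float], recon: Optional[float],
                   name: str, warn_list: list[str]) -> Optional[float]:
    if orig is None or recon is None or orig == 0:
        warn_list.append(f"{name}: undefined delta (original metric is 0 or undefined)")
        return None
    return 100.0 * (recon - orig) / orig


def assess_pair(pair: ScenePair, bins: int = DEFAULT_BINS,
                estimator: Literal["gaussian", "histogram"] = "gaussian",
                channel: Literal["luminance", "mean"] = "luminance",
                ) -> PairShiftRecord:
    """Compute per-region summaries and percent shifts for one scene pair.

    Background is the complement of the bush mask; alpha-invalid pixels
    are excluded from both regions.  Shifts are relative to the original
    image, so swapping the pair does not negate them (a +100% shift maps
    to -50%).
    """
    bg_mask = complement_mask(pair.bush_mask)
    warn_list: list[str] = []
    s_bush_o = summarize_region(pair.original, pair.bush_mask, bins, channel)
    s_bg_o = summarize_region(pair.original, bg_mask, bins, channel)
    s_bush_r = summarize_region(pair.reconstructed, pair.bush_mask, bins, channel)
    s_bg_r = summarize_region(pair.reconstructed, bg_mask, bins, channel)

    def _sep(a: RegionSpectralSummary, b: RegionSpectralSummary) -> float:
        if estimator == "gaussian":
            return jm_distance(bhattacharyya_gaussian(a, b)).jm
        return jm_distance(bhattacharyya_histogram(a.histogram, b.histogram)).jm

    jm_o = _sep(s_bush_o, s_bg_o)
    jm_r = _sep(s_bush_r, s_bg_r)
    rec = PairShiftRecord(
        pair_id=pair.pair_id,
        class_label=pair.class_label,
        delta_cov_bg=_percent_shift(s_bg_o.cov_percent, s_bg_r.cov_percent,
                                    "dCoV_Bg_pct", warn_list),
        delta_entropy_bg=_percent_shift(s_bg_o.entropy_nats, s_bg_r.entropy_nats,
                                        "dH_Bg_pct", warn_list),
        delta_cov_bush=_percent_shift(s_bush_o.cov_percent, s_bush_r.cov_percent,
                                      "dCoV_Bush_pct", warn_list),
        delta_jm=_percent_shift(jm_o, jm_r, "dJM_pct", warn_list),
        jm_original=jm_o,
        jm_reconstructed=jm_r,
        summary_bush_orig=s_bush_o,
        summary_bg_orig=s_bg_o,
        summary_bush_recon=s_bush_r,
        summary_bg_recon=s_bg_r,
        warnings=tuple(warn_list),
    )
    for msg in warn_list:
        warnings.warn(f"pair {pair.pair_id}: {msg}", stacklevel=2)
    return rec


def aggregate_shifts(records: Sequence[PairShiftRecord]) -> ShiftTable:
    """Per-class arithmetic means of the per-pair percent shifts plus a Global row.

    The Global row pools all pairs (mean of per-pair deltas, not mean of
    class means).  Undefined deltas are excluded from the means and
    counted in ``n_undefined``.
    """
    records = list(records)
    if not records:
        raise ValueError("no shift records to aggregate")
    rows = [{"Class": r.class_label, **r.deltas()} for r in records]
    df = pd.DataFrame(rows)
    n_undef = int(df[list(DELTA_COLUMNS)].isna().sum().sum())
    per_class = (
        df.groupby("Class", sort=True)
        .agg(n=("Class", "size"),
             **{c: (c, "mean") for c in DELTA_COLUMNS})
        .reset_index()
    )
    global_row = pd.DataFrame([{
        "Class": "Global", "n": len(df),
        **{c: df[c].mean() for c in DELTA_COLUMNS},
    }])
    frame = pd.concat([per_class, global_row], ignore_index=True)
    frame["n"] = frame["n"].astype(int)
    return ShiftTable(frame=frame, n_undefined=n_undef)
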