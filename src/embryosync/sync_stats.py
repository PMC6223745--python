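"""Synchronization statistics for embryo-length distributions.

The degree of synchronization of somatic-embryo maturation is quantified by
the spread of the mature-embryo length distribution.  Two families of
measures are implemented:

* widths of the normalized length-distribution function phi(q-bar) at
  fractions of its maximum (the 50% width is the FWHM) — smaller widths mean
  more uniform embryo lengths;
* the coefficient of variation (CV) of lengths, with a McKay chi-square
  confidence interval for the population CV.

Supporting routines cover binning, replicate summaries, pooled/Welch
two-sample t-tests, yield extrapolation from a sampled tissue fraction, and
germination-rate summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LengthSample",
    "BinnedDistribution",
    "WidthSet",
    "CVEstimate",
    "YieldStats",
    "TTestResult",
    "GerminationRecord",
    "bin_lengths",
    "width_at_fraction",
    "widths",
    "replicate_width_summary",
    "cv",
    "mckay_ci",
    "ttest_two_sample",
    "yield_per_gfw",
    "germination_rates",
]

DEFAULT_FRACTIONS = (0.50, 0.66, 0.75)


# ---------------------------------------------------------------------------
# containers


@dataclass
class LengthSample:
    """Embryo lengths (mm) with replicate and treatment labels.

    Parameters
    ----------
    lengths
        Embryo lengths in millimetres; all strictly positive.
    replicates
        Replicate identifier per length (e.g. bioreactor or plate number).
        Defaults to a single replicate ``1``.
    treatment
        Group label (e.g. ``"dispersed"``).
    """

    lengths: np.ndarray
    replicates: np.ndarray = None  # type: ignore[assignment]
    treatment: str = ""

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float).ravel()
        if self.lengths.size and not np.all(self.lengths > 0):
            raise ValueError("all lengths must be strictly positive (mm)")
        if self.replicates is None:
            self.replicates = np.ones(self.lengths.size, dtype=int)
        else:
            self.replicates = np.asarray(self.replicates).ravel()
        if self.replicates.size != self.lengths.size:
            raise ValueError("replicates and lengths must have equal length")

    @property
    def n(self) -> int:
        return int(self.lengths.size)

    def replicate_ids(self) -> list:
        """Distinct replicate ids, in order of first appearance."""
        _, idx = np.unique(self.replicates, return_index=True)
        return list(self.replicates[np.sort(idx)])

    def by_replicate(self) -> list["LengthSample"]:
        """Split into one sample per replicate (order of first appearance)."""
        out = []
        for rid in self.replicate_ids():
            mask = self.replicates == rid
            out.append(
                LengthSample(self.lengths[mask], self.replicates[mask], self.treatment)
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": self.replicates,
                "treatment": self.treatment,
                "length_mm": self.lengths,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, treatment: str | None = None) -> "LengthSample":
        required = {"replicate", "length_mm"}
        if not required.issubset(df.columns):
            raise ValueError(f"length table must have columns {sorted(required)}")
        if treatment is None:
            labels = df["treatment"].unique() if "treatment" in df else [""]
            if len(labels) > 1:
                raise ValueError("mixed treatments; pass `treatment` to select one")
            treatment = str(labels[0])
        else:
            if "treatment" in df:
                df = df[df["treatment"] == treatment]
        return cls(df["length_mm"].to_numpy(float), df["replicate"].to_numpy(), treatment)

    @classmethod
    def from_csv(cls, path, treatment: str | None = None) -> "LengthSample":
        return cls.from_frame(pd.read_csv(path), treatment=treatment)


@dataclass
class BinnedDistribution:
    """Histogram of lengths with the normalized curve phi at bin centers.

    Bins are half-open intervals ``[origin + k*delta, origin + (k+1)*delta)``
    starting at ``origin``; ``phi`` is the counts divided by the maximum
    count, so the curve peaks at exactly 1.
    """

    delta: float
    origin: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.delta <= 0:
            raise ValueError("bin width delta must be positive")
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def edges(self) -> np.ndarray:
        k = self.counts.size
        return self.origin + self.delta * np.arange(k + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.origin + self.delta * (np.arange(self.counts.size) + 0.5)

    @property
    def phi(self) -> np.ndarray:
        m = self.counts.max()
        if m == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / m


@dataclass(frozen=True)
class WidthSet:
    """Widths of phi at 50% (FWHM), 66% and 75% of maximum, in mm."""

    width_50: float
    width_66: float
    width_75: float

    def as_dict(self) -> dict:
        return {"width_50": self.width_50, "width_66": self.width_66, "width_75": self.width_75}


@dataclass(frozen=True)
class CVEstimate:
    """A coefficient of variation with a McKay confidence interval."""

    cv: float
    n: int
    level: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.cv <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")


@dataclass(frozen=True)
class YieldStats:
    """Extrapolated embryo yield per gram of starting fresh weight."""

    harvested_count: float
    sampled_fraction: float
    initial_fw_g: float
    embryos_per_gfw: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


@dataclass(frozen=True)
class GerminationRecord:
    """Counts from one germination trial: collected -> started -> rooted."""

    collected: int
    started: int
    rooted: int
    treatment: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.rooted <= self.started <= self.collected):
            raise ValueError("require rooted <= started <= collected, all >= 0")


# ---------------------------------------------------------------------------
# binning and widths


def bin_lengths(sample, delta: float = 1.0, origin: float = 0.0) -> BinnedDistribution:
    """Bin lengths into half-open intervals of width ``delta`` from ``origin``.

    Bins run from ``origin`` up to the largest observed length, so leading
    empty bins are kept (the reported length intervals conventionally start
    at 0.0 mm).
    """
    lengths = sample.lengths if isinstance(sample, LengthSample) else np.asarray(sample, float)
    if delta <= 0:
        raise ValueError("delta must be positive")
    if lengths.size == 0:
        raise ValueError("cannot bin an empty length sample")
    if np.any(lengths < origin):
        raise ValueError("lengths below the bin origin")
    idx = np.floor((lengths - origin) / delta).astype(int)
    counts = np.bincount(idx)
    return BinnedDistribution(delta=delta, origin=origin, counts=counts)


def _padded_curve(dist: BinnedDistribution) -> tuple[np.ndarray, np.ndarray]:
    """phi linearly interpolated between bin centers, 0 one delta beyond each end."""
    c = dist.centers
    x = np.concatenate(([c[0] - dist.delta], c, [c[-1] + dist.delta]))
    y = np.concatenate(([0.0], dist.phi, [0.0]))
    return x, y


def _peak_estimate(dist: BinnedDistribution, fit_fraction: float = 0.9) -> float:
    """Noise-robust estimate of the curve maximum, in units of the raw bin max.

    The largest of many noisy bins overestimates the true curve peak, which
    systematically narrows every fractional-maximum width on finely binned
    data.  When at least three bins lie within ``fit_fraction`` of the raw
    maximum, the vertex of a least-squares parabola through them estimates
    the peak instead, averaging the noise away; the estimate is clipped to
    at most 1 so it can only remove the upward bias.  The fit region is
    kept narrow (within 90% of the peak) so the parabola approximates any
    smooth unimodal peak well.  Coarse histograms (fewer than three
    near-peak bins, the usual case at delta of 0.5-1 mm) fall back to the
    raw maximum, leaving hand-checkable small cases exact.
    """
    phi = dist.phi
    sel = phi >= fit_fraction
    if int(sel.sum()) >= 3:
        centers = dist.centers
        x0 = centers[int(np.argmax(phi))]
        a, b, c = np.polyfit(centers[sel] - x0, phi[sel], 2)
        if a < 0:
            vertex = c - b * b / (4 * a)
            if 0.0 < vertex < 1.0:
                return float(vertex)
    return 1.0


def width_at_fraction(dist: BinnedDistribution, f: float) -> float:
    """Width of the normalized curve phi at level ``f`` of its maximum.

    The curve is phi interpolated linearly between successive bin centers and
    taken as zero one bin-width beyond each end; the width is the distance
    between the outermost crossings of the level ``f`` times the estimated
    curve maximum (see :func:`_peak_estimate`).
    ``width_at_fraction(dist, 0.5)`` is the FWHM.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if dist.counts.max() == 0:
        raise ValueError("all-zero distribution has no width")
    level = f * _peak_estimate(dist)
    x, y = _padded_curve(dist)

    # leftmost upward crossing
    i = int(np.argmax(y >= level))  # first index at or above the level; y[0] = 0 < level
    x_left = x[i - 1] + (level - y[i - 1]) / (y[i] - y[i - 1]) * (x[i] - x[i - 1])
    # rightmost downward crossing
    j = len(y) - 1 - int(np.argmax(y[::-1] >= level))  # last index at or above the level
    x_right = x[j] + (y[j] - level) / (y[j] - y[j + 1]) * (x[j + 1] - x[j])
    return float(x_right - x_left)


def widths(dist: BinnedDistribution, fractions: Sequence[float] = DEFAULT_FRACTIONS) -> WidthSet:
    """Widths of phi at 50, 66 and 75% of maximum (monotone non-increasing)."""
    w = [width_at_fraction(dist, f) for f in fractions]
    return WidthSet(*w)


def replicate_width_summary(
    samples: Iterable[LengthSample],
    delta: float = 1.0,
    origin: float = 0.0,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> pd.DataFrame:
    """Per-fraction mean and SD of widths across replicates.

    Each replicate is binned and normalized on its own, then widths are
    averaged; the SD uses the n-1 denominator.  With a single replicate the
    SD is reported as NaN.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one replicate")
    per_rep = np.array(
        [
            [width_at_fraction(bin_lengths(s, delta, origin), f) for f in fractions]
            for s in samples
        ]
    )
    mean = per_rep.mean(axis=0)
    sd = per_rep.std(axis=0, ddof=1) if len(samples) >= 2 else np.full(len(list(fractions)), np.nan)
    return pd.DataFrame(
        {"fraction": list(fractions), "width_mean": mean, "width_sd": sd, "n_replicates": len(samples)}
    )


# ---------------------------------------------------------------------------
# CV and its McKay interval


def cv(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over sample mean."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("CV requires at least two values")
    m = x.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(x.std(ddof=1) / m)


def mckay_ci(cv_value: float, n: int, level: float = 0.90) -> tuple[float, float]:
    """McKay confidence interval for a population coefficient of variation.

    With K the observed CV, v = n - 1 degrees of freedom and u the
    chi-square quantiles u1 = chi2(1 - alpha/2, v), u2 = chi2(alpha/2, v),
    each limit is ``K / sqrt((u/v) * (1 + K^2) - K^2)``; the larger quantile
    gives the lower limit.  The approximation is accurate for K below about
    0.3 and moderate n.
    """
    if n < 2:
        raise ValueError("McKay interval requires n >= 2")
    if cv_value <= 0:
        raise ValueError("McKay interval requires a positive CV")
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    K = float(cv_value)
    v = n - 1
    alpha = 1.0 - level
    limits = []
    for u in (stats.chi2.ppf(1 - alpha / 2, v), stats.chi2.ppf(alpha / 2, v)):
        radicand = (u / v) * (1 + K**2) - K**2
        if radicand <= 0:
            raise ValueError(
                f"McKay radicand non-positive (u/v={u / v:.4f}, K={K:.4f}): "
                "CV too large for this sample size"
            )
        limits.append(K / math.sqrt(radicand))
    return (limits[0], limits[1])


def cv_estimate(values, level: float = 0.90) -> CVEstimate:
    """CV of ``values`` together with its McKay interval."""
    x = np.asarray(values, dtype=float).ravel()
    k = cv(x)
    if k == 0.0:
        return CVEstimate(cv=0.0, n=x.size, level=level, ci_low=0.0, ci_high=0.0)
    low, high = mckay_ci(k, x.size, level)
    return CVEstimate(cv=k, n=x.size, level=level, ci_low=low, ci_high=high)


# ---------------------------------------------------------------------------
# group comparison, yield, germination


def ttest_two_sample(a, b, welch: bool = False) -> TTestResult:
    """Independent two-sample t-test (Student's pooled-variance by default).

    ``welch=True`` switches to the unequal-variance Welch form.  Degenerate
    zero-variance input yields t = 0, p = 1 when the means agree, and is an
    error otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    # zero variance up to float round-off in the mean subtraction
    degenerate = all(
        x.std(ddof=1) <= 1e-12 * max(1.0, abs(x.mean())) for x in (a, b)
    )
    if degenerate:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if not welch else float("nan")
            return TTestResult(statistic=0.0, df=float(df), pvalue=1.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(statistic=float(res.statistic), df=float(res.df), pvalue=float(res.pvalue))


def yield_per_gfw(harvested_count: float, sampled_fraction: float, initial_fw_g: float) -> YieldStats:
    """Extrapolate embryos per gram fresh weight from a sampled fraction.

    ``harvested_count`` embryos were harvested from ``sampled_fraction`` of
    the tissue area, from a culture started with ``initial_fw_g`` grams of
    tissue; the total yield is ``harvested / fraction / grams``.
    """
    if not 0 < sampled_fraction <= 1:
        raise ValueError("sampled_fraction must lie in (0, 1]")
    if initial_fw_g <= 0:
        raise ValueError("initial fresh weight must be positive")
    if harvested_count < 0:
        raise ValueError("harvested_count must be non-negative")
    return YieldStats(
        harvested_count=harvested_count,
        sampled_fraction=sampled_fraction,
        initial_fw_g=initial_fw_g,
        embryos_per_gfw=harvested_count / sampled_fraction / initial_fw_g,
    )


def germination_rates(rec: GerminationRecord) -> tuple[int, int]:
    """Percent of collected embryos that started germination / rooted >= 1 cm.

    Rounded to integer percent, the reporting precision for germination
    tables.
    """
    if rec.collected == 0:
        raise ValueError("no embryos collected; rates undefined")
    pct_started = int(round(100.0 * rec.started / rec.collected))
    pct_rooted = int(round(100.0 * rec.rooted / rec.collected))
    return pct_started, pct_rooted
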