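"""Synthetic inputs for the maturation-quantification pipeline.

No raw study data (plate photographs, per-embryo length lists) are publicly
deposited for this kind of experiment, so every downstream stage is
exercised on generated inputs that carry the reported statistical
structure:

* near-normal embryo-length populations (truncated at zero) with
  replicate-level mean shifts emulating between-bioreactor variation;
* binary plate images of embryos rendered as filled ellipses, with a
  ground-truth table for every rendered object;
* right-skewed (log-normal) PEM aggregate-area distributions, calibrated so
  a stated fraction falls below a stated threshold area;
* germination count tables as a chain of binomial draws.

All generators take an integer seed (or a ``numpy.random.Generator``) and
are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import draw as _draw
from skimage import morphology as _morphology

from .sync_stats import GerminationRecord, LengthSample

__all__ = [
    "PopulationSpec",
    "PlateImageSpec",
    "AggregateSizeSpec",
    "GerminationSpec",
    "sample_lengths",
    "render_plate_image",
    "sample_aggregate_areas",
    "simulate_germination",
]

GROUND_TRUTH_COLUMNS = ["id", "cx_px", "cy_px", "theta_rad", "major_mm", "area_mm2"]

_MAX_REJECTION_ROUNDS = 1000


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# specs


@dataclass
class PopulationSpec:
    """Parameters of one embryo-length population.

    ``mean_length``/``sd_length`` are the within-replicate normal parameters
    (mm); ``between_replicate_sd`` shifts each replicate's mean by an
    independent normal perturbation, emulating between-bioreactor variation.
    Lengths are truncated to the interval ``(truncation_low,
    truncation_high]`` by rejection (negative lengths are physically
    impossible, hence the default lower bound at 0).
    """

    mean_length: float
    sd_length: float
    n_embryos: int
    n_replicates: int = 1
    between_replicate_sd: float = 0.0
    truncation_low: float = 0.0
    truncation_high: float = math.inf
    label: str = ""

    def __post_init__(self) -> None:
        if self.mean_length <= 0:
            raise ValueError("mean_length must be positive")
        if self.sd_length < 0 or self.between_replicate_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_embryos < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if not self.truncation_low < self.mean_length:
            raise ValueError("truncation_low must lie below the mean")
        if not self.truncation_low < self.truncation_high:
            raise ValueError("empty truncation interval")


@dataclass
class PlateImageSpec:
    """Geometry of a rendered binary plate image.

    Embryos are drawn as filled ellipses whose major axis equals the embryo
    length at ``mm_per_px`` calibration; the minor/major aspect ratio is
    drawn per embryo from a clipped normal.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    mm_per_px: float = 0.02
    aspect_ratio_mean: float = 0.35
    aspect_ratio_sd: float = 0.05
    max_placement_attempts: int = 200
    allow_touching: bool = False

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if not 0 < self.aspect_ratio_mean < 1:
            raise ValueError("aspect_ratio_mean must lie in (0, 1)")
        if self.image_height_px < 64 or self.image_width_px < 64:
            raise ValueError("image dimensions must be at least 64 px")


@dataclass
class AggregateSizeSpec:
    """Log-normal model of dispersed PEM aggregate areas (mm^2).

    When ``target_fraction_leq = (threshold, fraction)`` is given, the
    location parameter is re-solved (keeping ``log_sd``) so that the
    distribution puts exactly ``fraction`` of its mass at or below
    ``threshold`` mm^2.
    """

    log_mean: float = math.log(0.08)
    log_sd: float = 1.0
    n_aggregates: int = 651
    target_fraction_leq: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_aggregates < 1:
            raise ValueError("n_aggregates must be >= 1")
        if self.log_sd < 0:
            raise ValueError("log_sd must be non-negative")
        if self.target_fraction_leq is not None:
            threshold, fraction = self.target_fraction_leq
            if threshold <= 0:
                raise ValueError("threshold area must be positive")
            if not 0 <= fraction <= 1:
                raise ValueError("target fraction must lie in [0, 1]")


@dataclass
class GerminationSpec:
    """Per-embryo germination probabilities."""

    p_start: float
    p_root_given_start: float

    def __post_init__(self) -> None:
        for p in (self.p_start, self.p_root_given_start):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# generators


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, low: float, high: float
) -> np.ndarray:
    """n draws from N(mean, sd) restricted to (low, high] by rejection."""
    if sd == 0.0:
        if not low < mean <= high:
            raise RuntimeError("degenerate population lies outside the truncation interval")
        return np.full(n, mean)
    out = np.empty(0)
    for _ in range(_MAX_REJECTION_ROUNDS):
        batch = rng.normal(mean, sd, size=max(n, 128))
        keep = batch[(batch > low) & (batch <= high)]
        out = np.concatenate([out, keep])
        if out.size >= n:
            return out[:n]
    raise RuntimeError(
        f"rejection sampling failed: truncation to ({low}, {high}] leaves almost "
        f"no mass for N({mean}, {sd})"
    )


def sample_lengths(spec: PopulationSpec, seed) -> LengthSample:
    """Draw a replicated embryo-length sample from a truncated-normal model.

    Each replicate r gets an independent mean shift
    ``N(0, between_replicate_sd)``; its ``n_embryos`` lengths are then drawn
    from ``N(mean_length + shift, sd_length)`` truncated to
    ``(truncation_low, truncation_high]``.
    """
    rng = _rng(seed)
    lengths, reps = [], []
    for r in range(1, spec.n_replicates + 1):
        shift = rng.normal(0.0, spec.between_replicate_sd) if spec.between_replicate_sd else 0.0
        vals = _truncated_normal(
            rng,
            spec.mean_length + shift,
            spec.sd_length,
            spec.n_embryos,
            spec.truncation_low,
            spec.truncation_high,
        )
        lengths.append(vals)
        reps.append(np.full(vals.size, r, dtype=int))
    return LengthSample(np.concatenate(lengths), np.concatenate(reps), spec.label)


def _empty_ground_truth() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in GROUND_TRUTH_COLUMNS})


def render_plate_image(
    spec: PlateImageSpec, lengths, seed
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render embryos as filled ellipses on a black plate image.

    Each length becomes one ellipse with major axis ``length / mm_per_px``
    pixels, random orientation and random position.  Unless
    ``spec.allow_touching``, candidate placements that would overlap or
    8-touch an already placed object are rejected and re-drawn, up to
    ``spec.max_placement_attempts`` per embryo.

    Returns
    -------
    image : uint8 array, background 0 / foreground 255
    ground_truth : DataFrame with one row per rendered object
        (``id, cx_px, cy_px, theta_rad, major_mm, area_mm2``); ``area_mm2``
        is the rasterized pixel area, ``theta_rad`` the rotation passed to
        the rasterizer (counter-clockwise in image coordinates).
    """
    rng = _rng(seed)
    vals = np.asarray(lengths.lengths if isinstance(lengths, LengthSample) else lengths, float)
    H, W = spec.image_height_px, spec.image_width_px
    img = np.zeros((H, W), dtype=np.uint8)
    if vals.size == 0:
        return img, _empty_ground_truth()

    major_px = vals / spec.mm_per_px
    if np.any(major_px < 4):
        raise ValueError("every embryo must span at least 4 px at this calibration")
    if np.any(major_px / 2 + 2 > min(H, W) / 2):
        raise ValueError("image too small for the longest embryo")

    occupied = np.zeros((H, W), dtype=bool)
    footprint = _morphology.footprint_rectangle((3, 3))
    rows = []
    for i, (L, a2) in enumerate(zip(vals, major_px)):
        a = a2 / 2.0
        placed = False
        for _ in range(spec.max_placement_attempts):
            aspect = float(np.clip(rng.normal(spec.aspect_ratio_mean, spec.aspect_ratio_sd), 0.05, 0.95))
            theta = float(rng.uniform(0.0, math.pi))
            b = aspect * a
            margin = a + 2.0
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            rr, cc = _draw.ellipse(cy, cx, b, a, shape=(H, W), rotation=theta)
            if rr.size == 0:
                continue
            if not spec.allow_touching:
                # test the candidate, dilated by one pixel, against what is
                # already placed — rules out both overlap and 8-touching
                r0, r1 = rr.min() - 1, rr.max() + 2
                c0, c1 = cc.min() - 1, cc.max() + 2
                r0, c0 = max(r0, 0), max(c0, 0)
                patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
                patch[rr - r0, cc - c0] = True
                grown = _morphology.binary_dilation(patch, footprint)
                if np.any(grown & occupied[r0:r1, c0:c1]):
                    continue
            img[rr, cc] = 255
            occupied[rr, cc] = True
            rows.append(
                {
                    "id": i,
                    "cx_px": cx,
                    "cy_px": cy,
                    "theta_rad": theta,
                    "major_mm": float(L),
                    "area_mm2": rr.size * spec.mm_per_px**2,
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place embryo {i} after {spec.max_placement_attempts} "
                f"attempts ({len(rows)} of {vals.size} placed); enlarge the image "
                "or allow touching"
            )
    return img, pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def calibrate_log_mean(log_sd: float, threshold: float, fraction: float) -> float:
    """Location parameter putting ``fraction`` of log-normal mass at or below ``threshold``.

    Solves P(X <= t) = p for mu with sigma fixed: ``mu = ln t - sigma *
    Phi^-1(p)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("calibration infeasible: target fraction must lie strictly in (0, 1)")
    if log_sd <= 0:
        raise ValueError("calibration infeasible: requires a positive log_sd")
    return math.log(threshold) - log_sd * float(stats.norm.ppf(fraction))


def sample_aggregate_areas(spec: AggregateSizeSpec, seed) -> np.ndarray:
    """Draw dispersed-aggregate areas (mm^2) from the log-normal model."""
    rng = _rng(seed)
    mu, sigma = spec.log_mean, spec.log_sd
    if spec.target_fraction_leq is not None:
        threshold, fraction = spec.target_fraction_leq
        mu = calibrate_log_mean(sigma, threshold, fraction)
    if sigma == 0.0:
        return np.full(spec.n_aggregates, math.exp(mu))
    return rng.lognormal(mu, sigma, size=spec.n_aggregates)


def simulate_germination(
    spec: GerminationSpec, n_collected: int, seed, treatment: str = ""
) -> GerminationRecord:
    """Simulate a germination trial as a chain of binomial stages.

    ``started ~ Binomial(collected, p_start)``;
    ``rooted ~ Binomial(started, p_root_given_start)``; the ordering
    ``rooted <= started <= collected`` holds by construction.
    """
    if n_collected < 0:
        raise ValueError("n_collected must be non-negative")
    rng = _rng(seed)
    started = int(rng.binomial(n_collected, spec.p_start))
    rooted = int(rng.binomial(started, spec.p_root_given_start))
    return GerminationRecord(collected=int(n_collected), started=started, rooted=rooted, treatment=treatment)
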