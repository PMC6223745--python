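"""Model/Results interface over a single embryo-length sample.

``EmbryoLengthModel`` holds the data and the analysis settings (bin width,
origin, width fractions, CI level); ``fit()`` computes everything at once
and returns a ``SynchronizationResults`` carrying the estimates, their
uncertainty, diagnostics, a ``summary()`` table, plotting, and parametric
simulation of new samples from the fitted truncated-normal description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import synthetic_data as _synth
from .sync_stats import (
    DEFAULT_FRACTIONS,
    BinnedDistribution,
    CVEstimate,
    LengthSample,
    WidthSet,
    bin_lengths,
    cv_estimate,
    replicate_width_summary,
    widths,
)

__all__ = ["EmbryoLengthModel", "SynchronizationResults"]


class EmbryoLengthModel:
    """Synchronization analysis of one treatment group's embryo lengths.

    Parameters
    ----------
    sample
        A :class:`LengthSample` or a plain array of lengths (mm).
    delta, origin
        Bin width and left edge of the first length interval (mm).
    fractions
        Fractions of the curve maximum at which widths are read off.
    ci_level
        Confidence level for the McKay CV interval.
    """

    def __init__(
        self,
        sample,
        delta: float = 1.0,
        origin: float = 0.0,
        fractions: Sequence[float] = DEFAULT_FRACTIONS,
        ci_level: float = 0.90,
    ) -> None:
        if not isinstance(sample, LengthSample):
            sample = LengthSample(np.asarray(sample, dtype=float))
        if sample.n == 0:
            raise ValueError("cannot model an empty length sample")
        self.sample = sample
        self.delta = float(delta)
        self.origin = float(origin)
        self.fractions = tuple(fractions)
        self.ci_level = float(ci_level)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, treatment: str | None = None, **kwargs) -> "EmbryoLengthModel":
        return cls(LengthSample.from_frame(df, treatment=treatment), **kwargs)

    @classmethod
    def from_csv(cls, path, treatment: str | None = None, **kwargs) -> "EmbryoLengthModel":
        return cls(LengthSample.from_csv(path, treatment=treatment), **kwargs)

    def fit(self) -> "SynchronizationResults":
        s = self.sample
        x = s.lengths
        mean = float(x.mean())
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        cv_est = cv_estimate(x, level=self.ci_level) if x.size > 1 else None
        dist = bin_lengths(s, self.delta, self.origin)
        width_set = widths(dist, self.fractions)
        reps = s.by_replicate()
        rep_widths = (
            replicate_width_summary(reps, self.delta, self.origin, self.fractions)
            if len(reps) > 1
            else None
        )
        # normality is an assumption of the truncated-normal description;
        # reported as a diagnostic, never used as a gate
        normality_p = float(_stats.shapiro(x).pvalue) if 3 <= x.size <= 5000 else float("nan")
        return SynchronizationResults(
            model=self,
            n=s.n,
            mean=mean,
            sd=sd,
            cv=cv_est,
            distribution=dist,
            widths=width_set,
            replicate_widths=rep_widths,
            normality_p=normality_p,
        )


@dataclass
class SynchronizationResults:
    """Fitted synchronization statistics for one length sample."""

    model: EmbryoLengthModel
    n: int
    mean: float
    sd: float
    cv: CVEstimate | None
    distribution: BinnedDistribution
    widths: WidthSet
    replicate_widths: pd.DataFrame | None
    normality_p: float

    def summary(self) -> str:
        """Plain-text summary table of the fitted statistics."""
        m = self.model
        lines = [
            "Embryo length synchronization analysis",
            "=" * 46,
            f"treatment:            {m.sample.treatment or '(unlabelled)'}",
            f"n lengths:            {self.n}",
            f"n replicates:         {len(m.sample.replicate_ids())}",
            f"mean length (mm):     {self.mean:.2f}",
            f"SD (mm):              {self.sd:.2f}",
        ]
        if self.cv is not None:
            c = self.cv
            lines.append(
                f"CV [McKay {c.level:.0%} CI]:   {c.cv:.2f}  ({c.ci_low:.2f}, {c.ci_high:.2f})"
            )
        lines.append(f"bin width delta (mm): {m.delta:g} (origin {m.origin:g})")
        for f, w in zip(m.fractions, (self.widths.width_50, self.widths.width_66, self.widths.width_75)):
            lines.append(f"width at {f:.0%} max:     {w:.2f} mm")
        if self.replicate_widths is not None:
            lines.append("per-replicate widths (mean +/- SD):")
            for _, row in self.replicate_widths.iterrows():
                lines.append(
                    f"  {row['fraction']:.0%}: {row['width_mean']:.2f} +/- {row['width_sd']:.2f} mm"
                )
        if np.isfinite(self.normality_p):
            lines.append(f"Shapiro-Wilk normality p: {self.normality_p:.3g}")
            if self.normality_p < 0.05:
                lines.append("  warning: lengths deviate from normality (diagnostic only)")
        return "\n".join(lines)

    def simulate(self, n_replicates: int | None = None, seed=0) -> LengthSample:
        """Draw a new sample from the fitted truncated-normal description."""
        m = self.model
        spec = _synth.PopulationSpec(
            mean_length=self.mean,
            sd_length=self.sd,
            n_embryos=max(1, self.n // max(1, len(m.sample.replicate_ids()))),
            n_replicates=n_replicates or len(m.sample.replicate_ids()),
            label=m.sample.treatment,
        )
        return _synth.sample_lengths(spec, seed)

    def plot_distribution(self, ax=None):
        """Plot phi(q-bar) with horizontal lines at the width fractions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.distribution
        centers = np.concatenate(
            ([d.centers[0] - d.delta], d.centers, [d.centers[-1] + d.delta])
        )
        phi = np.concatenate(([0.0], d.phi, [0.0]))
        ax.plot(centers, phi, marker="o")
        for f in self.model.fractions:
            ax.axhline(f, linestyle="--", linewidth=0.8, alpha=0.6)
        ax.set_xlabel("embryo length $\\bar{q}$ (mm)")
        ax.set_ylabel("$\\varphi(\\bar{q})$")
        ax.set_title(self.model.sample.treatment or "normalized length distribution")
        return ax
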