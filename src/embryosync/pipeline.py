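"""Study orchestration: generate -> measure -> analyze -> report.

A study configuration mirrors the experimental design of a dispersion
experiment: treatment groups (cell line x dispersed/non-dispersed x
bioreactor/solid) with replicates, each resolvable either to a synthetic
population spec or to a lengths CSV on disk, plus analysis settings and one
global seed.  ``run_study`` executes every stage deterministically for a
fixed seed, writes all intermediate artifacts and report tables under the
output directory, and returns a :class:`RunReport`.

Output files: per-group length CSVs (and rendered plate PNGs when the image
route is enabled), ``table1_lengths_cv.csv``, ``table2_widths.csv``,
``table3_germination.csv``, ``summary.json`` and ``run.log``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import EmbryoLengthModel
from .morphometry import CalibrationInfo, measure_all, measurements_to_frame
from .sync_stats import GerminationRecord, LengthSample, germination_rates, ttest_two_sample, yield_per_gfw
from .synthetic_data import (
    GerminationSpec,
    PlateImageSpec,
    PopulationSpec,
    render_plate_image,
    sample_lengths,
    simulate_germination,
)

__all__ = ["StudyConfig", "GroupConfig", "AnalysisConfig", "RunReport", "run_study", "compare_treatments"]

logger = logging.getLogger("embryosync")


@dataclass
class AnalysisConfig:
    delta: float = 1.0
    origin: float = 0.0
    fractions: tuple = (0.50, 0.66, 0.75)
    ci_level: float = 0.90
    welch: bool = False
    alpha_levels: tuple = (0.01, 0.05, 0.10)


@dataclass
class GroupConfig:
    """One treatment group of the study design."""

    cell_line: str
    treatment: str  # "dispersed" | "non-dispersed"
    culture: str = "bioreactor"  # "bioreactor" | "solid"
    population: PopulationSpec | None = None
    lengths_csv: str | None = None
    sampled_fraction: float = 1.0
    initial_fw_g: float = 1.0
    germination: GerminationSpec | None = None
    germination_n_collected: int = 0
    germination_csv: str | None = None
    via_images: bool = False
    image: PlateImageSpec | None = None

    def __post_init__(self) -> None:
        if self.treatment not in ("dispersed", "non-dispersed"):
            raise ValueError("treatment must be 'dispersed' or 'non-dispersed'")
        if self.culture not in ("bioreactor", "solid"):
            raise ValueError("culture must be 'bioreactor' or 'solid'")
        if (self.population is None) == (self.lengths_csv is None):
            raise ValueError(f"group {self.label}: exactly one of population/lengths_csv required")

    @property
    def label(self) -> str:
        return f"{self.cell_line}|{self.treatment}|{self.culture}"


@dataclass
class StudyConfig:
    groups: list[GroupConfig]
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    output_dir: str = "embryosync_out"

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels (cell_line|treatment|culture) must be unique")

    @classmethod
    def from_dict(cls, doc: dict) -> "StudyConfig":
        groups = []
        for g in doc.get("groups", []):
            g = dict(g)
            if "population" in g and g["population"] is not None:
                g["population"] = PopulationSpec(**g["population"])
            if "image" in g and g["image"] is not None:
                g["image"] = PlateImageSpec(**g["image"])
            germ = g.pop("germination", None)
            if germ is not None:
                germ = dict(germ)
                g["germination_n_collected"] = int(germ.pop("n_collected", 0))
                g["germination"] = GerminationSpec(**germ)
            groups.append(GroupConfig(**g))
        analysis = AnalysisConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in doc.get("analysis", {}).items()})
        return cls(
            groups=groups,
            analysis=analysis,
            seed=int(doc.get("seed", 0)),
            output_dir=str(doc.get("output_dir", "embryosync_out")),
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunReport:
    """All per-group summaries plus pairwise treatment comparisons."""

    groups: list[dict]
    comparisons: list[dict]
    provenance: dict
    # raw per-group data kept for further comparisons; not serialized
    samples: dict = field(default_factory=dict, repr=False)
    replicate_yields: dict = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        doc = {"groups": self.groups, "comparisons": self.comparisons, "provenance": self.provenance}
        return json.dumps(doc, indent=2, sort_keys=True, allow_nan=True)


def _config_hash(config: StudyConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(config, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _auto_image_spec(lengths_mm: np.ndarray, mm_per_px: float = 0.02) -> PlateImageSpec:
    """Size a plate image generously enough for non-touching placement."""
    max_px = float(np.max(lengths_mm)) / mm_per_px
    side = int(max(512, np.ceil(np.sqrt(lengths_mm.size) * max_px * 1.8)))
    return PlateImageSpec(image_height_px=side, image_width_px=side, mm_per_px=mm_per_px)


def _lengths_via_images(
    group: GroupConfig, sample: LengthSample, rng: np.random.Generator, outdir: Path
) -> LengthSample:
    """Replace true lengths by lengths measured from rendered plate images."""
    import imageio.v3 as iio

    measured, reps = [], []
    for rep_sample in sample.by_replicate():
        spec = group.image or _auto_image_spec(rep_sample.lengths)
        img, _truth = render_plate_image(spec, rep_sample, rng)
        rid = rep_sample.replicates[0]
        iio.imwrite(outdir / f"plate_rep{rid}.png", img)
        ms = measure_all(img, CalibrationInfo(spec.mm_per_px))
        measurements_to_frame(ms).to_csv(outdir / f"measurements_rep{rid}.csv", index=False)
        measured.append([m.major_mm for m in ms])
        reps.append(np.full(len(ms), rid))
    return LengthSample(np.concatenate(measured), np.concatenate(reps), sample.treatment)


def _load_germination(path, treatment: str) -> GerminationRecord:
    df = pd.read_csv(path)
    row = df.iloc[0]
    return GerminationRecord(
        collected=int(row["collected"]), started=int(row["started"]), rooted=int(row["rooted"]),
        treatment=treatment,
    )


def run_study(config: StudyConfig, output_dir: str | None = None) -> RunReport:
    """Execute the full study: data, morphometry, statistics, report tables."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    ss = np.random.SeedSequence(config.seed)
    group_seeds = ss.spawn(len(config.groups))
    a = config.analysis
    report = RunReport(
        groups=[],
        comparisons=[],
        provenance={"config_hash": _config_hash(config), "seed": config.seed, "version": __version__},
    )
    try:
        logger.info("run start: %d groups, seed %d", len(config.groups), config.seed)
        for group, gseed in zip(config.groups, group_seeds):
            t0 = time.perf_counter()
            s_lengths, s_images, s_germ = (np.random.default_rng(s) for s in gseed.spawn(3))
            gdir = outdir / group.label.replace("|", "_").replace(":", "-").replace("/", "-")
            gdir.mkdir(exist_ok=True)
            stage = {"name": "setup"}
            try:
                summary = _run_group(group, a, s_lengths, s_images, s_germ, gdir, report, stage)
            except Exception as exc:
                logger.error("group %s failed at stage %s: %s", group.label, stage["name"], exc)
                raise RuntimeError(
                    f"group {group.label} failed at stage {stage['name']}: {exc}"
                ) from exc
            report.groups.append(summary)
            logger.info("group %s done in %.2fs", group.label, time.perf_counter() - t0)

        for cell_line, culture in sorted({(g.cell_line, g.culture) for g in config.groups}):
            has_both = {
                g.treatment for g in config.groups if g.cell_line == cell_line and g.culture == culture
            } >= {"dispersed", "non-dispersed"}
            if has_both:
                report.comparisons.append(
                    compare_treatments(report, cell_line, culture, a.alpha_levels, welch=a.welch)
                )

        _write_tables(report, outdir)
        (outdir / "summary.json").write_text(report.to_json(), encoding="utf-8")
        logger.info("run complete")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report


def _run_group(
    group: GroupConfig,
    a: AnalysisConfig,
    s_lengths: np.random.Generator,
    s_images: np.random.Generator,
    s_germ: np.random.Generator,
    gdir: Path,
    report: RunReport,
    stage: dict | None = None,
) -> dict:
    stage = stage if stage is not None else {"name": "setup"}
    stage["name"] = "lengths"
    if group.population is not None:
        sample = sample_lengths(group.population, s_lengths)
        sample.treatment = group.population.label or group.treatment
    else:
        sample = LengthSample.from_csv(group.lengths_csv)
        sample.treatment = group.treatment

    if group.via_images:
        stage["name"] = "imaging"
        sample = _lengths_via_images(group, sample, s_images, gdir)
    sample.to_csv(gdir / "lengths.csv")

    stage["name"] = "analysis"
    results = EmbryoLengthModel(
        sample, delta=a.delta, origin=a.origin, fractions=a.fractions, ci_level=a.ci_level
    ).fit()

    stage["name"] = "yield"
    rep_samples = sample.by_replicate()
    per_rep_yields = [
        yield_per_gfw(s.n, group.sampled_fraction, group.initial_fw_g).embryos_per_gfw
        for s in rep_samples
    ]
    yields = np.asarray(per_rep_yields)
    yield_cv = float(yields.std(ddof=1) / yields.mean()) if yields.size >= 2 and yields.mean() > 0 else None

    stage["name"] = "germination"
    germination = None
    if group.germination_csv is not None:
        rec = _load_germination(group.germination_csv, group.treatment)
    elif group.germination is not None:
        rec = simulate_germination(group.germination, group.germination_n_collected, s_germ, group.treatment)
    else:
        rec = None
    if rec is not None:
        pct_started, pct_rooted = germination_rates(rec)
        germination = {
            "collected": rec.collected,
            "started": rec.started,
            "rooted": rec.rooted,
            "pct_started": pct_started,
            "pct_rooted": pct_rooted,
        }

    report.samples[group.label] = sample
    report.replicate_yields[group.label] = yields

    summary = {
        "label": group.label,
        "cell_line": group.cell_line,
        "treatment": group.treatment,
        "culture": group.culture,
        "n": results.n,
        "n_replicates": len(rep_samples),
        "mean_length_mm": results.mean,
        "sd_length_mm": results.sd,
        "cv": results.cv.cv if results.cv else None,
        "cv_ci_low": results.cv.ci_low if results.cv else None,
        "cv_ci_high": results.cv.ci_high if results.cv else None,
        "ci_level": a.ci_level,
        "widths_mm": results.widths.as_dict(),
        "replicate_widths": (
            results.replicate_widths.to_dict(orient="records")
            if results.replicate_widths is not None
            else None
        ),
        "yield_mean_per_gfw": float(yields.mean()),
        "yield_cv": yield_cv,
        "germination": germination,
        "normality_p": results.normality_p if np.isfinite(results.normality_p) else None,
    }
    if results.normality_p < 0.05:
        logger.warning("group %s: Shapiro-Wilk p=%.3g suggests non-normal lengths", group.label, results.normality_p)
    return summary


def compare_treatments(
    report: RunReport,
    cell_line: str,
    culture: str,
    alpha_levels: Sequence[float] = (0.01, 0.05, 0.10),
    welch: bool = False,
) -> dict:
    """Dispersed vs non-dispersed t-tests on replicate yields and on lengths."""
    key_d = f"{cell_line}|dispersed|{culture}"
    key_n = f"{cell_line}|non-dispersed|{culture}"
    missing = [k for k in (key_d, key_n) if k not in report.samples]
    if missing:
        raise ValueError(f"missing counterpart group(s) for comparison: {missing}")
    row: dict = {"cell_line": cell_line, "culture": culture}

    ya, yb = report.replicate_yields[key_d], report.replicate_yields[key_n]
    if ya.size >= 2 and yb.size >= 2:
        try:
            t = ttest_two_sample(ya, yb, welch=welch)
        except ValueError as exc:
            # constant replicate yields (e.g. fixed per-replicate counts)
            row["yield_p"] = None
            row["yield_note"] = str(exc)
        else:
            row["yield_t"] = t.statistic
            row["yield_p"] = t.pvalue
            row["yield_significant_at"] = [a for a in alpha_levels if t.pvalue < a]

    t = ttest_two_sample(report.samples[key_d].lengths, report.samples[key_n].lengths, welch=welch)
    row["length_t"] = t.statistic
    row["length_p"] = t.pvalue
    row["length_significant_at"] = [a for a in alpha_levels if t.pvalue < a]
    return row


def _write_tables(report: RunReport, outdir: Path) -> None:
    t1 = pd.DataFrame(
        [
            {
                "cell_line": g["cell_line"],
                "treatment": g["treatment"],
                "culture": g["culture"],
                "n": g["n"],
                "mean_length_mm": round(g["mean_length_mm"], 2),
                "sd_length_mm": round(g["sd_length_mm"], 2),
                "cv": round(g["cv"], 2) if g["cv"] is not None else None,
                "cv_ci_low": round(g["cv_ci_low"], 2) if g["cv_ci_low"] is not None else None,
                "cv_ci_high": round(g["cv_ci_high"], 2) if g["cv_ci_high"] is not None else None,
            }
            for g in report.groups
        ]
    )
    t1.to_csv(outdir / "table1_lengths_cv.csv", index=False)

    rows2 = []
    for g in report.groups:
        if g["replicate_widths"]:
            for r in g["replicate_widths"]:
                rows2.append(
                    {
                        "cell_line": g["cell_line"],
                        "treatment": g["treatment"],
                        "culture": g["culture"],
                        "fraction": r["fraction"],
                        "width_mean_mm": round(r["width_mean"], 2),
                        "width_sd_mm": round(r["width_sd"], 2) if np.isfinite(r["width_sd"]) else None,
                    }
                )
        else:
            for name, w in g["widths_mm"].items():
                rows2.append(
                    {
                        "cell_line": g["cell_line"],
                        "treatment": g["treatment"],
                        "culture": g["culture"],
                        "fraction": float(name.split("_")[1]) / 100,
                        "width_mean_mm": round(w, 2),
                        "width_sd_mm": None,
                    }
                )
    pd.DataFrame(rows2).to_csv(outdir / "table2_widths.csv", index=False)

    rows3 = [
        {
            "cell_line": g["cell_line"],
            "treatment": g["treatment"],
            "culture": g["culture"],
            **g["germination"],
        }
        for g in report.groups
        if g["germination"]
    ]
    pd.DataFrame(rows3).to_csv(outdir / "table3_germination.csv", index=False)
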