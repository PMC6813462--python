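"""End-to-end orchestration: filter → metrics → classify → curves → stats.

``run_analysis`` reproduces the shape of a full track-analysis report for one
dataset (per-track metrics, population fractions, displacement/MSD curves,
between-group comparisons); ``run_blockade_contrast`` lines up two cohorts —
e.g. before and after an adhesion-blocking treatment — and reports
side-by-side deltas with per-metric tests.  Every report embeds the exact
configuration and software version so each number is recomputable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (DEFAULT_NEAR_DISTANCE, DEFAULT_NEAR_FRACTION,
                       classification_table, population_fractions)
from .metrics import (DEFAULT_ARREST_THRESHOLD, displacement_curve,
                      metrics_table, msd_curve)
from .stats import compare_displacement_slopes, mann_whitney
from .track_model import (FieldMeta, FilterPolicy, Track, VesselGeometry,
                          apply_filters, read_tracks, read_vessels)

log = logging.getLogger("sasmotility")

COMPARED_METRICS = ("mean_velocity", "meandering_index", "arrest_index")


@dataclass
class AnalysisConfig:
    """Configuration for one end-to-end run (YAML-serializable)."""

    tracks: str = ""
    vessels: str | None = None
    out_dir: str = "analysis_out"
    filter_policy: FilterPolicy = dc_field(default_factory=FilterPolicy)
    stationary_threshold: float = DEFAULT_ARREST_THRESHOLD  # μm/min
    near_distance: float = DEFAULT_NEAR_DISTANCE            # μm
    near_fraction: float = DEFAULT_NEAR_FRACTION
    curve_grid_step: float = 37.5                           # s
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        fp = FilterPolicy(**raw.pop("filter_policy", {}))
        return cls(filter_policy=fp, **raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["software_version"] = __version__
        return d


@dataclass
class AnalysisReport:
    """All tables produced by one run, plus provenance."""

    metrics: pd.DataFrame
    classes: pd.DataFrame
    population_per_field: pd.DataFrame
    population_mean: pd.Series
    population_sem: pd.Series
    displacement: pd.DataFrame
    msd: pd.DataFrame
    comparisons: dict
    filter_log: dict
    config: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.classes.to_csv(out / "classes.csv", index=False)
        self.population_per_field.to_csv(out / "population_per_field.csv")
        pd.DataFrame({"mean": self.population_mean,
                      "sem": self.population_sem}
                     ).to_csv(out / "population_summary.csv")
        self.displacement.to_csv(out / "displacement_curve.csv", index=False)
        self.msd.to_csv(out / "msd_curve.csv", index=False)
        with open(out / "comparisons.json", "w", encoding="utf-8") as fh:
            json.dump(self.comparisons, fh, indent=1, default=float)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump({"config": self.config, "filter_log": self.filter_log},
                      fh, indent=1, default=float)


def _infer_fields(tracks: Sequence[Track]) -> dict[str, FieldMeta]:
    """Field metadata inferred from the tracks themselves: the number of
    visible cells per field defaults to the number of tracked cells."""
    counts: dict[str, int] = {}
    for tr in tracks:
        counts[tr.field_id] = counts.get(tr.field_id, 0) + 1
    return {fid: FieldMeta(field_id=fid, n_cells_visible=n)
            for fid, n in counts.items()}


def analyze_tracks(
    tracks: Sequence[Track],
    vessels: VesselGeometry = VesselGeometry(),
    fields: Mapping[str, FieldMeta] | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Pure in-memory pipeline over already-loaded tracks."""
    cfg = config or AnalysisConfig()
    if fields is None:
        fields = _infer_fields(tracks)
    kept, rep = apply_filters(tracks, fields, cfg.filter_policy)
    log.info("filter: %d tracks in, %d kept (%s)", rep.n_input, rep.n_kept,
             rep.as_dict())
    if not kept:
        raise ValueError("no tracks survive the inclusion filters")

    met = metrics_table(kept, cfg.stationary_threshold)
    cls = classification_table(kept, vessels, cfg.stationary_threshold,
                               cfg.near_distance, cfg.near_fraction)
    pop = population_fractions(cls, fields)
    disp = displacement_curve(kept, cfg.curve_grid_step).as_frame()
    msd = msd_curve(kept, cfg.curve_grid_step).as_frame()

    comparisons: dict = {}
    groups = sorted(met["group"].unique())
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            for metric in COMPARED_METRICS:
                a = met.loc[met["group"] == ga, metric]
                b = met.loc[met["group"] == gb, metric]
                if len(a) and len(b):
                    comparisons[f"{metric}:{ga}_vs_{gb}"] = mann_whitney(
                        a, b).as_dict()
    log.info("analyzed %d tracks in %d fields, %d group comparison(s)",
             len(kept), len(pop.per_field), len(comparisons))
    return AnalysisReport(
        metrics=met, classes=cls, population_per_field=pop.per_field,
        population_mean=pop.cohort_mean, population_sem=pop.cohort_sem,
        displacement=disp, msd=msd, comparisons=comparisons,
        filter_log=rep.as_dict(), config=cfg.snapshot(),
    )


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """File-driven pipeline: read tracks (and vessels), analyze, write the
    report tables under ``config.out_dir``."""
    tracks = read_tracks(config.tracks)
    vessels = read_vessels(config.vessels) if config.vessels \
        else VesselGeometry()
    if vessels.is_empty:
        log.warning("empty vessel geometry: perivascular class unavailable")
    report = analyze_tracks(tracks, vessels, config=config)
    report.write(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# paired before/after contrast
# ---------------------------------------------------------------------------

@dataclass
class ContrastReport:
    """Side-by-side deltas between two cohorts (e.g. CTRL vs treated)."""

    summary: pd.DataFrame          # metric × (mean_pre, mean_post, delta, p)
    nonmotile_fraction: dict
    slope_comparison: dict
    pre: AnalysisReport
    post: AnalysisReport

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "contrast_summary.csv")
        with open(out / "contrast.json", "w", encoding="utf-8") as fh:
            json.dump({"nonmotile_fraction": self.nonmotile_fraction,
                       "slope_comparison": self.slope_comparison},
                      fh, indent=1, default=float)
        self.pre.write(out / "pre")
        self.post.write(out / "post")


def run_blockade_contrast(
    tracks_pre: Sequence[Track],
    tracks_post: Sequence[Track],
    vessels: VesselGeometry = VesselGeometry(),
    config: AnalysisConfig | None = None,
) -> ContrastReport:
    """Compare two cohorts metric-by-metric (observational deltas only).

    Reports, for each per-track metric, the cohort means before/after, the
    delta, and a Mann–Whitney p; plus the non-motile (stationary) fraction
    shift and the equality-of-slopes test on the displacement-vs-√time
    curves.
    """
    cfg = config or AnalysisConfig()
    rep_pre = analyze_tracks(tracks_pre, vessels, config=cfg)
    rep_post = analyze_tracks(tracks_post, vessels, config=cfg)
    schema = set(rep_pre.metrics.columns)
    if schema != set(rep_post.metrics.columns):
        raise ValueError("cohort metric tables have mismatched schemas")

    rows = []
    for metric in COMPARED_METRICS:
        a = rep_pre.metrics[metric]
        b = rep_post.metrics[metric]
        cmp_ = mann_whitney(a, b)
        rows.append({
            "metric": metric,
            "mean_pre": float(a.mean()), "mean_post": float(b.mean()),
            "delta": float(b.mean() - a.mean()),
            "mw_u": cmp_.statistic, "p_value": cmp_.p_value,
        })
    summary = pd.DataFrame(rows).set_index("metric")

    def nonmotile(rep: AnalysisReport) -> float:
        return float((rep.metrics["mean_velocity"]
                      <= cfg.stationary_threshold).mean())

    kept_pre, _ = apply_filters(tracks_pre, _infer_fields(tracks_pre),
                                cfg.filter_policy)
    kept_post, _ = apply_filters(tracks_post, _infer_fields(tracks_post),
                                 cfg.filter_policy)
    slope = compare_displacement_slopes(
        displacement_curve(kept_pre, cfg.curve_grid_step),
        displacement_curve(kept_post, cfg.curve_grid_step))
    return ContrastReport(
        summary=summary,
        nonmotile_fraction={"pre": nonmotile(rep_pre),
                            "post": nonmotile(rep_post)},
        slope_comparison=slope.as_dict(),
        pre=rep_pre, post=rep_post,
    )
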