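"""End-to-end orchestration: single-image analysis and cohort statistics.

``analyze_image`` chains the whole single-photograph pipeline — red-free
conversion, vessel extraction, per-segment tracking/caliber/tortuosity, AVR,
and the automated disc/ROI/fractal chain — into one report. Stage failures
are caught and recorded with the stage name so a partial report (for
instance, fractal results without AVR when the annotation file is short) is
still produced. ``analyze_cohort`` runs the statistical layer on a subject
table: paired Wilcoxon tests per index, k-means (or fixed) cutoffs,
confusion tables with exact CIs, and interrater ICCs when two-rater columns
are present.

Every report embeds the effective configuration, so re-running with the
reported parameters reproduces the report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import caliber, extraction, fractal, io, stats, tortuosity, tracking
from .errors import RetmorphError

__all__ = ["AnalysisConfig", "analyze_image", "analyze_cohort", "save_report"]


@dataclass
class AnalysisConfig:
    """Every tunable default of the pipeline, JSON-serializable."""

    # extraction
    rolling_ball_radius: int = 25
    background_iterations: int = 2
    outlier_radius: int = 4
    outlier_threshold: float = 30.0
    threshold_method: str = "otsu"
    remove_outliers_first: bool = True
    min_object_px: int = 20
    # tracking
    max_snap: float = 10.0
    # caliber
    width_method: str = "edt"
    # tortuosity
    spline_smoothing: float = 0.25
    k_dc: float = 1000.0
    k_area: float = 100.0
    # disc / fractal
    variance_window: int = 15
    circularity_min: float = 0.6
    roi_factor: float = fractal.ROI_DIAMETER_FACTOR
    exclude_disc: bool = True
    n_grid_origins: int = 4
    fractal_seed: int = 17
    manual_roi_center: tuple[float, float] | None = None
    manual_roi_radius: float | None = None
    # cohort
    combined_rule: str = "avr"
    fixed_cutoffs: tuple[float, float, float] | None = None  # (avr, ti, mean_d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        clean = {}
        for k, v in d.items():
            if k not in known:
                raise RetmorphError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            clean[k] = v
        return cls(**clean)


def _catch(report: dict, stage: str):
    """Context manager recording stage errors into the report."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                report["errors"].append({"stage": stage, "error": str(exc)})
                return isinstance(exc, (RetmorphError, ValueError))
            return False
    return _Ctx()


def analyze_image(
    image: io.FundusImage | str | Path,
    annotations: list[io.SegmentAnnotation] | str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the full single-image analysis; returns the report dict.

    ``annotations`` may be a CSV path or a pre-parsed list; without
    annotations only the automated disc/fractal chain runs.
    """
    cfg = config or AnalysisConfig()
    report: dict = {"config": cfg.to_dict(), "warnings": [], "errors": [],
                    "segments": [], "avr": None, "tortuosity": None,
                    "fractal": None, "optic_disc": None}

    if not isinstance(image, io.FundusImage):
        image = io.load_image(image)
    red_free = io.to_red_free(image)
    if annotations is not None and not isinstance(annotations, list):
        annotations = io.load_annotations(
            annotations, image_shape=(image.height, image.width))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        seg = None
        with _catch(report, "vessel_extraction"):
            seg = extraction.segment_vessels(
                red_free.pixels.astype(float),
                rolling_ball_radius=cfg.rolling_ball_radius,
                background_iterations=cfg.background_iterations,
                outlier_radius=cfg.outlier_radius,
                outlier_threshold=cfg.outlier_threshold,
                threshold_method=cfg.threshold_method,
                remove_outliers_first=cfg.remove_outliers_first,
                min_object_px=cfg.min_object_px,
            )

        profiles, ti_results = [], []
        if seg is not None and annotations:
            for ann in annotations:
                entry = {"vessel_id": ann.vessel_id,
                         "vessel_class": ann.vessel_class}
                with _catch(report, f"tracking[{ann.vessel_id}]"):
                    path = tracking.track_segment(
                        ann.start, ann.end, seg.skeleton,
                        vessel_class=ann.vessel_class, max_snap=cfg.max_snap)
                    entry["n_points"] = int(len(path.points))
                    entry["length_px"] = path.length
                    with _catch(report, f"caliber[{ann.vessel_id}]"):
                        prof = caliber.width_profile(
                            path, seg.vessel_mask, method=cfg.width_method)
                        profiles.append(prof)
                        entry["mean_width_px"] = prof.mean_width
                    with _catch(report, f"tortuosity[{ann.vessel_id}]"):
                        ti = tortuosity.compute_ti(
                            path, smoothing=cfg.spline_smoothing,
                            k_dc=cfg.k_dc, k_area=cfg.k_area)
                        ti_results.append(ti)
                        entry["tortuosity"] = {
                            "n_dc": ti.n_dc, "area_px2": ti.area,
                            "chord_px": ti.chord_length,
                            "curve_px": ti.curve_length,
                            "ti_composite": ti.ti_composite,
                            "ti_integral": ti.ti_integral,
                            "ti_arc_chord": ti.ti_arc_chord,
                            "fallback": ti.fallback,
                        }
                report["segments"].append(entry)

            with _catch(report, "compute_avr"):
                avr = caliber.compute_avr(profiles)
                report["avr"] = {"arteriole_mean_px": avr.arteriole_mean,
                                 "venule_mean_px": avr.venule_mean,
                                 "avr": avr.avr}
            if ti_results:
                report["tortuosity"] = {
                    "mean_ti_composite": tortuosity.average_ti(ti_results),
                    "mean_ti_integral": float(np.mean(
                        [t.ti_integral for t in ti_results])),
                    "mean_ti_arc_chord": float(np.mean(
                        [t.ti_arc_chord for t in ti_results])),
                }

        with _catch(report, "disc_fractal"):
            disc = None
            if cfg.manual_roi_center is not None and cfg.manual_roi_radius:
                disc = fractal.OpticDisc(
                    center=tuple(cfg.manual_roi_center),
                    radius=cfg.manual_roi_radius / cfg.roi_factor,
                    circularity=1.0, detection_mode="manual")
            result, disc, roi = fractal.mean_fractal_dimension(
                red_free.pixels.astype(float), disc=disc,
                exclude_disc=cfg.exclude_disc,
                n_origins=cfg.n_grid_origins, seed=cfg.fractal_seed,
                variance_window=cfg.variance_window,
                circularity_min=cfg.circularity_min,
                rolling_ball_radius=cfg.rolling_ball_radius,
                background_iterations=cfg.background_iterations)
            report["optic_disc"] = {
                "center": [float(v) for v in disc.center],
                "radius_px": disc.radius,
                "circularity": disc.circularity,
                "detection_mode": disc.detection_mode,
                "roi_radius_px": roi.radius,
                "roi_clip_fraction": roi.clip_fraction,
            }
            report["fractal"] = {
                "mean_d": result.mean_d,
                "grid_dims": [float(v) for v in result.grid_dims],
                "box_sizes": [int(v) for v in result.box_sizes],
                "r_squared": [float(v) for v in result.r_squared],
            }

        report["warnings"] = [str(w.message) for w in caught]
    return report


def analyze_cohort(
    table: pd.DataFrame | str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Cohort statistics from a subject table.

    Required columns: ``subject_id, group, pair_id, avr, ti, mean_d``;
    optional second-rater columns ``avr_b, ti_b, mean_d_b`` enable the ICC
    section. Cutoffs come from pooled 1-D 2-means clustering unless fixed
    cutoffs are set in the config.
    """
    cfg = config or AnalysisConfig()
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    for col in ("subject_id", "group", "pair_id", *stats.INDEX_COLUMNS):
        if col not in df.columns:
            raise RetmorphError(f"cohort table missing column {col!r}")

    dis = df[df.group == "disease"].set_index("pair_id")
    con = df[df.group == "control"].set_index("pair_id")
    unmatched = sorted(set(dis.index) ^ set(con.index))
    if unmatched:
        raise RetmorphError(f"unmatched pair id(s): {unmatched}")
    pairs = sorted(dis.index)

    report: dict = {"config": cfg.to_dict(), "n_pairs": len(pairs),
                    "wilcoxon": {}, "cutoffs": None, "classification": {},
                    "icc": None}
    for idx in stats.INDEX_COLUMNS:
        stat, p = stats.paired_wilcoxon(dis.loc[pairs, idx], con.loc[pairs, idx])
        report["wilcoxon"][idx] = {
            "statistic": stat, "p_value": p,
            "disease_mean": float(dis[idx].mean()),
            "control_mean": float(con[idx].mean()),
        }

    if cfg.fixed_cutoffs is not None:
        cuts = stats.Cutoffs(*cfg.fixed_cutoffs)
        source = "fixed"
    else:
        cuts = stats.derive_cutoffs_kmeans(df.avr, df.ti, df.mean_d)
        source = "kmeans"
    report["cutoffs"] = {"avr_max": cuts.avr_max, "ti_min": cuts.ti_min,
                         "mean_d_max": cuts.mean_d_max, "source": source}

    for idx in (*stats.INDEX_COLUMNS, "combined"):
        tab = stats.classify(df, cuts, index=idx,
                             combined_rule=cfg.combined_rule)
        report["classification"][idx] = {
            **tab.as_dict(), "ci_95": stats.metric_cis(tab)}

    if all(f"{c}_b" in df.columns for c in stats.INDEX_COLUMNS):
        report["icc"] = {
            c: stats.icc_two_rater(df[c], df[f"{c}_b"])
            for c in stats.INDEX_COLUMNS
        }
    return report


def save_report(report: dict, path: str | Path) -> None:
    """Write a report as pretty-printed JSON."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
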