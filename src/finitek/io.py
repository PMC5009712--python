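"""Readers, writers, parcel filtering, and the end-to-end analysis runner.

Canonical interchange is a flat CSV with columns ``x, y, mark, is_case``
(one row per candidate location, coordinates in projected metres).  GeoJSON
(RFC 7946) FeatureCollections of Point or Polygon features with ``mark`` and
``is_case`` properties are also accepted; polygons are reduced to their
centroids.  Distances in this method are metric, so the reader refuses
input that looks like unprojected longitude/latitude unless explicitly
overridden.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import shutil

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from . import __version__
from .model import FiniteRipleyK
from .ripley import CaseSet, MarkedLocationSet

logger = logging.getLogger("finitek")

__all__ = [
    "AnalysisConfig",
    "ValidationError",
    "filter_parcels_by_area",
    "read_locations",
    "run_analysis",
    "write_locations",
]


class ValidationError(ValueError):
    """Input data failed validation; the message names the offending row."""


def _looks_geographic(coords: np.ndarray) -> bool:
    return bool((np.abs(coords[:, 0]) <= 180).all() and (np.abs(coords[:, 1]) <= 90).all())


def _validate_table(df: pd.DataFrame, mark_set=None, allow_geographic=False
                    ) -> tuple[MarkedLocationSet, CaseSet]:
    for col in ("x", "y", "mark", "is_case"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    for col in ("x", "y"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric or non-finite coordinate {col!r} at data row {row}"
                f" (value {df[col].iloc[row]!r})")
    marks_num = pd.to_numeric(df["mark"], errors="coerce")
    bad = marks_num.isna() | (marks_num != marks_num.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"non-integer mark at data row {row}"
                              f" (value {df['mark'].iloc[row]!r})")
    marks = marks_num.astype(np.int64).to_numpy()
    if mark_set is not None:
        allowed = set(int(m) for m in mark_set)
        outside = ~np.isin(marks, sorted(allowed))
        if outside.any():
            row = int(np.flatnonzero(outside)[0])
            raise ValidationError(
                f"mark {marks[row]} at data row {row} is outside the declared "
                f"mark set {sorted(allowed)}")
    coords = df[["x", "y"]].astype(float).to_numpy()
    if not allow_geographic and _looks_geographic(coords):
        raise ValidationError(
            "coordinates look like longitude/latitude degrees; this method "
            "requires projected metres (pass allow_geographic=True / "
            "--allow-geographic to override)")
    flags = df["is_case"].astype(bool).to_numpy()
    if not flags.any():
        raise ValidationError("no rows flagged is_case; at least one case is required")
    locations = MarkedLocationSet(coords=coords, marks=marks)
    return locations, CaseSet(indices=np.flatnonzero(flags))


def read_locations(path, fmt: str | None = None, mark_set=None,
                   allow_geographic: bool = False
                   ) -> tuple[MarkedLocationSet, CaseSet]:
    """Read a location universe and its flagged cases from CSV or GeoJSON.

    ``fmt`` is inferred from the file suffix when omitted.  Polygon features
    are reduced to representative centroids.
    """
    path = pathlib.Path(path)
    if fmt is None:
        fmt = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    if fmt == "csv":
        # round_trip parsing so write -> read reproduces coordinates exactly
        df = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "geojson":
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj.get("features")
        if feats is None:
            raise ValidationError("GeoJSON input must be a FeatureCollection")
        rows = []
        for i, feat in enumerate(feats):
            geom = shape(feat.get("geometry") or {})
            if geom.geom_type == "Point":
                x, y = geom.x, geom.y
            elif geom.geom_type in ("Polygon", "MultiPolygon"):
                c = geom.centroid
                x, y = c.x, c.y
            else:
                raise ValidationError(
                    f"feature {i}: unsupported geometry type {geom.geom_type!r}")
            props = feat.get("properties") or {}
            if "mark" not in props or "is_case" not in props:
                raise ValidationError(
                    f"feature {i}: missing 'mark' or 'is_case' property")
            rows.append({"x": x, "y": y, "mark": props["mark"],
                         "is_case": props["is_case"]})
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _validate_table(df, mark_set=mark_set, allow_geographic=allow_geographic)


def write_locations(locations: MarkedLocationSet, cases: CaseSet, path,
                    fmt: str | None = None) -> None:
    """Write a universe + case flags to CSV or GeoJSON (Point features)."""
    path = pathlib.Path(path)
    if fmt is None:
        fmt = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    flags = np.zeros(len(locations), dtype=bool)
    flags[cases.indices] = True
    if fmt == "csv":
        pd.DataFrame({"x": locations.coords[:, 0], "y": locations.coords[:, 1],
                      "mark": locations.marks, "is_case": flags.astype(int)}
                     ).to_csv(path, index=False)
    elif fmt == "geojson":
        feats = [{"type": "Feature",
                  "geometry": {"type": "Point",
                               "coordinates": [float(xy[0]), float(xy[1])]},
                  "properties": {"mark": int(m), "is_case": int(f)}}
                 for xy, m, f in zip(locations.coords, locations.marks, flags)]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def filter_parcels_by_area(polygons, lower_pct: float = 5.0, upper_pct: float = 95.0):
    """Drop the smallest and largest parcels by area percentile.

    Retains polygons whose area lies within the [lower_pct, upper_pct]
    percentile band (linear-interpolation percentiles, inclusive bounds, so
    a bulk of tied typical areas is never discarded).  Defaults remove the
    smallest 5% and largest 5%, the usual screen for non-residential space
    fillers such as parks and schools.
    """
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    polys = list(polygons)
    if not polys:
        raise ValueError("no polygons to filter")
    areas = np.array([p.area for p in polys], dtype=float)
    lo, hi = np.percentile(areas, [lower_pct, upper_pct])
    keep = (areas >= lo) & (areas <= hi)
    if not keep.any():
        raise ValueError("area filter removed every parcel")
    return [p for p, k in zip(polys, keep) if k]


def polygons_from_geojson(path):
    """Load shapely polygons (with their feature dicts) from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features") or []
    return [(shape(f["geometry"]), f) for f in feats
            if shape(f["geometry"]).geom_type in ("Polygon", "MultiPolygon")]


@dataclasses.dataclass
class AnalysisConfig:
    """Validated configuration for an end-to-end analysis run."""

    input_path: str
    output_dir: str
    input_format: str | None = None
    threshold_start: float = 25.0
    threshold_stop: float = 1000.0
    threshold_step: float = 25.0
    metric: str = "l2"
    rotations: list | None = None   # degrees; enables the rotated-L1 sweep
    n_sim: int = 1000
    alpha: float = 0.05
    null_mode: str = "mark-matched"
    lambda_reference: str = "universe"
    seed: int = 0
    make_plots: bool = False
    allow_geographic: bool = False

    def __post_init__(self):
        if self.metric not in ("l1", "l2"):
            raise ValueError("metric must be 'l1' or 'l2'")
        if self.null_mode not in ("mark-matched", "uniform"):
            raise ValueError("null_mode must be 'mark-matched' or 'uniform'")
        if self.lambda_reference not in ("universe", "cases"):
            raise ValueError("lambda_reference must be 'universe' or 'cases'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.threshold_start <= 0 or self.threshold_step <= 0 \
                or self.threshold_stop < self.threshold_start:
            raise ValueError("invalid threshold grid")
        if self.rotations is not None:
            self.rotations = [float(t) for t in self.rotations]
            if any(not 0 <= t <= 90 for t in self.rotations):
                raise ValueError("rotations must lie in [0, 90] degrees")

    def thresholds(self) -> np.ndarray:
        return np.arange(self.threshold_start,
                         self.threshold_stop + self.threshold_step / 2,
                         self.threshold_step)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))


def _trace_filename(tag: str) -> str:
    return "k_trace_" + tag.replace("@", "_theta").replace("°", "") + ".csv"


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline and write the result bundle to disk.

    Writes one K-trace CSV per metric/rotation (columns: r, k_obs,
    scaled_k_obs, envelope_median, critical_value, excess_above_median,
    significant), a JSON run manifest, and optional plots.  Any stage error
    aborts with a stage-named message and removes partial outputs.
    """
    out_dir = pathlib.Path(config.output_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []
    stage = "read-input"
    try:
        locations, cases = read_locations(config.input_path, fmt=config.input_format,
                                          allow_geographic=config.allow_geographic)
        logger.info("read %d locations, %d cases", len(locations), len(cases))
        stage = "model-setup"
        model = FiniteRipleyK(locations, cases, thresholds=config.thresholds(),
                              metric=config.metric,
                              lambda_reference=config.lambda_reference)
        traces = {}
        if config.rotations is None:
            stage = "envelope"
            res = model.fit(n_sim=config.n_sim, alpha=config.alpha,
                            null_mode=config.null_mode, seed=config.seed)
            traces[res.envelope.metric.tag] = res.trace
            rank = res.envelope.threshold_rank
        else:
            stage = "rotation-sweep"
            sweep = model.fit_rotations(rotations=config.rotations,
                                        n_sim=config.n_sim, alpha=config.alpha,
                                        null_mode=config.null_mode, seed=config.seed)
            for theta, trace in sweep.traces.items():
                traces[trace.envelope.metric.tag] = trace
            rank = next(iter(sweep.traces.values())).envelope.threshold_rank
        stage = "write-output"
        for tag, trace in traces.items():
            path = out_dir / _trace_filename(tag)
            trace.to_frame().to_csv(path, index=False)
            written.append(path)
        manifest = {
            "finitek_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "n_locations": len(locations),
            "q_cases": len(cases),
            "threshold_rank": rank,
            "config": dataclasses.asdict(config),
            "outputs": [p.name for p in written],
        }
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        written.append(mpath)
        if config.make_plots:
            stage = "plots"
            import matplotlib
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            for tag, trace in traces.items():
                from .model import FiniteRipleyKResults

                res = FiniteRipleyKResults(model, trace)
                fig, axes = plt.subplots(1, 2, figsize=(10, 4))
                res.plot(ax=axes[0])
                res.plot_excess(ax=axes[1])
                fig.suptitle(tag)
                ppath = out_dir / (_trace_filename(tag).replace(".csv", ".png"))
                fig.savefig(ppath, dpi=120)
                plt.close(fig)
                written.append(ppath)
        logger.info("analysis complete: %d files in %s", len(written), out_dir)
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise RuntimeError(f"analysis failed at stage '{stage}': {exc}") from exc
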