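"""Config-driven pipeline chaining the analysis stages.

Fixed stage order: load -> merge -> ripley -> filter -> segment ->
features -> group -> modules -> retrieve. Stages can be individually
disabled; every random stage takes an explicit seed, so an identical
config on identical input reproduces byte-identical outputs. Each stage
writes its CSV products into the output directory, and a run log records
every parameter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import denoise, features, graphnet, grouping, locio, modules, segment

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (see ``load_config`` for the file form)."""

    input: str = ""
    dialect: str = "generic_xy"
    unit: str = "nm"
    pixel_size: Optional[float] = None
    outdir: str = "smlmnet_out"

    # blink merging (default off: public NPC reference data arrive
    # temporally pre-merged)
    merge: bool = False
    merge_threshold: float = 0.0

    ripley: bool = True
    ripley_rmin: float = 5.0
    ripley_rmax: float = 200.0
    ripley_step: float = 1.0

    filter: bool = True
    filter_r: float = 12.0
    filter_alpha: float = 13.0
    filter_seed: int = 1

    segment: bool = True
    segment_method: str = "meanshift"  # or "dbscan"
    segment_bandwidth: float = 118.0
    segment_eps: float = 20.0
    segment_minpts: int = 5

    features: bool = True
    features_network_r: float = 12.0

    group: bool = True
    group_k: int = 2
    group_seed: int = 1

    retrieve: bool = True
    retrieve_group: int = 1
    retrieve_top_n: int = 10

    modules: bool = True
    modules_rmin: float = 6.0
    modules_rmax: float = 20.0
    modules_step: float = 1.0
    modules_summary_r: float = 10.0
    modules_min_locs: Union[int, str] = 0  # "auto" -> dispersion inflection

    log: dict = field(default_factory=dict, repr=False)


_BOOL_KEYS = {"merge", "ripley", "filter", "segment", "features", "group",
              "retrieve", "modules"}
_INT_KEYS = {"filter_seed", "segment_minpts", "group_k", "group_seed",
             "retrieve_group", "retrieve_top_n"}
_STR_KEYS = {"input", "dialect", "unit", "outdir", "segment_method"}


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` text config (# comments allowed)."""
    cfg = PipelineConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if not hasattr(cfg, key) or key == "log":
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
        if key in _BOOL_KEYS:
            setattr(cfg, key, value.lower() in ("1", "true", "yes", "on"))
        elif key in _INT_KEYS:
            setattr(cfg, key, int(value))
        elif key in _STR_KEYS:
            setattr(cfg, key, value)
        elif key == "modules_min_locs":
            cfg.modules_min_locs = value if value == "auto" else int(value)
        elif key == "pixel_size":
            cfg.pixel_size = None if value.lower() == "none" else float(value)
        else:
            setattr(cfg, key, float(value))
    return cfg


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return inner
    return wrap


def run_pipeline(cfg: PipelineConfig,
                 table: Optional[locio.LocalizationTable] = None) -> dict:
    """Run the enabled stages; returns a dict of in-memory stage outputs.

    ``table`` bypasses the load stage (for synthetic input); otherwise
    ``cfg.input`` is read. CSV products and ``run_log.json`` are written
    to ``cfg.outdir``. Partial outputs are retained on stage failure.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    log = {k: v for k, v in asdict(cfg).items() if k != "log"}

    if table is None:
        table = _stage("load")(locio.read_localizations)(
            cfg.input, dialect=cfg.dialect, unit=cfg.unit,
            pixel_size=cfg.pixel_size,
        )
    results["table"] = table
    log["n_loaded"] = table.n

    if cfg.merge and cfg.merge_threshold > 0:
        table, merge_map = _stage("merge")(graphnet.merge_blinks)(
            table, cfg.merge_threshold
        )
        results["table"] = table
        results["merge_map"] = merge_map
        locio.write_table(table, outdir / "merged.csv")
        log["n_after_merge"] = table.n

    if cfg.ripley:
        radii = np.arange(cfg.ripley_rmin, cfg.ripley_rmax + cfg.ripley_step / 2,
                          cfg.ripley_step)
        curve = _stage("ripley")(graphnet.ripley_h)(table, radii)
        curve.to_csv(outdir / "ripley_h.csv")
        scales = graphnet.find_scales(curve)
        results["ripley"] = curve
        results["scales"] = scales
        log["ripley_peak_nm"] = scales.peak_radius
        log["ripley_inflection_nm"] = scales.inflection_radius

    if cfg.filter:
        params = denoise.DenoiseParams(r=cfg.filter_r, alpha=cfg.filter_alpha,
                                       seed=cfg.filter_seed)
        table, keep, report = _stage("filter")(denoise.alpha_filter)(
            table, params
        )
        results["table"] = table
        results["filter_report"] = report
        locio.write_table(table, outdir / "filtered.csv")
        (outdir / "filter_report.json").write_text(
            json.dumps(report.to_dict(), indent=1)
        )
        log["filter"] = report.to_dict()

    blobs = None
    if cfg.segment:
        if cfg.segment_method == "meanshift":
            blobs = _stage("segment")(segment.mean_shift)(
                table, cfg.segment_bandwidth
            )
        elif cfg.segment_method == "dbscan":
            blobs, _noise = _stage("segment")(segment.dbscan)(
                table, cfg.segment_eps, cfg.segment_minpts
            )
        else:
            raise PipelineError(
                f"stage 'segment' failed: unknown method {cfg.segment_method!r}"
            )
        results["blobs"] = blobs
        labels = segment.blob_labels(blobs, table.n)
        locio.write_blob_assignments(labels, outdir / "blob_assignments.csv")
        log["n_blobs"] = len(blobs)

    matrix = None
    if cfg.features and blobs is not None:
        matrix, names = _stage("features")(features.feature_matrix)(
            blobs, table, cfg.features_network_r
        )
        results["feature_matrix"] = matrix
        results["feature_names"] = names
        locio.write_feature_matrix(matrix, names, outdir / "blob_features.csv")

    grouping_result = None
    if cfg.group and matrix is not None and matrix.shape[0] >= max(2, cfg.group_k):
        z, mu, sd, zero_var = grouping.normalize_features(matrix)
        grouping_result = _stage("group")(grouping.kmeans_group)(
            z, cfg.group_k, seed=cfg.group_seed
        )
        results["grouping"] = grouping_result
        results["normalized_features"] = z
        pd.DataFrame({
            "blob_id": [b.id for b in blobs],
            "group": grouping_result.labels,
        }).to_csv(outdir / "blob_groups.csv", index=False)
        log["group_fractions"] = grouping_result.group_fractions.tolist()
        log["silhouette_mean"] = grouping_result.silhouette_mean

        if cfg.retrieve:
            reps = _stage("retrieve")(grouping.retrieve_representatives)(
                z, grouping_result.labels, cfg.retrieve_group,
                min(cfg.retrieve_top_n,
                    int(np.sum(grouping_result.labels == cfg.retrieve_group))),
            )
            results["representatives"] = reps
            pd.DataFrame({"rank": np.arange(1, len(reps) + 1),
                          "blob_id": reps}).to_csv(
                outdir / "representatives.csv", index=False)

    if cfg.modules and blobs is not None:
        thresholds = np.arange(
            cfg.modules_rmin, cfg.modules_rmax + cfg.modules_step / 2,
            cfg.modules_step,
        )
        sweep = _stage("modules")(modules.module_count_sweep)(
            blobs, table, thresholds
        )
        results["module_sweep"] = sweep
        rows = [{"threshold_nm": r, "n_modules": k, "n_blobs": c}
                for r, hist in sweep.items() for k, c in sorted(hist.items())]
        pd.DataFrame(rows).to_csv(outdir / "module_sweep.csv", index=False)

        min_locs = cfg.modules_min_locs
        if min_locs == "auto":
            pairs = []
            for blob in blobs:
                dec = modules.newman_modules(blob, table, cfg.modules_summary_r)
                if dec.n_modules == 2:
                    pairs.append((blob.n_locs, float(dec.centroid_distances[0])))
            disp = _stage("modules")(modules.dispersion_filter)(pairs)
            min_locs = disp.inflection_n or 0
            results["dispersion"] = disp
            log["dispersion_inflection_n"] = disp.inflection_n
        try:
            summary = modules.two_module_summary(
                blobs, table, cfg.modules_summary_r, min_locs=int(min_locs)
            )
        except ValueError:
            summary = None
        if summary is not None:
            results["module_summary"] = summary
            log["module_summary"] = {
                "mean_distance_nm": summary["mean_distance"],
                "sem_nm": summary["sem"],
                "n_blobs_used": summary["n_blobs_used"],
                "min_locs": int(min_locs),
            }
            (outdir / "module_summary.json").write_text(
                json.dumps(log["module_summary"], indent=1)
            )

    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    results["log"] = log
    return results
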