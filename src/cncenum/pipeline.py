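"""Run orchestration: simulate -> quantify -> gate -> enumerate, reproducibly.

A run is driven by a single :class:`RunConfig` (YAML-serializable).  One
mandatory seed governs every stochastic stage; per-stage generators are
spawned from it with numpy's SeedSequence splitting, so each stage is
independently reproducible.  All tabular/JSON outputs of a run are
checksummed into a manifest; two runs with the same config produce
byte-identical files.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chipsim import (
    FIXED_ROUND,
    LIVE_ROUND,
    ChipLayout,
    PopulationModel,
    SceneImage,
    build_layout,
    render_images,
    sample_population,
    write_fixture,
)
from .errors import (
    ConfigurationError,
    InputSchemaError,
    PipelineStageError,
)
from .gatecore import (
    GateModel,
    classify_cells,
    dapi_threshold_from_noise,
    export_scatter,
    fit_cd45_threshold,
    fit_neun_cutoff,
    summarize_gating,
)
from .enumstats import enumerate_sample, viability_ratio
from .wellquant import RECORD_COLUMNS, match_rounds, quantify_round

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": None,  # mandatory
    "sample_id": "sim-sample",
    "volume_ml": 0.5,
    "group": "mcao",
    "layout": {},       # ChipLayout field overrides (see chipsim.build_layout)
    "population": {},   # PopulationModel field overrides
    "detection": {
        "min_area": 20,
        "detect_k": 3.0,
        "measure_frac": 0.7,
        "match_tolerance": 3.0,
    },
    "gate": {
        "k": 3.0,
        "cd45_method": "auto",
        "cd45_value": None,
        "dapi_threshold": "auto",
        "min_reference": 50,
        "log_scale": False,
    },
    "stats": {
        "variance_mode": "pooled",
        "nbdg_threshold": "auto",
    },
    "output": {
        "write_images": False,
    },
}


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    seed: int
    sample_id: str = "sim-sample"
    volume_ml: float = 0.5
    group: str = "mcao"
    layout: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    detection: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG["detection"]))
    gate: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG["gate"]))
    stats: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG["stats"]))
    output: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG["output"]))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def layout_obj(self) -> ChipLayout:
        return build_layout(self.layout)

    def population_obj(self) -> PopulationModel:
        return PopulationModel(**self.population)


def _merge_validate(defaults: Mapping[str, Any], given: Mapping[str, Any],
                    prefix: str, errors: list[str]) -> dict:
    merged = copy.deepcopy(dict(defaults))
    for key, value in given.items():
        if key not in defaults:
            errors.append(f"unknown config key: {prefix}{key}")
            continue
        if isinstance(defaults[key], Mapping) and not isinstance(value, Mapping):
            errors.append(f"{prefix}{key} must be a mapping")
        elif isinstance(defaults[key], Mapping):
            merged[key] = _merge_validate(defaults[key], value, f"{prefix}{key}.", errors)
        else:
            merged[key] = value
    return merged


def resolve_config(raw: Mapping[str, Any]) -> RunConfig:
    """Validate a raw mapping against the default schema and resolve defaults.

    Every offending key/value is collected and reported together.  Layout and
    population sections are passed through (their own constructors validate
    them), but are test-constructed here so config errors surface at load
    time rather than mid-run.
    """
    errors: list[str] = []
    top = dict(DEFAULT_CONFIG)
    merged: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in top:
            errors.append(f"unknown config key: {key}")
    for key, default in top.items():
        value = raw.get(key, default)
        if key in ("layout", "population"):
            merged[key] = dict(value or {})
        elif isinstance(default, Mapping):
            merged[key] = _merge_validate(default, value or {}, f"{key}.", errors)
        else:
            merged[key] = value

    if merged["seed"] is None:
        errors.append("seed is mandatory")
    elif not isinstance(merged["seed"], (int, np.integer)) or isinstance(merged["seed"], bool):
        errors.append("seed must be an integer")
    if not isinstance(merged["volume_ml"], (int, float)) or merged["volume_ml"] <= 0:
        errors.append("volume_ml must be a positive number")
    det = merged["detection"]
    if det["min_area"] <= 0:
        errors.append("detection.min_area must be positive")
    if det["detect_k"] <= 0:
        errors.append("detection.detect_k must be positive")
    if not 0 < det["measure_frac"] < 1:
        errors.append("detection.measure_frac must lie in (0, 1)")
    gate = merged["gate"]
    if not isinstance(gate["k"], (int, float)) or gate["k"] < 0:
        errors.append("gate.k must be a nonnegative number")
    if gate["cd45_method"] not in ("auto", "otsu", "fixed"):
        errors.append("gate.cd45_method must be 'auto', 'otsu' or 'fixed'")
    if gate["dapi_threshold"] != "auto" and not isinstance(gate["dapi_threshold"], (int, float)):
        errors.append("gate.dapi_threshold must be 'auto' or a number")
    if gate["min_reference"] < 1:
        errors.append("gate.min_reference must be >= 1")
    if merged["stats"]["variance_mode"] not in ("pooled", "welch"):
        errors.append("stats.variance_mode must be 'pooled' or 'welch'")

    if not errors:
        try:
            build_layout(merged["layout"])
        except ConfigurationError as exc:
            errors.append(f"layout: {exc}")
        try:
            PopulationModel(**merged["population"])
        except (TypeError, ConfigurationError) as exc:
            errors.append(f"population: {exc}")

    if errors:
        raise ConfigurationError("invalid configuration: " + "; ".join(errors))
    return RunConfig(**merged)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (all defaults resolved)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    config = resolve_config(raw)
    logger.info("loaded config from %s: %s", path, json.dumps(config.to_dict(), sort_keys=True))
    return config


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# core analysis (in-memory, used by run_pipeline, tests and scripts)
# ---------------------------------------------------------------------------

def analyze_chip(
    layout: ChipLayout,
    model: PopulationModel,
    seed: int | np.random.SeedSequence,
    sample_id: str = "sample",
    detection: Mapping[str, Any] | None = None,
    gate_cfg: Mapping[str, Any] | None = None,
    exact_n_cnc: int | None = None,
    keep_images: bool = False,
) -> dict[str, Any]:
    """Simulate one chip and run the full per-cell analysis in memory.

    Returns a dict with the ground truth, per-round records, the matched
    two-round table, the fitted gate, labeled cells and the gating summary
    (plus the rendered images when ``keep_images``).
    """
    det = {**DEFAULT_CONFIG["detection"], **(detection or {})}
    gcfg = {**DEFAULT_CONFIG["gate"], **(gate_cfg or {})}

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pop, s_live, s_fixed = ss.spawn(3)

    truth = sample_population(layout, model, s_pop, exact_n_cnc=exact_n_cnc)
    logger.info("simulated %d cells (%d cnc, %d leukocyte, %d debris)",
                len(truth),
                int((truth["true_class"] == "cnc").sum()),
                int((truth["true_class"] == "leukocyte").sum()),
                int((truth["true_class"] == "debris").sum()))

    img_live = render_images(truth, layout, model, LIVE_ROUND, s_live)
    img_fixed = render_images(truth, layout, model, FIXED_ROUND, s_fixed)

    rec_live, info_live = quantify_round(
        img_live, layout, sample_id,
        min_area=det["min_area"], detect_k=det["detect_k"], measure_frac=det["measure_frac"],
    )
    rec_fixed, info_fixed = quantify_round(
        img_fixed, layout, sample_id,
        min_area=det["min_area"], detect_k=det["detect_k"], measure_frac=det["measure_frac"],
    )
    logger.info("detected %d live-round and %d fixed-round objects",
                len(rec_live), len(rec_fixed))

    merged = match_rounds(rec_live, rec_fixed, tolerance=det["match_tolerance"])

    dapi_thr = gcfg["dapi_threshold"]
    if dapi_thr == "auto":
        dapi_thr = dapi_threshold_from_noise(info_fixed.noise_sd)
    cd45_thr = fit_cd45_threshold(merged, method=gcfg["cd45_method"],
                                  fixed_value=gcfg["cd45_value"])
    gate = fit_neun_cutoff(
        merged, cd45_thr, dapi_thr,
        k=gcfg["k"], min_reference=gcfg["min_reference"], log_scale=gcfg["log_scale"],
    )
    labeled = classify_cells(merged, gate)
    summary = summarize_gating(labeled)
    logger.info("gated: %d counted, %d cnc, %d leukocyte, %d other, %d excluded",
                summary.n_total_counted, summary.n_cnc, summary.n_leukocyte,
                summary.n_other, summary.n_excluded)

    result: dict[str, Any] = {
        "truth": truth,
        "records_live": rec_live,
        "records_fixed": rec_fixed,
        "merged": merged,
        "gate": gate,
        "labeled": labeled,
        "summary": summary,
        "seg_info_live": info_live,
        "seg_info_fixed": info_fixed,
    }
    if keep_images:
        result["images"] = {LIVE_ROUND: img_live, FIXED_ROUND: img_fixed}
    return result


# ---------------------------------------------------------------------------
# manifest + full run
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Audit record of one run: config snapshot, versions, output checksums."""

    config: dict
    package_version: str
    created: str
    files: dict[str, str]
    stage_counts: dict[str, int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute the full run and write all outputs plus the manifest.

    Stages: simulate -> render (two rounds) -> quantify -> match -> gate ->
    enumerate -> viability.  Any stage failure aborts with the stage name and
    the propagated cause.  Idempotent: re-running with the same config yields
    byte-identical CSV/JSON outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "configure"
    try:
        layout = config.layout_obj()
        model = config.population_obj()
        stage = "analyze"
        result = analyze_chip(
            layout, model, config.seed,
            sample_id=config.sample_id,
            detection=config.detection,
            gate_cfg=config.gate,
            keep_images=bool(config.output.get("write_images")),
        )
        stage = "enumerate"
        summary = result["summary"]
        cncs_per_ml = enumerate_sample(summary.n_cnc, config.volume_ml)
        stage = "viability"
        viability = viability_ratio(result["labeled"],
                                    nbdg_threshold=config.stats["nbdg_threshold"])
        stage = "write-outputs"
        files: dict[str, str] = {}

        def _write_csv(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            df.to_csv(path, index=False)
            files[name] = _sha256(path)

        _write_csv(result["truth"], "truth.csv")
        _write_csv(result["records_live"][RECORD_COLUMNS], "cells_live.csv")
        _write_csv(result["records_fixed"][RECORD_COLUMNS], "cells_fixed.csv")
        _write_csv(result["labeled"], "cells_labeled.csv")

        scatter, scatter_meta = export_scatter(result["labeled"], result["gate"], scale="log10")
        _write_csv(scatter, "scatter_log10.csv")

        gate_path = outdir / "gate.json"
        result["gate"].to_json(gate_path)
        files["gate.json"] = _sha256(gate_path)

        summary_payload = {
            "sample_id": config.sample_id,
            "subject_group": config.group,
            "volume_ml": config.volume_ml,
            "gating": summary.to_dict(),
            "cncs_per_ml": cncs_per_ml,
            "viability": viability.to_dict(),
            "scatter_meta": scatter_meta,
        }
        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary_payload, fh, indent=2, sort_keys=True)
        files["summary.json"] = _sha256(summary_path)

        sample_row = pd.DataFrame([{
            "sample_id": config.sample_id,
            "subject_group": config.group,
            "volume_ml": config.volume_ml,
            "n_cnc": summary.n_cnc,
            "cncs_per_ml": cncs_per_ml,
        }])
        _write_csv(sample_row, "sample_summary.csv")

        if config.output.get("write_images"):
            written = write_fixture(result["truth"],
                                    list(result["images"].values()), outdir, model)
            for key, fpath in written.items():
                p = Path(fpath)
                files[p.name] = _sha256(p)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    manifest = RunManifest(
        config=config.to_dict(),
        package_version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        files=files,
        stage_counts={
            "cells_simulated": len(result["truth"]),
            "objects_live_round": len(result["records_live"]),
            "objects_fixed_round": len(result["records_fixed"]),
            "cells_counted": summary.n_total_counted,
            "cnc_called": summary.n_cnc,
            "leukocytes_called": summary.n_leukocyte,
        },
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# external per-cell tables
# ---------------------------------------------------------------------------

_NUMERIC_RECORD_COLUMNS = ["x_px", "y_px", "area_px2", "dapi", "neun", "cd45", "nbdg"]


def ingest_external_cells(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell CSV in the canonical schema.

    This is the entry point for real chip exports: any table with the exact
    canonical column set can be gated and enumerated without the simulator.
    Missing/extra columns raise :class:`InputSchemaError`; malformed rows
    (non-numeric coordinates or area, negative area) are rejected with their
    CSV line numbers logged.  Intensities are floored at 0.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in RECORD_COLUMNS]
    if missing or extra:
        raise InputSchemaError(
            f"per-cell table schema mismatch: missing columns {missing}, "
            f"extra columns {extra}"
        )
    df = df[RECORD_COLUMNS].copy()
    for col in _NUMERIC_RECORD_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = (
        df["x_px"].isna()
        | df["y_px"].isna()
        | df["area_px2"].isna()
        | (df["area_px2"] < 0)
    )
    if bad.any():
        # +2: 1-based line numbers plus the header row
        lines = [int(i) + 2 for i in df.index[bad]]
        logger.warning("rejected %d malformed row(s) at line(s) %s", len(lines), lines)
        df = df[~bad].copy()

    for col in ("dapi", "neun", "cd45", "nbdg"):
        df[col] = df[col].clip(lower=0)

    dup = df.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        raise InputSchemaError(
            f"duplicate (sample_id, cell_id) pairs in {path}: "
            f"{df.loc[dup, 'cell_id'].head().tolist()}"
        )
    return df.reset_index(drop=True)
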