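"""End-to-end orchestration: simulate -> segment -> measure -> junction metrics.

A :class:`RunConfig` selects one of five modes:

``hemodynamics``
    condition summary table for the microchannel (no images involved);
``simulate``
    render synthetic monolayer fields with ground truth;
``measure``
    segment stacks and write the per-cell morphometry CSV;
``junctions``
    junction band / stain width / protrusion metrics per field;
``full``
    simulate then measure then junctions, plus a condition summary.

Every run writes a provenance sidecar (config hash, seed, package
version, artifact list) next to its outputs so any artifact can be
regenerated from the sidecar alone.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hemodynamics as hemo
from . import imgio, junctions, segment, synthgen

__all__ = ["RunConfig", "run", "summarize"]

log = logging.getLogger("endoflow")

_MODES = ("hemodynamics", "simulate", "measure", "junctions", "full")

_CONFIG_KEYS = {
    "mode", "seed", "out_dir", "input", "channel_order",
    "channel", "fluid", "conditions", "synth", "segmentation", "junctions",
}


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable, unknown keys rejected)."""

    mode: str
    out_dir: str = "endoflow_out"
    seed: int = 0
    input: str | None = None
    channel_order: tuple[str, ...] = segment.CHANNELS
    channel: dict = field(default_factory=dict)  # width/height/length (m)
    fluid: dict = field(default_factory=dict)  # density/viscosity
    conditions: list = field(default_factory=list)
    synth: dict = field(default_factory=dict)  # SyntheticSpec overrides
    segmentation: dict = field(default_factory=dict)
    junctions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode in ("measure", "junctions") and not self.input:
            raise ValueError(f"mode {self.mode!r} requires an input path")
        if self.input is not None and not pathlib.Path(self.input).exists():
            raise ValueError(f"input path {self.input!r} does not exist")
        bad_synth = set(self.synth) - {f.name for f in dataclasses.fields(synthgen.SyntheticSpec)}
        if bad_synth:
            raise ValueError(f"unknown synth keys {sorted(bad_synth)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = imgio.load_yaml_strict(path, _CONFIG_KEYS)
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _geometry(cfg: RunConfig) -> hemo.ChannelGeometry:
    ch = {"width": 1.0e-3, "height": 100e-6, "length": 17e-3, **cfg.channel}
    return hemo.ChannelGeometry.from_full_dimensions(ch["width"], ch["height"], ch["length"])


def _fluid(cfg: RunConfig) -> hemo.Fluid:
    fl = {"density": 1000.0, "viscosity": 0.00072, **cfg.fluid}
    return hemo.Fluid(density=fl["density"], dynamic_viscosity=fl["viscosity"])


def _conditions(cfg: RunConfig) -> list[hemo.FlowCondition]:
    if not cfg.conditions:
        # the four perfusion conditions of the chip experiment
        rows = [
            {"label": "SS high only", "flow_rate_ul_min": 13.0, "outlet_head_cm": 0.0},
            {"label": "SS low only", "flow_rate_ul_min": 1.3, "outlet_head_cm": 0.0},
            {"label": "SS high+HP", "flow_rate_ul_min": 13.0, "outlet_head_cm": 40.0},
            {"label": "SS low+HP", "flow_rate_ul_min": 1.3, "outlet_head_cm": 40.0},
        ]
    else:
        rows = cfg.conditions
    return [hemo.FlowCondition.from_lab_units(**row) for row in rows]


def _stage_hemodynamics(cfg: RunConfig, out: pathlib.Path) -> list[str]:
    table = hemo.summarize_conditions(_geometry(cfg), _fluid(cfg), _conditions(cfg))
    path = out / "hemodynamics_summary.csv"
    table.to_csv(path, index=False)
    return [str(path)]


def _stage_simulate(cfg: RunConfig, out: pathlib.Path) -> tuple[list[str], pd.DataFrame]:
    spec = synthgen.SyntheticSpec(**{"rng_seed": cfg.seed, **cfg.synth})
    manifest = synthgen.sweep([spec], out / "simulated")
    return [str(out / "simulated" / "manifest.json")], manifest


def _measure_one(cfg: RunConfig, stack: segment.ImageStack, stem: str, out: pathlib.Path):
    maps = segment.segment_stack(stack, **cfg.segmentation)
    cells = segment.measure_cells(stack, maps)
    cells.insert(0, "field", stem)
    paths = [
        imgio.write_labels(out / f"{stem}_primary.tif", maps.primary),
        imgio.write_labels(out / f"{stem}_secondary.tif", maps.secondary),
        imgio.write_labels(out / f"{stem}_membrane.tif", maps.membrane),
    ]
    return maps, cells, [str(p) for p in paths]


def _stack_inputs(cfg: RunConfig) -> list[pathlib.Path]:
    p = pathlib.Path(cfg.input)
    if p.is_dir():
        label_suffixes = ("_cells", "_nuclei", "_primary", "_secondary", "_membrane")
        return sorted(
            f for f in p.glob("*.tif") if not f.stem.endswith(label_suffixes)
        )
    return [p]


def _stage_junctions(
    cfg: RunConfig, stack: segment.ImageStack, maps: segment.LabelMaps, stem: str, out: pathlib.Path
) -> list[str]:
    jcfg = {"search_d": 5, "min_len": 3.0, **cfg.junctions}
    band = junctions.junction_band(stack.ve_cadherin, maps.secondary, jcfg["search_d"])
    width_px, per_edge = junctions.stain_width(band, stack.pixel_size)
    baseline = jcfg.get("baseline_w") or (width_px if np.isfinite(width_px) else 3.0)
    fingers = junctions.detect_protrusions(
        band.foreground, band.boundary, baseline, jcfg["min_len"], stack.pixel_size,
        channel="ve_cadherin", edge_map=band.edge_map,
    )
    actin_fg = stack.actin > segment.li_threshold(stack.actin)
    filopodia = junctions.detect_protrusions(
        actin_fg, band.boundary, baseline, jcfg["min_len"], stack.pixel_size,
        channel="actin", edge_map=band.edge_map,
    )
    per_edge.insert(0, "field", stem)
    summary = pd.DataFrame(
        [
            {
                "field": stem,
                "band_coverage": band.coverage,
                "stain_width_px": width_px,
                "stain_width_um": width_px * stack.pixel_size,
                "n_fingers": len(fingers),
                "mean_finger_length_px": fingers["length_px"].mean() if len(fingers) else np.nan,
                "n_filopodia": len(filopodia),
                "mean_filopodial_length_px": filopodia["length_px"].mean()
                if len(filopodia)
                else np.nan,
            }
        ]
    )
    paths = []
    for name, df in (
        ("edges", per_edge),
        ("fingers", pd.concat([fingers, filopodia], ignore_index=True)),
        ("junction_summary", summary),
    ):
        p = out / f"{stem}_{name}.csv"
        df.to_csv(p, index=False)
        paths.append(str(p))
    return paths


def run(config: RunConfig) -> dict:
    """Execute the configured stage chain; returns artifact paths."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    t0 = time.perf_counter()
    try:
        if config.mode == "hemodynamics":
            artifacts += _stage_hemodynamics(config, out)
        elif config.mode == "simulate":
            paths, _ = _stage_simulate(config, out)
            artifacts += paths
        elif config.mode in ("measure", "junctions", "full"):
            if config.mode == "full":
                spec = synthgen.SyntheticSpec(**{"rng_seed": config.seed, **config.synth})
                stack, _ = synthgen.generate_monolayer(spec)
                stacks = [("simulated", stack)]
            else:
                stacks = [
                    (p.stem, imgio.read_stack(p, channel_order=config.channel_order))
                    for p in _stack_inputs(config)
                ]
            all_cells = []
            for stem, stack in stacks:
                maps, cells, paths = _measure_one(config, stack, stem, out)
                all_cells.append(cells)
                artifacts += paths
                if config.mode in ("junctions", "full"):
                    artifacts += _stage_junctions(config, stack, maps, stem, out)
            cells_df = pd.concat(all_cells) if all_cells else pd.DataFrame()
            cells_path = out / "cells.csv"
            cells_df.to_csv(cells_path)
            artifacts.append(str(cells_path))
            if config.mode == "full" and len(cells_df):
                summary = summarize(cells_df.reset_index(), "field")
                spath = out / "condition_summary.csv"
                summary.to_csv(spath, index=False)
                artifacts.append(str(spath))
    except Exception:
        log.exception("stage failed in mode %s", config.mode)
        raise
    imgio.write_provenance(out / "provenance.json", config.as_dict(), config.seed, artifacts)
    log.info("mode=%s finished in %.2fs (%d artifacts)", config.mode, time.perf_counter() - t0, len(artifacts))
    return {"artifacts": artifacts, "out_dir": str(out)}


_SUMMARY_METRICS = [
    "area_um2", "eccentricity", "circularity", "junctional_ratio",
]


def summarize(per_cell: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Condition-level mean +/- sd of the per-cell metrics.

    Groups with fewer than 50 cells are flagged (underpowered relative to
    the usual >= 50 cells-per-repeat analysis convention); empty groups
    are omitted with a warning, and single-cell groups carry NaN sd.
    """
    if len(per_cell) == 0:
        raise ValueError("per-cell table is empty")
    rows = []
    for key, grp in per_cell.groupby(grouping):
        if len(grp) == 0:
            log.warning("group %r is empty; omitted", key)
            continue
        row: dict = {grouping: key, "n_cells": len(grp), "underpowered": len(grp) < 50}
        for m in _SUMMARY_METRICS:
            if m in grp:
                row[f"{m}_mean"] = grp[m].mean()
                row[f"{m}_sd"] = grp[m].std(ddof=1) if len(grp) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
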