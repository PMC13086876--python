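"""End-to-end orchestration: fields in, per-cell tables and stats out.

A run is described by a :class:`RunConfig` (usually loaded from YAML)
with exactly one source of fields: ``inputs`` (paths to multi-page TIFF
files per condition) or ``simulate`` (synthetic conditions rendered by
:mod:`nucoloc.simgen`).  Each field is segmented on the DAPI channel,
every nucleus is scored for query/marker colocalization, optionally
phase-classified from a PCNA channel, and the per-condition coefficient
distributions are compared (Welch t for two conditions, ANOVA plus
Dunnett against the designated control for more).  All artifacts —
label maps, per-cell CSV, phase CSV, calibration JSON, comparison
tables, and a run manifest with QC counts — land in ``output_dir``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .coloc import (
    DEFAULT_MIN_PIXELS,
    DEFAULT_TAU,
    calibrate_controls,
    records_table,
    score_cells,
    _marker_submask,
)
from .phase import PhaseParams, classify_pcna, phase_calls_table, stratified_summary
from .segment import RegionFilterParams, segment_nuclei
from .simgen import FieldImage, SimulationConfig, generate_control_field, generate_field
from .stats import anova_dunnett, anova_tukey, two_group_test

logger = logging.getLogger("nucoloc")

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (detected before any computation)."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``inputs`` (condition -> list of TIFF paths) or
    ``simulate`` (condition -> simulation overrides) must be set.
    """

    output_dir: str = "nucoloc_out"
    seed: int = 0
    inputs: dict[str, list[str]] | None = None
    channel_order: list[str] | None = None
    simulate: dict | None = None          # {"conditions": {...}, "base": {...}, "n_fields": k, "controls": bool}
    segmentation: RegionFilterParams = dc_field(default_factory=RegionFilterParams)
    query_role: str = "query"
    marker_role: str = "marker"
    min_pixels: int = DEFAULT_MIN_PIXELS
    tau: float = DEFAULT_TAU
    phase_params: PhaseParams = dc_field(default_factory=PhaseParams)
    control_group: str | None = None
    multigroup_test: str = "dunnett"      # or "tukey"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'inputs' or 'simulate' must be given")
        if self.inputs is not None and not self.channel_order:
            raise ConfigError("'inputs' mode requires 'channel_order'")
        if self.channel_order is not None:
            needed = {"dapi", self.marker_role, self.query_role}
            missing = needed - set(self.channel_order)
            if missing:
                raise ConfigError(f"channel_order lacks required roles: {sorted(missing)}")
        if self.multigroup_test not in ("dunnett", "tukey"):
            raise ConfigError("multigroup_test must be 'dunnett' or 'tukey'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = RegionFilterParams(**d["segmentation"])
        if "phase_params" in d and isinstance(d["phase_params"], dict):
            d["phase_params"] = PhaseParams(**d["phase_params"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _field_seed(base_seed: int, cond_idx: int, field_idx: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), cond_idx, field_idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _simulated_fields(cfg: RunConfig, cond_idx: int, name: str, spec: dict):
    base = dict((cfg.simulate or {}).get("base", {}))
    spec = dict(spec)
    n_fields = int(spec.pop("n_fields", (cfg.simulate or {}).get("n_fields", 1)))
    base.update(spec)
    for j in range(n_fields):
        sim = SimulationConfig(**{**base, "seed": _field_seed(cfg.seed, cond_idx, j)})
        yield generate_field(sim)


def _input_fields(cfg: RunConfig, paths: list[str]):
    for p in paths:
        yield nio.read_field(p, channel_order=cfg.channel_order), None


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns a manifest dict (also written to disk).

    Deterministic for a fixed config seed: rerunning writes identical
    per-cell tables.
    """
    cfg = config
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels_dir = out / "labels"
    labels_dir.mkdir(exist_ok=True)

    if cfg.simulate is not None:
        conditions = cfg.simulate.get("conditions")
        if not conditions:
            raise ConfigError("simulate block needs a 'conditions' mapping")
        sources = {
            name: _simulated_fields(cfg, i, name, spec)
            for i, (name, spec) in enumerate(conditions.items())
        }
    else:
        sources = {
            name: _input_fields(cfg, paths) for name, paths in (cfg.inputs or {}).items()
        }

    all_records: list = []
    all_calls: list = []
    rows_extra: list[dict] = []
    next_id = 1
    qc = {"analyzed": 0, "undefined": 0, "discarded_phase": 0}

    for name, fields in sources.items():
        for j, item in enumerate(fields):
            field_img, truth = item if isinstance(item, tuple) else (item, None)
            labels = segment_nuclei(field_img.channels["dapi"], cfg.segmentation)
            nio.write_label_map(labels_dir / f"{name}_{j:03d}_labels.tif", labels)
            if labels.n_regions == 0:
                logger.warning("field %s/%d: no nuclei segmented", name, j)
            records = score_cells(
                field_img,
                labels,
                query_role=cfg.query_role,
                marker_role=cfg.marker_role,
                condition=name,
                min_pixels=cfg.min_pixels,
                tau=cfg.tau,
            )
            has_pcna = "pcna" in field_img.channels
            marker = field_img.channels[cfg.marker_role]
            for rec, (lab, mask) in zip(records, labels.masks()):
                rec.cell_id = next_id
                call = None
                if has_pcna:
                    sub = _marker_submask(marker, mask)
                    call = classify_pcna(
                        field_img.channels["pcna"], mask, sub,
                        params=cfg.phase_params, cell_id=next_id,
                    )
                    all_calls.append(call)
                if rec.pearson_r is None:
                    cat = "undefined"
                elif call is not None and call.label == "discarded":
                    cat = "discarded_phase"
                else:
                    cat = "analyzed"
                qc[cat] += 1
                rows_extra.append(
                    {"cell_id": next_id, "field": f"{name}_{j:03d}", "qc_category": cat}
                )
                next_id += 1
            all_records.extend(records)

    cells = records_table(all_records).merge(pd.DataFrame(rows_extra), on="cell_id")
    cells.to_csv(out / "cells.csv", index=False)

    if all_calls:
        phase_calls_table(all_calls).to_csv(out / "phases.csv", index=False)
        strat = stratified_summary(all_records, all_calls)
        strat.to_csv(out / "phase_summary.csv", index=False)

    calibration = _maybe_calibrate(cfg, out)

    comparison = _compare(cfg, all_records)
    if comparison is not None:
        comparison.to_frame().to_csv(out / "group_summary.csv", index=False)
        if comparison.comparisons is not None:
            comparison.comparisons.to_csv(out / "comparisons.csv", index=False)
        nio.write_json(
            out / "comparison.json",
            {
                "method": comparison.method,
                "groups": comparison.groups,
                "n": comparison.n,
                "mean": comparison.mean,
                "sd": comparison.sd,
                "statistic": comparison.statistic,
                "p_raw": comparison.p_raw,
                "n_excluded": comparison.n_excluded,
                "comparisons": None
                if comparison.comparisons is None
                else comparison.comparisons.to_dict(orient="records"),
            },
        )

    import nucoloc

    manifest = {
        "package_version": nucoloc.__version__,
        "seed": cfg.seed,
        "n_cells": len(all_records),
        "qc_counts": qc,
        "conditions": {
            name: int((cells["condition"] == name).sum())
            for name in cells["condition"].unique()
        },
        "calibration": None
        if calibration is None
        else dataclasses.asdict(calibration),
        "config": _config_echo(cfg),
    }
    nio.write_json(out / "manifest.json", manifest)
    return manifest


def _maybe_calibrate(cfg: RunConfig, out: Path):
    """Simulated positive/negative control calibration, when requested."""
    if cfg.simulate is None or not cfg.simulate.get("controls"):
        return None
    base = dict(cfg.simulate.get("base", {}))
    sim = SimulationConfig(**{**base, "seed": _field_seed(cfg.seed, 9999, 0)})
    pos_img, pos_truth = generate_control_field(sim, "positive")
    neg_img, neg_truth = generate_control_field(
        dataclasses.replace(sim, seed=_field_seed(cfg.seed, 9999, 1)), "negative"
    )
    pos_labels = segment_nuclei(pos_img.channels["dapi"], cfg.segmentation)
    neg_labels = segment_nuclei(neg_img.channels["dapi"], cfg.segmentation)
    pos = score_cells(pos_img, pos_labels, condition="POS", min_pixels=cfg.min_pixels)
    neg = score_cells(
        neg_img, neg_labels, query_role="dapi", marker_role="marker",
        condition="NEG", min_pixels=cfg.min_pixels,
    )
    cal = calibrate_controls(pos, neg)
    nio.write_json(out / "calibration.json", dataclasses.asdict(cal))
    return cal


def _compare(cfg: RunConfig, records):
    by_cond: dict[str, list[float]] = {}
    for r in records:
        by_cond.setdefault(r.condition, []).append(r.pearson_r)
    names = list(by_cond)
    if len(names) < 2:
        return None
    if len(names) == 2:
        return two_group_test(by_cond[names[0]], by_cond[names[1]], names=tuple(names))
    control = cfg.control_group or names[0]
    if control not in by_cond:
        raise ConfigError(f"control group {control!r} not among conditions {names}")
    idx = names.index(control)
    groups = [by_cond[n] for n in names]
    if cfg.multigroup_test == "tukey":
        return anova_tukey(groups, names=names)
    return anova_dunnett(
        groups, control_index=idx, names=names,
        rng=np.random.default_rng(_field_seed(cfg.seed, 8888, 0)),
    )


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
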