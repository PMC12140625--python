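"""Config-driven pipeline orchestration.

A run config is one flat YAML document: a global seed, an output directory,
and an ordered list of stages whose parameter blocks mirror the library
functions' arguments. Running it produces a deterministic directory of
CSV/JSON artifacts plus a ``manifest.json`` recording every input,
parameter, seed, and output so each number is traceable to the config.
"""

from __future__ import annotations

import logging
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import align_curves, pool_tables, AlignmentParams
from .history import parse_condition, condition_name, label_joint
from .interaction import interaction_scan, predict_joint
from .simulate import GeneratorParams, generate
from .tachometric import (TachometricCurve, floor_ceiling, rt_summary,
                          tachometric_curve)
from .trials import TrialTable, read_trials, write_trials, write_json

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def generator_params_from_dict(d: dict, seed: int | None = None) -> GeneratorParams:
    """Build GeneratorParams from a flat mapping, rejecting unknown keys."""
    known = {f.name for f in dc_fields(GeneratorParams)}
    unknown = set(d) - known
    if unknown:
        raise StageError(f"unknown generator parameter(s): {sorted(unknown)}")
    d = dict(d)
    if "gap_range_ms" in d:
        d["gap_range_ms"] = tuple(d["gap_range_ms"])
    if seed is not None and "seed" not in d:
        d["seed"] = seed
    return GeneratorParams(**d)


def _load_curve(path) -> TachometricCurve:
    import json
    d = json.loads(Path(path).read_text())
    return TachometricCurve(np.asarray(d["bin_center_ms"], float),
                            np.asarray(d["frac_correct"], float),
                            np.asarray(d["n_trials"], int),
                            d.get("bin_width_ms", 50.0),
                            d.get("step_ms", 1.0))


def _mask_from_column(table: TrialTable, mask_col: str | None):
    if mask_col is None:
        return None
    if mask_col not in table.data.columns:
        raise StageError(f"mask column {mask_col!r} not in table")
    return table.data[mask_col].astype(bool).to_numpy()


def append_condition_columns(table: TrialTable, conditions) -> TrialTable:
    """Append one boolean column per requested history condition label."""
    df = table.data.copy()
    for text in conditions:
        conds = parse_condition(text)
        name = condition_name(conds)
        df[name] = label_joint(table, conds)
    return TrialTable(df, dict(table.meta))


def run(config: dict, outdir=None) -> Path:
    """Execute a staged pipeline; returns the artifact directory."""
    outdir = Path(outdir or config.get("outdir", "selhist_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "seed": seed, "config": config,
                "stages": []}
    tables: dict = {}

    def load_table(name) -> TrialTable:
        if name in tables:
            return tables[name]
        path = Path(name)
        if not path.is_absolute():
            path = outdir / path
        if not path.exists():
            raise StageError(f"input not found: {name}")
        t = read_trials(path)
        tables[name] = t
        return t

    for i, stage in enumerate(config.get("stages", [])):
        kind = stage.get("stage")
        record = {"stage": kind, "spec": stage}
        try:
            if kind == "simulate":
                params = generator_params_from_dict(
                    stage.get("params", {}), seed=seed + i)
                table = generate(params)
                out = stage.get("out", "trials.csv")
                write_trials(table, outdir / out)
                tables[out] = table
                record["out"] = out
                record["params"] = params.to_dict()
                record["n_trials"] = len(table)
            elif kind == "validate":
                table = read_trials(stage["in"] if Path(stage["in"]).is_absolute()
                                    else outdir / stage["in"],
                                    drop_invalid=stage.get("drop_invalid",
                                                           False))
                out = stage.get("out")
                if out:
                    write_trials(table, outdir / out)
                    tables[out] = table
                record["n_trials"] = len(table)
                record["n_dropped"] = table.meta.get("n_dropped", 0)
            elif kind == "history":
                table = load_table(stage["in"])
                labeled = append_condition_columns(table,
                                                   stage["conditions"])
                out = stage.get("out", "labeled.csv")
                labeled.data.to_csv(outdir / out, index=False)
                tables[out] = labeled
                record["out"] = out
                record["conditions"] = list(stage["conditions"])
            elif kind == "tacho":
                table = load_table(stage["in"])
                mask = _mask_from_column(table, stage.get("mask_col"))
                result = {}
                curve = tachometric_curve(
                    table, mask, stage.get("bin_width_ms", 50.0),
                    stage.get("step_ms", 1.0))
                result["curve"] = curve.to_dict()
                fl, ce = floor_ceiling(
                    table, mask,
                    stage.get("floor_max_ms", 100.0),
                    stage.get("ceiling_min_ms", 150.0))
                result["floor"] = fl.to_dict()
                result["ceiling"] = ce.to_dict()
                result["rt"] = rt_summary(table, mask).to_dict()
                out = stage.get("json", "tacho.json")
                write_json(result, outdir / out)
                record["out"] = out
                record["floor"] = fl.estimate
                record["ceiling"] = ce.estimate
            elif kind == "align":
                y1 = _load_curve(outdir / stage["curve1"])
                y2 = _load_curve(outdir / stage["curve2"])
                grid = stage.get("delta_grid", [-100, 100])
                params = align_curves(
                    y1, y2, np.arange(grid[0], grid[1] + 1),
                    min_overlap=stage.get("min_overlap", 50),
                    weight_by_n=stage.get("weight_by_n", False))
                out = stage.get("json", "alignment.json")
                write_json(params.to_dict(), outdir / out)
                record["out"] = out
                record["delta_ms"] = params.delta_ms
                if stage.get("pool"):
                    t1 = load_table(stage["table1"])
                    t2 = load_table(stage["table2"])
                    pooled = pool_tables(t1, t2, params)
                    pout = stage.get("pooled_out", "pooled.csv")
                    write_trials(pooled, outdir / pout)
                    tables[pout] = pooled
                    record["pooled_out"] = pout
            elif kind == "interact":
                table = load_table(stage["in"])
                pair = stage.get("pair", ["color", "location"])
                result = interaction_scan(
                    table, tuple(pair), H=stage.get("H", 1),
                    ceiling_min_ms=stage.get("ceiling_min_ms", 150.0),
                    reliability_max_span=stage.get("reliability_max_span",
                                                   0.15),
                    fit_intercept=stage.get("fit_intercept", True))
                out = stage.get("json", "interaction.json")
                write_json(result.to_dict(), outdir / out)
                record["out"] = out
                record["slope"] = result.slope
            elif kind == "predict":
                q = predict_joint(stage["p_a"], stage["p_b"], stage["prior"])
                out = stage.get("json", "predict.json")
                write_json({"p_a": stage["p_a"], "p_b": stage["p_b"],
                            "prior": stage["prior"], "predicted": q},
                           outdir / out)
                record["out"] = out
                record["predicted"] = q
            else:
                raise StageError(f"unknown stage kind: {kind!r}")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {i} ({kind}) failed: {exc}") from exc
        manifest["stages"].append(record)
        logger.info("stage %d (%s) done", i, kind)

    write_json(manifest, outdir / "manifest.json")
    return outdir


def demo_config() -> dict:
    """A small end-to-end demonstration: simulate unbiased trials, check
    the chance floor, and evaluate the no-interaction prediction on two
    textbook probability triples."""
    return {
        "seed": 7,
        "stages": [
            {"stage": "simulate", "out": "trials.csv",
             "params": {"n_trials_per_session": 500, "n_sessions": 20,
                        "loc_bias_gain": 0.0, "color_bias_gain": 0.0,
                        "base_ceiling": 0.70}},
            {"stage": "history", "in": "trials.csv",
             "conditions": ["1S:color", "1D:color", "1S:location",
                            "1C", "1SC:color"],
             "out": "labeled.csv"},
            {"stage": "tacho", "in": "labeled.csv", "json": "tacho_all.json"},
            {"stage": "tacho", "in": "labeled.csv", "mask_col": "1S_color",
             "json": "tacho_1S_color.json"},
            {"stage": "interact", "in": "labeled.csv",
             "pair": ["color", "location"], "H": 1,
             "json": "interaction.json"},
            {"stage": "predict", "p_a": 0.80, "p_b": 0.75, "prior": 0.70,
             "json": "predict_methods.json"},
            {"stage": "predict", "p_a": 0.59, "p_b": 0.71, "prior": 0.66,
             "json": "predict_results.json"},
        ],
    }


def load_config(path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict) or "stages" not in config:
        raise StageError("config must be a mapping with a 'stages' list")
    return config
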