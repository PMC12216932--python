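"""Configuration-driven experiment runner.

Each experiment kind wires the library modules into one reproducible
protocol: a resolved configuration plus one root seed fully determines
every output file.  Configurations are plain dictionaries (loadable from
YAML or JSON); :func:`validate` normalises them against a per-kind schema
and :func:`run` executes and writes CSV results next to a JSON manifest
from which the run can be reconstructed.

Two scale presets exist per kind: ``"test"`` (desk-scale, minutes) and
``"paper"`` (the published protocol sizes — roster sizes of 1000, thousands
of averaging runs — intended for long unattended jobs; phase maps
checkpoint cell-by-cell as they go).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import datasets as ds
from . import ensemble as ens
from . import population as pop
from .errors import SchemaError, SeatingInfeasibleError
from .seeding import derive_seeds

__all__ = ["ExperimentConfig", "validate", "run", "KINDS", "PRESETS"]

logger = logging.getLogger("crowdcourt.experiments")

KINDS = (
    "synthetic-curve",
    "synthetic-phase",
    "ensemble-curve",
    "ensemble-phase",
    "decorrelate",
    "nH-sweep",
    "learning-curve",
)


# --- field validators -------------------------------------------------------

def _prob(v, key):
    v = float(v)
    if not (0.0 <= v <= 1.0):
        raise SchemaError(f"{key}: must lie in [0, 1], got {v}")
    return v


def _pos_int(v, key):
    if isinstance(v, bool) or int(v) != float(v) or int(v) < 1:
        raise SchemaError(f"{key}: must be a positive integer, got {v!r}")
    return int(v)


def _int_list(v, key):
    if not isinstance(v, (list, tuple)) or not v:
        raise SchemaError(f"{key}: must be a non-empty list of integers")
    return [_pos_int(x, key) for x in v]


def _float_list(v, key):
    if not isinstance(v, (list, tuple)) or not v:
        raise SchemaError(f"{key}: must be a non-empty list of numbers")
    return [float(x) for x in v]


def _prob_list(v, key):
    return [_prob(x, key) for x in _float_list(v, key)]


def _string(v, key):
    if not isinstance(v, str):
        raise SchemaError(f"{key}: must be a string")
    return v


def _choice(options):
    def check(v, key):
        if v not in options:
            raise SchemaError(f"{key}: must be one of {options}, got {v!r}")
        return v

    return check


def _dataset_cfg(v, key):
    if not isinstance(v, dict):
        raise SchemaError(f"{key}: must be a mapping")
    v = dict(v)
    kind = v.pop("type", "circles")
    if kind == "circles":
        out = {
            "type": "circles",
            "n_samples": _pos_int(v.pop("n_samples", 5000), f"{key}.n_samples"),
            "factor": float(v.pop("factor", 0.85)),
            "noise_sd": float(v.pop("noise_sd", ds.DEFAULT_CIRCLES_NOISE)),
        }
    elif kind == "csv":
        if "path" not in v or "label_column" not in v:
            raise SchemaError(f"{key}: csv dataset requires 'path' and 'label_column'")
        out = {
            "type": "csv",
            "path": _string(v.pop("path"), f"{key}.path"),
            "label_column": _string(v.pop("label_column"), f"{key}.label_column"),
            "standardize": bool(v.pop("standardize", True)),
        }
    else:
        raise SchemaError(f"{key}.type: must be 'circles' or 'csv', got {kind!r}")
    if v:
        raise SchemaError(f"{key}: unknown keys {sorted(v)}")
    return out


def _classifier_cfg(v, key):
    if not isinstance(v, dict):
        raise SchemaError(f"{key}: must be a mapping")
    v = dict(v)
    out = {
        "kind": _choice(("decision_tree", "rbf_svm"))(v.pop("kind", "rbf_svm"), f"{key}.kind"),
        "hyperparameters": dict(v.pop("hyperparameters", {})),
        "train_seed_policy": _choice(("fixed", "per-judge"))(
            v.pop("train_seed_policy", "per-judge"), f"{key}.train_seed_policy"
        ),
    }
    if v:
        raise SchemaError(f"{key}: unknown keys {sorted(v)}")
    return out


_REQUIRED = object()

_COMMON = {
    "seed": (_pos_int, 1),
    "out": (_string, "results"),
}

_ENSEMBLE_COMMON = {
    "dataset": (_dataset_cfg, {"type": "circles"}),
    "classifier": (_classifier_cfg, {"kind": "rbf_svm"}),
    "train_fraction": (_prob, ds.DEFAULT_TRAIN_FRACTION),
    "stratified": (lambda v, k: bool(v), False),
    "L": (_pos_int, 200),
    "H": (_pos_int, 50),
    "M": (_pos_int, 500),
    "runs": (_pos_int, 20),
}

_SCHEMAS: dict[str, dict[str, tuple]] = {
    "synthetic-curve": {
        **_COMMON,
        "p": (_prob, _REQUIRED),
        "r_L": (_prob, _REQUIRED),
        "r_H": (_prob, _REQUIRED),
        "group_sizes": (_int_list, list(range(1, 101))),
        "mode": (_choice(("exact", "simulate")), "exact"),
        "M": (_pos_int, 100_000),
    },
    "synthetic-phase": {
        **_COMMON,
        "r_L_grid": (_prob_list, [round(v, 3) for v in np.linspace(0.5, 1.0, 11)]),
        "p_grid": (_prob_list, [round(v, 3) for v in np.linspace(0.0, 1.0, 11)]),
        "r_H": (_prob, 0.5),
        "N_max": (_pos_int, pop.DEFAULT_N_MAX),
        "mode": (_choice(("exact", "simulate")), "exact"),
        "M": (_pos_int, 100_000),
    },
    "ensemble-curve": {
        **_COMMON,
        **_ENSEMBLE_COMMON,
        "p": (_prob, _REQUIRED),
        "n_L": (_pos_int, _REQUIRED),
        "n_H": (_pos_int, _REQUIRED),
        "group_sizes": (_int_list, [1, 3, 5, 7, 11, 15, 21, 31, 41, 61, 81, 100]),
    },
    "ensemble-phase": {
        **_COMMON,
        **_ENSEMBLE_COMMON,
        "n_L_grid": (_int_list, [10, 20, 40, 80, 160]),
        "p_grid": (_prob_list, [0.1, 0.3, 0.5, 0.7, 0.9]),
        "n_H": (_pos_int, _REQUIRED),
        "N_max": (_pos_int, 100),
        "group_sizes": (_int_list, [1, 3, 5, 7, 11, 15, 21, 31, 41, 61, 81, 100]),
    },
    "decorrelate": {
        **_COMMON,
        **_ENSEMBLE_COMMON,
        "p": (_prob, 0.75),
        "n_L": (_pos_int, 40),
        "n_H": (_pos_int, 50),
        "alphas": (_prob_list, [0.0, 0.25, 0.5, 0.75, 1.0]),
        "group_sizes": (_int_list, [1, 3, 5, 7, 11, 15, 21, 31, 41, 61, 81, 100]),
    },
    "nH-sweep": {
        **_COMMON,
        **_ENSEMBLE_COMMON,
        "n_L_grid": (_int_list, [10, 20, 40, 80, 160]),
        "p_grid": (_prob_list, [0.1, 0.3, 0.5, 0.7, 0.9]),
        "n_H_list": (_int_list, [10, 100, 125, 140, 150]),
        "N_max": (_pos_int, 100),
        "group_sizes": (_int_list, [1, 3, 5, 7, 11, 15, 21, 31, 41, 61, 81, 100]),
    },
    "learning-curve": {
        **_COMMON,
        "dataset": (_dataset_cfg, {"type": "circles"}),
        "classifier": (_classifier_cfg, {"kind": "rbf_svm"}),
        "train_fraction": (_prob, ds.DEFAULT_TRAIN_FRACTION),
        "stratified": (lambda v, k: bool(v), False),
        "sample_sizes": (_int_list, [10, 20, 50, 100, 250, 500, 1250]),
        "repeats": (_pos_int, 30),
    },
}

#: Published protocol sizes per experiment kind (long jobs); the "test"
#: preset is simply each schema's defaults.
PRESETS: dict[str, dict[str, dict[str, Any]]] = {
    "synthetic-curve": {
        "test": {},
        "paper": {"mode": "simulate", "M": 100_000, "r_H": 0.5},
    },
    "synthetic-phase": {
        "test": {"N_max": 30, "mode": "exact"},
        "paper": {
            "mode": "simulate", "M": 100_000, "r_H": 0.5, "N_max": 100,
            "r_L_grid": [round(v, 4) for v in np.linspace(0.5, 1.0, 21)],
            "p_grid": [round(v, 4) for v in np.linspace(0.0, 1.0, 21)],
        },
    },
    "ensemble-curve": {
        "test": {},
        "paper": {"n_H": 50, "L": 1000, "H": 100, "runs": 1000, "M": 3500,
                  "group_sizes": list(range(1, 101))},
    },
    "ensemble-phase": {
        "test": {},
        "paper": {"n_H": 50, "L": 1000, "H": 100, "runs": 1000, "M": 3500,
                  "N_max": 100, "group_sizes": list(range(1, 101))},
    },
    "decorrelate": {
        "test": {},
        "paper": {"p": 0.75, "n_L": 40, "n_H": 50, "L": 1000, "H": 100,
                  "runs": 100, "M": 3500, "group_sizes": list(range(1, 101))},
    },
    "nH-sweep": {
        "test": {},
        "paper": {"n_H_list": [10, 100, 125, 140, 150], "L": 1000, "H": 100,
                  "runs": 100, "M": 3500, "N_max": 100,
                  "group_sizes": list(range(1, 101))},
    },
    "learning-curve": {
        "test": {},
        "paper": {"repeats": 100},
    },
}


class ExperimentConfig(dict):
    """A validated, fully resolved experiment configuration."""

    @property
    def kind(self) -> str:
        return self["kind"]


def validate(config: dict, preset: str | None = None) -> ExperimentConfig:
    """Normalise a raw config dict against its kind's schema.

    Missing keys receive defaults (optionally from a named preset first);
    unknown keys and out-of-range values raise :class:`SchemaError` naming
    the offending key(s).
    """
    if not isinstance(config, dict):
        raise SchemaError("config must be a mapping")
    config = copy.deepcopy(config)
    problems: list[str] = []
    kind = config.pop("kind", None)
    if kind is None:
        raise SchemaError(["missing required key 'kind'"])
    if kind not in _SCHEMAS:
        raise SchemaError([f"kind: unknown experiment kind {kind!r} (choose from {KINDS})"])
    schema = _SCHEMAS[kind]

    if preset is not None:
        if preset not in PRESETS[kind]:
            raise SchemaError([f"preset: unknown preset {preset!r}"])
        merged = dict(PRESETS[kind][preset])
        merged.update(config)  # explicit keys beat preset values
        config = merged

    resolved: dict[str, Any] = {"kind": kind}
    for key, (check, default) in schema.items():
        if key in config:
            try:
                resolved[key] = check(config.pop(key), key)
            except SchemaError as exc:
                problems.extend(exc.problems)
            except (TypeError, ValueError):
                problems.append(f"{key}: invalid value")
        elif default is _REQUIRED:
            problems.append(f"missing required key '{key}'")
        else:
            # defaults pass through the same normaliser so nested configs
            # (dataset, classifier) get their own sub-defaults resolved
            resolved[key] = check(copy.deepcopy(default), key)
    if config:
        problems.extend(f"unknown key '{k}'" for k in sorted(config))
    if problems:
        raise SchemaError(problems)
    return ExperimentConfig(resolved)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_dataset(cfg: dict, seed: int) -> ds.LabeledDataset:
    if cfg["type"] == "circles":
        return ds.make_circles_clusters(
            cfg["n_samples"], factor=cfg["factor"], noise_sd=cfg["noise_sd"], seed=seed
        )
    return ds.load_and_preprocess_tabular(
        cfg["path"], cfg["label_column"], standardize=cfg["standardize"]
    )


def _classifier_spec(cfg: dict) -> ens.ClassifierSpec:
    return ens.ClassifierSpec(
        kind=cfg["kind"],
        hyperparameters=cfg["hyperparameters"],
        train_seed_policy=cfg["train_seed_policy"],
    )


def _prepare_split(cfg: ExperimentConfig, seeds: list[int]):
    """Dataset -> split -> test subsample of size M, from derived seeds."""
    data = _build_dataset(cfg["dataset"], seeds[0])
    pair = ds.split_train_test(
        data, cfg["train_fraction"], stratified=cfg["stratified"], seed=seeds[1]
    )
    test = pair.test
    if cfg.get("M") and cfg["M"] < len(test):
        rng = np.random.default_rng(seeds[2])
        idx = rng.choice(len(test), size=cfg["M"], replace=False)
        test = test.subset(idx, name=f"{test.name}[:{cfg['M']}]")
    return pair.train, test


def run(config: ExperimentConfig | dict, out: str | Path | None = None) -> dict:
    """Execute one experiment and write its outputs.

    Results go to the configured output directory as CSV, together with a
    ``manifest.json`` holding the resolved config, the seed and a config
    hash — everything needed to reproduce the files byte-for-byte.
    Returns a summary dict with the written paths and in-memory results.
    """
    cfg = config if isinstance(config, ExperimentConfig) else validate(dict(config))
    out_dir = Path(out) if out is not None else Path(cfg["out"])
    seed = cfg["seed"]
    kind = cfg.kind

    # fail fast on infeasible seating before any dataset or training work
    if kind in ("ensemble-curve", "decorrelate", "ensemble-phase", "nH-sweep"):
        n_seats = max(cfg["group_sizes"])
        p_vals = cfg["p_grid"] if "p_grid" in cfg else [cfg["p"]]
        infeasible = (
            n_seats > cfg["L"] + cfg["H"]
            or (any(p == 1.0 for p in p_vals) and n_seats > cfg["L"])
            or (any(p == 0.0 for p in p_vals) and n_seats > cfg["H"])
        )
        if infeasible or ("N_max" in cfg and n_seats > cfg["N_max"]):
            raise SeatingInfeasibleError(
                f"group sizes up to {n_seats} infeasible for L={cfg['L']}, "
                f"H={cfg['H']}" + (f", N_max={cfg['N_max']}" if "N_max" in cfg else "")
            )

    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(seed, 8)
    outputs: list[str] = []
    results: dict[str, Any] = {}

    def _write(name: str, obj) -> Path:
        path = out_dir / name
        obj.to_csv(path)
        outputs.append(name)
        return path

    logger.info("running %s (seed=%s) -> %s", kind, seed, out_dir)

    if kind == "synthetic-curve":
        params = pop.SyntheticParams(p=cfg["p"], r_L=cfg["r_L"], r_H=cfg["r_H"])
        if cfg["mode"] == "exact":
            accs = [pop.exact_accuracy(params, N) for N in cfg["group_sizes"]]
            curve = pop.AccuracyCurve(cfg["group_sizes"], accs)
        else:
            rng_seeds = derive_seeds(seeds[0], len(cfg["group_sizes"]))
            ests = [
                pop.simulate_decisions(params, N, cfg["M"], s)
                for N, s in zip(cfg["group_sizes"], rng_seeds)
            ]
            curve = pop.AccuracyCurve(cfg["group_sizes"], ests)
        _write("curve.csv", curve)
        results["curve"] = curve

    elif kind == "synthetic-phase":
        diagram = pop.phase_diagram(
            cfg["r_L_grid"], cfg["p_grid"], cfg["r_H"], N_max=cfg["N_max"],
            mode=cfg["mode"], M=cfg["M"], seed=seeds[0],
        )
        _write("phase.csv", diagram)
        results["diagram"] = diagram

    elif kind == "ensemble-curve":
        train, test = _prepare_split(cfg, seeds)
        spec = _classifier_spec(cfg["classifier"])
        params = ens.EnsembleParams(
            L=cfg["L"], H=cfg["H"], p=cfg["p"], n_L=cfg["n_L"], n_H=cfg["n_H"],
            N=max(cfg["group_sizes"]), M=len(test),
        )
        pool = ens.train_judge_pool(train, spec, params, seed=seeds[3])
        curve = ens.accuracy_vs_group_size(
            pool, test, cfg["p"], cfg["group_sizes"], runs=cfg["runs"], seed=seeds[4]
        )
        _write("curve.csv", curve)
        results["curve"] = curve

    elif kind == "ensemble-phase":
        train, test = _prepare_split(cfg, seeds)
        spec = _classifier_spec(cfg["classifier"])
        # checkpoint cells as they complete (long jobs are resumable by eye)
        cell_path = out_dir / "cells.csv"
        with open(cell_path, "w") as fh:
            fh.write("n_L,p,optimal_N,max_accuracy\n")

            def checkpoint(cell: dict) -> None:
                fh.write(
                    f"{cell['n_L']},{cell['p']},{cell['optimal_N']},"
                    f"{cell['max_accuracy']}\n"
                )
                fh.flush()
                logger.info("cell n_L=%(n_L)s p=%(p)s -> N*=%(optimal_N)s", cell)

            diagram = ens.ensemble_phase_map(
                train, test, spec, cfg["n_L_grid"], cfg["p_grid"], cfg["n_H"],
                N_max=cfg["N_max"], runs=cfg["runs"], seed=seeds[3],
                L=cfg["L"], H=cfg["H"], group_sizes=cfg["group_sizes"],
                progress=checkpoint,
            )
        outputs.append("cells.csv")
        _write("phase.csv", diagram)
        results["diagram"] = diagram

    elif kind == "decorrelate":
        train, test = _prepare_split(cfg, seeds)
        spec = _classifier_spec(cfg["classifier"])
        params = ens.EnsembleParams(
            L=cfg["L"], H=cfg["H"], p=cfg["p"], n_L=cfg["n_L"], n_H=cfg["n_H"],
            N=max(cfg["group_sizes"]), M=len(test),
        )
        curves = ens.decorrelation_experiment(
            train, test, spec, params, cfg["alphas"], cfg["group_sizes"],
            runs=cfg["runs"], seed=seeds[3],
        )
        for a, curve in curves.items():
            _write(f"curve_alpha_{a}.csv", curve)
        results["curves"] = curves

    elif kind == "nH-sweep":
        train, test = _prepare_split(cfg, seeds)
        spec = _classifier_spec(cfg["classifier"])
        sweep = ens.boundary_vs_nH(
            train, test, spec, cfg["n_L_grid"], cfg["p_grid"], cfg["n_H_list"],
            N_max=cfg["N_max"], runs=cfg["runs"], seed=seeds[3],
            L=cfg["L"], H=cfg["H"], group_sizes=cfg["group_sizes"],
        )
        for item in sweep:
            _write(f"phase_nH_{item.n_H}.csv", item.diagram)
        import pandas as pd

        areas = pd.DataFrame(
            {"n_H": [i.n_H for i in sweep], "breakdown_cells": [i.area for i in sweep]}
        )
        path = out_dir / "breakdown_areas.csv"
        areas.to_csv(path, index=False)
        outputs.append("breakdown_areas.csv")
        results["sweep"] = sweep

    elif kind == "learning-curve":
        data = _build_dataset(cfg["dataset"], seeds[0])
        pair = ds.split_train_test(
            data, cfg["train_fraction"], stratified=cfg["stratified"], seed=seeds[1]
        )
        spec = _classifier_spec(cfg["classifier"])
        curve = ds.learning_curve(
            spec, pair, cfg["sample_sizes"], repeats=cfg["repeats"], seed=seeds[3]
        )
        _write("learning_curve.csv", curve)
        results["curve"] = curve

    manifest = {
        "kind": kind,
        "config": {k: v for k, v in cfg.items()},
        "seed": seed,
        "config_hash": _config_hash(dict(cfg)),
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    results["out_dir"] = out_dir
    return results
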