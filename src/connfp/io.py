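"""Serialization: run TSVs + cohort JSON sidecars, HDF5 pattern sets and
model containers, JSON metrics."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import CohortSpec, GroundTruth, ROIRunSeries
from .features import FeatureIndexMap, PatternSet
from .mlp import DualHeadMLP

PATTERNS_SCHEMA = "connfp-patterns-1"
MODEL_SCHEMA = "connfp-model-1"


class SchemaError(RuntimeError):
    pass


def _check_schema(found: str, expected: str) -> None:
    if found != expected:
        raise SchemaError(f"schema version mismatch: found {found!r}, expected {expected!r}")


# -- cohorts (TSV + JSON sidecar) --------------------------------------


def write_cohort(
    runs: list[ROIRunSeries],
    out_dir: str | Path,
    spec: CohortSpec | None = None,
    truth: GroundTruth | None = None,
    roi_names: list[str] | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_roi = runs[0].n_roi
    roi_names = roi_names or [f"ROI{k:03d}" for k in range(n_roi)]
    manifest: dict = {"schema": "connfp-cohort-1", "runs": []}
    for run in runs:
        stem = f"{run.participant_id}_run-{run.run_index:02d}"
        pd.DataFrame(run.values, columns=roi_names).to_csv(
            out_dir / f"{stem}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        if run.nuisance.size:
            pd.DataFrame(
                run.nuisance, columns=[f"nuisance{q}" for q in range(run.nuisance.shape[1])]
            ).to_csv(out_dir / f"{stem}_nuisance.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["runs"].append(
            {
                "file": f"{stem}.tsv",
                "nuisance_file": f"{stem}_nuisance.tsv" if run.nuisance.size else None,
                "participant_id": run.participant_id,
                "group_label": int(run.group_label),
                "condition_label": int(run.condition_label),
                "run_index": int(run.run_index),
                "timepoint": int(run.timepoint),
            }
        )
    if spec is not None:
        echo = {k: v for k, v in spec.__dict__.items() if k != "cluster_assignment"}
        echo = {k: (list(v) if isinstance(v, tuple) else v) for k, v in echo.items()}
        manifest["spec"] = json.loads(json.dumps(echo, default=lambda o: np.asarray(o).tolist()))
        manifest["cluster_assignment"] = np.asarray(spec.cluster_assignment).tolist()
    if truth is not None:
        manifest["ground_truth"] = {
            "group_edges": [list(map(int, e)) for e in truth.group_edges],
            "condition_edges": [list(map(int, e)) for e in truth.condition_edges],
            "delta_group": truth.delta_group,
            "delta_condition": truth.delta_condition,
        }
    sidecar = out_dir / "cohort.json"
    sidecar.write_text(json.dumps(manifest, indent=1))
    return sidecar


def read_cohort(cohort_dir: str | Path) -> tuple[list[ROIRunSeries], dict]:
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "cohort.json").read_text())
    if manifest.get("schema") != "connfp-cohort-1":
        raise SchemaError(f"unexpected cohort schema {manifest.get('schema')!r}")
    runs = []
    for entry in manifest["runs"]:
        values = pd.read_csv(cohort_dir / entry["file"], sep="\t").to_numpy()
        if entry.get("nuisance_file"):
            nuis = pd.read_csv(cohort_dir / entry["nuisance_file"], sep="\t").to_numpy()
        else:
            nuis = np.zeros((values.shape[0], 0))
        runs.append(
            ROIRunSeries(
                values=values,
                participant_id=entry["participant_id"],
                group_label=entry["group_label"],
                condition_label=entry["condition_label"],
                run_index=entry["run_index"],
                nuisance=nuis,
                timepoint=entry.get("timepoint", 1),
            )
        )
    return runs, manifest


# -- pattern sets (HDF5) -----------------------------------------------


def save_pattern_set(patterns: PatternSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = PATTERNS_SCHEMA
        f.attrs["provenance"] = json.dumps(patterns.provenance)
        f.create_dataset("features", data=patterns.features)
        f.create_dataset("group", data=patterns.group)
        f.create_dataset("lexicality", data=patterns.lexicality)
        f.create_dataset("run_index", data=patterns.run_index)
        str_dt = h5py.string_dtype()
        f.create_dataset("participant", data=[str(s) for s in patterns.participant], dtype=str_dt)
        f.create_dataset("half", data=[str(s) for s in patterns.half], dtype=str_dt)
        f.create_dataset("method", data=[str(s) for s in patterns.method], dtype=str_dt)
        f.create_dataset("pairs", data=patterns.index_map.pairs)
        f.create_dataset("within_cluster_mask", data=patterns.index_map.within_cluster_mask)
        f.create_dataset("roi_names", data=[str(s) for s in patterns.index_map.roi_names], dtype=str_dt)


def load_pattern_set(path: str | Path) -> PatternSet:
    with h5py.File(path, "r") as f:
        _check_schema(str(f.attrs.get("schema_version", "")), PATTERNS_SCHEMA)
        index_map = FeatureIndexMap(
            pairs=f["pairs"][()],
            within_cluster_mask=f["within_cluster_mask"][()].astype(bool),
            roi_names=tuple(s.decode() if isinstance(s, bytes) else s for s in f["roi_names"][()]),
        )
        decode = lambda d: np.array([s.decode() if isinstance(s, bytes) else s for s in d], dtype=object)
        return PatternSet(
            features=f["features"][()],
            group=f["group"][()],
            lexicality=f["lexicality"][()],
            participant=decode(f["participant"][()]),
            run_index=f["run_index"][()],
            half=decode(f["half"][()]),
            method=decode(f["method"][()]),
            index_map=index_map,
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )


# -- trained models (HDF5) ---------------------------------------------


def save_model(model: DualHeadMLP, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = MODEL_SCHEMA
        f.attrs["n_features_in"] = model.n_features_in_
        f.attrs["hidden_sizes"] = model.hidden_sizes_
        f.attrs["hyperparams"] = json.dumps(model.get_params())
        g = f.create_group("params")
        for k, v in model.params_.items():
            g.create_dataset(k, data=v)
        r = f.create_group("running_stats")
        for k, v in model.running_stats_.items():
            r.create_dataset(k, data=v)


def load_model(path: str | Path) -> DualHeadMLP:
    with h5py.File(path, "r") as f:
        _check_schema(str(f.attrs.get("schema_version", "")), MODEL_SCHEMA)
        params = json.loads(f.attrs["hyperparams"])
        model = DualHeadMLP(**params)
        model.n_features_in_ = int(f.attrs["n_features_in"])
        model.hidden_sizes_ = tuple(int(v) for v in f.attrs["hidden_sizes"])
        model.params_ = {k: f["params"][k][()] for k in f["params"]}
        model.running_stats_ = {k: f["running_stats"][k][()] for k in f["running_stats"]}
    return model


def write_metrics_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
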