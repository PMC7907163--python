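"""End-to-end orchestration: simulate -> featurize -> decimation families
-> composite -> transfer, with deterministic per-stage seeds and a single
JSON run report."""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .cohort import CohortSpec, generate_cohort, generate_transfer_cohort
from .features import ConnectivityConfig, FeatureIndexMap, build_pattern_set
from .mlp import TrainingConfig, GROUP_HEAD
from .decimation import run_families
from .composite import CompositeConfig, build_composite_result, tune_min_family_count
from .transfer import TransferConfig, run_transfer, lexicality_profile
from .metrics import summarize_families

logger = logging.getLogger("connfp")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: a pure function of (global seed,
    stage name); stages never consume one another's RNG streams."""
    return int(
        np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    connectivity: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    decimation: dict = field(default_factory=dict)
    composite: dict = field(default_factory=dict)
    transfer: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=stage_seed(self.seed, "simulate"), **self.cohort)

    def connectivity_config(self) -> ConnectivityConfig:
        cfg = dict(self.connectivity)
        if "methods" in cfg:
            cfg["methods"] = tuple(cfg["methods"])
        return ConnectivityConfig(**cfg)

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(**self.training)


def run_end_to_end(config: PipelineConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Execute every stage in order and write artifacts + one JSON report
    under ``out_dir``. Deterministic given ``config.seed``."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": json.loads(json.dumps(config.__dict__, default=str)), "stages": {}}

    def _stage(name):
        logger.info("stage %s starting", name)
        return time.time()

    # simulate
    t0 = _stage("simulate")
    spec = config.cohort_spec()
    runs, truth = generate_cohort(spec)
    cohort_dir = out / "cohort"
    cio.write_cohort(runs, cohort_dir, spec=spec, truth=truth)
    report["stages"]["simulate"] = {
        "seconds": time.time() - t0,
        "n_runs": len(runs),
        "artifact": str(cohort_dir),
    }

    # featurize
    t0 = _stage("featurize")
    conn = config.connectivity_config()
    full_map = FeatureIndexMap.for_parcellation(spec.n_roi, spec.cluster_assignment)
    patterns = build_pattern_set(runs, conn, map_=full_map)
    patterns_path = out / "patterns.h5"
    cio.save_pattern_set(patterns, patterns_path)
    report["stages"]["featurize"] = {
        "seconds": time.time() - t0,
        "n_patterns": patterns.n_patterns,
        "n_features": patterns.n_features,
        "artifact": str(patterns_path),
    }

    # decimation families
    t0 = _stage("decimate")
    training = config.training_config()
    dec = {"n_families": 2, "stop_fraction": 0.05, "fraction": 0.1}
    dec.update(config.decimation)
    families = run_families(
        patterns,
        training,
        n_families=dec["n_families"],
        base_seed=stage_seed(config.seed, "decimate"),
        stop_fraction=dec["stop_fraction"],
        fraction=dec["fraction"],
    )
    fam_dir = out / "families"
    fam_dir.mkdir(exist_ok=True)
    family_metrics = []
    for k, fam in enumerate(families):
        fdir = fam_dir / f"family-{k:02d}"
        fdir.mkdir(exist_ok=True)
        per_gen = []
        for gen in fam.generations:
            per_gen.append(
                {
                    "generation": gen.generation,
                    "n_features_in": int(gen.features_in.size),
                    "n_features_out": int(gen.features_out.size),
                    "hidden_sizes": list(gen.hidden_sizes),
                    "group": gen.group_metrics.to_dict(),
                    "lexical": gen.lexical_metrics.to_dict(),
                }
            )
        cio.write_metrics_json({"family_seed": fam.family_seed, "generations": per_gen}, fdir / "metrics.json")
        pairs = patterns.index_map.pairs[fam.final_features]
        (fdir / "final_features.txt").write_text(
            "\n".join(f"{i} {j}" for i, j in pairs) + "\n"
        )
        family_metrics.append(per_gen)
    first_gen_group = [f.first_generation().group_metrics for f in families]
    first_gen_lex = [f.first_generation().lexical_metrics for f in families]
    summary = None
    if len(families) >= 2:
        s = summarize_families(first_gen_group, first_gen_lex)
        summary = {"means": s.means, "sds": s.sds, "dprime_correlation": s.dprime_correlation}
    report["stages"]["decimate"] = {
        "seconds": time.time() - t0,
        "n_families": len(families),
        "generations_per_family": [f.n_generations for f in families],
        "first_generation_summary": summary,
        "artifact": str(fam_dir),
    }

    # composite
    t0 = _stage("composite")
    comp_cfg = dict(config.composite)
    auto_tune = comp_cfg.pop("auto_tune_threshold", True)
    composite_config = CompositeConfig(**comp_cfg) if comp_cfg else CompositeConfig()
    if auto_tune:
        from .composite import feature_frequencies

        counts = feature_frequencies(families, patterns.n_features)
        n_roi = patterns.index_map.n_roi
        t = tune_min_family_count(counts, n_roi * (n_roi - 1) // 2, n_families=len(families))
        composite_config = CompositeConfig(
            min_family_count=t,
            composite_k_folds=composite_config.composite_k_folds,
            z_threshold=composite_config.z_threshold,
        )
    comp = build_composite_result(
        patterns, families, training, composite_config, seed=stage_seed(config.seed, "composite")
    )
    comp_dir = out / "composite"
    comp_dir.mkdir(exist_ok=True)
    (comp_dir / "composite_features.txt").write_text(
        "\n".join(
            f"{patterns.index_map.pairs[k][0]} {patterns.index_map.pairs[k][1]} {comp.counts[k]}"
            for k in comp.composite_features
        )
        + "\n"
    )
    edge_rows = ["source\tdestination\thead\tz\tclass\tmean_connectivity"]
    for e in comp.relevant_edges:
        edge_rows.append(
            f"{e.roi_pair[0]}\t{e.roi_pair[1]}\t{'group' if e.head == GROUP_HEAD else 'lexicality'}"
            f"\t{e.z:.4f}\t{e.class_name}\t{e.mean_connectivity:.4f}"
        )
    (comp_dir / "relevant_edges.tsv").write_text("\n".join(edge_rows) + "\n")
    for name, adj in comp.class_adjacency.items():
        np.savetxt(comp_dir / f"adjacency_{name}.tsv", adj, delimiter="\t", fmt="%.6g")
    cio.write_metrics_json(
        {
            "min_family_count": composite_config.min_family_count,
            "n_composite_features": int(comp.composite_features.size),
            "group": comp.group_metrics.to_dict(),
            "lexical": comp.lexical_metrics.to_dict(),
            "n_relevant_edges": len(comp.relevant_edges),
        },
        comp_dir / "metrics.json",
    )
    report["stages"]["composite"] = {
        "seconds": time.time() - t0,
        "n_composite_features": int(comp.composite_features.size),
        "group_d_prime": comp.group_metrics.d_prime,
        "lexical_d_prime": comp.lexical_metrics.d_prime,
        "artifact": str(comp_dir),
    }

    # transfer
    t0 = _stage("transfer")
    transfer_cfg = dict(config.transfer)
    n_per_group = transfer_cfg.pop("n_per_group", 5)
    runs_per_participant = transfer_cfg.pop("runs_per_participant", 4)
    transfer_config = TransferConfig(**transfer_cfg) if transfer_cfg else TransferConfig()
    transfer_runs = generate_transfer_cohort(
        spec, truth, n_per_group=n_per_group, runs_per_participant=runs_per_participant
    )
    transfer_patterns = build_pattern_set(transfer_runs, conn, map_=full_map)
    tres = run_transfer(
        patterns, transfer_patterns, training, transfer_config, seed=stage_seed(config.seed, "transfer")
    )
    profile = lexicality_profile(tres)
    transfer_dir = out / "transfer"
    transfer_dir.mkdir(exist_ok=True)
    cio.write_metrics_json(
        {
            "mean_group_accuracy": tres.mean_group_accuracy,
            "mean_group_d_prime": tres.mean_group_dprime,
            "pooled_lexicality": profile.pooled,
            "unanimous_class": profile.unanimous_class,
        },
        transfer_dir / "metrics.json",
    )
    report["stages"]["transfer"] = {
        "seconds": time.time() - t0,
        "mean_group_accuracy": tres.mean_group_accuracy,
        "pooled_lexicality": profile.pooled,
        "artifact": str(transfer_dir),
    }

    cio.write_metrics_json(report, out / "report.json")
    return report
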