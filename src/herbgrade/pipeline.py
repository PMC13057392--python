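"""End-to-end pipeline: simulate, grade, screen, correlate, classify.

A single :class:`PipelineConfig` drives every stage. One master seed
spawns a named integer sub-seed per stage, so adding a stage never
perturbs earlier stages' random draws, and the whole run is
reproducible to the byte. The :class:`RunManifest` records the config
hash and a checksum inventory of every emitted file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import NoiseModel, StudyDesign, default_effects
from .fusion import ClassifierConfig, SplitSpec, compare_sources
from .io import write_dataset
from .opls import permutation_test
from .screening import (
    score_compound_correlation,
    screen_compounds,
    screen_sensor_array,
    sensor_compound_map,
)
from .sensory import PairwiseComparison, batch_scores, binary_comparison_weights
from .synthetic import CRITERIA, generate_dataset

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]

_STAGE_NAMES = ("simulate", "grade", "screen_volatile", "screen_nonvolatile",
                "screen_sensors", "correlate", "classify")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    idx = _STAGE_NAMES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    seed: int = 42
    replicates_per_batch: int = 5
    effect_scale: float = 1.0
    batch_sigma: float = 0.08
    variable_sigma: float = 0.02
    replicate_sigma: float = 0.01
    n_orthogonal: int = 1
    k_folds: int = 7
    n_permutations: int = 200
    vip_threshold: float = 1.0
    alpha: float = 0.05
    cum_var: float = 0.95
    train_fraction: float = 0.7
    study_size: bool = False
    knn_k: int = 2
    bpnn_hidden_neurons: int = 5
    bpnn_max_iterations: int = 1000
    rf_n_trees: int = 500
    rf_mtry: int = 3
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key: {sorted(unknown)[0]!r}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def noise(self) -> NoiseModel:
        return NoiseModel(self.batch_sigma, self.variable_sigma,
                          self.replicate_sigma)

    def classifier(self, seed: int) -> ClassifierConfig:
        return ClassifierConfig(knn_k=self.knn_k,
                                bpnn_hidden_neurons=self.bpnn_hidden_neurons,
                                bpnn_max_iterations=self.bpnn_max_iterations,
                                rf_n_trees=self.rf_n_trees,
                                rf_mtry=self.rf_mtry, seed=seed)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict]
    files: dict[str, str]
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), ensure_ascii=False, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage, writing artifacts and a manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    files: list[Path] = []
    notes: list[str] = []

    def _stage(name):
        stages.append({"name": name, "started": time.time()})

    def _done():
        stages[-1]["seconds"] = round(time.time() - stages[-1].pop("started"), 3)

    try:
        # -- simulate --------------------------------------------------
        _stage("simulate")
        design = StudyDesign(replicates_per_batch=config.replicates_per_batch,
                             seed=stage_seed(config.seed, "simulate"))
        effects = default_effects().scaled(config.effect_scale)
        dataset = generate_dataset(design, effects, config.noise())
        files += write_dataset(dataset, out / "data")
        _done()

        # -- sensory grading -------------------------------------------
        _stage("grade")
        weights = binary_comparison_weights(PairwiseComparison.from_ranking(CRITERIA))
        scores = batch_scores(dataset.evaluator_counts, weights)
        p = out / "sensory_scores.csv"
        scores.to_csv(p, index=False)
        files.append(p)
        _done()

        # -- compound screening ----------------------------------------
        for platform, stage in (("volatile", "screen_volatile"),
                                ("nonvolatile", "screen_nonvolatile")):
            _stage(stage)
            res = screen_compounds(
                dataset, platform, n_orthogonal=config.n_orthogonal,
                threshold=config.vip_threshold,
                n_permutations=config.n_permutations, alpha=config.alpha,
                seed=stage_seed(config.seed, stage))
            if config.n_permutations == 0:
                notes.append(f"{stage}: permutation validation skipped")
            payload = {
                "union": res.union, "shared": res.shared,
                "sets": {k: {"variables": v.variables,
                             "valid": v.valid,
                             "permutation_p": v.permutation_p}
                         for k, v in res.sets.items()},
            }
            p = out / f"differentials_{platform}.json"
            p.write_text(json.dumps(payload, ensure_ascii=False, indent=2))
            files.append(p)
            _done()

        # -- sensor screening ------------------------------------------
        _stage("screen_sensors")
        sensor_sets = {}
        for platform in ("enose", "etongue"):
            dset = screen_sensor_array(
                dataset, platform, n_orthogonal=config.n_orthogonal,
                threshold=config.vip_threshold,
                n_permutations=config.n_permutations, alpha=config.alpha,
                seed=stage_seed(config.seed, "screen_sensors"))
            sensor_sets[platform] = dset
        p = out / "differential_sensors.json"
        p.write_text(json.dumps(
            {k: {"sensors": v.variables, "valid": v.valid,
                 "permutation_p": v.permutation_p}
             for k, v in sensor_sets.items()}, indent=2))
        files.append(p)
        _done()

        # -- correlation maps ------------------------------------------
        _stage("correlate")
        cm = score_compound_correlation(dataset, weights, alpha=config.alpha)
        cm.rho.to_csv(out / "score_compound_rho.csv")
        cm.p.to_csv(out / "score_compound_p.csv")
        files += [out / "score_compound_rho.csv", out / "score_compound_p.csv"]
        for sensor_platform, compound_platform in (("enose", "volatile"),
                                                   ("etongue", "nonvolatile")):
            sm = sensor_compound_map(dataset, sensor_platform, compound_platform,
                                     sensors=sensor_sets[sensor_platform].variables,
                                     alpha=config.alpha)
            rp = out / f"{sensor_platform}_compound_rho.csv"
            pp = out / f"{sensor_platform}_compound_p.csv"
            sm.rho.to_csv(rp)
            sm.p.to_csv(pp)
            files += [rp, pp]
        _done()

        # -- classification --------------------------------------------
        _stage("classify")
        seed = stage_seed(config.seed, "classify")
        table, reports = compare_sources(
            dataset, config.classifier(seed),
            SplitSpec(config.train_fraction, True, seed, config.study_size),
            cum_var=config.cum_var)
        p = out / "classification_accuracy.csv"
        table.to_csv(p, index=False)
        files.append(p)
        conf = {f"{s}|{c}": r.confusion.to_dict() for (s, c), r in reports.items()}
        p2 = out / "confusion_matrices.json"
        p2.write_text(json.dumps(conf, ensure_ascii=False, indent=2))
        files.append(p2)
        _done()
    except Exception as err:
        stage = stages[-1]["name"] if stages else "setup"
        manifest = RunManifest(config.config_hash(), config.seed, __version__,
                               stages, {str(f.relative_to(out)): _sha256(f)
                                        for f in files},
                               notes + [f"aborted at stage {stage}: {err}"])
        (out / "manifest.json").write_text(manifest.to_json())
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    cfg_path = out / "config.yaml"
    config.to_yaml(cfg_path)
    files.append(cfg_path)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, version=__version__,
        stages=stages,
        files={str(f.relative_to(out)): _sha256(f) for f in files},
        notes=notes,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
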