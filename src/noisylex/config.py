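"""Experiment configuration and end-to-end orchestration.

A single :class:`ExperimentConfig` captures everything needed to reproduce
a run: lexicon source (synthetic parameters or a TSV path), architecture
and training settings, test grids, replication count and the master seed.
Every stochastic stage derives its own seed from the master seed through a
fixed tag scheme (see :mod:`noisylex._util`), so identical configs yield
byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import derive_seed
from . import lexicon as lexmod
from . import mechanistic as mech
from . import stats as statsmod
from . import tasks
from .network import ArchitectureSpec, save_checkpoint

__all__ = ["ExperimentConfig", "run_experiment"]

log = logging.getLogger("noisylex")


@dataclass
class ExperimentConfig:
    # lexicon source: synthetic parameters, or a TSV path overriding them
    lexicon_path: str | None = None
    n_pairs: int = 121
    disyllabic_a: int = 39
    disyllabic_b: int = 45
    sem_ones_target: float = 52.7
    n_sem_clusters: int = 8
    sem_flip: float = 0.3
    # architecture (None entries fall back to ArchitectureSpec defaults)
    arch: dict = field(default_factory=dict)
    # training
    target_language: str = "B"
    replications: int = 5
    pretrain_epochs: int = 50
    epochs: int | None = None  # None = default total-presentation budget
    corruption_sd: float = 0.1
    sem_mask_frac: float = 0.9
    phases_schedule: str = "interleaved"
    lr: float = 0.03
    batch_size: int = 64
    # offline test grid
    offline_sds: list = field(default_factory=lambda: [0.0, 0.30, 0.60, 0.90])
    positions: list = field(default_factory=lambda: ["initial", "final"])
    offline_repetitions: int = 10
    # online test grid
    online_sds: list = field(default_factory=lambda: [0.0, 0.30, 0.60])
    max_timestep: int = 5
    online_repetitions: int = 10
    # mechanistic analysis
    mechanistic_sd: float = 0.75
    mechanistic_repetitions: int = 10
    # master seed
    seed: int = 0

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()

    # -- derived objects ---------------------------------------------------

    def make_lexicon(self) -> lexmod.BilingualLexicon:
        if self.lexicon_path:
            return lexmod.load_lexicon(self.lexicon_path)
        return lexmod.generate_synthetic_lexicon(
            n_pairs=self.n_pairs,
            disyllabic_counts={"A": self.disyllabic_a, "B": self.disyllabic_b},
            sem_ones_target=self.sem_ones_target,
            n_sem_clusters=self.n_sem_clusters,
            sem_flip=self.sem_flip,
            seed=derive_seed(self.seed, "lexicon"),
        )

    def make_arch(self) -> ArchitectureSpec:
        return ArchitectureSpec(**self.arch)

    def train(self, lexicon: lexmod.BilingualLexicon) -> dict[str, list]:
        return tasks.train_model_versions(
            lexicon,
            target_language=self.target_language,
            n_replications=self.replications,
            arch=self.make_arch(),
            pretrain_epochs=self.pretrain_epochs,
            seed=derive_seed(self.seed, "exposure"),
            epochs=self.epochs,
            corruption_sd=self.corruption_sd,
            sem_mask_frac=self.sem_mask_frac,
            phases_schedule=self.phases_schedule,
            lr=self.lr,
            batch_size=self.batch_size,
        )


def _stage(name: str, t0: float, timings: dict) -> None:
    timings[name] = round(time.perf_counter() - t0, 3)
    log.info("stage %s done in %.1fs", name, timings[name])


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict[str, str]:
    """Run the full pipeline and write all result tables under ``out_dir``.

    Stages: lexicon -> exposure (training both versions) -> offline
    simulation (+ Input-based baseline + effect models) -> online
    simulation (+ binwise tests) -> mechanistic ranks -> RSA.  A manifest
    records the config, its hash, and stage timings.  Any stage failure
    propagates after partial outputs have been written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    lexicon = config.make_lexicon()
    lexmod.save_lexicon(lexicon, out / "lexicon.tsv")
    paths["lexicon"] = str(out / "lexicon.tsv")
    _stage("lexicon", t0, timings)

    t0 = time.perf_counter()
    models = config.train(lexicon)
    ckpt_dir = out / "models"
    ckpt_dir.mkdir(exist_ok=True)
    for version, reps in models.items():
        for i, m in enumerate(reps):
            save_checkpoint(m, ckpt_dir / f"{version}_{i}.npz")
            pd.DataFrame(m.training_log).to_csv(
                ckpt_dir / f"{version}_{i}_log.csv", index=False)
    paths["models"] = str(ckpt_dir)
    _stage("exposure", t0, timings)

    t0 = time.perf_counter()
    offline = tasks.run_offline_experiment(
        models, lexicon, target_language=config.target_language,
        noise_sds=config.offline_sds, positions=config.positions,
        repetitions=config.offline_repetitions,
        seed=derive_seed(config.seed, "offline"))
    offline.to_csv(out / "offline_trials.csv", index=False)
    paths["offline_trials"] = str(out / "offline_trials.csv")
    baseline = tasks.run_offline_input_based(
        lexicon, target_language=config.target_language,
        noise_sds=config.offline_sds, positions=config.positions,
        repetitions=config.offline_repetitions,
        seed=derive_seed(config.seed, "offline"))
    baseline.to_csv(out / "offline_input_based.csv", index=False)
    paths["offline_input_based"] = str(out / "offline_input_based.csv")
    errors = tasks.aggregate_unique_misperceptions(offline)
    errors.to_csv(out / "offline_unique_errors.csv", index=False)
    paths["offline_unique_errors"] = str(out / "offline_unique_errors.csv")
    effects = statsmod.effect_model_accuracy(offline)
    (out / "offline_effects.json").write_text(json.dumps(
        {k: dataclasses.asdict(v) for k, v in effects.items()}, indent=2))
    paths["offline_effects"] = str(out / "offline_effects.json")
    _stage("offline", t0, timings)

    t0 = time.perf_counter()
    displays = tasks.build_all_displays(lexicon, config.target_language)
    pd.DataFrame(
        [dataclasses.asdict(d) for d in displays.values()]
    ).to_csv(out / "displays.tsv", sep="\t", index=False)
    paths["displays"] = str(out / "displays.tsv")
    looks = tasks.run_online_experiment(
        models, lexicon, displays, target_language=config.target_language,
        noise_sds=config.online_sds,
        timesteps=range(config.max_timestep + 1),
        repetitions=config.online_repetitions,
        seed=derive_seed(config.seed, "online"))
    looks.to_csv(out / "online_looks.csv", index=False)
    paths["online_looks"] = str(out / "online_looks.csv")
    series = tasks.looking_preference_series(looks)
    series.to_csv(out / "online_series.csv", index=False)
    paths["online_series"] = str(out / "online_series.csv")
    per_item = tasks.looking_preference_series(looks, per_item=True)
    tests = []
    for (version, sd, dtype), g in per_item.groupby(
            ["version", "sd", "display_type"], sort=False):
        tt = statsmod.binwise_ttests(g)
        tt["version"], tt["sd"], tt["display_type"] = version, sd, dtype
        tests.append(tt)
    pd.concat(tests, ignore_index=True).to_csv(
        out / "online_binwise_tests.csv", index=False)
    paths["online_binwise_tests"] = str(out / "online_binwise_tests.csv")
    _stage("online", t0, timings)

    t0 = time.perf_counter()
    ranks = mech.rank_series(
        models, lexicon, target_language=config.target_language,
        noise_sds=(0.0, config.mechanistic_sd),
        timesteps=range(1, config.max_timestep + 1),
        repetitions=config.mechanistic_repetitions,
        seed=derive_seed(config.seed, "mech"))
    ranks.to_csv(out / "mechanistic_ranks.csv", index=False)
    paths["mechanistic_ranks"] = str(out / "mechanistic_ranks.csv")
    _stage("mechanistic", t0, timings)

    t0 = time.perf_counter()
    rsa = mech.rsa_table(
        models, lexicon, target_language=config.target_language,
        noise_sds=(0.0, config.mechanistic_sd),
        timesteps=range(1, config.max_timestep + 1),
        repetitions=config.mechanistic_repetitions,
        seed=derive_seed(config.seed, "rsa"))
    rsa.to_csv(out / "rsa.csv", index=False)
    paths["rsa"] = str(out / "rsa.csv")
    _stage("rsa", t0, timings)

    config.to_yaml(out / "config.yaml")
    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "timings": timings,
        "outputs": paths,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(out / "manifest.json")
    return paths
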