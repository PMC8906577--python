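"""Configuration-driven end-to-end orchestration.

A :class:`RunConfig` (YAML-serializable) names the input — a synthetic-
screen recipe or a profile table on disk — the processing options, the VAE
variants to train and the analyses to run.  :func:`run_pipeline` executes
the requested stages in dependency order

    simulate/ingest -> process -> calibrate -> train -> interpret -> lsa -> evaluate

writing per-stage outputs, a JSON-lines log and a run manifest (inputs,
seeds, outputs, timings) under the output directory.  Every stage derives
its seed from the global seed plus the stage name, so a re-run of the same
config reproduces all outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import calibration, evaluation, lsa, synthetic
from .models import VAEConfig, encode_decode, simulate_profiles, train_vae
from .interpretation import contribution_matrix
from .profiles import (
    ProfileTable,
    collapse_consensus,
    normalize_zero_one,
    read_profiles,
    select_features,
    shuffle_columns,
    split_stratified,
)

ALL_STAGES = ("data", "process", "calibrate", "train", "interpret", "lsa", "evaluate")


class ConfigError(ValueError):
    """The run configuration is inconsistent."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the name."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return (global_seed * 1_000_003 + h) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    outdir: str = "morphvae_run"
    seed: int = 0
    # data: either a synthetic recipe or a file to ingest
    synthetic: dict[str, Any] | None = field(default_factory=dict)
    input_path: str | None = None
    input_dialect: str = "csv"
    input_level: str = "level4"
    column_map: dict[str, str] = field(default_factory=dict)
    # processing
    blocklist: list[str] = field(default_factory=list)
    variance_threshold: float = 1e-8
    outlier_sd: float = 15.0
    collapse_to_level5: bool = True
    normalize: bool = True
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    # models
    variants: tuple[str, ...] = ("vanilla", "beta", "mmd")
    vae: dict[str, Any] = field(default_factory=dict)  # VAEConfig overrides
    # calibration
    run_calibration: bool = False
    beta_grid: list[float] = field(default_factory=lambda: [0.01, 0.3, 10.0])
    lambda_grid: list[float] = field(default_factory=lambda: [10.0, 100.0, 1000.0])
    # lsa
    n_shuffles: int = 10
    pca_components: int = 10
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_path is None:
            raise ConfigError("config needs either a synthetic recipe or an input_path")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split_fractions must sum to 1")

    # -- serialization --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["split_fractions"] = list(self.split_fractions)
        payload["variants"] = list(self.variants)
        payload["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "RunConfig":
        for key in ("split_fractions", "variants", "stages"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def vae_config(self, variant: str, n_features: int) -> VAEConfig:
        defaults = dict(
            variant=variant,
            hidden_dim=max(50, n_features // 2),
            seed=stage_seed(self.seed, f"train:{variant}"),
        )
        defaults.update(self.vae)
        defaults["variant"] = variant
        return VAEConfig(**defaults)


class _Logger:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "a")

    def log(self, **fields: Any) -> None:
        fields.setdefault("time", time.time())
        self._fh.write(json.dumps(fields, default=str) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = _Logger(outdir / "run_log.jsonl")
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "started": time.time(),
    }
    config.to_yaml(outdir / "config.yaml")

    state: dict[str, Any] = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            _check_dependencies(stage, config, state)
            t0 = time.time()
            logger.log(stage=stage, event="start")
            _STAGE_FUNCS[stage](config, state, outdir, manifest)
            manifest["stages"][stage] = {
                "status": "complete",
                "seconds": round(time.time() - t0, 3),
            }
            logger.log(stage=stage, event="done", seconds=time.time() - t0)
    except Exception as exc:  # record partial completion, then re-raise
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest["finished"] = time.time()
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logger.log(stage=stage, event="failed", error=str(exc))
        logger.close()
        raise
    manifest["finished"] = time.time()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.close()
    return manifest


def _check_dependencies(stage: str, config: RunConfig, state: dict[str, Any]) -> None:
    needs = {
        "process": ("table",),
        "calibrate": ("processed",),
        "train": ("processed",),
        "interpret": ("models",),
        "lsa": ("models",),
        "evaluate": ("models",),
    }.get(stage, ())
    missing = [n for n in needs if n not in state]
    if missing:
        raise ConfigError(
            f"stage {stage!r} requires earlier stage output {missing}; "
            "add the producing stage to config.stages"
        )


# ----------------------------------------------------------------------
# Stage implementations


def _stage_data(config, state, outdir, manifest) -> None:
    if config.input_path is not None:
        table = read_profiles(
            config.input_path,
            dialect=config.input_dialect,
            level=config.input_level,
            column_map=config.column_map,
        )
        manifest["outputs"]["input"] = str(config.input_path)
    else:
        seed = stage_seed(config.seed, "simulate")
        spec = synthetic.generate_spec(config.synthetic, seed=seed)
        table = synthetic.generate_profiles(spec)
        spec.to_yaml(outdir / "synthetic_spec.yaml")
        state["spec"] = spec
        manifest["outputs"]["synthetic_spec"] = "synthetic_spec.yaml"
    state["table"] = table


def _stage_process(config, state, outdir, manifest) -> None:
    table = state["table"]
    table, report = select_features(
        table, config.blocklist, config.variance_threshold, config.outlier_sd
    )
    (outdir / "feature_selection.json").write_text(json.dumps(report, indent=2))
    if config.collapse_to_level5 and table.level == "level4":
        table = collapse_consensus(table)
    if config.normalize:
        table, record = normalize_zero_one(table)
        state["minmax"] = record
    split = split_stratified(
        table,
        config.split_fractions,
        seed=stage_seed(config.seed, "split"),
        strat_column="plate",
    )
    (outdir / "split_manifest.json").write_text(json.dumps(split.to_manifest()))
    table.write(outdir / "processed.parquet", dialect="parquet")
    state["processed"] = table
    state["split"] = split
    manifest["outputs"]["processed"] = "processed.parquet"


def _stage_calibrate(config, state, outdir, manifest) -> None:
    if not config.run_calibration:
        manifest["stages"].setdefault("calibrate", {})
        state["calibration"] = None
        return
    table = state["processed"]
    train_tab = table.subset(state["split"].indices("train"))
    seed = stage_seed(config.seed, "calibrate")
    cfg = VAEConfig(
        variant="beta",
        latent_dim=min(50, table.n_features // 2, train_tab.n_samples - 1),
        hidden_dim=max(50, table.n_features // 2),
        batch_size=128,
        epochs=min(50, config.vae.get("epochs", 50)),
        seed=seed,
    )
    beta_rep = calibration.select_beta(train_tab, config.beta_grid, cfg, seed=seed)
    lam_rep = calibration.select_lambda(
        train_tab, config.lambda_grid,
        replace(cfg, variant="mmd"), seed=seed,
    )
    payload = {"beta": beta_rep.to_json_dict(), "lambda": lam_rep.to_json_dict()}
    (outdir / "calibration.json").write_text(json.dumps(payload, indent=2))
    state["calibration"] = payload
    config.vae.setdefault("beta", beta_rep.selected)
    config.vae.setdefault("lam", lam_rep.selected)
    manifest["outputs"]["calibration"] = "calibration.json"


def _stage_train(config, state, outdir, manifest) -> None:
    table = state["processed"]
    split = state["split"]
    train_tab = table.subset(split.indices("train"))
    val_tab = table.subset(split.indices("validation"))
    models = {}
    for variant in config.variants:
        cfg = config.vae_config(variant, table.n_features)
        model = train_vae(train_tab, val_tab if val_tab.n_samples else None, cfg)
        model.history.to_csv(outdir / f"history_{variant}.csv", index=False)
        models[variant] = model
    state["models"] = models
    manifest["outputs"]["histories"] = [f"history_{v}.csv" for v in config.variants]


def _stage_interpret(config, state, outdir, manifest) -> None:
    table = state["processed"]
    descriptors = table.descriptors()
    for variant, model in state["models"].items():
        cm = contribution_matrix(model, descriptors)
        cm.to_frame().to_csv(outdir / f"contributions_{variant}.csv")
    manifest["outputs"]["contributions"] = [
        f"contributions_{v}.csv" for v in state["models"]
    ]


def _stage_lsa(config, state, outdir, manifest) -> None:
    table = state["processed"]
    groups = lsa.build_moa_groups(table)
    (outdir / "lsa_filter_report.json").write_text(
        json.dumps(groups.filter_report, indent=2)
    )
    results: dict[str, list] = {}
    nulls: dict[str, dict] = {}
    seed = stage_seed(config.seed, "lsa")
    for variant, model in state["models"].items():
        results[variant] = lsa.run_lsa(model, table, groups)
        nulls[variant] = lsa.null_significance(
            model, table, groups, n_shuffles=config.n_shuffles, seed=seed
        )
    for tag, res in lsa.run_baselines(table, groups, k=config.pca_components).items():
        results[tag] = res
    frame = lsa.results_frame(results, nulls)
    frame.to_csv(outdir / "lsa_results.csv", index=False)
    state["lsa_results"] = frame
    state["lsa_nulls"] = nulls
    manifest["outputs"]["lsa_results"] = "lsa_results.csv"


def _stage_evaluate(config, state, outdir, manifest) -> None:
    table = state["processed"]
    split = state["split"]
    test_tab = table.subset(split.indices("test"))
    if test_tab.n_samples == 0:
        test_tab = table
    rows = []
    for variant, model in state["models"].items():
        rep = evaluation.reconstruction_metrics(model, test_tab, dataset_tag=table.level)
        rows.append(rep.to_dict())
        evaluation.export_latent_diagnostics(
            model, table, csv_path=outdir / f"latent_correlation_{variant}.csv"
        )
    pd.DataFrame(rows).to_csv(outdir / "reconstruction_metrics.csv", index=False)
    manifest["outputs"]["reconstruction_metrics"] = "reconstruction_metrics.csv"


_STAGE_FUNCS = {
    "data": _stage_data,
    "process": _stage_process,
    "calibrate": _stage_calibrate,
    "train": _stage_train,
    "interpret": _stage_interpret,
    "lsa": _stage_lsa,
    "evaluate": _stage_evaluate,
}
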