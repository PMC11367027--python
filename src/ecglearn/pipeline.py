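"""End-to-end orchestration: generate -> preprocess -> train BiLSTM ->
extract -> DFA-tune -> train SSAE -> evaluate.

Every stage reads and writes disk artifacts under one output directory, so
``run_all`` and the chained CLI subcommands produce identical results for
the same config and seed.  Stage seeds are derived from the global seed by
fixed offsets; reports are deterministic given (config, seed).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bilstm as _bilstm
from . import dataio, dfa, evaluation, ssae, synthetic

log = logging.getLogger("ecglearn")

#: Fixed per-stage seed offsets (global seed + offset).
SEED_OFFSETS = {
    "generate": 11, "split": 13, "bilstm": 17, "tune": 19,
    "ssae": 23, "eval": 29,
}

DEFAULT_CONFIG: dict = {
    "data": {
        "preset": "tiny",
        "n_records": None,          # overrides the preset when set
        "n_null_labels": None,
        "sampling_rate": 100,
        "train_fraction": 0.8,
    },
    "bilstm": {
        "hidden_size": 32,
        "stride": 10,
        "epochs": 50,
        "batch_size": 7,
        "dropout": 0.5,
        "standardize": True,
    },
    "adamax": {
        "eta": 0.1,
        "beta1": 0.9,
        "beta2": 0.999,
        "epsilon": 1e-8,
    },
    "ssae": {
        "epochs": 20,
        "finetune": True,
        "threshold": 0.5,
    },
    "dfa": {
        "enabled": True,
        "pop_size": 6,
        "iterations": 8,
        "fitness_epochs": 5,
        "val_fraction": 0.2,
    },
    "eval": {
        "positive_label": "present",
        "cv_folds": 0,              # 0 = holdout on the test split
    },
}


@dataclass
class PipelineConfig:
    """Validated nested configuration plus the global seed."""

    sections: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))
    seed: int = 0

    def __getitem__(self, key: str) -> dict:
        return self.sections[key]

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + SEED_OFFSETS[stage]

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "PipelineConfig":
        raw = copy.deepcopy(raw or {})
        cfg_seed = raw.pop("seed", 0)
        merged = copy.deepcopy(DEFAULT_CONFIG)
        for section, values in raw.items():
            if section not in merged:
                raise ConfigError(f"unknown config section {section!r}")
            if not isinstance(values, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            for key, val in values.items():
                if key not in merged[section]:
                    raise ConfigError(f"unknown key {section}.{key}")
                merged[section][key] = val
        return cls(sections=merged, seed=cfg_seed if seed is None else seed)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw, seed=seed)

    def to_dict(self) -> dict:
        return {"seed": int(self.seed), **copy.deepcopy(self.sections)}


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# Artifact paths and logging helpers
# ---------------------------------------------------------------------------

def _paths(out: Path) -> dict[str, Path]:
    return {
        "raw": out / "dataset_raw",
        "clean": out / "dataset",
        "split": out / "split.json",
        "extractor": out / "extractor",
        "bilstm_history": out / "bilstm_history.csv",
        "features": out / "features.npz",
        "hyperparams": out / "hyperparams.json",
        "dfa_history": out / "dfa_history.csv",
        "classifier": out / "classifier",
        "report_json": out / "report.json",
        "report_csv": out / "report.csv",
        "log": out / "pipeline_log.jsonl",
    }


def _hash_path(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    elif path.is_file():
        h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _log_stage(out: Path, stage: str, seed: int, elapsed: float,
               inputs: list[Path], outputs: list[Path]) -> None:
    entry = {
        "stage": stage, "seed": seed, "wall_time_s": round(elapsed, 3),
        "inputs": {p.name: _hash_path(p) for p in inputs if p.exists()},
        "outputs": {p.name: _hash_path(p) for p in outputs if p.exists()},
    }
    with open(_paths(out)["log"], "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    log.info("stage %s done in %.2fs", stage, elapsed)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"stage {stage!r}: missing upstream artifact {path}")
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _generator_config(config: PipelineConfig) -> synthetic.GeneratorConfig:
    data = config["data"]
    gen = synthetic.preset_config(data["preset"], seed=config.stage_seed("generate"))
    if data["n_records"] is not None:
        gen.n_records = int(data["n_records"])
    if data["n_null_labels"] is not None:
        gen.n_null_labels = int(data["n_null_labels"])
    return gen


def stage_generate(config: PipelineConfig, out: Path) -> Path:
    t0 = time.perf_counter()
    p = _paths(out)
    ds = synthetic.generate_dataset(_generator_config(config))
    dataio.write_dataset(ds, p["raw"])
    _log_stage(out, "generate", config.stage_seed("generate"),
               time.perf_counter() - t0, [], [p["raw"]])
    return p["raw"]


def stage_preprocess(config: PipelineConfig, out: Path) -> Path:
    t0 = time.perf_counter()
    p = _paths(out)
    ds = dataio.read_dataset(_require(p["raw"], "preprocess"))
    n_before = len(ds)
    ds = dataio.filter_null_labels(ds)
    ds = dataio.select_sampling_rate(ds, int(config["data"]["sampling_rate"]))
    log.info("preprocess: %d -> %d records after null-label filter",
             n_before, len(ds))
    dataio.write_dataset(ds, p["clean"])
    _log_stage(out, "preprocess", config.seed, time.perf_counter() - t0,
               [p["raw"]], [p["clean"]])
    return p["clean"]


def _load_split(config: PipelineConfig, out: Path):
    p = _paths(out)
    ds = dataio.read_dataset(_require(p["clean"], "split"))
    if p["split"].exists():
        ids = json.loads(p["split"].read_text())
        train_ids = set(ids["train"])
        tr = [r for r in ds.records if r.record_id in train_ids]
        te = [r for r in ds.records if r.record_id not in train_ids]
        train = dataio.Dataset(tr, ds.vocabulary, dict(ds.provenance))
        test = dataio.Dataset(te, ds.vocabulary, dict(ds.provenance))
    else:
        train, test = synthetic.split_dataset(
            ds, float(config["data"]["train_fraction"]),
            config.stage_seed("split"))
        p["split"].write_text(json.dumps({
            "train": [r.record_id for r in train.records],
            "test": [r.record_id for r in test.records],
        }, indent=0))
    return train, test


def stage_train_bilstm(config: PipelineConfig, out: Path) -> Path:
    t0 = time.perf_counter()
    p = _paths(out)
    train, _ = _load_split(config, out)
    bl = config["bilstm"]
    extractor = _bilstm.BiLSTMExtractor.create(
        n_leads=train.records[0].n_leads, hidden_size=int(bl["hidden_size"]),
        n_classes=len(train.vocabulary), stride=int(bl["stride"]),
        standardize=bool(bl["standardize"]), seed=config.stage_seed("bilstm"))
    labels = dataio.encode_labels(train)
    extractor, history = _bilstm.train_bilstm(
        extractor, train, labels, epochs=int(bl["epochs"]),
        batch_size=int(bl["batch_size"]), dropout=float(bl["dropout"]),
        adamax_config=dict(config["adamax"]), seed=config.stage_seed("bilstm"))
    _bilstm.save_extractor(extractor, p["extractor"])
    import pandas as pd

    pd.DataFrame({"epoch": range(1, len(history) + 1),
                  "loss": history}).to_csv(p["bilstm_history"], index=False)
    _log_stage(out, "train-bilstm", config.stage_seed("bilstm"),
               time.perf_counter() - t0, [p["clean"]],
               [p["extractor"], p["bilstm_history"]])
    return p["extractor"]


def stage_extract(config: PipelineConfig, out: Path) -> Path:
    t0 = time.perf_counter()
    p = _paths(out)
    extractor = _bilstm.load_extractor(_require(p["extractor"], "extract"))
    train, test = _load_split(config, out)
    np.savez_compressed(
        p["features"],
        train=_bilstm.extract_features(extractor, train),
        test=_bilstm.extract_features(extractor, test),
        train_labels=dataio.encode_labels(train),
        test_labels=dataio.encode_labels(test))
    _log_stage(out, "extract", config.seed, time.perf_counter() - t0,
               [p["extractor"], p["clean"]], [p["features"]])
    return p["features"]


def stage_tune(config: PipelineConfig, out: Path) -> Path:
    t0 = time.perf_counter()
    p = _paths(out)
    dcfg = config["dfa"]
    with np.load(_require(p["features"], "tune")) as npz:
        X, Y = npz["train"], npz["train_labels"]
    if not dcfg["enabled"]:
        best = {"size1": 64, "size2": 32, "rho": 0.05, "beta": 3.0,
                "eta": float(config["adamax"]["eta"])}
        history = []
        best_fit = float("nan")
    else:
        rng = np.random.default_rng(config.stage_seed("tune"))
        n = X.shape[0]
        n_val = max(1, int(round(float(dcfg["val_fraction"]) * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        best, best_fit, history = dfa.tune_ssae(
            X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx],
            pop_size=int(dcfg["pop_size"]), iterations=int(dcfg["iterations"]),
            seed=config.stage_seed("tune"),
            fitness_epochs=int(dcfg["fitness_epochs"]))
    p["hyperparams"].write_text(json.dumps(
        {"best": best, "best_fitness": best_fit}, indent=1, sort_keys=True))
    dfa.write_history_csv(history, p["dfa_history"])
    _log_stage(out, "tune", config.stage_seed("tune"), time.perf_counter() - t0,
               [p["features"]], [p["hyperparams"], p["dfa_history"]])
    return p["hyperparams"]


def stage_train_ssae(config: PipelineConfig, out: Path) -> Path:
    t0 = time.perf_counter()
    p = _paths(out)
    hp = json.loads(_require(p["hyperparams"], "train-ssae").read_text())["best"]
    scfg = config["ssae"]
    with np.load(_require(p["features"], "train-ssae")) as npz:
        X, Y = npz["train"], npz["train_labels"]
    l1, l2, _ = ssae.pretrain_stack(
        X, sizes=(hp["size1"], hp["size2"]), rho=hp["rho"], beta=hp["beta"],
        epochs=int(scfg["epochs"]), adamax_config={"eta": hp["eta"]},
        seed=config.stage_seed("ssae"))
    clf = ssae.fit_classifier(
        (l1, l2), X, Y, epochs=int(scfg["epochs"]),
        adamax_config={"eta": hp["eta"]}, seed=config.stage_seed("ssae") + 1,
        finetune=bool(scfg["finetune"]), rho=hp["rho"], beta=hp["beta"],
        threshold=float(scfg["threshold"]))
    ssae.save_classifier(clf, p["classifier"])
    _log_stage(out, "train-ssae", config.stage_seed("ssae"),
               time.perf_counter() - t0, [p["features"], p["hyperparams"]],
               [p["classifier"]])
    return p["classifier"]


def stage_evaluate(config: PipelineConfig, out: Path) -> evaluation.EvalReport:
    t0 = time.perf_counter()
    p = _paths(out)
    clf = ssae.load_classifier(_require(p["classifier"], "evaluate"))
    with np.load(_require(p["features"], "evaluate")) as npz:
        X, Y = npz["test"], npz["test_labels"]
    scores, pred = ssae.predict(clf, X)
    report = evaluation.evaluate_predictions(
        Y, pred, scores, dataio.DEFAULT_VOCABULARY,
        positive_label=str(config["eval"]["positive_label"]))
    report.extra["n_test"] = int(Y.shape[0])
    report.extra["error_rate_pct"] = dfa.classifier_error_rate(Y, pred)
    k = int(config["eval"]["cv_folds"])
    if k > 1:
        report.extra["cv"] = _crossval_metrics(config, out, k)
    evaluation.write_report_json(report, p["report_json"])
    evaluation.write_metrics_csv(report, p["report_csv"])
    _log_stage(out, "evaluate", config.stage_seed("eval"),
               time.perf_counter() - t0, [p["classifier"], p["features"]],
               [p["report_json"], p["report_csv"]])
    return report


def _crossval_metrics(config: PipelineConfig, out: Path, k: int) -> dict:
    """k-fold CV over the SSAE stage on the training features.

    Emits both pooled (confusions summed over folds) and fold-averaged macro
    metrics, since printed tables rarely say which convention they use.
    """
    p = _paths(out)
    hp = json.loads(p["hyperparams"].read_text())["best"]
    scfg = config["ssae"]
    with np.load(p["features"]) as npz:
        X, Y = npz["train"], npz["train_labels"]
    folds = evaluation.kfold_plan(X.shape[0], k, seed=config.stage_seed("eval"))
    pooled_true, pooled_pred = [], []
    fold_macros = []
    for fold in range(k):
        te = folds == fold
        l1, l2, _ = ssae.pretrain_stack(
            X[~te], sizes=(hp["size1"], hp["size2"]), rho=hp["rho"],
            beta=hp["beta"], epochs=int(scfg["epochs"]),
            adamax_config={"eta": hp["eta"]},
            seed=config.stage_seed("ssae") + fold)
        clf = ssae.fit_classifier(
            (l1, l2), X[~te], Y[~te], epochs=int(scfg["epochs"]),
            adamax_config={"eta": hp["eta"]},
            seed=config.stage_seed("ssae") + 100 + fold,
            finetune=bool(scfg["finetune"]), rho=hp["rho"], beta=hp["beta"])
        _, pred = ssae.predict(clf, X[te])
        pooled_true.append(Y[te])
        pooled_pred.append(pred)
        rep = evaluation.evaluate_predictions(
            Y[te], pred, None, dataio.DEFAULT_VOCABULARY,
            positive_label=str(config["eval"]["positive_label"]))
        fold_macros.append(rep.macro)
    pooled = evaluation.evaluate_predictions(
        np.concatenate(pooled_true), np.concatenate(pooled_pred), None,
        dataio.DEFAULT_VOCABULARY,
        positive_label=str(config["eval"]["positive_label"]))
    from dataclasses import asdict

    return {
        "k": k,
        "pooled_macro": asdict(pooled.macro),
        "fold_mean_macro": asdict(evaluation.macro_average(fold_macros)),
    }


_STAGES = (
    ("generate", stage_generate),
    ("preprocess", stage_preprocess),
    ("train-bilstm", stage_train_bilstm),
    ("extract", stage_extract),
    ("tune", stage_tune),
    ("train-ssae", stage_train_ssae),
    ("evaluate", stage_evaluate),
)


def run_all(config: PipelineConfig, out: str | Path) -> evaluation.EvalReport:
    """Execute every stage in order; returns the final report.

    On a stage failure the partial artifacts are retained and a
    :class:`StageError` naming the stage is raised.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    result = None
    for name, fn in _STAGES:
        try:
            result = fn(config, out)
        except (StageError, ConfigError):
            raise
        except Exception as exc:  # noqa: BLE001 - stage isolation boundary
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    return result
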