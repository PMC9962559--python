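"""End-to-end experiment driver: simulate -> label -> train -> evaluate.

Runs the repeated-training protocol: one synthetic dataset, then
``n_repetitions`` independent training sessions, each with its own
seeded stratified split and random initialization, aggregated into a
median/IQR report.  Two evaluation protocols are provided:

``split``
    honest held-out evaluation on each repetition's disjoint test split
    (the default);
``paper_protocol``
    each repetition is evaluated on the full labeled dataset, which
    reproduces the support arithmetic of instrument-scale studies where
    every labeled sample is scored by every trained model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import __version__
from .cnn import (ModelConfig, TrainedModel, predict, predict_proba,
                  preprocess, train)
from .curves import read_curve
from .errors import InvalidInputError
from .evaluation import EvalReport, aggregate_repetitions, evaluate, report_table
from .simulate import (AcquisitionConfig, PfgseConfig, SampleRecord,
                       generate_dataset, write_dataset)

logger = logging.getLogger("oxirelax")

#: Class mix proportional to a 126/77/187 (Good/Fair/Bad) labeled corpus.
REFERENCE_MIX = (126 / 390, 77 / 390, 187 / 390)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a repeated-training experiment."""

    n_samples: int = 600
    class_mix: tuple = REFERENCE_MIX
    acq: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    pfgse: PfgseConfig = field(default_factory=PfgseConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    labeling_policy: str = "worst_case"
    n_repetitions: int = 30
    split: tuple = (0.70, 0.15, 0.15)   # train / validation / test
    protocol: str = "split"             # or "paper_protocol"
    master_seed: int = 0

    def __post_init__(self):
        if self.n_repetitions < 1:
            raise InvalidInputError("n_repetitions must be >= 1")
        if not np.isclose(sum(self.split), 1.0):
            raise InvalidInputError("split fractions must sum to 1")
        if self.protocol not in ("split", "paper_protocol"):
            raise InvalidInputError(f"unknown protocol {self.protocol!r}")


def stratified_split(y: np.ndarray, fractions, seed: int):
    """Indices of a stratified train/validation/test split."""
    idx = np.arange(y.size)
    f_train, f_val, f_test = fractions
    idx_trval, idx_test = train_test_split(
        idx, test_size=f_test, stratify=y, random_state=int(seed) % (2**32))
    rel_val = f_val / (f_train + f_val)
    idx_train, idx_val = train_test_split(
        idx_trval, test_size=rel_val, stratify=y[idx_trval],
        random_state=(int(seed) + 1) % (2**32))
    return idx_train, idx_val, idx_test


def _dataset_arrays(records: list[SampleRecord], target_len: int):
    X = np.stack([preprocess(r.curve, target_len) for r in records])
    y = np.array([int(r.true_class) for r in records], dtype=np.int64)
    return X, y


def run_session(
    X: np.ndarray, y: np.ndarray, model_cfg: ModelConfig,
    split=(0.70, 0.15, 0.15), seed: int = 0, protocol: str = "split",
) -> tuple[TrainedModel, EvalReport]:
    """One seeded training session: split, train, evaluate."""
    idx_train, idx_val, idx_test = stratified_split(y, split, seed)
    cfg = dataclasses.replace(model_cfg, seed=int(seed))
    model = train(X[idx_train], y[idx_train], cfg,
                  validation=(X[idx_val], y[idx_val]))
    eval_idx = np.arange(y.size) if protocol == "paper_protocol" else idx_test
    probs = predict_proba(model, X[eval_idx])
    pred = probs.argmax(axis=1)
    report = evaluate(y[eval_idx], pred)
    return model, report


def run_reference_benchmark(
    master_seed: int = 0,
    n_samples: int = 600,
    epochs: int = 210,
    model_cfg: ModelConfig | None = None,
) -> EvalReport:
    """One full held-out benchmark session at the default study conditions.

    Generates ``n_samples`` labeled synthetic curves with the reference
    class mix, splits 70/15/15 stratified, trains the default dilated CNN
    for ``epochs`` epochs and scores the held-out test split.  All
    randomness derives from ``master_seed``.
    """
    cfg = dataclasses.replace(model_cfg or ModelConfig(), epochs=epochs)
    rng = np.random.default_rng(master_seed)
    data_seed = int(rng.integers(0, 2**31 - 1))
    session_seed = int(rng.integers(0, 2**31 - 1))
    records = generate_dataset(n_samples, REFERENCE_MIX, seed=data_seed)
    X, y = _dataset_arrays(records, cfg.target_len)
    _, report = run_session(X, y, cfg, (0.70, 0.15, 0.15), session_seed)
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> EvalReport:
    """Run the full repeated-training experiment and write all artifacts.

    Writes the dataset (curves + manifest), one model directory and
    report per repetition, the aggregate report (JSON), a tabular
    summary (CSV), and a run manifest listing every artifact with its
    SHA-256 checksum, the seeds used, and the package version.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cfg_json = json.dumps(_config_dict(cfg), indent=1, sort_keys=True)
        (out_dir / "experiment_config.json").write_text(cfg_json)
        cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()
        logger.info("oxirelax %s; config sha256 %s; master seed %d",
                    __version__, cfg_hash, cfg.master_seed)

        rng = np.random.default_rng(cfg.master_seed)
        data_seed = int(rng.integers(0, 2**31 - 1))
        rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=cfg.n_repetitions)]
        logger.info("dataset seed %d; repetition seeds %s", data_seed, rep_seeds)

        records = generate_dataset(cfg.n_samples, cfg.class_mix, cfg.acq,
                                   cfg.pfgse, seed=data_seed)
        write_dataset(records, out_dir / "dataset")
        X, y = _dataset_arrays(records, cfg.model.target_len)

        reports = []
        for i, seed in enumerate(rep_seeds):
            model, report = run_session(X, y, cfg.model, cfg.split, seed, cfg.protocol)
            rep_dir = out_dir / f"rep{i:02d}"
            model.save(rep_dir)
            (rep_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
            logger.info("repetition %d (seed %d): accuracy %.4f, weighted F1 %.4f",
                        i, seed, report.accuracy, report.weighted_avg_f1)
            reports.append(report)

        agg = aggregate_repetitions(reports)
        (out_dir / "aggregate_report.json").write_text(json.dumps(agg.to_dict(), indent=1))
        report_table(agg).to_csv(out_dir / "aggregate_table.csv")

        artifacts = sorted(p for p in out_dir.rglob("*")
                           if p.is_file() and p.name != "run_manifest.json"
                           and p.name != "run.log")
        manifest = {
            "package_version": __version__,
            "config_sha256": cfg_hash,
            "master_seed": cfg.master_seed,
            "dataset_seed": data_seed,
            "repetition_seeds": rep_seeds,
            "artifacts": {str(p.relative_to(out_dir)): _sha256(p) for p in artifacts},
        }
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("aggregate: accuracy %.4f, weighted F1 %.4f, total tests %d",
                    agg.accuracy, agg.weighted_avg_f1, agg.total_tests)
        return agg
    finally:
        logger.removeHandler(handler)
        handler.close()


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["class_mix"] = list(cfg.class_mix)
    return json.loads(json.dumps(d, default=list))


def classify_workflow(curve_file: str | Path, model_dir: str | Path) -> dict:
    """Classify one curve file with a saved model; returns the JSON verdict."""
    curve = read_curve(curve_file)
    model = TrainedModel.load(model_dir)
    label, prob = predict(model, curve)
    return {
        "sample_id": Path(curve_file).stem,
        "class": label,
        "probability": round(prob, 6),
        "model_version": __version__,
    }
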