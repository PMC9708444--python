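"""End-to-end experiment wiring: decoys -> tables -> features -> model -> report.

`run_pipeline` reproduces the whole training/evaluation workflow at desk
scale on synthetic decoy sets: generate a benchmark, learn preference
tables from the training-split natives, extract the 19-feature descriptor
for every structure, train the MLP on the training targets (natives enter
with target 1.0), score the held-out targets and evaluate with the
CASP-style metrics.  Every artifact lands in ``config.out_dir``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoygen import DEFAULT_DIHEDRAL_GRID, generate_benchmark
from .evaluation import DecoySet, EvaluationReport, evaluate_method
from .features import FEATURE_NAMES, extract_features
from .qa_model import ModelConfig, QAModel, save_model, train
from .tables import build_preference_tables

logger = logging.getLogger("protqa")


@dataclasses.dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "protqa_run"
    seed: int = 0
    n_targets: int = 20
    decoys_per_target: int = 30
    noise_grid: tuple[float, ...] = DEFAULT_DIHEDRAL_GRID
    noise_mode: str = "dihedral"
    length_range: tuple[int, int] = (50, 120)
    train_fraction: float = 0.65
    bin_width: float = 20.0
    pseudocount: float = 1.0
    gdt_convention: str = "conventional"
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)

    @classmethod
    def quick(cls, out_dir: str = "protqa_quick", seed: int = 0) -> "RunConfig":
        """A small profile that still satisfies the minimum training size."""
        return cls(out_dir=out_dir, seed=seed, n_targets=8,
                   decoys_per_target=20, length_range=(50, 60))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["noise_grid"] = list(self.noise_grid)
        d["length_range"] = list(self.length_range)
        d["model"]["hidden_layers"] = list(self.model.hidden_layers)
        Path(path).write_text(yaml.safe_dump({"protqa": d}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())["protqa"]
        model = d.pop("model", {})
        if "hidden_layers" in model:
            model["hidden_layers"] = tuple(model["hidden_layers"])
        d["noise_grid"] = tuple(d.get("noise_grid", DEFAULT_DIHEDRAL_GRID))
        d["length_range"] = tuple(d.get("length_range", (50, 120)))
        return cls(model=ModelConfig(**model), **d)


def features_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["target_id", "model_id", "observed_gdt",
                                       *FEATURE_NAMES])


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """Execute the full workflow; returns the held-out evaluation report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    config.to_yaml(out / "config.yaml")
    logger.info("protqa %s: run config written to %s", __version__, out / "config.yaml")

    def stage(name: str, start: float) -> float:
        now = time.perf_counter()
        logger.info("[%s] done in %.1f s", name, now - start)
        return now

    t = t0
    bench = generate_benchmark(
        config.n_targets, config.decoys_per_target,
        noise_grid=config.noise_grid, seed=config.seed,
        length_range=config.length_range, mode=config.noise_mode)
    bench.manifest().to_csv(out / "manifest.tsv", sep="\t", index=False)
    t = stage("gen-decoys", t)

    target_ids = sorted(bench.natives)
    n_train = max(2, int(round(config.train_fraction * len(target_ids))))
    train_targets = target_ids[:n_train]
    test_targets = target_ids[n_train:]
    if not test_targets:
        raise ValueError("train fraction leaves no held-out targets")

    tables = build_preference_tables(
        [bench.natives[t_] for t_ in train_targets],
        bin_width=config.bin_width, pseudocount=config.pseudocount)
    tables.save(out / "tables.npz")
    t = stage("build-tables", t)

    rows = []
    for target_id in target_ids:
        native_fv = extract_features(bench.natives[target_id], tables)
        rows.append({"target_id": target_id, "model_id": f"{target_id}_native",
                     "observed_gdt": 1.0, **native_fv.as_dict()})
        for rec in bench.decoys[target_id]:
            fv = extract_features(rec.structure, tables)
            rows.append({"target_id": target_id, "model_id": rec.model_id,
                         "observed_gdt": rec.observed_gdt, **fv.as_dict()})
    frame = features_to_frame(rows)
    frame.to_csv(out / "features.tsv", sep="\t", index=False)
    t = stage("extract-features", t)

    train_mask = frame["target_id"].isin(train_targets)
    X_train = frame.loc[train_mask, list(FEATURE_NAMES)].to_numpy()
    y_train = frame.loc[train_mask, "observed_gdt"].to_numpy()
    model = train(X_train, y_train, config.model)
    save_model(model, out / "model.joblib")
    t = stage("train", t)

    report = evaluate_on_frame(model, frame[frame["target_id"].isin(test_targets)],
                               convention=config.gdt_convention,
                               include_natives=False)
    report.per_target.to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    stage("evaluate", t)
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return report


def evaluate_on_frame(
    model: QAModel,
    frame: pd.DataFrame,
    convention: str = "conventional",
    include_natives: bool = True,
) -> EvaluationReport:
    """Score a feature frame with a trained model and evaluate per target."""
    if not include_natives:
        frame = frame[~frame["model_id"].str.endswith("_native")]
    sets = []
    for target_id, grp in frame.groupby("target_id"):
        pred = model.predict(grp[list(FEATURE_NAMES)].to_numpy())
        sets.append(DecoySet(
            target_id=str(target_id),
            model_ids=grp["model_id"].tolist(),
            predicted=pred,
            observed=grp["observed_gdt"].to_numpy()))
    return evaluate_method(sets, convention=convention)
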