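"""End-to-end modeling workflow: descriptors -> split -> fit -> validate.

``run_pipeline`` ties the library together the way the skin-permeability
study proceeds: compute (or take tabulated) descriptors, Kennard-Stone split,
fit an MLR or epsilon-SVR model on the training partition, predict the test
partition and score it with rms/R² and the Golbraikh-Tropsha battery.  All
artifacts are plain CSV/JSON and byte-reproducible for a fixed config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import dataset as ds_mod
from . import mlr as mlr_mod
from . import svr as svr_mod
from . import validation as val_mod

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

# stage-named exit codes for the CLI
STAGE_EXIT_CODES = {"read": 3, "descriptors": 4, "split": 5, "fit": 6, "validate": 7}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one modeling run."""

    input_path: str
    output_dir: str
    model: str = "mlr"  # "mlr" | "svr" | a published equation id
    n_train: Optional[int] = None  # default: round(139/274 * n)
    svr_c: float = 7.2906
    svr_gamma: float = 1.7200
    svr_epsilon: float = 0.001
    tune: bool = False
    ga: svr_mod.GaConfig = field(default_factory=svr_mod.GaConfig)
    compute_descriptors: bool = False
    seed: int = 0

    def effective_n_train(self, n: int) -> int:
        if self.n_train is not None:
            return self.n_train
        return max(2, round(n * 139 / 274))


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full workflow; returns a summary dict of the written artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        data = ds_mod.read_table(cfg.input_path)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc

    if cfg.compute_descriptors or not data.has_descriptors:
        try:
            data = data.compute_descriptors()
        except Exception as exc:
            raise PipelineError("descriptors", str(exc)) from exc
    ds_mod.write_table(data, out / "descriptors.csv")

    try:
        n_train = cfg.effective_n_train(len(data))
        data, split = ds_mod.assign_split(data, n_train)
    except Exception as exc:
        raise PipelineError("split", str(exc)) from exc
    ds_mod.write_table(data, out / "split.csv")

    train = data.subset("train")
    test = data.subset("test")
    X_train = train.descriptor_matrix()
    y_train = train.endpoint()
    X_test = test.descriptor_matrix()
    y_test = test.endpoint()

    try:
        if cfg.model == "mlr":
            fit = mlr_mod.ols_fit(X_train, y_train, names=ds_mod.MODEL_DESCRIPTORS)
            _write_json(out / "fit.json", fit.as_dict())
            predict = fit.predict
        elif cfg.model == "svr":
            c, gamma = cfg.svr_c, cfg.svr_gamma
            if cfg.tune:
                c, gamma, history = svr_mod.ga_optimize(X_train, y_train, cfg.ga)
                np.savetxt(out / "tune_history.csv",
                           np.column_stack([np.arange(len(history)), history]),
                           delimiter=",", header="generation,best_cv_mse", comments="")
            model = svr_mod.train_svr(X_train, y_train, C=c, gamma=gamma,
                                      epsilon=cfg.svr_epsilon)
            (out / "model.json").write_text(model.to_json() + "\n")
            predict = model.predict
        elif cfg.model in mlr_mod.PUBLISHED_EQUATIONS:
            eq = mlr_mod.PUBLISHED_EQUATIONS[cfg.model]

            def predict(X, _eq=eq):
                X = np.atleast_2d(np.asarray(X, dtype=float))
                return np.array([
                    _eq.predict(dict(zip(ds_mod.MODEL_DESCRIPTORS, row))) for row in X
                ])
        else:
            raise ValueError(f"unknown model {cfg.model!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    try:
        pred_train = np.asarray(predict(X_train)).ravel()
        pred_test = np.asarray(predict(X_test)).ravel()
        rms_train, r2_train = val_mod.rms_r2(y_train, pred_train)
        rms_test, r2_test = val_mod.rms_r2(y_test, pred_test)
        y_all = np.concatenate([y_train, y_test])
        pred_all = np.concatenate([pred_train, pred_test])
        rms_total, r2_total = val_mod.rms_r2(y_all, pred_all)
        gt = val_mod.golbraikh_tropsha(y_test, pred_test, float(y_train.mean()))
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc

    report = {
        "model": cfg.model,
        "n_train": len(y_train),
        "n_test": len(y_test),
        "train": {"rms": rms_train, "r2": r2_train},
        "test": {"rms": rms_test, "r2": r2_test},
        "total": {"rms": rms_total, "r2": r2_total},
        "golbraikh_tropsha": gt.as_dict(),
    }
    _write_json(out / "validation.json", report)

    pred_frame = data.frame.loc[:, ["id", "smiles", "split", "logkp"]].copy()
    preds = np.empty(len(data))
    preds[list(split.train_indices)] = pred_train
    preds[list(split.test_indices)] = pred_test
    pred_frame["logkp_pred"] = preds
    pred_frame["residual"] = pred_frame["logkp"] - pred_frame["logkp_pred"]
    pred_frame.to_csv(out / "predictions.csv", index=False)
    return report
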