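"""Binary-relevance one-vs-rest SVM banks with calibrated probabilities.

Each sub-classifier standardizes its (SDA-selected) feature subset and fits
seven RBF-kernel SVMs, one per class against the pooled rest, each wrapped
in Platt sigmoid calibration so the outputs are per-class probabilities (a
7-D confidence vector; entries need not sum to 1).  Five such banks — one
per abstract tap (H1, H2, H3, G) concatenated with the shallow block, plus
a shallow-only bank — make up the multi-classifier stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import NUM_CLASSES
from .fusion import SdaResult, concat_features, sda_select
from .harnet import TAP_ORDER

SUBPREDICTOR_ORDER = ("h1_s", "h2_s", "h3_s", "g_s", "s")


class TrainingError(ValueError):
    pass


@dataclass
class BrConfig:
    C: float = 1.0
    gamma: str = "scale"  # 1 / (p * var)
    calibration_folds: int = 3
    standardize: bool = True
    seed: int = 0


@dataclass
class BrModel:
    """Seven calibrated OvR scorers over a standardized feature subset."""

    scorers: list
    scaler: StandardScaler
    feature_subset: SdaResult
    config: BrConfig

    def _prepare(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_subset is not None:
            X = X[:, self.feature_subset.selected]
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X


def fit_br(X, y, config: BrConfig = None, feature_subset: SdaResult = None) -> BrModel:
    """Fit the 7-scorer binary-relevance bank on (optionally SDA-sliced) X."""
    config = config or BrConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    present = np.unique(y)
    if set(range(NUM_CLASSES)) - set(present.tolist()):
        raise TrainingError("every class 0..6 must be present in y")
    if feature_subset is not None:
        X = X[:, feature_subset.selected]
    scaler = None
    if config.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    scorers = []
    for cls in range(NUM_CLASSES):
        yb = (y == cls).astype(int)
        base = SVC(C=config.C, kernel="rbf", gamma=config.gamma, random_state=config.seed)
        folds = min(config.calibration_folds, int(yb.sum()), int((1 - yb).sum()))
        clf = CalibratedClassifierCV(base, method="sigmoid", cv=max(2, folds))
        clf.fit(X, yb)
        scorers.append(clf)
    return BrModel(scorers=scorers, scaler=scaler, feature_subset=feature_subset, config=config)


def predict_confidence(model: BrModel, x) -> np.ndarray:
    """7-D calibrated per-class probability vector(s) for sample(s) x."""
    X = model._prepare(x)
    conf = np.column_stack(
        [s.predict_proba(X)[:, list(s.classes_).index(1)] if 1 in s.classes_ else np.zeros(len(X))
         for s in model.scorers]
    )
    return conf[0] if np.asarray(x).ndim == 1 else conf


@dataclass
class SubPredictors:
    """The five fitted banks, keyed 'h1_s', 'h2_s', 'h3_s', 'g_s', 's'."""

    models: dict

    def __len__(self):
        return len(self.models)

    def confidences(self, mvf_arrays, shallow_matrix):
        """Stacked per-bank confidence matrices for a batch of samples.

        ``mvf_arrays`` maps tap name -> (n, width) matrix; ``shallow_matrix``
        is (n, 1096).  Returns dict bank name -> (n, 7).
        """
        out = {}
        for name, model in self.models.items():
            X = _bank_matrix(name, mvf_arrays, shallow_matrix)
            out[name] = predict_confidence(model, X) if X.ndim > 1 else predict_confidence(
                model, X[None, :]
            )
        return out


def _bank_matrix(name, mvf_arrays, shallow_matrix):
    if name == "s":
        return np.asarray(shallow_matrix, dtype=float)
    tap = name[:-2]  # strip "_s"
    return np.hstack([np.asarray(mvf_arrays[tap], dtype=float), shallow_matrix])


def save_br(model: BrModel, out_dir):
    """Write a model bundle: per-scorer joblib files plus ``meta.json``."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, scorer in enumerate(model.scorers):
        joblib.dump(scorer, out / f"scorer_{k}.joblib")
    if model.scaler is not None:
        joblib.dump(model.scaler, out / "scaler.joblib")
    meta = {
        "class_order": list(range(NUM_CLASSES)),
        "subset": None if model.feature_subset is None else {
            "selected": model.feature_subset.selected,
            "lambda_trace": model.feature_subset.lambda_trace,
            "f_enter": model.feature_subset.f_enter,
            "f_remove": model.feature_subset.f_remove,
        },
        "config": asdict(model.config),
        "standardized": model.scaler is not None,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def load_br(bundle_dir) -> BrModel:
    """Load a model bundle written by :func:`save_br`."""
    import json
    from pathlib import Path

    import joblib

    src = Path(bundle_dir)
    meta = json.loads((src / "meta.json").read_text())
    scorers = [joblib.load(src / f"scorer_{k}.joblib") for k in range(NUM_CLASSES)]
    scaler = joblib.load(src / "scaler.joblib") if meta["standardized"] else None
    subset = None
    if meta["subset"] is not None:
        subset = SdaResult(
            selected=meta["subset"]["selected"],
            lambda_trace=meta["subset"]["lambda_trace"],
            f_enter=meta["subset"]["f_enter"],
            f_remove=meta["subset"]["f_remove"],
        )
    return BrModel(
        scorers=scorers, scaler=scaler, feature_subset=subset,
        config=BrConfig(**meta["config"]),
    )


def build_subpredictors(
    mvf_arrays, shallow_matrix, y, br_config: BrConfig = None,
    f_enter=3.84, f_remove=2.71, max_features=None,
) -> SubPredictors:
    """Fit the five sub-classifier banks (abstract-tap + shallow, and shallow-only).

    SDA feature selection runs per bank on the training data only.
    """
    shallow_matrix = np.asarray(shallow_matrix, dtype=float)
    models = {}
    for name in SUBPREDICTOR_ORDER:
        X = _bank_matrix(name, mvf_arrays, shallow_matrix)
        subset = sda_select(X, y, f_enter=f_enter, f_remove=f_remove, max_features=max_features)
        if not subset.selected:  # degenerate: keep every column
            subset = SdaResult(list(range(X.shape[1])), [], f_enter, f_remove)
        models[name] = fit_br(X, y, config=br_config, feature_subset=subset)
    return SubPredictors(models=models)
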