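"""Stratified 10-fold evaluation harness and end-to-end pipeline.

Per outer fold: HARnet is trained on the training split, multi-view
features are extracted, SDA + the five binary-relevance banks are fit, the
ANN stacker is trained on confidences produced *out-of-fold* via an
internal stratified CV over the training split, and only then is the test
fold scored.  No fitted object sees test-fold data (the per-image unmix
basis aside, which is image-local by construction).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import precision_score, recall_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import NUM_CLASSES
from .classifiers import BrConfig, SUBPREDICTOR_ORDER, build_subpredictors
from .decision import (
    DecisionAnnConfig,
    fit_decision_ann,
    mean_rule,
    predict_final,
    stack_confidence_matrices,
)
from .harnet import HarnetConfig, TrainConfig, build_harnet, extract_multiview_batch, train_harnet
from .preprocess import preprocess_image
from .shallow import shallow_vector
from .synthetic import SynthConfig, generate_dataset

log = logging.getLogger("har_locator")


class DegenerateInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# folds and metrics


def kfold_split(labels, k=10, seed=0) -> np.ndarray:
    """Stratified fold id (0..k-1) per sample; each class needs >= k members."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} < k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for fid, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = fid
    return folds


def compute_metrics(y_true, y_pred):
    """Accuracy, macro precision/recall and the 7x7 confusion matrix.

    Per-class precision with an empty prediction column counts as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    for arr in (y_true, y_pred):
        if arr.min() < 0 or arr.max() >= NUM_CLASSES:
            raise ValueError("label outside 0..6")
    cm = np.zeros((NUM_CLASSES, NUM_CLASSES), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    acc = float(np.trace(cm) / cm.sum())
    # macro means over the classes present in the truth; a class that is
    # never predicted contributes precision 0
    labels = np.unique(y_true).tolist()
    prec = float(precision_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))
    rec = float(recall_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))
    return {"accuracy": acc, "precision": prec, "recall": rec, "confusion": cm}


def roc_auc(y_true, scores):
    """Micro-averaged one-vs-rest ROC over all (sample, class) pairs.

    Returns ``(fpr, tpr, auc)``; AUC by the trapezoid rule.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise DegenerateInputError("ROC undefined: only one class present")
    onehot = np.zeros_like(scores)
    onehot[np.arange(len(y_true)), y_true] = 1.0
    fpr, tpr, _ = roc_curve(onehot.ravel(), scores.ravel())
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything the end-to-end cross-validated run needs."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    harnet: HarnetConfig = field(default_factory=HarnetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    br: BrConfig = field(default_factory=BrConfig)
    ann: DecisionAnnConfig = field(default_factory=DecisionAnnConfig)
    k_folds: int = 10
    internal_folds: int = 5
    f_enter: float = 3.84
    f_remove: float = 2.71
    max_features: int = None
    seed: int = 0

    @classmethod
    def tiny(cls, seed=0):
        """70-image, width-reduced preset for single-CPU runs."""
        return cls(
            synth=SynthConfig(n_per_class=10, image_size=128, seed=seed),
            harnet=HarnetConfig.tiny(seed=seed),
            train=TrainConfig(epochs=6, batch_size=8, seed=seed),
            ann=DecisionAnnConfig(epochs=300, seed=seed),
            max_features=40,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path):
        """Build a config from a YAML file of per-section overrides.

        Top-level keys mirror the dataclass fields (``synth``, ``harnet``,
        ``train``, ``br``, ``ann`` as mappings; scalars at the root).  An
        optional ``preset: tiny`` starts from the tiny preset.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        preset = raw.pop("preset", None)
        cfg = cls.tiny(seed=raw.get("seed", 0)) if preset == "tiny" else cls()
        sections = {
            "synth": SynthConfig,
            "harnet": HarnetConfig,
            "train": TrainConfig,
            "br": BrConfig,
            "ann": DecisionAnnConfig,
        }
        for key, value in raw.items():
            if key in sections:
                base = asdict(getattr(cfg, key))
                base.update(value or {})
                setattr(cfg, key, sections[key](**base))
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


@dataclass
class EvalReport:
    pooled: dict
    per_fold: list
    per_class_accuracy: list
    subpredictor_accuracy: dict
    mean_rule_accuracy: float
    auc: float
    roc: dict
    confusion: list
    config: dict
    seconds: float
    y_true: list = field(default_factory=list)
    y_pred: list = field(default_factory=list)

    def to_json(self):
        return json.dumps(
            {
                "pooled": self.pooled,
                "per_fold": self.per_fold,
                "per_class_accuracy": self.per_class_accuracy,
                "subpredictor_accuracy": self.subpredictor_accuracy,
                "mean_rule_accuracy": self.mean_rule_accuracy,
                "auc": self.auc,
                "confusion": self.confusion,
                "config": self.config,
                "seconds": self.seconds,
            },
            indent=2,
        )


def featurize_images(images, input_size, crop=True):
    """Preprocess + shallow-featurize a list of RGB images.

    Returns ``(rgb_resized_list, shallow_matrix)``.
    """
    rgbs, shallow = [], []
    for im in images:
        rgb, pair, _, _ = preprocess_image(im, input_size=input_size, crop=crop)
        rgbs.append(rgb)
        shallow.append(shallow_vector(pair).vector)
    return rgbs, np.vstack(shallow)


def _oof_confidences(mvf, shallow, y, cfg, rng_seed):
    """Out-of-fold stacked confidences over the training split."""
    n = len(y)
    folds = kfold_split(y, k=min(cfg.internal_folds, int(np.bincount(y).min())), seed=rng_seed)
    stacked = np.zeros((n, len(SUBPREDICTOR_ORDER) * NUM_CLASSES))
    for fid in np.unique(folds):
        tr = folds != fid
        te = ~tr
        banks = build_subpredictors(
            {k: v[tr] for k, v in mvf.items()},
            shallow[tr],
            y[tr],
            br_config=cfg.br,
            f_enter=cfg.f_enter,
            f_remove=cfg.f_remove,
            max_features=cfg.max_features,
        )
        conf = banks.confidences({k: v[te] for k, v in mvf.items()}, shallow[te])
        stacked[te] = stack_confidence_matrices(conf)
    return stacked


def run_pipeline(config: PipelineConfig, images=None, labels=None) -> EvalReport:
    """Execute the full cross-validated pipeline and assemble the report.

    With ``images=None`` a synthetic dataset is generated from
    ``config.synth``.
    """
    t0 = time.time()
    if images is None:
        log.info("generating synthetic dataset: %s", config.synth)
        samples = generate_dataset(config.synth)
        images = [s.image for s in samples]
        labels = np.array([s.label for s in samples])
    else:
        labels = np.asarray(labels)

    log.info("preprocessing %d images", len(images))
    rgbs, shallow = featurize_images(images, input_size=config.harnet.input_size)

    folds = kfold_split(labels, k=config.k_folds, seed=config.seed)
    n = len(labels)
    y_pred = np.full(n, -1)
    probs = np.zeros((n, NUM_CLASSES))
    sub_pred = {name: np.full(n, -1) for name in SUBPREDICTOR_ORDER}
    mean_pred = np.full(n, -1)
    per_fold = []

    for fid in range(config.k_folds):
        tr = folds != fid
        te = ~tr
        tr_idx = np.flatnonzero(tr)
        log.info("fold %d: %d train / %d test", fid, tr.sum(), te.sum())

        hcfg = HarnetConfig(**{**asdict(config.harnet), "seed": config.harnet.seed + fid})
        model = build_harnet(hcfg)
        train_harnet(model, [rgbs[i] for i in tr_idx], labels[tr],
                     TrainConfig(**{**asdict(config.train), "seed": config.train.seed + fid}))
        mvf_all = extract_multiview_batch(model, rgbs)
        mvf_tr = {k: v[tr] for k, v in mvf_all.items()}
        mvf_te = {k: v[te] for k, v in mvf_all.items()}

        banks = build_subpredictors(
            mvf_tr, shallow[tr], labels[tr], br_config=config.br,
            f_enter=config.f_enter, f_remove=config.f_remove,
            max_features=config.max_features,
        )
        oof = _oof_confidences(mvf_tr, shallow[tr], labels[tr], config, config.seed + 1000 + fid)
        ann = fit_decision_ann(oof, labels[tr], config.ann)

        conf_te = banks.confidences(mvf_te, shallow[te])
        stacked_te = stack_confidence_matrices(conf_te)
        pred, pr = predict_final(ann, stacked_te)
        y_pred[te] = pred
        probs[te] = pr
        for name in SUBPREDICTOR_ORDER:
            sub_pred[name][te] = np.asarray(conf_te[name]).argmax(axis=1)
        mean_pred[te] = mean_rule(stacked_te)
        fold_m = compute_metrics(labels[te], pred)
        per_fold.append(
            {"fold": fid, "accuracy": fold_m["accuracy"],
             "precision": fold_m["precision"], "recall": fold_m["recall"]}
        )

    pooled = compute_metrics(labels, y_pred)
    cm = pooled.pop("confusion")
    per_class = [float(cm[i, i] / cm[i].sum()) if cm[i].sum() else 0.0 for i in range(NUM_CLASSES)]
    fpr, tpr, auc = roc_auc(labels, probs)
    report = EvalReport(
        pooled=pooled,
        per_fold=per_fold,
        per_class_accuracy=per_class,
        subpredictor_accuracy={
            name: float(np.mean(sub_pred[name] == labels)) for name in SUBPREDICTOR_ORDER
        },
        mean_rule_accuracy=float(np.mean(mean_pred == labels)),
        auc=auc,
        roc={"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        confusion=cm.tolist(),
        y_true=labels.tolist(),
        y_pred=y_pred.tolist(),
        config={
            "k_folds": config.k_folds,
            "seed": config.seed,
            "n_samples": int(n),
            "image_size": config.harnet.input_size,
            "harnet": asdict(config.harnet),
            "train": asdict(config.train),
        },
        seconds=time.time() - t0,
    )
    log.info("pooled accuracy %.3f, AUC %.3f", pooled["accuracy"], auc)
    return report


def write_report(report: EvalReport, out_dir):
    """Write report.json, roc.csv and predictions.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    with open(out / "roc.csv", "w") as fh:
        fh.write("fpr,tpr\n")
        for a, b in zip(report.roc["fpr"], report.roc["tpr"]):
            fh.write(f"{a},{b}\n")
    if report.y_true and report.y_pred:
        with open(out / "predictions.csv", "w") as fh:
            fh.write("sample,true,pred\n")
            for i, (t, p) in enumerate(zip(report.y_true, report.y_pred)):
                fh.write(f"{i},{t},{p}\n")
    return out / "report.json"
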