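"""ANN stacking decision layer over the five 7-D confidence vectors.

The five sub-classifier confidence vectors (order H1_S, H2_S, H3_S, G_S, S)
are concatenated into a 35-D input to a fully connected 35->256->128->64->7
network (ReLU hidden, softmax output, cross-entropy loss).  To avoid
leakage, the stacker should be trained on confidences produced out-of-fold
within the training split (see ``har_locator.evaluate``).  A mean-rule
baseline (average the five blocks, argmax) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier

from . import NUM_CLASSES
from .classifiers import SUBPREDICTOR_ORDER

STACKED_DIM = len(SUBPREDICTOR_ORDER) * NUM_CLASSES  # 35


@dataclass
class DecisionAnnConfig:
    hidden_sizes: tuple = (256, 128, 64)
    epochs: int = 200
    lr: float = 1e-3
    batch_size: int = 32
    seed: int = 0


@dataclass
class DecisionAnn:
    mlp: MLPClassifier
    config: DecisionAnnConfig

    @property
    def hidden_layer_sizes(self):
        return tuple(self.config.hidden_sizes)


def stack_confidences(conf_vectors) -> np.ndarray:
    """Concatenate exactly five 7-D confidence vectors into the 35-D input.

    Accepts a sequence (fixed order H1_S, H2_S, H3_S, G_S, S) or a dict
    keyed by bank name, which is ordered canonically first.
    """
    if isinstance(conf_vectors, dict):
        conf_vectors = [conf_vectors[k] for k in SUBPREDICTOR_ORDER]
    vecs = [np.asarray(v, dtype=float).ravel() for v in conf_vectors]
    if len(vecs) != len(SUBPREDICTOR_ORDER):
        raise ValueError(f"need exactly {len(SUBPREDICTOR_ORDER)} confidence vectors")
    for v in vecs:
        if v.shape != (NUM_CLASSES,):
            raise ValueError("each confidence vector must have length 7")
    return np.concatenate(vecs)


def stack_confidence_matrices(conf_by_bank) -> np.ndarray:
    """(n, 35) stacked matrix from a dict of per-bank (n, 7) matrices."""
    return np.hstack([np.asarray(conf_by_bank[k], dtype=float) for k in SUBPREDICTOR_ORDER])


def fit_decision_ann(X, y, cfg: DecisionAnnConfig = None) -> DecisionAnn:
    """Train the 35->256->128->64->7 stacking network."""
    cfg = cfg or DecisionAnnConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != STACKED_DIM:
        raise ValueError(f"stacked input must be (n, {STACKED_DIM})")
    mlp = MLPClassifier(
        hidden_layer_sizes=tuple(cfg.hidden_sizes),
        activation="relu",
        solver="adam",
        learning_rate_init=cfg.lr,
        max_iter=cfg.epochs,
        batch_size=min(cfg.batch_size, len(X)),
        random_state=cfg.seed,
        alpha=1e-4,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, np.asarray(y))
    return DecisionAnn(mlp=mlp, config=cfg)


def predict_final(model: DecisionAnn, x):
    """Final label (argmax, lowest index on ties) and 7 softmax probabilities."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != STACKED_DIM:
        raise ValueError(f"input width must be {STACKED_DIM}")
    raw = model.mlp.predict_proba(X)
    probs = np.zeros((len(X), NUM_CLASSES))
    for j, cls in enumerate(model.mlp.classes_):
        probs[:, int(cls)] = raw[:, j]
    labels = probs.argmax(axis=1)
    if single:
        return int(labels[0]), probs[0]
    return labels, probs


def mean_rule(stacked) -> np.ndarray:
    """Prior-work baseline: average the five 7-D blocks, argmax the mean."""
    X = np.atleast_2d(np.asarray(stacked, dtype=float))
    blocks = X.reshape(len(X), len(SUBPREDICTOR_ORDER), NUM_CLASSES)
    return blocks.mean(axis=1).argmax(axis=1)
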