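"""Classifier suite: sequence CNN, random forest, logistic regression, and
the ensemble forest that receives the CNN probability as an extra feature.

Protocol: the CNN is trained on the training split with early stopping on
validation loss; the tabular models are then fitted on train+validation
rows and everything is evaluated on the held-out test split.  AUROC is
computed by the rank (Mann-Whitney) statistic with tie correction and
AUPRC by the step-wise precision-recall sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .cnn import CNNSpec, ResidualCNN, TrainConfig, build_cnn, train_cnn
from .dataset import (DEFAULT_FEATURES, GenomicWindow, assign_splits,
                      build_feature_table, encode_batch, extract_sv_windows,
                      sample_background)
from .errors import ConfigurationError

__all__ = ["EvalReport", "ModelBundle", "evaluate", "train_tabular",
           "predict_windows", "train_model_bundle", "train_subclass_suite"]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    auroc: float
    auprc: float
    roc_curve: pd.DataFrame      # columns fpr, tpr, threshold
    pr_curve: pd.DataFrame       # columns recall, precision, threshold
    n_positive: int
    n_negative: int

    def to_dict(self):
        return {"auroc": self.auroc, "auprc": self.auprc,
                "n_positive": self.n_positive, "n_negative": self.n_negative}


def evaluate(probabilities: Sequence[float], labels: Sequence[int]) -> EvalReport:
    """Threshold-free evaluation of binary scores.

    AUROC is the Mann-Whitney U statistic divided by ``n1 * n0`` (ties
    contribute 1/2); AUPRC is the step-wise interpolation
    ``sum((R_i - R_{i-1}) * P_i)`` over descending score thresholds.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if p.shape != y.shape:
        raise ConfigurationError("probabilities and labels must align")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ConfigurationError("need at least one positive and one negative")
    ranks = rankdata(p)                      # average ranks on ties
    auroc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    order = np.argsort(-p, kind="mergesort")
    ys = y[order]
    ps = p[order]
    # collapse tied thresholds: evaluate only at the last index of each tie run
    distinct = np.nonzero(np.diff(ps))[0]
    idx = np.r_[distinct, len(ps) - 1]
    tp = np.cumsum(ys)[idx]
    fp = (idx + 1) - tp
    precision = tp / (tp + fp)
    recall = tp / n1
    fpr = fp / n0
    auprc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    roc = pd.DataFrame({"fpr": np.r_[0.0, fpr], "tpr": np.r_[0.0, recall],
                        "threshold": np.r_[np.inf, ps[idx]]})
    pr = pd.DataFrame({"recall": recall, "precision": precision,
                       "threshold": ps[idx]})
    return EvalReport(float(auroc), auprc, roc, pr, n1, n0)


# ---------------------------------------------------------------------------
# Tabular models
# ---------------------------------------------------------------------------

def train_tabular(features: pd.DataFrame, labels: Sequence[int], kind: str,
                  cnn_probs: Optional[Sequence[float]] = None, seed: int = 42):
    """Fit a forest / linear / ensemble classifier on a feature table.

    The forest uses 1000 trees, balanced class weights, sqrt feature
    subsampling and bootstrap resampling; the linear model is an
    L2-regularised logistic regression on standardised features; the
    ensemble is the same forest with the CNN probability appended as a
    feature column.  Returns a fitted object with ``predict_proba`` over
    feature DataFrames and a ``feature_names`` attribute.
    """
    X = features.to_numpy(dtype=np.float64)
    y = np.asarray(labels)
    names = list(features.columns)
    if kind == "ensemble":
        if cnn_probs is None or len(cnn_probs) != len(features):
            raise ConfigurationError("ensemble requires cnn_probs aligned to rows")
        X = np.column_stack([X, np.asarray(cnn_probs, dtype=np.float64)])
        names = names + ["cnn_probability"]
    if kind in ("forest", "ensemble"):
        model = RandomForestClassifier(
            n_estimators=1000, class_weight="balanced", max_features="sqrt",
            bootstrap=True, random_state=seed, n_jobs=1)
    elif kind == "linear":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        # sklearn's default penalty is the L2 ridge term
        model = make_pipeline(StandardScaler(),
                              LogisticRegression(max_iter=2000,
                                                 random_state=seed))
    else:
        raise ConfigurationError(f"unknown tabular model kind {kind!r}")
    model.fit(X, y)
    model.feature_names = names
    return model


def tabular_proba(model, features: pd.DataFrame,
                  cnn_probs: Optional[Sequence[float]] = None) -> np.ndarray:
    X = features.to_numpy(dtype=np.float64)
    if "cnn_probability" in getattr(model, "feature_names", []):
        if cnn_probs is None:
            raise ConfigurationError("this model needs the cnn_probability column")
        X = np.column_stack([X, np.asarray(cnn_probs, dtype=np.float64)])
    return model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def predict_windows(model: ResidualCNN, windows: Sequence[GenomicWindow | str],
                    batch_size: int = 512) -> np.ndarray:
    """CNN probabilities for raw windows/sequences."""
    return model.predict_proba(encode_batch(windows), batch_size=batch_size)


@dataclass
class ModelBundle:
    cnn: ResidualCNN
    cnn_spec: CNNSpec
    train_config: TrainConfig
    forest: object
    linear: object
    ensemble: object
    history: dict
    feature_names: list[str]
    reports: dict[str, EvalReport]
    test_table: pd.DataFrame = None
    test_cnn_probs: np.ndarray = None


def train_model_bundle(windows: Sequence[GenomicWindow],
                       feature_table: pd.DataFrame,
                       cnn_spec: CNNSpec, train_config: TrainConfig,
                       registry: Sequence[str] = DEFAULT_FEATURES,
                       seed: int = 42) -> ModelBundle:
    """Train all four models on pre-built windows + aligned feature table.

    ``windows`` must already carry split assignments; ``feature_table`` rows
    align 1:1 with windows.
    """
    splits = np.array([w.split for w in windows])
    labels = np.array([1 if w.label == "sv" else 0 for w in windows])
    if set(splits) - {"train", "val", "test"}:
        raise ConfigurationError("all windows need a split assignment")
    enc = encode_batch(windows)
    tr, va, te = (splits == "train"), (splits == "val"), (splits == "test")
    cnn = build_cnn(cnn_spec, seed=seed)
    history = train_cnn(cnn, enc[tr], labels[tr], enc[va], labels[va], train_config)
    cnn_probs = cnn.predict_proba(enc)

    feats = feature_table[list(registry)]
    trva = tr | va
    forest = train_tabular(feats[trva], labels[trva], "forest", seed=seed)
    linear = train_tabular(feats[trva], labels[trva], "linear", seed=seed)
    ensemble = train_tabular(feats[trva], labels[trva], "ensemble",
                             cnn_probs=cnn_probs[trva], seed=seed)

    reports = {
        "cnn": evaluate(cnn_probs[te], labels[te]),
        "forest": evaluate(tabular_proba(forest, feats[te]), labels[te]),
        "linear": evaluate(tabular_proba(linear, feats[te]), labels[te]),
        "ensemble": evaluate(tabular_proba(ensemble, feats[te], cnn_probs[te]),
                             labels[te]),
    }
    return ModelBundle(cnn=cnn, cnn_spec=cnn_spec, train_config=train_config,
                       forest=forest, linear=linear, ensemble=ensemble,
                       history=history, feature_names=list(registry),
                       reports=reports,
                       test_table=feature_table[te].reset_index(drop=True),
                       test_cnn_probs=cnn_probs[te])


def build_windows_and_features(reference, records, bundle, context_length,
                               seed=42, fractions=(0.6, 0.2, 0.2),
                               registry: Sequence[str] = DEFAULT_FEATURES):
    """Positives + equal background negatives, split-stamped, with features."""
    from .dataset import BreakpointIndex
    pos, _ = extract_sv_windows(reference, records, context_length)
    forbidden = BreakpointIndex(records).all_positions()
    neg = sample_background(reference, forbidden, len(pos), context_length,
                            seed=seed)
    windows = pos + neg
    assign_splits(windows, fractions=fractions, seed=seed)
    table = build_feature_table(windows, bundle, registry)
    return windows, table


def train_subclass_suite(reference, records, bundle, classes: Sequence[str],
                         cnn_spec: CNNSpec, train_config: TrainConfig,
                         context_length: Optional[int] = None,
                         registry: Sequence[str] = DEFAULT_FEATURES,
                         seed: int = 42) -> dict[str, ModelBundle]:
    """Per-class models: positives restricted to the class (``INV`` selects
    inversions), fresh balanced negatives, the same split procedure, all
    four model kinds.  Classes with no records are skipped with a warning.
    """
    import logging
    logger = logging.getLogger(__name__)
    L = context_length or cnn_spec.context_length
    out = {}
    for ci, cls in enumerate(classes):
        if cls == "INV":
            subset = [r for r in records if r.svtype == "INV"]
        else:
            subset = [r for r in records if r.repeat_class == cls
                      and r.svtype != "INV"]
        if not subset:
            logger.warning("subclass %s has no records; skipped", cls)
            continue
        windows, table = build_windows_and_features(
            reference, subset, bundle, L, seed=seed + ci, registry=registry)
        out[cls] = train_model_bundle(windows, table, cnn_spec, train_config,
                                      registry=registry, seed=seed + ci)
    return out
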