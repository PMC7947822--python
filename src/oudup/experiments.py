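"""Simulation studies: dataset generation, classifier/predictor evaluation,
and robustness to mechanism mixtures across tissues.

The default design is a balanced training set of 10,000 observations per
retention class (50,000 total) and a balanced test set of 1,000 per class
(5,000 total), each observation being one expression triplet simulated under
one independent parameter draw.  A ``scale`` factor proportionally shrinks
every count for quick runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc, roc_curve

from .background import BackgroundDistributions
from .features import assemble_feature_matrix, n_features
from .netmodel import TrainedModel, classify, predict_parameters
from .ou_model import (
    CLASS_LABELS,
    ParameterRanges,
    RetentionClass,
    draw_parameter_batch,
    sample_triplet_batch,
)

__all__ = [
    "LabeledDataset",
    "ClassifierEvaluation",
    "RocSummary",
    "generate_training_set",
    "generate_test_set",
    "evaluate_classifier",
    "evaluate_predictor",
    "mixed_mechanism_test",
    "evaluate_external_calls",
    "PARAM_NAMES",
]

#: per-tissue parameter order in the truth/target matrix
PARAM_NAMES = ("theta_p", "theta_c", "theta_a", "log10_alpha", "log10_sigma2")

DEFAULT_TPC_RANGE = (0.05, 0.95)


@dataclass
class LabeledDataset:
    """Feature matrix plus full simulation truth.

    ``params`` holds, per observation, the 5m values
    (theta_p, theta_c, theta_a, log10 alpha, log10 sigma2) per tissue, the
    regression targets of the predictor.
    """

    X: np.ndarray
    class_labels: np.ndarray
    params: np.ndarray
    t_pc: np.ndarray
    m: int

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.class_labels) == len(self.params) == len(self.t_pc) == n):
            raise ValueError("inconsistent dataset lengths")
        if self.X.shape[1] != n_features(self.m):
            raise ValueError("feature width does not match m")

    @property
    def n(self) -> int:
        return len(self.X)


def _param_targets(batch: dict[str, np.ndarray]) -> np.ndarray:
    """(n, 5m) target matrix in tissue-major (theta_p..log10_sigma2) order."""
    n, m = batch["theta_p"].shape
    out = np.empty((n, 5 * m))
    out[:, 0::5] = batch["theta_p"]
    out[:, 1::5] = batch["theta_c"]
    out[:, 2::5] = batch["theta_a"]
    out[:, 3::5] = np.log10(batch["alpha"])
    out[:, 4::5] = np.log10(batch["sigma2"])
    return out


def _draw_tpc(
    n: int, tree_time_pool: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    if tree_time_pool is not None:
        pool = np.asarray(tree_time_pool, dtype=float)
        return pool[rng.integers(0, len(pool), size=n)]
    return rng.uniform(*DEFAULT_TPC_RANGE, size=n)


def _generate(
    background: BackgroundDistributions,
    n_per_class: int,
    m: int,
    tree_time_pool: np.ndarray | None,
    ranges: ParameterRanges | None,
    rng: np.random.Generator,
) -> LabeledDataset:
    xs, labels, params, tpcs = [], [], [], []
    for cls in RetentionClass:
        t_pc = _draw_tpc(n_per_class, tree_time_pool, rng)
        batch = draw_parameter_batch(cls, n_per_class, m, t_pc, ranges, rng)
        triplets = sample_triplet_batch(batch, rng)
        xs.append(assemble_feature_matrix(triplets, t_pc, background))
        labels.append(np.full(n_per_class, int(cls)))
        params.append(_param_targets(batch))
        tpcs.append(t_pc)
    return LabeledDataset(
        X=np.vstack(xs),
        class_labels=np.concatenate(labels),
        params=np.vstack(params),
        t_pc=np.concatenate(tpcs),
        m=m,
    )


def generate_training_set(
    background: BackgroundDistributions,
    n_per_class: int = 10_000,
    m: int = 6,
    tree_time_pool: np.ndarray | None = None,
    ranges: ParameterRanges | None = None,
    rng_seed: int | np.random.Generator = 0,
    scale: float = 1.0,
) -> LabeledDataset:
    """Balanced training set: ``n_per_class`` scenarios per retention class,
    one triplet each, features assembled against ``background``."""
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    n = max(1, int(round(n_per_class * scale)))
    return _generate(background, n, m, tree_time_pool, ranges, rng)


def generate_test_set(
    background: BackgroundDistributions,
    n_per_class: int = 1_000,
    m: int = 6,
    tree_time_pool: np.ndarray | None = None,
    ranges: ParameterRanges | None = None,
    rng_seed: int | np.random.Generator = 0,
    scale: float = 1.0,
) -> LabeledDataset:
    """Balanced test set (default 1,000 per class), independent seed stream."""
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    n = max(1, int(round(n_per_class * scale)))
    return _generate(background, n, m, tree_time_pool, ranges, rng)


@dataclass
class RocSummary:
    """One-vs-rest ROC curves per class plus a macro average on a fixed grid."""

    per_class: dict[int, tuple[np.ndarray, np.ndarray]]
    per_class_auc: dict[int, float]
    macro_fpr: np.ndarray
    macro_tpr: np.ndarray
    macro_auc: float


@dataclass
class ClassifierEvaluation:
    accuracy: float
    confusion: np.ndarray  # row-normalized, true class x called class
    roc: RocSummary

    def __post_init__(self) -> None:
        if not np.allclose(self.confusion.sum(axis=1), 1.0):
            raise ValueError("confusion matrix rows must sum to 1")


def _confusion(true: np.ndarray, called: np.ndarray, k: int = 5) -> np.ndarray:
    cm = np.zeros((k, k))
    np.add.at(cm, (true.astype(int), called.astype(int)), 1.0)
    return cm / cm.sum(axis=1, keepdims=True)


def _roc_summary(true: np.ndarray, probs: np.ndarray) -> RocSummary:
    grid = np.linspace(0.0, 1.0, 101)
    per_class, per_auc, tprs = {}, {}, []
    for k in range(probs.shape[1]):
        fpr, tpr, _ = roc_curve((true == k).astype(int), probs[:, k])
        per_class[k] = (fpr, tpr)
        per_auc[k] = float(auc(fpr, tpr))
        tprs.append(np.interp(grid, fpr, tpr))
    macro_tpr = np.mean(tprs, axis=0)
    macro_tpr[0], macro_tpr[-1] = 0.0, 1.0
    return RocSummary(
        per_class=per_class,
        per_class_auc=per_auc,
        macro_fpr=grid,
        macro_tpr=macro_tpr,
        macro_auc=float(auc(grid, macro_tpr)),
    )


def evaluate_classifier(model: TrainedModel, test: LabeledDataset) -> ClassifierEvaluation:
    """Accuracy, row-normalized confusion matrix and one-vs-rest ROC."""
    probs, called = classify(model, test.X)
    return _evaluate_calls(test, called, probs)


def _evaluate_calls(
    test: LabeledDataset, called: np.ndarray, probs: np.ndarray | None = None
) -> ClassifierEvaluation:
    accuracy = float(np.mean(called == test.class_labels))
    cm = _confusion(test.class_labels, called)
    if probs is None:
        # degenerate probabilities from hard calls (for external classifiers)
        probs = np.zeros((test.n, 5))
        probs[np.arange(test.n), called.astype(int)] = 1.0
    roc = _roc_summary(test.class_labels, probs)
    return ClassifierEvaluation(accuracy=accuracy, confusion=cm, roc=roc)


def evaluate_external_calls(calls_path: str, test: LabeledDataset) -> ClassifierEvaluation:
    """Evaluate any external classifier's hard calls supplied as a TSV with a
    ``call`` column holding class labels (names or integer codes), one row per
    test observation in order."""
    df = pd.read_csv(calls_path, sep="\t")
    if "call" not in df.columns:
        raise ValueError("external calls TSV must have a 'call' column")
    if len(df) != test.n:
        raise ValueError(f"expected {test.n} calls, got {len(df)}")
    raw = df["call"]
    if raw.dtype.kind in "iu":
        called = raw.to_numpy()
    else:
        lut = {name: i for i, name in enumerate(CLASS_LABELS)}
        called = raw.map(lut).to_numpy()
        if np.any(pd.isna(called)):
            raise ValueError("unknown class label in external calls")
    return _evaluate_calls(test, called.astype(int))


def evaluate_predictor(model: TrainedModel, test: LabeledDataset) -> pd.DataFrame:
    """Per-parameter, per-class prediction error summary.

    The per-observation error for a parameter is the mean over the m tissues
    of (predicted - true).  Returns one row per (class, parameter) with the
    error mean, sd, and a two-sided one-sample t-test of zero mean with
    Bonferroni correction over the 5 x 5 grid.
    """
    pred = predict_parameters(model, test.X)
    err = pred - test.params  # (n, 5m)
    rows = []
    n_tests = len(CLASS_LABELS) * len(PARAM_NAMES)
    for ci, cname in enumerate(CLASS_LABELS):
        mask = test.class_labels == ci
        for pi, pname in enumerate(PARAM_NAMES):
            e = err[mask][:, pi::5].mean(axis=1)  # mean across tissues
            t, p = sps.ttest_1samp(e, 0.0)
            rows.append(
                {
                    "class": cname,
                    "param": pname,
                    "mean_error": float(e.mean()),
                    "sd_error": float(e.std(ddof=1)),
                    "t_stat": float(t),
                    "p_value": float(min(1.0, p * n_tests)),
                    "n": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def mixed_mechanism_test(
    classifier: TrainedModel,
    mech_a: RetentionClass,
    mech_b: RetentionClass,
    k: int,
    background: BackgroundDistributions,
    predictor: TrainedModel | None = None,
    n_reps: int = 1_000,
    m: int = 6,
    tree_time_pool: np.ndarray | None = None,
    ranges: ParameterRanges | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> dict:
    """Robustness probe: k tissues evolve under ``mech_a``'s optimum
    constraints and the remaining m - k under ``mech_b``'s.

    Returns call frequencies over the five classes, the modal call, and (when
    a predictor is given) per-parameter mean errors averaged over tissues.
    """
    if mech_a == mech_b:
        raise ValueError("mech_a and mech_b must differ")
    if not 1 <= k <= m - 1:
        raise ValueError(f"k must be in [1, m-1], got k={k}")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed

    t_pc = _draw_tpc(n_reps, tree_time_pool, rng)
    ba = draw_parameter_batch(mech_a, n_reps, m, t_pc, ranges, rng)
    bb = draw_parameter_batch(mech_b, n_reps, m, t_pc, ranges, rng)
    batch = {"t_pc": t_pc}
    for key in ("theta_p", "theta_c", "theta_a", "alpha", "sigma2"):
        merged = bb[key].copy()
        merged[:, :k] = ba[key][:, :k]
        batch[key] = merged

    triplets = sample_triplet_batch(batch, rng)
    X = assemble_feature_matrix(triplets, t_pc, background)
    _, called = classify(classifier, X)
    freqs = np.bincount(called, minlength=5) / n_reps

    result = {
        "call_frequencies": {CLASS_LABELS[i]: float(freqs[i]) for i in range(5)},
        "modal_call": CLASS_LABELS[int(freqs.argmax())],
        "k": k,
        "mech_a": CLASS_LABELS[int(mech_a)],
        "mech_b": CLASS_LABELS[int(mech_b)],
    }
    if predictor is not None:
        err = predict_parameters(predictor, X) - _param_targets(batch)
        result["param_errors"] = {
            pname: {
                "mean": float(err[:, pi::5].mean()),
                "sd": float(err[:, pi::5].mean(axis=1).std(ddof=1)),
            }
            for pi, pname in enumerate(PARAM_NAMES)
        }
    return result
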