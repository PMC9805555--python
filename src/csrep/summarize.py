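"""Group-wise probabilistic summarization of chromatin state maps.

The core model is an ensemble of N multinomial logistic regression
classifiers for a group of N samples.  Classifier n predicts sample n's
chromatin state at each genomic bin from the one-hot encoded states of the
other N-1 samples at the same bin (plus an intercept).  Training uses a
random subset of bins (10% of the genome by default); prediction is
genome-wide.  Averaging the N prediction matrices yields a G x S summary
probability matrix whose rows sum to 1; the per-row argmax gives a single
representative state map for the group.

The counting baseline (``base_count``) simply reports, per bin, the fraction
of member samples assigned to each state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .genome import GenomeIndex, SampleGroup, StateScheme

__all__ = [
    "TrainingIndex",
    "ClassifierModel",
    "SummaryMatrix",
    "sample_training_positions",
    "one_hot_features",
    "fit_classifier",
    "predict_probabilities",
    "summarize_group",
    "base_count_summary",
    "argmax_state_map",
]

DEFAULT_FRACTION = 0.1
DEFAULT_L2_STRENGTH = 1.0


@dataclass(frozen=True)
class TrainingIndex:
    """A reproducible random subset of bin indices used to train all
    classifiers of one group (one shared draw per group)."""

    positions: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)


def sample_training_positions(index: GenomeIndex, fraction: float, seed: int) -> TrainingIndex:
    """Sample ``floor(fraction * G)`` distinct bin indices uniformly.

    Deterministic given ``seed``; the same (G, fraction, seed) triple always
    regenerates the identical set.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    G = index.n_bins
    n = int(np.floor(fraction * G))
    if n == 0:
        raise ValueError(f"fraction {fraction} of G={G} bins selects zero training positions")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(G, size=n, replace=False))
    return TrainingIndex(positions=pos, fraction=fraction, seed=seed)


def _one_hot(states: np.ndarray, S: int) -> np.ndarray:
    """One-hot encode a (M, K) matrix of 1-based state integers into
    (M, K*S) binary columns, blocks in column order."""
    M, K = states.shape
    out = np.zeros((M, K * S), dtype=np.float64)
    rows = np.repeat(np.arange(M), K)
    cols = (np.arange(K) * S)[None, :] + (states - 1)
    out[rows, cols.ravel()] = 1.0
    return out


def one_hot_features(
    group: SampleGroup, target_sample: str, positions: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Build the predictor matrix for one target sample.

    One block of S binary indicators per non-target member (in group member
    order, target removed), plus a trailing constant-1 intercept column:
    (N-1)*S + 1 predictors total.
    """
    if group.N < 2:
        raise ValueError("need at least 2 samples to build features")
    ids = group.sample_ids
    if target_sample not in ids:
        raise KeyError(f"{target_sample!r} not in group {group.group_id!r}")
    others = [m for m in group.members if m.sample_id != target_sample]
    pos = np.asarray(positions, dtype=np.int64)
    states = np.stack([m.states[pos] for m in others], axis=1)
    X = _one_hot(states, group.scheme.S)
    return np.hstack([X, np.ones((X.shape[0], 1))])


@dataclass
class ClassifierModel:
    """A fitted multinomial (softmax) logistic regression.

    ``coefficients`` has one row per state present in training, over
    (N-1)*S + 1 predictors with the intercept as the last entry.  The
    symmetric softmax parameterization is used (one coefficient vector per
    state), with an L2 penalty of (1 / (2 * l2_strength)) * ||beta||^2 on the
    non-intercept coefficients.
    """

    target_sample: str
    coefficients: np.ndarray  # (n_classes_seen, width) incl. intercept column
    classes: np.ndarray  # 1-based state integers seen in training
    n_states: int
    l2_strength: float = DEFAULT_L2_STRENGTH
    parameterization_tag: str = "symmetric"
    converged: bool = True

    @property
    def feature_width(self) -> int:
        return self.coefficients.shape[1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax probabilities over all ``n_states`` states (columns for
        states absent from training are exactly 0)."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.feature_width:
            raise ValueError(
                f"feature width {X.shape[1]} != model width {self.feature_width}"
            )
        z = X @ self.coefficients.T
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p_seen = ez / ez.sum(axis=1, keepdims=True)
        out = np.zeros((X.shape[0], self.n_states))
        out[:, self.classes - 1] = p_seen
        return out


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    l2_strength: float = DEFAULT_L2_STRENGTH,
    target_sample: str = "",
    n_states: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ClassifierModel:
    """Fit a multinomial logistic regression with L2 penalty.

    ``features`` must carry the constant-1 intercept as its last column (as
    produced by :func:`one_hot_features`); the intercept itself is not
    penalized.  ``l2_strength`` follows the inverse-regularization
    convention: penalty = (1 / (2 * l2_strength)) * ||beta||^2.
    Deterministic (L-BFGS, zero initialization).
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need at least one training row")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if not np.allclose(X[:, -1], 1.0):
        raise ValueError("last feature column must be the constant-1 intercept")
    S = int(n_states) if n_states is not None else int(y.max())
    if y.min() < 1 or y.max() > S:
        raise ValueError("labels must lie in 1..S")
    width = X.shape[1]
    classes = np.unique(y)
    if classes.size == 1:
        # degenerate: one observed class -> constant predictor on that class
        warnings.warn(
            f"training labels contain a single state ({classes[0]}); "
            "fitting a constant predictor",
            RuntimeWarning,
        )
        coef = np.zeros((1, width))
        return ClassifierModel(
            target_sample=target_sample, coefficients=coef, classes=classes,
            n_states=S, l2_strength=l2_strength,
        )
    est = LogisticRegression(
        C=l2_strength, solver="lbfgs", tol=tol, max_iter=max_iter,
        fit_intercept=True,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*lbfgs failed to converge.*")
        est.fit(X[:, :-1], y)
    n_iter = int(np.max(est.n_iter_))
    converged = n_iter < max_iter
    if not converged:
        warnings.warn(
            f"classifier for {target_sample!r} hit max_iter={max_iter} "
            f"(n_iter={n_iter}); results may be short of tolerance {tol}",
            RuntimeWarning,
        )
    coef = np.hstack([est.coef_, est.intercept_[:, None]])
    if coef.shape[0] == 1:
        # sklearn collapses 2 classes to a single logit row; expand to the
        # equivalent two-row softmax (first class as zero row)
        coef = np.vstack([np.zeros((1, width)), coef])
    model = ClassifierModel(
        target_sample=target_sample, coefficients=coef, classes=est.classes_.astype(np.int64),
        n_states=S, l2_strength=l2_strength, converged=converged,
    )
    return model


def predict_probabilities(model: ClassifierModel, group: SampleGroup) -> np.ndarray:
    """Genome-wide softmax predictions for the model's target sample.

    Bins sharing the same combination of other-sample states share one
    prediction, so probabilities are computed once per distinct combination
    and broadcast back to all G bins.
    """
    if model.target_sample not in group.sample_ids:
        raise KeyError(f"model target {model.target_sample!r} not in group")
    others = [m for m in group.members if m.sample_id != model.target_sample]
    S = group.scheme.S
    expected = len(others) * S + 1
    if model.feature_width != expected:
        raise ValueError(
            f"model width {model.feature_width} incompatible with group "
            f"((N-1)*S+1 = {expected})"
        )
    states = np.stack([m.states for m in others], axis=1)  # G x (N-1)
    uniq, inverse = np.unique(states, axis=0, return_inverse=True)
    Xu = np.hstack([_one_hot(uniq, S), np.ones((uniq.shape[0], 1))])
    Pu = model.predict_proba(Xu)
    return Pu[inverse]


@dataclass
class SummaryMatrix:
    """G x S matrix of per-bin state assignment probabilities for a group."""

    group_id: str
    method: str  # "csrep" | "base_count"
    probs: np.ndarray
    index: GenomeIndex
    scheme: StateScheme

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (self.index.n_bins, self.scheme.S):
            raise ValueError("probs must be G x S")

    def validate(self, atol: float = 1e-6) -> None:
        if self.probs.min() < -atol or self.probs.max() > 1 + atol:
            raise ValueError("probabilities outside [0, 1]")
        rs = self.probs.sum(axis=1)
        if np.max(np.abs(rs - 1.0)) > atol:
            raise ValueError("rows do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: chrom/start/end plus one probability column per state."""
        rows = [self.index.bin_interval(i) for i in range(self.index.n_bins)]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        for s, name in enumerate(self.scheme.names):
            df[name] = self.probs[:, s]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, index: GenomeIndex, scheme: StateScheme,
                 group_id: str = "", method: str = "csrep") -> "SummaryMatrix":
        df = pd.read_csv(path, sep="\t")
        probs = df[list(scheme.names)].to_numpy(dtype=np.float64)
        return cls(group_id=group_id, method=method, probs=probs, index=index, scheme=scheme)


def summarize_group(
    group: SampleGroup,
    fraction: float = DEFAULT_FRACTION,
    seed: int = 0,
    l2_strength: float = DEFAULT_L2_STRENGTH,
    training: TrainingIndex | None = None,
) -> SummaryMatrix:
    """Ensemble summary of a sample group.

    For each member n, fits a classifier on the shared training positions
    (labels = member n's states, features = one-hot states of the others),
    predicts genome-wide, and averages the N prediction matrices.
    """
    if group.N < 2:
        raise ValueError("ensemble summarization needs N >= 2 samples")
    if training is None:
        training = sample_training_positions(group.index, fraction, seed)
    pos = training.positions
    S = group.scheme.S
    acc = np.zeros((group.index.n_bins, S))
    for member in group.members:
        X = one_hot_features(group, member.sample_id, pos)
        y = member.states[pos]
        model = fit_classifier(
            X, y, l2_strength=l2_strength,
            target_sample=member.sample_id, n_states=S,
        )
        acc += predict_probabilities(model, group)
    acc /= group.N
    return SummaryMatrix(group_id=group.group_id, method="csrep",
                         probs=acc, index=group.index, scheme=group.scheme)


def base_count_summary(group: SampleGroup) -> SummaryMatrix:
    """Counting baseline: per-bin state frequencies across members."""
    S = group.scheme.S
    states = group.state_matrix()  # G x N
    counts = np.zeros((group.index.n_bins, S), dtype=np.float64)
    for s in range(1, S + 1):
        counts[:, s - 1] = (states == s).sum(axis=1)
    return SummaryMatrix(group_id=group.group_id, method="base_count",
                         probs=counts / group.N, index=group.index, scheme=group.scheme)


def argmax_state_map(summary: SummaryMatrix) -> np.ndarray:
    """Per-bin state with maximal probability; ties go to the lowest state
    index. Returns 1-based state integers of length G."""
    return np.argmax(summary.probs, axis=1).astype(np.int32) + 1
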