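"""GentleBoost ensemble for catheter/non-catheter event classification.

Gentle AdaBoost builds an additive model F(x) = sum_m nu * f_m(x) where each
f_m is a regression stump fitted by weighted least squares to the +/-1 labels,
and sample weights are updated multiplicatively, w_i <- w_i exp(-y_i nu
f_m(x_i)).  Defaults follow the study configuration: 480 learners with
shrinkage (learning rate) 0.006.  Undefined-moment feature sentinels (NaN)
are imputed with the training-set median before fitting.

Metrics reported are sensitivity, specificity, precision, false-discovery
rate and accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "BoostConfig",
    "Stump",
    "TrainedEnsemble",
    "ClassificationMetrics",
    "train_ensemble",
    "predict",
    "evaluate",
    "holdout_split",
    "random_search",
]

DEFAULT_N_LEARNERS = 480
DEFAULT_LEARNING_RATE = 0.006


@dataclass(frozen=True)
class BoostConfig:
    n_learners: int = DEFAULT_N_LEARNERS
    learning_rate: float = DEFAULT_LEARNING_RATE
    seed: int = 0


@dataclass(frozen=True)
class Stump:
    """Regression stump: feature index, threshold, and the two leaf values."""

    feature: int
    threshold: float
    left: float  # response for x[feature] <= threshold
    right: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.where(x[:, self.feature] <= self.threshold, self.left, self.right)


@dataclass
class TrainedEnsemble:
    """Fitted GentleBoost model plus its training metadata."""

    stumps: list[Stump]
    learning_rate: float
    n_features: int
    feature_names: list[str] | None = None
    medians: np.ndarray | None = None
    seed: int = 0
    train_loss: list[float] = field(default_factory=list)

    @property
    def n_learners(self) -> int:
        return len(self.stumps)

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        x = _impute(np.atleast_2d(np.asarray(x, dtype=float)), self.medians)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: {x.shape[1]} != {self.n_features}"
            )
        score = np.zeros(len(x))
        for st in self.stumps:
            score += self.learning_rate * st(x)
        return score

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "cathcalib-gentleboost-v1",
                "learning_rate": self.learning_rate,
                "n_features": self.n_features,
                "feature_names": self.feature_names,
                "medians": None if self.medians is None else self.medians.tolist(),
                "seed": self.seed,
                "stumps": [
                    [s.feature, s.threshold, s.left, s.right] for s in self.stumps
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedEnsemble":
        d = json.loads(text)
        if d.get("format") != "cathcalib-gentleboost-v1":
            raise ValueError("unrecognized model format")
        return cls(
            stumps=[Stump(int(f), float(t), float(a), float(b)) for f, t, a, b in d["stumps"]],
            learning_rate=d["learning_rate"],
            n_features=d["n_features"],
            feature_names=d.get("feature_names"),
            medians=None if d.get("medians") is None else np.array(d["medians"]),
            seed=d.get("seed", 0),
        )


def _impute(x: np.ndarray, medians: np.ndarray | None) -> np.ndarray:
    if medians is None or not np.isnan(x).any():
        return x
    x = x.copy()
    rr, cc = np.nonzero(np.isnan(x))
    x[rr, cc] = medians[cc]
    return x


def _fit_stump(
    x: np.ndarray, z: np.ndarray, w: np.ndarray, order: np.ndarray
) -> Stump:
    """Best weighted-least-squares stump over all features and cut points.

    ``order`` is the per-feature argsort of x (precomputed once).  For each
    candidate split the optimal leaf values are the weighted means of z on
    each side; the split minimizing weighted SSE is kept.
    """
    n, d = x.shape
    sw = w.sum()
    swz = (w * z).sum()
    best = (np.inf, 0, 0.0, 0.0, 0.0)
    for j in range(d):
        idx = order[:, j]
        xs = x[idx, j]
        ws = w[idx]
        wzs = (w * z)[idx]
        cw = np.cumsum(ws)
        cwz = np.cumsum(wzs)
        # valid cut after position i (between xs[i] and xs[i+1]); skip ties
        valid = np.nonzero(xs[:-1] < xs[1:])[0]
        if len(valid) == 0:
            continue
        wl, wr = cw[valid], sw - cw[valid]
        zl, zr = cwz[valid], swz - cwz[valid]
        with np.errstate(divide="ignore", invalid="ignore"):
            ml = np.where(wl > 0, zl / wl, 0.0)
            mr = np.where(wr > 0, zr / wr, 0.0)
        # weighted SSE up to the constant sum w z^2
        score = -(ml**2 * wl + mr**2 * wr)
        k = int(np.argmin(score))
        if score[k] < best[0]:
            thr = 0.5 * (xs[valid[k]] + xs[valid[k] + 1])
            best = (score[k], j, thr, ml[k], mr[k])
    if not np.isfinite(best[0]):
        # all features constant: predict the weighted mean everywhere
        m = swz / sw if sw > 0 else 0.0
        return Stump(0, np.inf, m, m)
    return Stump(best[1], best[2], best[3], best[4])


def train_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    config: BoostConfig = BoostConfig(),
    feature_names: list[str] | None = None,
) -> TrainedEnsemble:
    """Fit a GentleBoost stump ensemble to binary labels (0/1 or +/-1).

    Raises on single-class label sets.  Deterministic given the data (the
    algorithm itself has no randomness; ``config.seed`` is stored for
    provenance of any upstream split).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    y = np.where(y > 0, 1.0, -1.0)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    medians = np.nanmedian(x, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    x = _impute(x, medians)
    n = len(x)
    w = np.full(n, 1.0 / n)
    order = np.argsort(x, axis=0, kind="stable")
    nu = config.learning_rate
    stumps: list[Stump] = []
    fx = np.zeros(n)
    loss_trace: list[float] = []
    for _ in range(config.n_learners):
        st = _fit_stump(x, y, w, order)
        out = st(x)
        fx += nu * out
        w = w * np.exp(-y * nu * out)
        w /= w.sum()
        stumps.append(st)
        loss_trace.append(float(np.mean(np.exp(-y * fx))))
    return TrainedEnsemble(
        stumps=stumps,
        learning_rate=nu,
        n_features=x.shape[1],
        feature_names=feature_names,
        medians=medians,
        seed=config.seed,
        train_loss=loss_trace,
    )


def predict(model: TrainedEnsemble, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(scores, labels) with labels = score > 0 (catheter)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    scores = model.decision_function(x)
    return scores, scores > 0


@dataclass(frozen=True)
class ClassificationMetrics:
    """Sensitivity, specificity, precision, FDR and accuracy as fractions."""

    sensitivity: float
    specificity: float
    precision: float
    fdr: float
    accuracy: float

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            k: (v * scale if np.isfinite(v) else v)
            for k, v in self.__dict__.items()
        }


def evaluate(pred_labels: np.ndarray, true_labels: np.ndarray) -> ClassificationMetrics:
    """Confusion-matrix metrics of a binary prediction.

    Precision and FDR are NaN when there are no predicted positives.
    """
    yp = np.asarray(pred_labels).astype(bool)
    yt = np.asarray(true_labels).astype(bool)
    if len(yp) != len(yt):
        raise ValueError("length mismatch")
    if yt.all() or not yt.any():
        raise ValueError("truth must contain both classes")
    tp = int((yp & yt).sum())
    tn = int((~yp & ~yt).sum())
    fp = int((yp & ~yt).sum())
    fn = int((~yp & yt).sum())
    pos_pred = tp + fp
    if pos_pred == 0:
        warnings.warn("no predicted positives: precision/FDR undefined", stacklevel=2)
        precision = fdr = float("nan")
    else:
        precision = tp / pos_pred
        fdr = fp / pos_pred
    return ClassificationMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        precision=precision,
        fdr=fdr,
        accuracy=(tp + tn) / len(yt),
    )


def holdout_split(
    features: np.ndarray, labels: np.ndarray, fraction: float = 0.25, seed: int = 0
):
    """Stratified holdout split (default 25% validation); falls back to an
    unstratified split, with a warning, when a class has < 2 samples."""
    x = np.atleast_2d(np.asarray(features))
    y = np.asarray(labels)
    if len(x) < 4:
        raise ValueError("need at least 4 samples")
    _, counts = np.unique(y, return_counts=True)
    strat = y if counts.min() >= 2 else None
    if strat is None:
        warnings.warn("class with <2 samples: unstratified split", stacklevel=2)
    xtr, xva, ytr, yva = train_test_split(
        x, y, test_size=fraction, random_state=seed, stratify=strat
    )
    return (xtr, ytr), (xva, yva)


def random_search(
    features: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 10,
    seed: int = 0,
    fraction: float = 0.25,
) -> tuple[BoostConfig, float]:
    """Optional random search over (n_learners, learning_rate) by holdout accuracy."""
    rng = np.random.default_rng(seed)
    (xtr, ytr), (xva, yva) = holdout_split(features, labels, fraction, seed)
    best_cfg, best_acc = BoostConfig(), -1.0
    for _ in range(n_iter):
        cfg = BoostConfig(
            n_learners=int(rng.integers(50, 500)),
            learning_rate=float(10 ** rng.uniform(-3, 0)),
            seed=seed,
        )
        model = train_ensemble(xtr, ytr, cfg)
        _, pred = predict(model, xva)
        acc = float((pred == (np.asarray(yva) > 0)).mean())
        if acc > best_acc:
            best_cfg, best_acc = cfg, acc
    return best_cfg, best_acc
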