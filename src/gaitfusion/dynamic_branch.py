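"""Dynamic branch: calibrated soft-voting ensemble over dynamic gaits.

Base learners: a gradient-boosted tree ensemble (GBDT) and a random forest
on the handcrafted feature vectors, plus an optional dual-branch 1D CNN on
the raw windows.  Each learner's outputs pass through its own probability
calibrator -- Platt (sigmoid) scaling for the GBDT, vote averaging (the
forest's native averaged vote, an identity map) for the RF, temperature
scaling for the network -- before a weighted soft vote:

    P_final(y = k) = sum_j w_j * p_j(k),   sum_j w_j = 1,  w_j >= 0.

Vote weights default to accuracy-proportional weights measured on the
held-out calibration split (equal weights are config-selectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, train_test_split

from .nn import DualBranchNet1D, DualBranchNetSpec

__all__ = [
    "EnsembleWeights", "soft_vote", "TemperatureScaler", "PlattCalibrator",
    "DynamicEnsemble", "DEFAULT_RF_GRID", "DEFAULT_GBDT_GRID",
]

DEFAULT_RF_GRID = {"max_depth": [None, 12]}
DEFAULT_GBDT_GRID = {"learning_rate": [0.1, 0.3]}


@dataclass(frozen=True)
class EnsembleWeights:
    """Normalized nonnegative vote weights keyed by base-model name."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")


def soft_vote(probabilities, weights) -> np.ndarray:
    """Weighted linear combination of base-model probability vectors.

    ``probabilities`` is a sequence of (n, k) arrays (or (k,) vectors), one
    per model; ``weights`` is the matching weight vector.  Inputs must be
    valid probability distributions and the weights a convex combination;
    the output rows then sum to 1 by construction.
    """
    probs = [np.atleast_2d(np.asarray(p, dtype=float)) for p in probabilities]
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(probs) != w.size:
        raise ValueError("one weight per model required")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    for p in probs:
        if p.shape != probs[0].shape:
            raise ValueError("probability arrays must share a shape")
        if np.any(p < -1e-9) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("inputs must be probability distributions")
    return sum(wi * p for wi, p in zip(w, probs))


# ---------------------------------------------------------------------------
# calibrators
# ---------------------------------------------------------------------------

class TemperatureScaler:
    """Single-parameter temperature scaling of logits.

    Minimizes the negative log-likelihood of softmax(logits / T) on a
    held-out split.  Dividing by a positive scalar is a monotone transform
    of each logit vector, so the top-class ranking is preserved.
    """

    def __init__(self) -> None:
        self.temperature_: float | None = None

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, logits: np.ndarray, y_idx: np.ndarray) -> "TemperatureScaler":
        logits = np.asarray(logits, dtype=float)
        y_idx = np.asarray(y_idx)

        def nll(log_t: float) -> float:
            p = self._softmax(logits / np.exp(log_t))
            return -np.mean(np.log(p[np.arange(y_idx.size), y_idx] + 1e-12))

        res = minimize_scalar(nll, bounds=(-3.0, 3.0), method="bounded")
        self.temperature_ = float(np.exp(res.x))
        return self

    def transform(self, logits: np.ndarray) -> np.ndarray:
        if self.temperature_ is None:
            raise ValueError("scaler is not fitted")
        return self._softmax(np.asarray(logits, dtype=float)
                             / self.temperature_)


class PlattCalibrator:
    """Per-class sigmoid (Platt) scaling of decision scores.

    One univariate logistic model per class maps that class's score to a
    probability; the per-class probabilities are then renormalized.
    """

    def __init__(self) -> None:
        self.models_: list[LogisticRegression] | None = None

    def fit(self, scores: np.ndarray, y_idx: np.ndarray) -> "PlattCalibrator":
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        self.models_ = []
        for k in range(scores.shape[1]):
            target = (np.asarray(y_idx) == k).astype(int)
            lr = LogisticRegression(C=1e3)
            if target.min() == target.max():  # degenerate one-class column
                lr = None
            else:
                lr.fit(scores[:, k:k + 1], target)
            self.models_.append(lr)
        return self

    def transform(self, scores: np.ndarray) -> np.ndarray:
        if self.models_ is None:
            raise ValueError("calibrator is not fitted")
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        cols = []
        for k, lr in enumerate(self.models_):
            if lr is None:
                cols.append(np.full(scores.shape[0], 1e-6))
            else:
                cols.append(lr.predict_proba(scores[:, k:k + 1])[:, 1])
        p = np.column_stack(cols)
        return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    use_deep: bool = False
    weight_mode: str = "accuracy"     # "accuracy" | "equal"
    calibration_fraction: float = 0.2
    rf_n_estimators: int = 150
    rf_grid: dict = field(default_factory=lambda: dict(DEFAULT_RF_GRID))
    gbdt_grid: dict = field(default_factory=lambda: dict(DEFAULT_GBDT_GRID))
    grid_cv: int = 3
    net_spec: DualBranchNetSpec = field(default_factory=DualBranchNetSpec)


class DynamicEnsemble:
    """Trainable calibrated soft-voting ensemble for dynamic gaits."""

    def __init__(self, config: EnsembleConfig | None = None, seed: int = 0):
        self.config = config or EnsembleConfig()
        self.seed = seed
        self.models_: dict[str, object] = {}
        self.calibrators_: dict[str, object] = {}
        self.weights_: EnsembleWeights | None = None
        self.classes_: np.ndarray | None = None

    # -- helpers -------------------------------------------------------------

    def _grid_fit(self, estimator, grid, x, y):
        n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
        min_count = int(np.bincount(np.unique(y, return_inverse=True)[1]).min())
        if grid and n_combos > 1 and min_count >= 2:
            search = GridSearchCV(estimator, grid,
                                  cv=min(self.config.grid_cv, min_count),
                                  n_jobs=1)
            search.fit(x, y)
            return search.best_estimator_
        if grid and n_combos == 1:
            estimator.set_params(**{k: v[0] for k, v in grid.items()})
        estimator.fit(x, y)
        return estimator

    def _base_probs(self, name: str, x_feat, raw_p, raw_e,
                    calibrated: bool = True) -> np.ndarray:
        model = self.models_[name]
        if name == "nn":
            logits = model.predict_logits(raw_p, raw_e)
            return self.calibrators_["nn"].transform(logits) if calibrated \
                else model.predict_proba(raw_p, raw_e)
        if name == "gbdt":
            scores = model.decision_function(x_feat)
            if scores.ndim == 1:  # binary: one column of log odds
                scores = np.column_stack([-scores, scores])
            return self.calibrators_["gbdt"].transform(scores) if calibrated \
                else model.predict_proba(x_feat)
        return model.predict_proba(x_feat)  # rf: vote averaging

    # -- API -----------------------------------------------------------------

    def fit(self, features: np.ndarray, labels,
            raw_pressure: np.ndarray | None = None,
            raw_euler: np.ndarray | None = None,
            expected_classes=None) -> "DynamicEnsemble":
        """Train base learners, calibrators and vote weights.

        ``features`` (n, d) are the handcrafted vectors; ``raw_pressure`` /
        ``raw_euler`` (n, 12, 128) are required only when the deep path is
        enabled.  A fifth of the training windows (stratified, seeded) is
        held out to fit the calibrators and the vote weights.
        """
        x = np.asarray(features, dtype=float)
        y = np.asarray(labels)
        if x.shape[0] != y.shape[0]:
            raise ValueError("features and labels are misaligned")
        if expected_classes is not None:
            missing = set(expected_classes) - set(np.unique(y))
            if missing:
                raise ValueError(f"missing classes in training data: "
                                 f"{sorted(missing)}")
        if np.unique(y).size < 2:
            raise ValueError("need at least two classes to train")
        use_deep = self.config.use_deep
        if use_deep:
            if raw_pressure is None or raw_euler is None:
                raise ValueError("deep path enabled but raw windows missing")
            raw_pressure = np.asarray(raw_pressure, dtype=float)
            raw_euler = np.asarray(raw_euler, dtype=float)
            if raw_pressure.shape[0] != x.shape[0] \
                    or raw_euler.shape[0] != x.shape[0]:
                raise ValueError("raw windows misaligned with features")

        idx = np.arange(x.shape[0])
        tr, cal = train_test_split(
            idx, test_size=self.config.calibration_fraction,
            stratify=y, random_state=self.seed)
        self.classes_ = np.unique(y)
        y_cal_idx = np.searchsorted(self.classes_, y[cal])

        rf = RandomForestClassifier(
            n_estimators=self.config.rf_n_estimators,
            random_state=self.seed, n_jobs=1)
        self.models_["rf"] = self._grid_fit(rf, self.config.rf_grid,
                                            x[tr], y[tr])
        self.calibrators_["rf"] = None  # vote averaging: native probabilities

        gbdt = HistGradientBoostingClassifier(random_state=self.seed,
                                              max_iter=150)
        self.models_["gbdt"] = self._grid_fit(gbdt, self.config.gbdt_grid,
                                              x[tr], y[tr])
        scores = self.models_["gbdt"].decision_function(x[cal])
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
        self.calibrators_["gbdt"] = PlattCalibrator().fit(scores, y_cal_idx)

        if use_deep:
            net = DualBranchNet1D(self.config.net_spec, seed=self.seed)
            net.fit(raw_pressure[tr], raw_euler[tr], y[tr])
            self.models_["nn"] = net
            self.calibrators_["nn"] = TemperatureScaler().fit(
                net.predict_logits(raw_pressure[cal], raw_euler[cal]),
                y_cal_idx)

        # vote weights on the calibration split
        names = list(self.models_)
        if self.config.weight_mode == "equal":
            w = np.full(len(names), 1.0 / len(names))
        else:
            accs = []
            for name in names:
                p = self._base_probs(name, x[cal],
                                     raw_pressure[cal] if use_deep else None,
                                     raw_euler[cal] if use_deep else None)
                accs.append((self.classes_[p.argmax(axis=1)]
                             == y[cal]).mean())
            accs = np.asarray(accs, dtype=float)
            w = accs / accs.sum() if accs.sum() > 0 \
                else np.full(len(names), 1.0 / len(names))
        self.weights_ = EnsembleWeights(dict(zip(names, w)))
        return self

    def predict_proba(self, features, raw_pressure=None, raw_euler=None):
        if self.weights_ is None:
            raise ValueError("ensemble is not trained")
        x = np.asarray(features, dtype=float)
        names = list(self.models_)
        probs = [self._base_probs(n, x, raw_pressure, raw_euler)
                 for n in names]
        w = [self.weights_.weights[n] for n in names]
        return soft_vote(probs, w)

    def predict(self, features, raw_pressure=None, raw_euler=None):
        """Final labels: calibrate, soft-vote, argmax (ties -> first class)."""
        p = self.predict_proba(features, raw_pressure, raw_euler)
        return self.classes_[np.argmax(p, axis=1)]
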