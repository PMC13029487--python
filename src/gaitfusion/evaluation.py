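"""Leave-one-subject-out evaluation of the full two-stage pipeline,
accuracy statistics, and the modality / dimensionality-reduction ablations.

The synthetic benchmark population consists of simulated subjects whose
activity parameters (cadence, amplitudes, peak pressure) are jittered
multiplicatively by +-10% per subject, emulating inter-subject variation;
static and transitional data are generated as continuous labeled sessions
so that transition windows carry true per-frame labels, while each dynamic
gait is a separate uniform-label recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .config import PipelineConfig
from .detector import DYNAMIC, classify_state
from .dynamic_branch import DynamicEnsemble
from .features import FeatureOptions, assemble_features, feature_names
from .preprocessing import GaitWindow, preprocess_recording, segment_windows
from .static_branch import StaticFSM, fsm_smooth, train_static_classifier
from .types import (ACTIVITIES, DYNAMIC_ACTIVITIES, SITTING, SIT_TO_STAND,
                    STANDING, STAND_TO_SIT, STATIC_ACTIVITIES, GaitParams,
                    Recording, SensorLayout)
from .synthetic import simulate_activity, simulate_session

__all__ = [
    "accuracy_stats", "make_benchmark", "extract_windows", "GaitPipeline",
    "LoocvResult", "loocv_evaluate", "ablation_run", "pca_ablation",
]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def accuracy_stats(accuracies) -> tuple[float, float, tuple[float, float]]:
    """Mean, sample SD (n-1 denominator) and t-based 95% CI of accuracies.

    CI = mean +- t(n-1, 0.975) * SD / sqrt(n).  With fewer than two values
    the SD and CI are undefined and returned as NaN with a warning.
    """
    a = np.asarray(list(accuracies), dtype=float)
    mean = float(a.mean())
    if a.size < 2:
        warnings.warn("CI undefined for fewer than two accuracies",
                      stacklevel=2)
        return mean, float("nan"), (float("nan"), float("nan"))
    sd = float(a.std(ddof=1))
    half = sps.t.ppf(0.975, a.size - 1) * sd / np.sqrt(a.size)
    return mean, sd, (mean - half, mean + half)


# ---------------------------------------------------------------------------
# benchmark data
# ---------------------------------------------------------------------------

def make_benchmark(
    n_subjects: int = 6,
    seed: int = 0,
    static_reps: int = 6,
    static_hold: float = 4.0,
    dynamic_duration: float = 36.0,
    jitter: float = 0.1,
) -> dict[str, list[Recording]]:
    """Simulate the benchmark population, one recording list per subject.

    Each subject contributes one continuous posture session (``static_reps``
    repetitions of sitting -> sit-to-stand -> standing -> stand-to-sit) and
    one recording of each dynamic gait.  Per-subject parameter jitter is
    ``+-jitter`` (relative) on cadence and amplitudes.
    """
    dataset: dict[str, list[Recording]] = {}
    root = np.random.default_rng(seed)
    for s in range(n_subjects):
        sid = f"S{s + 1}"
        rng = np.random.default_rng(root.integers(2**31))
        params = {act: GaitParams.for_activity(act).jittered(rng, jitter)
                  for act in ACTIVITIES}
        plan: list = []
        for _ in range(static_reps):
            plan += [(SITTING, static_hold), SIT_TO_STAND,
                     (STANDING, static_hold), STAND_TO_SIT]
        plan += [(SITTING, static_hold)]
        recs = [simulate_session(plan, seed=int(rng.integers(2**31)),
                                 base_params=params, subject_id=sid)]
        for act in DYNAMIC_ACTIVITIES:
            recs.append(simulate_activity(params[act], dynamic_duration,
                                          seed=int(rng.integers(2**31)),
                                          subject_id=sid))
        dataset[sid] = recs
    return dataset


def extract_windows(
    recordings: list[Recording],
    config: PipelineConfig,
    layout: SensorLayout | None = None,
):
    """Condition, segment and featurize a list of recordings.

    Returns (windows, features, labels); window order is preserved within
    each recording, which the FSM smoothing downstream relies on.  Features
    are always assembled fused (510 + optional add-ons); modality masking is
    applied by column selection at train/predict time.
    """
    layout = layout or SensorLayout()
    options = FeatureOptions(modality="fused",
                             include_addons=config.include_addons)
    windows: list[GaitWindow] = []
    bounds: list[int] = []
    for rec in recordings:
        rec = preprocess_recording(rec, config.sg_config())
        w = segment_windows(rec)
        windows.extend(w)
        bounds.append(len(windows))
    feats = np.array([assemble_features(w, layout, options).values
                      for w in windows])
    labels = np.array([w.label for w in windows])
    return windows, feats, labels, bounds


def _modality_columns(config: PipelineConfig) -> np.ndarray:
    """Column indices of the configured modality inside the fused vector."""
    fused = feature_names(FeatureOptions(modality="fused",
                                         include_addons=config.include_addons))
    if config.modality == "fused":
        return np.arange(len(fused))
    if config.modality == "pressure":
        prefixes = ("p_", "glob_")
    else:  # imu; the add-ons are inertial quantities
        prefixes = ("imu_", "addon_")
    return np.array([i for i, n in enumerate(fused)
                     if n.startswith(prefixes)])


_PRESSURE_DIM = 222  # leading pressure-part columns of the fused vector


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class GaitPipeline:
    """Stage-1 router + static branch + dynamic branch, as one estimator."""

    config: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0

    def fit(self, windows, features, labels) -> "GaitPipeline":
        x = np.asarray(features, dtype=float)
        y = np.asarray(labels)
        self._thr = self.config.detector_thresholds()
        self._fsm = StaticFSM()
        self._static_pca = self._dyn_pca = None

        if self.config.modality == "imu":
            # no pressure -> no router; dynamic branch absorbs all 8 classes
            cols = _modality_columns(self.config)
            xd = x[:, cols]
            self._dyn_cols = cols
            if self.config.pca_variance:
                xd, self._dyn_pca = _fit_pca(xd, self.config.pca_variance)
            self._ensemble = DynamicEnsemble(self.config.ensemble_config(),
                                             seed=self.seed)
            self._ensemble.fit(xd, y, *self._raws(windows))
            self._svm = None
            return self

        static_mask = np.isin(y, STATIC_ACTIVITIES)
        xs = x[static_mask][:, :_PRESSURE_DIM]
        if self.config.pca_variance:
            xs, self._static_pca = _fit_pca(xs, self.config.pca_variance)
        self._svm = train_static_classifier(xs, y[static_mask],
                                            grid=self.config.svm_grid,
                                            seed=self.seed)

        dyn_mask = np.isin(y, DYNAMIC_ACTIVITIES)
        cols = _modality_columns(self.config)
        self._dyn_cols = cols
        xd = x[dyn_mask][:, cols]
        if self.config.pca_variance:
            xd, self._dyn_pca = _fit_pca(xd, self.config.pca_variance)
        self._ensemble = DynamicEnsemble(self.config.ensemble_config(),
                                         seed=self.seed)
        raws = self._raws([w for w, m in zip(windows, dyn_mask) if m])
        self._ensemble.fit(xd, y[dyn_mask], *raws,
                           expected_classes=DYNAMIC_ACTIVITIES)
        return self

    def _raws(self, windows):
        if not self.config.use_deep:
            return None, None
        rp = np.stack([w.pressure for w in windows])
        re = np.stack([w.euler for w in windows])
        return rp, re

    def predict(self, windows, features) -> np.ndarray:
        """Predict one label per window, windows in temporal order.

        Static-routed windows are classified by the margin model and FSM
        smoothing is applied to each contiguous run of static routings (the
        FSM restarts after a dynamic interruption).
        """
        x = np.asarray(features, dtype=float)
        n = x.shape[0]
        out = np.empty(n, dtype=object)
        if n == 0:
            return out

        if self.config.modality == "imu":
            xd = x[:, self._dyn_cols]
            if self._dyn_pca is not None:
                xd = self._dyn_pca.transform(xd)
            out[:] = self._ensemble.predict(xd, *self._raws(windows))
            return out

        routes = [classify_state(w, self._thr) for w in windows]
        dyn_idx = np.array([r.state == DYNAMIC for r in routes])

        if dyn_idx.any():
            xd = x[dyn_idx][:, self._dyn_cols]
            if self._dyn_pca is not None:
                xd = self._dyn_pca.transform(xd)
            raws = self._raws([w for w, d in zip(windows, dyn_idx) if d])
            out[dyn_idx] = self._ensemble.predict(xd, *raws)

        stat_positions = np.flatnonzero(~dyn_idx)
        if stat_positions.size:
            xs = x[stat_positions][:, :_PRESSURE_DIM]
            if self._static_pca is not None:
                xs = self._static_pca.transform(xs)
            raw = [str(lab) for lab in self._svm.predict(xs)]
            # smooth each contiguous run of static routings independently
            run_start = 0
            for i in range(1, stat_positions.size + 1):
                if i == stat_positions.size or \
                        stat_positions[i] != stat_positions[i - 1] + 1:
                    seg = fsm_smooth(raw[run_start:i], self._fsm)
                    out[stat_positions[run_start:i]] = seg
                    run_start = i
        return out


def _fit_pca(x: np.ndarray, variance_kept: float):
    keep = x.std(axis=0) > 0
    pca = PCA(n_components=variance_kept, svd_solver="full")

    class _Reducer:
        def __init__(self, keep, pca):
            self.keep, self.pca = keep, pca
            self.n_components_ = None

        def fit(self, x):
            self.pca.fit(x[:, self.keep])
            self.n_components_ = int(self.pca.n_components_)
            return self

        def transform(self, x):
            return self.pca.transform(x[:, self.keep])

    red = _Reducer(keep, pca).fit(x)
    return red.transform(x), red


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

@dataclass
class LoocvResult:
    per_subject: dict[str, float]           # accuracy in %
    confusion: pd.DataFrame                 # rows = true, cols = predicted
    mean: float
    sd: float
    ci95: tuple[float, float]

    @property
    def per_class_recall(self) -> pd.Series:
        c = self.confusion
        return (np.diag(c) / c.sum(axis=1).replace(0, np.nan)) * 100

    @property
    def per_class_precision(self) -> pd.Series:
        c = self.confusion
        return pd.Series(np.diag(c) / c.sum(axis=0).replace(0, np.nan),
                         index=c.index) * 100

    @property
    def overall_accuracy(self) -> float:
        c = self.confusion.to_numpy()
        return float(np.trace(c) / c.sum()) * 100


def loocv_evaluate(
    dataset: dict[str, list[Recording]],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> LoocvResult:
    """Leave-one-subject-out evaluation of the full pipeline.

    One fold per subject: the pipeline (router + both branches) is trained
    on the remaining subjects and tested on the held-out subject's windows.
    A fold whose training remainder lacks a class required by either branch
    is skipped with a warning.  Fold assignment is by subject, never by
    window.
    """
    config = config or PipelineConfig()
    subjects = list(dataset)
    if len(subjects) < 2:
        raise ValueError("LOOCV needs at least two subjects")

    cache = {sid: extract_windows(recs, config)
             for sid, recs in dataset.items()}

    per_subject: dict[str, float] = {}
    conf = pd.DataFrame(0, index=list(ACTIVITIES), columns=list(ACTIVITIES))
    for sid in subjects:
        train_ids = [s for s in subjects if s != sid]
        y_train = np.concatenate([cache[s][2] for s in train_ids])
        required = set(ACTIVITIES) if config.modality != "imu" \
            else set(np.unique(np.concatenate([cache[s][2]
                                               for s in subjects])))
        if set(np.unique(y_train)) < required:
            warnings.warn(f"fold {sid} skipped: training remainder lacks "
                          f"{sorted(required - set(np.unique(y_train)))}",
                          stacklevel=2)
            continue
        windows = [w for s in train_ids for w in cache[s][0]]
        x_train = np.concatenate([cache[s][1] for s in train_ids])
        pipe = GaitPipeline(config=config, seed=seed).fit(windows, x_train,
                                                          y_train)
        # predict per recording to keep FSM runs within one recording
        w_test, x_test, y_test, bounds = cache[sid]
        preds = []
        start = 0
        for stop in bounds:
            preds.append(pipe.predict(w_test[start:stop],
                                      x_test[start:stop]))
            start = stop
        y_pred = np.concatenate(preds) if preds else np.empty(0, dtype=object)
        per_subject[sid] = float((y_pred == y_test).mean()) * 100
        for t, p in zip(y_test, y_pred):
            conf.loc[t, p] += 1

    mean, sd, ci = accuracy_stats(per_subject.values())
    return LoocvResult(per_subject=per_subject, confusion=conf,
                       mean=mean, sd=sd, ci95=ci)


def ablation_run(
    dataset: dict[str, list[Recording]],
    modality: str,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> float:
    """LOOCV mean accuracy (%) for one sensing configuration."""
    config = (config or PipelineConfig()).with_(modality=modality)
    return loocv_evaluate(dataset, config, seed=seed).mean


def pca_ablation(
    features: np.ndarray,
    variance_kept: float = 0.95,
    test_features: np.ndarray | None = None,
):
    """Linear reduction retaining the stated fraction of total variance.

    Constant (zero-variance) columns are dropped before fitting.  Returns
    ``(reduced, n_components)``; with ``test_features`` given, also the
    transformed test block (fitted on the training block only).
    """
    x = np.asarray(features, dtype=float)
    reduced, red = _fit_pca(x, variance_kept)
    if test_features is None:
        return reduced, red.n_components_
    return reduced, red.n_components_, red.transform(
        np.asarray(test_features, dtype=float))
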