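"""Static branch: pressure-only SVM over the four postural states, with a
finite-state machine enforcing physically legal posture successions.

The FSM's default transition table allows each state to persist or to move
one step along the sitting -> sit-to-stand -> standing -> stand-to-sit ->
sitting cycle; aborted transitions are illegal by default (configurable).
An illegal prediction is rejected and the current state is held.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import SITTING, SIT_TO_STAND, STANDING, STAND_TO_SIT, STATIC_ACTIVITIES

__all__ = ["StaticFSM", "fsm_smooth", "train_static_classifier",
           "predict_static", "DEFAULT_SVM_GRID"]

DEFAULT_SVM_GRID = {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale"]}


def _default_transitions() -> dict[str, frozenset[str]]:
    return {
        SITTING: frozenset({SITTING, SIT_TO_STAND}),
        SIT_TO_STAND: frozenset({SIT_TO_STAND, STANDING}),
        STANDING: frozenset({STANDING, STAND_TO_SIT}),
        STAND_TO_SIT: frozenset({STAND_TO_SIT, SITTING}),
    }


@dataclass
class StaticFSM:
    """Posture-legality automaton over the four static states."""

    transitions: dict[str, frozenset[str]] = field(
        default_factory=_default_transitions)

    def __post_init__(self) -> None:
        for state, nxt in self.transitions.items():
            if state not in STATIC_ACTIVITIES:
                raise ValueError(f"unknown FSM state {state!r}")
            unknown = set(nxt) - set(STATIC_ACTIVITIES)
            if unknown:
                raise ValueError(f"unknown FSM targets {unknown}")

    def is_legal(self, current: str, proposed: str) -> bool:
        return proposed in self.transitions[current]


def fsm_smooth(labels, fsm: StaticFSM | None = None) -> list[str]:
    """Reject physically impossible posture jumps by holding the last state.

    The initial state is the first prediction; a prediction that is not a
    legal successor of the current state is replaced by the current state.
    Every consecutive output pair is therefore an allowed transition, and a
    legal prediction is never altered.
    """
    fsm = fsm or StaticFSM()
    labels = list(labels)
    for lab in labels:
        if lab not in STATIC_ACTIVITIES:
            raise ValueError(f"unknown static label {lab!r}")
    if not labels:
        return []
    out = [labels[0]]
    for lab in labels[1:]:
        out.append(lab if fsm.is_legal(out[-1], lab) else out[-1])
    return out


def train_static_classifier(
    features: np.ndarray,
    labels,
    grid: dict | None = None,
    cv: int = 3,
    seed: int = 0,
) -> Pipeline:
    """Fit the pressure-only maximum-margin classifier.

    Features are standardized inside the pipeline; hyperparameters are
    selected by a small grid search.  The classifier exposes per-class
    scores through ``decision_function``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train")
    pipe = Pipeline([
        ("scaler", StandardScaler()),
        ("svc", SVC(kernel="rbf", decision_function_shape="ovr",
                    random_state=seed)),
    ])
    grid = DEFAULT_SVM_GRID if grid is None else grid
    min_count = int(np.bincount(np.unique(y, return_inverse=True)[1]).min())
    if grid and min_count >= 2:
        search = GridSearchCV(pipe, grid, cv=min(cv, min_count), n_jobs=1)
        search.fit(x, y)
        return search.best_estimator_
    pipe.fit(x, y)
    return pipe


def predict_static(
    model: Pipeline,
    features: np.ndarray,
    fsm: StaticFSM | None = None,
) -> tuple[list[str], np.ndarray]:
    """Classifier scores -> argmax labels -> FSM smoothing.

    Returns the corrected label sequence (FSM-legal by construction) plus
    the raw per-window decision scores.  Windows must be given in temporal
    order.  An empty window list yields an empty output.
    """
    if not hasattr(model, "classes_") and not hasattr(
            getattr(model, "named_steps", {}).get("svc", None), "classes_"):
        raise ValueError("model is not trained")
    x = np.asarray(features, dtype=float)
    if x.size == 0:
        return [], np.empty((0,))
    scores = model.decision_function(x)
    raw = [str(lab) for lab in model.predict(x)]
    return fsm_smooth(raw, fsm), scores
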