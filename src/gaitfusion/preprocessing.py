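"""Signal conditioning: Kalman update, angle unwrapping, Savitzky-Golay
smoothing, and sliding-window segmentation.

The orientation filter here is the generic linear Kalman predict/correct
step used by 9-axis fusion firmware; the simulator emits Euler angles
directly, so the Kalman operation is exposed as a standalone primitive
rather than wired into the synthesis path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .types import Recording

__all__ = [
    "KalmanModel",
    "kalman_update",
    "unwrap_angles",
    "wrap_angles",
    "SGConfig",
    "savgol_coeffs_center",
    "savgol_smooth",
    "GaitWindow",
    "segment_windows",
    "preprocess_recording",
]

WINDOW_SIZE = 128  # samples: 1.28 s at 100 Hz
WINDOW_STEP = 32   # samples: 75% overlap between adjacent windows


# ---------------------------------------------------------------------------
# Kalman filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KalmanModel:
    """Linear-Gaussian state-space model with its current estimate.

    Time update:    x_prior = A x + B u,       P_prior = A P A' + Q
    State update:   K = P_prior H' (H P_prior H' + R)^-1
                    x = x_prior + K (z - H x_prior)
                    P = (I - K H) P_prior
    """

    A: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    x: np.ndarray
    P: np.ndarray
    B: np.ndarray | None = None
    u: np.ndarray | None = None
    K: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("A", "H", "Q", "R", "P"):
            object.__setattr__(self, name,
                               np.atleast_2d(np.asarray(getattr(self, name),
                                                        dtype=float)))
        object.__setattr__(self, "x",
                           np.asarray(self.x, dtype=float).reshape(-1))
        n = self.A.shape[0]
        m = self.H.shape[0]
        if self.A.shape != (n, n) or self.P.shape != (n, n) \
                or self.Q.shape != (n, n):
            raise ValueError("A, P, Q must be square and consistent")
        if self.H.shape != (m, n) or self.R.shape != (m, m):
            raise ValueError("H, R dimensions inconsistent with the state")
        if self.x.shape != (n,):
            raise ValueError("state estimate has wrong dimension")
        for name in ("Q", "R", "P"):
            mat = getattr(self, name)
            if not np.allclose(mat, mat.T) or np.any(np.diag(mat) < 0):
                raise ValueError(f"{name} must be symmetric with a "
                                 "nonnegative diagonal")


def kalman_update(model: KalmanModel, z: np.ndarray | float) -> KalmanModel:
    """One predict + correct step; returns the updated model.

    Raises a numerical-domain error when the innovation covariance
    ``H P_prior H' + R`` is singular.
    """
    z = np.asarray(z, dtype=float).reshape(-1)
    # predict
    x_prior = model.A @ model.x
    if model.B is not None:
        u = np.zeros(np.atleast_2d(model.B).shape[1]) if model.u is None \
            else np.asarray(model.u, dtype=float).reshape(-1)
        x_prior = x_prior + np.atleast_2d(model.B) @ u
    p_prior = model.A @ model.P @ model.A.T + model.Q
    # correct
    s = model.H @ p_prior @ model.H.T + model.R
    if np.linalg.cond(s) > 1e14:
        raise np.linalg.LinAlgError("innovation covariance is singular")
    k = p_prior @ model.H.T @ np.linalg.inv(s)
    x_new = x_prior + k @ (z - model.H @ x_prior)
    p_new = (np.eye(p_prior.shape[0]) - k @ model.H) @ p_prior
    return replace(model, x=x_new, P=p_new, K=k)


# ---------------------------------------------------------------------------
# angle unwrapping
# ---------------------------------------------------------------------------

def unwrap_angles(theta_raw: np.ndarray) -> np.ndarray:
    """Remove the +-360 degree jumps of a wrapped Euler-angle sequence.

    The sensor reports angles in (-180, 180]; whenever the increment between
    adjacent samples falls below -180 deg the cycle counter k is raised by
    one (and lowered when it exceeds +180), and the corrected angle is
    ``theta_raw + k * 360``.  The output has no adjacent difference of
    magnitude > 180 deg, and wrapping it back recovers the input exactly.
    """
    theta = np.asarray(theta_raw, dtype=float)
    if theta.size == 0:
        return theta.copy()
    d = np.diff(theta)
    k = np.concatenate([[0], np.cumsum((d < -180.0).astype(int)
                                       - (d > 180.0).astype(int))])
    return theta + 360.0 * k


def wrap_angles(theta: np.ndarray) -> np.ndarray:
    """Inverse of :func:`unwrap_angles`: map angles back into (-180, 180]."""
    w = (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0
    if np.ndim(w) == 0:
        return np.asarray(180.0 if w == -180.0 else w)
    w[w == -180.0] = 180.0
    return w


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay window: half-width ``m`` and polynomial degree ``k``.

    The window length is ``p = 2 m + 1`` and the degree must satisfy
    ``k < p``.  Defaults (m=5, k=3) suppress high-frequency noise while
    preserving gait pulse shape.
    """

    half_width: int = 5
    degree: int = 3

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half-width must be >= 1")
        if self.degree < 0 or self.degree >= self.window_length:
            raise ValueError("degree must satisfy 0 <= k < 2m+1")

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1


def _design_matrix(offsets: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(offsets, degree + 1, increasing=True)


def savgol_coeffs_center(config: SGConfig) -> np.ndarray:
    """Convolution weights evaluating the local LS polynomial fit at i = 0.

    Solves the normal equations (A'A) a = A'X on the centered window; the
    smoothed value is the fitted constant term a0, i.e. the row of
    (A'A)^-1 A' belonging to a0.
    """
    offsets = np.arange(-config.half_width, config.half_width + 1, dtype=float)
    a = _design_matrix(offsets, config.degree)
    return np.linalg.solve(a.T @ a, a.T)[0]


def savgol_smooth(signal: np.ndarray, config: SGConfig = SGConfig()) -> np.ndarray:
    """Savitzky-Golay smoothing by local polynomial least squares.

    Interior points use the centered window of length ``2m+1``.  At the
    boundaries the window is truncated to the available samples and the fit
    is repeated with the same degree (reduced only if fewer points than
    coefficients remain), evaluated at the point's own offset.
    Works on 1-D signals or on the last axis of a 2-D array.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim == 2:
        return np.stack([savgol_smooth(row, config) for row in x])
    m = config.half_width
    p = config.window_length
    if x.size < p:
        raise ValueError(f"signal shorter than the window ({x.size} < {p})")
    out = np.convolve(x, savgol_coeffs_center(config)[::-1], mode="same")
    # boundary refits on truncated windows
    n = x.size
    for i in list(range(m)) + list(range(n - m, n)):
        lo, hi = max(0, i - m), min(n, i + m + 1)
        offsets = np.arange(lo - i, hi - i, dtype=float)
        deg = min(config.degree, offsets.size - 1)
        a = _design_matrix(offsets, deg)
        coef, *_ = np.linalg.lstsq(a, x[lo:hi], rcond=None)
        out[i] = coef[0]
    return out


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

@dataclass
class GaitWindow:
    """One 128-sample analysis window of both modalities.

    pressure : (12, size) kPa
    euler    : (12, size) degrees (nodes x roll/pitch/yaw, flattened)
    """

    pressure: np.ndarray
    euler: np.ndarray
    label: str
    start: int

    @property
    def size(self) -> int:
        return self.pressure.shape[1]


def _majority_label(labels: np.ndarray) -> str:
    """Most frequent frame label; ties go to the label seen earliest."""
    uniq, first_idx, counts = np.unique(labels, return_index=True,
                                        return_counts=True)
    order = np.lexsort((first_idx, -counts))
    return str(uniq[order[0]])


def segment_windows(
    recording: Recording,
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> list[GaitWindow]:
    """Slice a recording into overlapping analysis windows.

    Windows start at 0, step, 2*step, ...; the count is
    ``floor((T - size) / step) + 1``.  Each window carries the majority of
    its frame labels.  A recording shorter than one window yields an empty
    list with a warning.
    """
    t = recording.n_frames
    if t < size:
        warnings.warn(f"recording shorter than one window ({t} < {size})",
                      stacklevel=2)
        return []
    flat = recording.euler_flat
    starts = range(0, t - size + 1, step)
    return [
        GaitWindow(
            pressure=recording.pressure[:, s:s + size],
            euler=flat[:, s:s + size],
            label=_majority_label(recording.labels[s:s + size]),
            start=s,
        )
        for s in starts
    ]


def preprocess_recording(
    recording: Recording,
    sg_config: SGConfig | None = SGConfig(),
    unwrap: bool = True,
) -> Recording:
    """Standard conditioning applied before feature extraction.

    Euler angles are unwrapped into continuous trajectories and both
    modalities are Savitzky-Golay smoothed; smoothed pressure is clipped at
    zero to preserve its physical nonnegativity.
    """
    euler = recording.euler.copy()
    if unwrap:
        for node in range(4):
            for ang in range(3):
                euler[node, ang] = unwrap_angles(euler[node, ang])
    pressure = recording.pressure
    if sg_config is not None:
        pressure = np.clip(savgol_smooth(pressure, sg_config), 0.0, None)
        euler = np.stack([savgol_smooth(euler[node], sg_config)
                          for node in range(4)])
    return Recording(pressure=pressure, euler=euler,
                     labels=recording.labels.copy(),
                     sample_rate=recording.sample_rate,
                     subject_id=recording.subject_id)
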