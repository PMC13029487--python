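"""Handcrafted gait features.

Per pressure channel: 15 time-domain statistics and 3 frequency-domain
values; with 12 channels plus 6 global biomechanical features the pressure
vector has 222 dimensions.  Per Euler-angle channel: 14 time-domain and 10
frequency-domain values; with 4 nodes x 3 angles the inertial vector has
288 dimensions.  Fused: 510.  Optional add-ons: 4 roll range-of-motion
values and the left/right thigh-roll zero-lag cross-correlation.

Spectra use a Hanning taper and zero-padding to N = 512, giving a bin width
of fs/N = 100/512 ~ 0.195 Hz; all band-limited quantities live in the
physiological gait band 0.5-20 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .preprocessing import GaitWindow
from .types import ANGLE_NAMES, IMU_NODES, PRESSURE_CHANNELS, SensorLayout

__all__ = [
    "Spectrum",
    "spectrum",
    "band_spectral_features",
    "cop_trajectory",
    "pressure_time_features",
    "pressure_freq_features",
    "global_biomech_features",
    "imu_time_features",
    "imu_freq_features",
    "rom_and_symmetry",
    "assemble_features",
    "feature_names",
    "FeatureVector",
    "FeatureOptions",
    "GAIT_BAND",
    "ENERGY_SUBBANDS",
]

FS = 100.0
N_FFT = 512
GAIT_BAND = (0.5, 20.0)  # Hz, physiological gait bandwidth
# low/mid/high partition of the gait band for band-energy ratios
ENERGY_SUBBANDS = ((0.5, 3.0), (3.0, 8.0), (8.0, 20.0))
CONTACT_FRAC = 0.05  # contact floor as a fraction of peak pressure

_PRESSURE_TIME_NAMES = (
    "max", "min", "mean", "rms", "abs_mean", "var", "sd", "ptp", "iqr",
    "skew", "kurtosis", "zcr", "energy", "crest", "contact_ratio",
)
_IMU_TIME_NAMES = _PRESSURE_TIME_NAMES[:14]
_IMU_FREQ_NAMES = (
    "main_freq", "amp_mean", "amp_median", "amp_max", "amp_sd",
    "low_band_ratio", "mid_band_ratio", "high_band_ratio",
    "spectral_centroid", "spectral_bandwidth",
)
_PRESSURE_FREQ_NAMES = ("main_freq", "spectral_centroid", "spectral_prominence")
_GLOBAL_NAMES = (
    "cop_x_mean", "cop_y_mean", "cop_path_length",
    "dual_support_ratio", "stance_ratio", "load_symmetry",
)
_ADDON_NAMES = tuple(f"rom_roll_{n}" for n in IMU_NODES) + ("thigh_roll_xcorr",)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """Magnitude spectrum of a Hanning-tapered, zero-padded window."""

    freqs: np.ndarray   # Hz, nonnegative bins
    amps: np.ndarray    # |X[k]|, same length
    df: float           # bin width fs / N
    fs: float = FS


def spectrum(window: np.ndarray, n_fft: int = N_FFT, fs: float = FS) -> Spectrum:
    """Hanning-tapered, zero-padded magnitude spectrum (DFT)."""
    x = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    tapered = x * np.hanning(x.size)
    amps = np.abs(np.fft.rfft(tapered, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    return Spectrum(freqs=freqs, amps=amps, df=fs / n_fft, fs=fs)


def _band_mask(spec: Spectrum, band: tuple[float, float]) -> np.ndarray:
    f_min, f_max = band
    if not 0.0 < f_min < f_max or f_max > spec.fs / 2.0:
        raise ValueError(f"band {band} must lie within (0, fs/2)")
    mask = (spec.freqs >= f_min) & (spec.freqs <= f_max)
    if not mask.any():
        raise ValueError(f"band {band} contains no spectral bins")
    return mask


def band_spectral_features(
    spec: Spectrum, band: tuple[float, float] = GAIT_BAND
) -> tuple[float, float, float]:
    """(main frequency, spectral centroid, spectral prominence) within a band.

    The main frequency is the bin with the largest amplitude, the centroid
    is the amplitude-weighted mean frequency, and the prominence is the peak
    amplitude divided by the mean in-band amplitude (>= 1; exactly 1 for a
    flat spectrum).  A silent window degenerates to (f_min, 0, 1).
    """
    mask = _band_mask(spec, band)
    f = spec.freqs[mask]
    s = spec.amps[mask]
    total = s.sum()
    if total <= 0.0:
        return float(band[0]), 0.0, 1.0
    f_dom = float(f[np.argmax(s)])
    centroid = float((f * s).sum() / total)
    prominence = float(s.max() / s.mean())
    return f_dom, centroid, prominence


# ---------------------------------------------------------------------------
# centre of pressure
# ---------------------------------------------------------------------------

def cop_trajectory(
    pressure: np.ndarray,
    layout: SensorLayout | None = None,
    floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pressure-weighted centroid (X_cop(t), Y_cop(t)) over all 12 sensors.

    Frames whose total pressure falls below ``floor`` (default: 5% of the
    window's peak total) are undefined and returned as NaN rather than
    fabricated.
    """
    p = np.asarray(pressure, dtype=float)
    if p.ndim != 2 or p.shape[0] != 12:
        raise ValueError("pressure must be (12, T)")
    if np.any(p < 0):
        raise ValueError("pressure must be nonnegative")
    layout = layout or SensorLayout()
    coords = layout.coords12()
    total = p.sum(axis=0)
    if floor is None:
        floor = CONTACT_FRAC * total.max() if total.max() > 0 else 0.0
    defined = total > max(floor, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (coords[:, 0:1] * p).sum(axis=0) / total
        y = (coords[:, 1:2] * p).sum(axis=0) / total
    x[~defined] = np.nan
    y[~defined] = np.nan
    return x, y


# ---------------------------------------------------------------------------
# per-channel statistics
# ---------------------------------------------------------------------------

def _zero_crossing_rate(x: np.ndarray) -> float:
    xc = x - x.mean()
    s = np.sign(xc)
    s = s[s != 0]
    if s.size < 2:
        return 0.0
    return float(np.count_nonzero(s[1:] != s[:-1]) / (x.size - 1))


def _base_time_stats(x: np.ndarray) -> list[float]:
    """The 14 shared statistics: amplitude, fluctuation, morphology, energy."""
    sd = float(x.std())
    rms = float(np.sqrt(np.mean(x**2)))
    q1, q3 = np.percentile(x, [25, 75])
    # higher moments are meaningless (and numerically unstable) for a
    # (near-)constant window; report the symmetric-reference values instead
    if sd > 1e-8 * max(1.0, float(np.abs(x).max())):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(np.nan_to_num(sps.skew(x)))
            kurt = float(np.nan_to_num(sps.kurtosis(x)))
    else:
        skew = kurt = 0.0
    peak = float(np.max(np.abs(x)))
    return [
        float(x.max()), float(x.min()), float(x.mean()), rms,
        float(np.mean(np.abs(x))), float(x.var()), sd,
        float(x.max() - x.min()), float(q3 - q1), skew, kurt,
        _zero_crossing_rate(x),
        float(np.mean(x**2)),                # signal energy (mean square)
        peak / rms if rms > 0 else 0.0,      # crest factor
    ]


def pressure_time_features(
    channel: np.ndarray, contact_floor: float | None = None
) -> np.ndarray:
    """15 time-domain values for one pressure channel.

    The 14 shared statistics plus the contact ratio: the fraction of samples
    above the contact floor (default 5% of the channel's window peak).
    """
    x = np.asarray(channel, dtype=float)
    feats = _base_time_stats(x)
    if contact_floor is None:
        contact_floor = CONTACT_FRAC * x.max() if x.max() > 0 else 0.0
    feats.append(float((x > contact_floor).mean()) if x.max() > 0 else 0.0)
    return np.array(feats)


def pressure_freq_features(
    channel: np.ndarray, band: tuple[float, float] = GAIT_BAND
) -> np.ndarray:
    """3 frequency-domain values: main frequency, centroid, prominence."""
    return np.array(band_spectral_features(spectrum(channel), band))


def imu_time_features(channel: np.ndarray) -> np.ndarray:
    """14 time-domain values for one Euler-angle channel."""
    return np.array(_base_time_stats(np.asarray(channel, dtype=float)))


def imu_freq_features(
    channel: np.ndarray,
    band: tuple[float, float] = GAIT_BAND,
    subbands: tuple = ENERGY_SUBBANDS,
) -> np.ndarray:
    """10 frequency-domain values for one Euler-angle channel.

    Main frequency; mean/median/max in-band amplitude; amplitude standard
    deviation; low/mid/high band-energy ratios (partition of the in-band
    power); power-weighted spectral centroid; and spectral bandwidth (the
    power-weighted RMS deviation from the centroid).
    """
    spec = spectrum(channel)
    mask = _band_mask(spec, band)
    f = spec.freqs[mask]
    a = spec.amps[mask]
    power = a**2
    total_power = power.sum()

    f_dom, _, _ = band_spectral_features(spec, band)
    if total_power > 0:
        centroid = float((f * power).sum() / total_power)
        bandwidth = float(np.sqrt((power * (f - centroid) ** 2).sum()
                                  / total_power))
        ratios = []
        for lo, hi in subbands:
            sub = (f >= lo) & (f < hi)
            if hi == band[1]:
                sub = (f >= lo) & (f <= hi)
            ratios.append(float(power[sub].sum() / total_power))
    else:
        centroid = bandwidth = 0.0
        ratios = [0.0, 0.0, 0.0]

    return np.array([
        f_dom, float(a.mean()), float(np.median(a)), float(a.max()),
        float(a.std()), *ratios, centroid, bandwidth,
    ])


# ---------------------------------------------------------------------------
# global biomechanics
# ---------------------------------------------------------------------------

def _foot_contact(pressure: np.ndarray, floor: float | None = None):
    left = pressure[:6].sum(axis=0)
    right = pressure[6:].sum(axis=0)
    if floor is None:
        peak = max(left.max(), right.max())
        floor = CONTACT_FRAC * peak if peak > 0 else 0.0
    return left, right, left > floor, right > floor


def global_biomech_features(
    window: GaitWindow | np.ndarray,
    layout: SensorLayout | None = None,
    contact_floor: float | None = None,
) -> np.ndarray:
    """6 global values: mean COP-X/Y, COP path length, dual-support ratio,
    stance ratio, left/right load-symmetry index.

    The symmetry index is (L - R) / (L + R) of the mean foot loads: 0 for
    perfectly symmetric loading, +-1 for single-sided loading.  COP means
    are taken over defined frames only; a window with no defined COP frame
    reports zeros for the COP values.
    """
    pressure = window.pressure if isinstance(window, GaitWindow) else window
    layout = layout or SensorLayout()
    left, right, l_on, r_on = _foot_contact(pressure, contact_floor)
    x, y = cop_trajectory(pressure, layout)
    ok = np.isfinite(x)
    if ok.any():
        cop_x, cop_y = float(np.mean(x[ok])), float(np.mean(y[ok]))
        both = ok[:-1] & ok[1:]
        path = float(np.sum(np.hypot(np.diff(x), np.diff(y))[both])) \
            if both.any() else 0.0
    else:
        cop_x = cop_y = path = 0.0
    dual = float((l_on & r_on).mean())
    stance = float((l_on.mean() + r_on.mean()) / 2.0)
    tot = left.mean() + right.mean()
    sym = float((left.mean() - right.mean()) / tot) if tot > 0 else 0.0
    return np.array([cop_x, cop_y, path, dual, stance, sym])


def rom_and_symmetry(window: GaitWindow) -> np.ndarray:
    """4 roll range-of-motion values + left/right thigh-roll cross-correlation.

    ROM is max - min of each node's roll angle within the window.  The
    cross-correlation is the zero-lag normalized correlation of the two
    thigh roll sequences (about -1 for anti-phase gait); it is NaN
    (undefined) when either sequence has zero variance.
    """
    euler = window.euler.reshape(4, 3, -1)
    rom = euler[:, 0].max(axis=1) - euler[:, 0].min(axis=1)
    lt = euler[0, 0] - euler[0, 0].mean()
    rt = euler[1, 0] - euler[1, 0].mean()
    denom = np.sqrt((lt**2).sum() * (rt**2).sum())
    xcorr = float((lt * rt).sum() / denom) if denom > 0 else np.nan
    return np.concatenate([rom, [xcorr]])


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureOptions:
    """What goes into an assembled vector."""

    modality: str = "fused"          # "fused" | "pressure" | "imu"
    include_addons: bool = False
    band: tuple[float, float] = GAIT_BAND
    subbands: tuple = ENERGY_SUBBANDS

    def __post_init__(self) -> None:
        if self.modality not in ("fused", "pressure", "imu"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    label: str
    modality: str


def feature_names(options: FeatureOptions = FeatureOptions()) -> tuple[str, ...]:
    """Stable, unique feature names in assembly order."""
    names: list[str] = []
    if options.modality in ("fused", "pressure"):
        for ch in PRESSURE_CHANNELS:
            names += [f"p_{ch}_{s}" for s in _PRESSURE_TIME_NAMES]
            names += [f"p_{ch}_{s}" for s in _PRESSURE_FREQ_NAMES]
        names += [f"glob_{s}" for s in _GLOBAL_NAMES]
    if options.modality in ("fused", "imu"):
        for node in IMU_NODES:
            for ang in ANGLE_NAMES:
                names += [f"imu_{node}_{ang}_{s}" for s in _IMU_TIME_NAMES]
                names += [f"imu_{node}_{ang}_{s}" for s in _IMU_FREQ_NAMES]
    if options.include_addons:
        names += [f"addon_{s}" for s in _ADDON_NAMES]
    return tuple(names)


def assemble_features(
    window: GaitWindow,
    layout: SensorLayout | None = None,
    options: FeatureOptions = FeatureOptions(),
) -> FeatureVector:
    """Assemble the handcrafted vector for one window.

    Pressure part: 12 channels x (15 time + 3 freq) + 6 global = 222.
    Inertial part: 4 nodes x 3 angles x (14 time + 10 freq) = 288.
    Fused: 510.  Add-ons (4 ROM + thigh-roll cross-correlation) are appended
    only when enabled; an undefined cross-correlation is reported as 0.
    """
    layout = layout or SensorLayout()
    parts: list[np.ndarray] = []
    if options.modality in ("fused", "pressure"):
        for ch in range(12):
            parts.append(pressure_time_features(window.pressure[ch]))
            parts.append(pressure_freq_features(window.pressure[ch],
                                                options.band))
        parts.append(global_biomech_features(window, layout))
    if options.modality in ("fused", "imu"):
        for ch in range(12):
            parts.append(imu_time_features(window.euler[ch]))
            parts.append(imu_freq_features(window.euler[ch], options.band,
                                           options.subbands))
    if options.include_addons:
        addons = rom_and_symmetry(window)
        parts.append(np.nan_to_num(addons, nan=0.0))
    values = np.concatenate(parts)
    names = feature_names(options)
    assert values.size == len(names)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values")
    return FeatureVector(values=values, names=names, label=window.label,
                         modality=options.modality)
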