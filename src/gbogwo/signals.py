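"""Raw tri-axial accelerometer signal -> 150-feature table.

The chain mirrors the standard smartphone-accelerometer preprocessing:
zero-phase low-pass denoising, body/gravity separation at 0.3 Hz,
fixed-width 128-sample windows with 50% overlap, then 75 features per
source signal (66 time-domain + 9 frequency-domain) computed for the body
and gravity components alike — 150 columns in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from statsmodels.regression.linear_model import burg

__all__ = [
    "RawRecording",
    "Segment",
    "FeatureConfig",
    "lowpass_denoise",
    "split_body_gravity",
    "segment_windows",
    "time_features",
    "freq_features",
    "build_feature_table",
    "feature_names",
]

_AXES = ("x", "y", "z")
_AR_ORDER = 4
_HIST_BINS = 5


@dataclass
class RawRecording:
    """Uniformly sampled (t, x, y, z, label) accelerometer stream."""

    t: np.ndarray
    xyz: np.ndarray          # (n, 3)
    labels: np.ndarray       # (n,)
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if not (self.t.shape[0] == self.xyz.shape[0] == self.labels.shape[0]):
            raise ValueError("t, xyz and labels must have equal length")

    @property
    def n_samples(self) -> int:
        return int(self.xyz.shape[0])

    @classmethod
    def from_csv(cls, path, fs: float) -> "RawRecording":
        df = pd.read_csv(path)
        required = {"t", "x", "y", "z", "label"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"raw CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        return cls(df["t"].to_numpy(), df[["x", "y", "z"]].to_numpy(),
                   df["label"].to_numpy(), fs)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "x": self.xyz[:, 0], "y": self.xyz[:, 1],
                      "z": self.xyz[:, 2], "label": self.labels}).to_csv(
            path, index=False)


@dataclass
class Segment:
    """One analysis window: 3 x L body and gravity arrays plus a label."""

    body: np.ndarray
    gravity: np.ndarray
    label: object
    fs: float


@dataclass
class FeatureConfig:
    """Tunables of the feature pipeline.

    ``corner_hz`` is the denoising low-pass corner (use a value below the
    Nyquist frequency of the recording; None skips denoising),
    ``gravity_hz`` the body/gravity split corner, windows are
    ``window_len`` samples with ``overlap_frac`` overlap.
    """

    corner_hz: float | None = 20.0
    gravity_hz: float = 0.3
    window_len: int = 128
    overlap_frac: float = 0.5
    filter_order: int = 3


def _butter_lowpass(data: np.ndarray, corner_hz: float, fs: float,
                    order: int) -> np.ndarray:
    sos = sp_signal.butter(order, corner_hz, btype="low", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, data, axis=0)


def lowpass_denoise(recording: RawRecording, corner_hz: float = 20.0,
                    order: int = 3) -> RawRecording:
    """Zero-phase Butterworth low-pass applied per axis."""
    if corner_hz >= recording.fs / 2:
        raise ValueError(
            f"corner frequency {corner_hz} Hz must be below the Nyquist "
            f"frequency {recording.fs / 2} Hz"
        )
    filtered = _butter_lowpass(recording.xyz, corner_hz, recording.fs, order)
    return RawRecording(recording.t, filtered, recording.labels, recording.fs)


def split_body_gravity(recording: RawRecording, gravity_hz: float = 0.3,
                       order: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """(body, gravity) with gravity = low-pass at ``gravity_hz`` and
    body = input - gravity, so the two reconstruct the input exactly."""
    gravity = _butter_lowpass(recording.xyz, gravity_hz, recording.fs, order)
    return recording.xyz - gravity, gravity


def _majority_label(labels: np.ndarray):
    # majority vote, ties broken by first appearance within the window
    values, first_pos, counts = np.unique(labels, return_index=True,
                                          return_counts=True)
    order = np.lexsort((first_pos, -counts))
    return values[order[0]]


def segment_windows(body: np.ndarray, gravity: np.ndarray,
                    labels: np.ndarray, fs: float, window_len: int = 128,
                    overlap_frac: float = 0.5) -> list[Segment]:
    """Fixed-width sliding windows; trailing partial window dropped."""
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    step = max(1, int(round(window_len * (1.0 - overlap_frac))))
    n = body.shape[0]
    out = []
    for start in range(0, n - window_len + 1, step):
        sl = slice(start, start + window_len)
        out.append(Segment(body[sl].T.copy(), gravity[sl].T.copy(),
                           _majority_label(labels[sl]), fs))
    return out


# ---------------------------------------------------------------------------
# feature computation
# ---------------------------------------------------------------------------


def _ar_coeffs(v: np.ndarray) -> np.ndarray:
    """Burg AR(4) coefficients; degenerate (constant) input yields zeros."""
    if np.ptp(v) == 0 or v.shape[0] <= _AR_ORDER + 1:
        warnings.warn("constant or too-short axis: AR coefficients set to 0")
        return np.zeros(_AR_ORDER)
    try:
        rho, _ = burg(v, order=_AR_ORDER, demean=True)
        return np.asarray(rho, dtype=float)
    except (ValueError, np.linalg.LinAlgError):
        warnings.warn("AR estimation degenerate: coefficients set to 0")
        return np.zeros(_AR_ORDER)


def _power_spectrum(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    spec = np.abs(np.fft.rfft(v)) ** 2
    return spec, spec.sum()


def _spectral_entropy(v: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalized one-sided power spectrum."""
    spec, total = _power_spectrum(v)
    if total <= 1e-300:
        return 0.0
    p = spec / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _histogram_counts(v: np.ndarray) -> np.ndarray:
    """5 equal-width bins over the axis's own range, normalized by L.

    A constant axis has zero width; all mass goes to the middle bin.
    """
    if v.min() == v.max():
        counts = np.zeros(_HIST_BINS)
        counts[_HIST_BINS // 2] = v.shape[0]
    else:
        counts, _ = np.histogram(v, bins=_HIST_BINS, range=(v.min(), v.max()))
    return counts / v.shape[0]


def _moment_or_zero(fn, v: np.ndarray) -> float:
    out = fn(v)
    return float(out) if np.isfinite(out) else 0.0


def time_features(source: np.ndarray, fs: float) -> dict[str, float]:
    """66 time-domain features of one 3 x L source signal.

    Grouping: per-axis AR(4) (12), AR(4) of the magnitude signal (4),
    mean jerk magnitude "acceleration" (1), per-axis jerk spectral entropy
    (3), per-axis 5-bin histogram (15), per-axis kurtosis / mean / max /
    skewness / STD / mean absolute difference (3 each), per-axis jerk mean
    and STD (3 + 3), magnitude mean and STD (1 + 1), per-axis mean-square
    power (3), SMA (1), tilt angle (1).
    """
    if source.shape[0] != 3:
        raise ValueError("source must be a 3 x L array")
    L = source.shape[1]
    if L < 8:
        raise ValueError("segment too short for feature extraction (L >= 8)")
    mag = np.linalg.norm(source, axis=0)
    jerk = np.diff(source, axis=1) * fs
    jerk_mag = np.linalg.norm(jerk, axis=0)

    f: dict[str, float] = {}
    for a, ax in enumerate(_AXES):
        for k, c in enumerate(_ar_coeffs(source[a]), start=1):
            f[f"ar_{ax}_{k}"] = float(c)
    for k, c in enumerate(_ar_coeffs(mag), start=1):
        f[f"ar_mag_{k}"] = float(c)
    f["acceleration"] = float(jerk_mag.mean())
    for a, ax in enumerate(_AXES):
        f[f"jerk_entropy_{ax}"] = _spectral_entropy(jerk[a])
    for a, ax in enumerate(_AXES):
        for k, c in enumerate(_histogram_counts(source[a]), start=1):
            f[f"hist_{ax}_{k}"] = float(c)
    for a, ax in enumerate(_AXES):
        v = source[a]
        f[f"kurtosis_{ax}"] = _moment_or_zero(sp_stats.kurtosis, v)
        f[f"mean_{ax}"] = float(v.mean())
        f[f"jerk_mean_{ax}"] = float(jerk[a].mean())
        f[f"max_{ax}"] = float(v.max())
        f[f"mad_{ax}"] = float(np.abs(v - v.mean()).mean())
        f[f"power_{ax}"] = float((v ** 2).mean())
        f[f"skewness_{ax}"] = _moment_or_zero(sp_stats.skew, v)
        f[f"std_{ax}"] = float(v.std())
        f[f"jerk_std_{ax}"] = float(jerk[a].std())
    f["mag_mean"] = float(mag.mean())
    f["mag_std"] = float(mag.std())
    f["sma"] = float(np.abs(source).sum() / L)
    mean_vec = source.mean(axis=1)
    norm = np.linalg.norm(mean_vec)
    # tilt: angle between the window's mean vector and the vertical (z) axis
    f["tilt_angle"] = (float(np.degrees(np.arccos(
        np.clip(mean_vec[2] / norm, -1.0, 1.0)))) if norm > 0 else 0.0)
    return f


def freq_features(source: np.ndarray, fs: float) -> dict[str, float]:
    """9 frequency-domain features: per-axis mean / max / median frequency
    of the one-sided power spectrum (zero-power axes report 0)."""
    if source.shape[0] != 3:
        raise ValueError("source must be a 3 x L array")
    L = source.shape[1]
    if L < 8:
        raise ValueError("segment too short for feature extraction (L >= 8)")
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    f: dict[str, float] = {}
    for a, ax in enumerate(_AXES):
        spec, total = _power_spectrum(source[a])
        if total <= 1e-300:
            warnings.warn(f"zero-power axis {ax}: frequency features set to 0")
            f[f"freq_mean_{ax}"] = 0.0
            f[f"freq_max_{ax}"] = 0.0
            f[f"freq_median_{ax}"] = 0.0
            continue
        f[f"freq_mean_{ax}"] = float((freqs * spec).sum() / total)
        f[f"freq_max_{ax}"] = float(freqs[int(np.argmax(spec))])
        cum = np.cumsum(spec)
        f[f"freq_median_{ax}"] = float(freqs[int(np.searchsorted(
            cum, total / 2.0))])
    return f


def _source_features(source: np.ndarray, fs: float, prefix: str
                     ) -> dict[str, float]:
    out = {f"{prefix}_{k}": v for k, v in time_features(source, fs).items()}
    out.update({f"{prefix}_{k}": v
                for k, v in freq_features(source, fs).items()})
    return out


def feature_names() -> list[str]:
    """Stable, documented column order of the 150-feature table."""
    probe = np.vstack([np.linspace(0, 1, 16), np.ones(16), np.zeros(16)])
    names = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for prefix in ("body", "grav"):
            names.extend(_source_features(probe, 16.0, prefix))
    return names


def build_feature_table(recording: RawRecording,
                        config: FeatureConfig | None = None) -> pd.DataFrame:
    """Full chain: denoise -> body/gravity split -> windows -> 150 features.

    Returns a DataFrame with 150 feature columns (75 body + 75 gravity per
    segment) and a trailing ``label`` column.
    """
    config = config or FeatureConfig()
    rec = recording
    if config.corner_hz is not None:
        rec = lowpass_denoise(rec, config.corner_hz, config.filter_order)
    body, gravity = split_body_gravity(rec, config.gravity_hz,
                                       config.filter_order)
    segments = segment_windows(body, gravity, rec.labels, rec.fs,
                               config.window_len, config.overlap_frac)
    rows = []
    for seg in segments:
        row = _source_features(seg.body, seg.fs, "body")
        row.update(_source_features(seg.gravity, seg.fs, "grav"))
        row["label"] = seg.label
        rows.append(row)
    table = pd.DataFrame(rows)
    if rows:
        expected = feature_names() + ["label"]
        table = table[expected]
    return table
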