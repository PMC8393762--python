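"""Synthetic signals, feature-selection problems, and reference fixtures.

Everything other modules need is generated with known ground truth:
quasi-periodic tri-axial accelerometer recordings (gravity projection +
class-specific band-limited oscillation + Gaussian noise), tabular
feature-selection problems with a known informative subset, and two
verbatim published-style confusion-count fixtures for the evaluation
arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix
from .signals import RawRecording

__all__ = [
    "ActivityClassSpec",
    "FSProblemSpec",
    "default_activity_classes",
    "simulate_recording",
    "make_fs_problem",
    "fixture_confusion_matrices",
]

GRAVITY = 9.8


@dataclass
class ActivityClassSpec:
    """One simulated activity: orientation, oscillation, and noise level."""

    name: str
    fundamental_hz: float
    amplitude: tuple[float, float, float]
    gravity_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sd: float = 0.3
    harmonics: int = 2

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fundamental_hz <= 0:
            raise ValueError("fundamental_hz must be positive")

    def unit_orientation(self) -> np.ndarray:
        v = np.asarray(self.gravity_orientation, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("gravity orientation must be a non-zero vector")
        return v / n


@dataclass
class FSProblemSpec:
    """A tabular selection problem with a known informative subset."""

    n_instances: int = 200
    n_informative: int = 5
    n_noise: int = 45
    n_classes: int = 6
    effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


def default_activity_classes(fs: float = 20.0) -> list[ActivityClassSpec]:
    """Three stylized activities distinguishable in rhythm, intensity and
    device orientation (walk / jog / sit)."""
    return [
        ActivityClassSpec("walk", fundamental_hz=2.0,
                          amplitude=(1.2, 2.0, 0.8),
                          gravity_orientation=(0.0, 0.0, 1.0),
                          noise_sd=0.3, harmonics=2),
        ActivityClassSpec("jog", fundamental_hz=2.8,
                          amplitude=(2.5, 4.0, 1.8),
                          gravity_orientation=(0.0, 0.2, 1.0),
                          noise_sd=0.5, harmonics=3),
        ActivityClassSpec("sit", fundamental_hz=0.5,
                          amplitude=(0.05, 0.05, 0.05),
                          gravity_orientation=(0.0, 1.0, 0.3),
                          noise_sd=0.1, harmonics=1),
    ]


def simulate_recording(class_specs: list[ActivityClassSpec],
                       seconds_per_class: float, fs: float,
                       rng: np.random.Generator) -> RawRecording:
    """Concatenate per-class segments of gravity + oscillation + noise.

    Per class: the 9.8-unit gravity vector projected onto the class
    orientation, plus per-axis sinusoids at the fundamental frequency with
    1/h-weighted harmonics and random phases, plus white Gaussian noise.
    Harmonics at or above the Nyquist frequency are dropped.
    """
    n_per = int(round(seconds_per_class * fs))
    chunks, labels = [], []
    for spec in class_specs:
        if spec.fundamental_hz >= fs / 2:
            raise ValueError(
                f"class {spec.name!r}: fundamental {spec.fundamental_hz} Hz "
                f"is at or above the Nyquist frequency {fs / 2} Hz"
            )
        t = np.arange(n_per) / fs
        sig = np.tile(GRAVITY * spec.unit_orientation(), (n_per, 1))
        amp = np.asarray(spec.amplitude, dtype=float)
        for h in range(1, spec.harmonics + 1):
            f_h = h * spec.fundamental_hz
            if f_h >= fs / 2:
                break
            phases = rng.uniform(0, 2 * np.pi, size=3)
            sig += (amp / h) * np.sin(2 * np.pi * f_h * t[:, None]
                                      + phases[None, :])
        sig += rng.normal(0.0, spec.noise_sd, size=(n_per, 3))
        chunks.append(sig)
        labels.append(np.full(n_per, spec.name, dtype=object))
    xyz = np.vstack(chunks)
    n = xyz.shape[0]
    return RawRecording(np.arange(n) / fs, xyz,
                        np.concatenate(labels), fs)


def make_fs_problem(spec: FSProblemSpec
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table plus the boolean ground-truth informative mask.

    Informative feature j shifts the class mean by ``effect_size`` standard
    deviations across the class cut ``1 + (j mod (K-1))`` (a thermometer
    code over the K ordered classes), so with n_informative = K-1 every
    informative feature is individually necessary to separate one adjacent
    class pair.  Noise features are standard Gaussians independent of the
    class.  At effect_size 0 no feature carries any class signal.
    """
    rng = np.random.default_rng(spec.seed)
    n, d_inf, d_noise = spec.n_instances, spec.n_informative, spec.n_noise
    K = spec.n_classes
    classes = np.arange(n) % K
    classes = rng.permutation(classes)
    X = rng.standard_normal((n, d_inf + d_noise))
    for j in range(d_inf):
        cut = 1 + (j % (K - 1))
        X[:, j] += spec.effect_size * (classes >= cut)
    # shuffle column placement so informative features are not a prefix
    perm = rng.permutation(d_inf + d_noise)
    X = X[:, perm]
    truth = np.zeros(d_inf + d_noise, dtype=bool)
    truth[np.flatnonzero(perm < d_inf)] = True
    table = pd.DataFrame(X, columns=[f"f{j:03d}"
                                     for j in range(d_inf + d_noise)])
    table["label"] = [f"c{c}" for c in classes]
    return table, truth


# ---------------------------------------------------------------------------
# published-style confusion-count fixtures
# ---------------------------------------------------------------------------

_UCI_LABELS = ["WK", "WU", "WD", "ST", "SD", "LD"]
_UCI_COUNTS = [
    [496, 0, 0, 0, 0, 0],
    [0, 471, 0, 0, 0, 0],
    [4, 10, 406, 0, 0, 0],
    [0, 1, 0, 454, 36, 0],
    [0, 0, 0, 8, 524, 0],
    [0, 0, 0, 0, 0, 537],
]

_WISDM_LABELS = ["WD", "ST", "SD", "WU", "WK", "JG"]
_WISDM_COUNTS = [
    [426, 0, 0, 27, 0, 2],
    [0, 266, 1, 3, 0, 0],
    [0, 0, 216, 0, 0, 0],
    [7, 0, 0, 539, 0, 15],
    [0, 0, 0, 0, 1943, 0],
    [0, 0, 0, 2, 0, 1588],
]


def fixture_confusion_matrices() -> dict[str, ConfusionMatrix]:
    """The two reference 6-activity confusion matrices (rows predicted,
    columns true).  Counts only — every rate is recomputed downstream."""
    return {
        "uci_har": ConfusionMatrix(np.array(_UCI_COUNTS), list(_UCI_LABELS)),
        "wisdm": ConfusionMatrix(np.array(_WISDM_COUNTS), list(_WISDM_LABELS)),
    }


def write_ground_truth(path, class_specs: list[ActivityClassSpec],
                       fs: float, seconds_per_class: float,
                       seed: int) -> None:
    """JSON sidecar describing a simulated recording."""
    payload = {
        "fs": fs,
        "seconds_per_class": seconds_per_class,
        "seed": seed,
        "classes": [
            {
                "name": s.name,
                "fundamental_hz": s.fundamental_hz,
                "amplitude": list(s.amplitude),
                "gravity_orientation": list(s.gravity_orientation),
                "noise_sd": s.noise_sd,
                "harmonics": s.harmonics,
            }
            for s in class_specs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
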