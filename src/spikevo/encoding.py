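"""Population encoding of real-valued features into first-spike times.

Each analog feature is presented to ``L`` overlapping Gaussian receptive
fields ("encoding neurons").  The response of field *i* to a value *x* is

    r_i = exp(-(x - mu_i)^2 / (2 sigma^2))            in [0, 1]

and responses are mapped linearly onto an encoding window [t_min, t_max]
(default [0, 10] ms) with the time-to-first-spike convention: the strongest
response fires earliest,

    t_i = round_to_dt((1 - r_i) * (t_max - t_min) + t_min).

Field centres and the common spread are derived from the feature's value
range [I_min, I_max]:

    mu_i  = I_min + (2i - 3)/2 * (I_max - I_min)/(L - 2),   i = 1..L
    sigma = (1/beta) * (I_max - I_min)/(L - 2)

with ``beta`` an overlap-adjustment factor in [1, 2] (default 1.5).  A bias
neuron that always fires at 0 ms is appended to every encoded sample, so a
table with F features becomes F*L + 1 input spike times per instance.

Class labels are coded as desired *output* spike times placed after the
encoding window (e.g. three classes at 11, 12 and 13 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncoderConfig",
    "ClassCodebook",
    "gaussian_centers",
    "gaussian_sigma",
    "round_to_dt",
    "encode_feature",
    "encode_sample",
    "encode_dataset",
    "infer_feature_ranges",
    "make_codebook",
]


class ConfigurationError(ValueError):
    """Raised for invalid encoder/simulator/GA configurations."""


def gaussian_centers(i_min: float, i_max: float, n_fields: int) -> np.ndarray:
    """Centre positions of the receptive fields for one feature.

    Centres are evenly spaced with step (i_max - i_min)/(L - 2) and are
    symmetric about the midpoint of the range; the outermost two centres
    lie half a step *outside* [i_min, i_max].
    """
    if n_fields < 3:
        raise ConfigurationError(f"need at least 3 encoding neurons per feature, got {n_fields}")
    if not i_min < i_max:
        raise ConfigurationError(f"feature range must satisfy I_min < I_max, got ({i_min}, {i_max})")
    i = np.arange(1, n_fields + 1, dtype=float)
    return i_min + (2.0 * i - 3.0) / 2.0 * (i_max - i_min) / (n_fields - 2)


def gaussian_sigma(i_min: float, i_max: float, n_fields: int, beta: float) -> float:
    """Common spread of the receptive fields, sigma = (1/beta)*(range/(L-2))."""
    if n_fields < 3:
        raise ConfigurationError(f"need at least 3 encoding neurons per feature, got {n_fields}")
    if not i_min < i_max:
        raise ConfigurationError(f"feature range must satisfy I_min < I_max, got ({i_min}, {i_max})")
    if not 1.0 <= beta <= 2.0:
        warnings.warn(
            f"beta={beta} is outside the recommended range [1, 2]; 1.5 is the usual choice",
            stacklevel=2,
        )
    return (i_max - i_min) / (n_fields - 2) / beta


def round_to_dt(t, dt: float):
    """Round times to the nearest multiple of ``dt``, half-steps rounding up.

    A 1e-9-step epsilon keeps exact half-steps on the "up" side despite
    binary floating point (e.g. 6.75 ms at dt=0.1 rounds to 6.8).
    """
    return np.floor(np.asarray(t, dtype=float) / dt + 0.5 + 1e-9) * dt


@dataclass(frozen=True)
class EncoderConfig:
    """Configuration of the population encoder.

    Parameters
    ----------
    n_fields : int
        Encoding neurons per feature (L >= 3; the centre/spread formulas
        divide by L - 2).
    beta : float
        Spread adjustment factor, recommended in [1, 2].
    t_min, t_max : float
        Bounds of the encoding window in ms.
    dt : float
        Time step (ms) that spike times are rounded to; must match the
        simulator's step.
    feature_ranges : tuple of (I_min, I_max)
        Per-feature value ranges used to place the receptive fields.
        Normally inferred from the *training* split.
    """

    n_fields: int = 4
    beta: float = 1.5
    t_min: float = 0.0
    t_max: float = 10.0
    dt: float = 1.0
    feature_ranges: tuple = field(default=())

    def __post_init__(self):
        if self.n_fields < 3:
            raise ConfigurationError(f"n_fields must be >= 3, got {self.n_fields}")
        if not self.t_min < self.t_max:
            raise ConfigurationError("t_min must be < t_max")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        for lo, hi in self.feature_ranges:
            if not lo < hi:
                raise ConfigurationError(f"feature range ({lo}, {hi}) is not ordered")
        if not 1.0 <= self.beta <= 2.0:
            warnings.warn(
                f"beta={self.beta} is outside the recommended range [1, 2]",
                stacklevel=2,
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ranges)

    @property
    def n_input_neurons(self) -> int:
        """Total input neurons: F*L receptive fields plus one bias neuron."""
        return self.n_features * self.n_fields + 1


def infer_feature_ranges(features: np.ndarray) -> tuple:
    """Per-column (min, max) pairs of a feature matrix.

    Constant columns get a degenerate range widened by +/-0.5 so the
    encoder stays defined.
    """
    x = np.asarray(features, dtype=float)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    flat = hi <= lo
    lo = np.where(flat, lo - 0.5, lo)
    hi = np.where(flat, hi + 0.5, hi)
    return tuple((float(a), float(b)) for a, b in zip(lo, hi))


def encode_feature(x: float, centers: np.ndarray, sigma: float, cfg: EncoderConfig) -> np.ndarray:
    """Spike times (ms) of one feature's L encoding neurons.

    Values outside the configured feature range are allowed: their
    responses simply approach 0, i.e. spikes near ``t_max``.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    r = np.exp(-((x - centers) ** 2) / (2.0 * sigma**2))
    raw = (1.0 - r) * (cfg.t_max - cfg.t_min) + cfg.t_min
    return round_to_dt(raw, cfg.dt)


def encode_sample(features, cfg: EncoderConfig) -> np.ndarray:
    """Encode one instance into a vector of F*L + 1 input spike times.

    The final entry is the bias neuron, which always fires at 0 ms.
    Non-finite feature values are rejected (missing data must be handled
    by the loading policy before encoding).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 1 or x.size != cfg.n_features:
        raise ValueError(f"expected {cfg.n_features} features, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature value; impute or drop missing data before encoding")
    parts = []
    for value, (lo, hi) in zip(x, cfg.feature_ranges):
        centers = gaussian_centers(lo, hi, cfg.n_fields)
        sigma = gaussian_sigma(lo, hi, cfg.n_fields, cfg.beta)
        parts.append(encode_feature(value, centers, sigma, cfg))
    parts.append(np.array([0.0]))  # bias neuron
    return np.concatenate(parts)


def encode_dataset(features, cfg: EncoderConfig) -> np.ndarray:
    """Encode an (n, F) feature matrix into an (n, F*L + 1) spike-time matrix."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    return np.stack([encode_sample(row, cfg) for row in x])


@dataclass(frozen=True)
class ClassCodebook:
    """Mapping from class label to desired output spike time (ms)."""

    times: dict

    def __post_init__(self):
        values = list(self.times.values())
        if len(set(values)) != len(values):
            raise ConfigurationError("codebook target times must be distinct per class")

    @property
    def labels(self) -> list:
        return list(self.times.keys())

    def target_times(self, labels) -> np.ndarray:
        return np.array([self.times[lab] for lab in labels], dtype=float)

    def decode(self, t_out: float, no_spike_time: float) -> object:
        """Class whose target time is nearest to ``t_out``.

        A missing output spike is scored at ``no_spike_time`` (the end of
        the simulation window).  Ties go to the class with the earlier
        target time.
        """
        t = no_spike_time if not np.isfinite(t_out) else t_out
        items = sorted(self.times.items(), key=lambda kv: kv[1])
        best = min(items, key=lambda kv: abs(t - kv[1]))
        return best[0]


def make_codebook(
    class_labels,
    start_time: float = 11.0,
    spacing: float = 1.0,
    t_max_encoding: float = 10.0,
    t_total: float = 20.0,
) -> ClassCodebook:
    """Assign evenly spaced target output times to classes, in label order.

    Targets must sit strictly after the encoding window and at or before
    the simulation horizon ``t_total``.
    """
    labels = list(class_labels)
    if not labels:
        raise ConfigurationError("need at least one class label")
    if start_time <= t_max_encoding:
        raise ConfigurationError(
            f"codebook start {start_time} ms must lie after the encoding window (> {t_max_encoding} ms)"
        )
    last = start_time + (len(labels) - 1) * spacing
    if last > t_total:
        raise ConfigurationError(
            f"codebook extends to {last} ms, beyond the simulation horizon T={t_total} ms"
        )
    return ClassCodebook({lab: start_time + i * spacing for i, lab in enumerate(labels)})
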