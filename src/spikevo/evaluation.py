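"""Decoding, classification metrics and the computational-efficiency metric.

The output neuron's first-spike time is decoded to the class whose
codebook target time is nearest (ties to the earlier target; a silent
output is scored at the simulation horizon T).  Computational efficiency
summarises a training run as

    CE = dt / (T * G)

where dt is the integration step, T the simulation horizon and G the
generation at which training converged — larger is better (coarser steps,
shorter horizons and faster convergence all raise it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import ClassCodebook

__all__ = ["EvalReport", "decode_class", "decode_outputs", "accuracy", "confusion_matrix", "compute_ce"]


def decode_class(t_out: float, codebook: ClassCodebook, no_spike_time: float = 20.0):
    """Nearest-target decoding of one output spike time."""
    if not codebook.times:
        raise ValueError("codebook is empty")
    return codebook.decode(t_out, no_spike_time)


def decode_outputs(t_out, codebook: ClassCodebook, no_spike_time: float = 20.0) -> list:
    """Decode a vector of output spike times to class labels."""
    return [decode_class(t, codebook, no_spike_time) for t in np.asarray(t_out, dtype=float)]


def accuracy(predicted, actual) -> float:
    """Percentage of matching labels."""
    predicted = list(predicted)
    actual = list(actual)
    if len(predicted) != len(actual):
        raise ValueError("label vectors must have equal length")
    if not predicted:
        raise ValueError("cannot compute accuracy of an empty label set")
    return 100.0 * sum(p == a for p, a in zip(predicted, actual)) / len(predicted)


def confusion_matrix(actual, predicted, labels) -> np.ndarray:
    """k x k count matrix with rows = true class, columns = predicted class.

    ``labels`` fixes the class order; any label outside it is an error.
    """
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(actual, predicted, strict=True):
        if a not in index or p not in index:
            raise ValueError(f"label outside the declared set: true={a!r}, predicted={p!r}")
        mat[index[a], index[p]] += 1
    return mat


def compute_ce(dt: float, t_total: float, generations: int) -> float:
    """Computational efficiency CE = dt / (T * G)."""
    if dt <= 0 or t_total <= 0:
        raise ValueError("dt and T must be positive")
    if generations < 1:
        raise ValueError("CE is undefined for G < 1")
    return dt / (t_total * generations)


@dataclass
class EvalReport:
    """Classification report for one dataset split."""

    accuracy: float
    confusion: np.ndarray
    labels: list
    ce: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy must be a percentage")

    @property
    def n_instances(self) -> int:
        return int(self.confusion.sum())

    def to_text(self) -> str:
        lines = [f"accuracy: {self.accuracy:.2f}% over {self.n_instances} instances"]
        if self.ce is not None:
            lines.append(f"computational efficiency CE = {self.ce:.3e}")
        header = "true \\ pred".ljust(12) + "".join(str(l).rjust(10) for l in self.labels)
        lines.append(header)
        for lab, row in zip(self.labels, self.confusion):
            lines.append(str(lab).ljust(12) + "".join(str(int(c)).rjust(10) for c in row))
        for key, value in self.meta.items():
            lines.append(f"{key}: {value}")
        return "\n".join(lines)
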