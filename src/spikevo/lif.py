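"""Leaky integrate-and-fire neurons with trainable integer synaptic delays.

The sub-threshold membrane potential of post-synaptic neuron j follows

    tau_m * dv_j/dt = -(v_j - v_rest) + xi_j(t) * R_m

integrated with explicit Euler on a grid t = dt, 2dt, ..., T.  The drive is
a weighted, delayed sum over pre-synaptic first-spike times t_i:

    xi_j(t) = sum_i  w_ij * Psi(t - t_i - kappa_ij)

with the double-exponential synaptic current kernel

    Psi(x) = [exp(-x/tau_m) - exp(-x/tau_s)] * H(x),   0 < tau_s < tau_m,

where H is the Heaviside step (H(x)=1 for x>0, else 0).  Each neuron fires
at most once: the first grid time where v reaches the threshold ``theta``
is its spike time; a neuron that never crosses by T emits no spike (NaN
sentinel).  R_m is treated as a dimensionless gain on the drive.

The network is feed-forward with one hidden layer and a single output
neuron; hidden first-spike times are the pre-synaptic spikes of the output
neuron, and hidden neurons that stay silent contribute no drive downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import ConfigurationError

__all__ = [
    "LIFConfig",
    "NetworkShape",
    "SynapseSet",
    "MembraneTrace",
    "NO_SPIKE",
    "heaviside",
    "kernel_psi",
    "kernel_peak_time",
    "kernel_peak_value",
    "input_stimulus",
    "simulate_neuron",
    "forward_pass",
    "layer_spike_times",
    "forward_pass_batch",
]

#: sentinel for "neuron never fired" (propagates as zero drive downstream)
NO_SPIKE = np.nan


@dataclass(frozen=True)
class LIFConfig:
    """Neuron and simulation constants.

    tau_m, tau_s : membrane and synaptic time constants (ms), 0 < tau_s < tau_m
    r_m          : gain applied to the synaptic drive (dimensionless, default 100)
    theta        : firing threshold (mV)
    v_rest       : resting potential (mV)
    dt           : integration step (ms)
    t_total      : simulation horizon T (ms); must cover the codebook times
    """

    tau_m: float = 10.0
    tau_s: float = 5.0
    r_m: float = 100.0
    theta: float = 1.0
    v_rest: float = 0.0
    dt: float = 1.0
    t_total: float = 20.0

    def __post_init__(self):
        if not 0 < self.tau_s < self.tau_m:
            raise ConfigurationError(
                f"time constants must satisfy 0 < tau_s < tau_m, got tau_s={self.tau_s}, tau_m={self.tau_m}"
            )
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.t_total <= 0:
            raise ConfigurationError("t_total must be positive")
        if self.theta <= self.v_rest:
            raise ConfigurationError("threshold must exceed the resting potential")

    def time_grid(self) -> np.ndarray:
        """Integration grid t = dt, 2dt, ..., T (v(0) = v_rest is implicit)."""
        n = int(round(self.t_total / self.dt))
        return np.arange(1, n + 1, dtype=float) * self.dt


@dataclass(frozen=True)
class NetworkShape:
    """Feed-forward topology: M input neurons (incl. bias), N hidden, P=1 output."""

    n_input: int
    n_hidden: int
    n_output: int = 1

    def __post_init__(self):
        if self.n_input < 1 or self.n_hidden < 1:
            raise ConfigurationError("need at least one input and one hidden neuron")
        if self.n_output != 1:
            raise ConfigurationError("the architecture uses a single output neuron")

    @property
    def n_synapses(self) -> int:
        """Synapse count M*N + N*P (one terminal per neuron pair)."""
        return self.n_input * self.n_hidden + self.n_hidden * self.n_output


@dataclass
class SynapseSet:
    """Weights and integer delays for one layer, both of shape (pre, post)."""

    weights: np.ndarray
    delays: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        if self.weights.shape != self.delays.shape:
            raise ValueError(
                f"weight shape {self.weights.shape} != delay shape {self.delays.shape}"
            )


@dataclass
class MembraneTrace:
    """One neuron's simulated membrane trajectory.

    ``times`` is the grid 0..T, ``v`` the potential at each grid point and
    ``spike_time`` the first threshold crossing (NaN if the neuron never
    fired).  Under the single-spike scheme integration stops at the spike;
    later grid points hold NaN.
    """

    times: np.ndarray
    v: np.ndarray
    spike_time: float

    @property
    def fired(self) -> bool:
        return np.isfinite(self.spike_time)


def heaviside(x):
    """Step function with H(x) = 1 for x > 0 and H(0) = 0 (strict)."""
    x = np.asarray(x)
    out = np.where(x > 0, 1.0, 0.0)
    return float(out) if out.ndim == 0 else out


def kernel_psi(x, tau_m: float, tau_s: float):
    """Double-exponential synaptic kernel, zero for x <= 0.

    The exponentials are only evaluated where x > 0, which also keeps very
    negative arguments from overflowing.
    """
    if not 0 < tau_s < tau_m:
        raise ConfigurationError(
            f"time constants must satisfy 0 < tau_s < tau_m, got tau_s={tau_s}, tau_m={tau_m}"
        )
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0  # NaN compares False, so missing spikes contribute nothing
    xp = x[pos]
    out[pos] = np.exp(-xp / tau_m) - np.exp(-xp / tau_s)
    return float(out) if out.ndim == 0 else out


def kernel_peak_time(tau_m: float, tau_s: float) -> float:
    """Argmax of the kernel: x* = tau_m*tau_s/(tau_m - tau_s) * ln(tau_m/tau_s)."""
    return tau_m * tau_s / (tau_m - tau_s) * np.log(tau_m / tau_s)


def kernel_peak_value(tau_m: float, tau_s: float) -> float:
    """Maximum of the kernel, Psi evaluated at its analytic argmax."""
    return kernel_psi(kernel_peak_time(tau_m, tau_s), tau_m, tau_s)


def input_stimulus(t: float, pre_spikes, weights_col, delays_col, cfg: LIFConfig) -> float:
    """Synaptic drive xi_j(t) on one post-synaptic neuron.

    Pre-synaptic neurons whose delayed spike has not yet arrived (or that
    never fired) contribute zero.
    """
    pre = np.asarray(pre_spikes, dtype=float)
    w = np.asarray(weights_col, dtype=float)
    d = np.asarray(delays_col, dtype=float)
    if not (pre.shape == w.shape == d.shape):
        raise ValueError("pre_spikes, weights and delays must share one length")
    return float(np.sum(w * kernel_psi(t - pre - d, cfg.tau_m, cfg.tau_s)))


def simulate_neuron(pre_spikes, weights_col, delays_col, cfg: LIFConfig) -> MembraneTrace:
    """Euler-integrate one LIF neuron and record its first spike.

    Update per step: v(t) = v(t-dt) + (dt/tau_m) * (-(v(t-dt) - v_rest)
    + xi(t) * R_m).  Integration halts at the first t with v >= theta;
    not firing by T is a valid outcome, reported as spike_time = NaN.
    """
    grid = cfg.time_grid()
    times = np.concatenate([[0.0], grid])
    v = np.full(times.shape, np.nan)
    v[0] = cfg.v_rest
    spike_time = NO_SPIKE
    vi = cfg.v_rest
    for k, t in enumerate(grid, start=1):
        xi = input_stimulus(t, pre_spikes, weights_col, delays_col, cfg)
        vi = vi + cfg.dt / cfg.tau_m * (-(vi - cfg.v_rest) + xi * cfg.r_m)
        v[k] = vi
        if vi >= cfg.theta:
            spike_time = float(t)
            break
    return MembraneTrace(times=times, v=v, spike_time=spike_time)


def forward_pass(sample_spikes, input_hidden: SynapseSet, hidden_output: SynapseSet, cfg: LIFConfig):
    """Run one encoded sample through the network.

    Returns (hidden_spike_times, output_spike_time); silent neurons are NaN.
    """
    pre = np.asarray(sample_spikes, dtype=float)
    m, n = input_hidden.weights.shape
    if pre.shape != (m,):
        raise ValueError(f"expected {m} input spike times, got shape {pre.shape}")
    if hidden_output.weights.shape[0] != n:
        raise ValueError("hidden layer width mismatch between the two synapse sets")
    hidden = np.array(
        [
            simulate_neuron(pre, input_hidden.weights[:, j], input_hidden.delays[:, j], cfg).spike_time
            for j in range(n)
        ]
    )
    out = simulate_neuron(hidden, hidden_output.weights[:, 0], hidden_output.delays[:, 0], cfg).spike_time
    return hidden, out


def layer_spike_times(pre_spikes: np.ndarray, weights: np.ndarray, delays: np.ndarray, cfg: LIFConfig) -> np.ndarray:
    """Vectorised first-spike times of one layer for a batch of samples.

    ``pre_spikes`` is (batch, pre); weights/delays are (pre, post).  Because
    the membrane recursion has no reset, the first threshold crossing of
    the full trajectory equals the stop-at-spike result.
    Returns (batch, post) spike times with NaN for silent neurons.
    """
    pre = np.atleast_2d(np.asarray(pre_spikes, dtype=float))
    grid = cfg.time_grid()
    # x[g, b, i, j] = t_g - t_{b,i} - kappa_{i,j}
    x = grid[:, None, None, None] - pre[None, :, :, None] - delays[None, None, :, :]
    kern = np.zeros_like(x)
    pos = x > 0
    xp = x[pos]
    kern[pos] = np.exp(-xp / cfg.tau_m) - np.exp(-xp / cfg.tau_s)
    xi = np.einsum("gbij,ij->gbj", kern, weights)

    b, n_post = pre.shape[0], weights.shape[1]
    v = np.full((b, n_post), cfg.v_rest)
    spikes = np.full((b, n_post), NO_SPIKE)
    a = cfg.dt / cfg.tau_m
    for g, t in enumerate(grid):
        v = v + a * (-(v - cfg.v_rest) + xi[g] * cfg.r_m)
        newly = (v >= cfg.theta) & np.isnan(spikes)
        spikes[newly] = t
    return spikes


def forward_pass_batch(spike_matrix: np.ndarray, input_hidden: SynapseSet, hidden_output: SynapseSet, cfg: LIFConfig):
    """Vectorised forward pass: (batch, M) spikes -> hidden (batch, N), output (batch,)."""
    hidden = layer_spike_times(spike_matrix, input_hidden.weights, input_hidden.delays, cfg)
    out = layer_spike_times(hidden, hidden_output.weights, hidden_output.delays, cfg)
    return hidden, out[:, 0]
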