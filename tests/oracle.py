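"""Independent brute-force reference simulator used only by the tests.

Written straight from the model definitions with plain Python loops and
``math`` — no shared code with the package — so that agreement between the
two is meaningful.  Silent neurons are represented by ``None``.
"""

import math


def oracle_psi(x: float, tau_m: float, tau_s: float) -> float:
    if x <= 0:
        return 0.0
    return math.exp(-x / tau_m) - math.exp(-x / tau_s)


def oracle_neuron(pre_spikes, weights, delays, tau_m, tau_s, r_m, theta, dt, t_total):
    """First-spike time of one LIF neuron, or None if it never fires."""
    v = 0.0
    n_steps = int(round(t_total / dt))
    for step in range(1, n_steps + 1):
        t = step * dt
        xi = 0.0
        for tp, w, d in zip(pre_spikes, weights, delays):
            if tp is None:
                continue
            xi += w * oracle_psi(t - tp - d, tau_m, tau_s)
        v = v + dt / tau_m * (-v + xi * r_m)
        if v >= theta:
            return t
    return None


def oracle_forward(pre_spikes, w_ih, d_ih, w_ho, d_ho, tau_m=10.0, tau_s=5.0,
                   r_m=100.0, theta=1.0, dt=1.0, t_total=20.0):
    """(hidden spike times, output spike time) for one sample; None = silent."""
    n_hidden = len(w_ih[0])
    hidden = []
    for j in range(n_hidden):
        hidden.append(
            oracle_neuron(
                pre_spikes,
                [row[j] for row in w_ih],
                [row[j] for row in d_ih],
                tau_m, tau_s, r_m, theta, dt, t_total,
            )
        )
    out = oracle_neuron(
        hidden,
        [row[0] for row in w_ho],
        [row[0] for row in d_ho],
        tau_m, tau_s, r_m, theta, dt, t_total,
    )
    return hidden, out
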