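"""Calcium-kinetics short-term synaptic plasticity (facilitation + depression).

Every presynaptic neuron carries two state variables: the available
resources x (neurotransmitter, in [0, 1]) and the residual calcium /
utilization u (in [U, 1]).  Between spikes both relax exponentially to
their baselines (x -> 1 with time constant tau_D, u -> U with tau_F).  When
the neuron fires, calcium first jumps by U*(1 - u) and the resources are
then depleted by u_new * x.  Synaptic efficiency is the product u*x
normalized by its baseline U, so outgoing weights are w = (u*x/U) * w0:
momentarily depressed after a burst (resources gone, tau_D timescale) and
facilitated afterwards (calcium elevated, tau_F timescale) -- the substrate
of activity-silent memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class STSPParams:
    """Baseline utilization and the two kinetic time constants (seconds)."""

    U: float = 0.2
    tau_D: float = 0.2
    tau_F: float = 1.5

    def __post_init__(self):
        if not (0 < self.U <= 1):
            raise ValueError("U must lie in (0, 1]")
        if self.tau_D <= 0 or self.tau_F <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class STSPState:
    """Per-presynaptic-neuron calcium u and resources x, (batch, n) each."""

    u: np.ndarray
    x: np.ndarray

    @classmethod
    def rest(cls, batch: int, n: int, params: STSPParams) -> "STSPState":
        return cls(np.full((batch, n), params.U), np.ones((batch, n)))


def stsp_step(state: STSPState, spikes: np.ndarray, dt: float,
              params: STSPParams) -> np.ndarray:
    """Advance u and x by one timestep, in place; returns the release.

    Decay uses the exact per-step exponential (unconditionally stable at
    any dt); the spike jumps are then applied to neurons that fired this
    step, calcium first so that depletion uses the post-influx u.  The
    returned array holds, per neuron, the fraction of resources released
    by this step's spike (u+ * x-, zero without a spike) -- the quantity
    that scales synaptic transmission.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u, x = state.u, state.x
    du = np.exp(-dt / params.tau_F)
    dx = np.exp(-dt / params.tau_D)
    u *= du
    u += params.U * (1.0 - du)
    x += (1.0 - x) * (1.0 - dx)
    release = np.zeros_like(x)
    if np.any(spikes):
        s = spikes
        u[s] += params.U * (1.0 - u[s])
        release[s] = u[s] * x[s]
        x[s] -= release[s]
    return release


def efficiency(state: STSPState, params: STSPParams) -> np.ndarray:
    """Per-neuron synaptic efficiency u*x/U (1 at rest, at most 1/U)."""
    return state.u * state.x / params.U


def modulate_spikes(release: np.ndarray, params: STSPParams) -> np.ndarray:
    """Scale spike impulses by the normalized released fraction.

    The effective weight at a spike is w = (u+ x- / U) w0: the calcium
    jump precedes transmitter release and the resources consulted are
    those available just before depletion, so a facilitated neuron
    (elevated u, recovered x) transmits monotonically more.  ``release``
    is the u+ * x- product that :func:`stsp_step` returns; dividing by the
    baseline U normalizes transmission so that a long-rested synapse
    driven at vanishing rate transmits with its baseline weight on
    average.  Because the modulation depends only on the presynaptic
    neuron, scaling each presynaptic spike before the decoder/encoder
    product transmits exactly what the full-matrix weights would.
    """
    return release / params.U


def euler_reference(spike_train: np.ndarray, dt_coarse: float,
                    params: STSPParams, dt_fine: float = 1e-5):
    """Brute-force forward-Euler integration of the kinetics on a fine grid.

    ``spike_train`` holds one spike flag per coarse step for a single
    neuron; spikes are applied at the coarse step boundaries.  Returns u and
    x sampled at the end of every coarse step -- an independent oracle for
    the exact-exponential update.
    """
    n_sub = int(round(dt_coarse / dt_fine))
    u = params.U
    x = 1.0
    us, xs = [], []
    for s in spike_train:
        for _ in range(n_sub):
            u += dt_fine * (params.U - u) / params.tau_F
            x += dt_fine * (1.0 - x) / params.tau_D
        if s:
            u += params.U * (1.0 - u)
            x -= u * x
        us.append(u)
        xs.append(x)
    return np.array(us), np.array(xs)
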