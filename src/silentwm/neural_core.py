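"""Leaky integrate-and-fire population coding and least-squares decoding.

A population of n LIF neurons represents a D-dimensional vector x through
per-neuron input currents J_i = gain_i * (e_i . x) / radius + bias_i, where
e_i is the neuron's unit-norm preferred-direction encoder.  Gains and biases
are solved so that each neuron is silent below its intercept and fires at
its maximum rate when the projection reaches the representational radius.
Decoding is linear: regularized least squares maps filtered spike trains
back to the represented vector or to an arbitrary target function of it.

All dynamic state carries a leading batch axis so that many independent
trials are integrated in lock-step by the same population object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

DT_DEFAULT = 0.001  # s


@dataclass
class LIFParams:
    """Membrane constants and tuning-curve distributions for one population."""

    tau_rc: float = 0.02
    tau_ref: float = 0.002
    intercept_low: float = 0.01
    intercept_high: float = 0.1
    max_rate_low: float = 200.0
    max_rate_high: float = 400.0

    def __post_init__(self):
        if self.tau_rc <= 0:
            raise ValueError("tau_rc must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        # the upper bound is an exclusive sampling bound, so 1.0 is allowed
        if not (-1.0 <= self.intercept_low <= self.intercept_high <= 1.0):
            raise ValueError("intercepts must lie in [-1, 1]")
        if self.intercept_low >= 1.0:
            raise ValueError("intercept lower bound of 1 is degenerate")


def lif_rate(J, tau_rc: float = 0.02, tau_ref: float = 0.002):
    """Closed-form steady-state LIF rate for normalized current J.

    rate = 1 / (tau_ref - tau_rc * ln(1 - 1/J)) for J > 1, else 0.
    """
    J = np.asarray(J, dtype=float)
    out = np.zeros_like(J)
    sup = J > 1.0 + 1e-12
    out[sup] = 1.0 / (tau_ref - tau_rc * np.log1p(-1.0 / J[sup]))
    return out


def gain_bias(intercepts, max_rates, tau_rc: float = 0.02, tau_ref: float = 0.002):
    """Solve per-neuron gain and bias from intercept and max rate.

    The current at the maximum rate follows from inverting the rate
    equation; the line J = gain*proj + bias then passes through
    (intercept, 1) and (1, J_max).
    """
    intercepts = np.asarray(intercepts, dtype=float)
    max_rates = np.asarray(max_rates, dtype=float)
    if np.any(intercepts >= 1.0):
        raise ValueError("intercept of 1 makes gain/bias degenerate")
    inv = tau_ref - 1.0 / max_rates
    if np.any(inv >= 0):
        raise ValueError("max rate must be below 1/tau_ref")
    j_max = 1.0 / (1.0 - np.exp(inv / tau_rc))
    gain = (j_max - 1.0) / (1.0 - intercepts)
    bias = j_max - gain
    return gain, bias


class Population:
    """An LIF ensemble with NEF encoders/decoders and batched dynamics."""

    def __init__(self, n: int, dims: int, params: LIFParams | None = None,
                 encoders: np.ndarray | None = None, radius: float = 1.0,
                 rng: np.random.Generator | None = None, label: str = ""):
        if n < 1:
            raise ValueError("need at least one neuron")
        if rng is None:
            rng = np.random.default_rng()
        self.n = int(n)
        self.dims = int(dims)
        self.params = params or LIFParams()
        self.radius = float(radius)
        self.label = label
        if encoders is None:
            encoders = rng.standard_normal((n, dims))
        encoders = np.asarray(encoders, dtype=float)
        if encoders.shape != (n, dims):
            raise ValueError("encoders must be (n, dims)")
        norms = np.linalg.norm(encoders, axis=1, keepdims=True)
        self.encoders = encoders / np.maximum(norms, 1e-300)
        self.intercepts = rng.uniform(self.params.intercept_low,
                                      self.params.intercept_high, size=n)
        self.max_rates = rng.uniform(self.params.max_rate_low,
                                     self.params.max_rate_high, size=n)
        self.gain, self.bias = gain_bias(self.intercepts, self.max_rates,
                                         self.params.tau_rc, self.params.tau_ref)
        # encoders scaled by gain/radius: current J = x @ emap.T + bias
        self.emap = self.encoders * (self.gain / self.radius)[:, None]

    # -- static (rate) description -------------------------------------

    def current(self, x: np.ndarray) -> np.ndarray:
        """Input current for represented vectors x (..., dims)."""
        return np.asarray(x, dtype=float) @ self.emap.T + self.bias

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Steady-state firing rates at represented vectors x."""
        return lif_rate(self.current(x), self.params.tau_rc, self.params.tau_ref)

    # -- dynamics ------------------------------------------------------

    def initial_state(self, batch: int = 1):
        return LIFState(np.zeros((batch, self.n)), np.zeros((batch, self.n)))

    def step(self, state: "LIFState", J: np.ndarray, dt: float) -> np.ndarray:
        """Advance one timestep; returns the spike indicator array (batch, n).

        Uses the standard partial-timestep discretization: the membrane
        relaxes exponentially toward J over the non-refractory part of the
        step, and threshold crossings are located by interpolating the spike
        time inside the step so that firing rates are accurate at coarse dt.
        """
        return lif_step(state, J, dt, self.params.tau_rc, self.params.tau_ref)


@dataclass
class LIFState:
    """Membrane voltage and remaining refractory time, (batch, n) each."""

    voltage: np.ndarray
    refractory: np.ndarray


def lif_step(state: LIFState, J, dt: float, tau_rc: float = 0.02,
             tau_ref: float = 0.002) -> np.ndarray:
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = state.voltage
    ref = state.refractory
    ref -= dt
    # most neurons are out of refractory, so their integration factor is a
    # constant; only the (sparse) recently-spiked set needs the general form
    decay = -np.expm1(-dt / tau_rc)
    in_ref = ref > 0.0
    V += (J - V) * decay
    if np.any(in_ref):
        delta_t = np.clip(dt - ref[in_ref], 0.0, dt)
        Jr = np.broadcast_to(J, V.shape)[in_ref]
        Vr = (V[in_ref] - Jr * decay) / (1.0 - decay)  # undo the bulk update
        V[in_ref] = Vr - (Jr - Vr) * np.expm1(-delta_t / tau_rc)
    spiked = V > 1.0
    if np.any(spiked):
        Js = np.broadcast_to(J, V.shape)[spiked]
        # time after threshold crossing, interpolated within the step; a
        # crossing forced with subthreshold drive (e.g. direct injection)
        # is placed at the step boundary
        with np.errstate(invalid="ignore", divide="ignore"):
            t_spike = dt + tau_rc * np.log1p(-(V[spiked] - 1.0) / (Js - 1.0))
        t_spike = np.where(np.isfinite(t_spike), np.clip(t_spike, 0.0, dt), dt)
        V[spiked] = 0.0
        ref[spiked] = tau_ref + t_spike
    np.maximum(V, 0.0, out=V)
    np.clip(ref, 0.0, None, out=ref)
    return spiked


# -- synaptic filtering ------------------------------------------------


class Lowpass:
    """First-order exponential synapse; tau = 0 is a pass-through.

    Discrete update y <- y + (1 - exp(-dt/tau)) * (u - y), which preserves
    the integral of an impulse delivered as a 1/dt-scaled sample.
    """

    def __init__(self, tau: float, dt: float = DT_DEFAULT):
        if tau < 0:
            raise ValueError("tau must be >= 0")
        self.tau = float(tau)
        self.dt = float(dt)
        self.alpha = 0.0 if tau == 0 else float(np.exp(-dt / tau))
        self.state = None

    def reset(self, shape):
        self.state = np.zeros(shape)
        return self.state

    def step(self, u: np.ndarray) -> np.ndarray:
        if self.tau == 0.0:
            self.state = np.asarray(u, dtype=float)
            return self.state
        self.state *= self.alpha
        self.state += (1.0 - self.alpha) * u
        return self.state


def lowpass_filter(signal: np.ndarray, tau: float, dt: float = DT_DEFAULT,
                   axis: int = -1) -> np.ndarray:
    """Offline first-order lowpass of a sampled signal along ``axis``."""
    sig = np.moveaxis(np.asarray(signal, dtype=float), axis, 0)
    out = np.empty_like(sig)
    f = Lowpass(tau, dt)
    f.reset(sig.shape[1:])
    for t in range(sig.shape[0]):
        out[t] = f.step(sig[t])
    return np.moveaxis(out, 0, axis)


# -- decoder solving ---------------------------------------------------


def solve_decoders(population: Population, eval_points: np.ndarray,
                   targets: np.ndarray | None = None,
                   reg: float = 0.1,
                   null_activity: np.ndarray | None = None) -> np.ndarray:
    """Regularized least-squares decoders mapping activity to targets.

    ``eval_points`` are represented vectors (m, dims); ``targets`` (m, d_out)
    default to the points themselves (identity decoding).  ``reg`` scales the
    ridge term relative to the largest firing rate, the conventional NEF
    regularization.  ``null_activity`` rows are raw activity patterns that
    must decode to zero (used to make decoders ignore non-selective
    population-wide activation, e.g. a uniform reactivation current); they
    are weighted to carry the same total weight as the data block.
    Returns a (d_out, n) decoder matrix.
    """
    A = population.rates(eval_points)  # (m, n)
    if targets is None:
        targets = eval_points
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[0] != A.shape[0]:
        raise ValueError("targets must match eval points")
    sigma = reg * np.max(A)
    if sigma <= 0:
        raise ValueError("regularization collapsed: population never fires "
                         "on the evaluation points")
    if null_activity is not None:
        null_activity = np.atleast_2d(np.asarray(null_activity, dtype=float))
        w = np.sqrt(A.shape[0] / null_activity.shape[0])
        A = np.vstack([A, w * null_activity])
        targets = np.vstack([targets,
                             np.zeros((null_activity.shape[0], targets.shape[1]))])
    m = A.shape[0]
    G = A.T @ A + m * sigma**2 * np.eye(population.n)
    dec = scipy.linalg.solve(G, A.T @ targets, assume_a="pos")
    return dec.T
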