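"""The two-module working-memory network and its trial simulator.

Each module is an independent copy of the four-stage architecture: a
sensory population with Gabor-derived encoders turns a 128x128 image into
spiking over a 24-dimensional vector code; a recurrently connected memory
population maintains that vector, with calcium-kinetics STSP on the
recurrent connection providing activity-silent storage; a comparison
population receives the orientation (as sine/cosine of the doubled angle)
read out from both the sensory and the memory population; and its outgoing
connection computes the signed orientation difference that drives a
one-dimensional decision population.

Orientations are read out as (sin 2*theta, cos 2*theta): the doubled angle
maps theta and theta + 180 deg -- pixel-identical stimuli -- onto the same
point, and the ratio of the pair encodes the orientation independently of
response amplitude.  The comparison output d = sin_s*cos_m - cos_s*sin_m =
sin(2*(theta_s - theta_m)) is monotone in the difference over +-45 deg,
comfortably covering the task's largest angular difference of 42 deg, with
its sign encoding clockwise versus counter-clockwise.

All trial dynamics are integrated with a batch axis so that a whole block
of trials with a common event timeline runs in lock-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import ModelConfig
from .neural_core import Lowpass, Population, solve_decoders
from .stsp import STSPState, stsp_step
from .visual_basis import VisualBasis, generate_gabor_bank, build_basis


# ---------------------------------------------------------------------
# orientation readout helpers


def doubled_angle(theta_deg):
    """(sin, cos) of the doubled orientation angle."""
    phi = 2.0 * np.deg2rad(np.asarray(theta_deg, dtype=float))
    return np.stack([np.sin(phi), np.cos(phi)], axis=-1)


def angle_difference(sensory_pair, memory_pair):
    """Signed difference sin(phi_s - phi_m) from two (sin, cos) pairs."""
    s = np.asarray(sensory_pair, dtype=float)
    m = np.asarray(memory_pair, dtype=float)
    return s[..., 0] * m[..., 1] - s[..., 1] * m[..., 0]


# ---------------------------------------------------------------------
# module construction


class WMModule:
    """One visual hemifield: basis, four populations, solved decoders."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        d = config.sensory.dims
        gabor_rng = np.random.default_rng(rng.integers(2**31 - 1))
        G = generate_gabor_bank(config.n_gabors, rng=gabor_rng, d=d)
        self.basis = build_basis(G, d=d, step_deg=config.basis_step_deg,
                                 random_state=int(rng.integers(2**31 - 1)))

        pop_rng = np.random.default_rng(rng.integers(2**31 - 1))
        self.sensory = Population(config.sensory.n, d,
                                  config.sensory.lif_params(),
                                  encoders=self.basis.E, rng=pop_rng,
                                  label="sensory")
        self.memory = Population(config.memory.n, d,
                                 config.memory.lif_params(), rng=pop_rng,
                                 label="memory")
        self.comparison = Population(config.comparison.n, 4,
                                     config.comparison.lif_params(),
                                     radius=np.sqrt(2.0), rng=pop_rng,
                                     label="comparison")
        self.decision = Population(config.decision.n, 1,
                                   config.decision.lif_params(), rng=pop_rng,
                                   label="decision")
        self._solve_all_decoders(pop_rng)

    # -- decoder training sets -----------------------------------------

    def _vector_eval_points(self, rng: np.random.Generator,
                            amps=(0.35, 0.7, 1.0)):
        """Stimulus-manifold plus volume-filling points for the 24-D code.

        Dense orientation-by-phase coverage keeps the identity decode's
        angular bias small; the recurrent loop otherwise amplifies any
        systematic rotation of the represented grating."""
        thetas = np.arange(-88.0, 92.0, 3.0)
        phases = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        vecs, targets_ori = [], []
        for th in thetas:
            for ph in phases:
                v = self.basis.ideal_vector(th, ph)
                v = v / max(np.linalg.norm(v), 1e-12)
                sc = doubled_angle(th)
                for a in amps:
                    vecs.append(a * v)
                    targets_ori.append(a * sc)
        d = self.basis.D
        n_ball = 300
        ball = rng.standard_normal((n_ball, d))
        ball /= np.linalg.norm(ball, axis=1, keepdims=True)
        ball *= rng.uniform(0, 1, size=(n_ball, 1)) ** (1.0 / d)
        vecs = np.vstack([np.array(vecs), ball, np.zeros((1, d))])
        targets_ori = np.vstack([np.array(targets_ori),
                                 np.zeros((n_ball + 1, 2))])
        return vecs, targets_ori

    def _nonspecific_patterns(self, pop: Population, r0: float = 150.0):
        """Activity patterns of non-selective population-wide drive.

        Uniform current recruits neurons in order of excitability (low
        intercept, high bias), regardless of their preferred direction.
        Decoders trained to null these patterns report only the selective
        part of a reactivation response.
        """
        rows = [r0 * (pop.intercepts < a) for a in np.linspace(0.015, 0.1, 20)]
        rows += [r0 * (pop.bias > b)
                 for b in np.quantile(pop.bias, np.linspace(0.7, 0.99, 20))]
        rows.append(np.full(pop.n, r0))
        return np.array(rows, dtype=float)

    def _ori_eval_points(self):
        """Dense phase coverage for the orientation readout: residual,
        phase-conditional readout bias is the model's dominant source of
        behavioral noise, so this readout is trained harder than the rest."""
        thetas = np.arange(-88.0, 92.0, 3.0)
        phases = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        amps = (0.2, 0.5, 0.75, 1.0)
        vecs, tg = [], []
        for th in thetas:
            sc = doubled_angle(th)
            for ph in phases:
                v = self.basis.ideal_vector(th, ph)
                v /= max(np.linalg.norm(v), 1e-12)
                for a in amps:
                    vecs.append(a * v)
                    tg.append(a * sc)
        d = self.basis.D
        return (np.vstack([vecs, np.zeros((1, d))]),
                np.vstack([tg, np.zeros((1, 2))]))

    def _solve_all_decoders(self, rng: np.random.Generator):
        reg = self.config.decoder_reg
        pts, _ = self._vector_eval_points(rng)
        ori_pts, ori_targets = self._ori_eval_points()
        self.dec_sens_ident = solve_decoders(self.sensory, pts, reg=reg)
        self.dec_sens_ori = solve_decoders(self.sensory, ori_pts, ori_targets,
                                           reg=0.02)
        # the recurrent identity decode must stay accurate down to the small
        # amplitudes a reactivation pulse seeds, and must ignore the
        # non-selective part of pulse-driven activity
        mem_pts, _ = self._vector_eval_points(
            rng, amps=(0.02, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0))
        self.dec_mem_ident = solve_decoders(
            self.memory, mem_pts, reg=self.config.memory_decoder_reg,
            null_activity=self._nonspecific_patterns(self.memory))
        self.dec_mem_ori = solve_decoders(self.memory, ori_pts, ori_targets,
                                          reg=0.02)

        m = 1200
        phis = rng.uniform(0, 2 * np.pi, size=(m, 2))
        a = rng.uniform(0, 1.25, size=(m, 2))
        cpts = np.stack([a[:, 0] * np.sin(phis[:, 0]), a[:, 0] * np.cos(phis[:, 0]),
                         a[:, 1] * np.sin(phis[:, 1]), a[:, 1] * np.cos(phis[:, 1])],
                        axis=1)
        # train on swapped pairs too so the decoded difference is exactly
        # antisymmetric and carries no systematic sign bias
        cpts = np.vstack([cpts, cpts[:, [2, 3, 0, 1]]])
        diff = (cpts[:, 0] * cpts[:, 3] - cpts[:, 1] * cpts[:, 2])[:, None]
        self.dec_comp_diff = solve_decoders(self.comparison, cpts, diff, reg=reg)

        dpts = rng.uniform(-1, 1, size=(600, 1))
        self.dec_decision = solve_decoders(self.decision, dpts, reg=reg)

    def orientation_readout(self, vectors: np.ndarray) -> np.ndarray:
        """Rate-level (sin, cos) readout of represented vectors (for tests)."""
        rates = self.memory.rates(vectors)
        return rates @ self.dec_mem_ori.T


class WMModel:
    """A set of independent modules sharing one configuration."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 n_modules: Optional[int] = None):
        config.validate()
        self.config = config
        self.seed = int(seed)
        n_mod = config.n_modules if n_modules is None else n_modules
        seqs = np.random.SeedSequence(self.seed).spawn(n_mod)
        self.modules = [WMModule(config, np.random.default_rng(s)) for s in seqs]

    def __len__(self):
        return len(self.modules)


# ---------------------------------------------------------------------
# trial events and results


@dataclass
class InputEvent:
    """A visual input: vectors (batch, D) applied to one module's sensory
    population over [onset, offset) ms."""

    module: int
    onset_ms: int
    offset_ms: int
    vectors: np.ndarray


@dataclass
class PulseEvent:
    """Non-specific reactivation current to one module's memory neurons."""

    module: int
    onset_ms: int
    offset_ms: int
    amplitude: float

    def __post_init__(self):
        if self.offset_ms < self.onset_ms:
            raise ValueError("pulse duration must be non-negative")


@dataclass
class ModuleTrace:
    """Recorded signals for one module over a batch of trials."""

    decision: np.ndarray  # (B, T) decoded decision value
    mem_decoded: Optional[np.ndarray]  # (B, T, D) instantaneous decode
    mem_spike_count: np.ndarray  # (B, T) population spikes per step
    u_mean: np.ndarray  # (B, T)
    x_mean: np.ndarray  # (B, T)
    mem_raster: Optional[np.ndarray] = None  # (B, T, n) bool, if requested
    sens_spike_count: Optional[np.ndarray] = None
    ori_sens: Optional[np.ndarray] = None  # (B, T, 2) sensory (sin, cos)
    ori_mem: Optional[np.ndarray] = None  # (B, T, 2) memory (sin, cos)
    comp_out: Optional[np.ndarray] = None  # (B, T) comparison difference


@dataclass
class TrialResult:
    """Batched simulation output: one ModuleTrace per simulated module."""

    dt_ms: float
    horizon_ms: int
    modules: list

    @property
    def time_ms(self):
        return np.arange(self.modules[0].decision.shape[1]) * self.dt_ms


# ---------------------------------------------------------------------
# the simulator


def run_trial(model: WMModel, events: Sequence[InputEvent],
              pulses: Sequence[PulseEvent], horizon_ms: int, batch: int,
              record_decoded: bool = True, record_raster: bool = False,
              noise_std: Optional[float] = None,
              noise_seed: Optional[int] = None,
              modules: Optional[Sequence[int]] = None) -> TrialResult:
    """Integrate a batch of trials through the selected modules.

    Events within one module must not overlap in time on the same port.
    ``noise_std`` (projection units) adds zero-mean Gaussian current noise
    to the memory population, used for the bi-stable regime.
    """
    cfg = model.config
    dt = cfg.dt
    n_steps = int(round(horizon_ms / (dt * 1000.0)))
    for ev in list(events) + list(pulses):
        if ev.offset_ms > horizon_ms or ev.onset_ms < 0:
            raise ValueError("event outside the simulation horizon")
    if noise_std is None:
        noise_std = cfg.noise_std
    module_ids = list(range(len(model.modules))) if modules is None else list(modules)
    traces = []
    for mi in module_ids:
        mod = model.modules[mi]
        mod_events = [e for e in events if e.module == mi]
        _check_overlap(mod_events)
        mod_pulses = [p for p in pulses if p.module == mi]
        traces.append(_run_module(mod, mod_events, mod_pulses, n_steps, batch,
                                  dt, record_decoded, record_raster,
                                  noise_std, noise_seed, mi))
    return TrialResult(dt_ms=dt * 1000.0, horizon_ms=horizon_ms, modules=traces)


def _check_overlap(events):
    spans = sorted((e.onset_ms, e.offset_ms) for e in events)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("overlapping input events on one module")


def _segment_currents(mod: WMModule, events, n_steps, batch, dt):
    """Precompute per-segment sensory currents (input is constant within
    an event, so the encoder product is done once per event)."""
    steps_per_ms = 1.0 / (dt * 1000.0)
    segs = []
    for e in events:
        v = np.atleast_2d(np.asarray(e.vectors, dtype=float))
        if v.shape[0] == 1:
            v = np.broadcast_to(v, (batch, v.shape[1]))
        J = v @ mod.sensory.emap.T  # (B, n_s); bias added in the loop
        segs.append((int(round(e.onset_ms * steps_per_ms)),
                     int(round(e.offset_ms * steps_per_ms)), J))
    return segs


def _run_module(mod: WMModule, events, pulses, n_steps, batch, dt,
                record_decoded, record_raster, noise_std, noise_seed,
                module_index):
    cfg = mod.config
    inv_dt = 1.0 / dt
    sens, mem, comp, deci = mod.sensory, mod.memory, mod.comparison, mod.decision
    segs = _segment_currents(mod, events, n_steps, batch, dt)
    steps_per_ms = 1.0 / (dt * 1000.0)
    pulse_segs = [(int(round(p.onset_ms * steps_per_ms)),
                   int(round(p.offset_ms * steps_per_ms)),
                   p.amplitude) for p in pulses]

    s_state = sens.initial_state(batch)
    m_state = mem.initial_state(batch)
    c_state = comp.initial_state(batch)
    d_state = deci.initial_state(batch)
    stsp_state = STSPState.rest(batch, mem.n, cfg.stsp)

    f_sens = Lowpass(cfg.tau_feedforward, dt)
    f_sens.reset((batch, sens.n))
    f_mem = Lowpass(cfg.tau_feedforward, dt)
    f_mem.reset((batch, mem.n))
    f_rec_fast = Lowpass(cfg.tau_recurrent_fast, dt)
    f_rec_fast.reset((batch, mem.n))
    f_rec_slow = Lowpass(cfg.tau_recurrent_slow, dt)
    f_rec_slow.reset((batch, mem.n))
    lam = cfg.recurrent_slow_weight
    f_comp = Lowpass(cfg.tau_feedforward, dt)
    f_comp.reset((batch, comp.n))
    f_dec = Lowpass(cfg.tau_feedforward, dt)
    f_dec.reset((batch, deci.n))

    decision_tr = np.zeros((batch, n_steps), dtype=np.float32)
    mem_count = np.zeros((batch, n_steps), dtype=np.int32)
    sens_count = np.zeros((batch, n_steps), dtype=np.int32)
    u_mean = np.zeros((batch, n_steps), dtype=np.float32)
    x_mean = np.zeros((batch, n_steps), dtype=np.float32)
    mem_dec = (np.zeros((batch, n_steps, mem.dims), dtype=np.float32)
               if record_decoded else None)
    raster = (np.zeros((batch, n_steps, mem.n), dtype=bool)
              if record_raster else None)
    ori_s_tr = np.zeros((batch, n_steps, 2), dtype=np.float32)
    ori_m_tr = np.zeros((batch, n_steps, 2), dtype=np.float32)
    comp_tr = np.zeros((batch, n_steps), dtype=np.float32)

    noise_rng = None
    if noise_std > 0:
        noise_rng = np.random.default_rng(
            noise_seed if noise_seed is not None else (hash((module_index, 0)) & 0x7FFFFFFF))
        noise_scale = noise_std * mem.gain  # pre-gain projection units

    J_sens_base = np.broadcast_to(sens.bias, (batch, sens.n))
    # transmission normalization: a spike from a long-rested synapse
    # (u jumps to U*(2-U), full resources) transmits with weight 1
    rest_release = cfg.stsp.U * (2.0 - cfg.stsp.U)

    for t in range(n_steps):
        # sensory input current for this step
        J_s = None
        for (a, b, J) in segs:
            if a <= t < b:
                J_s = J + sens.bias
                break
        if J_s is None:
            J_s = J_sens_base
        s_spikes = sens.step(s_state, J_s, dt)
        sf = f_sens.step(s_spikes * inv_dt)

        # memory input: feedforward identity + STSP-modulated recurrent
        v_ff = sf @ mod.dec_sens_ident.T
        v_rec = (f_rec_fast.state + lam * f_rec_slow.state) @ mod.dec_mem_ident.T
        J_m = (v_ff + v_rec) @ mem.emap.T + mem.bias
        if noise_rng is not None:
            J_m = J_m + noise_scale * noise_rng.standard_normal((batch, mem.n))
        # the reactivation pulse depolarizes every memory neuron directly
        for (a, b, amp) in pulse_segs:
            if a <= t < b:
                m_state.voltage += amp * (dt * 1000.0) * (m_state.refractory <= 0)
        m_spikes = mem.step(m_state, J_m, dt)
        release = stsp_step(stsp_state, m_spikes, dt, cfg.stsp)
        transmitted = release * (inv_dt / rest_release)
        f_rec_fast.step(transmitted)
        f_rec_slow.step(transmitted)
        mf = f_mem.step(m_spikes * inv_dt)

        # comparison: (sin, cos) of doubled angle from both streams
        ori_s = sf @ mod.dec_sens_ori.T
        ori_m = mf @ mod.dec_mem_ori.T
        c_in = np.concatenate([ori_s, ori_m], axis=1)
        J_c = c_in @ comp.emap.T + comp.bias
        c_spikes = comp.step(c_state, J_c, dt)
        cf = f_comp.step(c_spikes * inv_dt)

        # decision: signed orientation difference
        d_in = cf @ mod.dec_comp_diff.T
        J_d = d_in @ deci.emap.T + deci.bias
        d_spikes = deci.step(d_state, J_d, dt)
        df = f_dec.step(d_spikes * inv_dt)
        decision_tr[:, t] = (df @ mod.dec_decision.T)[:, 0]
        ori_s_tr[:, t] = ori_s
        ori_m_tr[:, t] = ori_m
        comp_tr[:, t] = d_in[:, 0]

        mem_count[:, t] = m_spikes.sum(axis=1)
        sens_count[:, t] = s_spikes.sum(axis=1)
        u_mean[:, t] = stsp_state.u.mean(axis=1)
        x_mean[:, t] = stsp_state.x.mean(axis=1)
        if mem_dec is not None:
            mem_dec[:, t] = (m_spikes * inv_dt) @ mod.dec_mem_ident.T
        if raster is not None:
            raster[:, t] = m_spikes

    return ModuleTrace(decision=decision_tr, mem_decoded=mem_dec,
                       mem_spike_count=mem_count, u_mean=u_mean,
                       x_mean=x_mean, mem_raster=raster,
                       sens_spike_count=sens_count, ori_sens=ori_s_tr,
                       ori_mem=ori_m_tr, comp_out=comp_tr)


def apply_reactivation(module_index: int, onset_ms: int, duration_ms: int,
                       amplitude: float) -> PulseEvent:
    """Build the non-specific reactivation pulse event (defaults 0.02, 20 ms)."""
    if duration_ms < 0:
        raise ValueError("duration must be non-negative")
    return PulseEvent(module_index, onset_ms, onset_ms + duration_ms, amplitude)
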