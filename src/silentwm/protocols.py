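"""Standard evaluation protocols: the quantitative checks the model makes.

These routines reproduce, at desk scale, the study's benchmark
measurements: the kinetics-integration accuracy of the plasticity state,
the LIF rate calibration, the representational time courses of a
reference trial (encode - cue - impulse - probe), the cued/uncued and
primary/secondary similarity ratios, psychometric curves, the
impulse-duration (SOA) accuracies, and the noise-driven bi-stable regime.
Both the test suite and the acceptance script drive these functions.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .analysis import (impulse_response_summary, psychometric,
                       reactivation_stats, similarity_trace)
from .config import ModelConfig
from .experiments import (EXP1_TIMES, EXP2_TIMES, ParticipantPlan,
                          realize_events, run_participants, schedule_exp1,
                          schedule_exp2, schedule_exp3)
from .neural_core import LIFState, lif_rate, lif_step
from .stimuli import make_grating, make_impulse
from .stsp import STSPParams, STSPState, euler_reference, stsp_step
from .wm_model import InputEvent, PulseEvent, WMModel, run_trial

CANON = np.pi / 2


def stsp_oracle_deviation(seed: int = 0, seconds: float = 3.0,
                          rate_hz: float = 20.0,
                          dt_fine: float = 1e-5) -> dict:
    """Max |du|, |dx| between 1 ms exact stepping and 0.01 ms Euler."""
    params = STSPParams()
    rng = np.random.default_rng(seed)
    train = rng.random(int(seconds * 1000)) < rate_hz / 1000.0
    state = STSPState.rest(1, 1, params)
    us, xs = [], []
    for s in train:
        stsp_step(state, np.array([[s]]), 0.001, params)
        us.append(state.u[0, 0])
        xs.append(state.x[0, 0])
    u_ref, x_ref = euler_reference(train, 0.001, params, dt_fine=dt_fine)
    return {"max_du": float(np.max(np.abs(np.array(us) - u_ref))),
            "max_dx": float(np.max(np.abs(np.array(xs) - x_ref))),
            "n_spikes": int(train.sum())}


def stsp_analytic_checks() -> dict:
    """Single-spike jump and 1.5 s relaxation against the closed forms."""
    params = STSPParams()
    state = STSPState.rest(1, 1, params)
    stsp_step(state, np.ones((1, 1), bool), 0.001, params)
    jump_u, jump_x = float(state.u[0, 0]), float(state.x[0, 0])
    for _ in range(1500):
        stsp_step(state, np.zeros((1, 1), bool), 0.001, params)
    return {"u_after_spike": jump_u, "x_after_spike": jump_x,
            "u_after_1p5s": float(state.u[0, 0]),
            "u_after_1p5s_expected": 0.2 + 0.16 * np.exp(-1.0)}


def lif_rate_check(J: float = 2.0, seconds: float = 10.0,
                   dt: float = 0.001) -> dict:
    st = LIFState(np.zeros((1, 1)), np.zeros((1, 1)))
    Jarr = np.array([[float(J)]])
    count = 0
    for _ in range(int(round(seconds / dt))):
        count += lif_step(st, Jarr, dt).sum()
    emp = count / seconds
    ana = float(lif_rate(J))
    return {"empirical_hz": float(emp), "analytic_hz": ana,
            "rel_error": abs(emp - ana) / ana}


def reference_trial_run(model: WMModel, n_trials: int = 20,
                        item_deg: float = 0.0, probe_deg: float = 42.0,
                        impulse_style: str = "bullseye-black") -> dict:
    """The Fig-3-style reference condition: both modules encode the same
    item, the first module is cued; constant within-trial phase.

    Returns, per module, the delay spike counts, the cue-window decoding
    (top ideal-vector orientation), and the impulse-window item/impulse
    similarity summary.
    """
    t = EXP1_TIMES
    events, pulses = [], [PulseEvent(0, t["cue_on"], t["cue_off"],
                                     model.config.reactivation_amplitude)]
    for m, mod in enumerate(model.modules):
        item = mod.basis.encode_image(make_grating(item_deg, CANON))
        imp = mod.basis.encode_image(make_impulse(impulse_style))
        probe = mod.basis.encode_image(make_grating(probe_deg, CANON))
        events += [
            InputEvent(m, t["item_on"], t["item_off"],
                       np.broadcast_to(item, (n_trials, item.size))),
            InputEvent(m, t["impulse_on"], t["impulse_off"],
                       np.broadcast_to(imp, (n_trials, imp.size))),
            InputEvent(m, t["probe_on"], t["probe_off"],
                       np.broadcast_to(probe, (n_trials, probe.size))),
        ]
    res = run_trial(model, events, pulses, t["horizon"], n_trials)
    out = {}
    for m, mod in enumerate(model.modules):
        tr = res.modules[m]
        refs = np.vstack([mod.basis.R,
                          mod.basis.encode_image(make_impulse(impulse_style))])
        item_idx = int(np.argmin(np.abs(mod.basis.R_theta - item_deg)))
        strace = similarity_trace(tr.mem_decoded, refs,
                                  peak_window=slice(0, 400))
        # cue-window decoding: orientation of the best-matching ideal vector
        # at the reactivation response's peak
        w = slice(t["cue_on"], t["cue_on"] + 350)
        tpk = t["cue_on"] + int(np.argmax(strace.norm[w]))
        cue_sims = strace.similarity[tpk, :180]
        cue_top = float(mod.basis.R_theta[int(np.argmax(cue_sims))])
        imp_summary = impulse_response_summary(
            strace, item_idx, 180, (t["impulse_on"] + 10, t["impulse_on"] + 500))
        out[m] = {
            "silent_window_spikes": int(tr.mem_spike_count[:, 1500:2000].sum()),
            "delay_spikes_per_trial": float(
                tr.mem_spike_count[:, 1500:2000].sum() / n_trials),
            "cue_top_theta": cue_top,
            "cue_top_error_deg": abs((cue_top - item_deg + 90) % 180 - 90),
            "cue_peak_norm": float(strace.norm[tpk]),
            "cue_window_spikes": int(tr.mem_spike_count[:, w].sum()),
            "impulse": imp_summary,
        }
    return out


def cue_recovery_errors(model: WMModel, n_trials: int = 20,
                        seed: int = 0) -> np.ndarray:
    """Per-trial cue-reactivation decoding errors at random orientations.

    Each trial encodes a random item (constant phase), is cued at 1050 ms,
    and the decoded vector at the reactivation peak is matched against the
    ideal-vector set; returns |top orientation - item| in degrees.
    """
    rng = np.random.default_rng(seed)
    mod = model.modules[0]
    thetas = rng.uniform(-90, 90, n_trials)
    items = np.array([mod.basis.encode_image(make_grating(th, CANON))
                      for th in thetas])
    events = [InputEvent(0, 0, 250, items)]
    pulses = [PulseEvent(0, 1050, 1070, model.config.reactivation_amplitude)]
    res = run_trial(model, events, pulses, 1500, n_trials, modules=[0])
    tr = res.modules[0]
    errors = []
    for i in range(n_trials):
        strace = similarity_trace(tr.mem_decoded[i], mod.basis.R,
                                  peak_window=slice(0, 400))
        w = slice(1050, 1450)
        tpk = 1050 + int(np.argmax(strace.norm[w]))
        top = float(mod.basis.R_theta[int(np.argmax(strace.similarity[tpk]))])
        errors.append(abs((top - thetas[i] + 90) % 180 - 90))
    return np.array(errors)


def exp2_reference_run(model: WMModel, n_trials: int = 20,
                       probe_deg: float = 40.0) -> dict:
    """Fig-10/11-style run: 0-degree items, both probes at +40 degrees.

    Returns the item/impulse similarity ratios at the second impulse for
    the primary (module 0) and secondary (module 1) items.
    """
    sched = schedule_exp2(probe_deg, probe_deg)
    item = np.zeros((n_trials, 2))
    probe = np.full((n_trials, 2), probe_deg)
    ph = np.full((n_trials, 2), CANON)
    events, pulses = realize_events(model, sched, item, probe, ph, ph,
                                    model.config)
    res = run_trial(model, events, pulses, sched.horizon_ms, n_trials)
    t = EXP2_TIMES
    out = {}
    for m, lab in ((0, "primary"), (1, "secondary")):
        mod = model.modules[m]
        refs = np.vstack([mod.basis.ideal_vector(0.0),
                          mod.basis.encode_image(make_impulse("bullseye-grey60"))])
        strace = similarity_trace(res.modules[m].mem_decoded, refs,
                                  peak_window=slice(0, 400))
        s2 = impulse_response_summary(
            strace, 0, 1, (t["impulse2_on"] + 10, t["impulse2_on"] + 500))
        s1 = impulse_response_summary(
            strace, 0, 1, (t["impulse1_on"] + 10, t["impulse1_on"] + 500))
        out[lab] = {
            "impulse1_item_over_impulse": 1.0 / s1["ratio_impulse_over_item"],
            "impulse2_item_over_impulse": 1.0 / s2["ratio_impulse_over_item"],
            "impulse2": s2,
        }
    return out


def psychometric_run(config: ModelConfig, participants: int = 2,
                     reps_per_level: int = 20, seed: int = 0):
    """Scaled Experiment-1 behavior: returns (table, curve)."""
    plan = ParticipantPlan(participants, reps_per_level)
    table = run_participants("exp1", plan, config, master_seed=seed)
    return table, psychometric(table)


def monotonicity_violation(curve, z: float = 3.0) -> float:
    """Largest pairwise decrease of P(CW) beyond z binomial standard errors.

    0 means the curve is monotone non-decreasing within sampling noise.
    """
    p, n = curve.p_clockwise, curve.n_trials
    worst = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            pbar = 0.5 * (p[i] + p[j])
            se = np.sqrt(max(pbar * (1 - pbar), 1e-6) * (1 / n[i] + 1 / n[j]))
            worst = max(worst, (p[i] - p[j]) - z * se)
    return float(worst)


def symmetry_deviation(curve) -> float:
    """|mean over levels of P(CW|+d) + P(CW|-d) - 1|."""
    levels = curve.levels
    sums = []
    for d in levels[levels > 0]:
        if -d in levels:
            sums.append(curve.p_clockwise[levels == d][0]
                        + curve.p_clockwise[levels == -d][0])
    return float(abs(np.mean(sums) - 1.0))


def soa_accuracy_run(config: ModelConfig, soas: Sequence[int] = (0, 100, 500),
                     trials_per_soa: int = 30, seed: int = 0,
                     impulse_style: str = "bullseye-black",
                     model: Optional[WMModel] = None) -> dict:
    """Exp-3 accuracy per SOA at +-16 degrees (scaled)."""
    if model is None:
        model = WMModel(config, seed=seed, n_modules=1)
    rng = np.random.default_rng(seed + 1)
    mod = model.modules[0]
    acc = {}
    for soa in soas:
        sched = schedule_exp3(16.0, soa, impulse_style=impulse_style)
        b = trials_per_soa
        items = rng.uniform(-90, 90, (b, 2))
        signs = rng.choice([-1.0, 1.0], b)
        deltas = 16.0 * signs
        probes = items + deltas[:, None]
        iph = rng.uniform(0, 2 * np.pi, (b, 2))
        pph = rng.uniform(0, 2 * np.pi, (b, 2))
        events, pulses = realize_events(model, sched, items, probes, iph, pph,
                                        config)
        res = run_trial(model, events, pulses, sched.horizon_ms, b,
                        record_decoded=False, modules=[0])
        a, bb = sched.decision_windows[0][1], sched.decision_windows[0][2]
        integ = res.modules[0].decision[:, a:bb].sum(axis=1)
        sign = np.sign(integ)
        ties = sign == 0
        sign[ties] = rng.choice([-1.0, 1.0], int(ties.sum()))
        acc[soa] = float((sign == signs).mean())
    return acc


def impulse_drive_comparison(model: WMModel, soa: int = 500) -> dict:
    """Peak memory-population response to the white vs black impulse."""
    out = {}
    for style in ("bullseye-black", "uniform-white"):
        sched = schedule_exp3(16.0, soa, impulse_style=style)
        b = 4
        items = np.zeros((b, 2))
        probes = np.full((b, 2), 16.0)
        ph = np.full((b, 2), CANON)
        events, pulses = realize_events(model, sched, items, probes, ph, ph,
                                        model.config)
        res = run_trial(model, events, pulses, sched.horizon_ms, b,
                        record_decoded=False, modules=[0])
        cnt = res.modules[0].mem_spike_count.mean(axis=0)
        imp_on = 2650 - soa
        out[style] = {"peak_rate": float(cnt[imp_on:2650].max()),
                      "total_spikes": float(cnt[imp_on:2650].sum())}
    return out


BISTABLE_NOISE_STD = 0.02
BISTABLE_SLOW_WEIGHT = 1.6


def bistable_run(config: Optional[ModelConfig] = None, n_runs: int = 10,
                 seed: int = 0, window_ms: tuple = (400, 1400),
                 burst_threshold: float = 8.0) -> dict:
    """Noise-driven spontaneous reactivation after encoding.

    Uses the bi-stable preset (background current noise plus a stronger
    slow recurrent component); returns burst counts per run in a 1 s
    window and the pooled inter-burst intervals.
    """
    import copy

    cfg = copy.deepcopy(config) if config is not None else ModelConfig()
    cfg.noise_std = BISTABLE_NOISE_STD
    cfg.recurrent_slow_weight = BISTABLE_SLOW_WEIGHT
    model = WMModel(cfg, seed=seed, n_modules=1)
    mod = model.modules[0]
    item = mod.basis.ideal_vector(0.0)[None]
    counts, intervals = [], []
    for k in range(n_runs):
        res = run_trial(model, [InputEvent(0, 0, 250, item)], [],
                        window_ms[1] + 100, batch=1, record_decoded=False,
                        noise_std=cfg.noise_std,
                        noise_seed=seed * 1000 + k, modules=[0])
        cnt = res.modules[0].mem_spike_count[0].astype(float)
        st = reactivation_stats(cnt[window_ms[0]:window_ms[1]],
                                threshold_rate=burst_threshold)
        counts.append(st["n_bursts"])
        intervals += list(st["intervals_ms"])
    return {"bursts_per_run": counts,
            "mean_bursts": float(np.mean(counts)),
            "intervals_ms": intervals,
            "median_interval_ms": (float(np.median(intervals))
                                   if intervals else float("nan")),
            "tau_D_ms": cfg.stsp.tau_D * 1000.0}
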