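"""Trial schedules and run orchestration for the three delayed-response tasks.

All event times are integer milliseconds.  The reference experiment
(Experiment 1) presents two gratings for 250 ms (one per module), reactivates
the cued module's memory population 800 ms after item offset (cue onset
1050 ms, 20 ms pulse), shows the black bull's-eye impulse to both sensory
populations at 2150-2250 ms (1100 ms after cue onset) and the probe at
2650-2900 ms (400 ms after impulse offset).  The impulse-duration
generalization (Experiment 3) moves the impulse onset to probe-onset minus
the stimulus-onset asynchrony and stretches it until the probe appears.  The
two-item generalization (Experiment 2) runs a longer timeline with two grey
bull's-eye impulses and two probes, the second module encoding at 90% input
strength and being reactivated 450 ms after the first probe's onset.

Responses are always read from the probed module's decision population; a
simulated participant is a freshly seeded model (new Gabor banks, new
neuron parameters) performing a block of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig
from .stimuli import (DESIGN_DELTAS, make_grating, make_impulse,
                      wrap_orientation)
from .wm_model import InputEvent, PulseEvent, WMModel, run_trial

EXP1_TIMES = {
    "item_on": 0, "item_off": 250,
    "cue_on": 1050, "cue_off": 1070,
    "impulse_on": 2150, "impulse_off": 2250,
    "probe_on": 2650, "probe_off": 2900,
    "horizon": 3200,
}

EXP2_TIMES = {
    "item_on": 0, "item_off": 250,
    "impulse1_on": 1200, "impulse1_off": 1300,
    "probe1_on": 1800, "probe1_off": 2050,
    "react_on": 2250, "react_off": 2270,
    "impulse2_on": 3550, "impulse2_off": 3650,
    "probe2_on": 4050, "probe2_off": 4300,
    "horizon": 4600,
}

EXP3_SOAS = (0, 50, 100, 250, 500)
DECISION_WINDOW_MS = 500

#: full-size participant plans as in the original simulations
FULL_PLANS = {"exp1": (30, 1344), "exp2": (19, 1728), "exp3": (20, 280)}


@dataclass
class ScheduleEvent:
    """One schedule entry: what appears on which port and when."""

    port: str  # "visual" or "reactivation"
    module: int
    onset_ms: int
    offset_ms: int
    stimulus: Optional[dict] = None  # kind + parameters
    amplitude: Optional[float] = None

    def __post_init__(self):
        if self.onset_ms < 0 or self.offset_ms < self.onset_ms:
            raise ValueError("invalid event times")


@dataclass
class TrialSchedule:
    """Ordered events plus the simulation horizon and decision windows."""

    design: str
    events: list
    horizon_ms: int
    decision_windows: list  # (module, start_ms, end_ms) per probe
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        for e in self.events:
            if e.offset_ms > self.horizon_ms:
                raise ValueError("event exceeds horizon")


def _grating_ev(module, onset, offset, scale=1.0):
    return ScheduleEvent("visual", module, onset, offset,
                         {"kind": "grating", "scale": scale})


def schedule_exp1(delta_signed: float, cued_module: int = 0) -> TrialSchedule:
    """Experiment-1 schedule for a signed item-probe difference."""
    if abs(delta_signed) not in DESIGN_DELTAS["exp1"]:
        raise ValueError(f"invalid Exp1 angular difference: {delta_signed}")
    t = EXP1_TIMES
    events = []
    for m in (0, 1):
        events.append(_grating_ev(m, t["item_on"], t["item_off"]))
        events.append(ScheduleEvent("visual", m, t["impulse_on"], t["impulse_off"],
                                    {"kind": "impulse", "style": "bullseye-black"}))
        events.append(_grating_ev(m, t["probe_on"], t["probe_off"]))
    events.append(ScheduleEvent("reactivation", cued_module,
                                t["cue_on"], t["cue_off"], amplitude=None))
    return TrialSchedule("exp1", events, t["horizon"],
                         [(cued_module, t["probe_on"],
                           t["probe_on"] + DECISION_WINDOW_MS)],
                         {"delta": float(delta_signed), "cued_module": cued_module})


def schedule_exp3(delta_signed: float, soa_ms: int,
                  impulse_style: str = "bullseye-black",
                  cued_module: int = 0) -> TrialSchedule:
    """Impulse-duration generalization: impulse lasts from probe-onset - SOA
    until the probe; SOA 0 means no impulse at all."""
    if abs(delta_signed) not in DESIGN_DELTAS["exp3"]:
        raise ValueError(f"invalid Exp3 angular difference: {delta_signed}")
    if soa_ms not in EXP3_SOAS:
        raise ValueError(f"invalid SOA: {soa_ms}")
    if impulse_style not in ("bullseye-black", "uniform-white"):
        raise ValueError(f"invalid Exp3 impulse style: {impulse_style}")
    t = EXP1_TIMES
    events = []
    for m in (0, 1):
        events.append(_grating_ev(m, t["item_on"], t["item_off"]))
        if soa_ms > 0:
            events.append(ScheduleEvent(
                "visual", m, t["probe_on"] - soa_ms, t["probe_on"],
                {"kind": "impulse", "style": impulse_style}))
        events.append(_grating_ev(m, t["probe_on"], t["probe_off"]))
    events.append(ScheduleEvent("reactivation", cued_module,
                                t["cue_on"], t["cue_off"], amplitude=None))
    return TrialSchedule("exp3", events, t["horizon"],
                         [(cued_module, t["probe_on"],
                           t["probe_on"] + DECISION_WINDOW_MS)],
                         {"delta": float(delta_signed), "soa": soa_ms,
                          "impulse_style": impulse_style,
                          "cued_module": cued_module})


def schedule_exp2(delta1_signed: float, delta2_signed: float) -> TrialSchedule:
    """Two-item generalization: module 0 holds the primary item (probed
    first), module 1 the secondary item (90% input, reactivated after the
    first probe, probed last)."""
    for d in (delta1_signed, delta2_signed):
        if abs(d) not in DESIGN_DELTAS["exp2"]:
            raise ValueError(f"invalid Exp2 angular difference: {d}")
    t = EXP2_TIMES
    events = [
        _grating_ev(0, t["item_on"], t["item_off"], scale=1.0),
        _grating_ev(1, t["item_on"], t["item_off"], scale=0.9),
    ]
    for m in (0, 1):
        events.append(ScheduleEvent("visual", m, t["impulse1_on"], t["impulse1_off"],
                                    {"kind": "impulse", "style": "bullseye-grey60"}))
        events.append(ScheduleEvent("visual", m, t["impulse2_on"], t["impulse2_off"],
                                    {"kind": "impulse", "style": "bullseye-grey60"}))
    events.append(_grating_ev(0, t["probe1_on"], t["probe1_off"]))
    events.append(ScheduleEvent("reactivation", 1, t["react_on"], t["react_off"],
                                amplitude=None))
    events.append(_grating_ev(1, t["probe2_on"], t["probe2_off"]))
    return TrialSchedule("exp2", events, t["horizon"],
                         [(0, t["probe1_on"], t["probe1_on"] + DECISION_WINDOW_MS),
                          (1, t["probe2_on"], t["probe2_on"] + DECISION_WINDOW_MS)],
                         {"delta": float(delta1_signed),
                          "delta2": float(delta2_signed)})


def make_schedule(design: str, **kwargs) -> TrialSchedule:
    if design == "exp1":
        return schedule_exp1(**kwargs)
    if design == "exp2":
        return schedule_exp2(**kwargs)
    if design == "exp3":
        return schedule_exp3(**kwargs)
    raise ValueError(f"unknown design: {design!r}")


# ---------------------------------------------------------------------
# realizing schedules as model events


def realize_events(model: WMModel, schedule: TrialSchedule,
                   item_deg: np.ndarray, probe_deg: np.ndarray,
                   item_phase: np.ndarray, probe_phase: np.ndarray,
                   config: ModelConfig):
    """Turn a schedule plus per-trial orientations into batched model events.

    ``item_deg`` etc. have shape (batch, n_modules).  Grating events before
    1000 ms use the item orientation of the event's module; later grating
    events are probes.  Exp-2's second probe targets the second module's own
    item/probe pair.
    """
    item_deg = np.atleast_2d(item_deg)
    probe_deg = np.atleast_2d(probe_deg)
    batch = item_deg.shape[0]
    events, pulses = [], []
    for ev in schedule.events:
        if ev.module >= len(model.modules):
            continue  # single-module runs skip the other hemifield
        if ev.port == "reactivation":
            amp = ev.amplitude
            if amp is None:
                amp = config.reactivation_amplitude
            pulses.append(PulseEvent(ev.module, ev.onset_ms, ev.offset_ms, amp))
            continue
        stim = ev.stimulus
        mod = model.modules[ev.module]
        if stim["kind"] == "impulse":
            v = mod.basis.encode_image(make_impulse(stim["style"]))
            vecs = np.broadcast_to(v, (batch, v.size))
        else:
            is_probe = ev.onset_ms >= 1000
            theta = probe_deg[:, ev.module] if is_probe else item_deg[:, ev.module]
            phase = probe_phase[:, ev.module] if is_probe else item_phase[:, ev.module]
            scale = stim.get("scale", 1.0)
            vecs = np.array([scale * mod.basis.encode_image(make_grating(t, p))
                             for t, p in zip(theta, phase)])
        events.append(InputEvent(ev.module, ev.onset_ms, ev.offset_ms, vecs))
    return events, pulses


def decide_from_result(result, windows, rng: np.random.Generator) -> np.ndarray:
    """Sign of the integrated decision trace per probe window, (batch, n_windows);
    +1 is clockwise.  Exact zero integrals are broken at random."""
    out = []
    for (module, a, b) in windows:
        tr = result.modules[module]
        ia = int(round(a / result.dt_ms))
        ib = int(round(b / result.dt_ms))
        integ = tr.decision[:, ia:ib].sum(axis=1) * (result.dt_ms / 1000.0)
        sign = np.sign(integ)
        ties = sign == 0
        if np.any(ties):
            sign[ties] = rng.choice([-1.0, 1.0], size=int(ties.sum()))
        out.append(sign)
    return np.stack(out, axis=1)


# ---------------------------------------------------------------------
# participant-level orchestration


@dataclass
class ParticipantPlan:
    """How many participants and how many repetitions of each condition
    cell each of them performs."""

    participants: int = 2
    reps_per_cell: int = 1

    def cells(self, design: str, impulse_style: str = "bullseye-black"):
        """The design's condition cells (signed difference + extras)."""
        if design == "exp1":
            return [{"delta_signed": d * s}
                    for d in DESIGN_DELTAS["exp1"] for s in (+1, -1)]
        if design == "exp3":
            return [{"delta_signed": d * s, "soa_ms": soa,
                     "impulse_style": impulse_style}
                    for soa in EXP3_SOAS for d in DESIGN_DELTAS["exp3"]
                    for s in (+1, -1)]
        if design == "exp2":
            return [{"delta1_signed": d1 * s1, "delta2_signed": d2 * s2}
                    for d1 in DESIGN_DELTAS["exp2"] for s1 in (+1, -1)
                    for d2 in DESIGN_DELTAS["exp2"] for s2 in (+1, -1)]
        raise ValueError(f"unknown design: {design!r}")


def participant_seeds(master_seed: int, n: int):
    """Stable per-participant integer seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_participants(design: str, plan: ParticipantPlan, config: ModelConfig,
                     master_seed: int = 0, impulse_style: str = "bullseye-black",
                     batch_size: int = 56, record_traces: bool = False,
                     constant_phase: Optional[float] = None) -> pd.DataFrame:
    """Simulate the plan and return one row per response.

    Each participant gets a fresh model (new Gabor banks and neuron
    parameters).  Exp-2 yields two rows per trial (one per probe).  Trials
    are grouped by condition timing and run in batches.
    """
    seeds = participant_seeds(master_seed, plan.participants)
    rows = []
    for p, seed in enumerate(seeds):
        model = WMModel(config, seed=seed)
        rng = np.random.default_rng(seed)
        # one entry per trial; cells sharing event timing run in one batch
        trials = [dict(cell) for cell in plan.cells(design, impulse_style)
                  for _ in range(plan.reps_per_cell)]
        rng.shuffle(trials)

        def timing_key(cell):
            return (cell.get("soa_ms"), cell.get("impulse_style"))

        groups = {}
        for cell in trials:
            groups.setdefault(timing_key(cell), []).append(cell)
        trial_counter = 0
        for cells in groups.values():
            sched = make_schedule(design, **cells[0])
            for start in range(0, len(cells), batch_size):
                chunk = cells[start:start + batch_size]
                b = len(chunk)
                item, probe, iph, pph = _draw_trials(design, chunk, rng,
                                                     constant_phase)
                events, pulses = realize_events(model, sched, item, probe,
                                                iph, pph, config)
                probed = sorted({w[0] for w in sched.decision_windows})
                needed = probed if not record_traces else None
                res = run_trial(model, events, pulses, sched.horizon_ms, b,
                                record_decoded=record_traces, modules=needed)
                remap = (sched.decision_windows if needed is None else
                         [(probed.index(m), a, bb)
                          for (m, a, bb) in sched.decision_windows])
                signs = decide_from_result(res, remap, rng)
                for i, cell in enumerate(chunk):
                    for w, (module, a, _) in enumerate(sched.decision_windows):
                        d = (cell.get("delta_signed")
                             if design != "exp2" else
                             (cell["delta1_signed"] if w == 0 else cell["delta2_signed"]))
                        rows.append({
                            "design": design, "participant": p, "seed": seed,
                            "trial": trial_counter + i, "probe_index": w,
                            "module": module, "delta": float(d),
                            "response": int(signs[i, w]),
                            "correct": int(np.sign(d) == signs[i, w]),
                            **{k: v for k, v in cell.items()
                               if k not in ("delta_signed", "delta1_signed",
                                            "delta2_signed")},
                        })
                trial_counter += b
    return pd.DataFrame(rows)


def _draw_trials(design, cells, rng, constant_phase):
    batch = len(cells)
    items = rng.uniform(-90.0, 90.0, size=(batch, 2))
    items = np.vectorize(wrap_orientation)(items)
    deltas = np.empty((batch, 2))
    for i, cell in enumerate(cells):
        if design == "exp2":
            deltas[i] = (cell["delta1_signed"], cell["delta2_signed"])
        else:
            # both modules receive items; only the cued one is probed against
            # its own item, the other gets an independent difference draw
            mags = DESIGN_DELTAS[design]
            d1 = rng.choice(mags) * rng.choice([-1.0, 1.0])
            deltas[i] = (cell["delta_signed"], d1)
    probes = np.vectorize(wrap_orientation)(items + deltas)
    if constant_phase is None:
        iph = rng.uniform(0, 2 * np.pi, size=(batch, 2))
        pph = rng.uniform(0, 2 * np.pi, size=(batch, 2))
    else:
        iph = np.full((batch, 2), float(constant_phase))
        pph = np.full((batch, 2), float(constant_phase))
    return items, probes, iph, pph


# ---------------------------------------------------------------------
# parameter exploration


def parameter_grid(tau_d_values: Sequence[float], tau_f_values: Sequence[float],
                   plan: ParticipantPlan, config: ModelConfig,
                   master_seed: int = 0,
                   reference_curve: Optional[pd.DataFrame] = None,
                   batch_size: int = 56) -> pd.DataFrame:
    """Run a scaled Exp-1 plan for each (tau_D, tau_F) cell.

    Values outside the standard exploration ranges (0.1-0.4 s and
    0.6-1.8 s) trigger a warning but still run.  Returns one row per cell
    with the psychometric curve and, when a reference curve is given,
    R-squared and root-mean-square deviation against it.
    """
    import copy
    import warnings

    from .analysis import fit_metrics, psychometric

    out = []
    for td in tau_d_values:
        for tf in tau_f_values:
            if not (0.1 <= td <= 0.4) or not (0.6 <= tf <= 1.8):
                warnings.warn(f"(tau_D={td}, tau_F={tf}) outside the explored "
                              "ranges [0.1, 0.4] x [0.6, 1.8] s")
            cfg = copy.deepcopy(config)
            cfg.stsp.tau_D = float(td)
            cfg.stsp.tau_F = float(tf)
            table = run_participants("exp1", plan, cfg, master_seed,
                                     batch_size=batch_size)
            curve = psychometric(table) if len(table) else None
            row = {"tau_D": td, "tau_F": tf, "curve": curve,
                   "n_trials": len(table)}
            if reference_curve is not None:
                r2, rmsd = fit_metrics(curve, reference_curve)
                row["r2"] = r2
                row["rmsd"] = rmsd
            out.append(row)
    return pd.DataFrame(out)
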