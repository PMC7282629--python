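"""Representational and behavioral analyses.

The central representational quantity is the absolute cosine similarity
between the vector decoded from a memory population's spikes and the ideal
vectors of candidate stimuli: 1 when the population unambiguously
represents that stimulus, 0 when orthogonal, and masked out whenever the
population is quiet (a near-zero decoded vector has no meaningful
direction).  Behavior is summarized as the proportion of clockwise
responses per signed angular difference, the psychometric curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .neural_core import lowpass_filter

SIMILARITY_FILTER_TAU = 0.02  # s, lowpass on the decoded trace
ACTIVITY_THRESHOLD_FRAC = 0.05  # of the encoding-peak norm


@dataclass
class SimilarityTrace:
    """Per-timestep |cosine| similarity to a set of reference vectors."""

    time_ms: np.ndarray
    similarity: np.ndarray  # (T, n_refs) in [0, 1], 0 where masked
    norm: np.ndarray  # (T,) decoded-vector norm after filtering
    active: np.ndarray  # (T,) bool, norm above the activity threshold


def similarity_trace(decoded: np.ndarray, references: np.ndarray,
                     dt_ms: float = 1.0,
                     filter_tau: float = SIMILARITY_FILTER_TAU,
                     threshold_frac: float = ACTIVITY_THRESHOLD_FRAC,
                     peak_window: Optional[slice] = None) -> SimilarityTrace:
    """Absolute cosine similarity of a decoded trace to reference vectors.

    ``decoded`` is (T, D) (or (B, T, D), averaged over the batch first);
    it is lowpass-filtered before normalization.  Timesteps whose decoded
    norm falls below ``threshold_frac`` of the peak norm (measured over
    ``peak_window``, default the whole trace) are masked to 0: with no
    spiking there is nothing to decode.
    """
    decoded = np.asarray(decoded, dtype=float)
    if decoded.ndim == 3:
        decoded = decoded.mean(axis=0)
    refs = np.atleast_2d(np.asarray(references, dtype=float))
    ref_norms = np.linalg.norm(refs, axis=1)
    if np.any(ref_norms < 1e-12):
        raise ValueError("zero-norm reference vector")
    f = lowpass_filter(decoded, filter_tau, dt=dt_ms / 1000.0, axis=0)
    norms = np.linalg.norm(f, axis=1)
    peak = norms[peak_window].max() if peak_window is not None else norms.max()
    active = norms > threshold_frac * max(peak, 1e-12)
    sims = np.abs(f @ refs.T) / np.maximum(norms[:, None] * ref_norms[None, :],
                                           1e-12)
    sims[~active] = 0.0
    return SimilarityTrace(np.arange(len(norms)) * dt_ms, sims, norms, active)


def impulse_response_summary(trace: SimilarityTrace, item_index: int,
                             impulse_index: int,
                             window_ms: tuple) -> dict:
    """Peak similarity to the stored item and to the impulse in a window.

    Returns the two peaks, their ratio (impulse over item), and whether any
    active timestep shows the item more strongly than the impulse.
    """
    a, b = window_ms
    sel = (trace.time_ms >= a) & (trace.time_ms < b)
    if not np.any(sel):
        raise ValueError("empty analysis window")
    s_item = trace.similarity[sel, item_index]
    s_imp = trace.similarity[sel, impulse_index]
    act = trace.active[sel]
    peak_item = float(s_item.max())
    peak_imp = float(s_imp.max())
    return {
        "peak_item": peak_item,
        "peak_impulse": peak_imp,
        "ratio_impulse_over_item": peak_imp / max(peak_item, 1e-12),
        "item_exceeds_impulse_steps": int(np.sum(act & (s_item > s_imp))),
    }


def decide(decision_trace: np.ndarray, window: tuple, dt_ms: float = 1.0,
           rng: Optional[np.random.Generator] = None) -> int:
    """Sign of the integrated decision value over the window: +1 clockwise.

    An exactly zero integral is broken at random with ``rng``.
    """
    a, b = window
    trace = np.asarray(decision_trace, dtype=float)
    ia, ib = int(round(a / dt_ms)), int(round(b / dt_ms))
    if ia < 0 or ib > trace.shape[-1] or ib <= ia:
        raise ValueError("decision window outside the trace")
    integ = trace[..., ia:ib].sum(axis=-1) * dt_ms / 1000.0
    if np.ndim(integ) == 0:
        if integ == 0:
            if rng is None:
                rng = np.random.default_rng()
            return int(rng.choice([-1, 1]))
        return int(np.sign(integ))
    sign = np.sign(integ)
    ties = sign == 0
    if np.any(ties):
        if rng is None:
            rng = np.random.default_rng()
        sign[ties] = rng.choice([-1, 1], size=int(ties.sum()))
    return sign.astype(int)


@dataclass
class PsychometricCurve:
    """Proportion of clockwise responses per signed angular difference."""

    levels: np.ndarray
    p_clockwise: np.ndarray
    n_trials: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_deg": self.levels,
                             "p_clockwise": self.p_clockwise,
                             "n": self.n_trials})


def psychometric(table: pd.DataFrame, by_participant: bool = False):
    """Aggregate a response table into a psychometric curve.

    The table needs ``delta`` (signed degrees) and ``response`` (+1
    clockwise / -1 counter-clockwise) columns.
    """
    if len(table) == 0:
        raise ValueError("empty response table")
    if by_participant:
        return {p: psychometric(g) for p, g in table.groupby("participant")}
    grouped = table.groupby("delta")["response"]
    levels = np.array(sorted(grouped.groups))
    p_cw = np.array([float((grouped.get_group(l) > 0).mean()) for l in levels])
    n = np.array([int(grouped.get_group(l).size) for l in levels])
    return PsychometricCurve(levels, p_cw, n)


def fit_metrics(model_curve, reference_curve) -> tuple:
    """Coefficient of determination and RMSD between two curves.

    Both arguments may be :class:`PsychometricCurve` or data frames with
    ``delta_deg``/``p_clockwise`` columns; the angular levels must match.
    """
    def unpack(c):
        if isinstance(c, PsychometricCurve):
            return c.levels, c.p_clockwise
        return (np.asarray(c["delta_deg"], dtype=float),
                np.asarray(c["p_clockwise"], dtype=float))

    lm, pm = unpack(model_curve)
    lr, pr = unpack(reference_curve)
    order_m, order_r = np.argsort(lm), np.argsort(lr)
    if len(lm) != len(lr) or not np.allclose(lm[order_m], lr[order_r]):
        raise ValueError("angular levels do not match")
    pm, pr = pm[order_m], pr[order_r]
    resid = pm - pr
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((pr - pr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    rmsd = float(np.sqrt(np.mean(resid**2)))
    return r2, rmsd


def reactivation_stats(spike_counts: np.ndarray, dt_ms: float = 1.0,
                       smooth_tau: float = 0.01,
                       threshold_rate: Optional[float] = None,
                       baseline_window: Optional[tuple] = None,
                       threshold_factor: float = 3.0,
                       min_separation_ms: float = 20.0) -> dict:
    """Burst onsets and inter-burst intervals from a population spike count.

    The per-step population count is smoothed with a 10 ms lowpass; bursts
    are upward crossings of a threshold (either given absolutely in
    spikes/step, or ``threshold_factor`` times the mean smoothed rate in
    ``baseline_window``, with a small floor so an all-zero baseline does
    not make everything a burst).  Crossings closer than
    ``min_separation_ms`` merge into one burst.
    """
    counts = np.asarray(spike_counts, dtype=float)
    if counts.ndim == 2:
        counts = counts.mean(axis=0)
    sm = lowpass_filter(counts, smooth_tau, dt=dt_ms / 1000.0, axis=0)
    if threshold_rate is None:
        if baseline_window is not None:
            a, b = baseline_window
            base = sm[int(a / dt_ms):int(b / dt_ms)].mean()
        else:
            base = sm.mean()
        threshold_rate = max(threshold_factor * base, 0.5)
    above = sm > threshold_rate
    onsets = np.where(above[1:] & ~above[:-1])[0] + 1
    merged = []
    for t in onsets:
        if not merged or (t - merged[-1]) * dt_ms >= min_separation_ms:
            merged.append(int(t))
    onsets_ms = np.array(merged, dtype=float) * dt_ms
    intervals = np.diff(onsets_ms)
    return {"onsets_ms": onsets_ms, "intervals_ms": intervals,
            "n_bursts": len(onsets_ms), "threshold": float(threshold_rate)}
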