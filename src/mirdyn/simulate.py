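"""Coherent feed-forward / feed-back regulatory-motif simulation.

A miRNA-inhibition impulse de-represses a transcription factor (TF) whose
protein level Y follows the first-order kinetics dY/dt = beta - alpha*Y
(beta = production, alpha = degradation; alpha set by a 10 h half-life).
In the coherent feed-forward and positive feed-back motifs the target
gene shows a direct de-repression bump at the impulse time plus a
secondary response that switches on once Y crosses an activation
threshold theta, introducing the characteristic delay; the simple
indirect motif shows the delayed secondary response only.  All
trajectories are piecewise exponentials computed in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "SimTrajectory",
    "simulate_tf",
    "simulate_target",
    "threshold_crossing_time",
    "population_simulate",
]

MOTIFS = ("ffl", "feedback", "simple_indirect")


@dataclass(frozen=True)
class SimParams:
    """Motif simulation parameters.

    TF levels are normalized so the during-impulse asymptote equals 1;
    ``theta`` is the activation threshold on that scale.  The impulse is
    a box drive (onset, duration, amplitude) representing sustained
    antimiR de-repression; the target's direct bump is a Gaussian at the
    impulse onset + ``direct_bump_delay``.
    """

    half_life: float = 10.0               # h; alpha = ln2 / half_life
    theta: float = 0.6
    impulse: tuple[float, float, float] = (2.0, 30.0, 1.0)  # onset,dur,amp
    motif: str = "ffl"
    tf_sign: int = 1                      # +1 activator, -1 repressor
    beta_base: float = 0.0                # basal production (normalized)
    y0: float = 0.0                       # initial TF level (normalized)
    direct_bump_amplitude: float = 1.0
    direct_bump_time: float = 4.0
    direct_bump_width: float = 1.5
    secondary_amplitude: float = 0.6
    grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.linspace(0, 60, 241)))

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; "
                             f"expected one of {MOTIFS}")
        if self.tf_sign not in (-1, 1):
            raise ValueError("tf_sign must be +1 or -1")
        if not np.isfinite(self.impulse).all():
            raise ValueError("impulse values must be finite")

    @property
    def alpha(self) -> float:
        return np.log(2) / self.half_life


@dataclass
class SimTrajectory:
    times: np.ndarray
    impulse: np.ndarray       # normalized drive level
    tf: np.ndarray            # Y(t), normalized
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.tf):
            raise ValueError("length mismatch")


def _piecewise_first_order(times: np.ndarray, alpha: float,
                           breaks: list[tuple[float, float]],
                           y0: float) -> np.ndarray:
    """Solve y' = alpha*(u(t) - y) for piecewise-constant u.

    ``breaks`` is a list of (start_time, u_level) segments covering
    [times[0], inf); returns y at ``times`` exactly (closed form).
    """
    y = np.empty(len(times))
    seg_starts = [b[0] for b in breaks]
    y_start = y0
    for si, (t0, u) in enumerate(breaks):
        t1 = seg_starts[si + 1] if si + 1 < len(breaks) else np.inf
        mask = (times >= t0) & (times < t1)
        y[mask] = u + (y_start - u) * np.exp(-alpha * (times[mask] - t0))
        if np.isfinite(t1):
            y_start = u + (y_start - u) * np.exp(-alpha * (t1 - t0))
    return y


def _drive_segments(params: SimParams) -> list[tuple[float, float]]:
    onset, dur, amp = params.impulse
    total = params.beta_base + amp
    if total > 0:
        u_on, u_off = 1.0, params.beta_base / total
    else:  # pure decay scenario (no drive): stay in raw units
        u_on = u_off = 0.0
    t0 = 0.0
    segs = [(t0, u_off)]
    if dur > 0 and amp > 0:
        segs = [(t0, u_off), (onset, u_on), (onset + dur, u_off)]
    return segs


def simulate_tf(params: SimParams, times=None) -> SimTrajectory:
    """Closed-form normalized TF trajectory under the box impulse."""
    t = np.asarray(params.grid if times is None else times, dtype=float)
    segs = _drive_segments(params)
    y = _piecewise_first_order(t, params.alpha, segs, params.y0)
    onset, dur, amp = params.impulse
    drive = np.where((t >= onset) & (t < onset + dur),
                     1.0 if amp > 0 else 0.0,
                     segs[0][1])
    return SimTrajectory(t, drive, y)


def threshold_crossing_time(params: SimParams) -> float | None:
    """First time Y(t) >= theta, computed analytically.

    For the canonical rise from 0 under constant normalized drive this is
    onset - ln(1 - theta)/alpha.  Returns None if Y never reaches theta.
    """
    alpha, theta = params.alpha, params.theta
    segs = _drive_segments(params)
    y_start, starts = params.y0, [s[0] for s in segs]
    for si, (t0, u) in enumerate(segs):
        t1 = starts[si + 1] if si + 1 < len(segs) else np.inf
        if y_start >= theta:
            return t0
        if u > theta:  # crossing possible within this segment
            tc = t0 - np.log((u - theta) / (u - y_start)) / alpha
            if tc < t1:
                return float(tc)
        if np.isfinite(t1):
            y_start = u + (y_start - u) * np.exp(-alpha * (t1 - t0))
    return None


def _gate_intervals(params: SimParams) -> list[tuple[float, float]]:
    """Time intervals where Y(t) >= theta (at most one for a box drive)."""
    up = threshold_crossing_time(params)
    if up is None:
        return []
    alpha, theta = params.alpha, params.theta
    onset, dur, amp = params.impulse
    segs = _drive_segments(params)
    end = onset + dur if (dur > 0 and amp > 0) else np.inf
    if up >= end:
        return []
    # Y at impulse end, then decay toward u_off until it falls below theta
    y_end = simulate_tf(params, times=np.array([end])).tf[0] \
        if np.isfinite(end) else 1.0
    u_off = segs[0][1]
    if not np.isfinite(end):
        return [(up, np.inf)]
    if y_end <= theta:
        return [(up, end)]
    if u_off >= theta:
        return [(up, np.inf)]
    down = end - np.log((theta - u_off) / (y_end - u_off)) / alpha
    return [(up, float(down))]


def simulate_target(params: SimParams, times=None) -> SimTrajectory:
    """Target trajectory for the selected motif.

    ffl / feedback: direct Gaussian de-repression bump + secondary
    first-order response gated on Y >= theta, signed by tf_sign.
    simple_indirect: secondary response only.
    """
    traj = simulate_tf(params, times)
    t = traj.times
    gates = _gate_intervals(params)
    # secondary response: s' = alpha*(sign*amp*1[gate] - s)
    segs: list[tuple[float, float]] = [(float(t[0]), 0.0)]
    for lo, hi in gates:
        level = params.tf_sign * params.secondary_amplitude
        segs = [s for s in segs if s[0] < lo]
        segs += [(max(lo, float(t[0])), level)]
        if np.isfinite(hi):
            segs += [(hi, 0.0)]
    segs.sort()
    secondary = _piecewise_first_order(t, params.alpha, segs, 0.0)
    target = secondary.copy()
    if params.motif in ("ffl", "feedback"):
        target = target + params.direct_bump_amplitude * np.exp(
            -0.5 * ((t - params.direct_bump_time)
                    / params.direct_bump_width) ** 2)
    return SimTrajectory(t, traj.impulse, traj.tf, target)


def population_simulate(n_ffl: int, n_indirect: int, n_null: int,
                        params: SimParams, noise_sd: float = 0.15,
                        grid=None, rng_seed: int = 0
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Mechanistic population generator on an output time grid.

    ffl genes follow the coherent motif (upward direct + secondary),
    indirect genes the simple-indirect motif with mixed activator /
    repressor TFs, null genes are pure noise.  Per-gene amplitudes carry
    lognormal scale jitter; i.i.d. Gaussian noise is added in log2 space.
    """
    from .synthetic import MICROARRAY_TIME_GRID
    t = np.asarray(MICROARRAY_TIME_GRID if grid is None else grid, float)
    rng = np.random.default_rng(rng_seed)
    rows, ids, labels = [], [], []

    base_ffl = simulate_target(replace(params, motif="ffl", tf_sign=1), t)
    base_act = simulate_target(
        replace(params, motif="simple_indirect", tf_sign=1), t)
    base_rep = simulate_target(
        replace(params, motif="simple_indirect", tf_sign=-1), t)

    for i in range(n_ffl):
        scale = np.exp(rng.normal(0, 0.2))
        rows.append(scale * base_ffl.target)
        ids.append(f"F{i:04d}")
        labels.append("direct")
    for i in range(n_indirect):
        scale = np.exp(rng.normal(0, 0.2))
        base = base_act if rng.random() < 0.5 else base_rep
        rows.append(scale * base.target)
        ids.append(f"S{i:04d}")
        labels.append("indirect")
    for i in range(n_null):
        rows.append(np.zeros(len(t)))
        ids.append(f"Z{i:04d}")
        labels.append("nontarget")

    X = np.asarray(rows) if rows else np.empty((0, len(t)))
    X = X + rng.normal(0, noise_sd, X.shape)
    fc = pd.DataFrame(X, index=pd.Index(ids, name="gene_id"),
                      columns=[f"t{g:g}" for g in t])
    return fc, pd.Series(labels, index=fc.index, name="label")
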