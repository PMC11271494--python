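"""Synthetic dwell-time samples and bead-height traces with ground truth.

Emulates the statistical structure of magnetic-tweezers recordings of
multi-domain dimers so that every analysis stage is testable without
experimental data:

* exponentially distributed, force-dependent dwell times with Bell-model
  rate dependence (optionally right-censored);
* clustered dwell populations whose hidden sub-state persists over blocks
  of cycles with slow interconversion;
* full (time, force, bead-height) traces at 200 Hz with 2-5 nm Gaussian
  noise under constant-force, linear-ramp and force-jump-cycle protocols,
  with every structural transition recorded in a ground-truth sidecar.

Bead heights are emitted relative to the initial-state extension. Force
jumps carry an optional instantaneous offset artifact (bead re-orientation
after a jump) that is *not* listed among the ground-truth events — the
extraction stage is expected to ignore it, mirroring the real analysis
hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constructs import ConstructSpec, TetherState, state_to_series
from .kinetics import (
    OPEN_UNFOLDED,
    PAIRED,
    BellParams,
    ForceProtocol,
    MultivalentDimerModel,
    bell_rate,
    simulate_constant_force,
    simulate_ramp,
)
from .polymer import DEFAULT_ENV, PolymerEnvironment, series_extension
from .traces import Trace

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "generate_dwells",
    "generate_clustered_dwells",
    "generate_trace",
    "generate_hopping_trace",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: Gaussian height sd (nm) and sampling rate (Hz)."""

    height_sd: float = 3.0
    sampling_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.height_sd < 0:
            raise ValueError("height_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


@dataclass
class GroundTruth:
    """True transitions behind a generated trace.

    ``events``: list of dicts with ``time_s``, ``transition``, ``step_nm``,
    ``force_pN``. ``dwells``: per-cycle (force, dwell, censored) for
    jump-cycle traces. ``state_path``: (time, state description) pairs.
    """

    events: list[dict] = field(default_factory=list)
    dwells: list[dict] = field(default_factory=list)
    state_path: list[tuple[float, str]] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "events": self.events,
            "dwells": self.dwells,
            "state_path": self.state_path,
            "seed": self.seed,
        }


def generate_dwells(
    params: BellParams,
    force: float,
    n: int,
    censor_at: float | None = None,
    rng_seed: int | np.random.Generator = 0,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> pd.DataFrame:
    """I.i.d. exponential dwell times at the Bell rate for ``force``.

    Returns a table with columns ``force_pN``, ``dwell_s``, ``censored``;
    dwells beyond ``censor_at`` are truncated there and flagged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    rate = bell_rate(params, force, env)
    if rate <= 0:
        if censor_at is None:
            raise ValueError("zero rupture rate and no censoring horizon")
        t = np.full(n, float(censor_at))
        censored = np.ones(n, dtype=bool)
    else:
        t = rng.exponential(1.0 / rate, size=n)
        censored = np.zeros(n, dtype=bool)
        if censor_at is not None:
            censored = t >= censor_at
            t = np.minimum(t, censor_at)
    return pd.DataFrame(
        {"force_pN": force, "dwell_s": t, "censored": censored}
    )


def generate_clustered_dwells(
    substates: Sequence[tuple[BellParams, float]],
    switch_prob: float,
    force: float,
    n: int,
    censor_at: float | None = None,
    rng_seed: int | np.random.Generator = 0,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> pd.DataFrame:
    """Dwell times from slowly interconverting hidden sub-states.

    The active sub-state persists from cycle to cycle; after each cycle it
    is redrawn from the weights with probability ``switch_prob`` (blocks of
    correlated cycles, as seen in clustered lifetime measurements). Output
    adds a hidden ``substate`` label column.
    """
    weights = np.array([w for _, w in substates], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("sub-state weights must sum to 1")
    if not (0.0 <= switch_prob <= 1.0):
        raise ValueError("switch_prob must be in [0, 1]")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    rates = [bell_rate(p, force, env) for p, _ in substates]
    state = int(rng.choice(len(substates), p=weights))
    rows = []
    for _ in range(n):
        rate = rates[state]
        t = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        censored = censor_at is not None and t >= censor_at
        if censored:
            t = censor_at
        elif not np.isfinite(t):
            raise ValueError("zero rate in a sub-state requires a censoring horizon")
        rows.append(
            {"force_pN": force, "dwell_s": float(t), "censored": censored, "substate": state}
        )
        if rng.random() < switch_prob:
            state = int(rng.choice(len(substates), p=weights))
    return pd.DataFrame(rows, columns=["force_pN", "dwell_s", "censored", "substate"])


# ---------------------------------------------------------------------------
# Trace generation
# ---------------------------------------------------------------------------


def _kinetic_to_tether(state: tuple[int, ...]) -> TetherState:
    dimerized = any(s == PAIRED for s in state)
    n_open = sum(1 for s in state if s != PAIRED)
    n_unfolded = sum(1 for s in state if s == OPEN_UNFOLDED)
    if dimerized:
        return TetherState(dimerized=True, open_pairs=n_open, unfolded=n_unfolded)
    return TetherState(dimerized=False, unfolded=n_unfolded)


def _apply_label(state: list[int], label: str) -> None:
    kind, idx = label.split(":")
    i = int(idx)
    state[i] = {
        "unpair": 1,
        "repair": 0,
        "unfold": 2,
        "refold": 1,
    }[kind]


def _series_heights(
    construct: ConstructSpec,
    state: TetherState,
    forces: np.ndarray,
    env: PolymerEnvironment,
) -> np.ndarray:
    """Extension of a tether state over a force array (interpolated)."""
    series = state_to_series(construct, state)
    fmin, fmax = float(forces.min()), float(forces.max())
    if np.isclose(fmin, fmax):
        return np.full(forces.shape, series_extension(max(fmin, 1e-6), series, env))
    grid = np.linspace(fmin, fmax, 64)
    vals = np.array([series_extension(max(f, 1e-6), series, env) for f in grid])
    return np.interp(forces, grid, vals)


def _state_extension(construct, state, force, env):
    return series_extension(
        max(force, 1e-6), state_to_series(construct, state), env
    )


def generate_trace(
    construct: ConstructSpec,
    protocol: ForceProtocol,
    noise: NoiseModel = NoiseModel(),
    model: MultivalentDimerModel | None = None,
    script: Sequence[tuple[float, TetherState]] | None = None,
    rng_seed: int = 0,
    jump_artifact_nm: float = 5.0,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> tuple[Trace, GroundTruth]:
    """Generate a bead-height trace plus ground truth.

    The structural state path comes either from the stochastic multivalent
    model (``model``) or from an explicit schedule (``script``: a list of
    (time, state) pairs, state holding from that time onward). Heights are
    the series extension of the current state at the instantaneous force,
    relative to the initial state, plus Gaussian noise.
    """
    if (model is None) == (script is None):
        raise ValueError("provide exactly one of `model` or `script`")
    if model is not None and model.n_pairs > construct.n_pairs:
        raise ValueError(
            f"model has {model.n_pairs} pairs but construct has only "
            f"{construct.n_pairs}; a smaller model treats the interface as "
            "fewer effective bonds"
        )
    rng = np.random.default_rng(rng_seed)
    truth = GroundTruth(seed=rng_seed)

    if protocol.kind == "jump_cycle":
        if script is not None:
            raise ValueError("jump_cycle generation requires a kinetic model")
        return _generate_jump_cycles(
            construct, protocol, noise, model, rng, jump_artifact_nm, truth, env
        )

    # --- constant / ramp: one continuous segment ------------------------
    dt = 1.0 / noise.sampling_rate
    if protocol.kind == "constant":
        duration = protocol.duration_s
        if duration is None:
            raise ValueError("constant-protocol traces need duration_s")
        time = np.arange(0.0, duration, dt)
        force = np.full(time.shape, float(protocol.force))
    else:  # ramp
        duration = (protocol.f_end - protocol.f_start) / protocol.loading_rate
        time = np.arange(0.0, duration, dt)
        force = protocol.f_start + protocol.loading_rate * time

    # Build the (time, state) schedule.
    if script is not None:
        schedule = sorted(script, key=lambda p: p[0])
        if not schedule or schedule[0][0] > 0.0:
            schedule = [(0.0, TetherState(dimerized=True))] + list(schedule)
    else:
        schedule = _simulate_schedule(model, protocol, rng, env)

    height = np.empty_like(time)
    baseline = _state_extension(construct, schedule[0][1], float(force[0]), env)
    change_times = [t for t, _ in schedule[1:]] + [np.inf]
    start_idx = 0
    for (t0, state), t1 in zip(schedule, change_times):
        end_idx = int(np.searchsorted(time, t1))
        if end_idx <= start_idx:
            continue
        sl = slice(start_idx, end_idx)
        height[sl] = _series_heights(construct, state, force[sl], env) - baseline
        start_idx = end_idx
    if start_idx < len(time):  # schedule exhausted before trace end
        height[start_idx:] = height[start_idx - 1] if start_idx else 0.0

    for (t0, s0), (t1, s1) in zip(schedule, schedule[1:]):
        if t1 >= time[-1]:
            continue
        f_at = float(np.interp(t1, time, force))
        step = _state_extension(construct, s1, f_at, env) - _state_extension(
            construct, s0, f_at, env
        )
        truth.events.append(
            {
                "time_s": float(t1),
                "transition": f"{s0.describe()}->{s1.describe()}",
                "step_nm": float(step),
                "force_pN": f_at,
            }
        )
    truth.state_path = [(float(t), s.describe()) for t, s in schedule]

    if noise.height_sd > 0:
        height = height + rng.normal(0.0, noise.height_sd, size=height.shape)
    trace = Trace(
        time=time,
        force=force,
        height=height,
        sampling_rate=noise.sampling_rate,
        metadata={"protocol": protocol.kind, "construct": construct.name, "seed": rng_seed},
    )
    return trace, truth


def _simulate_schedule(model, protocol, rng, env):
    """(time, TetherState) schedule from the stochastic model."""
    initial = (PAIRED,) * model.n_pairs
    if protocol.kind == "constant":
        res = simulate_constant_force(
            model,
            protocol.force,
            n_runs=1,
            rng_seed=rng,
            max_time=protocol.duration_s or np.inf,
            record_events=True,
        )
    else:
        res = simulate_ramp(model, protocol, n_runs=1, rng_seed=rng, record_events=True)
    schedule = [(0.0, _kinetic_to_tether(initial))]
    state = list(initial)
    for t, label in res.events[0]:
        _apply_label(state, label)
        schedule.append((float(t), _kinetic_to_tether(tuple(state))))
    return schedule


def _generate_jump_cycles(
    construct, protocol, noise, model, rng, jump_artifact_nm, truth, env
):
    dt = 1.0 / noise.sampling_rate
    post_s = 0.5  # brief post-rupture tail kept in each cycle
    times, forces, heights = [], [], []
    hold_phases = []
    t_global = 0.0
    folded = TetherState(dimerized=True)
    f_high = float(protocol.high_force)
    baseline = _state_extension(construct, folded, protocol.low_force, env)

    for cycle in range(protocol.n_cycles):
        # Low-force phase: fully re-dimerized and refolded (re-formation
        # kinetics at low force are not resolved in this protocol mode).
        n_low = max(int(round(protocol.low_duration_s / dt)), 1)
        t_low = t_global + dt * np.arange(n_low)
        times.append(t_low)
        forces.append(np.full(n_low, float(protocol.low_force)))
        heights.append(
            np.full(n_low, _state_extension(construct, folded, protocol.low_force, env) - baseline)
        )
        t_global = t_low[-1] + dt

        # High-force hold until rupture or censoring.
        res = simulate_constant_force(
            model, f_high, n_runs=1, rng_seed=rng,
            max_time=protocol.max_hold_s, record_events=True,
        )
        ruptured = not bool(res.censored[0])
        dwell = float(res.times[0])
        hold_start = t_global
        hold_len = (dwell if ruptured else protocol.max_hold_s) + (post_s if ruptured else 0.0)
        n_hold = max(int(round(hold_len / dt)), 2)
        t_hold = t_global + dt * np.arange(n_hold)
        h_hold = np.empty(n_hold)
        state = [PAIRED] * model.n_pairs
        seg_start = 0
        prev_t = 0.0
        prev_state = _kinetic_to_tether(tuple(state))
        events = list(res.events[0]) if res.events else []
        for t_ev, label in events:
            idx = int(np.searchsorted(t_hold - hold_start, t_ev))
            h_hold[seg_start:idx] = _state_extension(construct, prev_state, f_high, env) - baseline
            _apply_label(state, label)
            new_state = _kinetic_to_tether(tuple(state))
            step = _state_extension(construct, new_state, f_high, env) - _state_extension(
                construct, prev_state, f_high, env
            )
            truth.events.append(
                {
                    "time_s": float(hold_start + t_ev),
                    "transition": f"{prev_state.describe()}->{new_state.describe()}",
                    "step_nm": float(step),
                    "force_pN": f_high,
                    "cycle": cycle,
                }
            )
            prev_state = new_state
            seg_start = idx
        h_hold[seg_start:] = _state_extension(construct, prev_state, f_high, env) - baseline
        # Bead re-orientation offset after the jump (not a true event).
        h_hold += jump_artifact_nm
        times.append(t_hold)
        forces.append(np.full(n_hold, f_high))
        heights.append(h_hold)
        hold_phases.append(
            {
                "start_s": float(hold_start),
                "end_s": float(hold_start + (dwell if ruptured else protocol.max_hold_s) + (post_s if ruptured else 0.0)),
                "force_pN": f_high,
            }
        )
        truth.dwells.append(
            {
                "cycle": cycle,
                "force_pN": f_high,
                "dwell_s": dwell if ruptured else protocol.max_hold_s,
                "censored": not ruptured,
            }
        )
        t_global = t_hold[-1] + dt

    time = np.concatenate(times)
    force = np.concatenate(forces)
    height = np.concatenate(heights)
    if noise.height_sd > 0:
        height = height + rng.normal(0.0, noise.height_sd, size=height.shape)
    trace = Trace(
        time=time,
        force=force,
        height=height,
        sampling_rate=noise.sampling_rate,
        metadata={
            "protocol": "jump_cycle",
            "construct": construct.name,
            "hold_phases": hold_phases,
        },
    )
    return trace, truth


def generate_hopping_trace(
    construct: ConstructSpec,
    force: float,
    open_rate: float,
    close_rate: float,
    duration_s: float,
    noise: NoiseModel = NoiseModel(height_sd=2.0),
    rng_seed: int = 0,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> tuple[Trace, GroundTruth]:
    """Two-level hopping trace: reversible rupture/re-dimerization at low force.

    A telegraph process between the dimerized and ruptured (folded) states
    with the given opening/closing rates, suitable for two-state HMM
    fitting. Occupancy of the open level converges to
    ``open_rate / (open_rate + close_rate)``.
    """
    if open_rate <= 0 or close_rate <= 0:
        raise ValueError("hopping requires positive open and close rates")
    rng = np.random.default_rng(rng_seed)
    dt = 1.0 / noise.sampling_rate
    time = np.arange(0.0, duration_s, dt)
    low = _state_extension(construct, TetherState(dimerized=True), force, env)
    high = _state_extension(construct, TetherState(dimerized=False), force, env)
    truth = GroundTruth(seed=rng_seed)
    height = np.empty_like(time)
    t, state = 0.0, 0  # 0 = dimerized, 1 = open
    idx = 0
    while idx < len(time):
        rate = open_rate if state == 0 else close_rate
        t_next = t + rng.exponential(1.0 / rate)
        end = int(np.searchsorted(time, t_next))
        height[idx:end] = 0.0 if state == 0 else high - low
        if end < len(time):
            truth.events.append(
                {
                    "time_s": float(t_next),
                    "transition": "rupture" if state == 0 else "re-dimerize",
                    "step_nm": float((high - low) * (1 if state == 0 else -1)),
                    "force_pN": force,
                }
            )
        state, t, idx = 1 - state, t_next, end
    if noise.height_sd > 0:
        height = height + rng.normal(0.0, noise.height_sd, size=height.shape)
    trace = Trace(
        time=time,
        force=np.full(time.shape, force),
        height=height,
        sampling_rate=noise.sampling_rate,
        metadata={"protocol": "constant", "construct": construct.name, "hopping": True},
    )
    return trace, truth
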