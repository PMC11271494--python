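"""Bell slip-bond rates and multivalent dimer rupture kinetics.

The mechanical lifetime of a multi-domain dimer is modelled as a
continuous-time Markov chain over the pairing/folding states of its domain
pairs. Each pair is in one of three states: paired, un-paired with the
force-bearing domain folded, or un-paired with that domain unfolded. Rules:

* only boundary pairs may un-pair — a pair is at the boundary when it is
  terminal or every pair between it and one force-bearing terminus is
  already un-paired (dissociation unzips inward from the loaded ends);
* an un-paired, still-folded domain adjacent to the intact block may
  re-pair (the partners are held in proximity by the remaining pairs);
* any un-paired force-bearing domain may unfold, and unfolded domains may
  refold, but an unfolded domain cannot re-pair;
* full rupture (every pair un-paired) is absorbing.

All rates follow the Bell model ``k(f) = k0 * exp(delta * f / kBT)``:
positive ``delta`` for force-accelerated transitions (un-pairing,
unfolding), non-positive ``delta`` for force-suppressed ones (re-pairing,
refolding).

The module provides the exact mean first-passage time of the chain (linear
solve), a Gillespie simulator at constant force, and a time-stepped
stochastic simulator for linear force ramps, together with the
Evans-Ritchie closed form for the modal rupture force of a single bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .polymer import DEFAULT_ENV, PolymerEnvironment

__all__ = [
    "BellParams",
    "PairKinetics",
    "DomainKinetics",
    "MultivalentDimerModel",
    "ForceProtocol",
    "SimulationResult",
    "bell_rate",
    "enumerate_states",
    "mean_lifetime_exact",
    "simulate_constant_force",
    "simulate_ramp",
    "lifetime_vs_pairs",
    "evans_ritchie_modal_force",
    "modal_rupture_force",
    "single_bond_model",
]

# Numerical guards: cap the Bell exponent, and treat rates beyond this as
# effectively instantaneous.
_EXP_CAP = 700.0
_RATE_CAP = 1e12

PAIRED, OPEN_FOLDED, OPEN_UNFOLDED = 0, 1, 2


@dataclass(frozen=True)
class BellParams:
    """Zero-force rate ``k0`` (1/s) and transition distance ``delta`` (nm).

    ``delta > 0``: the force tilts the barrier down (slip bond);
    ``delta < 0``: the transition is suppressed by force (re-pairing,
    refolding).
    """

    k0: float
    delta: float

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ValueError(f"BellParams.k0 must be >= 0, got {self.k0}")


def bell_rate(
    params: BellParams, force: float, env: PolymerEnvironment = DEFAULT_ENV
) -> float:
    """Force-dependent rate ``k0 * exp(delta * f / kBT)`` in 1/s."""
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    if params.k0 == 0.0:
        return 0.0
    exponent = min(params.delta * force / env.kBT, _EXP_CAP)
    return min(params.k0 * math.exp(exponent), _RATE_CAP)


@dataclass(frozen=True)
class PairKinetics:
    """Un-pairing / re-pairing kinetics of one domain pair."""

    unpair: BellParams
    repair: BellParams

    def __post_init__(self) -> None:
        if self.repair.delta > 0:
            raise ValueError("re-pairing must not be force-accelerated (delta <= 0)")


@dataclass(frozen=True)
class DomainKinetics:
    """Unfolding / refolding kinetics of one force-bearing domain."""

    unfold: BellParams
    refold: BellParams

    def __post_init__(self) -> None:
        if self.refold.delta > 0:
            raise ValueError("refolding must not be force-accelerated (delta <= 0)")


@dataclass(frozen=True)
class MultivalentDimerModel:
    """A dimer held by ``n_pairs`` domain pairs with boundary-only kinetics.

    ``pairs`` and ``domains`` may be a single kinetics object (shared by all
    pairs) or one per pair. ``domains=None`` disables the unfolding branch
    entirely (pure pairing/un-pairing chain).
    """

    n_pairs: int
    pairs: PairKinetics | tuple[PairKinetics, ...]
    domains: DomainKinetics | tuple[DomainKinetics, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for name in ("pairs", "domains"):
            val = getattr(self, name)
            if isinstance(val, tuple) and len(val) != self.n_pairs:
                raise ValueError(f"{name} must have one entry per pair")

    def pair_kinetics(self, i: int) -> PairKinetics:
        return self.pairs[i] if isinstance(self.pairs, tuple) else self.pairs

    def domain_kinetics(self, i: int) -> DomainKinetics | None:
        if self.domains is None:
            return None
        return self.domains[i] if isinstance(self.domains, tuple) else self.domains


def single_bond_model(params: BellParams) -> MultivalentDimerModel:
    """A one-pair, irreversible model: a single Bell slip bond."""
    return MultivalentDimerModel(
        n_pairs=1,
        pairs=PairKinetics(unpair=params, repair=BellParams(0.0, 0.0)),
    )


@dataclass(frozen=True)
class ForceProtocol:
    """Force schedule applied to the tether.

    kind="constant": hold ``force`` (optionally for ``duration_s``).
    kind="ramp": linear sweep from ``f_start`` to ``f_end`` at
    ``loading_rate`` pN/s (the experimentally used regime is within
    +-10 pN/s).
    kind="jump_cycle": repeat ``n_cycles`` of [hold ``low_force`` for
    ``low_duration_s``, jump instantaneously to ``high_force``, hold until
    rupture or ``max_hold_s``].
    """

    kind: str
    force: float | None = None
    duration_s: float | None = None
    f_start: float = 0.0
    f_end: float = 0.0
    loading_rate: float = 0.0
    low_force: float = 1.0
    low_duration_s: float = 2.0
    high_force: float | None = None
    max_hold_s: float = 300.0
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "ramp", "jump_cycle"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "constant" and (self.force is None or self.force < 0):
            raise ValueError("constant protocol needs a non-negative force")
        if self.kind == "ramp":
            if self.loading_rate == 0.0:
                raise ValueError("ramp protocol needs a non-zero loading_rate")
            if abs(self.loading_rate) > 10.0:
                raise ValueError(
                    "loading_rate outside the +-10 pN/s regime the model covers"
                )
            if (self.f_end - self.f_start) * self.loading_rate <= 0:
                raise ValueError("ramp direction must match the loading rate sign")
        if self.kind == "jump_cycle":
            if self.high_force is None or self.high_force <= 0:
                raise ValueError("jump_cycle protocol needs a positive high_force")
            if self.n_cycles < 1 or self.max_hold_s <= 0 or self.low_duration_s <= 0:
                raise ValueError("jump_cycle timing parameters must be positive")


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------


def _is_absorbing(state: tuple[int, ...]) -> bool:
    return all(s != PAIRED for s in state)


def _transitions(
    model: MultivalentDimerModel,
    state: tuple[int, ...],
    force: float,
    env: PolymerEnvironment,
) -> list[tuple[float, tuple[int, ...], str]]:
    """Outgoing (rate, next_state, label) channels of a state."""
    if _is_absorbing(state):
        return []
    intact = [i for i, s in enumerate(state) if s == PAIRED]
    lo, hi = min(intact), max(intact)
    out: list[tuple[float, tuple[int, ...], str]] = []

    def moved(i: int, new: int) -> tuple[int, ...]:
        lst = list(state)
        lst[i] = new
        return tuple(lst)

    for i in intact:
        if i == lo or i == hi:  # boundary pairs only
            r = bell_rate(model.pair_kinetics(i).unpair, force, env)
            if r > 0:
                out.append((r, moved(i, OPEN_FOLDED), f"unpair:{i}"))
    for i, s in enumerate(state):
        if s == OPEN_FOLDED:
            if i == lo - 1 or i == hi + 1:  # adjacent to the intact block
                r = bell_rate(model.pair_kinetics(i).repair, force, env)
                if r > 0:
                    out.append((r, moved(i, PAIRED), f"repair:{i}"))
            dk = model.domain_kinetics(i)
            if dk is not None:
                r = bell_rate(dk.unfold, force, env)
                if r > 0:
                    out.append((r, moved(i, OPEN_UNFOLDED), f"unfold:{i}"))
        elif s == OPEN_UNFOLDED:
            dk = model.domain_kinetics(i)
            if dk is not None:
                r = bell_rate(dk.refold, force, env)
                if r > 0:
                    out.append((r, moved(i, OPEN_FOLDED), f"refold:{i}"))
    return out


def enumerate_states(
    model: MultivalentDimerModel,
    force: float,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> tuple[list[tuple[int, ...]], dict[tuple[int, ...], list[tuple[float, tuple[int, ...], str]]]]:
    """Breadth-first enumeration of states reachable from fully paired.

    Returns the ordered state list (initial state first) and the per-state
    transition channels at the given force.
    """
    initial = (PAIRED,) * model.n_pairs
    order = [initial]
    seen = {initial}
    channels: dict[tuple[int, ...], list[tuple[float, tuple[int, ...], str]]] = {}
    queue = [initial]
    while queue:
        s = queue.pop(0)
        outs = _transitions(model, s, force, env)
        channels[s] = outs
        for _, nxt, _ in outs:
            if nxt not in seen:
                seen.add(nxt)
                order.append(nxt)
                queue.append(nxt)
    return order, channels


def mean_lifetime_exact(
    model: MultivalentDimerModel,
    force: float,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> float:
    """Mean first-passage time (s) from fully paired to full rupture.

    Solves the linear system of the continuous-time Markov chain over the
    reachable transient states: ``sum_j q_ij (t_j - t_i) = -1`` with
    ``t = 0`` on absorbing states.
    """
    order, channels = enumerate_states(model, force, env)
    transient = [s for s in order if not _is_absorbing(s)]
    if not any(_is_absorbing(s) for s in order):
        raise ValueError(
            "rupture is unreachable from the fully paired state at this force"
        )
    index = {s: i for i, s in enumerate(transient)}
    n = len(transient)
    A = np.zeros((n, n))
    b = np.ones(n)
    for s in transient:
        i = index[s]
        total = 0.0
        for rate, nxt, _ in channels[s]:
            total += rate
            if nxt in index:
                A[i, index[nxt]] -= rate
        if total == 0.0:
            raise ValueError(f"state {s} has no outgoing transitions (dead end)")
        A[i, i] += total
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular first-passage system: {exc}") from exc
    return float(t[index[(PAIRED,) * model.n_pairs]])


# ---------------------------------------------------------------------------
# Stochastic simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Rupture times/forces of a batch of stochastic trajectories.

    ``censored`` flags runs that did not rupture within the allowed time
    (including runs stuck in a state with all rates zero).
    """

    times: np.ndarray
    censored: np.ndarray
    events: list[list[tuple[float, str]]] | None = None
    forces: np.ndarray | None = None
    seed: int | None = None

    @property
    def rupture_times(self) -> np.ndarray:
        return self.times[~self.censored]

    @property
    def rupture_forces(self) -> np.ndarray:
        if self.forces is None:
            raise ValueError("no force record: not a ramp simulation")
        return self.forces[~self.censored]


def _as_rng(rng_seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def simulate_constant_force(
    model: MultivalentDimerModel,
    force: float,
    n_runs: int,
    rng_seed: int | np.random.Generator = 0,
    max_time: float = np.inf,
    record_events: bool = False,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> SimulationResult:
    """Gillespie trajectories of the dimer at constant force.

    Each run starts fully paired and ends at full rupture or at
    ``max_time`` (censored). With ``record_events`` the full event sequence
    (time, channel label) of every run is kept.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = _as_rng(rng_seed)
    order, channels = enumerate_states(model, force, env)
    # Precompute per-state sampling tables.
    table: dict[tuple[int, ...], tuple[float, np.ndarray, list, list]] = {}
    for s in order:
        outs = channels.get(s, [])
        rates = np.array([r for r, _, _ in outs])
        total = float(rates.sum())
        cum = np.cumsum(rates) / total if total > 0 else np.array([])
        table[s] = (total, cum, [nxt for _, nxt, _ in outs], [lab for _, _, lab in outs])

    initial = (PAIRED,) * model.n_pairs
    times = np.empty(n_runs)
    censored = np.zeros(n_runs, dtype=bool)
    all_events: list[list[tuple[float, str]]] | None = [] if record_events else None
    for run in range(n_runs):
        t = 0.0
        state = initial
        ev: list[tuple[float, str]] = []
        while not _is_absorbing(state):
            total, cum, nexts, labels = table[state]
            if total == 0.0:
                censored[run] = True
                t = max_time if np.isfinite(max_time) else t
                break
            t += rng.exponential(1.0 / total)
            if t >= max_time:
                censored[run] = True
                t = max_time
                break
            j = int(np.searchsorted(cum, rng.random()))
            if record_events:
                ev.append((t, labels[j]))
            state = nexts[j]
        times[run] = t
        if record_events:
            all_events.append(ev)
    return SimulationResult(times=times, censored=censored, events=all_events)


def simulate_ramp(
    model: MultivalentDimerModel | BellParams,
    protocol: ForceProtocol,
    n_runs: int,
    rng_seed: int | np.random.Generator = 0,
    record_events: bool = False,
    force_step: float = 0.01,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> SimulationResult:
    """Stochastic rupture under a linear force ramp.

    The ramp is discretized into force steps of at most ``force_step`` pN
    (rates held constant within a step); each run steps through the grid
    and fires transitions with probability ``1 - exp(-R dt)`` per step.
    Runs that survive to ``f_end`` are censored. Returns per-run rupture
    forces (and times).
    """
    if protocol.kind != "ramp":
        raise ValueError("simulate_ramp needs a protocol of kind 'ramp'")
    if protocol.loading_rate <= 0:
        raise ValueError("rupture ramps require a positive loading rate")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if isinstance(model, BellParams):
        model = single_bond_model(model)
    rng = _as_rng(rng_seed)

    r = protocol.loading_rate
    n_steps = int(math.ceil((protocol.f_end - protocol.f_start) / force_step))
    fgrid = protocol.f_start + force_step * (np.arange(n_steps) + 0.5)
    dt = force_step / r

    # Enumerate the topology once (rates are refreshed per force step).
    order, _ = enumerate_states(model, max(protocol.f_end, 1.0), env)
    state_index = {s: i for i, s in enumerate(order)}
    n_states = len(order)
    absorbing = np.array([_is_absorbing(s) for s in order])

    # Per-state channel structure (targets fixed; rates force-dependent).
    chan_params: list[list[tuple[BellParams, int, str]]] = [[] for _ in order]
    for s in order:
        if _is_absorbing(s):
            continue
        intact = [i for i, st in enumerate(s) if st == PAIRED]
        lo, hi = min(intact), max(intact)
        for i in intact:
            if i in (lo, hi) and model.pair_kinetics(i).unpair.k0 > 0:
                nxt = list(s)
                nxt[i] = OPEN_FOLDED
                chan_params[state_index[s]].append(
                    (model.pair_kinetics(i).unpair, state_index[tuple(nxt)], f"unpair:{i}")
                )
        for i, st in enumerate(s):
            if st == OPEN_FOLDED:
                if (i == lo - 1 or i == hi + 1) and model.pair_kinetics(i).repair.k0 > 0:
                    nxt = list(s)
                    nxt[i] = PAIRED
                    chan_params[state_index[s]].append(
                        (model.pair_kinetics(i).repair, state_index[tuple(nxt)], f"repair:{i}")
                    )
                dk = model.domain_kinetics(i)
                if dk is not None and dk.unfold.k0 > 0:
                    nxt = list(s)
                    nxt[i] = OPEN_UNFOLDED
                    chan_params[state_index[s]].append(
                        (dk.unfold, state_index[tuple(nxt)], f"unfold:{i}")
                    )
            elif st == OPEN_UNFOLDED:
                dk = model.domain_kinetics(i)
                if dk is not None and dk.refold.k0 > 0:
                    nxt = list(s)
                    nxt[i] = OPEN_FOLDED
                    chan_params[state_index[s]].append(
                        (dk.refold, state_index[tuple(nxt)], f"refold:{i}")
                    )

    # Total-rate table: n_states x n_steps.
    total_rate = np.zeros((n_states, n_steps))
    for si, chans in enumerate(chan_params):
        for params, _, _ in chans:
            expo = np.minimum(params.delta * fgrid / env.kBT, _EXP_CAP)
            total_rate[si] += np.minimum(params.k0 * np.exp(expo), _RATE_CAP)

    state = np.zeros(n_runs, dtype=np.intp)  # index of the fully paired state
    assert order[0] == (PAIRED,) * model.n_pairs
    alive = np.ones(n_runs, dtype=bool)
    rupture_force = np.full(n_runs, np.nan)
    rupture_time = np.full(n_runs, np.nan)
    all_events: list[list[tuple[float, str]]] | None = (
        [[] for _ in range(n_runs)] if record_events else None
    )
    for step in range(n_steps):
        if not alive.any():
            break
        f = fgrid[step]
        t = (step + 0.5) * dt
        idx = np.flatnonzero(alive)
        R = total_rate[state[idx], step]
        fire = rng.random(idx.size) < -np.expm1(-R * dt)
        for run in idx[fire]:
            chans = chan_params[state[run]]
            rates = np.array([bell_rate(p, f, env) for p, _, _ in chans])
            tot = rates.sum()
            if tot <= 0:
                continue
            j = int(np.searchsorted(np.cumsum(rates) / tot, rng.random()))
            _, target, label = chans[j]
            if record_events:
                all_events[run].append((t, label))
            state[run] = target
            if absorbing[target]:
                alive[run] = False
                rupture_force[run] = f
                rupture_time[run] = t
    return SimulationResult(
        times=rupture_time,
        censored=alive.copy(),
        events=all_events,
        forces=rupture_force,
    )


def evans_ritchie_modal_force(
    params: BellParams,
    loading_rate: float,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> float:
    """Most probable rupture force of a single Bell bond under a ramp.

    ``F* = (kBT / delta) * ln(r * delta / (k0 * kBT))`` — the mode of the
    inhomogeneous-Poisson rupture-force distribution.
    """
    if params.delta <= 0 or params.k0 <= 0 or loading_rate <= 0:
        raise ValueError("modal force requires k0 > 0, delta > 0, rate > 0")
    return (
        env.kBT
        / params.delta
        * math.log(loading_rate * params.delta / (params.k0 * env.kBT))
    )


def modal_rupture_force(forces: np.ndarray, grid_points: int = 512) -> float:
    """Mode of an empirical rupture-force sample via a Gaussian KDE."""
    forces = np.asarray(forces, dtype=float)
    forces = forces[np.isfinite(forces)]
    if forces.size < 10:
        raise ValueError("need at least 10 rupture forces for a modal estimate")
    kde = gaussian_kde(forces)
    grid = np.linspace(forces.min(), forces.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def lifetime_vs_pairs(
    pair_kinetics: PairKinetics,
    forces: Sequence[float],
    n_values: Sequence[int] = (1, 2, 3, 4),
    domain_kinetics: DomainKinetics | None = None,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> pd.DataFrame:
    """Exact mean lifetime as a function of pair count on a force grid.

    All pairs share the given kinetics; returns a tidy table with columns
    ``n_pairs``, ``force_pN`` and ``lifetime_s``.
    """
    rows = []
    for n in n_values:
        model = MultivalentDimerModel(
            n_pairs=n, pairs=pair_kinetics, domains=domain_kinetics
        )
        for f in forces:
            rows.append(
                {
                    "n_pairs": n,
                    "force_pN": f,
                    "lifetime_s": mean_lifetime_exact(model, f, env),
                }
            )
    return pd.DataFrame(rows, columns=["n_pairs", "force_pN", "lifetime_s"])
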