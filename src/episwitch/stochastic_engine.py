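"""Exact stochastic simulation of continuous-time Markov reaction systems.

Implements the direct (cumulative-propensity inversion) Gillespie method
with support for deterministically scheduled events such as DNA
replication: the pending exponential waiting time is truncated at the next
event boundary and redrawn afterwards, which is exact by memorylessness of
the exponential distribution.

Also provides an exact mean-first-passage-time (MFPT) solver for systems
with enumerable state spaces and no scheduled events, used as an
independent oracle for the Monte-Carlo engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class PropensityError(RuntimeError):
    """A negative propensity was encountered at a visited state."""


class StateSpaceError(RuntimeError):
    """Exact enumeration is not feasible (cap exceeded or absorbing unreachable)."""


@dataclass(frozen=True)
class ScheduledEvent:
    """A deterministic event applied at exact multiples of ``period``.

    ``transform(state, rng) -> new state`` may use its own randomness
    (e.g. binomial dilution of methyl marks at DNA replication).
    """

    period: float  # hours
    transform: Callable[[np.ndarray, np.random.Generator], np.ndarray]
    label: str = "scheduled"

    def __post_init__(self):
        if not (self.period > 0):
            raise ValueError("scheduled event period must be positive")


@dataclass
class ReactionSystem:
    """A continuous-time Markov reaction system with optional scheduled events.

    Parameters
    ----------
    species_labels
        Name per state-vector component.
    propensities
        ``state -> per-reaction rates (1/h)``, one entry per reaction.
    stoichiometry
        Integer array ``(n_reactions, n_species)`` of state increments.
    scheduled_events
        Deterministically timed transformations (DNA replication).
    absorbing
        ``state -> bool``; once True ("gene active") no further reactions
        fire and the simulation stops.
    reaction_labels
        Optional human-readable reaction names (error messages, event logs).
    methyl_count
        Optional observable ``state -> methylated-nucleosome count`` used by
        steady-state methylation estimators; ``n_nucleosomes`` is the
        normalizing total.
    """

    species_labels: list[str]
    propensities: Callable[[np.ndarray], np.ndarray]
    stoichiometry: np.ndarray
    scheduled_events: list[ScheduledEvent] = field(default_factory=list)
    absorbing: Callable[[np.ndarray], bool] = lambda s: False
    reaction_labels: Optional[list[str]] = None
    methyl_count: Optional[Callable[[np.ndarray], float]] = None
    n_nucleosomes: Optional[int] = None
    # optional compiled acceleration; same dynamics as the generic engine,
    # checked against it (and the exact MFPT solver) in the test suite
    fast_first_passage: Optional[Callable[[np.ndarray, float, int], tuple[float, bool]]] = None
    fast_steady_methylation: Optional[
        Callable[[np.ndarray, float, float, int], tuple[float, bool]]
    ] = None

    def __post_init__(self):
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=np.int64)
        if self.stoichiometry.ndim != 2:
            raise ValueError("stoichiometry must be 2-D (n_reactions, n_species)")
        if self.stoichiometry.shape[1] != len(self.species_labels):
            raise ValueError("stoichiometry width must match species count")
        if self.reaction_labels is not None and len(self.reaction_labels) != self.stoichiometry.shape[0]:
            raise ValueError("reaction_labels length must match reaction count")

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[0]

    def _reaction_name(self, j: int) -> str:
        if self.reaction_labels is not None:
            return self.reaction_labels[j]
        return f"reaction[{j}]"

    def checked_propensities(self, state: np.ndarray) -> np.ndarray:
        """Evaluate propensities, raising a named error on any negative rate."""
        a = np.asarray(self.propensities(state), dtype=float)
        if a.shape != (self.n_reactions,):
            raise ValueError(
                f"propensity function returned shape {a.shape}, "
                f"expected ({self.n_reactions},)"
            )
        if np.any(a < 0):
            j = int(np.argmin(a))
            raise PropensityError(
                f"negative propensity {a[j]:g} for {self._reaction_name(j)} "
                f"at state {state.tolist()}"
            )
        return a


@dataclass
class Trajectory:
    """One simulated path: piecewise-constant states between events.

    ``times[0] == 0``; consecutive states differ by exactly one
    stoichiometry vector or one scheduled-event outcome. Bit-for-bit
    reproducible from ``(system, init, seed)``.
    """

    times: np.ndarray  # hours, strictly increasing from 0
    states: np.ndarray  # (n_points, n_species)
    event_log: list[tuple[float, str]]  # (time, reaction-or-event label)
    seed: int
    absorbed: bool = False

    def time_average(self, observable: Callable[[np.ndarray], float],
                     t_start: float = 0.0, t_end: Optional[float] = None) -> float:
        """Time-average of ``observable(state)`` over [t_start, t_end]."""
        if t_end is None:
            t_end = float(self.times[-1])
        if t_end <= t_start:
            raise ValueError("t_end must exceed t_start")
        vals = np.array([observable(s) for s in self.states])
        # piecewise-constant integration on the overlap of each segment
        lo = np.maximum(self.times[:-1], t_start)
        hi = np.minimum(self.times[1:], t_end)
        w = np.clip(hi - lo, 0.0, None)
        total = w.sum()
        if total <= 0:
            raise ValueError("window does not overlap trajectory")
        return float(np.dot(w, vals[:-1]) / total)

    def to_tsv(self, path: str | Path, params: Optional[dict] = None) -> None:
        """One row per event, with a JSON sidecar of parameters and seed."""
        import pandas as pd

        path = Path(path)
        df = pd.DataFrame(self.states, columns=None)
        df.insert(0, "time_h", self.times)
        df.to_csv(path, sep="\t", index=False)
        sidecar = {"seed": int(self.seed), "absorbed": bool(self.absorbed)}
        if params:
            sidecar.update(params)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


@dataclass
class FirstPassageSample:
    """An ensemble of simulated activation (first-passage) times.

    Censored runs (no activation by ``t_max``) carry ``time == t_max``
    with ``censored == True``. ``fully_censored`` is set when every run
    censored — callers decide whether that is an error.
    """

    activation_times: np.ndarray  # hours
    censored: np.ndarray  # bool per run
    n_runs: int
    t_max: float
    seed: int

    @property
    def fully_censored(self) -> bool:
        return bool(self.censored.all())

    @property
    def uncensored_times(self) -> np.ndarray:
        return self.activation_times[~self.censored]

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean())

    def to_tsv(self, path: str | Path, params: Optional[dict] = None) -> None:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            {"activation_time_h": self.activation_times, "censored": self.censored.astype(int)}
        ).to_csv(path, sep="\t", index=False)
        sidecar = {"seed": int(self.seed), "n_runs": int(self.n_runs), "t_max": float(self.t_max)}
        if params:
            sidecar.update(params)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _next_event_schedule(events: Sequence[ScheduledEvent]):
    """Initial (next_time, index) pairs for every scheduled event."""
    return [ev.period for ev in events]


def gillespie_run(
    system: ReactionSystem,
    init: np.ndarray,
    t_max: float,
    seed: int,
    record: bool = True,
) -> Trajectory:
    """Exact direct-method stochastic simulation.

    Waiting times are exponential with rate equal to the total propensity;
    scheduled events are applied at exact multiples of their period,
    interleaved with reactions (the pending waiting time is truncated at
    the event boundary and redrawn, exact by memorylessness). Stops at the
    first absorbing state or at ``t_max``.

    With ``record=False`` only the first and final states are kept
    (used by the first-passage fast path).
    """
    init = np.asarray(init, dtype=np.int64)
    if np.any(init < 0):
        raise ValueError("initial state must be non-negative")
    if not (t_max > 0):
        raise ValueError("t_max must be positive")

    rng = np.random.default_rng(seed)
    t = 0.0
    state = init.copy()
    times = [0.0]
    states = [state.copy()]
    log: list[tuple[float, str]] = []
    absorbed = system.absorbing(state)

    next_times = _next_event_schedule(system.scheduled_events)

    def _record(t_now, st, label):
        log.append((t_now, label))
        if record:
            times.append(t_now)
            states.append(st.copy())

    while not absorbed and t < t_max:
        a = system.checked_propensities(state)
        a_tot = float(a.sum())

        # next scheduled-event boundary, if any
        if next_times:
            i_ev = int(np.argmin(next_times))
            t_ev = next_times[i_ev]
        else:
            i_ev, t_ev = -1, np.inf

        if a_tot <= 0.0:
            t_next = min(t_ev, t_max)
            if t_next >= t_max:
                t = t_max
                break
            # jump straight to the scheduled event
            t = t_ev
            state = np.asarray(
                system.scheduled_events[i_ev].transform(state, rng), dtype=np.int64
            )
            next_times[i_ev] += system.scheduled_events[i_ev].period
            _record(t, state, system.scheduled_events[i_ev].label)
            absorbed = system.absorbing(state)
            continue

        dt = rng.exponential(1.0 / a_tot)
        if t + dt >= min(t_ev, t_max):
            if t_ev <= t_max:
                # truncate at the boundary, apply the event, redraw after
                t = t_ev
                state = np.asarray(
                    system.scheduled_events[i_ev].transform(state, rng), dtype=np.int64
                )
                next_times[i_ev] += system.scheduled_events[i_ev].period
                _record(t, state, system.scheduled_events[i_ev].label)
                absorbed = system.absorbing(state)
                continue
            t = t_max
            break

        # a reaction fires
        t += dt
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a_tot), side="left"))
        j = min(j, system.n_reactions - 1)
        state = state + system.stoichiometry[j]
        if np.any(state < 0):
            raise PropensityError(
                f"{system._reaction_name(j)} drove a count negative at state "
                f"{state.tolist()} (guard your propensities)"
            )
        _record(t, state, system._reaction_name(j))
        absorbed = system.absorbing(state)

    if not record:
        times = [0.0, t]
        states = [init, state]
    elif times[-1] < t:
        times.append(t)
        states.append(state.copy())

    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=np.asarray(states, dtype=np.int64),
        event_log=log,
        seed=int(seed),
        absorbed=bool(absorbed),
    )


def _first_passage_time(system: ReactionSystem, init: np.ndarray, t_max: float,
                        rng: np.random.Generator) -> tuple[float, bool]:
    """Single first-passage time without trajectory recording."""
    state = np.asarray(init, dtype=np.int64).copy()
    if system.absorbing(state):
        return 0.0, False
    t = 0.0
    next_times = _next_event_schedule(system.scheduled_events)
    stoich = system.stoichiometry
    while t < t_max:
        a = system.checked_propensities(state)
        a_tot = float(a.sum())
        if next_times:
            i_ev = int(np.argmin(next_times))
            t_ev = next_times[i_ev]
        else:
            i_ev, t_ev = -1, np.inf

        if a_tot <= 0.0:
            dt = np.inf
        else:
            dt = rng.exponential(1.0 / a_tot)

        if t + dt >= min(t_ev, t_max):
            if t_ev <= t_max:
                t = t_ev
                state = np.asarray(
                    system.scheduled_events[i_ev].transform(state, rng), dtype=np.int64
                )
                next_times[i_ev] += system.scheduled_events[i_ev].period
                if system.absorbing(state):
                    return t, False
                continue
            return t_max, True

        t += dt
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a_tot), side="left"))
        j = min(j, system.n_reactions - 1)
        state += stoich[j]
        if np.any(state < 0):
            raise PropensityError(
                f"{system._reaction_name(j)} drove a count negative at state "
                f"{state.tolist()}"
            )
        if system.absorbing(state):
            return t, False
    return t_max, True


def first_passage_ensemble(
    system: ReactionSystem,
    init: np.ndarray,
    n_runs: int,
    t_max: float,
    seed: int,
    use_fast: bool = True,
) -> FirstPassageSample:
    """Independent first-passage times, one per counter-spawned sub-seed.

    Sub-seeds are derived from the master seed with ``SeedSequence.spawn``,
    so the ensemble is reproducible and order-independent. A fully censored
    ensemble is returned (flagged), not raised. Systems carrying a compiled
    kernel use it unless ``use_fast=False``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    init = np.asarray(init, dtype=np.int64)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_runs)
    times = np.empty(n_runs)
    cens = np.empty(n_runs, dtype=bool)
    fast = system.fast_first_passage if use_fast else None
    for i, child in enumerate(children):
        if fast is not None:
            sub = int(child.generate_state(1)[0] % (2**31))
            times[i], cens[i] = fast(init, t_max, sub)
        else:
            rng = np.random.default_rng(child)
            times[i], cens[i] = _first_passage_time(system, init, t_max, rng)
    return FirstPassageSample(
        activation_times=times, censored=cens, n_runs=n_runs, t_max=float(t_max), seed=int(seed)
    )


def exact_mfpt(
    system: ReactionSystem,
    init: np.ndarray,
    max_states: int = 50_000,
) -> float:
    """Exact mean first-passage time to the absorbing set by linear solve.

    Enumerates the reachable state space by breadth-first search over the
    reaction network (scheduled events are not allowed — they break the
    time-homogeneous Markov structure), assembles the generator restricted
    to transient states and solves ``Q tau = -1``.

    Raises
    ------
    StateSpaceError
        If the reachable space exceeds ``max_states`` (use Monte-Carlo
        estimation instead) or the absorbing set is unreachable.
    """
    if system.scheduled_events:
        raise ValueError("exact_mfpt requires a system with no scheduled events")
    init = np.asarray(init, dtype=np.int64)
    if system.absorbing(init):
        return 0.0

    index: dict[tuple, int] = {tuple(init): 0}
    order: list[np.ndarray] = [init.copy()]
    is_absorbing = [False]
    frontier = [0]
    rows, cols, vals = [], [], []
    diag = []

    while frontier:
        i = frontier.pop()
        state = order[i]
        a = system.checked_propensities(state)
        out = 0.0
        for j in np.nonzero(a > 0)[0]:
            nxt = state + system.stoichiometry[j]
            if np.any(nxt < 0):
                continue  # guarded: reaction cannot fire out of bounds
            key = tuple(nxt)
            k = index.get(key)
            if k is None:
                if len(order) >= max_states:
                    raise StateSpaceError(
                        f"reachable state space exceeds cap ({max_states}); "
                        "use first_passage_ensemble for Monte-Carlo estimation"
                    )
                k = len(order)
                index[key] = k
                order.append(nxt)
                absorbed = bool(system.absorbing(nxt))
                is_absorbing.append(absorbed)
                if not absorbed:
                    frontier.append(k)
            rate = float(a[j])
            out += rate
            rows.append(i)
            cols.append(k)
            vals.append(rate)
        diag.append((i, out))

    n = len(order)
    absorbing_mask = np.asarray(is_absorbing)
    if not absorbing_mask.any():
        raise StateSpaceError("absorbing set unreachable from the initial state")

    transient = np.nonzero(~absorbing_mask)[0]
    remap = -np.ones(n, dtype=np.int64)
    remap[transient] = np.arange(transient.size)

    # generator restricted to transient states
    tri, tci, tvi = [], [], []
    for r, c, v in zip(rows, cols, vals):
        if absorbing_mask[r]:
            continue
        if not absorbing_mask[c]:
            tri.append(remap[r])
            tci.append(remap[c])
            tvi.append(v)
    for i, out in diag:
        if not absorbing_mask[i]:
            tri.append(remap[i])
            tci.append(remap[i])
            tvi.append(-out)

    Q = sp.csr_matrix((tvi, (tri, tci)), shape=(transient.size, transient.size))
    # states with no outflow at all (and not absorbing) make the MFPT infinite
    outflow = -Q.diagonal()
    b = -np.ones(transient.size)
    try:
        tau = spla.spsolve(Q.tocsc(), b)
    except Exception as exc:  # singular generator
        raise StateSpaceError(
            "absorbing set unreachable from part of the state space"
        ) from exc
    if np.any(~np.isfinite(tau)) or np.any(tau < 0) or np.any(outflow == 0):
        raise StateSpaceError("absorbing set unreachable from part of the state space")
    return float(tau[remap[index[tuple(init)]]])
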