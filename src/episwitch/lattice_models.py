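"""Methylation read-write (M) model on a linear nucleosome array.

The gene locus is a linear array of N nucleosomes, each methylated
(H3K27me3) or not. An unmethylated nucleosome is methylated at a rate that
increases with the local methylated fraction (read-write positive feedback
by the methyltransferase complex); a methylated nucleosome is demethylated
at a first-order rate alpha. At every DNA replication (period T_div) each
methylated nucleosome independently retains its mark with probability 1/2
(random segregation of parental histones). The gene counts as activated
when total methylation first drops to or below ``theta_act * N``.

Also provides the passive-dilution comparator: no enzymatic turnover, loss
of marks purely by replication dilution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from episwitch.stochastic_engine import (
    FirstPassageSample,
    ReactionSystem,
    ScheduledEvent,
    gillespie_run,
)


class MetastabilityError(RuntimeError):
    """The silent state is not metastable at the requested parameters."""


@dataclass(frozen=True)
class MModelParams:
    """Parameters of the methylation read-write model.

    Defaults define a deep-silent, locus-wide-feedback regime: the reach
    spans the array (the read-write complex acts across the whole compacted
    locus), cooperativity is strong (hill_n = 3), enzymatic turnover is
    fast relative to the cell cycle, and the silent-state methylated
    fraction is ~0.86 with a mean activation time of ~2.5e4 h. Raising
    alpha to ~2.6 lowers the silent methylated fraction by ~10 percentage
    points and shortens the mean activation time several-hundred-fold
    (the extreme-sensitivity regime).

    Attributes
    ----------
    N : nucleosome count of the modeled locus
    k0 : basal methylation rate (1/h)
    k_fb : feedback methylation gain (1/h), scaled by the local methylated
        fraction within ``reach`` (raised to ``hill_n``)
    reach : neighborhood half-width, in nucleosomes
    hill_n : cooperativity exponent of the feedback (1 = linear)
    alpha : demethylation rate (1/h)
    T_div : cell-cycle length (h); ``None`` or ``inf`` disables replication
    theta_act : activation threshold, as a fraction of N
    """

    N: int = 100
    k0: float = 0.42
    k_fb: float = 20.0
    reach: int = 99
    hill_n: float = 3.0
    alpha: float = 1.95
    T_div: float | None = 20.0
    theta_act: float = 0.1

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if min(self.k0, self.k_fb, self.alpha) < 0:
            raise ValueError("rates must be non-negative")
        if not (0 < self.theta_act < 1):
            raise ValueError("theta_act must lie in (0, 1)")
        if self.reach < 1:
            raise ValueError("reach must be >= 1")


@dataclass(frozen=True)
class DilutionParams:
    """Passive-dilution comparator: replication dilution only.

    ``residual_alpha`` allows a slow enzymatic demethylation on top of the
    dilution (default 0, pure dilution).
    """

    N: int = 40
    T_div: float = 20.0
    theta_act: float = 0.1
    residual_alpha: float = 0.0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not (0 < self.theta_act < 1):
            raise ValueError("theta_act must lie in (0, 1)")
        if self.residual_alpha < 0:
            raise ValueError("residual_alpha must be >= 0")


def methylation_propensity(i: int, methyl: np.ndarray, params: MModelParams) -> float:
    """Read-write methylation rate of nucleosome ``i``.

    ``k0 + k_fb * (n_me / window)**hill_n`` for an unmethylated site,
    where ``n_me`` counts methylated nucleosomes within ``reach`` of ``i``
    (excluding ``i``) and ``window`` is the size of that neighborhood,
    clipped at the array edges (no wraparound). Zero for methylated sites.
    """
    methyl = np.asarray(methyl)
    N = methyl.size
    if not (0 <= i < N):
        raise IndexError(f"site {i} out of bounds for array of length {N}")
    if methyl[i]:
        return 0.0
    lo = max(0, i - params.reach)
    hi = min(N, i + params.reach + 1)
    window = (hi - lo) - 1  # exclude site i itself
    n_me = int(methyl[lo:hi].sum()) - int(methyl[i])
    frac = n_me / window if window > 0 else 0.0
    return params.k0 + params.k_fb * frac**params.hill_n


def _neighbor_matrix(N: int, reach: int) -> np.ndarray:
    """(N, N) 0/1 matrix: W[i, j] = 1 if j is within reach of i, j != i."""
    idx = np.arange(N)
    d = np.abs(idx[:, None] - idx[None, :])
    W = ((d <= reach) & (d > 0)).astype(float)
    return W


def replicate_lattice(methyl: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random histone segregation at DNA replication.

    Each methylated nucleosome independently retains its mark with
    probability 1/2 (half of the methylated nucleosomes replaced by
    unmethylated ones on average); unmethylated sites are unchanged.
    """
    methyl = np.asarray(methyl, dtype=np.int64)
    keep = rng.random(methyl.size) < 0.5
    return methyl * keep


def build_m_model(params: MModelParams) -> ReactionSystem:
    """Assemble the read-write lattice model as a ReactionSystem.

    State vector = per-site methylation (0/1, length N). Reactions:
    per-site methylation (read-write propensity) and per-site
    demethylation (rate alpha). Scheduled event: replication dilution
    every T_div. Absorbing: total methylation <= theta_act * N.
    """
    N = params.N
    thresh = params.theta_act * N
    W = _neighbor_matrix(N, params.reach)
    window = W.sum(axis=1)  # neighborhood size per site (edge-clipped)

    stoich = np.vstack([np.eye(N, dtype=np.int64), -np.eye(N, dtype=np.int64)])
    labels = [f"methylate[{i}]" for i in range(N)] + [f"demethylate[{i}]" for i in range(N)]

    k0, k_fb, hn, alpha = params.k0, params.k_fb, params.hill_n, params.alpha

    def propensities(state: np.ndarray) -> np.ndarray:
        m = state.astype(float)
        frac = (W @ m) / window
        a_me = (k0 + k_fb * frac**hn) * (1.0 - m)
        a_de = alpha * m
        return np.concatenate([a_me, a_de])

    events = []
    if params.T_div is not None and np.isfinite(params.T_div):
        events.append(
            ScheduledEvent(
                period=params.T_div,
                transform=lambda s, rng: replicate_lattice(s, rng),
                label="replication",
            )
        )

    def absorbing(state: np.ndarray) -> bool:
        return state.sum() <= thresh

    init_methyl = N  # canonical fully methylated start
    if thresh >= init_methyl:
        raise ValueError(
            f"theta_act*N = {thresh:g} >= initial methylation {init_methyl}: "
            "switch already active at start"
        )

    from episwitch._kernels import (
        HAVE_NUMBA,
        m_first_passage,
        m_global_first_passage,
        m_global_steady_methylation,
        m_steady_methylation,
    )

    T_div_num = params.T_div if (params.T_div is not None and np.isfinite(params.T_div)) else -1.0
    fast_fp = fast_sm = None
    if HAVE_NUMBA and params.reach >= N - 1:
        # feedback spans the whole array: exact reduction to a chain on
        # total methylation (O(1) per event)
        def fast_fp(init, t_max, sub_seed):
            return m_global_first_passage(
                int(np.asarray(init).sum()), N, k0, k_fb, float(hn), alpha,
                float(T_div_num), float(thresh), float(t_max), sub_seed,
            )

        def fast_sm(init, burn_in, window_h, sub_seed):
            return m_global_steady_methylation(
                int(np.asarray(init).sum()), N, k0, k_fb, float(hn), alpha,
                float(T_div_num), float(thresh), float(burn_in), float(window_h), sub_seed,
            )
    elif HAVE_NUMBA:
        def fast_fp(init, t_max, sub_seed):
            return m_first_passage(
                np.asarray(init, dtype=np.int64), k0, k_fb, float(hn), alpha,
                params.reach, float(T_div_num), float(thresh), float(t_max), sub_seed,
            )

        def fast_sm(init, burn_in, window_h, sub_seed):
            return m_steady_methylation(
                np.asarray(init, dtype=np.int64), k0, k_fb, float(hn), alpha,
                params.reach, float(T_div_num), float(thresh), N,
                float(burn_in), float(window_h), sub_seed,
            )

    return ReactionSystem(
        species_labels=[f"me[{i}]" for i in range(N)],
        propensities=propensities,
        stoichiometry=stoich,
        scheduled_events=events,
        absorbing=absorbing,
        reaction_labels=labels,
        methyl_count=lambda s: float(s.sum()),
        n_nucleosomes=N,
        fast_first_passage=fast_fp,
        fast_steady_methylation=fast_sm,
    )


def m_model_init(params: MModelParams) -> np.ndarray:
    """Fully methylated initial lattice (the silent state)."""
    return np.ones(params.N, dtype=np.int64)


def build_dilution_model(params: DilutionParams) -> ReactionSystem:
    """Passive dilution: marks are lost only through replication.

    State vector = [methylated count]. Optional residual first-order
    demethylation; no methylation reactions.
    """
    N = params.N
    thresh = params.theta_act * N

    stoich = np.array([[-1]], dtype=np.int64)
    alpha = params.residual_alpha

    def propensities(state: np.ndarray) -> np.ndarray:
        return np.array([alpha * state[0]], dtype=float)

    def dilute(state: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        m = int(state[0])
        return np.array([rng.binomial(m, 0.5)], dtype=np.int64)

    events = []
    if params.T_div is not None and np.isfinite(params.T_div):
        events.append(ScheduledEvent(period=params.T_div, transform=dilute, label="replication"))

    return ReactionSystem(
        species_labels=["me_total"],
        propensities=propensities,
        stoichiometry=stoich,
        scheduled_events=events,
        absorbing=lambda s: s[0] <= thresh,
        reaction_labels=["residual_demethylation"],
        methyl_count=lambda s: float(s[0]),
        n_nucleosomes=N,
    )


def dilution_init(params: DilutionParams) -> np.ndarray:
    return np.array([params.N], dtype=np.int64)


def steady_methylation(
    system: ReactionSystem,
    init: np.ndarray,
    burn_in: float,
    window: float,
    seed: int,
    n_reps: int = 8,
    max_activated_fraction: float = 0.5,
) -> float:
    """Quasi-stationary silent-state methylated fraction.

    Time-averages the methylated fraction over ``[burn_in, burn_in+window]``
    across replicate trajectories that have not activated by the end of the
    window. Requires the silent state to be metastable on this horizon:
    raises :class:`MetastabilityError` if more than
    ``max_activated_fraction`` of replicates activate.

    Works for any system exposing ``methyl_count`` and ``n_nucleosomes``.
    """
    if system.methyl_count is None or system.n_nucleosomes is None:
        raise ValueError("system does not expose a methylation observable")
    t_end = burn_in + window
    ss = np.random.SeedSequence(seed)
    fracs = []
    n_activated = 0
    for child in ss.spawn(n_reps):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        if system.fast_steady_methylation is not None:
            mfrac, activated = system.fast_steady_methylation(init, burn_in, window, sub_seed)
            if activated:
                n_activated += 1
                continue
            fracs.append(mfrac)
            continue
        traj = gillespie_run(system, init, t_max=t_end, seed=sub_seed)
        if traj.absorbed:
            n_activated += 1
            continue
        mbar = traj.time_average(system.methyl_count, t_start=burn_in, t_end=t_end)
        fracs.append(mbar / system.n_nucleosomes)
    if n_activated > max_activated_fraction * n_reps or not fracs:
        raise MetastabilityError(
            f"silent state not metastable at these parameters: "
            f"{n_activated}/{n_reps} replicates activated within "
            f"burn_in + window = {t_end:g} h"
        )
    return float(np.mean(fracs))
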