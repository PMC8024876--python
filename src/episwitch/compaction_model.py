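"""Methylation-compaction (MC) model of the timed epigenetic switch.

Nucleosomes at the locus can be methylated (M) or unmethylated (U) and
included in or excluded from a compacted, phase-separated nucleosome
assembly (in/out). Methylation/demethylation are first-order; association
with and dissociation from the assembly occur at rates proportional to its
surface area, taken to scale as the two-thirds power of the assembly size
C_T (nucleosomes exchange only through the assembly surface). Methylation
and compaction are coupled: methylated nucleosomes associate faster
(``a_me >= 1``) and dissociate slower (``d_me <= 1``), and in-assembly
nucleosomes methylate faster (``gamma_c``) and demethylate slower
(``beta_c``). When C_T falls below a threshold ``C_min`` the assembly is
unstable and dissolves irreversibly — the locus decompacts and the gene
activates.

Two transcription-factor coupling mechanisms are provided: pioneer-factor
*blocking* of nucleosome association, and TF-induced *demethylation* of
``N_R`` nucleosomes around the binding vicinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from episwitch.stochastic_engine import ReactionSystem, ScheduledEvent, first_passage_ensemble

# state-vector component order, base model
M_IN, M_OUT, U_IN, U_OUT = 0, 1, 2, 3
# TF models append the bound-site count
TF_BOUND = 4


@dataclass(frozen=True)
class MCParams:
    """Methylation-compaction model parameters.

    Defaults define the documented fast-turnover, weak-coupling regime:
    enzymatic turnover on the minutes scale (20/h, far faster than
    division), slow surface exchange (k_off ~ 0.4/h) and a mild
    methylation-compaction coupling (a_me = 1.2). The silent assembly
    holds ~0.9 N nucleosomes with a dissolution threshold just below it;
    mean activation is ~130 h at T_div = 20 h, with exponential
    (CV ~ 1) activation-time statistics, graded (< 2-fold) response to
    2-fold enzyme-rate changes, and division-independent timing.

    Attributes
    ----------
    N : nucleosome count
    k_me : methylation rate U -> M outside the assembly (1/h)
    gamma_c : methylation-rate multiplier inside the assembly (>= 1)
    alpha : demethylation rate M -> U outside the assembly (1/h)
    beta_c : demethylation multiplier inside the assembly (<= 1)
    k_on, k_off : association / dissociation rate scales (1/h); both fluxes
        carry the surface factor C_T^(2/3)
    a_me : association affinity multiplier for methylated nucleosomes (>= 1)
    d_me : dissociation multiplier for methylated nucleosomes (<= 1)
    u_adhesion : methylation-independent adhesion scale on unmethylated
        association (default 1; setting it to 0 removes the
        methylation-independent pathway — the documented negative control
        that restores extreme sensitivity)
    C_min : dissolution threshold (assembly dissolves when C_T < C_min)
    phi : fraction of assembly nucleosomes ejected at each replication
    T_div : cell-cycle length (h); None or inf disables replication
    """

    N: int = 60
    k_me: float = 20.0
    gamma_c: float = 2.0
    alpha: float = 20.0
    beta_c: float = 0.5
    k_on: float = 0.4 / 7.0
    k_off: float = 0.4
    a_me: float = 1.2
    d_me: float = 1.0 / 1.2
    u_adhesion: float = 1.0
    C_min: int = 47
    phi: float = 0.01
    T_div: float | None = 20.0

    def __post_init__(self):
        if self.a_me < 1 or self.d_me > 1:
            raise ValueError("methylation must promote compaction: a_me >= 1, d_me <= 1")
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")
        if self.u_adhesion < 0:
            raise ValueError("u_adhesion must be >= 0")
        if not (1 <= self.C_min < self.N):
            raise ValueError("C_min must satisfy 1 <= C_min < N")
        if not (0 <= self.phi <= 1):
            raise ValueError("phi must lie in [0, 1]")
        if min(self.k_me, self.alpha, self.k_off) < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class TFParams:
    """Transcription-factor coupling parameters.

    ``mechanism='blocking'``: bound site-nucleosomes cannot associate with
    the assembly (pioneer-factor occlusion of internucleosomal contacts).
    ``mechanism='demethylation'``: while any site is bound, ``N_R``
    nucleosomes around the binding vicinity demethylate at
    ``alpha * alpha_mult``.
    """

    N_B: int = 2
    tf_conc: float = 1.0
    k_bind_per_conc: float = 10.0
    k_unbind: float = 1.0
    mechanism: Literal["blocking", "demethylation"] = "blocking"
    N_R: int = 0
    alpha_mult: float = 20.0

    def __post_init__(self):
        if self.N_B < 0:
            raise ValueError("N_B must be >= 0")
        if self.tf_conc < 0:
            raise ValueError("tf_conc must be >= 0")
        if self.mechanism == "demethylation" and self.N_R == 0:
            raise ValueError("demethylation mechanism requires N_R >= 1")


def surface_factor(C_T: float) -> float:
    """Surface-area scaling of assembly exchange rates: C_T^(2/3), 0 at 0.

    The exponent is fixed at 2/3 (volume-to-surface scaling of a
    three-dimensional condensate); it is deliberately not configurable.
    """
    if C_T < 0:
        raise ValueError("C_T must be >= 0")
    return float(C_T) ** (2.0 / 3.0)


def mc_init(params: MCParams) -> np.ndarray:
    """All N nucleosomes methylated and inside the assembly (silent state)."""
    return np.array([params.N, 0, 0, 0], dtype=np.int64)


def replicate_mc(state: np.ndarray, params: MCParams, rng: np.random.Generator) -> np.ndarray:
    """DNA replication for the MC model.

    Each methylated nucleosome (in or out) is demethylated with
    probability 1/2 (random histone segregation); independently, each
    in-assembly nucleosome is ejected with probability ``phi`` (partial
    assembly disruption by the replication fork). The dissolution check
    is applied by the caller afterwards.
    """
    m_in, m_out, u_in, u_out = (int(x) for x in state[:4])
    # methylation halving, tracked separately for in/out pools
    m_in_keep = rng.binomial(m_in, 0.5)
    m_out_keep = rng.binomial(m_out, 0.5)
    u_in += m_in - m_in_keep
    u_out += m_out - m_out_keep
    m_in, m_out = m_in_keep, m_out_keep
    # ejection of in-assembly nucleosomes
    if params.phi > 0:
        m_ej = rng.binomial(m_in, params.phi)
        u_ej = rng.binomial(u_in, params.phi)
        m_in -= m_ej
        m_out += m_ej
        u_in -= u_ej
        u_out += u_ej
    new = state.copy()
    new[:4] = (m_in, m_out, u_in, u_out)
    return new


def _mc_propensities(params: MCParams):
    """Reaction table and propensity function for the base MC model.

    Reactions (stoichiometry order):
      0 methylation out  (U_out -> M_out)
      1 methylation in   (U_in  -> M_in)
      2 demethylation out (M_out -> U_out)
      3 demethylation in  (M_in  -> U_in)
      4 association M (M_out -> M_in)
      5 association U (U_out -> U_in)
      6 dissociation M (M_in -> M_out)
      7 dissociation U (U_in -> U_out)
    """
    stoich = np.array(
        [
            # M_in M_out U_in U_out
            [0, 1, 0, -1],   # methylation out
            [1, 0, -1, 0],   # methylation in
            [0, -1, 0, 1],   # demethylation out
            [-1, 0, 1, 0],   # demethylation in
            [1, -1, 0, 0],   # association M
            [0, 0, 1, -1],   # association U
            [-1, 1, 0, 0],   # dissociation M
            [0, 0, -1, 1],   # dissociation U
        ],
        dtype=np.int64,
    )
    labels = [
        "methylation_out", "methylation_in", "demethylation_out", "demethylation_in",
        "association_M", "association_U", "dissociation_M", "dissociation_U",
    ]
    p = params

    def propensities(state: np.ndarray) -> np.ndarray:
        m_in, m_out, u_in, u_out = (float(x) for x in state[:4])
        c_t = m_in + u_in
        surf = surface_factor(c_t)
        a = np.empty(8)
        a[0] = p.k_me * u_out
        a[1] = p.k_me * p.gamma_c * u_in
        a[2] = p.alpha * m_out
        a[3] = p.alpha * p.beta_c * m_in
        a[4] = p.k_on * surf * p.a_me * m_out
        a[5] = p.k_on * surf * p.u_adhesion * u_out
        if c_t > 0:
            # total surface exchange flux, apportioned by bulk composition
            a[6] = p.k_off * surf * p.d_me * m_in / c_t
            a[7] = p.k_off * surf * u_in / c_t
        else:
            a[6] = a[7] = 0.0
        return a

    return stoich, labels, propensities


def build_mc_model(params: MCParams) -> ReactionSystem:
    """Assemble the base MC model as a ReactionSystem.

    State vector [M_in, M_out, U_in, U_out]; initial condition all N
    methylated and in the assembly. Dissolution (C_T < C_min after any
    reaction or scheduled event) is the absorbing "gene active" condition;
    it is irreversible by construction because the simulation stops there.
    """
    if params.C_min >= params.N:
        raise ValueError("C_min >= initial C_T = N: assembly dissolves at start")
    stoich, labels, propensities = _mc_propensities(params)

    events = []
    if params.T_div is not None and np.isfinite(params.T_div):
        events.append(
            ScheduledEvent(
                period=params.T_div,
                transform=lambda s, rng: replicate_mc(s, params, rng),
                label="replication",
            )
        )

    c_min = params.C_min

    def absorbing(state: np.ndarray) -> bool:
        return (state[M_IN] + state[U_IN]) < c_min

    from episwitch._kernels import HAVE_NUMBA, mc_first_passage, mc_steady_methylation

    p = params
    T_div_num = p.T_div if (p.T_div is not None and np.isfinite(p.T_div)) else -1.0
    fast_fp = fast_sm = None
    if HAVE_NUMBA:
        def fast_fp(init, t_max, sub_seed):
            s5 = np.zeros(5, dtype=np.int64)
            s5[:4] = init[:4]
            return mc_first_passage(
                s5, p.k_me, p.gamma_c, p.alpha, p.beta_c, p.k_on, p.k_off,
                p.a_me, p.d_me, p.u_adhesion, p.C_min, p.phi, float(T_div_num),
                p.N, 0, 0, 0.0, 0.0, 0.0, 0, 1.0,
                float(t_max), sub_seed,
            )

        def fast_sm(init, burn_in, window_h, sub_seed):
            return mc_steady_methylation(
                np.asarray(init[:4], dtype=np.int64), p.k_me, p.gamma_c, p.alpha,
                p.beta_c, p.k_on, p.k_off, p.a_me, p.d_me, p.u_adhesion,
                p.C_min, p.phi, float(T_div_num), p.N,
                float(burn_in), float(window_h), sub_seed,
            )

    return ReactionSystem(
        species_labels=["M_in", "M_out", "U_in", "U_out"],
        propensities=propensities,
        stoichiometry=stoich,
        scheduled_events=events,
        absorbing=absorbing,
        reaction_labels=labels,
        methyl_count=lambda s: float(s[M_IN] + s[M_OUT]),
        n_nucleosomes=params.N,
        fast_first_passage=fast_fp,
        fast_steady_methylation=fast_sm,
    )


def build_tf_model(params: MCParams, tf: TFParams) -> ReactionSystem:
    """MC model extended with transcription-factor binding.

    The state gains a bound-site count B (0..N_B). TFs bind only
    site-nucleosomes outside the assembly (pioneer access requires
    exposure): the binding propensity is scaled by the out-of-assembly
    fraction. Mechanisms:

    * ``blocking`` — bound site-nucleosomes are removed from the pool
      available for association (apportioned by out-pool composition).
    * ``demethylation`` — while any site is bound, up to ``N_R``
      methylated nucleosomes demethylate at ``alpha * alpha_mult``
      (apportioned in/out by composition).
    """
    base_stoich, base_labels, base_prop = _mc_propensities(params)
    n_extra = 4 if tf.mechanism == "demethylation" else 2
    n_base = base_stoich.shape[0]

    stoich = np.zeros((n_base + n_extra, 5), dtype=np.int64)
    stoich[:n_base, :4] = base_stoich
    labels = list(base_labels)
    # bind / unbind
    stoich[n_base, TF_BOUND] = 1
    stoich[n_base + 1, TF_BOUND] = -1
    labels += ["tf_bind", "tf_unbind"]
    if tf.mechanism == "demethylation":
        stoich[n_base + 2, :4] = [0, -1, 0, 1]   # TF demethylation out
        stoich[n_base + 3, :4] = [-1, 0, 1, 0]   # TF demethylation in
        labels += ["tf_demethylation_out", "tf_demethylation_in"]

    p, t = params, tf

    def propensities(state: np.ndarray) -> np.ndarray:
        base_state = state[:4]
        m_in, m_out, u_in, u_out = (float(x) for x in base_state)
        bound = float(state[TF_BOUND])
        a = np.empty(n_base + n_extra)
        a[:n_base] = base_prop(base_state)

        out_total = m_out + u_out
        if t.mechanism == "blocking" and bound > 0 and out_total > 0:
            # bound sites cannot associate: remove them from the out pool,
            # apportioned by its composition
            blocked = min(bound, out_total)
            scale = max(0.0, 1.0 - blocked / out_total)
            a[4] *= scale
            a[5] *= scale

        frac_out = out_total / p.N
        a[n_base] = t.k_bind_per_conc * t.tf_conc * (t.N_B - bound) * frac_out
        a[n_base + 1] = t.k_unbind * bound

        if t.mechanism == "demethylation":
            m_total = m_in + m_out
            if bound > 0 and m_total > 0:
                targets = min(float(t.N_R), m_total)
                extra = p.alpha * (t.alpha_mult - 1.0) * targets
                a[n_base + 2] = extra * (m_out / m_total)
                a[n_base + 3] = extra * (m_in / m_total)
            else:
                a[n_base + 2] = a[n_base + 3] = 0.0
        return a

    events = []
    if params.T_div is not None and np.isfinite(params.T_div):
        def replicate(state: np.ndarray, rng: np.random.Generator) -> np.ndarray:
            new = replicate_mc(state, params, rng)
            return new
        events.append(ScheduledEvent(period=params.T_div, transform=replicate,
                                     label="replication"))

    c_min = params.C_min

    from episwitch._kernels import HAVE_NUMBA, mc_first_passage

    T_div_num = p.T_div if (p.T_div is not None and np.isfinite(p.T_div)) else -1.0
    mech_code = 1 if t.mechanism == "blocking" else 2
    fast_fp = None
    if HAVE_NUMBA:
        def fast_fp(init, t_max, sub_seed):
            return mc_first_passage(
                np.asarray(init, dtype=np.int64), p.k_me, p.gamma_c, p.alpha,
                p.beta_c, p.k_on, p.k_off, p.a_me, p.d_me, p.u_adhesion,
                p.C_min, p.phi, float(T_div_num), p.N,
                mech_code, t.N_B, t.tf_conc, t.k_bind_per_conc, t.k_unbind,
                t.N_R, t.alpha_mult,
                float(t_max), sub_seed,
            )

    return ReactionSystem(
        species_labels=["M_in", "M_out", "U_in", "U_out", "tf_bound"],
        propensities=propensities,
        stoichiometry=stoich,
        scheduled_events=events,
        absorbing=lambda s: (s[M_IN] + s[U_IN]) < c_min,
        reaction_labels=labels,
        methyl_count=lambda s: float(s[M_IN] + s[M_OUT]),
        n_nucleosomes=params.N,
        fast_first_passage=fast_fp,
    )


def tf_init(params: MCParams) -> np.ndarray:
    """Silent initial state for the TF-extended model (no TF bound)."""
    return np.array([params.N, 0, 0, 0, 0], dtype=np.int64)


def _hill(c, lam0, lam_max, ec50, h):
    return lam0 + (lam_max - lam0) * c**h / (ec50**h + c**h)


def activation_rate_vs_tf(
    params: MCParams,
    tf: TFParams,
    tf_grid: np.ndarray,
    n_runs: int,
    seed: int,
    t_max: float = 2000.0,
) -> tuple[pd.DataFrame, dict]:
    """Dose-response of the gene-activation rate constant vs TF concentration.

    For each concentration in ``tf_grid`` (>= 4 points spanning the
    half-max), runs a first-passage ensemble, fits a censoring-aware
    exponential rate, then fits a Hill curve to extract the maximal
    activation rate and the half-maximal concentration (EC50).

    Returns a per-concentration table and a dict with the Hill-fit
    parameters (``lambda_max``, ``ec50``, ``hill_n``, ``baseline``,
    ``flagged`` if the response is non-monotone beyond noise or the fit
    failed).
    """
    from episwitch.timing_analysis import fit_exponential_survival

    tf_grid = np.asarray(tf_grid, dtype=float)
    if tf_grid.size < 4:
        raise ValueError("tf_grid must contain >= 4 concentrations")
    ss = np.random.SeedSequence(seed)
    rows = []
    for conc, child in zip(tf_grid, ss.spawn(tf_grid.size)):
        tf_c = TFParams(
            N_B=tf.N_B, tf_conc=float(conc), k_bind_per_conc=tf.k_bind_per_conc,
            k_unbind=tf.k_unbind, mechanism=tf.mechanism, N_R=tf.N_R,
            alpha_mult=tf.alpha_mult,
        )
        system = build_tf_model(params, tf_c)
        sample = first_passage_ensemble(
            system, tf_init(params), n_runs=n_runs, t_max=t_max,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        fit = fit_exponential_survival(sample, min_uncensored=1)
        rows.append(
            {"tf_conc": conc, "rate_per_h": fit.rate, "rate_lo": fit.ci95[0],
             "rate_hi": fit.ci95[1], "censored_fraction": sample.censored_fraction}
        )
    table = pd.DataFrame(rows)

    rates = table["rate_per_h"].to_numpy()
    flagged = False
    # non-monotonicity beyond CI overlap -> warn and flag
    for i in range(len(rates) - 1):
        if rates[i + 1] < rates[i] and table["rate_hi"].iloc[i + 1] < table["rate_lo"].iloc[i]:
            warnings.warn("activation rate non-monotone in TF concentration beyond noise")
            flagged = True
            break

    hill = {"flagged": flagged}
    try:
        lam0_guess = max(rates[0], 1e-8)
        lam_max_guess = max(rates.max(), lam0_guess * 1.01)
        ec50_guess = tf_grid[max(1, tf_grid.size // 2)]
        popt, _ = curve_fit(
            _hill, tf_grid, rates,
            p0=[lam0_guess, lam_max_guess, ec50_guess, 1.5],
            bounds=([0, 0, tf_grid[tf_grid > 0].min() * 1e-3, 0.2],
                    [np.inf, np.inf, tf_grid.max() * 1e3, 8.0]),
            maxfev=20000,
        )
        hill.update(
            baseline=float(popt[0]), lambda_max=float(popt[1]),
            ec50=float(popt[2]), hill_n=float(popt[3]),
        )
    except Exception:
        hill["flagged"] = True
        hill.update(baseline=np.nan, lambda_max=float(rates.max()), ec50=np.nan, hill_n=np.nan)
    return table, hill
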