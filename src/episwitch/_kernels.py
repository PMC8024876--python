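"""Compiled first-passage kernels (optional acceleration).

These numba kernels implement exactly the same direct-method Gillespie
dynamics as :mod:`episwitch.stochastic_engine` for the two workhorse
models, trading the generic reaction-table interface for speed. The
generic engine remains the reference implementation; equivalence is
checked against the exact MFPT solver in the test suite.

If numba is unavailable the package falls back to the generic engine.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def m_first_passage(
    methyl0,          # int64[N] initial lattice
    k0, k_fb, hill_n, alpha,
    reach,            # int
    T_div,            # <= 0 disables replication
    thresh,           # absorbing when total methylation <= thresh
    t_max,
    seed,
):
    """First-passage time of the read-write lattice model. Returns (t, censored)."""
    np.random.seed(seed)
    N = methyl0.size
    methyl = methyl0.copy()
    total_me = 0
    for i in range(N):
        total_me += methyl[i]
    if total_me <= thresh:
        return 0.0, False

    t = 0.0
    next_div = T_div if T_div > 0 else 1e300
    a = np.empty(2 * N)

    while t < t_max:
        a_tot = 0.0
        for i in range(N):
            if methyl[i] == 1:
                a[i] = 0.0
                a[N + i] = alpha
            else:
                lo = i - reach
                if lo < 0:
                    lo = 0
                hi = i + reach + 1
                if hi > N:
                    hi = N
                n_me = 0
                for j in range(lo, hi):
                    n_me += methyl[j]
                window = (hi - lo) - 1
                frac = n_me / window if window > 0 else 0.0
                a[i] = k0 + k_fb * frac**hill_n
                a[N + i] = 0.0
            a_tot += a[i] + a[N + i]

        if a_tot <= 0.0:
            dt = 1e300
        else:
            dt = np.random.exponential(1.0 / a_tot)

        boundary = next_div if next_div < t_max else t_max
        if t + dt >= boundary:
            if next_div <= t_max:
                t = next_div
                next_div += T_div
                total_me = 0
                for i in range(N):
                    if methyl[i] == 1 and np.random.random() >= 0.5:
                        methyl[i] = 0
                    total_me += methyl[i]
                if total_me <= thresh:
                    return t, False
                continue
            return t_max, True

        t += dt
        u = np.random.random() * a_tot
        acc = 0.0
        j = 2 * N - 1
        for k in range(2 * N):
            acc += a[k]
            if u < acc:
                j = k
                break
        if j < N:
            methyl[j] = 1
            total_me += 1
        else:
            methyl[j - N] = 0
            total_me -= 1
        if total_me <= thresh:
            return t, False
    return t_max, True


@njit(cache=True)
def mc_first_passage(
    state0,           # int64[5]: M_in, M_out, U_in, U_out, tf_bound
    k_me, gamma_c, alpha, beta_c,
    k_on, k_off, a_me, d_me, u_adhesion,
    C_min, phi, T_div,
    N,
    # TF coupling: mechanism 0 = none, 1 = blocking, 2 = demethylation
    mechanism, N_B, tf_conc, k_bind_per_conc, k_unbind, N_R, alpha_mult,
    t_max,
    seed,
):
    """First-passage (dissolution) time of the MC model. Returns (t, censored)."""
    np.random.seed(seed)
    m_in = state0[0]
    m_out = state0[1]
    u_in = state0[2]
    u_out = state0[3]
    bound = state0[4]
    if m_in + u_in < C_min:
        return 0.0, False

    t = 0.0
    next_div = T_div if T_div > 0 else 1e300
    a = np.empty(12)

    while t < t_max:
        c_t = float(m_in + u_in)
        surf = c_t ** (2.0 / 3.0)
        a[0] = k_me * u_out
        a[1] = k_me * gamma_c * u_in
        a[2] = alpha * m_out
        a[3] = alpha * beta_c * m_in
        a[4] = k_on * surf * a_me * m_out
        a[5] = k_on * surf * u_adhesion * u_out
        if c_t > 0:
            a[6] = k_off * surf * d_me * m_in / c_t
            a[7] = k_off * surf * u_in / c_t
        else:
            a[6] = 0.0
            a[7] = 0.0
        a[8] = 0.0
        a[9] = 0.0
        a[10] = 0.0
        a[11] = 0.0
        out_total = float(m_out + u_out)
        if mechanism >= 1:
            if mechanism == 1 and bound > 0 and out_total > 0:
                blocked = float(bound) if bound < out_total else out_total
                scale = 1.0 - blocked / out_total
                if scale < 0.0:
                    scale = 0.0
                a[4] *= scale
                a[5] *= scale
            a[8] = k_bind_per_conc * tf_conc * (N_B - bound) * (out_total / N)
            a[9] = k_unbind * bound
            if mechanism == 2:
                m_total = float(m_in + m_out)
                if bound > 0 and m_total > 0:
                    targets = float(N_R) if N_R < m_total else m_total
                    extra = alpha * (alpha_mult - 1.0) * targets
                    a[10] = extra * (m_out / m_total)
                    a[11] = extra * (m_in / m_total)

        a_tot = 0.0
        for k in range(12):
            a_tot += a[k]

        if a_tot <= 0.0:
            dt = 1e300
        else:
            dt = np.random.exponential(1.0 / a_tot)

        boundary = next_div if next_div < t_max else t_max
        if t + dt >= boundary:
            if next_div <= t_max:
                t = next_div
                next_div += T_div
                # halve methylation (random segregation), in/out separately
                keep_in = np.random.binomial(m_in, 0.5)
                keep_out = np.random.binomial(m_out, 0.5)
                u_in += m_in - keep_in
                u_out += m_out - keep_out
                m_in = keep_in
                m_out = keep_out
                # eject a fraction phi of the assembly
                if phi > 0.0:
                    m_ej = np.random.binomial(m_in, phi)
                    u_ej = np.random.binomial(u_in, phi)
                    m_in -= m_ej
                    m_out += m_ej
                    u_in -= u_ej
                    u_out += u_ej
                if m_in + u_in < C_min:
                    return t, False
                continue
            return t_max, True

        t += dt
        u = np.random.random() * a_tot
        acc = 0.0
        j = 11
        for k in range(12):
            acc += a[k]
            if u < acc:
                j = k
                break
        if j == 0:
            u_out -= 1
            m_out += 1
        elif j == 1:
            u_in -= 1
            m_in += 1
        elif j == 2:
            m_out -= 1
            u_out += 1
        elif j == 3:
            m_in -= 1
            u_in += 1
        elif j == 4:
            m_out -= 1
            m_in += 1
        elif j == 5:
            u_out -= 1
            u_in += 1
        elif j == 6:
            m_in -= 1
            m_out += 1
        elif j == 7:
            u_in -= 1
            u_out += 1
        elif j == 8:
            bound += 1
        elif j == 9:
            bound -= 1
        elif j == 10:
            m_out -= 1
            u_out += 1
        else:
            m_in -= 1
            u_in += 1
        if m_in + u_in < C_min:
            return t, False
    return t_max, True


@njit(cache=True)
def mc_steady_methylation(
    state0,
    k_me, gamma_c, alpha, beta_c,
    k_on, k_off, a_me, d_me, u_adhesion,
    C_min, phi, T_div, N,
    burn_in, window,
    seed,
):
    """Time-averaged methylated fraction over [burn_in, burn_in+window].

    Returns (mbar, activated): ``activated`` is True when the assembly
    dissolved before the window ended (the sample must then be discarded).
    Dynamics identical to :func:`mc_first_passage` with no TF coupling.
    """
    np.random.seed(seed)
    m_in = state0[0]
    m_out = state0[1]
    u_in = state0[2]
    u_out = state0[3]
    t_end = burn_in + window
    t = 0.0
    next_div = T_div if T_div > 0 else 1e300
    a = np.empty(8)
    acc_me_time = 0.0

    while t < t_end:
        if m_in + u_in < C_min:
            return 0.0, True
        c_t = float(m_in + u_in)
        surf = c_t ** (2.0 / 3.0)
        a[0] = k_me * u_out
        a[1] = k_me * gamma_c * u_in
        a[2] = alpha * m_out
        a[3] = alpha * beta_c * m_in
        a[4] = k_on * surf * a_me * m_out
        a[5] = k_on * surf * u_adhesion * u_out
        a[6] = k_off * surf * d_me * m_in / c_t if c_t > 0 else 0.0
        a[7] = k_off * surf * u_in / c_t if c_t > 0 else 0.0
        a_tot = 0.0
        for k in range(8):
            a_tot += a[k]

        dt = np.random.exponential(1.0 / a_tot) if a_tot > 0.0 else 1e300
        t_next = t + dt
        is_event = False
        if t_next >= next_div and next_div <= t_end:
            t_next = next_div
            is_event = True
        elif t_next > t_end:
            t_next = t_end

        # accumulate methylated dwell over the overlap with the window
        lo = t if t > burn_in else burn_in
        hi = t_next
        if hi > lo:
            acc_me_time += (m_in + m_out) * (hi - lo)

        t = t_next
        if t >= t_end:
            break
        if is_event:
            next_div += T_div
            keep_in = np.random.binomial(m_in, 0.5)
            keep_out = np.random.binomial(m_out, 0.5)
            u_in += m_in - keep_in
            u_out += m_out - keep_out
            m_in = keep_in
            m_out = keep_out
            if phi > 0.0:
                m_ej = np.random.binomial(m_in, phi)
                u_ej = np.random.binomial(u_in, phi)
                m_in -= m_ej
                m_out += m_ej
                u_in -= u_ej
                u_out += u_ej
            continue

        u = np.random.random() * a_tot
        acc = 0.0
        j = 7
        for k in range(8):
            acc += a[k]
            if u < acc:
                j = k
                break
        if j == 0:
            u_out -= 1
            m_out += 1
        elif j == 1:
            u_in -= 1
            m_in += 1
        elif j == 2:
            m_out -= 1
            u_out += 1
        elif j == 3:
            m_in -= 1
            u_in += 1
        elif j == 4:
            m_out -= 1
            m_in += 1
        elif j == 5:
            u_out -= 1
            u_in += 1
        elif j == 6:
            m_in -= 1
            m_out += 1
        else:
            u_in -= 1
            u_out += 1

    if m_in + u_in < C_min:
        return 0.0, True
    return acc_me_time / (window * N), False


@njit(cache=True)
def m_steady_methylation(
    methyl0,
    k0, k_fb, hill_n, alpha,
    reach, T_div, thresh, N,
    burn_in, window,
    seed,
):
    """Time-averaged methylated fraction for the lattice model.

    Returns (mbar, activated); dynamics identical to
    :func:`m_first_passage`.
    """
    np.random.seed(seed)
    methyl = methyl0.copy()
    total_me = 0
    for i in range(N):
        total_me += methyl[i]
    t_end = burn_in + window
    t = 0.0
    next_div = T_div if T_div > 0 else 1e300
    a = np.empty(2 * N)
    acc_me_time = 0.0

    while t < t_end:
        if total_me <= thresh:
            return 0.0, True
        a_tot = 0.0
        for i in range(N):
            if methyl[i] == 1:
                a[i] = 0.0
                a[N + i] = alpha
            else:
                lo_i = i - reach
                if lo_i < 0:
                    lo_i = 0
                hi_i = i + reach + 1
                if hi_i > N:
                    hi_i = N
                n_me = 0
                for j in range(lo_i, hi_i):
                    n_me += methyl[j]
                window_i = (hi_i - lo_i) - 1
                frac = n_me / window_i if window_i > 0 else 0.0
                a[i] = k0 + k_fb * frac**hill_n
                a[N + i] = 0.0
            a_tot += a[i] + a[N + i]

        dt = np.random.exponential(1.0 / a_tot) if a_tot > 0.0 else 1e300
        t_next = t + dt
        is_event = False
        if t_next >= next_div and next_div <= t_end:
            t_next = next_div
            is_event = True
        elif t_next > t_end:
            t_next = t_end

        lo = t if t > burn_in else burn_in
        hi = t_next
        if hi > lo:
            acc_me_time += total_me * (hi - lo)

        t = t_next
        if t >= t_end:
            break
        if is_event:
            next_div += T_div
            total_me = 0
            for i in range(N):
                if methyl[i] == 1 and np.random.random() >= 0.5:
                    methyl[i] = 0
                total_me += methyl[i]
            continue

        u = np.random.random() * a_tot
        acc = 0.0
        j = 2 * N - 1
        for k in range(2 * N):
            acc += a[k]
            if u < acc:
                j = k
                break
        if j < N:
            methyl[j] = 1
            total_me += 1
        else:
            methyl[j - N] = 0
            total_me -= 1

    if total_me <= thresh:
        return 0.0, True
    return acc_me_time / (window * N), False


@njit(cache=True)
def m_global_first_passage(
    n0,               # initial methylated count
    N, k0, k_fb, hill_n, alpha,
    T_div, thresh, t_max, seed,
):
    """Global-coupling lattice model: exact reduction to a chain on n.

    When the feedback neighborhood spans the whole array, every
    unmethylated site sees the same methylated fraction n/(N-1), so the
    lattice dynamics reduce exactly to a birth-death chain on the total
    methylation n. Returns (t, censored).
    """
    np.random.seed(seed)
    n = n0
    if n <= thresh:
        return 0.0, False
    t = 0.0
    next_div = T_div if T_div > 0 else 1e300
    while t < t_max:
        frac = n / (N - 1.0)
        if frac > 1.0:
            frac = 1.0
        birth = (N - n) * (k0 + k_fb * frac**hill_n)
        death = alpha * n
        a_tot = birth + death
        dt = np.random.exponential(1.0 / a_tot) if a_tot > 0.0 else 1e300
        boundary = next_div if next_div < t_max else t_max
        if t + dt >= boundary:
            if next_div <= t_max:
                t = next_div
                next_div += T_div
                n = np.random.binomial(n, 0.5)
                if n <= thresh:
                    return t, False
                continue
            return t_max, True
        t += dt
        if np.random.random() * a_tot < birth:
            n += 1
        else:
            n -= 1
        if n <= thresh:
            return t, False
    return t_max, True


@njit(cache=True)
def m_global_steady_methylation(
    n0, N, k0, k_fb, hill_n, alpha,
    T_div, thresh, burn_in, window, seed,
):
    """Time-averaged methylated fraction for the global-coupling chain.

    Returns (mbar, activated).
    """
    np.random.seed(seed)
    n = n0
    t_end = burn_in + window
    t = 0.0
    next_div = T_div if T_div > 0 else 1e300
    acc = 0.0
    while t < t_end:
        if n <= thresh:
            return 0.0, True
        frac = n / (N - 1.0)
        if frac > 1.0:
            frac = 1.0
        birth = (N - n) * (k0 + k_fb * frac**hill_n)
        death = alpha * n
        a_tot = birth + death
        dt = np.random.exponential(1.0 / a_tot) if a_tot > 0.0 else 1e300
        t_next = t + dt
        is_event = False
        if t_next >= next_div and next_div <= t_end:
            t_next = next_div
            is_event = True
        elif t_next > t_end:
            t_next = t_end
        lo = t if t > burn_in else burn_in
        if t_next > lo:
            acc += n * (t_next - lo)
        t = t_next
        if t >= t_end:
            break
        if is_event:
            next_div += T_div
            n = np.random.binomial(n, 0.5)
            continue
        if np.random.random() * a_tot < birth:
            n += 1
        else:
            n -= 1
    if n <= thresh:
        return 0.0, True
    return acc / (window * N), False
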