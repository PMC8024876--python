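"""Allele-activation kinetics from two-channel flow-cytometry events.

Quantifies the fraction of biallelically expressing cells over time by
two-component bivariate Gaussian deconvolution of the two-dimensional
histogram of log-transformed RFP/YFP intensities, then fits the
time course of that fraction to a first-order activation process,
``F_bi(t) = 1 - exp(-lambda t)`` (or the plateau form
``y = F (1 - exp(-k t))``).

The procedure is the standard two-step mixture fit: (1) a single
component is fit on an early time window where virtually all cells are
still monoallelic; (2) at each successive time bin both components are
fit with the first component's shape frozen (only its amplitude free) and
the second component's parameters constrained to bounds.

Inputs arrive as a :class:`pandas.DataFrame` with columns
``time_h, r, y, live`` (background-corrected intensities; dead cells are
excluded by the ``live`` flag). Native FCS parsing is out of scope — CSV
export is assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

FLOW_COLUMNS = ["time_h", "r", "y", "live"]
DEFAULT_BINS = 64
INTENSITY_FLOOR = 1.0  # linear-scale floor before log10


class FitError(RuntimeError):
    """A mixture or curve fit failed to converge."""


@dataclass(frozen=True)
class GaussianComponent:
    """One bivariate Gaussian population in (log r, log y) space.

    ``amplitude`` is the volume under the component (cell-count scale);
    ``rho`` is the channel correlation, |rho| < 1.
    """

    amplitude: float
    mu_r: float
    mu_y: float
    sigma_r: float
    sigma_y: float
    rho: float

    def __post_init__(self):
        if self.sigma_r <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_r, sigma_y must be positive")
        if not (-1 < self.rho < 1):
            raise ValueError("|rho| must be < 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def density(self, r: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Standard bivariate normal density scaled by the amplitude."""
        zr = (r - self.mu_r) / self.sigma_r
        zy = (y - self.mu_y) / self.sigma_y
        q = (zr**2 + zy**2 - 2.0 * self.rho * zr * zy) / (1.0 - self.rho**2)
        norm = self.amplitude / (2.0 * np.pi * self.sigma_r * self.sigma_y
                                 * np.sqrt(1.0 - self.rho**2))
        return norm * np.exp(-0.5 * q)


@dataclass
class ActivationCurve:
    """Per-time-bin biallelic fractions with propagated errors."""

    bin_centers: np.ndarray  # hours
    f2obs: np.ndarray  # fractions in [0, 1]
    delta_f2obs: np.ndarray  # >= 0
    n_per_bin: np.ndarray


@dataclass(frozen=True)
class Histogram2D:
    counts: np.ndarray  # (n_bins, n_bins)
    r_centers: np.ndarray
    y_centers: np.ndarray
    r_edges: np.ndarray
    y_edges: np.ndarray
    n_events: int


def _log_transform(values: np.ndarray) -> np.ndarray:
    return np.log10(np.maximum(np.asarray(values, dtype=float), INTENSITY_FLOOR))


def histogram2d(
    events: pd.DataFrame,
    n_bins: int = DEFAULT_BINS,
    r_range: Optional[tuple[float, float]] = None,
    y_range: Optional[tuple[float, float]] = None,
    label: str = "",
) -> Histogram2D:
    """2D histogram of log10-transformed, floored intensities.

    ``r_range``/``y_range`` are in log10 units; by default the data range
    is used. Requires >= 100 live events.
    """
    live = events[events["live"].astype(bool)]
    if len(live) < 100:
        raise ValueError(
            f"too few live events ({len(live)}) in bin {label or '<unnamed>'}: need >= 100"
        )
    lr = _log_transform(live["r"].to_numpy())
    ly = _log_transform(live["y"].to_numpy())
    counts, r_edges, y_edges = np.histogram2d(
        lr, ly, bins=n_bins, range=[r_range, y_range] if r_range else None
    )
    return Histogram2D(
        counts=counts,
        r_centers=0.5 * (r_edges[:-1] + r_edges[1:]),
        y_centers=0.5 * (y_edges[:-1] + y_edges[1:]),
        r_edges=r_edges,
        y_edges=y_edges,
        n_events=int(len(live)),
    )


def _model_surface(hist: Histogram2D, components: list[GaussianComponent]) -> np.ndarray:
    """Expected counts per bin: density x bin area."""
    R, Y = np.meshgrid(hist.r_centers, hist.y_centers, indexing="ij")
    area = np.diff(hist.r_edges).mean() * np.diff(hist.y_edges).mean()
    total = np.zeros_like(R)
    for c in components:
        total += c.density(R, Y)
    return total * area


N_IRLS = 3  # reweighting passes; Poisson weights from the fitted surface
MIN_VARIANCE = 0.25  # variance floor for empty bins


def _irls_curve_fit(model, counts, p0, bounds=None, maxfev=20000):
    """Poisson-weighted least squares with model-based iterated weights.

    Weighting by the observed counts (Neyman chi-square) biases widths and
    amplitudes low; weights from the fitted surface (Pearson chi-square,
    iterated) are asymptotically unbiased.
    """
    kwargs = {"maxfev": maxfev}
    if bounds is not None:
        kwargs["bounds"] = bounds
    popt, pcov = curve_fit(model, None, counts, p0=p0, **kwargs)
    for _ in range(N_IRLS):
        sigma = np.sqrt(np.maximum(model(None, *popt), MIN_VARIANCE))
        popt, pcov = curve_fit(model, None, counts, p0=popt, sigma=sigma,
                               absolute_sigma=True, **kwargs)
    return popt, pcov


def fit_single_component(hist: Histogram2D) -> GaussianComponent:
    """Weighted least-squares fit of one bivariate Gaussian to a histogram.

    Intended for an early time window (all cells still monoallelic).
    Poisson weights are iterated from the fitted surface (see
    :func:`_irls_curve_fit`).
    """
    R, Y = np.meshgrid(hist.r_centers, hist.y_centers, indexing="ij")
    area = np.diff(hist.r_edges).mean() * np.diff(hist.y_edges).mean()
    counts = hist.counts.ravel()

    # moment-based initialization
    total = counts.sum()
    mu_r0 = float((R.ravel() * counts).sum() / total)
    mu_y0 = float((Y.ravel() * counts).sum() / total)
    sr0 = np.sqrt(((R.ravel() - mu_r0) ** 2 * counts).sum() / total) or 0.1
    sy0 = np.sqrt(((Y.ravel() - mu_y0) ** 2 * counts).sum() / total) or 0.1
    rho0 = float(((R.ravel() - mu_r0) * (Y.ravel() - mu_y0) * counts).sum()
                 / (total * sr0 * sy0))
    rho0 = np.clip(rho0, -0.95, 0.95)

    def model(_, amp, mu_r, mu_y, s_r, s_y, rho):
        comp = GaussianComponent(amp, mu_r, mu_y, s_r, s_y, rho)
        return (comp.density(R, Y) * area).ravel()

    p0 = [total, mu_r0, mu_y0, sr0, sy0, rho0]
    bounds = ([0, R.min(), Y.min(), 1e-3, 1e-3, -0.99],
              [np.inf, R.max(), Y.max(), np.ptp(R) + 1, np.ptp(Y) + 1, 0.99])
    try:
        popt, _ = _irls_curve_fit(model, counts, p0, bounds=bounds)
    except RuntimeError as exc:
        resid = counts - model(None, *p0)
        raise FitError(
            f"single-component fit did not converge (initial residual norm "
            f"{np.linalg.norm(resid):.3g})"
        ) from exc
    return GaussianComponent(*popt)


@dataclass(frozen=True)
class TwoComponentFit:
    component1: GaussianComponent  # shape identical to the fixed input
    component2: GaussianComponent
    N1: float
    N2: float
    dN1: float
    dN2: float
    at_bound: bool  # any component-2 parameter pinned at its bound


def fit_two_component(
    hist: Histogram2D,
    fixed_component1: GaussianComponent,
    bounds2: dict[str, tuple[float, float]],
    p0_2: Optional[GaussianComponent] = None,
) -> TwoComponentFit:
    """Two-component mixture fit with component 1's shape frozen.

    Free parameters: N1 (component-1 amplitude) and all component-2
    parameters, the latter clamped to ``bounds2`` (keys ``mu_r, mu_y,
    sigma_r, sigma_y, rho``). Amplitude uncertainties come from the fit
    covariance. Solutions pinned at a bound are flagged, not rejected.
    """
    R, Y = np.meshgrid(hist.r_centers, hist.y_centers, indexing="ij")
    area = np.diff(hist.r_edges).mean() * np.diff(hist.y_edges).mean()
    counts = hist.counts.ravel()
    c1 = fixed_component1

    def model(_, n1, n2, mu_r, mu_y, s_r, s_y, rho):
        f1 = replace(c1, amplitude=n1).density(R, Y)
        f2 = GaussianComponent(n2, mu_r, mu_y, s_r, s_y, rho).density(R, Y)
        return ((f1 + f2) * area).ravel()

    lo = [0.0, 0.0] + [bounds2[k][0] for k in ("mu_r", "mu_y", "sigma_r", "sigma_y", "rho")]
    hi = [np.inf, np.inf] + [bounds2[k][1] for k in ("mu_r", "mu_y", "sigma_r", "sigma_y", "rho")]
    if p0_2 is None:
        p0_2 = GaussianComponent(
            max(1.0, 0.05 * counts.sum()),
            np.clip(c1.mu_r, lo[2], hi[2]),
            np.clip(c1.mu_y + 1.0, lo[3], hi[3]),
            np.clip(c1.sigma_r, lo[4], hi[4]),
            np.clip(c1.sigma_y, lo[5], hi[5]),
            np.clip(c1.rho, lo[6], hi[6]),
        )
    p0 = [max(counts.sum() - p0_2.amplitude, 1.0), p0_2.amplitude,
          p0_2.mu_r, p0_2.mu_y, p0_2.sigma_r, p0_2.sigma_y, p0_2.rho]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, pcov = _irls_curve_fit(model, counts, p0, bounds=(lo, hi), maxfev=40000)
    except RuntimeError as exc:
        raise FitError("two-component fit did not converge") from exc

    at_bound = bool(
        np.any(np.isclose(popt[2:], lo[2:], rtol=1e-6, atol=1e-9))
        or np.any(np.isclose(popt[2:], hi[2:], rtol=1e-6, atol=1e-9))
    )
    if at_bound:
        warnings.warn("component-2 parameter pinned at a bound")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    comp2 = GaussianComponent(popt[1], *popt[2:])
    return TwoComponentFit(
        component1=replace(c1, amplitude=float(popt[0])),
        component2=comp2,
        N1=float(popt[0]),
        N2=float(popt[1]),
        dN1=float(perr[0]),
        dN2=float(perr[1]),
        at_bound=at_bound,
    )


def fraction_error(N1: float, N2: float, dN1: float, dN2: float) -> tuple[float, float]:
    """Biallelic fraction and its propagated error.

    f2 = N2 / (N1 + N2);
    delta f2 = f2 * sqrt((dN2/N2)^2 + (dN1^2 + dN2^2) / (N1 + N2)^2).
    """
    total = N1 + N2
    if total <= 0:
        raise ValueError("N1 + N2 must be positive")
    f2 = N2 / total
    if N2 == 0:
        return 0.0, 0.0
    df = f2 * np.sqrt((dN2 / N2) ** 2 + (dN1**2 + dN2**2) / total**2)
    return float(f2), float(df)


def default_component2_bounds(comp1: GaussianComponent,
                              hist: Histogram2D) -> dict[str, tuple[float, float]]:
    """Biallelic-population bounds relative to the monoallelic component.

    The biallelic cloud shares the RFP channel with the monoallelic one
    but sits at elevated YFP; its shape is allowed the monoallelic shape
    within a factor of 2.
    """
    return {
        "mu_r": (comp1.mu_r - 2 * comp1.sigma_r, comp1.mu_r + 2 * comp1.sigma_r),
        "mu_y": (comp1.mu_y + 1.5 * comp1.sigma_y, float(hist.y_centers.max())),
        "sigma_r": (comp1.sigma_r / 2, comp1.sigma_r * 2),
        "sigma_y": (comp1.sigma_y / 2, comp1.sigma_y * 2),
        "rho": (-0.9, 0.9),
    }


def biallelic_fraction_series(
    events: pd.DataFrame,
    bin_width_h: float = 20.0,
    early_window_h: float = 20.0,
    n_bins: int = DEFAULT_BINS,
    bounds2: Optional[dict[str, tuple[float, float]]] = None,
) -> ActivationCurve:
    """Biallelic fraction per time bin from the two-step mixture fit.

    Only live events are used. The monoallelic component is fit on
    ``0 <= t < early_window_h``; each successive ``bin_width_h`` bin is
    then fit with that component's shape frozen. Bins whose fit fails are
    omitted with a warning, never silently dropped.
    """
    live = events[events["live"].astype(bool)].copy()
    if live.empty:
        raise ValueError("no live events")

    # shared histogram geometry across bins so component shapes transfer
    lr = _log_transform(live["r"].to_numpy())
    ly = _log_transform(live["y"].to_numpy())
    r_range = (float(lr.min()), float(lr.max()))
    y_range = (float(ly.min()), float(ly.max()))

    early = live[(live["time_h"] >= 0) & (live["time_h"] < early_window_h)]
    hist0 = histogram2d(early, n_bins=n_bins, r_range=r_range, y_range=y_range,
                        label="early window")
    comp1 = fit_single_component(hist0)
    if bounds2 is None:
        bounds2 = default_component2_bounds(comp1, hist0)

    t_max = float(live["time_h"].max())
    edges = np.arange(0.0, t_max + bin_width_h, bin_width_h)
    centers, fracs, errs, ns = [], [], [], []
    for lo_t, hi_t in zip(edges[:-1], edges[1:]):
        chunk = live[(live["time_h"] >= lo_t) & (live["time_h"] < hi_t)]
        label = f"[{lo_t:g}, {hi_t:g}) h"
        try:
            h = histogram2d(chunk, n_bins=n_bins, r_range=r_range,
                            y_range=y_range, label=label)
            fit = fit_two_component(h, comp1, bounds2)
            f2, df2 = fraction_error(fit.N1, fit.N2, fit.dN1, fit.dN2)
        except (ValueError, FitError) as exc:
            warnings.warn(f"time bin {label} omitted: {exc}")
            continue
        centers.append(0.5 * (lo_t + hi_t))
        fracs.append(np.clip(f2, 0.0, 1.0))
        errs.append(df2)
        ns.append(len(chunk))
    if not centers:
        raise FitError("every time bin failed to fit")
    return ActivationCurve(
        bin_centers=np.asarray(centers),
        f2obs=np.asarray(fracs),
        delta_f2obs=np.asarray(errs),
        n_per_bin=np.asarray(ns),
    )


@dataclass(frozen=True)
class FirstOrderFit:
    rate: float  # lambda or k, 1/h
    rate_ci95: tuple[float, float]
    plateau: float  # 1.0 when fixed
    plateau_ci95: tuple[float, float]


def fit_first_order(
    curve: ActivationCurve,
    plateau: Literal["fixed_1", "free_F"] = "fixed_1",
) -> FirstOrderFit:
    """Weighted first-order activation fit of a biallelic-fraction curve.

    ``fixed_1``: F_bi(t) = 1 - exp(-lambda t).
    ``free_F``:  y(t) = F (1 - exp(-k t)), the plateau form used when the
    activatable fraction is below 1. Weights are 1/delta_f^2; 95% CIs from
    the linearized covariance.
    """
    t = curve.bin_centers
    f = curve.f2obs
    n_par = 1 if plateau == "fixed_1" else 2
    if t.size < max(3, n_par + 1):
        raise ValueError("need at least 3 time bins (and more bins than parameters)")
    sig = np.where(curve.delta_f2obs > 0, curve.delta_f2obs, np.nan)
    sig = np.where(np.isnan(sig), np.nanmax(sig) if np.any(~np.isnan(sig)) else 1.0, sig)

    if plateau == "fixed_1":
        def model(tt, lam):
            return 1.0 - np.exp(-lam * tt)
        p0 = [max(1e-4, -np.log(max(1e-9, 1 - min(f.max(), 0.99))) / max(t.max(), 1.0))]
        popt, pcov = curve_fit(model, t, f, p0=p0, sigma=sig,
                               absolute_sigma=True, bounds=(0, np.inf), maxfev=20000)
        se = np.sqrt(pcov[0, 0])
        return FirstOrderFit(
            rate=float(popt[0]),
            rate_ci95=(float(popt[0] - 1.96 * se), float(popt[0] + 1.96 * se)),
            plateau=1.0, plateau_ci95=(1.0, 1.0),
        )

    def model(tt, F, k):
        return F * (1.0 - np.exp(-k * tt))

    p0 = [min(max(f.max(), 0.05), 1.0), 1.0 / max(t.max(), 1.0)]
    popt, pcov = curve_fit(model, t, f, p0=p0, sigma=sig, absolute_sigma=True,
                           bounds=([0, 0], [1.0, np.inf]), maxfev=20000)
    se = np.sqrt(np.diag(pcov))
    return FirstOrderFit(
        rate=float(popt[1]),
        rate_ci95=(float(popt[1] - 1.96 * se[1]), float(popt[1] + 1.96 * se[1])),
        plateau=float(popt[0]),
        plateau_ci95=(float(popt[0] - 1.96 * se[0]), float(popt[0] + 1.96 * se[0])),
    )


def read_flow_csv(path) -> pd.DataFrame:
    """Read a flow-event table (columns time_h, r, y, live; header mandatory)."""
    df = pd.read_csv(path)
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"flow CSV missing columns: {missing}")
    return df
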