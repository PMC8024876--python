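"""Synthetic inputs for every fitting stage in the package.

Each generator is a documented statistical model whose ground truth the
downstream fit must recover:

* flow-cytometry time courses — two correlated bivariate Gaussian clouds
  in log10-intensity space (log-normal on the linear scale, matching flow
  practice) whose mixing fraction follows a first-order activation
  process;
* time-lapse live/dead counts — an exact stochastic birth-death process
  with per-cell exponential loss of dead-cell detectability;
* dead-cell tracking curves — empirical survival of detectability from
  exponentially distributed disappearance times.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from episwitch.activation_fitting import GaussianComponent
from episwitch.population_dynamics import PopulationCounts

# Default clouds: monoallelic (RFP-high / YFP-low) and biallelic
# (RFP-high / YFP-high), well separated in YFP (~10 sigma), mildly
# correlated as for size-driven common-mode intensity variation.
DEFAULT_COMP1 = GaussianComponent(
    amplitude=1.0, mu_r=3.0, mu_y=1.0, sigma_r=0.25, sigma_y=0.25, rho=0.3
)
DEFAULT_COMP2 = GaussianComponent(
    amplitude=1.0, mu_r=3.0, mu_y=3.0, sigma_r=0.25, sigma_y=0.25, rho=0.3
)


def component_overlap(comp1: GaussianComponent, comp2: GaussianComponent) -> float:
    """Separation diagnostic: Mahalanobis-like distance between the means.

    Distance in units of the pooled per-axis standard deviation; values
    above ~4 mean the mixture is well identifiable.
    """
    dr = comp1.mu_r - comp2.mu_r
    dy = comp1.mu_y - comp2.mu_y
    sr = np.hypot(comp1.sigma_r, comp2.sigma_r) / np.sqrt(2)
    sy = np.hypot(comp1.sigma_y, comp2.sigma_y) / np.sqrt(2)
    return float(np.hypot(dr / sr, dy / sy))


def _draw_component(comp: GaussianComponent, n: int, rng: np.random.Generator) -> np.ndarray:
    """n samples of (log r, log y) from one correlated Gaussian."""
    cov = np.array(
        [
            [comp.sigma_r**2, comp.rho * comp.sigma_r * comp.sigma_y],
            [comp.rho * comp.sigma_r * comp.sigma_y, comp.sigma_y**2],
        ]
    )
    return rng.multivariate_normal([comp.mu_r, comp.mu_y], cov, size=n)


def simulate_flow_timecourse(
    lambda_: float,
    comp1: GaussianComponent = DEFAULT_COMP1,
    comp2: GaussianComponent = DEFAULT_COMP2,
    sample_times: Sequence[float] = tuple(np.arange(10.0, 100.0, 20.0)),
    n_per_time: int = 2000,
    start_fraction2: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-channel flow events whose biallelic fraction activates first-order.

    At time t each cell is biallelic (component 2) with probability
    ``start + (1 - start)(1 - exp(-lambda t))``; intensities are drawn
    from the corresponding correlated Gaussian in log10 space and
    exponentiated to the linear scale. All events are flagged live
    (backgrounds and dead cells are assumed removed upstream).
    """
    if not (0 <= start_fraction2 <= 1):
        raise ValueError("start_fraction2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    for t in sample_times:
        p2 = start_fraction2 + (1.0 - start_fraction2) * (1.0 - np.exp(-lambda_ * t))
        is2 = rng.random(n_per_time) < p2
        logs = np.empty((n_per_time, 2))
        n2 = int(is2.sum())
        if n_per_time - n2:
            logs[~is2] = _draw_component(comp1, n_per_time - n2, rng)
        if n2:
            logs[is2] = _draw_component(comp2, n2, rng)
        frames.append(
            pd.DataFrame(
                {
                    "time_h": t,
                    "r": 10.0 ** logs[:, 0],
                    "y": 10.0 ** logs[:, 1],
                    "live": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_population(
    kb: float,
    kd: float,
    delta: float,
    X0: int,
    Y0: int,
    sample_times: Sequence[float],
    seed: int = 0,
    max_cells: int = 1_000_000,
) -> PopulationCounts:
    """Exact stochastic birth-death counts with dead-cell clearance.

    Live cells divide at ``kb`` per cell and die at ``kd`` per cell; each
    dead cell independently becomes undetectable at rate ``delta``.
    Detected-dead counts are tracked by simulating the detectable-dead
    pool as a third species (death feeds it, clearance drains it).
    Raises if the live population exceeds ``max_cells``.
    """
    if min(kb, kd, delta) < 0:
        raise ValueError("rates must be >= 0")
    sample_times = np.asarray(sample_times, dtype=float)
    rng = np.random.default_rng(seed)
    t = 0.0
    x, y = int(X0), int(Y0)
    out_x = np.empty(sample_times.size)
    out_y = np.empty(sample_times.size)
    i = 0
    t_end = float(sample_times[-1])
    while True:
        total = kb * x + kd * x + delta * y
        t_next = t + (rng.exponential(1.0 / total) if total > 0 else np.inf)
        while i < sample_times.size and sample_times[i] < t_next:
            out_x[i] = x
            out_y[i] = y
            i += 1
        if i >= sample_times.size or t_next > t_end:
            break
        t = t_next
        u = rng.uniform(0, total)
        if u < kb * x:
            x += 1
        elif u < (kb + kd) * x:
            x -= 1
            y += 1
        else:
            y -= 1
        if x > max_cells:
            raise RuntimeError(
                f"population exceeded {max_cells} cells; shorten the horizon"
            )
    return PopulationCounts(times=sample_times, X=out_x, Y=out_y)


def simulate_detected_fraction(
    delta: float,
    n_cells: int = 30,
    seed: int = 0,
    tau_grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical 'fraction detected' curve from tracked dead cells.

    Disappearance times of ``n_cells`` dead cells are drawn from
    Exp(delta) (all detectable at tau = 0); the empirical survival curve
    is evaluated on ``tau_grid`` (default: 10 equal steps to the 90th
    percentile of the draws).
    """
    if n_cells < 5:
        raise ValueError("n_cells must be >= 5")
    rng = np.random.default_rng(seed)
    if delta <= 0:
        tau = tau_grid if tau_grid is not None else np.linspace(0, 40, 9)
        return np.asarray(tau, dtype=float), np.ones(len(tau))
    times = rng.exponential(1.0 / delta, size=n_cells)
    if tau_grid is None:
        tau_grid = np.linspace(0.0, float(np.quantile(times, 0.9)), 10)
    tau_grid = np.asarray(tau_grid, dtype=float)
    frac = np.array([(times > tau).mean() for tau in tau_grid])
    frac[tau_grid == 0] = 1.0
    return tau_grid, frac
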