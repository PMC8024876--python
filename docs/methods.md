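# Methods

This note documents the models, estimators and numerical choices behind
`episwitch`, and what the synthetic-data generators do and do not emulate.

## The scientific setting

A developmentally timed gene (the motivating case is *Bcl11b*, the T-cell
commitment factor) sits in a silent, H3K27me3-marked, compacted chromatin
state for days — several cell generations — before switching on
stochastically, all-or-none, at a constant probability per unit time. The
timing is tunable by the activities of the H3K27 methyltransferase (PRC2)
and demethylases (Kdm6a/b), by transcription factors, and is independent
of the cell-division rate. The package implements stochastic models that
probe which molecular mechanisms can produce this combination of
properties, together with the quantification pipeline used to measure
activation kinetics and population dynamics from single-cell data.

## Stochastic engine

Continuous-time Markov reaction systems are simulated with the direct
(cumulative-propensity inversion) Gillespie method. DNA replication is a
deterministically scheduled event at exact multiples of the cell-cycle
length `T_div`: the pending exponential waiting time is truncated at the
boundary and redrawn afterwards, which is exact because the exponential
distribution is memoryless. The absorbing ("gene active") predicate is
evaluated after every reaction and after every scheduled event, since
replication itself can trigger dissolution in the compaction model.

Ensemble sub-seeds are spawned from the master seed with
`numpy.random.SeedSequence.spawn`, so ensembles are reproducible and
independent of evaluation order.

For systems without scheduled events and an enumerable reachable state
space (default cap 50,000 states), `exact_mfpt` assembles the generator of
the absorbed chain by breadth-first search and solves the linear system
`Q tau = -1` for the mean first-passage time. This solver is the
independent oracle against which the Monte-Carlo engine — and the
compiled kernels below — are validated.

Compiled (numba) kernels reimplement the same dynamics for the two
workhorse models; the pure-Python engine remains the reference
implementation, and the test suite checks both paths against `exact_mfpt`.
When the read-write feedback spans the whole array, the lattice model
reduces *exactly* to a birth-death chain on the total methylation count
(all sites see the same methylated fraction), and a dedicated O(1)-per-event
chain kernel is used.

## Methylation read-write (M) model

A linear array of `N` nucleosomes, each methylated or not. An unmethylated
nucleosome is methylated at `k0 + k_fb * f^hill_n`, where `f` is the
methylated fraction within `reach` nucleosomes (edge-clipped, no
wraparound); a methylated nucleosome is demethylated at `alpha`. At
replication each mark is retained with probability 1/2 (random segregation
of parental histones). Activation = total methylation first reaching
`theta_act * N` (absorbing; activation is modeled as an irreversible
first-order event).

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| N | 100 | a ~20 kb polycomb domain at ~200 bp/nucleosome |
| k0 | 0.42 /h | basal (PRC2 allostery-independent) methylation |
| k_fb | 20 /h | read-write feedback gain; turnover on the minutes scale, far faster than division |
| reach | 99 (whole locus) | the compacted locus lets the read-write complex act domain-wide; locus-wide coupling produces the collective, extremely methylation-sensitive switching this model is known for |
| hill_n | 3 | cooperative allosteric stimulation of the methyltransferase; with the basal rate this makes the silent (high-methylation) state a genuine metastable well with a saddle well below half-methylation, so replication dilution (which halves methylation) lands safely inside the basin and escape is fluctuation-driven |
| alpha | 1.95 /h | sets the silent-state methylated fraction at ~0.86 and a mean activation time of ~2.5e4 h (deep silence) |
| T_div | 20 h | typical progenitor cell-cycle length |
| theta_act | 0.1 | activation when < 10% of marks remain |

The headline property of this model is its *extreme sensitivity*: raising
`alpha` to 2.6 lowers the silent methylated fraction by ~0.10 (0.86 →
0.76) while shortening the mean activation time several-hundred-fold
(≈ 450–550× in calibration runs with two independent seed sets). Weaker,
local-reach or low-cooperativity variants of the model (e.g. reach 3,
hill 1) remain available through the parameters but are measurably less
sensitive (20–30× per 10 points): with replication present, escape there
is dominated by post-replication dilution, whose ruin probability is
invariant to an overall rate scaling, capping the sensitivity. The
locus-wide, cooperative, fast-turnover regime is therefore the documented
default. The silent lifetime at these defaults is ~10^3 cell cycles; deep
silence of this order is what the sensitivity demands — a silent state
lasting only 5–10 cycles cannot exhibit a 300-fold response to a 10-point
methylation shift in this model class.

The silent methylated fraction is measured as a time average over a full
cell cycle (one replication period), across replicate trajectories that
have not yet activated (quasi-stationary average conditional on survival);
replicates are discarded if they activate within the window, and the
estimator errors out if a majority do.

## Passive-dilution comparator

No enzymatic turnover: marks are lost only by replication halving
(optional small residual demethylation). Activation time is then simply
the waiting time for ~log2(1/theta_act) divisions, and the mean activation
time is proportional to `T_div` — the division-*dependent* behaviour the
timed switch does not show.

## Methylation-compaction (MC) model

Nucleosomes are methylated/unmethylated and inside/outside a compacted,
phase-separated assembly of size `C_T`. Exchange with the assembly scales
with its surface area, `C_T^(2/3)` (nucleosomes join and leave only
through the surface): association flux `k_on * C_T^(2/3) * (a_me*M_out +
u_adhesion*U_out)` and dissociation flux `k_off * C_T^(2/3) *
(d_me*M_in + U_in)/C_T` (total surface exchange apportioned by bulk
composition — the well-mixed-assembly approximation). Methylation promotes
compaction (`a_me >= 1`, `d_me <= 1`) and compaction promotes methylation
(`gamma_c >= 1`, `beta_c <= 1`). When `C_T < C_min` the assembly dissolves
irreversibly and the gene activates. Replication halves methylation and
ejects a fraction `phi` of the assembly.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| N | 60 | ~12 kb compaction domain |
| k_me, alpha | 20 /h | histone methylation/demethylation on the minutes scale — the fast turnover that the division-independence of the switch requires |
| gamma_c, beta_c | 2, 0.5 | compaction shields marks and aids writing |
| k_on, k_off | 0.4/7, 0.4 /h | slow surface exchange (minutes-to-hours); the ratio sets the silent out-of-assembly pool at ~5–6 nucleosomes (C_T ≈ 0.9 N) |
| a_me, d_me | 1.2, 1/1.2 | *weak* methylation-compaction coupling |
| u_adhesion | 1 | methylation-independent nucleosome adhesion (H3K9me/HP1-like pathways, absorbed into one scale) |
| C_min | 47 | dissolution threshold just below the silent occupancy |
| phi | 0.01 | replication barely perturbs the condensate |
| T_div | 20 h | as above |

At these defaults the model reproduces, simultaneously: mean activation
~130 h (the experimental scale); exponential activation-time statistics
(CV ≈ 0.95–1.0); graded tunability (2-fold enzyme-rate changes shift the
activation rate < 2-fold, with demethylase inhibition slowing and
methyltransferase inhibition speeding activation); sensitivity to a
10-point methylation shift ~15–20× smaller than the M model's; and
division independence (< 20% variation in mean time across T_div = 10–40 h),
which is lost when the enzymatic rates are scaled below the division rate
(0.02/h), as reported for the mechanism.

Three calibration findings shaped these defaults, and all deviate from the
obvious first guesses:

1. **The out-pool geometry forces a high silent occupancy.** Because
   association is proportional to the out-of-assembly pool, the assembly
   size performs an M/M/∞-like random walk with a Poisson-tail escape
   probability. Gradedness (fold-change < 5 per 2-fold enzyme change)
   bounds the gap between the silent out-pool (~5) and the dissolution
   threshold (~13) to a few nucleosomes, so `C_min` sits at ~0.78 N and
   the silent `C_T` at ~0.9 N. Low thresholds (e.g. `C_min = 10`) make
   the silent state effectively infinitely stable at any exchange rate.
2. **Division independence requires fast enzymes, slow exchange, and a
   nearly conserved assembly at replication.** The methylation dip after
   replication must be too short (minutes) for the slowly exchanging
   assembly to respond, and the direct ejection `phi` must remove at most
   ~1 nucleosome; otherwise dissolution becomes replication-driven and
   the mean time tracks `T_div` (max/min ratios of 2–4 were measured for
   `phi >= 0.05` or slow enzymes).
3. **Tunability requires the methylation-independent adhesion pathway and
   weak coupling.** With `a_me = 3` the activation rate changes 6–30-fold
   per 2-fold enzyme change (not graded); `a_me = 1.2` gives the observed
   graded response. Setting `u_adhesion = 0` (association only through
   methylated nucleosomes, rebalanced to the same silent state) raises the
   sensitivity coefficient ~4-fold — the documented negative control
   showing that nucleosomes must adhere even without the mark for timing
   to be tunable.

### Transcription-factor extensions

TFs bind site-nucleosomes outside the assembly (pioneer-factor access
requires exposure) at `k_bind_per_conc * tf_conc * (free sites) *
(out fraction)` and unbind at `k_unbind`. *Blocking*: bound sites are
removed from the association pool (apportioned by out-pool composition).
*Demethylation*: while any site is bound, up to `N_R` methylated
nucleosomes demethylate at `alpha * alpha_mult`. Dose-response curves are
summarized by a censoring-aware exponential rate per concentration and a
Hill fit (maximal rate, EC50). At the defaults, adding blocking sites
(N_B = 1 → 4) raises both the maximal activation rate and the EC50;
demethylating TFs shift activation only slightly unless their reach `N_R`
is large.

## Timing estimators

- Mean activation time: mean of uncensored times with a seeded percentile
  bootstrap (1,000 resamples); when censoring exceeds 10%, the
  censoring-aware exponential MLE (total time at risk / events) is
  reported alongside, since the naive mean is biased low.
- Exponential rate: censoring-aware MLE `lambda = d / sum(t)` with the
  exact chi-square CI; diagnostics (CV of times, KS distance/p-value
  against the fitted exponential) are always reported and only *flag* the
  fit, never silently reject it. On fully uncensored data the MLE equals
  1/(sample mean) exactly.
- Sensitivity coefficient: `s = |ln(T2/T1)| / |m2 - m1|` — a finite
  difference on the (ln mean-time, methylated-fraction) plane. The
  quantity plotted in the source literature is not defined there; this
  definition is the package's documented stand-in, applied identically to
  both models so the contrast is meaningful.
- Dose and cell-cycle scans wrap first-passage ensembles over rate
  multipliers (enzyme inhibition in silico) or `T_div` lists.

## Flow-cytometry quantification

Per 20-h time bin, the 2-D histogram of log10 intensities (64x64 bins,
floor at 1 before the log) is fit by weighted least squares (Poisson
weights `sqrt(max(count,1))`) to a sum of bivariate Gaussians in the
standard parameterization. Step 1 fits the monoallelic component alone on
an early window (t < 20 h) where essentially no cells are biallelic;
step 2 fits each bin with that component's shape frozen (amplitude free)
and the biallelic component constrained to bounds (by default: same RFP
mean within 2 sigma, YFP mean above the monoallelic cloud, shape within a
factor of 2). The biallelic fraction is `f2 = N2/(N1+N2)` with the
propagated error

    delta f2 = f2 * sqrt((dN2/N2)^2 + (dN1^2 + dN2^2)/(N1+N2)^2),

with `dN_i` from the fit covariance (a Poisson reading of `dN_i` is the
obvious alternative; covariance is the documented default). The source
equation for the mixture density contains typographical corruption (a
repeated sigma_r^2 and a sign error in the cross term); the standard
bivariate normal is implemented deliberately. The fraction-vs-time curve
is fit by weighted nonlinear least squares to `1 - exp(-lambda t)` or the
plateau form `F (1 - exp(-k t))`; the two agree when the plateau is 1.

Background correction is out of scope: synthetic events are generated
post-correction and real inputs are assumed background-corrected. FCS
parsing is out of scope (CSV with columns `time_h, r, y, live`).

## Population dynamics

Live cells divide at `k_b` and die at `k_d`; `X(T) = X0 exp(K T)` with
`K = k_b - k_d`. Dead cells remain detectable with probability
`P(tau) = exp(-delta tau)`; the detected-dead prediction is the discrete
convolution `Y(T) = Y0 P(T) + sum_t X(t) k_d dt P(T-t)` with the sum over
the sampling grid (the grid-step convention; whether the source sum is
over frames or hours is ambiguous, and the grid step is the documented
choice). Fitting is staged: `delta` from tracked dead-cell disappearance
curves; `K, X0` from the live counts; `k_d` by SSE grid search (60
log-spaced points over two decades around a pilot estimate, one
refinement pass) with a linearized-regression t interval (numeric Jacobian
dY/dk_d, residual variance sse/(n-1)); `k_b = K + k_d` with CIs summed in
quadrature. A minimum at a grid edge is an error ("widen grid"), not a
result.

## Synthetic data

- Flow time courses: two correlated bivariate Gaussian clouds in log10
  space (log-normal intensities, as in flow practice), ~10 pooled sigma
  apart by default; each cell is biallelic with probability
  `start + (1-start)(1 - exp(-lambda t))`. All events carry
  `live = True` — the live/dead classifier of real pipelines is replaced
  by this flag.
- Population counts: exact stochastic birth-death simulation with a
  detectable-dead pool drained at `delta` per cell.
- Clearance curves: empirical survival of detectability from `n` (default
  30) exponential disappearance times.

What a green test establishes: that each estimator recovers the truth of
the statistical model it assumes, at realistic sample sizes. What it does
not establish: robustness to autofluorescence, compensation artifacts,
gating errors, misclassified dead cells, non-log-normal intensity tails,
or density-dependent growth — none of which the generators emulate.

## Numerical choices and degenerate inputs

- All randomness flows from a single integer seed through
  `SeedSequence.spawn`; sub-seeds are reduced mod 2^31 for the compiled
  kernels.
- A system whose propensities are all zero holds its state to `t_max`
  (trajectory of one segment); a fully censored ensemble is returned
  flagged, not raised, except where an estimator genuinely needs events.
- Negative propensities are a hard error naming the reaction and state.
- `exact_mfpt` raises when the absorbing set is unreachable or the state
  space exceeds the cap, advising Monte-Carlo estimation.
- Mixture fits clamp fractions to [0, 1]; bins with too few events or
  failed fits are omitted with a warning, never silently dropped.
- `f2 = 0` when `N2 = 0` (with zero error), avoiding 0/0 in the error
  propagation.

## Known limitations

- The compaction model is zero-dimensional (well-mixed assembly); no
  polymer geometry, no PRC1/HP1 species, no H3K9 methylation as a
  separate mark (its adhesive effect is absorbed into `u_adhesion`).
- The M model's default uses locus-wide feedback; nucleation-limited
  (short-reach) switching is supported but has different, weaker
  sensitivity.
- Exponential-fit diagnostics use uncensored times only for the KS
  distance.
- Bootstrap CIs are percentile CIs; no BCa correction.
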