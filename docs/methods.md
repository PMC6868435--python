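# Methods

This note documents the models behind `fretforce`, the defaults and why
they were chosen, the numerical machinery, and what the synthetic-data
generators do and do not emulate.

## Tether mechanics and the loading schedule

The construct is pulled through a ~48.5 kb λ-DNA handle held in an
optical trap. The handle is modelled as an extensible worm-like chain
(Marko–Siggia interpolation plus an enthalpic F/K term) in series with a
harmonic trap:

    F = (kBT/P)·[1/(4(1 − x/Lc + F/K)²) − 1/4 + x/Lc − F/K]
    x_total(F) = x_wlc(F) + F/κ

Defaults: contour length Lc = 16 400 nm (λ-DNA), persistence length
P = 50 nm, stretch modulus K = 1200 pN (standard double-stranded DNA
elasticity), trap stiffness κ = 0.046 pN/nm, stage speed v = 455 nm/s,
stage ramp 14 000 → 16 960 nm, kBT = 4.11 pN·nm (298 K; the experiment
temperature is not otherwise pinned). κ and the ramp endpoint were
chosen once so the protocol reproduces the instrument's printed
behaviour — the ramp tops out at ~28 pN after ~6.5 s, with the endpoint
inside the documented 16.8–17.2 µm window — and are not tuned further.
The model predicts ~1 pN at the 14 µm start rather than the ~0.3 pN the
instrument reads there; the discrepancy is noted rather than hidden,
and it is immaterial downstream because the kinetics are insensitive to
the sub-piconewton start of the ramp.

The full Marko–Siggia relation is solved numerically everywhere
(Brent's method on the monotone bracket), rather than switching to the
high-force interpolation, to keep a single branch. `wlc_extension` and
`force_at_stage` are mutual inverses to a relative 10⁻⁶ over
0.1–60 pN. Single-stranded DNA revealed by unfolding follows a freely
jointed chain (0.63 nm/nt contour, 1.5 nm Kuhn length); it is used only
by the generator's optional mechanistic FRET mode.

## Loading-rate convention

The instantaneous loading rate Ḟ(F) = v / (dx_total/dF) varies from
~0.35 pN/s near 1 pN to ~9 pN/s near 28 pN, because the tether is very
compliant at low force. If the rupture hazard is accumulated against
this full nonlinear schedule, the predicted rupture-force density
acquires a large low-force peak — the molecule simply spends a long
time below ~3 pN. The classical Dudko–Szabo treatment of rupture-force
histograms instead assumes a constant loading rate, and the published
kinetic parameters for these constructs are forward-consistent only
under that convention: with it they reproduce the printed force
clusters (~8 and ~16 pN), with the instantaneous schedule they do not.

The pipeline therefore defaults to `rate_mode="effective"`: a single
constant rate equal to the force-averaged instantaneous loading rate
over the ramp, ⟨Ḟ⟩_F = (1/(F_max−F_start))·∫Ḟ(F)dF = 7.12 pN/s for the
default schedule. Averaging over force rather than time weights the
rate by where ruptures are actually observed instead of by the slack,
low-force dwell. `rate_mode="instantaneous"` (the physically complete
schedule) and explicit numeric rates remain available everywhere, and
generator and analyzer always share one convention so recovery tests
close the loop regardless of the choice.

## Dudko–Szabo kinetics

Rate law, with ΔG‡ in units of kBT and ν ∈ {1/2, 2/3, 1}:

    k(F) = (1/τᵤ(0))·(1−u)^{1/ν−1}·exp{ΔG‡·[1−(1−u)^{1/ν}]},
    u = νFΔx‡/(ΔG‡·kBT)

ν = 1/2 (cusp barrier) is the pipeline default; ν = 1 is implemented
through the exact Bell exponent FΔx‡/kBT so the equivalence holds to
machine precision, and ν = 1/2 uses the expansion u(2−u) to avoid
cancellation. The barrier vanishes at F_c = ΔG‡kBT/(νΔx‡); rates are
only defined for F < F_c and a domain violation reports F_c.

The rupture-force density p(F) = [k/Ḟ]·exp(−∫k/Ḟ) is tabulated by
trapezoidal accumulation of the hazard on a 3001-point force grid
(conservation ∫p + S holds to better than 10⁻⁴; an independent
time-domain Euler oracle in the test suite confirms the density to
~10⁻³ relative). Components whose F_c lies inside the ramp are
truncated there and their residual survival is reported explicitly —
for ν = 1/2 the rate vanishes at F_c, so survivors at F_c are genuine
model mass, not a numerical artifact. Sampling inverts the cumulative
hazard (inverse-CDF); draws that exhaust the ramp are returned as
censored.

**Fitting** is maximum likelihood on raw rupture forces (not
least-squares on binned histograms): censored cycles contribute
survival factors, or, with `truncated=True`, the per-sample densities
are renormalized by 1−S for data known to contain only ruptured
cycles. Each component carries (log Δx‡, log τᵤ(0), log ΔG‡); mixture
weights ride a softmax. Optimization is multi-start Nelder-Mead
(default 20 starts, jittered) initialized from quantile-seeded 1-D
k-means clusters, each polished by a short single-component pre-fit —
the DS mixture likelihood has many shallow local optima and trades Δx‡
against τᵤ(0) and ΔG‡ along long flat valleys, so initialization
matters more than iterations. A penalty keeps at least one component's
F_c above the largest observed force (the mixture must be able to
explain every observation); weaker components may have smaller F_c and
simply contribute zero density beyond it, which is essential because
real weak clusters (F_c ≈ 12 pN) coexist with forces near 24 pN.
Standard errors come from a central-difference observed-information
matrix computed in log space; flat or boundary-pinned directions are
eigenvalue-floored so their variances stay finite but honestly large,
and weight uncertainties follow by the delta method.

## Zero-force smFRET

Corrections: I_D′ = I_D − bg_D, I_A′ = I_A − bg_A − α·I_D′,
E = I_A′/(I_A′+I_D′); frames with non-positive total are invalid. The
instrument's background and crosstalk values are not published, so the
defaults are zero and real data must supply them. Molecules are
summarized by the mean of their first ten valid frames; the donor-only
peak (acceptor-dark molecules at E ≈ 0) is removed at a default
threshold of 0.1. Histograms use 0.02-wide bins on [−0.1, 1.2).

Mixture decomposition fixes component centers and widths — calibrated
from single-position variants where available, otherwise σ = 0.05, a
typical shot-noise-limited smFRET peak width at these intensities
(peak widths are not published) — and estimates only the weights by EM
(convergence at Δlog-likelihood < 10⁻⁸, monotonicity asserted every
iteration). Standard errors come from the observed information of the
(K−1)-dimensional weight parameterization; weights that collapse to
zero are flagged as boundary estimates. Soft EM weights are the primary
output; maximum-posterior hard counts are also emitted for integer
event reporting.

## Pulling-cycle analysis

Cycles are split at the stage-velocity sign change; direction flags
must agree. An abrupt transition is a change of the 3-sample running
median by ≥ 0.3 completed within ≤ 3 samples (60 ms at 20 ms sampling)
and persisting beyond the transition midpoint for ≥ 5 samples; the
event force is read where the smoothed E first crosses the midpoint
(E_before+E_after)/2. Running medians, not means, are used throughout
for robustness to single-frame blinks. Classification uses the lowest
5-sample running-median E over the stretch half: complete (< 0.15, with
an abrupt event), Type I ([0.15, 0.30)), Type II ([0.30, 0.45)),
no unfolding (≥ 0.45). The boundaries bracket the experimental anchors
(E ~ 0, ~0.2, ~0.37); 0.45 separates Type II from ultrastable cycles. A
gradual decline below 0.15 without an abrupt event is grouped with
Type I (strand-slippage pathway). Cycles that never reach 90 % of the
maximum force (photobleaching, truncation) are excluded with a warning.
When several abrupt events share a half-cycle the largest-ΔE event
defines the cycle's f_unfold; all events stay in the table. Refolding
forces come only from abrupt refold events — gradual Type I/II
relaxations produce none. Cycles classified no-unfolding enter the
kinetic fit as right-censored observations at the maximum force.

## Vectorial folding

Baseline = median of the first 10 frames; a trace that never leaves
baseline ± 0.1 (for ≥ 3 consecutive smoothed frames) is not unwound.
The terminal state is the median of the last 20 frames: [0.68, 0.80]
is the direct 3′-GQ band, [0.55, 0.68) the 5′-GQ band, (0.15, 0.55)
unfolded ssDNA; the 0.68 boundary sits midway between the observed
anchors (0.73 vs 0.62). The direct label additionally requires a
pause-free rise, a pause being ≥ 10 consecutive smoothed frames inside
a ± 0.05 window at intermediate E (0.2–0.55) — an operational version
of a criterion the experiments leave qualitative. Rise duration runs
from the first persistent departure from the baseline band to the
first persistent entry into the terminal band. The folded fraction
uses a Wilson interval; donor-only exclusion is off by default in this
assay because the duplex baseline (E ≈ 0.07) lies inside the nominal
acceptor-dark zone and un-unwound duplexes belong in the denominator.

## Synthetic data

The generators produce every input the pipeline consumes, with ground
truth emitted next to the traces and byte-level reproducibility given a
seed.

* **TIRF traces** (30 ms/frame): a molecule draws a subpopulation and a
  steady E level from the component Gaussian — static heterogeneity, as
  individual telomeric GQ molecules hold their E for tens of seconds —
  then per frame the 500-count total intensity is split between
  channels with Poisson shot noise, donor→acceptor crosstalk
  (default α = 0.05), channel backgrounds (10 counts) and an
  exponential photobleaching truncation (0.02 s⁻¹).
* **Pulling cycles** (20 ms/sample): force-versus-time from the tether
  schedule; per cycle an archetype E(F) curve interpolated monotonically
  (PCHIP) through published anchors — complete: flat 0.80 then rupture
  to an ssDNA baseline declining from ~0.10; Type I: 0.75 → 0.245 at
  28 pN; Type II: 0.68 → 0.37; plus a single-register variant and an
  ultrastable archetype. Rupture-bearing archetypes draw their rupture
  force from the Dudko–Szabo hazard *conditioned on rupture within the
  ramp* (the archetype label asserts that the cycle unfolds; censored
  behaviour is carried by the ultrastable archetype), and refold
  abruptly at a force drawn uniformly from 1–7 pN on relaxation, the
  window in which refolding is observed. Archetypes either follow exact
  per-label counts or evolve across cycles as a Markov chain over a
  switching matrix. Gaussian E-noise (default σ = 0.03) is applied
  before conversion to counts.
* **Vectorial traces**: linear rises from the duplex baseline (0.07) to
  the class terminal E, scaled so the *detectable* band-to-band rise
  time matches the drawn value (normal around 0.7 s), or a flat
  baseline for un-unwound molecules; default class fractions correspond
  to ~47 % folding, of which ~64 % direct and ~22 % 5′-type.

What the generators do **not** emulate: camera drift and bead-tracking
noise, γ-factor (quantum-yield) asymmetries, acceptor blinking and
photophysics beyond a donor-only fraction, the true functional shape of
E(F) between published anchor points, hysteresis in gradual unfolding,
and any structural (CD/NMR) observables. Passing recovery tests
therefore demonstrate that the analyzers invert the assumed statistical
structure at matched noise — not that real traces satisfy that
structure.

## Problem sizes and numerical defaults

Simulation-backed tests run at desk scale chosen to keep estimator
error well inside the asserted tolerances: 200 molecules for mixture
decomposition (50 seeds for the bias check), 263 cycles for
classification recovery, 500 rupture forces over 20 seeds for kinetic
parameter recovery, 2000 draws for sampler-versus-quadrature KS checks.
Density grids use 3001 points (1201 inside the fit loop); EM tolerance
10⁻⁸; Nelder-Mead with xatol 10⁻⁵ / fatol 10⁻⁷ and a final restart at
the incumbent optimum.

## Known limitations

* The (Δx‡, τᵤ(0), ΔG‡) triple is weakly identified from a single
  loading rate; the reported observed-information errors are honest
  about this (τᵤ(0) uncertainties are on the log scale and can be
  large). Multi-speed protocols would break the degeneracy but are out
  of scope.
* The effective-rate convention is a modelling choice; predictions at
  forces below ~2 pN depend on it and should not be over-interpreted.
* Refolding is phenomenological (uniform window); no refolding kinetic
  model is fitted.
* The classification thresholds are operational definitions of
  qualitative experimental classes; molecules whose archetypes drift
  within a cycle are not modelled.
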