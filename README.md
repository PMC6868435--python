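# fretforce

Analysis pipeline for single-molecule **fluorescence–force spectroscopy** of
human telomeric G-quadruplexes (GQs): combined smFRET / optical-trap
experiments in which a five- or six-repeat telomeric DNA
(GGG(TTAGGG)₄T and longer) is pulled through a λ-DNA tether while its
FRET efficiency reports the fold state.

It is written for single-molecule biophysicists who need to

* turn donor/acceptor photon traces into FRET-efficiency histograms and
  decompose them into positional GQ subpopulations (3′ GQ, 5′ GQ,
  long-loop GQ) with a constrained Gaussian mixture;
* classify force-ramp pulling cycles (complete / Type I / Type II /
  no unfolding), extract unfolding and refolding forces at the midpoints of
  abrupt FRET transitions, and accumulate cycle-to-cycle switching
  statistics;
* fit rupture-force distributions with the Dudko–Szabo kinetic model and
  reconstruct force profiles from the fitted parameters;
* classify real-time *vectorial folding* traces from the superhelicase
  unwinding assay;
* generate synthetic traces with matched statistical structure, so every
  stage is testable without instrument data.

## Models

**Rupture kinetics (Dudko–Szabo, ν = 1/2 default).** The unfolding rate
under force is

    k(F) = (1/τᵤ(0)) · (1 − νFΔx‡/ΔG‡)^{1/ν−1} · exp{ ΔG‡/kBT · [1 − (1 − νFΔx‡/ΔG‡)^{1/ν}] }

with transition-state distance Δx‡ (nm), zero-force lifetime τᵤ(0) (s) and
activation free energy ΔG‡ (here in kBT; ΔG‡ above denotes the energy
ΔG‡·kBT in the bracketed ratio). ν = 1 recovers the Bell model exactly;
the barrier vanishes at the critical force F_c = ΔG‡·kBT/(νΔx‡). Under a
loading schedule with rate Ḟ the rupture-force density is
p(F) = [k(F)/Ḟ(F)]·S(F) with survival S(F) = exp(−∫ k/Ḟ dF). Fitting is
censored maximum likelihood on raw rupture forces: cycles that never
unfold by the maximum force enter as survival terms.

**Tether mechanics.** The λ-DNA handle is an extensible worm-like chain
(Marko–Siggia with a stretch modulus, Lc = 16.4 µm, P = 50 nm,
K = 1200 pN) in series with a harmonic trap (κ = 0.046 pN/nm). Driving
the stage at 455 nm/s from 14.00 to 16.96 µm yields the experiment's
force ramp (~1 → ~28 pN in ~6.5 s) and the loading rate Ḟ(F) used by the
kinetics.

**Zero-force smFRET.** E = I_A′/(I_A′+I_D′) from background- and
crosstalk-corrected intensities; molecules are summarized by the mean of
their first ten frames, donor-only molecules (E ≈ 0) are excluded, and
subpopulation weights are obtained by expectation–maximization with the
component centers/widths fixed to variant-calibrated values.

## Worked example

```python
import fretforce as ff

schedule = ff.loading_schedule()          # 14.00 -> 16.96 um at 455 nm/s
print(f"ramp: {schedule.f_start:.2f} -> {schedule.f_max:.1f} pN in {schedule.duration:.2f} s")
print(f"effective loading rate: {schedule.effective_rate:.2f} pN/s")

na_params = ff.DsParams(dx_dagger=4.3, tau0=50.0, dG_dagger=6.5)   # hTel28, 100 mM Na+
density = ff.rupture_pdf(na_params, schedule)
print(f"predicted f_unfold peak: {density.mode():.1f} pN (survival at F_max: {density.survival:.2f})")

samples = ff.sample_ruptures(na_params, schedule, n=500, seed=1)
fit = ff.fit_ds(samples, n_components=1, schedule=schedule, n_starts=6, seed=1)
c, u = fit.mixture.components[0], fit.uncertainties[0]
print(f"refit from {len(samples.forces)} ruptures + {samples.n_censored} censored cycles:")
print(f"  dx_dagger = {c.dx_dagger:.2f} +/- {u['dx_dagger_se_nm']:.2f} nm")
print(f"  tau_u(0)  = {c.tau0:.0f} s   (ln-scale se {u['se_ln_tau0']:.2f})")
```

prints

```
ramp: 0.98 -> 28.3 pN in 6.51 s
effective loading rate: 7.12 pN/s
predicted f_unfold peak: 7.2 pN (survival at F_max: 0.17)
refit from 423 ruptures + 77 censored cycles:
  dx_dagger = 4.28 +/- 0.25 nm
  tau_u(0)  = 44 s   (ln-scale se 0.26)
```

The stage ramp reaches ~28 pN in ~6.5 s; the sodium-condition kinetic
parameters place the unfolding-force peak near 8 pN; and a censored
maximum-likelihood refit of forces simulated from those parameters
recovers Δx‡ and τᵤ(0) within their standard errors — a closed
generator → analyzer loop.

The same stages are available from the shell:

```bash
fretforce simulate-pulling --seed 2 --out sim/
fretforce analyze-pulling --traces sim/pulling_cycles.tsv --out analysis/
fretforce fit-ds --ruptures analysis/rupture_forces.tsv --out fit/
```

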