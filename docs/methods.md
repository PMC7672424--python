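# Methods

`gqfret` analyses diffusion-based single-molecule FRET (smFRET) measurements
of a doubly labelled nucleic acid — the motivating system is a dimeric human
telomeric G-quadruplex carrying a 5′ donor (FAM) and 3′ acceptor (Cy5) —
recorded on a confocal microscope with pulsed interleaved excitation (PIE).
Because such raw photon data are rarely deposited, the package pairs the
analysis chain with a synthetic photon-stream generator with known ground
truth, so every stage is testable end to end.

## Photon-stream model (simulate)

A measurement at ~100 pM labelled DNA is a sparse stream of photon detection
events. The generator draws:

- **Burst arrivals** as a Poisson process at `burst_rate` (default 20 s⁻¹).
- **Burst sizes** from a geometric law with mean `burst_size_mean` (default
  60 photons), heavy-tailed like real diffusing-molecule transits; a
  lognormal option exists.
- **Burst temporal profile**: the photons of a burst are spread uniformly
  over an exponential-duration window (mean 1 ms). A diffusion model would
  add nothing observable, since the downstream burst search operates on 1-ms
  bins.
- **Conformational state** per burst from the configured `(true_E, weight)`
  mixture (default: low-FRET 0.6 at 38%, high-FRET 0.8 at 62%).
- **Photon partition**: a fraction `aa_fraction` (default 0.25) of each
  burst's photons falls in the acceptor-excitation PIE window (all acceptor
  channel); the remaining donor-window photons split donor/acceptor
  binomially with acceptor probability equal to the state's `true_E`.
- **Background** as independent Poisson streams per detection class
  (defaults 300/150/150 counts s⁻¹ for DD/DA/AA).

Ligand binding follows conformational selection: the ligand stabilizes the
pre-existing high-FRET conformation, so the high-FRET weight at total ligand
concentration *L* (μM) is

    f(L) = f0 + (f_inf − f0) · L / (K_D + L).

The hyperbolic form in *total* ligand is justified because the DNA (~100 pM)
is 3–4 orders of magnitude below the μM ligand concentrations, making ligand
depletion negligible; an exact quadratic 1:1 form is available
(`population_from_binding_depletion`) for cases where it is not.

Burst rate, burst size and background defaults are not measured values from
any specific instrument; they were fixed once at magnitudes typical for
~100 pM confocal measurements (a few tens of detected molecules per second,
tens of photons per transit, sub-kHz background) and produce realistic
per-burst shot noise (σ_E ≈ 0.08–0.10 for ≥25-photon bursts).

What the generator deliberately omits: Brownian-dynamics photon physics
(intensity profiles across the confocal volume), photobleaching and blinking
(suppressed chemically in the motivating experiments), detector dead time and
afterpulsing, and spectral cross-talk (which the correction algebra handles
on the analysis side). Passing tests therefore demonstrate the correctness of
the analysis chain under an idealized but statistically faithful photon
model, not robustness to instrument artefacts.

## Burst search (bursts)

Photon traces are binned at fixed width (1 ms default) into half-open bins
[k·w, (k+1)·w); a boundary photon belongs to the later bin. Maximal runs of
consecutive bins with ≥ `threshold` counts (practical range 4–9, default 5)
are candidate bursts; candidates with fewer than `min_photons` total photons
(default 25, all channels and excitation windows combined) are discarded. A
`gap_tolerance` parameter (default 0, i.e. strict contiguity) can merge runs
across short below-threshold gaps. The threshold range 4–9 is a soft bound:
values outside it trigger a validation warning, not an error.

One property worth noting: the number of detected bursts is *not* monotone in
the threshold — raising it can split one long run into several runs that each
still clear `min_photons`. What is monotone is the set of photons inside
bursts (shrinks with threshold) and the burst count as a function of
`min_photons`. The test suite asserts exactly these.

## Efficiency and stoichiometry (fret)

Standard PIE/ALEX correction algebra with background subtraction
proportional to burst duration, donor leakage `alpha`, acceptor direct
excitation `delta` and detection factor `gamma`:

    F_A = F_DA − α·F_DD − δ·F_AA
    E   = F_A / (F_A + γ·F_DD)
    S   = (γ·F_DD + F_A) / (γ·F_DD + F_A + F_AA)

Default factors (γ=1, α=δ=0, zero background) reduce E to the proximity
ratio. Calibration values are instrument-specific user configuration. E is
not clamped to [0, 1]: clamping would distort the mixture tails; the default
histogram range is −0.1 to 1.1 accordingly. Bursts with a non-positive
corrected denominator (background-only episodes) are excluded and logged. A
stoichiometry gate (default 0.25–0.85) for rejecting singly labelled
molecules is provided but applied only when requested.

## Mixture decomposition (mixture)

The per-burst E values are fitted with a K-component Gaussian mixture by
maximum likelihood (EM), not by least squares on the binned histogram —
binning discards information. A histogram least-squares backend is kept as a
cross-check, and the tests require the two to agree on well-separated data.

Numerics: deterministic initialization (means at the k-quantiles, shared
sigma = pooled SD/k, uniform weights); convergence at log-likelihood gain
< 1e−8 or 500 iterations; sigma floor 1e−3 against singular collapse;
components always reported sorted by mean, so the high-FRET species is the
last component. K defaults to 2 (the two-species regime of the motivating
system); BIC-based selection (`select_components`) is available but never
automatic.

**Titration fits share components.** Fitting every titration point with
free means and sigmas is unidentifiable near saturation: once the low-FRET
species is nearly gone, EM splits the dominant peak instead of resolving the
remnant, and the extracted fractions (hence K_D) are badly biased. Since the
species' FRET efficiencies do not shift with ligand — only their populations
do — the pipeline fits the lowest-concentration point freely and fits all
other points with means and sigmas fixed to that reference, estimating only
the weights (`fit_mixture(..., fixed_means=, fixed_sigmas=)`). Fully
independent per-point fits remain available via
`PipelineConfig(share_components=False)`.

## Binding isotherm (binding)

`build_titration` extracts the high-FRET (largest-mean) component weight per
concentration; `fit_kd` fits (K_D, f0, f_inf) by weighted nonlinear least
squares (weights ∝ per-point burst counts; unweighted optional), with a
deterministic multistart over log10(K_D) ∈ {−2…2} and box bounds
f0, f_inf ∈ [0, 1]. f_inf is free, not pinned to 1, because a residual
low-FRET population can persist at the highest measured concentration.
Standard errors come from the Gauss–Newton curvature at the optimum (delta
method for the log-parameterized K_D). A flat series raises an
identifiability error; a dynamic range below 0.05 produces a warning flag.

## Melting curves (melting)

Thermal melting curves (e.g. ellipticity at 295 nm, a wavelength diagnostic
for antiparallel/hybrid G-quadruplex folds) are fitted with a Boltzmann
sigmoid with horizontal baselines,

    s(T) = low + (high − low) / (1 + exp((T_m − T)/width)),

initialized from the extremum of the smoothed numerical derivative; that
derivative midpoint is also reported as a cross-check, with a warning when
the two disagree by > 1 °C. Sloped baselines are available by flag. The
no-transition check uses the amplitude the fitted sigmoid realizes *within*
the measured window, so a noise fit whose nominal midpoint escapes the range
cannot masquerade as a transition. ΔT_m = T_m(+ligand) − T_m(−ligand),
signed. Whether a published T_m table derives from sigmoid fits or
derivative maxima is often unstated; reporting both makes the comparison
explicit.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed; titration streams derive
per-point seeds from (master seed, point index) via a fixed hash, so runs
are reproducible photon for photon, and the pipeline writes a configuration
hash into every output file. The bundled verification runs use 5000 burst-E
values for ensemble recovery, ~240 s of simulated acquisition per titration
point (≈3000 detected bursts/point) for the full-pipeline K_D check, and
1 °C-step melting curves over 4–95 °C — sizes chosen to put Monte-Carlo error
well inside the assertion tolerances.

## Known limitations

- No shot-noise-aware distribution model (PDA) or lifetime analysis; mixture
  sigmas absorb shot noise empirically rather than being tied to burst size.
- No gamma self-calibration; correction factors are user input.
- The sliding-window (m-photons-in-Δt) burst search common in other packages
  is intentionally absent; the binned search mirrors the handwritten
  procedure this package reimplements.
- No Hill/cooperativity or global multi-dataset binding fits, and no van 't
  Hoff ΔH/ΔS extraction from melting curves.
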