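# gqfret

Single-molecule FRET (smFRET) burst analysis for resolving the
conformational ensemble of G-quadruplex nucleic acids and quantifying
ligand-driven population shifts — with a synthetic PIE photon-stream
generator, so the whole chain runs and is tested without any instrument
data.

## Who it is for and what it does

A G-rich sequence such as the human telomeric repeat folds into
G-quadruplexes, and multimeric constructs (two or more stacked quadruplex
units) populate several coexisting conformations. In a confocal smFRET
measurement of a freely diffusing donor/acceptor-labelled molecule, each
single-molecule transit appears as a photon burst whose FRET efficiency

    E = F_A / (F_A + γ·F_DD)

reports the dye–dye distance of that one molecule. The burst E histogram is
decomposed into a multi-Gaussian mixture: each component is one FRET species
and its weight is that species' population. Titrating a
conformation-selective ligand shifts the populations without moving the
species' efficiencies (conformational selection), and the high-FRET fraction
follows the 1:1 isotherm

    f(L) = f0 + (f_inf − f0) · L / (K_D + L),

from which the dissociation constant K_D is fitted. A companion module fits
melting curves with a Boltzmann sigmoid to obtain melting midpoints T_m and
the ligand-induced stabilization ΔT_m.

The stages (each usable on its own): `simulate` (synthetic PIE photon
streams, titrations, melting curves), `bursts` (1-ms binned burst search),
`fret` (PIE-corrected E and stoichiometry S per burst), `mixture`
(Gaussian-mixture EM with deterministic initialization and BIC selection),
`binding` (isotherm / K_D fitting), `melting` (T_m / ΔT_m), plus file I/O, a
composed pipeline and a `gqfret` command-line interface.

## Worked example

Simulate a two-species ensemble (low-FRET E=0.6 at 38%, high-FRET E=0.8 at
62%) for 120 s, search bursts, compute per-burst efficiencies, and
decompose the distribution; then run a seven-point ligand titration with
ground-truth K_D = 0.53 μM through the full pipeline:

```python
from gqfret import (SimulationConfig, BindingModelParams, simulate_photon_stream,
                    search_bursts, BurstSearchParams, burst_efficiencies,
                    fit_mixture, simulate_titration)
from gqfret.fret import CorrectionFactors
from gqfret.pipeline import analyze_titration

cfg = SimulationConfig(duration=120.0, seed=7)
stream = simulate_photon_stream(cfg)
bursts = search_bursts(stream, BurstSearchParams(threshold=5, min_photons=25))
corr = CorrectionFactors(bg_rate_dd=300, bg_rate_da=150, bg_rate_aa=150)
e, s, ok = burst_efficiencies(bursts, corr)
model = fit_mixture(e[ok], k=2)
print(f"{stream.size} photons, {len(bursts)} bursts, {ok.sum()} retained")
print(f"species means  : {model.means.round(3)}")
print(f"populations    : {(100*model.weights).round(1)} %")

binding = BindingModelParams(kd=0.53, f0=0.62, f_inf=1.0)
points = simulate_titration(cfg, binding, [0, 0.125, 0.25, 0.5, 1, 2, 4])
_, series, fit = analyze_titration(points, corrections=corr, k=2)
print(f"high-FRET fractions: {series.fractions.round(3)}")
print(f"K_D = {fit.kd:.2f} +/- {fit.se_kd:.2f} uM  (f0={fit.f0:.2f}, f_inf={fit.f_inf:.2f})")
```

Output:

```
220028 photons, 1604 bursts, 1604 retained
species means  : [0.6   0.804]
populations    : [42.1 57.9] %
high-FRET fractions: [0.56  0.629 0.688 0.777 0.806 0.857 0.911]
K_D = 0.47 +/- 0.09 uM  (f0=0.56, f_inf=0.94)
```

The mixture fit recovers the species positions (0.6/0.804 vs the true
0.6/0.8) and populations to within a few points of shot-noise scatter
(42/58% vs the true 38/62% at ~1600 bursts); the high-FRET fraction climbs
hyperbolically with ligand and the fitted K_D (0.47 ± 0.09 μM) brackets the
0.53 μM ground truth. The same chain is available from the shell:

```bash
gqfret simulate --config sim.yaml --out stream.h5
gqfret fret --stream stream.h5 --out bursts.csv --histogram hist.csv
gqfret fit-mixture --table bursts.csv --out mixture.json --print
gqfret melt --curve apo.csv --curve holo.csv
```

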