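# ramantrap

Toolkit for automated single-particle Raman trapping analysis. It implements
the full software stack of a trap-and-measure platform — acquisition control,
spectral preprocessing, solution-marker particle sizing and mixture-resolution
chemometrics — together with a physics-based virtual instrument that emulates
trapped-particle spectral streams, so the whole pipeline runs and is tested
without hardware.

## Modules

| Module | Purpose |
| --- | --- |
| `ramantrap.spectra` | `Spectrum`/`Band` types, two-column & matrix CSV I/O, truncation, cosmic-spike repair, asymmetric-least-squares (Whittaker) baseline subtraction, Savitzky-Golay smoothing, area normalisation, band intensities/areas |
| `ramantrap.instrument` | Virtual instrument: pseudo-Voigt component library, spectral rendering with the marker volume-displacement law, Brownian escape/arrival kinetics (Stokes-Einstein + chi-square(3) return probability, Monte-Carlo cross-check), composition arithmetic, population presets |
| `ramantrap.controller` | Acquisition state machine: threshold calibration, iteration loop with high-SNR capture and laser disabling, JSON-Lines trapping log, iteration-number check, post-threshold filtering |
| `ramantrap.sizing` | Marker displacement ratio `(A_t - A_p)/A_p`, calibration of mean ratio vs log10 volume, per-particle size inversion, distribution statistics (PDI) |
| `ramantrap.chemometrics` | Two-component 1-D Gaussian-mixture EM, PCA, Ward clustering (with "not classified" outlier rule), NIPALS PLS-DA with venetian-blinds CV, group band-area ratios, acquisition-order bias test |
| `ramantrap.kinetics` | Reaction time traces (population / single-particle-hold modes), completion-time estimation, photostability checks |

## CLI

```bash
ramantrap simulate --preset dppc_mixture --n 100 --seed 1 --out scratch/sim
ramantrap acquire  --n 50 --seed 1 --out scratch/acq
ramantrap size     --ratios ratios.csv --out sizes.csv
ramantrap classify --matrix spectra.csv --method gmm --band 2105 --out gmm.json
ramantrap kinetics --matrix spectra.csv --times times.csv --bands 2129,2116,1331 --out trace.csv
ramantrap prep     --matrix spectra.csv --out preprocessed.csv
```

`simulate` presets: `sizing`, `dppc_mixture`, `aba_mixture`,
`functionalisation`, `cuaac_kinetics`.

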