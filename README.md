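# trxmap

Post-merging analysis for time-resolved serial femtosecond crystallography
(TR-SFX) of photoactivated proteins, built around the pump-probe study of a
light-driven receptor whose chromophore isomerizes within a picosecond.
After the upstream steps of a TR-SFX experiment (indexing, integration,
merging) one is left with merged intensities for a resting "dark" state and
one or more pump-probe "light" time delays.  `trxmap` implements the chain
that turns those into interpretable structural signal:

1. **Lattice-translocation-disorder (LTD) correction.**  A crystal in which
   a fraction κ of layers is shifted by a fractional vector **t** scatters
   as two coherent domains, modulating intensities by
   `G(h) = (1−κ)² + κ² + 2κ(1−κ)cos(2π h·t)`.  The defect shows up as an
   off-origin Patterson peak at ±**t**; `trxmap` detects it, scans κ from 0
   to 0.5 in 0.01 steps until the peak is flattened, and divides the
   intensities by `G(h)` to recover single-domain data.
2. **Difference Fourier maps.**  French–Wilson amplitude estimation,
   relative (k, B) scaling, the standard rejection rules (|F|/σF ≥ 3,
   resolution window 9–1.8 Å), and synthesis of `Fo(light) − Fo(dark)` maps
   with phases of the refined dark model, plus sphere integration of
   difference density around chosen atoms (e.g. for a fluence-response
   curve).
3. **Extrapolated structure factors and activation level.**  A partial
   photoproduct occupancy A (percent) is amplified to notional full
   occupancy by the linear approximation
   `F_extra = (100/A)·(Fo(light) − Fo(dark)) + F_calc`.  The activation
   level itself is determined from the data: `2F_extra − F_calc` maps are
   computed for A = 10…50%, negative density around reporter atoms is
   integrated (1.5 Å radius, 1.5σ cut-off), and the elbow of the resulting
   curve — flat while A is overestimated, rising once it is underestimated
   — is located as the intersection of two fitted straight lines.
4. **Pump-laser dosimetry.**  Gaussian-beam fluences and power densities,
   the upper-bound excitation metric σF/hν, and heating-based
   photons-per-molecule estimates `ΔT·C_P/(c·N_A·hν)` with the temperature
   jump read from the principal SVD component of difference solution
   scattering against a calibration.

Because deposited XFEL datasets are far too large for a test suite, the
package ships a first-class synthetic generator: seeded toy two-state
crystals (point-atom direct-summation structure factors, coherent mixing of
a minority light state, optional LTD and Gaussian noise) on which every
stage is exercised end-to-end as a parameter-recovery problem.

## Worked example

Simulate a noisy two-state dataset with 20% light occupancy and an injected
translocation defect (t = (0, 0.245, 0), κ = 0.25), then run the full chain:

```sh
trxmap simulate --seed 7 --alpha 0.2 --noise 0.03 \
    --ltd-t 0 0.245 0 --ltd-kappa 0.25 --outdir fixture
trxmap ltd detect fixture/dark.tsv
```

```json
{ "t": [0.0, 0.25, 0.0], "peak_height_sigma": 24.368,
  "background_sigma": 0.429, "flatness": 23.939 }
```

The off-origin Patterson peak is found within one grid step of the injected
vector, 24σ above background.  The umbrella pipeline (config in YAML):

```sh
printf 'light: fixture/light.tsv\ndark: fixture/dark.tsv\nmodel: fixture/model.pdb\noutput_dir: out\n' > config.yaml
trxmap run config.yaml
```

reports `kappa_star: 0.24` (true 0.25; 3% intensity noise) and
`A_star: 19.628` (true 20%), and writes the corrected amplitudes, the
difference map (CCP4), the κ-scan and activation-scan tables (TSV) and a
provenance record under `out/`.  Closed-form dosimetry for a 5 µJ, 480 nm,
100 fs pulse focused to 47 µm FWHM:

```sh
trxmap dose --pulse-energy 5e-6 --fwhm 47e-4 --duration 100e-15 \
    --wavelength 480e-9 --epsilon 34000
```

```
photon energy            4.138e-19 J = 59.6 kcal/mol
peak fluence             200 mJ/cm2
FWHM-average fluence     144 mJ/cm2
peak power density       1998 GW/cm2
sigma*F/h*nu (FWHM avg)  45.3
```

i.e. ~45 photons incident per chromophore absorption cross-section per
pulse — an upper bound on excitation that the heating-based estimate
(`photons from heating`, ~1.2 at ΔT = 0.016 K) undercuts by more than an
order of magnitude.

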