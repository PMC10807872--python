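# nirsim

Simulation and analysis of **hyperspectral time-resolved (TR) near-infrared
spectroscopy** with single-pixel compressive acquisition, built around the
problem of monitoring blood oxygenation and cytochrome-c-oxidase (CCO) redox
state in deep tissue through a static superficial layer.

The package is aimed at diffuse-optics researchers who want a desk-scale,
fully synthetic testbed for the question: *how much of a chromophore change
in a deep layer does each analysis method actually recover?* It provides

- a **time-domain diffusion forward model** of diffuse reflectance for
  homogeneous semi-infinite and two-layer (slab over half-space) liquid
  phantoms, plus a photon-packet Monte-Carlo oracle for validation;
- an **instrument chain**: exponentially-modified-Gaussian instrument
  response functions (IRF), convolution, TCSPC-style Poisson counting at a
  capped count rate;
- a **differential-Hadamard single-pixel model** of the spectrometer's DMD
  acquisition, with exact inversion when uncompressed and regularized
  reconstruction (order-weighted l1 or smoothness-ridge in a DCT basis) at
  compression rates up to 90%;
- the two **analysis pipelines** the device comparison rests on:
  - TR late-photon tail fitting: mu_a(lambda) = -m(lambda) c/n from the
    log-slope m of the DTOF tail over an after-peak window (50-20% or 5-1%
    of peak), then constrained unmixing
    `dmua(lambda) = dHb eps_Hb + dHbO eps_HbO + doxCCO eps_oxredCCO`
    with dHbO = -dHb (conserved total hemoglobin);
  - CW spectral-derivative fitting: dA(lambda) = dmua(lambda) L(lambda)
    (modified Beer-Lambert), second-derivative fit for dHb over 720-780 nm,
    then a raw-dA fit for doxCCO over 815-845 nm (the 830 nm CCO band),
    with pathlength from mean time of flight or from the water absorption
    feature with TR shape correction;
- an **experiment harness** reproducing the 11-level oxygenation-ladder
  error study (percent error of each method against ground truth) and
  deoxygenation/reoxygenation time courses with TR-vs-CW Spearman
  correlation.

## Worked example

```python
from nirsim import ExperimentConfig, run_ladder

summaries, table = run_ladder(ExperimentConfig(scene="two_layer",
                                               n_wavelengths=40))
for s in summaries:
    if s.chromophore == "dHb":
        print(f"{s.method:9s} dHb mean error {s.mean:7.1f} +/- {s.sd:.1f} %")
```

prints (40-wavelength desk scale)

```
CW        dHb mean error   -57.5 +/- 0.2 %
TR_50_20  dHb mean error   -23.8 +/- 2.7 %
TR_5_1    dHb mean error    12.8 +/- 2.7 %
```

i.e. through a 10 mm static top layer the CW analysis recovers only ~40% of
the true bottom-layer hemoglobin change (partial-volume contamination),
while the TR tail fits — which isolate late-arriving, deep-penetrating
photons — lose far less; the later 5-1% window is the most depth-faithful.
The same harness run on the homogeneous scene shows the CW method nearly
unbiased, which is the control that separates superficial-layer
contamination from method bias.

A command-line interface mirrors the library
(`nirsim experiment ladder --out d/`, `nirsim analyze-tr --container c.h5
--out tc.csv`, ...); DTOF/TPSF/IRF cubes travel in a small HDF5 container
and all analysis outputs are CSV.

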