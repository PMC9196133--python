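# mft — mean-field analysis tools for neuronal network models

`mft` computes statistics of large networks of leaky integrate-and-fire
(LIF) or binary neurons directly from model parameters, without simulation:

- **Stationary theory** (`mft.lif_stationary`): mean/variance of the
  synaptic input, the first-passage (Siegert) firing rate for instantaneous
  and exponentially filtered synapses (shifted-boundary colored-noise
  correction, `alpha = sqrt(2)|zeta(1/2)| ≈ 2.07`), and two self-consistency
  solvers (auxiliary-ODE integration and bounded least squares).
- **Linear response** (`mft.lif_dynamics`): complex transfer functions built
  from parabolic cylinder functions, Fourier-domain delay kernels (delta and
  zero-truncated Gaussian), the effective connectivity matrix, population
  power spectra, and the eigenvalue sensitivity measure with its
  amplitude/frequency projections.
- **Rate-model mapping and spatial stability** (`mft.rate_stability`):
  calibration of external Poisson rates to a target working point, low-pass
  fits of the transfer function, boxcar spatial profiles, and the Lambert-W
  solution of the delayed characteristic equation
  `(1 + lambda*tau) = c(k) exp(-lambda*d)` with a stability verdict
  (oscillation frequency, wavenumber, phase velocity).
- **Binary neurons** (`mft.binary`): erfc mean-activity self-consistency,
  reusing the same solvers.
- **Parameter handling** (`mft.models_io`, `mft.units`): a small yaml
  dialect (`{val, unit}` entries, nested lists for matrices), conversion to
  SI, model flavors `basic_ei` and `microcircuit8` that build derived
  parameters (full weight matrices from scalar weights and ratios,
  in-degrees from connection probabilities), a digest-keyed result cache,
  and HDF5 export/import.
- **Fixtures** (`mft.fixtures`): deterministic example networks
  (`ei_delta`, `ei_exp`, `microcircuit_like`, `ring_spatial`) and parameter
  sweeps.

## CLI

```sh
mft fixture ei_exp -o net.yaml        # emit an example parameter file
mft validate net.yaml                 # load + validate
mft rates net.yaml --method ode -o results.h5
mft spectra net.yaml --fmin 1 --fmax 400 --nf 400 --csv spectra.csv
mft sensitivity net.yaml --freq 63 --mode closest
mft stability net.yaml --delay 0.0015 --kmax 3e4 --nk 200 --branches -3:3
mft binary binary.yaml
mft export results.h5                 # inspect an HDF5 results file
```

An eight-population microcircuit parameterization is shipped at
`src/mft/data/microcircuit8.yaml` (see note below).

## Conventions

- Weights `J` are stored signed (inhibitory entries negative), in volts.
- Public frequency interfaces take ordinary frequency `f` in Hz
  (`omega = 2*pi*f` internally).
- The transfer function carries the stationary refractory factor
  `(1 - nu*tau_r)` so that its zero-frequency limit equals `d(phi)/d(mu)`
  of the full refractory rate formula.
- The Siegert integrand is evaluated as `erfcx(-s)` with the growing part
  expressed through `erfi`, so no explicit `exp(s^2)` factor is ever formed;
  deep subthreshold rates switch to a log-domain asymptotic expansion.
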