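# lifmass

Validation of second-order ("Freeman-type") neural mass models against a
stochastic conductance-based leaky integrate-and-fire (LIF) network.

The package simulates a noisy LIF network on a directed Erdős–Rényi graph
(mixed excitatory/inhibitory units, independent Poisson external drive),
feeds the recorded population-mean spike input into two derived mass
models — the conventional variant (CFM, constant forcing potential) and a
modified variant (MFM, instantaneous potential in the driving forces) —
and quantifies their agreement with the network's mean membrane potential
across the {connection probability p, excitatory fraction λ} plane:

- **spike-contrast** synchrony of the raster (multi-scale, averaged over
  bin sizes);
- **spectral** comparison: Hamming-windowed periodograms averaged over
  repetitions, median frequency, and a χ² statistic with a
  χ²-distribution significance bound;
- **temporal** comparison: lag-optimized cross-correlation of z-scored
  traces with Fisher-transform agreement classification.

## Layout

| module | contents |
| --- | --- |
| `lifmass.config` | `NetworkConfig` (all simulation parameters), `MassConfig` |
| `lifmass.network` | graph builders, Poisson drive, the Euler–Maruyama LIF simulator, drive recomputation from rasters |
| `lifmass.mass` | CFM/MFM integrators, analytic second-order filter response |
| `lifmass.synchrony` | spike-contrast |
| `lifmass.spectral` | spectrum estimation, median frequency, χ² comparison |
| `lifmass.temporal` | lagged correlation, effective sample size, Fisher test |
| `lifmass.sweep` | per-point orchestration, resumable {p, λ} sweeps, heatmaps |
| `lifmass.io` | text raster/trace formats, HDF5 bundles, YAML configs |

## CLI

All functionality is reachable through the `lifmass` command:

```sh
# simulate and store raster + drive + mean potential in an HDF5 bundle
lifmass simulate --n-units 2000 --p 0.2 --lam 0.8 --t-total 10000 \
    --seed 1 --out run.h5 --raster-out run_raster.txt

# drive a mass model with the recorded input
lifmass mass --variant cfm --drive run.h5 --out cfm.h5

# statistics
lifmass synchrony run_raster.txt
lifmass spectrum run.h5 --label LIF --out spec_lif.csv
lifmass chi2 spec_lif.csv spec_cfm.csv
lifmass correlate run.h5 --model CFM

# full reduced-scale parameter sweep (resumable, one CSV row per point)
lifmass sweep --p-values 0.05,0.1,0.2 --lambda-values 0.6,0.7,0.8,0.9 \
    --reps 5 --seed 0 --out sweep_out --plot
```

`simulate` accepts a YAML config file (`--config`) mirroring the
`NetworkConfig` field names; any flag overrides the file.

## Notes on conventions

- Drive series are rate densities (1/ms): a spike delivered in a bin
  contributes `1/(N·dt)` to its channel. The mass models consume the
  per-step spike input; `MassConfig.from_network` sets
  `drive_scale = dt` accordingly.
- The simulation kernel (numba, single-threaded) is bit-reproducible for
  a given config and seed; sweep repetition seeds derive from the master
  seed and the grid coordinates, so sweeps are order-independent and
  resumable.
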