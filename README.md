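# ringbind

Spiking-network model of working-memory feature binding: two ring-attractor
networks ("color" and "location") of conductance-based leaky
integrate-and-fire neurons, coupled by weak untuned AMPA excitation, plus
the full analysis stack used to characterize their dynamics — spike-count
cross-correlograms, synthetic LFPs, wavelet phase / phase-preservation
index, a mixture-of-Gaussians rate decoder, and a swap-error taxonomy
(memory / attentional / decoding swaps).

## Layout

| module | contents |
| --- | --- |
| `ringbind.netmodel` | population/synapse parameters, tuned circulant ring connectivity, capacity-2/3 conductance sets, size scaling |
| `ringbind.engine` | forward-Euler integration of the coupled networks (numba-accelerated), Poisson background drive, spike records, TSV/HDF5 I/O |
| `ringbind.protocol` | trial schedules: cues, 7.5x/50 ms binding pulse, delay, weak 0.5 s probe |
| `ringbind.analysis` | binned counts, cross/sliding correlations, correlogram spectra, alpha-kernel LFP, Welch peaks, Morlet phase, PPI, bump strength |
| `ringbind.decoder` | rate profiles, two-Gaussian weighted EM, readout + on-target/swap labels, swap diagnosis |
| `ringbind.fixtures` | oscillatory Poisson ensembles with programmed phases/reversals (analysis test bed) |
| `ringbind.experiments` | conductance sweeps, swap-rate and readout-histogram experiments, PPI contrast, result I/O |

## CLI

```sh
ringbind simulate --load 2 --delay-ms 1500 --scale 8 --out results/
ringbind sweep --axis g_ee_ampa=0.05:0.14:3 --trials 3 --out results/
ringbind swaps --delays 1000,2000,3000 --distances 45,168.75 --trials 10
ringbind decode-hist --trials 100 --delay-ms 3000
ringbind ppi --n-on-target 10 --n-swap 10
ringbind fixtures --category memory
```

`--scale N` shrinks both populations by `N` while preserving each neuron's
total synaptic drive (unitary conductances are multiplied by `N`); the
printed network is `--scale 1`. `ringbind decode-hist --full-scale
--trials 1000` reproduces the paper-scale readout ensemble (very slow:
hours to days on one CPU).

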