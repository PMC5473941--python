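# dynquant

Quantification toolkit for the in-vitro and cellular assays used to study
cytoplasmic dynein auto-inhibition: how the motor switches between its
self-dimerized phi-particle, the open conformation, and the activated
dynein–dynactin–cargo-adaptor (DDB) complex.

The package covers five analysis stages, each usable on its own:

- **Single-molecule kinetics** (`dynquant.kinetics`) — microtubule binding
  rates from TIRF kymograph event tables, dwell-time survival curves, a
  two-phase exponential decay fit, and the lattice-site-normalized
  dissociation constant
  `Kd = (koff / kon) × N_sites`, with `N_sites = 13 × (1000 / 8.1) × ½ ≈ 802`
  accessible sites per µm of a 13-protofilament microtubule
  (`koff = 1/τ_fast`). Also Beer–Lambert molarity (ε = 797 340 M⁻¹cm⁻¹ per
  dynein monomer) and dimer labeling efficiency `1 − (1 − p)²`.
- **Motility** (`dynquant.motility`) — processive-event classification
  (duration > 0.625 s, unidirectional displacement > 500 nm), normalized
  processive-event rates, and gliding velocimetry from leading-edge tracks.
- **EM population statistics** (`dynquant.empop`) — conformational-class
  proportions (phi / open / ambiguous) via 25-micrograph × 9-round
  resampling without replacement, inter-motor distance histograms (2.5 nm
  bins), and motor-orientation (inverted / parallel / ambiguous) summaries.
- **SEC quantification** (`dynquant.sec`) — chromatogram baseline
  normalization at 5 mL, peak-window AUC fractions, and unpaired t-test
  group comparison.
- **Cell-image quantification** (`dynquant.imaging`) — 11-slice SUM
  projections, 12×12 ROI centrosome/spindle-pole intensities with
  mean-subtraction or median-ratio background correction, 3×3 ROI live-cell
  foci time courses with backward tracking, and the nonparametric
  Shapiro–Wilk / Bartlett / Kruskal–Wallis / paired-Wilcoxon workflow with
  max-p aggregation across experiments.

Every stage has a matching generator in `dynquant.synthetic` that emulates
its raw data (Poisson arrivals with two-phase exponential dwells quantized
to the 125 ms frame cycle, per-micrograph Poisson particle counts with
multinomial labels, multi-Gaussian chromatograms, Gaussian foci with shot
noise, …) together with a ground-truth sidecar, so the whole pipeline is
testable without any microscope data.

## Worked example

```python
import dynquant as dq

# generate a synthetic single-molecule binding assay: 50 microtubules,
# 0.58 nM motor, 360 s movies at 8 fps, two-phase dwells (w=0.8, 0.3 s / 3 s)
obs, truth = dq.simulate_binding_assay(
    mt_lengths_um=[10.0] * 50, duration_s=360.0, conc_nM=0.58, seed=1,
)
result = dq.analyze_binding_assay(obs)
print(result["fit"].summary())
print(f"kon  = {result['summary'].kon_mean:.4f} events/um/nM/s")
print(f"Kd   = {result['summary'].kd_uM:.1f} uM (truth {truth['kd_uM']:.1f})")
```

prints

```
Two-phase exponential decay fit
===============================
  n points          147
  w_fast            0.8079
  tau_fast_s        0.3120
  tau_slow_s        2.8166
  koff (1/tau_f)    3.2049 /s
  R-squared         0.99978
kon  = 0.0196 events/um/nM/s
Kd   = 131.0 uM (truth 133.3)
```

The fit recovers the generating fast-phase weight (0.81 vs 0.8) and time
constant (0.312 s vs 0.3 s); the Kd comes out within 2% of the generator's
ground truth. (The Kd of a real motor depends on its measured kon — the
synthetic demo uses a deliberately small per-site association rate.)

The end-to-end driver runs all five stages on synthetic data and writes a
deterministic report bundle (metrics JSON, CSV tables, checksummed run log):

```sh
dynquant run --seed 1 --out out/
```

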