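# dsgc-occlusion

A population model of On-Off direction-selective ganglion cells (DSGCs) and
the downstream decoders that read them out during smooth versus interrupted
("occluded") motion.

## The problem

On-Off DSGCs fire maximally for motion in a preferred direction, and retinas
carry mosaics of subtypes preferring opposite directions. Their spiking
receptive field (RF) is displaced toward the *preferred side* — the side a
preferred-direction stimulus enters first. A consequence: when a moving edge
emerges from behind an occluder, it abruptly activates only the exposed
preferred-side RF region of nearby cells, so cells of the *against-motion*
subtype fire a null-direction response at the same moment that with-motion
cells fire their preferred response. This package simulates that population
response and quantifies two proposed functions of the synchrony:

1. **Position coding.** A labeled-line (population-vector) decoder,

   x̂ = Σᵢ rᵢ x̃ᵢ/wᵢ² ÷ Σᵢ rᵢ/wᵢ² ,  x̃ᵢ ~ N(xᵢ, wᵢ²),

   estimates the edge position from per-10 ms firing rates rᵢ, RF-center
   labels xᵢ and RF widths wᵢ. Because both subtypes' labels are displaced
   toward their preferred sides, the coincidently firing cells' labels
   center exactly on the occluder exit — the population error in locating
   the re-emerging edge drops severalfold during the 125 ms after emergence.
2. **Event detection.** A difference-of-Gaussian temporal filter, fit to the
   null-direction occlusion transient and applied as a matched filter to the
   summed rate of against-motion cells near the occluder, flags occlusion
   trials with near-perfect accuracy at realistic baseline firing rates.

All inputs are synthetic and parameterized: mosaics with Gaussian
nearest-neighbor spacings (39 ± 16 µm), ±14.1° preferred-direction jitter,
RF widths 1.25 × N(88, 14.8²) µm, rectified-sine responses with
beta-distributed onsets, and sub-Poisson (variance 0.4) spike-count noise on
10 ms bins. See `docs/methods.md` for the model in full.

## Worked example

Simulate one paired block (shared mosaic and parameters, full-field vs
occluded) and decode the bar position around the emergence:

```python
import dsgc_occlusion as d

cfg = d.ExperimentConfig(seed=1)
res = d.paired_window_errors(cfg, speed=330.0, baseline_rate=0.0,
                             n_blocks=5, n_reps=5, seed=1)
print(f"full-field window RMSE: {res['rmse_ff_um']:.0f} um")
print(f"occluded   window RMSE: {res['rmse_occ_um']:.0f} um")
print(f"position-error decrease: {res['pct_position_decrease']:.0f}%")
```

prints

```
full-field window RMSE: 157 um
occluded   window RMSE: 36 um
position-error decrease: 77%
```

The full-field error (~150 µm ≈ 5° of visual angle at 31 µm/°) is the lag of
a causal population response — active cells trail the edge by about half a
response duration. In the occluded run the emergence burst is pinned to the
occluder exit, so the windowed error collapses to the label-noise floor.

The numbered drivers under `analysis/` run the paper-level experiments and
write tidy CSVs under `results/`:

```bash
python analysis/01_build_mosaic.py        # mosaic + spatial statistics
python analysis/02_decoding_sweep.py      # speeds x baselines error summary
python analysis/03_coincidence_roc.py     # ROC/accuracy per baseline rate
python analysis/04_metrics_validation.py  # metrics round-trip on synthetic data
```

For example `04_metrics_validation.py` prints:

```
rectified-sine round trip over 25 noisy 6-trial blocks (peak 40 Hz, var 0.4):
  peak:     41.4 Hz (true 40.0), median |err| 7.0%
  onset:    0.789 s (true 0.800)
  duration: 0.924 s (true 0.900)
  quality index: 0.60 (gate at 0.45)
tuning: preferred 115.6 deg (true 120), DSI 0.68
dF/F0 transient peak: 0.51 (true 0.5)
```

## Layout

```
src/dsgc_occlusion/   library: geometry, responses, stimulus, decoding,
                      coincidence, metrics, synthetic, experiments, config
analysis/             numbered narrative drivers (write to results/)
scripts/acceptance.py headline-quantity reproduction
tests/                pytest suite incl. acceptance-criteria tests
docs/methods.md       model description, defaults, limitations
```
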