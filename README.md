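# endozone

Quantitative image analysis of the postsynaptic **endocytic zone (EZ)** —
the stable clathrin-coated structure that sits beside the postsynaptic
density (PSD) of excitatory synapses and locally internalizes synaptic
membrane proteins. The package is written for neuroscientists and
microscopists who need the full quantitative chain behind EZ studies:

* **SMLM nanoscale maps** — localization-table preprocessing
  (consecutive-frame merging, 15 nm precision cutoff), DBSCAN clustering
  (eps 0.2 µm/100 pts for PSDs, 0.35 µm/50 pts for clathrin), polygon
  borders, signed border-to-centroid distances, FWTM length/width,
  primary/secondary structure classification, and border-scaled **ring
  density profiles** (rings at 0–20–…–160% of the cluster outline;
  density = per-ring localization fraction / area fraction, normalized to
  unit sum) that reveal whether an endocytic protein is enriched at the
  EZ edge.
* **Live-cell dynamics** — kymograph construction, Fourier direction
  filtering into stationary / anterograde / retrograde components (masks
  on the 2D spectrum: the `k_t ≈ 0` band vs the two `sign(k_x·k_t)`
  half-plane pairs), intensity coefficient of variation, greedy
  nearest-neighbour track linking, and lifetime classification with the
  strict short (< 3 min) / persistent (> 9 min) boundaries.
* **FRAP kinetics** — double normalization (background, reference
  bleaching, baseline, re-zeroing at the bleach frame) and bounded
  least-squares fitting of `I(t) = A(1 − e^{−Kt})` for the mobile
  fraction `A` and time constant `τ = 1/K`.
* **Morphometry** — max/min Feret diameters, circularity `4πA/P²`, and
  EZ–PSD association via a fixed-diameter circular ROI (default 0.79 µm)
  with per-PSD counts of clathrin-coated structures.
* **Synthetic data** — parametric generators for every input above, with
  ground truth (true borders, molecule→localization maps, per-direction
  movie components, true lifetimes and FRAP parameters), so the whole
  pipeline is testable without any acquisition.

## Worked example

Generate a synapse scene with an edge-enriched accessory protein
(Beta(8,2) radial law), run the nanoscale chain, and profile the
accessory channel against the clathrin border:

```python
import numpy as np
from endozone import synthetic, loc_io, nanomap

params = synthetic.SynapseSceneParams(
    seed=1, n_loc_ez=2000, n_loc_accessory=2000,
    edge_alpha=8.0, edge_beta=2.0, precision_sigma=0.0, blink_run_length=1.0,
)
table, truth = synthetic.make_localization_scene(params)

ez = table[table.channel == "ez"][["x", "y"]].to_numpy()
acc = table[table.channel == "accessory"][["x", "y"]].to_numpy()
labels = nanomap.dbscan_cluster(ez, nanomap.EZ_REGIME)   # eps 0.35 um, min 50
clusters = nanomap.extract_clusters(ez, labels)
border = clusters.borders[int(np.argmax(clusters.areas))]
profile = nanomap.ring_density_profile(border, acc)
print(np.round(profile.density, 3))
print("peak ring:", profile.ring_edges[np.argmax(profile.density)])
```

prints

```
[0.    0.009 0.094 0.392 0.502 0.004 0.    0.   ]
peak ring: 0.8
```

i.e. more than half of the area-normalized density falls in the 80–100%
ring: the accessory protein is concentrated *inside* the EZ but close to
its edge, with essentially nothing beyond the border (rings 100–160% ≈ 0).
The Beta(8,2) law has its mode at a normalized radius of 7/8 = 0.875, so
the peak ring is exactly where the generative ground truth puts it.

The numbered drivers under `analysis/` run the full study on synthetic
scenes (`01_simulate_scenes.py` → `04_frap_turnover.py`), writing tables
under `results/`. For example `04_frap_turnover.py` fits the
population-averaged FRAP curves of two simulated cohorts and prints

```
shaft (n=14): A=0.766, tau=13.4 min, recovery@20min=0.593
spine (n=30): A=0.376, tau=35.7 min, recovery@20min=0.161
```

recovering the fast/large (shaft-like) and slow/small (spine-like, EZ)
turnover regimes the cohorts were generated with. A thin CLI mirrors the
modules (`endozone simulate | merge | cluster | rings | morpho | dynamics
| frap | run`); `endozone run config.yaml` executes a configured
pipeline deterministically and writes a manifest.

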