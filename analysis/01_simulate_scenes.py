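#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes to results/raw/: a two-channel SMLM localization table of one
synapse (PSD disc + elliptical EZ + edge-enriched accessory channel), the
detection stream and line movie of a live-imaging scene, and raw FRAP
recordings for shaft-like and spine-like kinetics.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from endozone import loc_io, synthetic

SEED = 20240601
OUT = Path(__file__).resolve().parents[1] / "results" / "raw"
OUT.mkdir(parents=True, exist_ok=True)

# SMLM scene: blinking molecules, 6 nm precision, edge-enriched accessory
smlm = synthetic.SynapseSceneParams(
    seed=SEED, n_loc_psd=2000, n_loc_ez=2000, n_loc_accessory=1000,
    edge_alpha=8.0, edge_beta=2.0, blink_run_length=3.0, precision_sigma=6.0,
)
table, truth = synthetic.make_localization_scene(smlm)
loc_io.write_localizations(table, OUT / "localizations.csv")
(OUT / "ground_truth.json").write_text(json.dumps({
    "ez_centroid": truth.ez_centroid.tolist(),
    "psd_centroid": truth.psd_centroid.tolist(),
    "n_molecules": int(len(truth.molecules)),
    "true_ez_area_nm2": float(np.pi * smlm.ez_semi_axes[0] * smlm.ez_semi_axes[1]),
}))
print(f"SMLM scene: {len(table)} localizations from {len(truth.molecules)} molecules "
      f"-> {OUT / 'localizations.csv'}")

# dynamics scene: stationary + moving puncta, event stream, FRAP trace
dyn = synthetic.DynamicsSceneParams(seed=SEED, n_events=1000, duration=1200.0)
movie, detections, frap_rec, dtruth = synthetic.make_dynamics_scene(dyn)
np.save(OUT / "line_movie.npy", movie)
np.save(OUT / "line_movie_stationary.npy", dtruth.stationary_movie)
np.save(OUT / "line_movie_antero.npy", dtruth.antero_movie)
np.save(OUT / "line_movie_retro.npy", dtruth.retro_movie)
detections.to_csv(OUT / "detections.csv", index=False)
dtruth.events.to_csv(OUT / "events_truth.csv", index=False)
print(f"dynamics: movie {movie.shape}, {len(detections)} detections of "
      f"{dyn.n_events} events")

# FRAP cohorts: shaft-like (fast, large mobile pool, n=14 cells) and
# spine-like (slow, small mobile pool, n=30 cells)
for name, A, tau, n_cells in [("shaft", 0.758, 13.0, 14), ("spine", 0.38, 36.2, 30)]:
    params = synthetic.FrapParams(
        A=A, K=1.0 / tau, noise_sd=0.02, bleach_residual=0.1,
        reference_bleach_per_frame=0.01,
    )
    rng = np.random.default_rng(SEED + n_cells)
    recs = []
    for rep in range(n_cells):
        rec = synthetic.simulate_frap_recording(params, rng=rng)
        rec.insert(0, "replicate", rep)
        recs.append(rec)
    pd.concat(recs, ignore_index=True).to_csv(OUT / f"frap_{name}.csv", index=False)
    print(f"FRAP {name}: A={A}, tau={tau} min, {n_cells} cells -> frap_{name}.csv")
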