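"""End-to-end pipeline: simulate -> preprocess -> analyze, with a config.

The config is a flat, human-readable YAML/dict of per-stage parameters;
unknown keys are rejected before any stage runs.  A run writes per-stage
CSV/JSON outputs and a manifest (seed, parameter echo, stage list) and is
bit-identical when repeated with the same config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import frap as frap_mod
from . import loc_io, nanomap, synthetic

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every stage parameter of the standard pipeline, serializable."""

    seed: int = 0
    out_dir: str = "endozone_out"
    stages: tuple[str, ...] = ("simulate", "merge", "rings", "dynamics", "frap")
    # preprocessing
    merge_radius_nm: float = 30.0
    precision_cutoff_nm: float = 15.0
    # clustering
    eps_um: float = 0.35
    min_pts: int = 50
    border_method: str = "convex"
    # rings
    ring_edges: tuple[float, ...] = tuple(nanomap.DEFAULT_RING_EDGES.tolist())
    # synthetic scene
    edge_alpha: float = 8.0
    edge_beta: float = 2.0
    n_loc_ez: int = 2000
    n_loc_accessory: int = 2000
    # dynamics
    max_link_nm: float = 500.0
    max_gap_frames: int = 0
    # frap
    recovery_time_min: float = 10.0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("stages", "ring_edges"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["ring_edges"] = list(d["ring_edges"])
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write their outputs.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "config": config.to_dict(),
                      "outputs": {}}
    rng_seed = int(config.seed)
    state: dict = {}

    for stage in config.stages:
        try:
            if stage == "simulate":
                params = synthetic.SynapseSceneParams(
                    edge_alpha=config.edge_alpha, edge_beta=config.edge_beta,
                    n_loc_ez=config.n_loc_ez, n_loc_accessory=config.n_loc_accessory,
                    seed=rng_seed,
                )
                table, truth = synthetic.make_localization_scene(params)
                loc_io.write_localizations(table, out / "localizations.csv")
                state["table"], state["truth"] = table, truth
                manifest["outputs"]["localizations"] = "localizations.csv"
            elif stage == "merge":
                table = state.get("table")
                if table is None:
                    table = loc_io.read_localizations(out / "localizations.csv")
                merged = loc_io.merge_consecutive(table, config.merge_radius_nm)
                merged = loc_io.precision_filter(merged, config.precision_cutoff_nm)
                loc_io.write_localizations(merged, out / "merged.csv")
                state["merged"] = merged
                manifest["outputs"]["merged"] = "merged.csv"
            elif stage == "rings":
                merged = state.get("merged", state.get("table"))
                ez = merged[merged["channel"] == "ez"][["x", "y"]].to_numpy()
                acc = merged[merged["channel"] == "accessory"][["x", "y"]].to_numpy()
                labels = nanomap.dbscan_cluster(
                    ez, nanomap.DbscanParams(config.eps_um, config.min_pts)
                )
                clusters = nanomap.extract_clusters(ez, labels, config.border_method)
                if clusters.n_clusters == 0:
                    raise RuntimeError("no EZ cluster found")
                primary = int(np.argmax(clusters.areas))
                border = clusters.borders[primary]
                profile = nanomap.ring_density_profile(
                    border, acc, np.asarray(config.ring_edges)
                )
                ring_df = pd.DataFrame(
                    {
                        "ring_lo": profile.ring_edges[:-1],
                        "ring_hi": profile.ring_edges[1:],
                        "loc_fraction": profile.loc_fraction,
                        "area_fraction": profile.area_fraction,
                        "density": profile.density,
                    }
                )
                ring_df.to_csv(out / "ring_profile.csv", index=False)
                geom = pd.DataFrame(
                    {
                        "cluster": range(clusters.n_clusters),
                        "area_nm2": clusters.areas,
                        "fwtm_length_nm": clusters.fwtm_length,
                        "fwtm_width_nm": clusters.fwtm_width,
                    }
                )
                geom.to_csv(out / "cluster_geometry.csv", index=False)
                state["profile"] = profile
                manifest["outputs"]["ring_profile"] = "ring_profile.csv"
                manifest["outputs"]["cluster_geometry"] = "cluster_geometry.csv"
            elif stage == "dynamics":
                dparams = synthetic.DynamicsSceneParams(seed=rng_seed)
                movie, detections, _, truth = synthetic.make_dynamics_scene(dparams)
                kymo = dyn.build_kymograph(
                    movie, frame_interval_s=dparams.frame_interval,
                    pixel_size_nm=dparams.pixel_size_nm,
                )
                stat, ant, ret = dyn.fourier_direction_filter(kymo)
                tracks = dyn.link_tracks(
                    detections, config.max_link_nm, config.max_gap_frames,
                    frame_interval_s=dparams.frame_interval, n_frames=dparams.n_frames,
                )
                summary = dyn.lifetime_classify(tracks.lifetimes_min)
                pd.DataFrame({"lifetime_min": tracks.lifetimes_min}).to_csv(
                    out / "lifetimes.csv", index=False
                )
                with open(out / "lifetime_summary.json", "w") as fh:
                    json.dump(summary, fh, indent=1)
                manifest["outputs"]["lifetimes"] = "lifetimes.csv"
                state["kymo_components"] = (stat, ant, ret)
            elif stage == "frap":
                fparams = synthetic.FrapParams()
                rec = synthetic.simulate_frap_recording(
                    fparams, rng=np.random.default_rng(rng_seed)
                )
                norm = frap_mod.normalize_frap(rec)
                fit = frap_mod.fit_frap(norm, recovery_time_min=config.recovery_time_min)
                pd.DataFrame(
                    [{"A": fit.A, "K_per_min": fit.K, "tau_min": fit.tau,
                      "recovery_at": fit.recovery_at, "rss": fit.rss}]
                ).to_csv(out / "frap_fit.csv", index=False)
                manifest["outputs"]["frap_fit"] = "frap_fit.csv"
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
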