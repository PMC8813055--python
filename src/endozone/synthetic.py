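"""Synthetic scenes with known ground truth.

Two generators cover the inputs of the whole pipeline:

``make_localization_scene``
    A two-channel SMLM "synapse": a disc-shaped postsynaptic density (PSD)
    cluster, an elliptical endocytic-zone (EZ) cluster offset from the PSD
    border, and an accessory-protein channel whose radial placement inside
    the EZ follows a Beta law on the normalized centroid-to-border radius
    (Beta(1,1) = uniform in radius; Beta(8,2) = edge-enriched with mode at
    r = 0.875).  Each ground-truth molecule blinks: it is emitted as a run
    of localizations over consecutive frames (geometric run length) with
    isotropic Gaussian position noise.

``make_dynamics_scene``
    A 1D-line time-lapse movie (for kymographs) containing stationary and
    directed anterograde/retrograde particles, a stream of appearance/
    disappearance events with two-component exponential-mixture lifetimes,
    and a FRAP trace sampled on the non-uniform acquisition schedule used
    for dendritic spine recordings (2 min baseline at 20 s; recovery 3 min
    at 20 s, 12 min at 60 s, 4 min at 120 s).

All randomness flows through a single seed; identical parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SynapseSceneParams",
    "DynamicsSceneParams",
    "FrapParams",
    "LocalizationGroundTruth",
    "DynamicsGroundTruth",
    "make_localization_scene",
    "make_dynamics_scene",
    "frap_schedule",
    "simulate_frap_recording",
    "frap_model",
]


# --------------------------------------------------------------------------
# SMLM scene
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseSceneParams:
    """Geometry and imaging parameters of one synthetic synapse scene.

    Lengths in nm.  Defaults follow the measured scale of the endocytic
    zone (~225 x 145 nm) sitting within ~100 nm of the PSD border.
    """

    psd_center: tuple[float, float] = (0.0, 0.0)
    psd_radius: float = 180.0
    # EZ centroid sits essentially on the PSD border (measured
    # border-to-centroid distance ~10 nm for real synapses)
    ez_offset: tuple[float, float] = (10.6, 0.0)
    ez_semi_axes: tuple[float, float] = (112.0, 73.0)
    ez_rotation: float = 0.0
    n_loc_psd: int = 400
    n_loc_ez: int = 300
    n_loc_accessory: int = 300
    edge_alpha: float = 1.0
    edge_beta: float = 1.0
    precision_sigma: float = 8.0
    blink_run_length: float = 1.0
    n_frames: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psd_radius <= 0 or min(self.ez_semi_axes) <= 0:
            raise ValueError("lengths must be > 0")
        if min(self.n_loc_psd, self.n_loc_ez, self.n_loc_accessory) < 0:
            raise ValueError("counts must be >= 0")
        if self.edge_alpha <= 0 or self.edge_beta <= 0:
            raise ValueError("edge_alpha/edge_beta must be > 0")
        if self.precision_sigma < 0:
            raise ValueError("precision_sigma must be >= 0")
        if self.blink_run_length < 1:
            raise ValueError("blink_run_length must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class LocalizationGroundTruth:
    """True structure behind a synthetic localization table."""

    psd_border: np.ndarray          # (n, 2) polygon vertices, nm
    ez_border: np.ndarray           # (n, 2) polygon vertices, nm
    psd_centroid: np.ndarray
    ez_centroid: np.ndarray
    molecules: pd.DataFrame         # molecule_id, channel, x, y
    molecule_id: np.ndarray         # per localization row
    accessory_radii: np.ndarray     # normalized centroid-to-border radius per accessory molecule


def _ellipse_border(center, semi_axes, rotation, n=128) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    a, b = semi_axes
    pts = np.stack([a * np.cos(t), b * np.sin(t)], axis=1)
    c, s = np.cos(rotation), np.sin(rotation)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T + np.asarray(center)


def _ellipse_radius(theta: np.ndarray, semi_axes, rotation) -> np.ndarray:
    """Centroid-to-border distance of an ellipse along world-frame angles."""
    a, b = semi_axes
    t = theta - rotation
    return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def _uniform_in_disc(rng, n, radius) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def _blink(rng, molecules: np.ndarray, channel: str, params: SynapseSceneParams,
           start_id: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Emit each molecule as a run of jittered localizations on consecutive frames."""
    n = len(molecules)
    if params.blink_run_length == 1:
        runs = np.ones(n, dtype=int)
    else:
        runs = rng.geometric(1.0 / params.blink_run_length, size=n)
    runs = np.minimum(runs, params.n_frames)
    starts = rng.integers(0, params.n_frames - runs + 1)
    mol_idx = np.repeat(np.arange(n), runs)
    frame = np.concatenate([np.arange(s, s + L) for s, L in zip(starts, runs)])
    pos = molecules[mol_idx]
    if params.precision_sigma > 0:
        pos = pos + rng.normal(0.0, params.precision_sigma, size=pos.shape)
    table = pd.DataFrame(
        {
            "frame": frame,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "precision": np.full(len(frame), float(params.precision_sigma)),
            "channel": channel,
        }
    )
    return table, mol_idx + start_id


def make_localization_scene(
    params: SynapseSceneParams,
) -> tuple[pd.DataFrame, LocalizationGroundTruth]:
    """Generate the two-channel (plus accessory) localization table.

    Returns the canonical localization table (frame, x, y, precision,
    channel; channels ``"psd"``, ``"ez"``, ``"accessory"``) and the ground
    truth.  The accessory channel is placed at radius
    ``r = R(theta) * Beta(edge_alpha, edge_beta)`` along a uniformly random
    direction ``theta`` from the EZ centroid, where ``R(theta)`` is the EZ
    border radius in that direction.
    """
    rng = np.random.default_rng(params.seed)
    psd_center = np.asarray(params.psd_center, float)
    # EZ centroid sits at the +x point of the PSD border, displaced by ez_offset
    ez_centroid = psd_center + np.array([params.psd_radius, 0.0]) + np.asarray(params.ez_offset)

    psd_mol = psd_center + _uniform_in_disc(rng, params.n_loc_psd, params.psd_radius)
    # uniform in ellipse: uniform in unit disc, then anisotropic scale + rotation
    unit = _uniform_in_disc(rng, params.n_loc_ez, 1.0)
    a, b = params.ez_semi_axes
    c, s = np.cos(params.ez_rotation), np.sin(params.ez_rotation)
    rot = np.array([[c, -s], [s, c]])
    ez_mol = (unit * [a, b]) @ rot.T + ez_centroid

    theta = rng.uniform(0, 2 * np.pi, size=params.n_loc_accessory)
    u = rng.beta(params.edge_alpha, params.edge_beta, size=params.n_loc_accessory)
    radius = _ellipse_radius(theta, params.ez_semi_axes, params.ez_rotation) * u
    acc_mol = ez_centroid + np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)

    tables, ids, mol_rows = [], [], []
    next_id = 0
    for mol, channel in [(psd_mol, "psd"), (ez_mol, "ez"), (acc_mol, "accessory")]:
        t, mid = _blink(rng, mol, channel, params, next_id)
        tables.append(t)
        ids.append(mid)
        mol_rows.append(
            pd.DataFrame(
                {
                    "molecule_id": np.arange(next_id, next_id + len(mol)),
                    "channel": channel,
                    "x": mol[:, 0],
                    "y": mol[:, 1],
                }
            )
        )
        next_id += len(mol)

    table = pd.concat(tables, ignore_index=True)
    molecule_id = np.concatenate(ids)
    order = np.lexsort((table["frame"].to_numpy(), table["channel"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    molecule_id = molecule_id[order]

    truth = LocalizationGroundTruth(
        psd_border=psd_center
        + params.psd_radius
        * np.stack(
            [np.cos(np.linspace(0, 2 * np.pi, 128, endpoint=False)),
             np.sin(np.linspace(0, 2 * np.pi, 128, endpoint=False))],
            axis=1,
        ),
        ez_border=_ellipse_border(ez_centroid, params.ez_semi_axes, params.ez_rotation),
        psd_centroid=psd_center,
        ez_centroid=ez_centroid,
        molecules=pd.concat(mol_rows, ignore_index=True),
        molecule_id=molecule_id,
        accessory_radii=u,
    )
    return table, truth


# --------------------------------------------------------------------------
# Dynamics scene
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapParams:
    """Single-exponential recovery truth: F(t) = A (1 - exp(-K t))."""

    A: float = 0.38
    K: float = 1.0 / 36.2           # 1/min
    noise_sd: float = 0.0
    bleach_residual: float = 0.0    # normalized intensity right after bleach
    reference_bleach_per_frame: float = 0.0
    background: float = 100.0
    reference_level: float = 1000.0
    roi_scale: float = 800.0


@dataclass(frozen=True)
class DynamicsSceneParams:
    """Parameters of the time-lapse scene (velocities in um/min, times in s)."""

    n_stationary: int = 5
    n_antero: int = 2
    n_retro: int = 2
    velocities: tuple[float, ...] = ()   # per moving particle, signed; empty -> defaults
    intensity_cv_true: float = 0.06
    lifetime_mix: tuple[float, float, float] = (0.5, 1.5, 15.0)  # p_short, mean_short, mean_long (min)
    n_events: int = 200
    frame_interval: float = 5.0
    duration: float = 300.0
    line_length_px: int = 200
    pixel_size_nm: float = 100.0
    psf_sigma_px: float = 1.5
    frap: FrapParams = field(default_factory=FrapParams)
    seed: int = 0

    def __post_init__(self) -> None:
        p, m_short, m_long = self.lifetime_mix
        if not 0.0 <= p <= 1.0:
            raise ValueError("p_short must be in [0, 1]")
        if not m_short < m_long:
            raise ValueError("mean_short must be < mean_long")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1


@dataclass
class DynamicsGroundTruth:
    stationary_movie: np.ndarray
    antero_movie: np.ndarray
    retro_movie: np.ndarray
    particle_positions: pd.DataFrame      # particle, kind, x0_px, v_px_per_frame
    event_lifetimes_min: np.ndarray       # true lifetime per event
    events: pd.DataFrame                  # event, x_nm, y_nm, t_on_s, t_off_s
    frap_truth: FrapParams


def _render_line_movie(positions_px: np.ndarray, intensities: np.ndarray,
                       length_px: int, psf_sigma_px: float) -> np.ndarray:
    """Sum Gaussian spots onto a (T, L) line movie."""
    t_frames, n_particles = positions_px.shape
    xs = np.arange(length_px, dtype=float)
    movie = np.zeros((t_frames, length_px))
    for j in range(n_particles):
        d = xs[None, :] - positions_px[:, j][:, None]
        movie += intensities[:, j][:, None] * np.exp(-0.5 * (d / psf_sigma_px) ** 2)
    return movie


def frap_schedule() -> np.ndarray:
    """Acquisition times in minutes (baseline negative, bleach at t = 0).

    2 min baseline at 20 s intervals; first post-bleach frame at t = 0;
    then 3 min at 20 s, 12 min at 60 s and 4 min at 120 s (19 min total).
    """
    baseline = -np.arange(1, 7)[::-1] * 20.0
    fast = np.arange(0, 181, 20.0)
    mid = np.arange(240, 901, 60.0)
    slow = np.arange(1020, 1141, 120.0)
    return np.concatenate([baseline, fast, mid, slow]) / 60.0


def frap_model(t: np.ndarray, A: float, K: float) -> np.ndarray:
    return A * (1.0 - np.exp(-K * np.asarray(t, float)))


def simulate_frap_recording(
    params: FrapParams,
    schedule_min: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Raw ROI/background/reference intensities on the acquisition schedule.

    The ROI trace encodes the true recovery ``bleach_residual + (1 -
    bleach_residual) * A (1 - exp(-K t))`` multiplied by an exponential
    acquisition-photobleaching decay shared with the reference region, plus
    a constant background; the double-normalization of the analysis module
    recovers the noiseless model exactly.
    """
    rng = rng or np.random.default_rng(0)
    t = frap_schedule() if schedule_min is None else np.asarray(schedule_min, float)
    post = t >= 0
    g = np.ones_like(t)
    b = params.bleach_residual
    g[post] = b + (1.0 - b) * frap_model(t[post], params.A, params.K)
    decay = (1.0 - params.reference_bleach_per_frame) ** np.arange(len(t))
    roi = params.roi_scale * g * decay + params.background
    ref = params.reference_level * decay + params.background
    if params.noise_sd > 0:
        roi = roi + rng.normal(0.0, params.noise_sd * params.roi_scale, size=len(t))
    return pd.DataFrame(
        {"t_min": t, "roi": roi, "background": params.background, "reference": ref}
    )


def make_dynamics_scene(
    params: DynamicsSceneParams,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame, DynamicsGroundTruth]:
    """Generate the full dynamics bundle.

    Returns ``(movie, detections, frap_recording, truth)``:

    * ``movie`` — (T, L) line movie, sum of the stationary, anterograde and
      retrograde ground-truth components;
    * ``detections`` — per-frame spot table (frame, x, y, intensity; nm) of
      the appearance/disappearance event stream for track linking;
    * ``frap_recording`` — raw FRAP trace on the standard schedule;
    * ``truth`` — all ground-truth components and parameters.
    """
    rng = np.random.default_rng(params.seed)
    T = params.n_frames
    L = params.line_length_px

    def _intensity(n):
        base = rng.uniform(0.8, 1.2, size=n)
        fluct = rng.normal(1.0, params.intensity_cv_true, size=(T, n))
        return np.clip(base[None, :] * fluct, 0.0, None)

    # stationary particles
    x_st = rng.uniform(0.1 * L, 0.9 * L, size=params.n_stationary)
    pos_st = np.tile(x_st, (T, 1))
    stationary = _render_line_movie(pos_st, _intensity(params.n_stationary), L, params.psf_sigma_px)

    # moving particles: velocity um/min -> px/frame
    n_moving = params.n_antero + params.n_retro
    if params.velocities:
        v_um_min = np.asarray(params.velocities, float)
        if len(v_um_min) != n_moving:
            raise ValueError("velocities length must equal n_antero + n_retro")
    else:
        # default speeds keep per-frame displacement between ~1 and ~2 PSF
        # sigmas: slow enough to render continuous kymograph lines (no
        # temporal aliasing), fast enough that the motion is spectrally
        # separable from the stationary band within one acquisition
        v_um_min = np.concatenate(
            [rng.uniform(1.8, 3.6, params.n_antero), -rng.uniform(1.8, 3.6, params.n_retro)]
        )
    v_px = v_um_min * 1000.0 / 60.0 * params.frame_interval / params.pixel_size_nm
    frames = np.arange(T)[:, None]
    span = v_px * (T - 1)
    margin = 2.0
    lo = np.where(v_px >= 0, margin, margin - span)
    hi = np.where(v_px >= 0, L - margin - span, L - margin)
    # keep the whole trajectory in-field when the span allows it
    feasible = hi > lo
    x0 = np.where(
        feasible,
        rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi)),
        np.where(v_px >= 0, rng.uniform(0, 0.3 * L, n_moving), rng.uniform(0.7 * L, L, n_moving)),
    )
    pos_mv = x0[None, :] + frames * v_px[None, :]
    inten_mv = _intensity(n_moving)
    inten_mv[(pos_mv < 0) | (pos_mv >= L)] = 0.0
    antero = _render_line_movie(
        pos_mv[:, : params.n_antero], inten_mv[:, : params.n_antero], L, params.psf_sigma_px
    ) if params.n_antero else np.zeros((T, L))
    retro = _render_line_movie(
        pos_mv[:, params.n_antero:], inten_mv[:, params.n_antero:], L, params.psf_sigma_px
    ) if params.n_retro else np.zeros((T, L))

    movie = stationary + antero + retro

    # event stream with mixture lifetimes
    p_short, m_short, m_long = params.lifetime_mix
    n_ev = params.n_events
    short = rng.uniform(size=n_ev) < p_short
    life_min = np.where(
        short, rng.exponential(m_short, n_ev), rng.exponential(m_long, n_ev)
    )
    t_on = rng.uniform(0.0, max(params.duration - 1e-9, 0.0), size=n_ev)
    t_off = t_on + life_min * 60.0
    # sparse positions on a jittered grid so nearest-neighbour linking is unambiguous
    grid = int(np.ceil(np.sqrt(n_ev)))
    spacing_nm = 5000.0
    gx, gy = np.meshgrid(np.arange(grid), np.arange(grid))
    cells = np.stack([gx.ravel(), gy.ravel()], axis=1)[:n_ev] * spacing_nm
    jitter = rng.uniform(-0.1, 0.1, size=(n_ev, 2)) * spacing_nm
    exy = cells + jitter

    det_rows = []
    for k in range(n_ev):
        f0 = int(np.ceil(t_on[k] / params.frame_interval))
        f1 = int(np.floor(min(t_off[k], params.duration) / params.frame_interval))
        for f in range(f0, f1 + 1):
            det_rows.append((f, exy[k, 0], exy[k, 1], 1.0, k))
    detections = pd.DataFrame(det_rows, columns=["frame", "x", "y", "intensity", "true_event"])
    detections = detections.sort_values(["frame"], kind="stable").reset_index(drop=True)

    frap_recording = simulate_frap_recording(params.frap, rng=rng)

    truth = DynamicsGroundTruth(
        stationary_movie=stationary,
        antero_movie=antero,
        retro_movie=retro,
        particle_positions=pd.DataFrame(
            {
                "kind": ["stationary"] * params.n_stationary
                + ["antero"] * params.n_antero
                + ["retro"] * params.n_retro,
                "x0_px": np.concatenate([x_st, x0]),
                "v_px_per_frame": np.concatenate([np.zeros(params.n_stationary), v_px]),
            }
        ),
        event_lifetimes_min=life_min,
        events=pd.DataFrame(
            {"event": np.arange(n_ev), "x_nm": exy[:, 0], "y_nm": exy[:, 1],
             "t_on_s": t_on, "t_off_s": t_off}
        ),
        frap_truth=params.frap,
    )
    return movie, detections, frap_recording, truth
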