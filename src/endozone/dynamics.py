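"""Time-lapse dynamics: kymographs, direction filtering, CV, lifetimes.

A kymograph (distance x time intensity matrix sampled along a dendrite
path) mixes stationary clathrin structures (vertical bands) with
anterograde/retrograde transport (slanted lines).  The directional
decomposition works in 2D Fourier space: a feature moving with velocity v
lives on the line k_t = -v k_x, so the low-|k_t| band holds stationary
structures and the two sign(k_x * k_t) half-plane pairs hold the two
transport directions.

Also here: intensity coefficient of variation, greedy nearest-neighbour
track linking, and the short/intermediate/persistent lifetime
classification with strict < 3 min and > 9 min boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

__all__ = [
    "Kymograph",
    "Track",
    "TrackSet",
    "build_kymograph",
    "fourier_direction_filter",
    "trace_cv",
    "link_tracks",
    "lifetime_classify",
    "SHORT_LIFETIME_MIN",
    "PERSISTENT_LIFETIME_MIN",
]

SHORT_LIFETIME_MIN = 3.0
PERSISTENT_LIFETIME_MIN = 9.0


@dataclass
class Kymograph:
    """Distance x time intensity matrix; rows = time, cols = distance."""

    data: np.ndarray
    frame_interval_s: float = 1.0
    pixel_size_nm: float = 100.0
    stationary: np.ndarray | None = None
    anterograde: np.ndarray | None = None
    retrograde: np.ndarray | None = None


def build_kymograph(
    movie: np.ndarray,
    path: np.ndarray | None = None,
    line_width_px: int = 1,
    frame_interval_s: float = 1.0,
    pixel_size_nm: float = 100.0,
) -> Kymograph:
    """Sample a movie along a polyline to build a kymograph.

    ``movie`` is (T, H, W) with ``path`` an (m, 2) polyline of (x, y)
    pixel coordinates, or already a (T, L) line movie (``path`` ignored).
    Intensity is max-projected across ``line_width_px`` perpendicular to
    the path.
    """
    movie = np.asarray(movie, float)
    if movie.ndim == 2:
        return Kymograph(movie.copy(), frame_interval_s, pixel_size_nm)
    if movie.ndim != 3:
        raise ValueError("movie must be (T, L) or (T, H, W)")
    if path is None:
        raise ValueError("a path polyline is required for a 2D movie")
    path = np.asarray(path, float).reshape(-1, 2)
    T, H, W = movie.shape
    if (path[:, 0].min() < 0 or path[:, 0].max() > W - 1
            or path[:, 1].min() < 0 or path[:, 1].max() > H - 1):
        raise ValueError("path outside movie frame")
    # resample polyline at ~1 px spacing
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_samples = max(int(np.ceil(arclen[-1])) + 1, 2)
    s = np.linspace(0.0, arclen[-1], n_samples)
    xs = np.interp(s, arclen, path[:, 0])
    ys = np.interp(s, arclen, path[:, 1])
    # unit tangents -> normals, for the width offsets
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(line_width_px, dtype=float) - (line_width_px - 1) / 2.0
    data = np.zeros((T, n_samples))
    for t in range(T):
        profiles = np.empty((len(offsets), n_samples))
        for j, off in enumerate(offsets):
            cx = np.clip(xs + off * nx, 0, W - 1)
            cy = np.clip(ys + off * ny, 0, H - 1)
            profiles[j] = map_coordinates(movie[t], [cy, cx], order=1)
        data[t] = profiles.max(axis=0)
    return Kymograph(data, frame_interval_s, pixel_size_nm)


def _signed_freq_index(n: int) -> np.ndarray:
    return (np.arange(n) + n // 2) % n - (n // 2)


def fourier_direction_filter(
    kymo: Kymograph | np.ndarray, band_t: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a kymograph into stationary/anterograde/retrograde components.

    The 2D FFT spectrum is partitioned into three conjugate-symmetric
    masks: a temporal-frequency band of ``band_t`` bins around zero
    (|k_t| < band_t; the default of one bin keeps exactly the
    zero-temporal-frequency row, where time-constant structures live),
    and the two remaining half-plane pairs with sign(k_x * k_t) < 0
    (anterograde, positive velocity) and > 0 (retrograde).  The
    spatial-DC column and any Nyquist rows/columns are assigned to the
    stationary mask to keep every mask conjugate-symmetric, so the three
    inverse transforms are real and sum exactly to the input.
    """
    data = kymo.data if isinstance(kymo, Kymograph) else np.asarray(kymo, float)
    if data.ndim != 2 or min(data.shape) < 8:
        raise ValueError("kymograph must be at least 8 x 8")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in kymograph")
    T, L = data.shape
    kt = _signed_freq_index(T)[:, None]
    kx = _signed_freq_index(L)[None, :]
    if band_t < 1:
        raise ValueError("band_t must be >= 1 bin")
    stationary_mask = (np.abs(kt) < band_t) | (kx == 0)
    if T % 2 == 0:
        stationary_mask |= np.abs(kt) == T // 2
    if L % 2 == 0:
        stationary_mask |= np.abs(kx) == L // 2
    antero_mask = (~stationary_mask) & (kx * kt < 0)
    retro_mask = (~stationary_mask) & (kx * kt > 0)
    F = np.fft.fft2(data)
    parts = tuple(
        np.fft.ifft2(F * m).real for m in (stationary_mask, antero_mask, retro_mask)
    )
    return parts


def trace_cv(trace: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) of an intensity trace."""
    trace = np.asarray(trace, float)
    if trace.size < 2:
        raise ValueError("need >= 2 samples")
    mean = trace.mean()
    if mean <= 0:
        raise ValueError("trace mean must be > 0")
    return float(trace.std(ddof=1) / mean)


@dataclass
class Track:
    frames: list[int] = field(default_factory=list)
    x: list[float] = field(default_factory=list)
    y: list[float] = field(default_factory=list)
    intensity: list[float] = field(default_factory=list)

    def lifetime_min(self, frame_interval_s: float) -> float:
        return (self.frames[-1] - self.frames[0] + 1) * frame_interval_s / 60.0


@dataclass
class TrackSet:
    tracks: list[Track]
    frame_interval_s: float
    n_frames: int | None = None

    @property
    def lifetimes_min(self) -> np.ndarray:
        return np.array([t.lifetime_min(self.frame_interval_s) for t in self.tracks])

    @property
    def censored(self) -> np.ndarray:
        """True if the track touches the first or last frame of the movie."""
        if self.n_frames is None:
            return np.zeros(len(self.tracks), dtype=bool)
        return np.array(
            [t.frames[0] == 0 or t.frames[-1] == self.n_frames - 1 for t in self.tracks]
        )


def link_tracks(
    detections: pd.DataFrame,
    max_link_nm: float,
    max_gap_frames: int = 0,
    frame_interval_s: float = 1.0,
    n_frames: int | None = None,
) -> TrackSet:
    """Greedy nearest-neighbour frame-to-frame linking of spot detections.

    ``detections`` needs columns frame, x, y (nm) and optionally
    intensity.  Each detection joins at most one track; a track may skip
    up to ``max_gap_frames`` dark frames.
    """
    req = {"frame", "x", "y"}
    if not req.issubset(detections.columns):
        raise ValueError("detections need frame, x, y columns")
    has_int = "intensity" in detections.columns
    frames = detections["frame"].to_numpy(int)
    xy = detections[["x", "y"]].to_numpy(float)
    inten = detections["intensity"].to_numpy(float) if has_int else np.ones(len(detections))
    open_tracks: list[Track] = []
    closed: list[Track] = []
    for f in np.unique(frames):
        idx = np.flatnonzero(frames == f)
        keep, expired = [], []
        for tr in open_tracks:
            (keep if f - tr.frames[-1] <= max_gap_frames + 1 else expired).append(tr)
        closed.extend(expired)
        open_tracks = keep
        cands = [tr for tr in open_tracks if tr.frames[-1] < f]
        unmatched = list(range(len(idx)))
        if cands:
            last = np.array([[tr.x[-1], tr.y[-1]] for tr in cands])
            d = np.linalg.norm(xy[idx][:, None, :] - last[None, :, :], axis=2)
            pairs = sorted(
                ((d[i, j], i, j) for i in range(len(idx)) for j in range(len(cands)))
            )
            used_p: set[int] = set()
            used_t: set[int] = set()
            for dist, i, j in pairs:
                if dist > max_link_nm:
                    break
                if i in used_p or j in used_t:
                    continue
                used_p.add(i)
                used_t.add(j)
                tr = cands[j]
                k = idx[i]
                tr.frames.append(int(f))
                tr.x.append(float(xy[k, 0]))
                tr.y.append(float(xy[k, 1]))
                tr.intensity.append(float(inten[k]))
            unmatched = [i for i in range(len(idx)) if i not in used_p]
        for i in unmatched:
            k = idx[i]
            open_tracks.append(
                Track([int(f)], [float(xy[k, 0])], [float(xy[k, 1])], [float(inten[k])])
            )
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (tr.frames[0], tr.x[0], tr.y[0]))
    return TrackSet(closed, frame_interval_s, n_frames)


def lifetime_classify(
    lifetimes_min: np.ndarray,
    synapse_ids: np.ndarray | None = None,
) -> dict:
    """Short / intermediate / persistent lifetime fractions.

    Short means strictly < 3 min, persistent strictly > 9 min (a lifetime
    of exactly 3 min is intermediate).  If ``synapse_ids`` is given, a
    per-synapse ``stable`` flag marks synapses with at least one track
    persisting > 9 min.
    """
    lt = np.asarray(lifetimes_min, float)
    if np.any(lt < 0):
        raise ValueError("lifetimes must be >= 0")
    n = len(lt)
    frac_short = float((lt < SHORT_LIFETIME_MIN).mean()) if n else 0.0
    frac_persistent = float((lt > PERSISTENT_LIFETIME_MIN).mean()) if n else 0.0
    out = {
        "frac_short": frac_short,
        "frac_intermediate": float(1.0 - frac_short - frac_persistent) if n else 0.0,
        "frac_persistent": frac_persistent,
    }
    if synapse_ids is not None:
        ids = np.asarray(synapse_ids)
        out["stable_per_synapse"] = {
            sid: bool((lt[ids == sid] > PERSISTENT_LIFETIME_MIN).any())
            for sid in np.unique(ids)
        }
    return out
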