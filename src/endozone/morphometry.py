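"""Pixel-mask morphometry of clathrin puncta and EZ-PSD association.

Operates at the confocal/STED level: binary masks of clathrin-coated
structures (CCSs) and point lists of PSD centers.  Shape descriptors are
the max/min Feret (caliper) diameters and the circularity ratio
4*pi*A/P^2; association is scored with a fixed-diameter circular ROI
centered on each PSD (default 0.79 um, the midpoint of the 0.69-0.89 um
range used for synaptic regions).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = [
    "feret_dimensions",
    "circularity",
    "associate_ez_psd",
    "punctum_shapes",
    "DEFAULT_ROI_DIAMETER_UM",
]

DEFAULT_ROI_DIAMETER_UM = 0.79


def _pixel_coords(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask")
    return np.stack([xs, ys], axis=1).astype(float)


def feret_dimensions(mask: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) diameters of a mask, in um.

    Length is the maximum pairwise distance between pixel centers plus one
    pixel (so a single pixel measures one pixel across); width is the
    minimum caliper width over all orientations, plus one pixel.
    """
    pts = _pixel_coords(mask)
    if len(pts) == 1:
        return pixel_size_um, pixel_size_um
    # collinear masks: extent along the line, zero across
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        proj = centered @ (centered[np.argmax(np.linalg.norm(centered, axis=1))]
                           / np.linalg.norm(centered, axis=1).max())
        return (np.ptp(proj) + 1.0) * pixel_size_um, pixel_size_um
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    diff = hp[:, None, :] - hp[None, :, :]
    max_feret = np.sqrt((diff**2).sum(-1)).max()
    # min caliper width: for each hull edge, max distance of hull points to the edge line
    widths = []
    for i in range(len(hp)):
        a, b = hp[i], hp[(i + 1) % len(hp)]
        edge = b - a
        n = np.array([-edge[1], edge[0]]) / np.linalg.norm(edge)
        widths.append(np.abs((hp - a) @ n).max())
    min_feret = min(widths)
    return (max_feret + 1.0) * pixel_size_um, (min_feret + 1.0) * pixel_size_um


def circularity(mask: np.ndarray, clip: bool = True) -> float:
    """Circularity ratio 4*pi*area/perimeter^2 of a binary mask.

    Perimeter comes from contour-length estimation on the pixel grid;
    values are clipped to <= 1 (discretization can push a disc slightly
    above the analytic limit).
    """
    mask = np.asarray(mask).astype(bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    perim = sum(
        float(np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1)).sum()) for c in contours
    )
    if perim == 0:
        return 1.0
    c = 4.0 * np.pi * area / perim**2
    return min(c, 1.0) if clip else c


def punctum_shapes(label_image: np.ndarray, pixel_size_um: float):
    """Per-component shape table (area um^2, Feret length/width, circularity)."""
    import pandas as pd

    label_image = np.asarray(label_image)
    if label_image.dtype == bool:
        label_image = measure.label(label_image, connectivity=2)
    rows = []
    for k in range(1, label_image.max() + 1):
        m = label_image == k
        if not m.any():
            continue
        L, W = feret_dimensions(m, pixel_size_um)
        rows.append(
            {
                "label": k,
                "area_um2": float(m.sum()) * pixel_size_um**2,
                "feret_length_um": L,
                "feret_width_um": W,
                "circularity": circularity(m),
            }
        )
    return pd.DataFrame(rows)


def associate_ez_psd(
    psd_centers: np.ndarray,
    clathrin_mask: np.ndarray,
    pixel_size_um: float,
    roi_diameter_um: float = DEFAULT_ROI_DIAMETER_UM,
) -> tuple[float, np.ndarray]:
    """Fraction of PSDs with an associated CCS, and CCSs per PSD.

    A PSD counts as positive if at least one 8-connected component of the
    clathrin mask overlaps (partially or completely) the closed disc of
    ``roi_diameter_um`` centered on it; the per-PSD count is the number of
    distinct overlapping components.  ``psd_centers`` are (x, y) pixel
    coordinates.
    """
    psd_centers = np.asarray(psd_centers, float).reshape(-1, 2)
    if len(psd_centers) == 0:
        raise ValueError("no PSD centers")
    if not 0.1 <= roi_diameter_um <= 2.0:
        raise ValueError("roi_diameter_um outside the sensible 0.1-2 um range")
    radius_px = roi_diameter_um / 2.0 / pixel_size_um
    labels = measure.label(np.asarray(clathrin_mask).astype(bool), connectivity=2)
    ys, xs = np.nonzero(labels)
    comp = labels[ys, xs]
    counts = np.zeros(len(psd_centers), dtype=int)
    for i, (cx, cy) in enumerate(psd_centers):
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        hit = np.unique(comp[d2 <= radius_px**2])
        counts[i] = len(hit)
    fraction = float((counts > 0).mean())
    return fraction, counts
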