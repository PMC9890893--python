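"""Quantification of stained-section fluorescence images.

Operates on calibrated single-channel planes (intensity grid + pixel size)
with a region-of-interest mask: thresholded area fractions, plaque particle
detection with the standard diameter > 8 um filter, microglial soma density
and size, per-cell skeleton morphometry (branch count, junction count,
total branch length), plaque-centered 30 um neighborhoods, and two-channel
colocalization.

Conventions: pixel indices are 0-based with the origin at the top-left;
all reported geometry is in physical micrometres; objects are 8-connected
components of above-threshold pixels; the "diameter" of an irregular
object is its equivalent circular diameter 2*sqrt(area/pi); distances are
Euclidean distances between centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "ImagePlane",
    "RoiMask",
    "area_fraction",
    "detect_particles",
    "microglia_somata",
    "skeleton_morphometry",
    "plaque_neighborhood",
    "colocalized_area",
    "pooled_otsu_threshold",
    "read_plane",
]

EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ImagePlane:
    """Calibrated 2-D intensity grid for one stain channel."""

    data: np.ndarray
    pixel_size_um: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("plane must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("intensities must be finite and nonnegative")


@dataclass
class RoiMask:
    """Binary analysis region congruent with its plane."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    @classmethod
    def full(cls, plane: ImagePlane) -> "RoiMask":
        return cls(np.ones(plane.data.shape, dtype=bool), plane.pixel_size_um)


def _check_congruent(plane: ImagePlane, roi: RoiMask) -> None:
    if plane.data.shape != roi.mask.shape:
        raise ValueError("ROI mask is not congruent with the plane")


def area_fraction(plane: ImagePlane, roi: RoiMask, threshold: float) -> float:
    """Percent of ROI pixels with intensity above the threshold."""
    _check_congruent(plane, roi)
    inside = roi.mask.sum()
    if inside == 0:
        raise ValueError("ROI is empty")
    above = np.count_nonzero((plane.data > threshold) & roi.mask)
    return 100.0 * above / inside


def detect_particles(
    plane: ImagePlane,
    roi: RoiMask,
    threshold: float,
    min_diameter_um: float = 8.0,
    max_diameter_um: float = np.inf,
) -> tuple:
    """Particle analysis: 8-connected above-threshold objects within the ROI.

    Objects with equivalent circular diameter strictly greater than
    ``min_diameter_um`` (and at most ``max_diameter_um``) are retained.
    Returns ``(ParticleTable DataFrame, summary dict)`` with summary keys
    ``count``, ``density_per_mm2`` (count / ROI area) and
    ``mean_area_um2``.
    """
    _check_congruent(plane, roi)
    fg = (plane.data > threshold) & roi.mask
    labels, _ = ndimage.label(fg, structure=EIGHT)
    px = plane.pixel_size_um
    rows = []
    for rp in measure.regionprops(labels):
        area = rp.area * px**2
        diam = 2.0 * np.sqrt(area / np.pi)
        if diam > min_diameter_um and diam <= max_diameter_um:
            cy, cx = rp.centroid
            rows.append({
                "area_um2": area,
                "equivalent_diameter_um": diam,
                "centroid_x_um": cx * px,
                "centroid_y_um": cy * px,
            })
    table = pd.DataFrame(rows, columns=["area_um2", "equivalent_diameter_um",
                                        "centroid_x_um", "centroid_y_um"])
    roi_mm2 = roi.area_um2 / 1e6
    summary = {
        "count": len(table),
        "density_per_mm2": len(table) / roi_mm2,
        "mean_area_um2": float(table["area_um2"].mean()) if len(table) else np.nan,
    }
    return table, summary


def microglia_somata(
    plane: ImagePlane,
    threshold: float,
    roi: RoiMask | None = None,
    min_diameter_um: float = 4.0,
    max_diameter_um: float = 30.0,
) -> dict:
    """Microglial cell-body detection with a soma-scale size gate.

    The threshold should isolate the bright somata from the dimmer
    processes. Returns ``density_per_mm2``, ``mean_soma_area_um2``,
    ``count`` and the underlying particle ``table``.
    """
    roi = roi or RoiMask.full(plane)
    table, summary = detect_particles(plane, roi, threshold,
                                      min_diameter_um=min_diameter_um,
                                      max_diameter_um=max_diameter_um)
    return {
        "count": summary["count"],
        "density_per_mm2": summary["density_per_mm2"],
        "mean_soma_area_um2": summary["mean_area_um2"],
        "table": table,
    }


def skeleton_morphometry(plane: ImagePlane, threshold: float,
                         min_area_um2: float = 0.0) -> pd.DataFrame:
    """Per-cell skeleton morphometry of above-threshold structures.

    Each 8-connected foreground component is skeletonized (medial axis);
    junctions are clusters of skeleton pixels with 3 or more skeleton
    neighbors, branches are the connected skeleton segments remaining after
    junction removal, and total branch length is the weight of a minimum
    spanning tree over the skeleton pixel graph (straight steps = 1 pixel,
    diagonal steps = sqrt(2) pixels, so spurious corner diagonals are not
    double counted), scaled to micrometres.

    Returns a DataFrame with one row per cell: ``branch_count``,
    ``junction_count``, ``total_branch_length_um``, ``area_um2``,
    ``centroid_x_um``, ``centroid_y_um``. Empty when no foreground.
    """
    fg = plane.data > threshold
    labels, n = ndimage.label(fg, structure=EIGHT)
    px = plane.pixel_size_um
    rows = []
    for rp in measure.regionprops(labels):
        area = rp.area * px**2
        if area < min_area_um2:
            continue
        comp = labels[rp.slice] == rp.label
        skel = skeletonize(comp)
        if not skel.any():
            continue
        nbrs = ndimage.convolve(skel.astype(int), EIGHT.astype(int),
                                mode="constant") - skel.astype(int)
        junction_px = skel & (nbrs >= 3)
        _, n_junctions = ndimage.label(junction_px, structure=EIGHT)
        seg_labels, n_branches = ndimage.label(skel & ~junction_px, structure=EIGHT)
        if n_branches == 0 and skel.sum() > 0:
            n_branches = 1  # skeleton entirely junction-like (tiny blob)
        cy, cx = rp.centroid
        rows.append({
            "branch_count": int(n_branches),
            "junction_count": int(n_junctions),
            "total_branch_length_um": _skeleton_length_px(skel) * px,
            "area_um2": area,
            "centroid_x_um": cx * px,
            "centroid_y_um": cy * px,
        })
    return pd.DataFrame(rows, columns=["branch_count", "junction_count",
                                       "total_branch_length_um", "area_um2",
                                       "centroid_x_um", "centroid_y_um"])


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Total path length of a skeleton in pixel units via an MST over the
    pixel adjacency graph (1 for straight, sqrt(2) for diagonal steps)."""
    ys, xs = np.nonzero(skel)
    n = ys.size
    if n < 2:
        return 0.0
    index = -np.ones(skel.shape, dtype=int)
    index[ys, xs] = np.arange(n)
    rows_i, cols_j, weights = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1)]  # upper half; MST is undirected
    h, w = skel.shape
    for dy, dx in offsets:
        yy, xx = ys + dy, xs + dx
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        ok[ok] &= skel[yy[ok], xx[ok]]
        src = index[ys[ok], xs[ok]]
        dst = index[yy[ok], xx[ok]]
        wgt = np.full(src.size, np.sqrt(2.0) if dy * dx != 0 else 1.0)
        rows_i.append(src)
        cols_j.append(dst)
        weights.append(wgt)
    g = coo_matrix((np.concatenate(weights),
                    (np.concatenate(rows_i), np.concatenate(cols_j))),
                   shape=(n, n))
    return float(minimum_spanning_tree(g).sum())


def plaque_neighborhood(
    plaque_plane: ImagePlane,
    microglia_plane: ImagePlane,
    radius_um: float = 30.0,
    *,
    plaque_threshold: float,
    microglia_threshold: float,
    soma_threshold: float | None = None,
    min_plaque_diameter_um: float = 8.0,
    roi: RoiMask | None = None,
) -> pd.DataFrame:
    """Plaque-centered neighborhood analysis within ``radius_um``.

    For each plaque (diameter > ``min_plaque_diameter_um``): the number of
    microglia whose soma centroid lies within ``radius_um`` of the plaque
    centroid, and the plaque-microglia colocalized area inside that disk
    divided by the microglia count (``coverage_per_microglion_um2``; NaN
    and flagged when no microglia are near).

    ``soma_threshold`` (default: ``microglia_threshold``) isolates somata
    for the counting step; the coverage step uses ``microglia_threshold``
    on the full microglial signal.
    """
    if plaque_plane.data.shape != microglia_plane.data.shape:
        raise ValueError("plaque and microglia planes are not congruent")
    if plaque_plane.pixel_size_um != microglia_plane.pixel_size_um:
        raise ValueError("plaque and microglia planes have different calibrations")
    px = plaque_plane.pixel_size_um
    roi = roi or RoiMask.full(plaque_plane)
    plaques, _ = detect_particles(plaque_plane, roi, plaque_threshold,
                                  min_diameter_um=min_plaque_diameter_um)
    somata = microglia_somata(microglia_plane,
                              soma_threshold if soma_threshold is not None
                              else microglia_threshold, roi=roi)
    soma_xy = somata["table"][["centroid_x_um", "centroid_y_um"]].to_numpy()

    yy, xx = np.mgrid[0:plaque_plane.data.shape[0], 0:plaque_plane.data.shape[1]]
    coloc = (plaque_plane.data > plaque_threshold) & \
            (microglia_plane.data > microglia_threshold)
    rows = []
    for _, p in plaques.iterrows():
        cx, cy = p["centroid_x_um"], p["centroid_y_um"]
        if soma_xy.size:
            d = np.hypot(soma_xy[:, 0] - cx, soma_xy[:, 1] - cy)
            count = int((d <= radius_um).sum())
        else:
            count = 0
        disk = ((xx * px - cx) ** 2 + (yy * px - cy) ** 2) <= radius_um**2
        coloc_area = float(np.count_nonzero(coloc & disk)) * px**2
        rows.append({
            "centroid_x_um": cx,
            "centroid_y_um": cy,
            "plaque_area_um2": p["area_um2"],
            "microglia_count": count,
            "colocalized_area_um2": coloc_area,
            "coverage_per_microglion_um2":
                coloc_area / count if count else np.nan,
            "flag": "" if count else "no microglia within radius",
        })
    return pd.DataFrame(rows, columns=["centroid_x_um", "centroid_y_um",
                                       "plaque_area_um2", "microglia_count",
                                       "colocalized_area_um2",
                                       "coverage_per_microglion_um2", "flag"])


def colocalized_area(
    planeA: ImagePlane,
    planeB: ImagePlane,
    thresholds: tuple | None = None,
    roi: RoiMask | None = None,
) -> dict:
    """Two-channel colocalization: area where both channels exceed threshold.

    With explicit ``thresholds = (tA, tB)`` the measurement is exact and
    deterministic. Without them, a Costes-style automated search walks the
    two thresholds down a common intensity fraction and bisects for the
    point at which the below-threshold pixels are uncorrelated (their
    Pearson correlation crosses zero).

    Returns ``area_um2`` (pixels above both thresholds), ``fraction``
    (that area over the union of the two single-channel masks, 1.0 for
    identical masks, 0.0 for disjoint ones) and the thresholds used.
    """
    if planeA.data.shape != planeB.data.shape:
        raise ValueError("planes are not congruent")
    roi = roi or RoiMask.full(planeA)
    _check_congruent(planeA, roi)
    a, b = planeA.data[roi.mask], planeB.data[roi.mask]
    if thresholds is None:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("constant channel: automated thresholding is undefined")
        thresholds = _costes_thresholds(a, b)
    tA, tB = thresholds
    maskA = (planeA.data > tA) & roi.mask
    maskB = (planeB.data > tB) & roi.mask
    inter = np.count_nonzero(maskA & maskB)
    union = np.count_nonzero(maskA | maskB)
    return {
        "area_um2": inter * planeA.pixel_size_um**2,
        "fraction": inter / union if union else 0.0,
        "threshold_a": float(tA),
        "threshold_b": float(tB),
    }


def _costes_thresholds(a: np.ndarray, b: np.ndarray, n_iter: int = 60) -> tuple:
    """Bisection for the threshold fraction at which below-threshold pixels
    decorrelate, applied to both channels at the same intensity fraction."""

    def below_corr(frac: float) -> float:
        ta = a.min() + frac * np.ptp(a)
        tb = b.min() + frac * np.ptp(b)
        sel = (a < ta) | (b < tb)
        if sel.sum() < 3 or np.ptp(a[sel]) == 0 or np.ptp(b[sel]) == 0:
            return 0.0
        return float(np.corrcoef(a[sel], b[sel])[0, 1])
    lo, hi = 1e-6, 1.0
    if below_corr(hi) <= 0:
        frac = hi
    else:
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            if below_corr(mid) > 0:
                hi = mid
            else:
                lo = mid
        frac = 0.5 * (lo + hi)
    return (a.min() + frac * np.ptp(a), b.min() + frac * np.ptp(b))


def pooled_otsu_threshold(planes) -> float:
    """Otsu threshold on the pooled histogram of a batch of planes.

    Helper for choosing the single "unified" per-stain threshold that is
    then applied to every image of the batch.
    """
    pooled = np.concatenate([np.asarray(p.data).ravel() for p in planes])
    return float(threshold_otsu(pooled))


def read_plane(tiff_path, calibration_yaml=None, channel: str = "") -> ImagePlane:
    """Read a single-plane TIFF plus its YAML calibration sidecar.

    The sidecar must provide ``pixel_size_um`` (and may name the
    ``channel``); alternatively pass ``calibration_yaml`` as a dict.
    """
    import pathlib

    import tifffile
    import yaml

    data = tifffile.imread(tiff_path)
    if calibration_yaml is None:
        calibration_yaml = pathlib.Path(tiff_path).with_suffix(".yaml")
    if isinstance(calibration_yaml, dict):
        cal = calibration_yaml
    else:
        with open(calibration_yaml) as fh:
            cal = yaml.safe_load(fh)
    return ImagePlane(data, float(cal["pixel_size_um"]),
                      channel=channel or cal.get("channel", ""))
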