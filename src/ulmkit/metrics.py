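"""Quantitative and qualitative microvascular metrics.

From the tracks and the super-resolved density map this module computes the
standard microvasculature descriptors of a lesion ROI:

* mean / max flow velocity (mm/s) — per-track mean speeds over in-ROI steps;
* mean / max tortuosity — path length / chord length per track (distance
  metric; 1 for a straight vessel);
* mean / largest vessel diameter (um) — skeleton + Euclidean distance
  transform of the binarized vessel map;
* fractal dimension — box counting on the binary vessel raster (in [1, 2]);
* microvascular density (MVD, %) — tracked-microbubble area / ROI area;
* microvasculature distribution {central, peripheral, diffuse} and flow
  direction {toward, away} — rule-based operationalizations of the two
  reader-assessed qualitative features.

Velocities are mm/s everywhere in this package; any cm/s presentation is an
explicit conversion at the output layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .reconstruction import SRMap
from .tracking import Track, track_speeds

__all__ = [
    "ROIMask",
    "VascularMetrics",
    "roi_velocity_stats",
    "track_tortuosity",
    "vessel_diameters",
    "fractal_dimension",
    "microvascular_density",
    "tracked_pixel_mask",
    "classify_distribution",
    "classify_flow_direction",
    "compute_vascular_metrics",
]


@dataclass
class ROIMask:
    """Binary lesion mask on the frame grid."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size_um * 1e-3) ** 2

    def upsample(self, factor: int) -> np.ndarray:
        """Nearest-neighbour resample of the mask to the SR grid."""
        return np.repeat(np.repeat(self.mask, factor, axis=0), factor, axis=1)

    def contains_um(self, axial_um, lateral_um) -> np.ndarray:
        i = np.clip((np.asarray(axial_um) / self.pixel_size_um).astype(int),
                    0, self.mask.shape[0] - 1)
        j = np.clip((np.asarray(lateral_um) / self.pixel_size_um).astype(int),
                    0, self.mask.shape[1] - 1)
        return self.mask[i, j]


@dataclass
class VascularMetrics:
    """One lesion's microvascular descriptor record (Table-style row).

    NaN marks a flagged missing value (for example, no in-ROI track).
    """

    mean_flow_velocity_mm_s: float
    max_flow_velocity_mm_s: float
    mean_tortuosity: float
    max_tortuosity: float
    mean_diameter_um: float
    largest_diameter_um: float
    fractal_dimension: float
    mvd_percent: float
    distribution: str      # central | peripheral | diffuse | undefined
    flow_direction: str    # toward | away | indeterminate

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Velocity and tortuosity
# ---------------------------------------------------------------------------

def _in_roi_steps(track: Track, roi: ROIMask) -> np.ndarray:
    """Boolean mask over track steps whose midpoint lies inside the ROI."""
    p = track.positions_um
    mid = 0.5 * (p[:-1] + p[1:])
    return roi.contains_um(mid[:, 0], mid[:, 1])


def roi_velocity_stats(tracks: list[Track], roi: ROIMask,
                       frame_rate_hz: float) -> tuple[float, float]:
    """Mean and max flow velocity (mm/s) over tracks intersecting the ROI.

    Each track contributes the mean of its in-ROI step speeds; the ROI mean
    is the average over contributing tracks and the max is the largest
    per-track mean (robust to single-step noise).  Returns (nan, nan) when
    no track intersects the ROI.
    """
    per_track = []
    for tr in tracks:
        sel = _in_roi_steps(tr, roi)
        if not sel.any():
            continue
        speeds, _ = track_speeds(tr, frame_rate_hz)
        per_track.append(float(speeds[sel].mean()))
    if not per_track:
        return (float("nan"), float("nan"))
    return float(np.mean(per_track)), float(np.max(per_track))


def track_tortuosity(track: Track) -> float:
    """Distance-metric tortuosity: path length / chord length (>= 1).

    A closed loop (zero chord) yields NaN and is excluded from ROI
    statistics by callers.
    """
    chord = track.chord_length_um
    if chord <= 0:
        return float("nan")
    return track.path_length_um / chord


def roi_tortuosity_stats(tracks: list[Track], roi: ROIMask) -> tuple[float, float]:
    """Mean and max tortuosity over in-ROI tracks (NaN-tortuosity excluded)."""
    vals = [track_tortuosity(tr) for tr in tracks if _in_roi_steps(tr, roi).any()]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        return (float("nan"), float("nan"))
    return float(np.mean(vals)), float(np.max(vals))


# ---------------------------------------------------------------------------
# Geometry of the super-resolved vessel map
# ---------------------------------------------------------------------------

def binarize_sr_map(sr_map: SRMap, roi_sr: np.ndarray | None = None,
                    min_count: int = 1) -> np.ndarray:
    """Binary vessel mask: SR bins with >= min_count localizations, with
    isolated single-pixel bins removed (they are localization noise, not
    vessel)."""
    mask = sr_map.counts >= min_count
    if roi_sr is not None:
        mask = mask & roi_sr
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return np.isin(labels, np.flatnonzero(sizes >= 2))


def vessel_diameters(sr_map: SRMap, roi: ROIMask | None = None,
                     binary_mask: np.ndarray | None = None) -> tuple[float, float]:
    """Mean and largest vessel diameter (um) from the SR map.

    The binary vessel mask is skeletonized; the diameter at each skeleton
    pixel is twice the Euclidean distance-transform value times the SR grid
    spacing.  Returns (nan, nan) on an empty vessel mask.
    """
    if binary_mask is None:
        roi_sr = roi.upsample(sr_map.upsampling_factor) if roi is not None else None
        binary_mask = binarize_sr_map(sr_map, roi_sr)
    if not binary_mask.any():
        return (float("nan"), float("nan"))
    skel = morphology.skeletonize(binary_mask)
    if not skel.any():
        return (float("nan"), float("nan"))
    edt = ndimage.distance_transform_edt(binary_mask)
    diam = 2.0 * edt[skel] * sr_map.grid_spacing_um
    return float(diam.mean()), float(diam.max())


def fractal_dimension(binary_map: np.ndarray,
                      scales: np.ndarray | None = None) -> float:
    """Box-counting fractal dimension of a binary raster.

    N(s) = number of s x s boxes containing at least one foreground pixel,
    over dyadic scales; the dimension is the least-squares slope of
    log N(s) against log(1/s).  Returns NaN (degenerate) when all counts
    are equal; raises if fewer than two scales have non-zero counts.
    """
    m = np.asarray(binary_map, dtype=bool)
    if scales is None:
        max_exp = int(np.floor(np.log2(min(m.shape))))
        scales = 2 ** np.arange(0, max(max_exp, 1))
    counts = []
    used = []
    for s in scales:
        s = int(s)
        n_ax = int(np.ceil(m.shape[0] / s))
        n_la = int(np.ceil(m.shape[1] / s))
        padded = np.zeros((n_ax * s, n_la * s), dtype=bool)
        padded[:m.shape[0], :m.shape[1]] = m
        blocks = padded.reshape(n_ax, s, n_la, s).any(axis=(1, 3))
        n = int(blocks.sum())
        if n > 0:
            counts.append(n)
            used.append(s)
    if len(counts) < 2:
        raise ValueError("need >= 2 box scales with non-zero counts")
    counts = np.asarray(counts, float)
    if np.all(counts == counts[0]):
        return float("nan")
    slope = np.polyfit(np.log(1.0 / np.asarray(used, float)), np.log(counts), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Density and qualitative features
# ---------------------------------------------------------------------------

def tracked_pixel_mask(tracks: list[Track], fov_um: tuple[float, float],
                       grid_spacing_um: float) -> np.ndarray:
    """SR-grid mask of bins visited by any tracked microbubble position."""
    n_ax = int(round(fov_um[0] / grid_spacing_um))
    n_la = int(round(fov_um[1] / grid_spacing_um))
    mask = np.zeros((n_ax, n_la), dtype=bool)
    for tr in tracks:
        p = tr.positions_um
        i = np.clip((p[:, 0] // grid_spacing_um).astype(int), 0, n_ax - 1)
        j = np.clip((p[:, 1] // grid_spacing_um).astype(int), 0, n_la - 1)
        mask[i, j] = True
    return mask


def microvascular_density(tracked_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """MVD (%) = unique tracked-microbubble pixel area / ROI area x 100.

    Both masks must share one grid.
    """
    if tracked_mask.shape != roi_mask.shape:
        raise ValueError("tracked mask and ROI mask must share a grid")
    roi_area = roi_mask.sum()
    if roi_area == 0:
        raise ValueError("ROI area must be positive")
    return float((tracked_mask & roi_mask).sum() / roi_area * 100.0)


def _radial_positions_ray(points_px: np.ndarray, mask: np.ndarray,
                          centroid: np.ndarray) -> np.ndarray:
    """r = |p - c| / (boundary distance from c along the ray through p)."""
    out = np.empty(len(points_px))
    diag = float(np.hypot(*mask.shape))
    for k, p in enumerate(points_px):
        d = p - centroid
        dist = np.hypot(*d)
        if dist == 0:
            out[k] = 0.0
            continue
        u = d / dist
        # march from the centroid until the ray leaves the mask
        ts = np.arange(0.0, diag, 0.25)
        pts = centroid[None, :] + ts[:, None] * u[None, :]
        i = np.round(pts[:, 0]).astype(int)
        j = np.round(pts[:, 1]).astype(int)
        inside = ((i >= 0) & (i < mask.shape[0]) & (j >= 0) & (j < mask.shape[1]))
        inside[inside] = mask[i[inside], j[inside]]
        leave = np.flatnonzero(~inside)
        boundary_t = ts[leave[0]] if len(leave) else diag
        out[k] = dist / max(boundary_t, 1e-9)
    return np.clip(out, 0.0, None)


def _radial_positions_dt(points_px: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Distance-transform variant: r = 1 - D(p)/max(D), robust to holes."""
    dt = ndimage.distance_transform_edt(mask)
    dmax = dt.max()
    i = np.clip(np.round(points_px[:, 0]).astype(int), 0, mask.shape[0] - 1)
    j = np.clip(np.round(points_px[:, 1]).astype(int), 0, mask.shape[1] - 1)
    return 1.0 - dt[i, j] / max(dmax, 1e-9)


def classify_distribution(localizations_um: np.ndarray, roi: ROIMask,
                          peripheral_r: float = 0.7, central_r: float = 0.5,
                          majority: float = 0.6) -> str:
    """Classify microvessel spatial arrangement in the ROI.

    Each localization gets a normalized radial position r in [0, 1]
    (0 = ROI centroid, 1 = boundary).  The label is ``peripheral`` when at
    least ``majority`` of localizations have r > ``peripheral_r``,
    ``central`` when at least ``majority`` have r < ``central_r``, else
    ``diffuse``.  Ray casting is used for simply connected ROIs; a
    distance-transform fallback handles ROIs with holes.

    The default cuts are chosen so that the three canonical patterns
    separate on a convex ROI: a uniform fill has 1 - r0^2 of its mass beyond
    radius r0, so the peripheral cut must satisfy 1 - r^2 < majority
    (r = 0.7 gives 51% < 60%), while a boundary-hugging pattern still
    exceeds it easily.
    """
    pts = np.asarray(localizations_um, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("need >= 1 localization (N, 2)")
    px = pts / roi.pixel_size_um
    inside = roi.contains_um(pts[:, 0], pts[:, 1])
    px = px[inside]
    if len(px) == 0:
        raise ValueError("no localization inside the ROI")
    simply_connected = measure.euler_number(roi.mask, connectivity=2) == 1
    if simply_connected:
        centroid = np.array(ndimage.center_of_mass(roi.mask))
        r = _radial_positions_ray(px, roi.mask, centroid)
    else:
        r = _radial_positions_dt(px, roi.mask)
    r = np.clip(r, 0.0, 1.0)
    if np.mean(r > peripheral_r) >= majority:
        return "peripheral"
    if np.mean(r < central_r) >= majority:
        return "central"
    return "diffuse"


def classify_flow_direction(tracks: list[Track], roi: ROIMask,
                            frame_rate_hz: float) -> str:
    """Dominant axial flow direction in the ROI.

    Length-weighted mean of signed axial step velocities over in-ROI steps:
    positive (increasing depth) -> ``away`` from the transducer, negative ->
    ``toward``; an exact zero is reported ``indeterminate``.
    """
    num = 0.0
    den = 0.0
    for tr in tracks:
        p = tr.positions_um
        d = np.diff(p, axis=0)
        sel = _in_roi_steps(tr, roi)
        if not sel.any():
            continue
        lengths = np.hypot(d[sel, 0], d[sel, 1])
        v_ax = d[sel, 0] * frame_rate_hz * 1e-3
        num += float((lengths * v_ax).sum())
        den += float(lengths.sum())
    if den == 0:
        raise ValueError("no in-ROI track step")
    mean_vax = num / den
    if mean_vax > 0:
        return "away"
    if mean_vax < 0:
        return "toward"
    return "indeterminate"


# ---------------------------------------------------------------------------
# One-call lesion record
# ---------------------------------------------------------------------------

def compute_vascular_metrics(tracks: list[Track], sr_map: SRMap,
                             roi: ROIMask, frame_rate_hz: float,
                             fov_um: tuple[float, float]) -> VascularMetrics:
    """Assemble the full per-lesion microvascular record."""
    mean_v, max_v = roi_velocity_stats(tracks, roi, frame_rate_hz)
    mean_t, max_t = roi_tortuosity_stats(tracks, roi)
    roi_sr = roi.upsample(sr_map.upsampling_factor)
    vessel_mask = binarize_sr_map(sr_map, roi_sr)
    mean_d, max_d = vessel_diameters(sr_map, binary_mask=vessel_mask)
    # box counting runs on the vessel raster at frame resolution: the SR
    # grid is localization-sparse at finite acquisition length, which would
    # measure the dimension of the sampling dust rather than the network
    factor = sr_map.upsampling_factor
    occ = sr_map.counts > 0
    coarse = occ.reshape(occ.shape[0] // factor, factor,
                         occ.shape[1] // factor, factor).any(axis=(1, 3))
    coarse &= roi.mask
    try:
        fd = fractal_dimension(coarse)
    except ValueError:
        fd = float("nan")
    tracked = tracked_pixel_mask(tracks, fov_um, sr_map.grid_spacing_um)
    mvd = microvascular_density(tracked, roi_sr)
    locs = np.argwhere(sr_map.counts > 0) * sr_map.grid_spacing_um
    try:
        dist = classify_distribution(locs, roi)
    except ValueError:
        dist = "undefined"
    try:
        direction = classify_flow_direction(tracks, roi, frame_rate_hz)
    except ValueError:
        direction = "indeterminate"
    return VascularMetrics(
        mean_flow_velocity_mm_s=mean_v, max_flow_velocity_mm_s=max_v,
        mean_tortuosity=mean_t, max_tortuosity=max_t,
        mean_diameter_um=mean_d, largest_diameter_um=max_d,
        fractal_dimension=fd, mvd_percent=mvd,
        distribution=dist, flow_direction=direction,
    )
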