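"""Super-resolution reconstruction: clutter filtering, microbubble detection,
sub-pixel localization and density-map accumulation.

The chain is the standard ultrasound localization microscopy (ULM) pipeline:

1. SVD clutter filtering on the Casorati matrix (pixels x frames) separates
   slowly varying tissue signal (low-order singular components) from the
   fast-moving microbubble signal.
2. A per-frame intensity threshold isolates candidate microbubble blobs;
   area and eccentricity gates reject artifacts.
3. Each accepted blob is localized below the pixel grid with an
   intensity-weighted centroid.
4. Localizations from all frames accumulate on an upsampled grid into a
   super-resolved vessel-density map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .stack import FrameStack

__all__ = [
    "MBDetection",
    "Localization",
    "SRMap",
    "svd_clutter_filter",
    "suggest_rank_cut",
    "detect_microbubbles",
    "localize_centroid",
    "accumulate_density_map",
]


@dataclass
class MBDetection:
    """A connected supra-threshold component in one filtered frame."""

    frame: int
    pixels: np.ndarray        # (k, 2) integer (row, col) indices
    area_px: int
    peak_intensity: float
    eccentricity: float       # 0 = circle, -> 1 = line
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("detection area must be >= 1 pixel")
        if not (0.0 <= self.eccentricity < 1.0 + 1e-12):
            raise ValueError("eccentricity must lie in [0, 1)")


@dataclass
class Localization:
    """A sub-pixel microbubble position in micrometres."""

    frame: int
    axial_um: float
    lateral_um: float
    intensity: float


@dataclass
class SRMap:
    """Super-resolved localization-count grid.

    ``counts[i, j]`` is the number of localizations whose position falls in
    super-resolution bin (i, j); ``grid_spacing_um = pixel_size /
    upsampling_factor``.
    """

    counts: np.ndarray
    upsampling_factor: int
    grid_spacing_um: float

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("SR counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# SVD clutter filter
# ---------------------------------------------------------------------------

def svd_clutter_filter(stack: FrameStack, low_cut: int = 1,
                       high_cut: int | None = None) -> FrameStack:
    """Remove tissue clutter by zeroing low-order singular components.

    The stack is reshaped to the Casorati matrix (pixels as rows, frames as
    columns) and rebuilt from singular components with 1-based index in
    ``(low_cut, high_cut]``.  ``low_cut=0`` with ``high_cut=n_frames`` is the
    identity; ``low_cut=1`` removes the dominant (static tissue) component.
    """
    n_frames, n_ax, n_la = stack.shape
    if high_cut is None:
        high_cut = n_frames
    if not (0 <= low_cut < high_cut <= n_frames):
        raise ValueError(
            f"need 0 <= low_cut < high_cut <= n_frames, got "
            f"({low_cut}, {high_cut}] with {n_frames} frames"
        )
    casorati = stack.frames.reshape(n_frames, -1).T  # pixels x frames
    u, s, vt = np.linalg.svd(casorati, full_matrices=False)
    s_kept = s.copy()
    s_kept[:low_cut] = 0.0
    s_kept[high_cut:] = 0.0
    filtered = (u * s_kept) @ vt
    frames = filtered.T.reshape(n_frames, n_ax, n_la)
    meta = dict(stack.meta)
    meta.update({"svd_low_cut": low_cut, "svd_high_cut": high_cut,
                 "singular_values": s})
    return FrameStack(frames, stack.frame_rate_hz, stack.pixel_size_um, meta)


def suggest_rank_cut(singular_values: np.ndarray, gap_factor: float = 4.0,
                     minimum: int = 1) -> int:
    """Suggest how many low-order components carry tissue clutter.

    Returns the smallest ``k`` after which the normalized singular-value
    decay flattens: the largest index ``k`` (searching from the top) with
    ``s[k-1] / s[k] > gap_factor``, i.e. the last big relative gap in the
    spectrum.  A flat spectrum returns ``minimum``.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 singular values")
    if np.any(np.diff(s) > 1e-9 * s[0]):
        raise ValueError("singular values must be non-increasing")
    if s[0] <= 0:
        raise ValueError("all-zero singular spectrum")
    ratios = s[:-1] / np.maximum(s[1:], np.finfo(float).tiny * s[0])
    big = np.flatnonzero(ratios > gap_factor)
    if big.size == 0:
        return minimum
    return max(int(big[-1]) + 1, minimum)


# ---------------------------------------------------------------------------
# Detection and localization
# ---------------------------------------------------------------------------

def detect_microbubbles(frame: np.ndarray, threshold: float | str = "mean+3sd",
                        area_min_px: int = 2, area_max_px: int = 60,
                        ecc_max: float = 0.9,
                        frame_index: int = 0) -> list[MBDetection]:
    """Find microbubble blobs in one clutter-filtered frame.

    ``threshold`` is either an absolute intensity or the rule
    ``"mean+<k>sd"`` evaluated on the frame.  Components are 8-connected;
    those failing the area or eccentricity gates are dropped.  Components
    touching the frame border are kept but flagged.
    """
    frame = np.asarray(frame, dtype=float)
    if isinstance(threshold, str):
        rule = threshold.replace(" ", "")
        if not rule.startswith("mean+") or not rule.endswith("sd"):
            raise ValueError(f"unknown threshold rule {threshold!r}")
        k = float(rule[len("mean+"):-len("sd")])
        thr = frame.mean() + k * frame.std()
    else:
        thr = float(threshold)
    mask = frame > thr
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    out: list[MBDetection] = []
    n_ax, n_la = frame.shape
    for rp in measure.regionprops(labels, intensity_image=frame):
        if not (area_min_px <= rp.area <= area_max_px):
            continue
        ecc = float(rp.eccentricity)
        if ecc > ecc_max:
            continue
        coords = rp.coords
        touches = bool(
            coords[:, 0].min() == 0 or coords[:, 1].min() == 0
            or coords[:, 0].max() == n_ax - 1 or coords[:, 1].max() == n_la - 1
        )
        out.append(MBDetection(
            frame=frame_index, pixels=coords, area_px=int(rp.area),
            peak_intensity=float(rp.intensity_max),
            eccentricity=min(ecc, 1.0 - 1e-12), touches_border=touches,
        ))
    return out


def localize_centroid(frame: np.ndarray, detection: MBDetection,
                      pixel_size_um: float) -> Localization:
    """Sub-pixel position as the intensity-weighted centroid of a blob.

    Position = sum(intensity * pixel-centre position) / sum(intensity), in
    micrometres with the origin at the top-left pixel centre.
    """
    coords = detection.pixels
    if coords.shape[0] == 0:
        raise ValueError("empty detection pixel set")
    w = np.asarray(frame, dtype=float)[coords[:, 0], coords[:, 1]]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total intensity in detection")
    ax = float((w * coords[:, 0]).sum() / total) * pixel_size_um
    la = float((w * coords[:, 1]).sum() / total) * pixel_size_um
    return Localization(frame=detection.frame, axial_um=ax, lateral_um=la,
                        intensity=float(total))


def localize_stack(filtered: FrameStack, **detect_kwargs) -> list[Localization]:
    """Detect and localize microbubbles in every frame of a filtered stack."""
    locs: list[Localization] = []
    for f in range(filtered.n_frames):
        frame = filtered.frames[f]
        for det in detect_microbubbles(frame, frame_index=f, **detect_kwargs):
            locs.append(localize_centroid(frame, det, filtered.pixel_size_um))
    return locs


# ---------------------------------------------------------------------------
# Density-map accumulation
# ---------------------------------------------------------------------------

def accumulate_density_map(localizations: list[Localization],
                           fov_um: tuple[float, float],
                           pixel_size_um: float,
                           upsampling_factor: int = 10) -> SRMap:
    """Accumulate localizations on an upsampled grid.

    Each localization increments exactly one super-resolution bin, so the
    map total equals the number of localizations.  A localization outside
    the field of view raises (it signals a reconstruction bug).
    """
    if upsampling_factor < 1 or int(upsampling_factor) != upsampling_factor:
        raise ValueError("upsampling_factor must be a positive integer")
    spacing = pixel_size_um / upsampling_factor
    n_ax = int(round(fov_um[0] / spacing))
    n_la = int(round(fov_um[1] / spacing))
    counts = np.zeros((n_ax, n_la), dtype=np.int64)
    for loc in localizations:
        i = int(loc.axial_um // spacing)
        j = int(loc.lateral_um // spacing)
        if not (0 <= loc.axial_um <= fov_um[0] and 0 <= loc.lateral_um <= fov_um[1]):
            raise ValueError(
                f"localization ({loc.axial_um:.1f}, {loc.lateral_um:.1f}) um "
                f"outside field of view {fov_um}"
            )
        i = min(i, n_ax - 1)
        j = min(j, n_la - 1)
        counts[i, j] += 1
    return SRMap(counts=counts, upsampling_factor=int(upsampling_factor),
                 grid_spacing_um=spacing)
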