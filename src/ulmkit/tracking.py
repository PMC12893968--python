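"""Microbubble tracking: frame-to-frame pairing, track assembly, velocity maps.

For each localized microbubble in frame F the best match in frame F+1 is
sought within a circular search radius (default 700 um).  Candidate pairs are
scored by the zero-lag, zero-mean normalized cross-correlation (NCC) of small
image patches around the two positions in the clutter-filtered frames; pairs
below the NCC threshold (default 0.9) or outside the radius are rejected.
Accepted candidates are assigned one-to-one greedily in descending NCC order
(ties: smaller displacement, then lower frame-F index).  Chained pairs become
tracks, the carriers of all speed and tortuosity measurements.

Note the physics of the gates: a search radius ``r`` um at frame rate ``f``
Hz caps measurable speed at ``r * f / 1000`` mm/s (56 mm/s at 700 um and
80 Hz); the module never produces a speed above that cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reconstruction import Localization

__all__ = [
    "Pair",
    "Track",
    "VelocityMap",
    "pair_consecutive_frames",
    "assemble_tracks",
    "track_speeds",
    "build_velocity_direction_maps",
]


@dataclass
class Pair:
    """An accepted match between localizations in consecutive frames."""

    loc_f: Localization
    loc_f1: Localization
    displacement_um: tuple[float, float]  # (axial, lateral)
    ncc: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.ncc <= 1.0 + 1e-9):
            raise ValueError("NCC must lie in [-1, 1]")


@dataclass
class Track:
    """An ordered chain of localizations over strictly consecutive frames."""

    locs: list[Localization]

    def __post_init__(self) -> None:
        if len(self.locs) < 2:
            raise ValueError("a track needs >= 2 localizations")
        frames = [l.frame for l in self.locs]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frame indices must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.locs)

    @property
    def positions_um(self) -> np.ndarray:
        return np.array([[l.axial_um, l.lateral_um] for l in self.locs])

    @property
    def path_length_um(self) -> float:
        d = np.diff(self.positions_um, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def chord_length_um(self) -> float:
        p = self.positions_um
        return float(np.hypot(*(p[-1] - p[0])))


@dataclass
class VelocityMap:
    """Super-resolution grids of mean speed and mean signed axial velocity.

    Bins never visited by a track step are NaN (undefined), not zero.
    Positive axial velocity means increasing depth, i.e. flow away from the
    transducer.
    """

    mean_speed_mm_s: np.ndarray
    mean_axial_velocity_mm_s: np.ndarray
    counts: np.ndarray
    grid_spacing_um: float


def _patch(frame: np.ndarray, row: float, col: float, half: int) -> np.ndarray:
    """Square patch centred on the sub-pixel position (row, col).

    Sampled by bilinear interpolation so that two patches of the same
    microbubble align regardless of sampling phase; symmetrically cropped
    when the window would extend past the frame border.
    """
    from scipy.ndimage import map_coordinates

    n_ax, n_la = frame.shape
    h = int(min(half, row, col, n_ax - 1 - row, n_la - 1 - col))
    h = max(h, 0)
    offs = np.arange(-h, h + 1, dtype=float)
    rr = row + offs[:, None] + np.zeros((1, 2 * h + 1))
    cc = col + offs[None, :] + np.zeros((2 * h + 1, 1))
    return map_coordinates(frame, [rr.ravel(), cc.ravel()], order=1,
                           mode="nearest").reshape(2 * h + 1, 2 * h + 1)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation at zero lag."""
    if a.size == 0 or b.size == 0:
        return 0.0
    if a.shape != b.shape:
        # crop both to the common centred square
        h = (min(min(a.shape), min(b.shape)) - 1) // 2
        ca = (a.shape[0] // 2, a.shape[1] // 2)
        cb = (b.shape[0] // 2, b.shape[1] // 2)
        a = a[ca[0] - h:ca[0] + h + 1, ca[1] - h:ca[1] + h + 1]
        b = b[cb[0] - h:cb[0] + h + 1, cb[1] - h:cb[1] + h + 1]
        if a.shape != b.shape or a.size == 0:
            return 0.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def pair_consecutive_frames(locs_f: list[Localization],
                            locs_f1: list[Localization],
                            frames: np.ndarray,
                            pixel_size_um: float,
                            search_radius_um: float = 700.0,
                            ncc_threshold: float = 0.9,
                            patch_px: int = 9):
    """One-to-one matching of localizations between consecutive frames.

    ``frames`` is the clutter-filtered stack array used for NCC patches.
    Returns ``(pairs, unmatched_f, unmatched_f1)``; unmatched entries are
    indices into the input lists.
    """
    if patch_px % 2 != 1:
        raise ValueError("patch_px must be odd")
    half = patch_px // 2
    candidates = []
    for i, a in enumerate(locs_f):
        pa = _patch(frames[a.frame], a.axial_um / pixel_size_um,
                    a.lateral_um / pixel_size_um, half)
        for j, b in enumerate(locs_f1):
            d_ax = b.axial_um - a.axial_um
            d_la = b.lateral_um - a.lateral_um
            dist = np.hypot(d_ax, d_la)
            if dist > search_radius_um:
                continue
            pb = _patch(frames[b.frame], b.axial_um / pixel_size_um,
                        b.lateral_um / pixel_size_um, half)
            score = _ncc(pa, pb)
            if score < ncc_threshold:
                continue
            candidates.append((i, j, score, dist, d_ax, d_la))
    # greedy descending NCC; scores within one quantum (0.01) count as tied
    # and fall through to the smaller displacement, then the lower index i.
    # The quantum reflects that sub-pixel sampling phase alone perturbs the
    # patch NCC at the 1e-2 level, so finer differences carry no information.
    candidates.sort(key=lambda c: (-round(c[2], 2), c[3], c[0]))
    used_f: set[int] = set()
    used_f1: set[int] = set()
    pairs: list[Pair] = []
    for i, j, score, dist, d_ax, d_la in candidates:
        if i in used_f or j in used_f1:
            continue
        used_f.add(i)
        used_f1.add(j)
        pairs.append(Pair(locs_f[i], locs_f1[j], (d_ax, d_la), score))
    unmatched_f = [i for i in range(len(locs_f)) if i not in used_f]
    unmatched_f1 = [j for j in range(len(locs_f1)) if j not in used_f1]
    return pairs, unmatched_f, unmatched_f1


def assemble_tracks(pairs: list[Pair], min_track_len: int = 5) -> list[Track]:
    """Chain one-to-one pairs into maximal tracks.

    Tracks shorter than ``min_track_len`` localizations are discarded.  Each
    localization belongs to at most one track (guaranteed by one-to-one
    pairing; violated input trips an assertion).
    """
    nxt: dict[int, Pair] = {}
    heads: dict[int, Localization] = {}
    has_pred: set[int] = set()
    for p in pairs:
        assert id(p.loc_f) not in nxt, "localization paired twice as frame-F"
        assert id(p.loc_f1) not in has_pred, "localization paired twice as frame-F+1"
        nxt[id(p.loc_f)] = p
        heads[id(p.loc_f)] = p.loc_f
        has_pred.add(id(p.loc_f1))
    tracks: list[Track] = []
    for key, start in heads.items():
        if key in has_pred:
            continue
        chain = [start]
        cur = key
        while cur in nxt:
            nxt_loc = nxt[cur].loc_f1
            chain.append(nxt_loc)
            cur = id(nxt_loc)
        if len(chain) >= min_track_len:
            tracks.append(Track(chain))
    return tracks


def track_speeds(track: Track, frame_rate_hz: float):
    """Per-step and mean speed of a track in mm/s.

    Step speed = |displacement um| * frame_rate * 1e-3.
    """
    d = np.diff(track.positions_um, axis=0)
    per_step = np.hypot(d[:, 0], d[:, 1]) * frame_rate_hz * 1e-3
    return per_step, float(per_step.mean())


def build_velocity_direction_maps(tracks: list[Track], frame_rate_hz: float,
                                  fov_um: tuple[float, float],
                                  pixel_size_um: float,
                                  upsampling_factor: int = 10) -> VelocityMap:
    """Bin track steps onto the super-resolution grid.

    Each step contributes its speed and signed axial velocity to the bin
    containing the step midpoint.  Bin values are means over contributing
    steps; untouched bins stay NaN.
    """
    spacing = pixel_size_um / upsampling_factor
    n_ax = int(round(fov_um[0] / spacing))
    n_la = int(round(fov_um[1] / spacing))
    speed_sum = np.zeros((n_ax, n_la))
    vax_sum = np.zeros((n_ax, n_la))
    counts = np.zeros((n_ax, n_la), dtype=np.int64)
    for tr in tracks:
        p = tr.positions_um
        d = np.diff(p, axis=0)
        mid = 0.5 * (p[:-1] + p[1:])
        speeds = np.hypot(d[:, 0], d[:, 1]) * frame_rate_hz * 1e-3
        v_ax = d[:, 0] * frame_rate_hz * 1e-3
        i = np.clip((mid[:, 0] // spacing).astype(int), 0, n_ax - 1)
        j = np.clip((mid[:, 1] // spacing).astype(int), 0, n_la - 1)
        np.add.at(speed_sum, (i, j), speeds)
        np.add.at(vax_sum, (i, j), v_ax)
        np.add.at(counts, (i, j), 1)
    with np.errstate(invalid="ignore"):
        mean_speed = np.where(counts > 0, speed_sum / np.maximum(counts, 1), np.nan)
        mean_vax = np.where(counts > 0, vax_sum / np.maximum(counts, 1), np.nan)
    return VelocityMap(mean_speed, mean_vax, counts, spacing)
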