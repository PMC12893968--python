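"""Synthetic phantom generator with known ground truth.

Every downstream stage of the pipeline — clutter filtering, microbubble
detection and localization, tracking, vascular metrics, time–intensity-curve
analysis and the diagnostic statistics — is tested against data produced
here, where the truth (vessel centerlines, radii, flow speeds, tortuosity,
bolus parameters, cohort effect sizes) is known by construction.

The phantom emulates a high-frame-rate contrast acquisition: a vessel tree of
polyline centerlines carries point-like microbubbles advected at the segment
flow speed; frames are rendered as static/slowly drifting tissue clutter plus
a diffraction-limited Gaussian point-spread function at each bubble position
plus white noise.  Defaults are a 128x128 grid at 50 um/pixel imaged at
80 Hz — the scale of a linear-probe contrast acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import FrameStack
from .tic import TICurve

__all__ = [
    "VesselSegment",
    "VesselTree",
    "VesselTreeConfig",
    "MBGroundTruth",
    "CohortSpec",
    "segment_from_polyline",
    "straight_segment",
    "arc_segment",
    "make_vessel_tree",
    "simulate_mb_flow",
    "render_frames",
    "simulate_tic",
    "simulate_cohort",
    "default_cohort_spec",
]


# ---------------------------------------------------------------------------
# Vessel geometry
# ---------------------------------------------------------------------------

@dataclass
class VesselSegment:
    """One vessel: a centerline polyline with radius and flow speed.

    ``polyline_um`` is an (N, 2) array of (axial, lateral) positions in um.
    ``flow_speed_mm_s`` is the advection speed along the centerline; its sign
    is carried by the polyline direction (first point -> last point).
    ``tortuosity_true`` is path length / chord length (>= 1).
    """

    polyline_um: np.ndarray
    radius_um: float
    flow_speed_mm_s: float
    tortuosity_true: float = field(init=False)

    def __post_init__(self) -> None:
        self.polyline_um = np.asarray(self.polyline_um, dtype=float)
        if self.polyline_um.ndim != 2 or self.polyline_um.shape[1] != 2:
            raise ValueError("polyline must be (N, 2)")
        if self.polyline_um.shape[0] < 2:
            raise ValueError("polyline needs >= 2 points")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.flow_speed_mm_s < 0:
            raise ValueError("flow speed must be non-negative")
        steps = np.diff(self.polyline_um, axis=0)
        self._cumlen = np.concatenate(
            [[0.0], np.cumsum(np.hypot(steps[:, 0], steps[:, 1]))]
        )
        chord = float(np.hypot(*(self.polyline_um[-1] - self.polyline_um[0])))
        if chord <= 0:
            raise ValueError("closed-loop segment (zero chord)")
        self.tortuosity_true = float(self._cumlen[-1] / chord)

    @property
    def length_um(self) -> float:
        return float(self._cumlen[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Centerline point(s) at arc length ``s`` (um), linear interpolation."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        ax = np.interp(s, self._cumlen, self.polyline_um[:, 0])
        la = np.interp(s, self._cumlen, self.polyline_um[:, 1])
        return np.stack([ax, la], axis=-1)

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        """Unit tangent(s) at arc length ``s`` (central finite difference)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        h = max(self.length_um * 1e-4, 1e-6)
        lo = np.clip(s - h, 0, self.length_um)
        hi = np.clip(s + h, 0, self.length_um)
        d = self.point_at(hi) - self.point_at(lo)
        n = np.hypot(d[:, 0], d[:, 1])
        n[n == 0] = 1.0
        return d / n[:, None]


@dataclass
class VesselTree:
    """A collection of vessel segments inside a rectangular field of view."""

    segments: list[VesselSegment]
    fov_um: tuple[float, float]  # (axial, lateral)

    def __post_init__(self) -> None:
        ax_max, la_max = self.fov_um
        for i, seg in enumerate(self.segments):
            p = seg.polyline_um
            if (p[:, 0].min() < 0 or p[:, 1].min() < 0
                    or p[:, 0].max() > ax_max or p[:, 1].max() > la_max):
                raise ValueError(
                    f"segment {i} centerline leaves the field of view "
                    f"(fov_um={self.fov_um})"
                )


def segment_from_polyline(polyline_um, radius_um=20.0, flow_speed_mm_s=10.0):
    """Wrap an explicit centerline polyline as a :class:`VesselSegment`."""
    return VesselSegment(np.asarray(polyline_um, float), radius_um, flow_speed_mm_s)


def straight_segment(start_um, end_um, radius_um=20.0, flow_speed_mm_s=10.0,
                     n_points: int = 2) -> VesselSegment:
    """A straight vessel from ``start_um`` to ``end_um`` (tortuosity 1)."""
    t = np.linspace(0.0, 1.0, max(n_points, 2))[:, None]
    poly = np.asarray(start_um, float) + t * (
        np.asarray(end_um, float) - np.asarray(start_um, float))
    return VesselSegment(poly, radius_um, flow_speed_mm_s)


def arc_segment(center_um, arc_radius_um, theta_start, theta_end,
                radius_um=20.0, flow_speed_mm_s=10.0,
                n_points: int = 361) -> VesselSegment:
    """A circular-arc vessel; a half circle has tortuosity pi/2."""
    th = np.linspace(theta_start, theta_end, n_points)
    c = np.asarray(center_um, float)
    poly = np.stack(
        [c[0] + arc_radius_um * np.sin(th), c[1] + arc_radius_um * np.cos(th)],
        axis=1,
    )
    return VesselSegment(poly, radius_um, flow_speed_mm_s)


@dataclass
class VesselTreeConfig:
    """Geometry of a random vessel tree.

    Segments are sinusoid-perturbed straight lines spanning the lateral
    extent of the field of view; ``curvature_amp_um`` sets the perpendicular
    sinusoid amplitude (0 gives straight vessels).
    """

    fov_um: tuple[float, float] = (6400.0, 6400.0)
    n_segments: int = 3
    radius_um: tuple[float, float] = (20.0, 60.0)
    flow_speed_mm_s: tuple[float, float] = (5.0, 20.0)
    curvature_amp_um: float = 200.0
    curvature_periods: float = 1.5
    margin_um: float = 400.0
    n_points: int = 200
    seed: int = 0


def make_vessel_tree(config: VesselTreeConfig) -> VesselTree:
    """Generate a deterministic random vessel tree from a geometry config.

    Raises ``ValueError`` if the requested curvature would push a centerline
    outside the field of view.
    """
    ax_max, la_max = config.fov_um
    if ax_max <= 0 or la_max <= 0:
        raise ValueError("field of view must be positive")
    rng = np.random.default_rng(config.seed)
    segments = []
    for k in range(config.n_segments):
        depth = rng.uniform(config.margin_um, ax_max - config.margin_um)
        if depth - config.curvature_amp_um < 0 or depth + config.curvature_amp_um > ax_max:
            raise ValueError("curvature amplitude pushes centerline out of FOV")
        la = np.linspace(config.margin_um, la_max - config.margin_um, config.n_points)
        phase = rng.uniform(0, 2 * np.pi)
        ax = depth + config.curvature_amp_um * np.sin(
            2 * np.pi * config.curvature_periods * (la - la[0]) / (la[-1] - la[0])
            + phase
        )
        if ax.min() < 0 or ax.max() > ax_max:
            raise ValueError("curvature amplitude pushes centerline out of FOV")
        radius = rng.uniform(*config.radius_um)
        speed = rng.uniform(*config.flow_speed_mm_s)
        direction = 1 if rng.random() < 0.5 else -1
        poly = np.stack([ax, la], axis=1)
        if direction < 0:
            poly = poly[::-1]
        segments.append(VesselSegment(poly, radius, speed))
    return VesselTree(segments, config.fov_um)


# ---------------------------------------------------------------------------
# Microbubble flow
# ---------------------------------------------------------------------------

@dataclass
class MBGroundTruth:
    """Per-frame microbubble positions and velocities (the truth carrier).

    ``table`` columns: frame, bubble_id, segment_id, axial_um, lateral_um,
    v_axial_mm_s, v_lateral_mm_s, respawned.  Velocities are forward
    differences of position (backward for the final frame), so per-frame
    displacement equals v / frame_rate exactly except on respawn steps,
    which are flagged.
    """

    table: pd.DataFrame
    frame_rate_hz: float
    fov_um: tuple[float, float]
    n_frames_total: int | None = None

    @property
    def n_frames(self) -> int:
        if self.n_frames_total is not None:
            return self.n_frames_total
        if len(self.table) == 0:
            return 0
        return int(self.table["frame"].max()) + 1

    def frame_positions(self, frame: int) -> np.ndarray:
        sub = self.table[self.table["frame"] == frame]
        return sub[["axial_um", "lateral_um"]].to_numpy()


def simulate_mb_flow(tree: VesselTree, density: int, n_frames: int,
                     frame_rate_hz: float, seed: int = 0) -> MBGroundTruth:
    """Advect ``density`` bubbles per segment along centerlines.

    Bubbles move at the segment flow speed along the arc; a bubble reaching
    the segment end respawns at its start (stationary density).  Each bubble
    keeps a fixed perpendicular offset within the vessel radius.

    Raises ``ValueError`` when one frame interval would carry a bubble past
    the whole segment (undersampled phantom).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    bubble_id = 0
    dt = 1.0 / frame_rate_hz
    for seg_id, seg in enumerate(tree.segments):
        step_um = seg.flow_speed_mm_s * 1000.0 * dt
        if step_um > seg.length_um:
            raise ValueError(
                f"segment {seg_id}: per-frame displacement {step_um:.1f} um "
                f"exceeds segment length {seg.length_um:.1f} um"
            )
        for k in range(density):
            # stratified along the segment (steady inflow): bubbles sharing
            # one advection speed keep their spacing forever, so uniform
            # seeding could leave two bubbles permanently overlapping
            s0 = (k + 0.5 * rng.uniform()) * seg.length_um / density
            offset = rng.uniform(-seg.radius_um, seg.radius_um)
            s = (s0 + step_um * np.arange(n_frames))
            wrapped = np.floor(s / seg.length_um) if seg.length_um > 0 else 0
            s_mod = np.mod(s, seg.length_um)
            pts = seg.point_at(s_mod)
            tang = seg.tangent_at(s_mod)
            normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
            pos = pts + offset * normal
            # forward-difference velocity; respawn = wrap count increment
            v = np.empty_like(pos)
            v[:-1] = (pos[1:] - pos[:-1]) * frame_rate_hz / 1000.0
            v[-1] = v[-2] if n_frames > 2 else (pos[-1] - pos[-2]) * frame_rate_hz / 1000.0
            respawn = np.zeros(n_frames, dtype=bool)
            if np.ndim(wrapped):
                respawn[:-1] = np.diff(wrapped) > 0
                v[respawn] = tang[respawn] * seg.flow_speed_mm_s
            for f in range(n_frames):
                rows.append((f, bubble_id, seg_id, pos[f, 0], pos[f, 1],
                             v[f, 0], v[f, 1], bool(respawn[f])))
            bubble_id += 1
    table = pd.DataFrame(
        rows,
        columns=["frame", "bubble_id", "segment_id", "axial_um", "lateral_um",
                 "v_axial_mm_s", "v_lateral_mm_s", "respawned"],
    )
    return MBGroundTruth(table, frame_rate_hz, tree.fov_um, n_frames)


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def _smooth_clutter(shape, amplitude, rng, speckle_sigma_px: float = 2.0):
    """A static tissue background: speckle-like filtered noise.

    The correlation length is set near the resolution cell (a couple of
    pixels), as in real B-mode tissue speckle.
    """
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(rng.normal(size=shape), sigma=speckle_sigma_px)
    img -= img.min()
    if img.max() > 0:
        img /= img.max()
    return amplitude * img


def render_frames(gt: MBGroundTruth, psf_sigma_um: float = 150.0,
                  clutter_amplitude: float = 0.0,
                  clutter_image: np.ndarray | None = None,
                  drift_amplitude: float = 0.0,
                  drift_freq_hz: float = 0.5,
                  noise_sd: float = 0.0,
                  pixel_size_um: float = 50.0,
                  bubble_amplitude: float = 1.0,
                  grid_shape: tuple[int, int] | None = None,
                  seed: int = 0) -> FrameStack:
    """Render a frame stack: clutter(t) + Gaussian PSFs at bubbles + noise.

    The clutter is a static image modulated by an optional sinusoidal gain
    drift, ``clutter(t) = static * (1 + a sin(2 pi f t))`` — exactly rank 1
    in the Casorati matrix, so one singular component removes it.

    Pixel centres sit at ``index * pixel_size_um`` (origin = centre of the
    top-left pixel); PSFs are isotropic Gaussians of width ``psf_sigma_um``.
    """
    if psf_sigma_um < pixel_size_um / 2:
        raise ValueError("psf_sigma_um must be >= pixel_size_um / 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if grid_shape is None:
        grid_shape = (
            int(round(gt.fov_um[0] / pixel_size_um)),
            int(round(gt.fov_um[1] / pixel_size_um)),
        )
    n_ax, n_la = grid_shape
    n_frames = gt.n_frames
    if clutter_image is None:
        clutter_image = (
            _smooth_clutter(grid_shape, clutter_amplitude, rng)
            if clutter_amplitude > 0 else np.zeros(grid_shape)
        )
    frames = np.empty((n_frames, n_ax, n_la))
    t = np.arange(n_frames) / gt.frame_rate_hz
    gain = 1.0 + drift_amplitude * np.sin(2 * np.pi * drift_freq_hz * t)
    ax_centers = np.arange(n_ax) * pixel_size_um
    la_centers = np.arange(n_la) * pixel_size_um
    half = int(np.ceil(4 * psf_sigma_um / pixel_size_um))
    by_frame = {f: sub for f, sub in gt.table.groupby("frame")}
    for f in range(n_frames):
        img = gain[f] * clutter_image.copy()
        sub = by_frame.get(f)
        if sub is not None:
            for ax_um, la_um in sub[["axial_um", "lateral_um"]].to_numpy():
                i0 = int(round(ax_um / pixel_size_um))
                j0 = int(round(la_um / pixel_size_um))
                i_lo, i_hi = max(i0 - half, 0), min(i0 + half + 1, n_ax)
                j_lo, j_hi = max(j0 - half, 0), min(j0 + half + 1, n_la)
                if i_lo >= i_hi or j_lo >= j_hi:
                    continue
                da = ax_centers[i_lo:i_hi] - ax_um
                dl = la_centers[j_lo:j_hi] - la_um
                img[i_lo:i_hi, j_lo:j_hi] += bubble_amplitude * np.exp(
                    -(da[:, None] ** 2 + dl[None, :] ** 2) / (2 * psf_sigma_um ** 2)
                )
        frames[f] = img
    if noise_sd > 0:
        frames += rng.normal(scale=noise_sd, size=frames.shape)
    return FrameStack(frames, gt.frame_rate_hz, pixel_size_um,
                      meta={"scale": "linear", "synthetic": True})


# ---------------------------------------------------------------------------
# Time-intensity curves
# ---------------------------------------------------------------------------

def simulate_tic(baseline: float = 10.0, peak_amp: float = 30.0,
                 arrival_s: float = 10.0, ttp_s: float = 12.0,
                 washout_rate: float = 0.08, duration_s: float = 90.0,
                 sample_hz: float = 2.0, noise_sd: float = 0.0,
                 seed: int = 0) -> TICurve:
    """A bolus time–intensity curve with known descriptors.

    Shape: flat baseline until ``arrival_s``; linear wash-in to
    ``baseline + peak_amp`` over ``ttp_s``; exponential wash-out back toward
    baseline at ``washout_rate`` (1/s).  The returned curve stores the true
    peak intensity ratio, time to peak, area under the curve and wash-in /
    wash-out slopes in ``curve.truth``.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive (PI divides by it)")
    t_peak = arrival_s + ttp_s
    if not (arrival_s < t_peak < duration_s):
        raise ValueError("need arrival < arrival + ttp < duration")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sample_hz)
    y = np.full_like(t, baseline)
    rise = (t >= arrival_s) & (t <= t_peak)
    y[rise] = baseline + peak_amp * (t[rise] - arrival_s) / ttp_s
    fall = t > t_peak
    y[fall] = baseline + peak_amp * np.exp(-washout_rate * (t[fall] - t_peak))
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=y.shape)

    # closed-form truths
    k = washout_rate
    t_half = np.log(2.0) / k
    washout_slope = -0.5 * peak_amp / t_half  # chord slope peak -> 50% decay
    auc = (baseline * duration_s + 0.5 * peak_amp * ttp_s
           + peak_amp * (1 - np.exp(-k * (duration_s - t_peak))) / k)
    truth = {
        "pi": peak_amp / baseline,
        "ttp_s": ttp_s,
        "arrival_s": arrival_s,
        "auc": auc,
        "wash_in_rate": peak_amp / ttp_s,
        "wash_out_rate": washout_slope,
    }
    return TICurve(time_s=t, intensity=y, baseline=baseline,
                   arrival_time_s=arrival_s, truth=truth)


# ---------------------------------------------------------------------------
# Lesion cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-group cohort: per-feature normal / multinomial group distributions.

    ``continuous``: name -> (mean_pos, sd_pos, mean_neg, sd_neg).
    ``categorical``: name -> (levels, probs_pos, probs_neg).
    """

    n_pos: int
    n_neg: int
    continuous: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 lesions per group")
        for name, (_, sp, _, sn) in self.continuous.items():
            if sp < 0 or sn < 0:
                raise ValueError(f"{name}: sd must be >= 0")
        for name, (levels, pp, pn) in self.categorical.items():
            for p in (pp, pn):
                if len(p) != len(levels) or abs(sum(p) - 1.0) > 1e-9:
                    raise ValueError(f"{name}: probabilities must sum to 1")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a two-group lesion feature table; HER2 label in column ``her2``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    out = {"her2": ["positive"] * spec.n_pos + ["negative"] * spec.n_neg}
    for name, (mp, sp, mn, sn) in spec.continuous.items():
        out[name] = np.concatenate([
            rng.normal(mp, sp, spec.n_pos),
            rng.normal(mn, sn, spec.n_neg),
        ])
    for name, (levels, pp, pn) in spec.categorical.items():
        levels = np.asarray(levels, dtype=object)
        pos = rng.choice(len(levels), size=spec.n_pos, p=np.asarray(pp, float))
        neg = rng.choice(len(levels), size=spec.n_neg, p=np.asarray(pn, float))
        out[name] = levels[np.concatenate([pos, neg])]
    df = pd.DataFrame(out, index=pd.RangeIndex(n, name="lesion"))
    return df


def default_cohort_spec(n_pos: int = 23, n_neg: int = 49, seed: int = 0) -> CohortSpec:
    """Cohort with the published two-group summaries of a 72-lesion study.

    Continuous features use the reported mean +/- sd (or median with an sd
    approximated from the interquartile range as IQR/1.35); categorical
    features use the reported group proportions.
    """
    return CohortSpec(
        n_pos=n_pos, n_neg=n_neg, seed=seed,
        continuous={
            "age_years": (52.04, 8.93, 53.55, 9.16),
            "max_diameter_cm": (3.78, 1.38, 3.07, 1.34),
            "pi_db": (24.4, 8.2, 18.7, 10.9),
            "ttp_s": (21.9, 4.3, 20.9, 6.4),
            "auc_tic": (906.8, 601.6, 673.4, 625.7),
            "wash_in_rate": (1.17, 0.37, 0.88, 0.39),
            "mean_flow_velocity_cm_s": (6.0, 2.1, 4.1, 1.5),
            "max_flow_velocity_cm_s": (20.0, 11.0, 18.0, 2.3),
            "mean_tortuosity": (3.0, 0.67, 3.3, 0.44),
            "fractal_dimension": (1.4, 0.15, 1.4, 0.22),
        },
        categorical={
            "microcalcification": (["yes", "no"], [15 / 23, 8 / 23], [16 / 49, 33 / 49]),
            "orientation": (["parallel", "vertical"], [20 / 23, 3 / 23], [29 / 49, 20 / 49]),
            "area_of_enhancement": (["larger", "unchanged"], [18 / 23, 5 / 23], [2 / 49, 47 / 49]),
            "mv_distribution": (
                ["central", "peripheral", "diffuse"],
                [1 / 23, 12 / 23, 10 / 23],
                [6 / 49, 35 / 49, 8 / 49],
            ),
            "flow_direction": (["away", "toward"], [18 / 23, 5 / 23], [16 / 49, 33 / 49]),
            "adler_grade": (
                [0, 1, 2, 3],
                [1 / 23, 4 / 23, 10 / 23, 8 / 23],
                [1 / 49, 9 / 49, 19 / 49, 20 / 49],
            ),
        },
    )
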