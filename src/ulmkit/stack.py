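"""Frame-stack container for high-frame-rate contrast-enhanced ultrasound data.

A :class:`FrameStack` is the raw input to super-resolution reconstruction: a
3-D intensity array (frame, axial row, lateral column) together with the two
pieces of acquisition metadata every downstream stage needs — the frame rate
and the physical pixel size.  Axial row index increases with depth (away from
the transducer); the coordinate origin is the centre of the top-left pixel,
and continuous positions are expressed in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameStack:
    """An ultrasound image sequence with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_axial, n_lateral)``; finite intensities.
    frame_rate_hz
        Acquisition frame rate in Hz (> 0).
    pixel_size_um
        Physical size of one pixel in micrometres (> 0); pixels are square.
    meta
        Free-form provenance dictionary (intensity scale, source path, ...).
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (frame, axial, lateral)")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def fov_um(self) -> tuple[float, float]:
        """Field of view (axial, lateral) in micrometres."""
        return (
            self.frames.shape[1] * self.pixel_size_um,
            self.frames.shape[2] * self.pixel_size_um,
        )
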