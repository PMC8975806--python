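"""sCMOS camera calibration model.

Modern sCMOS sensors have pixel-dependent offset, gain and readout noise, so
every quantitative step (spot detection, maximum-likelihood localization,
CRLB precision) must carry per-pixel calibration maps rather than scalar
camera constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: nanometres per camera pixel at the sample plane
DEFAULT_PIXEL_SIZE_NM = 65.0


@dataclass
class CameraModel:
    """Per-pixel calibration of an sCMOS camera.

    Parameters
    ----------
    offset_map : ndarray
        ADU offset per pixel (counts recorded at zero illumination).
    variance_map : ndarray
        Readout-noise variance per pixel (ADU^2); strictly positive.
    gain_map : ndarray
        ADU per photoelectron, per pixel.
    pixel_size : float
        Back-projected pixel size in nm (default 65).
    frame_time : float
        Exposure per frame in seconds (default 0.03, i.e. 33 Hz).
    """

    offset_map: np.ndarray
    variance_map: np.ndarray
    gain_map: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    frame_time: float = 0.03

    def __post_init__(self) -> None:
        self.offset_map = np.asarray(self.offset_map, dtype=float)
        self.variance_map = np.asarray(self.variance_map, dtype=float)
        self.gain_map = np.asarray(self.gain_map, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if not (self.offset_map.shape == self.variance_map.shape == self.gain_map.shape):
            raise ValueError("calibration maps must share one shape")
        if np.any(self.variance_map <= 0):
            raise ValueError("variance_map must be strictly positive")
        if np.any(self.gain_map <= 0):
            raise ValueError("gain_map must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.offset_map.shape

    @classmethod
    def ideal(
        cls,
        shape: tuple[int, int],
        offset: float = 100.0,
        variance: float = 4.0,
        gain: float = 2.0,
        pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
        frame_time: float = 0.03,
    ) -> "CameraModel":
        """Uniform-map camera, convenient for simulation and tests."""
        return cls(
            offset_map=np.full(shape, float(offset)),
            variance_map=np.full(shape, float(variance)),
            gain_map=np.full(shape, float(gain)),
            pixel_size=pixel_size,
            frame_time=frame_time,
        )

    def crop(self, y0: int, x0: int, size: int) -> "CameraModel":
        """Calibration sub-maps for a square crop with corner (y0, x0)."""
        sl = (slice(y0, y0 + size), slice(x0, x0 + size))
        return CameraModel(
            offset_map=self.offset_map[sl],
            variance_map=self.variance_map[sl],
            gain_map=self.gain_map[sl],
            pixel_size=self.pixel_size,
            frame_time=self.frame_time,
        )
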