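"""Platform geometry and calibrated pressure recordings.

The measurement device is a pedobarographic pressure platform: a regular
grid of 1 cm² capacitive sensors sampled at a fixed frequency.  Each sensor
reports a calibrated pressure in kPa inside a bounded sensitivity range;
pressures below the floor read 0, and the acquisition software may impose a
manual calibration cap below the physical ceiling.

Coordinates: the platform origin is at the grid centre, x is latero-lateral
(the animal's left is negative x), y is craniocaudal (cranial positive, the
animal faces +y).  The sensor at grid cell (r, c) has its centre at
``((c - (cols-1)/2) * pitch, ((rows-1)/2 - r) * pitch)`` in mm, so row 0 is
the cranial edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class RecordingFormatError(ValueError):
    """A recording bundle is structurally malformed (missing keys, bad CSV)."""


class ValidationError(ValueError):
    """Data violate a platform or recording invariant."""


class ConfigurationError(ValueError):
    """A simulation or analysis configuration is inconsistent."""


class SegmentationError(ValueError):
    """A recording cannot be partitioned into two paw prints."""


class DegenerateEllipseError(ValueError):
    """An operation requires a non-degenerate prediction ellipse."""


@dataclass(frozen=True)
class PlatformSpec:
    """Geometry and calibration of a pressure platform.

    Defaults describe a 48 x 48 cm platform of 1 cm² sensors with a
    30-400 kPa sensitivity range sampled at 100 Hz, with the display
    calibration capped at 212 kPa.

    ``active_mask`` marks which grid cells contain a physical sensor
    (vendor platforms may leave corners unpopulated); ``None`` means the
    full grid is active.
    """

    grid_rows: int = 48
    grid_cols: int = 48
    sensor_pitch_mm: float = 10.0
    sensor_area_cm2: float = 1.0
    pressure_floor_kPa: float = 30.0
    pressure_ceiling_kPa: float = 400.0
    calibration_cap_kPa: float = 212.0
    sampling_hz: float = 100.0
    active_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValidationError("grid dimensions must be positive")
        if self.sampling_hz <= 0:
            raise ValidationError("sampling_hz must be positive")
        if not (0 < self.pressure_floor_kPa < self.calibration_cap_kPa
                <= self.pressure_ceiling_kPa):
            raise ValidationError(
                "require 0 < floor < calibration_cap <= ceiling, got "
                f"{self.pressure_floor_kPa}, {self.calibration_cap_kPa}, "
                f"{self.pressure_ceiling_kPa}")
        if self.active_mask is not None:
            mask = np.asarray(self.active_mask, dtype=bool)
            if mask.shape != (self.grid_rows, self.grid_cols):
                raise ValidationError(
                    f"active_mask shape {mask.shape} != grid "
                    f"({self.grid_rows}, {self.grid_cols})")
            if not mask.any():
                raise ValidationError("active_mask has no active sensors")
            object.__setattr__(self, "active_mask", mask)

    @property
    def sensor_count(self) -> int:
        if self.active_mask is None:
            return self.grid_rows * self.grid_cols
        return int(self.active_mask.sum())

    def mask_array(self) -> np.ndarray:
        """Active mask as a concrete boolean array (full grid if None)."""
        if self.active_mask is None:
            return np.ones((self.grid_rows, self.grid_cols), dtype=bool)
        return self.active_mask

    def sensor_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (rows, cols) with sensor centres in mm."""
        cols = np.arange(self.grid_cols)
        rows = np.arange(self.grid_rows)
        x = (cols - (self.grid_cols - 1) / 2.0) * self.sensor_pitch_mm
        y = ((self.grid_rows - 1) / 2.0 - rows) * self.sensor_pitch_mm
        return np.meshgrid(x, y)  # X varies along axis 1, Y along axis 0

    def cell_center_mm(self, row: int | np.ndarray,
                       col: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = (np.asarray(col) - (self.grid_cols - 1) / 2.0) * self.sensor_pitch_mm
        y = ((self.grid_rows - 1) / 2.0 - np.asarray(row)) * self.sensor_pitch_mm
        return x, y


@dataclass
class PressureRecording:
    """A stack of calibrated pressure frames from one standing trial.

    ``frames`` has shape (T, rows, cols) in kPa; inactive or sub-floor
    sensors read exactly 0.  ``cap_applied`` records whether the
    calibration cap was in force during acquisition (values then never
    exceed ``calibration_cap_kPa``).
    """

    spec: PlatformSpec
    frames: np.ndarray
    subject_id: str = "unknown"
    trial_id: str = "t1"
    duration_s: float = 10.0
    cap_applied: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def validate(self) -> None:
        spec = self.spec
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a T x rows x cols array")
        t, r, c = self.frames.shape
        if (r, c) != (spec.grid_rows, spec.grid_cols):
            raise ValidationError(
                f"frame grid {r}x{c} does not match platform "
                f"{spec.grid_rows}x{spec.grid_cols}")
        expected_t = round(self.duration_s * spec.sampling_hz)
        if t != expected_t:
            raise ValidationError(
                f"{t} frames inconsistent with duration {self.duration_s} s "
                f"at {spec.sampling_hz} Hz (expected {expected_t})")
        if np.any(self.frames < 0):
            raise ValidationError("negative pressures present")
        nonzero = self.frames[self.frames > 0]
        if nonzero.size and nonzero.min() < spec.pressure_floor_kPa - 1e-9:
            raise ValidationError(
                "non-zero pressures below the sensitivity floor "
                f"{spec.pressure_floor_kPa} kPa")
        ceiling = (spec.calibration_cap_kPa if self.cap_applied
                   else spec.pressure_ceiling_kPa)
        if nonzero.size and nonzero.max() > ceiling + 1e-9:
            raise ValidationError(
                f"pressures exceed the in-force ceiling {ceiling} kPa")
        if spec.active_mask is not None:
            outside = self.frames[:, ~spec.active_mask]
            if np.any(outside != 0):
                raise ValidationError("non-zero pressure outside active_mask")
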