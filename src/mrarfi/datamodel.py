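"""Core containers and file I/O for alternating-contrast MR-ARFI timeseries.

An MR-ARFI acquisition yields, per slice, a timeseries of complex-valued
images in which an ultrasound-induced tissue displacement is encoded as a
small image-phase shift whose sign alternates with the motion-encoding
gradient (MEG) that received the ultrasound trigger.  This module defines
the in-memory types shared by every estimator:

* :class:`AcquisitionParams` — MEG strength/duration and ultrasound metadata,
  which fix the phase-per-meter conversion 2π·42.58·G·T.
* :class:`TriggerSchedule` — the per-timepoint contrast indicator (0 =
  positive contrast, 1 = negated contrast).
* :class:`ComplexImageSeries` — the measured images I_n(x_j).
* :class:`DisplacementMap` — a per-voxel displacement estimate in meters.

On disk a series is a pair of 3D NIfTI volumes (time × row × col; suffixes
``_mag`` and ``_pha``, phase in radians in (−π, π]) plus a JSON sidecar
holding the trigger indicators and acquisition parameters in the units
stated on :class:`AcquisitionParams` (mT/m, ms, MHz, MPa).  Displacement
maps are written in nanometers with masked-out voxels stored as NaN.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Gyromagnetic constant (MHz/T scale) used verbatim in the displacement
#: conversion 2π·42.58·G·T; deliberately not the CODATA 42.5764.
GAMMA_BAR = 42.58


class ArfiError(Exception):
    """Base class for all package errors."""


class ValidationError(ArfiError, ValueError):
    """Input violates a documented contract (shapes, ranges, masks)."""


class ConfigurationError(ArfiError, ValueError):
    """A configuration source (sidecar, config file) is malformed."""


class IdentifiabilityError(ValidationError):
    """The trigger schedule cannot separate displacement phase from drift."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata needed to convert phase to displacement.

    Parameters
    ----------
    meg_amplitude:
        Motion-encoding gradient strength G, mT/m.
    meg_duration:
        Motion-encoding gradient duration T, ms.
    us_frequency:
        Ultrasound center frequency, MHz.
    gamma_bar:
        Gyromagnetic constant on the scale used by the conversion
        2π·gamma_bar·G·T (rad per meter of displacement).
    free_field_pressure:
        Optional peak negative pressure in free-field water, MPa.
    skull_transmission:
        Optional pressure transmission fraction through the skull, in (0, 1].
    """

    meg_amplitude: float
    meg_duration: float
    us_frequency: float
    gamma_bar: float = GAMMA_BAR
    free_field_pressure: float | None = None
    skull_transmission: float | None = None

    def __post_init__(self) -> None:
        if not self.meg_amplitude > 0:
            raise ValidationError("meg_amplitude must be > 0 (mT/m)")
        if not self.meg_duration > 0:
            raise ValidationError("meg_duration must be > 0 (ms)")
        if not self.us_frequency > 0:
            raise ValidationError("us_frequency must be > 0 (MHz)")
        if not self.gamma_bar > 0:
            raise ValidationError("gamma_bar must be > 0")
        if self.free_field_pressure is not None and not self.free_field_pressure > 0:
            raise ValidationError("free_field_pressure must be > 0 (MPa)")
        if self.skull_transmission is not None and not (
            0 < self.skull_transmission <= 1
        ):
            raise ValidationError("skull_transmission must be in (0, 1]")

    @property
    def phase_per_meter(self) -> float:
        """rad of displacement-encoding phase per meter of displacement."""
        return 2.0 * math.pi * self.gamma_bar * self.meg_amplitude * self.meg_duration


@dataclass(frozen=True)
class TriggerSchedule:
    """Per-timepoint contrast indicator 1[n]: 0 = positive, 1 = negated.

    A schedule must contain both contrast values; with a constant schedule
    the displacement phase is indistinguishable from baseline phase and
    fitting must refuse.
    """

    indicators: tuple[int, ...]

    def __post_init__(self) -> None:
        ind = tuple(int(i) for i in self.indicators)
        object.__setattr__(self, "indicators", ind)
        if len(ind) < 2:
            raise ValidationError("schedule needs at least 2 timepoints")
        if any(i not in (0, 1) for i in ind):
            raise ValidationError("indicators must be 0 or 1")
        if len(set(ind)) < 2:
            raise IdentifiabilityError(
                "constant trigger schedule: displacement phase is unidentifiable"
            )

    def __len__(self) -> int:
        return len(self.indicators)

    @property
    def signs(self) -> np.ndarray:
        """Contrast sign (−1)^1[n] per timepoint: +1 positive, −1 negated."""
        return 1.0 - 2.0 * np.asarray(self.indicators, dtype=float)


@dataclass(frozen=True)
class Grid:
    """In-plane voxel grid geometry (row-major, 0-based indices)."""

    spacing: tuple[float, float] = (1.0, 1.0)  # mm per voxel, (row, col)
    origin: tuple[float, float] = (0.0, 0.0)  # mm

    def __post_init__(self) -> None:
        if any(not s > 0 for s in self.spacing):
            raise ValidationError("grid spacing must be positive")


@dataclass
class ComplexImageSeries:
    """The measured complex images I_n(x_j), time as the slowest axis."""

    data: np.ndarray  # complex, shape (Nt, rows, cols)
    grid: Grid
    schedule: TriggerSchedule
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3:
            raise ValidationError(
                f"series data must be (time, row, col), got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("series data contains NaN or Inf")
        if len(self.schedule) != self.data.shape[0]:
            raise ValidationError(
                f"schedule length {len(self.schedule)} != "
                f"{self.data.shape[0]} timepoints"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def mean_magnitude(self) -> float:
        """Mean magnitude over all voxels and timepoints (λ auto-scaling)."""
        return float(np.mean(np.abs(self.data)))


@dataclass
class DisplacementMap:
    """Per-voxel tissue displacement in meters (reported in nm)."""

    values: np.ndarray  # meters, shape (rows, cols)
    grid: Grid = field(default_factory=Grid)
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("displacement map must be 2D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape must match map shape")
            inside = self.values[self.mask]
        else:
            inside = self.values
        if not np.all(np.isfinite(inside)):
            raise ValidationError("displacement map is not finite inside mask")

    @property
    def values_nm(self) -> np.ndarray:
        return self.values * 1e9


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_REQUIRED_SIDECAR_KEYS = (
    "indicators",
    "meg_amplitude",
    "meg_duration",
    "us_frequency",
)


def phase_companion_path(image_path: str | Path) -> Path:
    """Derive the ``_pha`` volume path from the ``_mag`` volume path."""
    p = Path(image_path)
    name = p.name
    if "_mag" not in name:
        raise ValidationError(
            f"magnitude image name must contain '_mag': {name!r}"
        )
    return p.with_name(name.replace("_mag", "_pha", 1))


def _affine(grid: Grid) -> np.ndarray:
    # time axis first (slowest); spatial spacing on the two in-plane axes
    aff = np.eye(4)
    aff[1, 1] = grid.spacing[0]
    aff[2, 2] = grid.spacing[1]
    aff[1, 3] = grid.origin[0]
    aff[2, 3] = grid.origin[1]
    return aff


def _save_volume(arr: np.ndarray, grid: Grid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), _affine(grid))
    nib.save(img, str(path))


def write_series(
    series: ComplexImageSeries,
    image_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """Write a series as ``_mag``/``_pha`` NIfTI volumes plus a JSON sidecar.

    Deterministic: identical input produces identical files.
    """
    image_path = Path(image_path)
    pha_path = phase_companion_path(image_path)
    _save_volume(series.magnitude, series.grid, image_path)
    _save_volume(series.phase, series.grid, pha_path)
    sidecar = {
        "indicators": list(series.schedule.indicators),
        "meg_amplitude": series.params.meg_amplitude,
        "meg_duration": series.params.meg_duration,
        "us_frequency": series.params.us_frequency,
        "gamma_bar": series.params.gamma_bar,
        "free_field_pressure": series.params.free_field_pressure,
        "skull_transmission": series.params.skull_transmission,
        "pixel_spacing_mm": list(series.grid.spacing),
        "origin_mm": list(series.grid.origin),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _params_from_sidecar(sidecar: dict) -> AcquisitionParams:
    return AcquisitionParams(
        meg_amplitude=sidecar["meg_amplitude"],
        meg_duration=sidecar["meg_duration"],
        us_frequency=sidecar["us_frequency"],
        gamma_bar=sidecar.get("gamma_bar", GAMMA_BAR),
        free_field_pressure=sidecar.get("free_field_pressure"),
        skull_transmission=sidecar.get("skull_transmission"),
    )


def read_series(
    image_path: str | Path, sidecar_path: str | Path
) -> ComplexImageSeries:
    """Read a magnitude/phase NIfTI pair plus sidecar into a series.

    ``image_path`` names the magnitude volume; the phase volume is its
    ``_pha`` companion.  Round-trips :func:`write_series` to floating-point
    equality of the stored magnitude and phase arrays.
    """
    image_path = Path(image_path)
    pha_path = phase_companion_path(image_path)
    if not image_path.exists():
        raise FileNotFoundError(f"magnitude volume not found: {image_path}")
    if not pha_path.exists():
        raise FileNotFoundError(f"phase volume not found: {pha_path}")
    if not Path(sidecar_path).exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
    sidecar = json.loads(Path(sidecar_path).read_text())
    for key in _REQUIRED_SIDECAR_KEYS:
        if key not in sidecar:
            raise ConfigurationError(f"sidecar is missing required key {key!r}")
    mag = np.asarray(nib.load(str(image_path)).get_fdata(), dtype=float)
    pha = np.asarray(nib.load(str(pha_path)).get_fdata(), dtype=float)
    if mag.shape != pha.shape:
        raise ValidationError(
            f"magnitude {mag.shape} and phase {pha.shape} shapes differ"
        )
    spacing = tuple(sidecar.get("pixel_spacing_mm", (1.0, 1.0)))
    origin = tuple(sidecar.get("origin_mm", (0.0, 0.0)))
    return ComplexImageSeries(
        data=mag * np.exp(1j * pha),
        grid=Grid(spacing=spacing, origin=origin),
        schedule=TriggerSchedule(tuple(sidecar["indicators"])),
        params=_params_from_sidecar(sidecar),
    )


def write_map(
    dmap: DisplacementMap, path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write a displacement map in nanometers; masked-out voxels as NaN."""
    values_nm = dmap.values_nm.copy()
    if dmap.mask is not None:
        values_nm[~dmap.mask] = np.nan
    _save_volume(values_nm, dmap.grid, path)
    if sidecar_path is None:
        sidecar_path = Path(str(path).split(".nii")[0] + ".json")
    sidecar = {
        "units": "nm",
        "provenance": dmap.provenance,
        "pixel_spacing_mm": list(dmap.grid.spacing),
        "origin_mm": list(dmap.grid.origin),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_map(path: str | Path, sidecar_path: str | Path | None = None) -> DisplacementMap:
    """Read a nanometer displacement map; NaN voxels become the mask."""
    if sidecar_path is None:
        sidecar_path = Path(str(path).split(".nii")[0] + ".json")
    values_nm = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    mask = np.isfinite(values_nm)
    values = np.where(mask, values_nm, 0.0) * 1e-9
    meta: dict = {}
    if Path(sidecar_path).exists():
        meta = json.loads(Path(sidecar_path).read_text())
    grid = Grid(
        spacing=tuple(meta.get("pixel_spacing_mm", (1.0, 1.0))),
        origin=tuple(meta.get("origin_mm", (0.0, 0.0))),
    )
    return DisplacementMap(
        values=values,
        grid=grid,
        mask=None if bool(mask.all()) else mask,
        provenance=meta.get("provenance", {}),
    )
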