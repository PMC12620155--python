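"""Synthetic MR-ARFI series with known ground truth.

The simulator emulates the statistical structure the reconstruction
assumes: a smooth complex baseline image (disk phantom or smooth random
field) with mean magnitude ~1e4, a compact Gaussian focal displacement
phase (default 200 nm peak, 2.2 mm lateral FWHM), per-timepoint spatially
smooth phase drift that is temporally AR(1)-correlated and contains
content both inside and beyond the second-order polynomial span, and
i.i.d. circular complex Gaussian noise.  Schedules: alternating (0,1,0,1…;
each consecutive pair is one "average"), blocked (all positive then all
negative), or the four-phase EPI-style cycle (FUS off/pos, on/pos,
off/neg, on/neg).

All randomness flows from one seeded generator; the ground truth records
the seed, the displacement-phase map, and the drift fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datamodel import (
    AcquisitionParams,
    ComplexImageSeries,
    Grid,
    TriggerSchedule,
    ValidationError,
)
from .polynomial import build_basis
from .units import displacement_to_phase

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_params() -> AcquisitionParams:
    """40 mT/m, 7 ms MEGs with a 0.65 MHz transducer."""
    return AcquisitionParams(
        meg_amplitude=40.0, meg_duration=7.0, us_frequency=0.65
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generation settings.

    Defaults describe the acquisition regime the package targets: a 64×64
    grid at 1 mm spacing, mean image amplitude 1e4, a 200 nm focal
    displacement with 2.2 mm FWHM, per-image phase noise of 0.01 rad
    (noise_std / amplitude), slow AR(1) drift with second-order polynomial
    structure (0.05 rad) plus super-polynomial smooth structure (0.02 rad),
    and 48 alternating timepoints (24 averages).
    """

    seed: int
    grid_shape: tuple[int, int] = (64, 64)
    baseline_kind: str = "disk"  # "disk" | "smooth_random"
    baseline_amplitude: float = 1e4
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    focus_center: tuple[int, int] | None = None  # default: grid center
    focus_fwhm_mm: float = 2.2
    displacement_nm: float = 200.0
    drift_poly_std: float = 0.05  # rad per 2nd-order coefficient
    drift_highorder_std: float = 0.02  # rad, spatial std of residual field
    drift_ar1: float = 0.9
    noise_std: float = 100.0  # per real/imag channel
    schedule_kind: str = "alternating"  # "alternating" | "blocked" | "epi4"
    n_timepoints: int = 48

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory for reproducibility")
        if self.displacement_nm < 0:
            raise ValidationError("displacement_nm must be >= 0")
        if not 0 <= self.drift_ar1 < 1:
            raise ValidationError("drift_ar1 must be in [0, 1)")
        if self.noise_std < 0 or self.drift_poly_std < 0 or self.drift_highorder_std < 0:
            raise ValidationError("noise/drift std values must be >= 0")
        if self.baseline_kind not in ("disk", "smooth_random"):
            raise ValidationError(f"unknown baseline_kind {self.baseline_kind!r}")


@dataclass
class GroundTruth:
    """Everything the simulator knows that an estimator must recover."""

    theta: np.ndarray  # true displacement phase, rad
    displacement_nm: np.ndarray  # true displacement map, nm
    drift: np.ndarray  # (Nt, rows, cols) drift phase, rad
    fus_on: np.ndarray  # bool per timepoint (all True except epi4 off frames)
    brain_mask: np.ndarray  # object support of the baseline
    focus_center: tuple[int, int]
    seed: int
    config: SimulationConfig = field(repr=False, default=None)


def make_schedule(kind: str, n_timepoints: int) -> TriggerSchedule:
    """Build the contrast-indicator schedule for a triggering scheme."""
    n = int(n_timepoints)
    if n < 2:
        raise ValidationError("need at least 2 timepoints")
    if kind == "alternating":
        ind = tuple(i % 2 for i in range(n))
    elif kind == "blocked":
        n_pos = (n + 1) // 2
        ind = (0,) * n_pos + (1,) * (n - n_pos)
    elif kind == "epi4":
        if n % 4 != 0:
            raise ValidationError("epi4 schedule needs a multiple of 4 timepoints")
        ind = (0, 0, 1, 1) * (n // 4)
    else:
        raise ValidationError(f"unknown schedule kind {kind!r}")
    return TriggerSchedule(ind)


def fus_on_flags(kind: str, n_timepoints: int) -> np.ndarray:
    """Which timepoints carry an ultrasound pulse (epi4 interleaves off frames)."""
    if kind == "epi4":
        return np.tile([False, True, False, True], n_timepoints // 4)
    return np.ones(n_timepoints, dtype=bool)


def _ar1_series(rng: np.random.Generator, n: int, k: int, std: float, rho: float
                ) -> np.ndarray:
    """Stationary AR(1) sequences, shape (n, k), marginal std ``std``."""
    x = np.empty((n, k))
    x[0] = rng.normal(0.0, std, k)
    innov = std * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + rng.normal(0.0, innov, k)
    return x


def _disk_baseline(rng, shape, amplitude):
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    dist = np.hypot(rr - r0, cc - c0)
    radius = 0.38 * min(rows, cols)
    mag = 0.02 + 0.98 * 0.5 * (1.0 + np.tanh((radius - dist) / 1.5))
    # mild smooth magnitude shading so the object is not flat
    x = np.linspace(-1, 1, cols)[None, :]
    y = np.linspace(-1, 1, rows)[:, None]
    mag = mag * (1.0 + 0.1 * x + 0.05 * y)
    phase = 0.3 * rng.normal() + 0.2 * rng.normal() * x + 0.2 * rng.normal() * y
    base = mag * np.exp(1j * phase)
    return base * (amplitude / np.mean(np.abs(base)))


def _smooth_random_baseline(rng, shape, amplitude):
    sigma = max(shape) / 8.0
    mag = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    mag = np.abs(mag) + 0.3 * np.std(mag)
    phase = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    phase = 0.5 * phase / max(np.std(phase), 1e-12)
    base = mag * np.exp(1j * phase)
    return base * (amplitude / np.mean(np.abs(base)))


def _focal_theta(config: SimulationConfig, params: AcquisitionParams,
                 center: tuple[int, int]) -> np.ndarray:
    rows, cols = config.grid_shape
    peak_phase = displacement_to_phase(config.displacement_nm * 1e-9, params)
    rr, cc = np.mgrid[0:rows, 0:cols]
    sig_r = config.focus_fwhm_mm * _FWHM_TO_SIGMA / config.pixel_spacing_mm[0]
    sig_c = config.focus_fwhm_mm * _FWHM_TO_SIGMA / config.pixel_spacing_mm[1]
    d2 = ((rr - center[0]) / sig_r) ** 2 + ((cc - center[1]) / sig_c) ** 2
    return peak_phase * np.exp(-0.5 * d2)


def _highorder_drift(rng, config, basis2) -> np.ndarray:
    """AR(1) fields from a 4th-order basis, projected off the 2nd-order span.

    Guarantees drift content outside the reconstruction model's basis —
    the regime in which the trigger schedule choice matters.
    """
    nt = config.n_timepoints
    basis4 = build_basis(config.grid_shape, 4)
    c4 = _ar1_series(rng, nt, basis4.n_terms, 1.0, config.drift_ar1)
    fields = c4 @ basis4.design.T  # (Nt, Ns)
    sol, *_ = np.linalg.lstsq(basis2.design, fields.T, rcond=None)
    resid = fields - (basis2.design @ sol).T
    scale = config.drift_highorder_std / max(np.std(resid), 1e-300)
    return (scale * resid).reshape(nt, *config.grid_shape)


def simulate(
    config: SimulationConfig, params: AcquisitionParams | None = None
) -> tuple[ComplexImageSeries, GroundTruth]:
    """Generate a synthetic series and its ground truth.

    Images are built by the forward model — baseline × exp(i·[drift +
    sign·θ]) — with θ applied only at FUS-on timepoints, plus complex
    Gaussian noise.  Bit-identical across runs for a fixed seed.
    """
    params = params or default_params()
    rows, cols = config.grid_shape
    center = config.focus_center or ((rows - 1) // 2, (cols - 1) // 2)
    if not (0 <= center[0] < rows and 0 <= center[1] < cols):
        raise ValidationError(f"focus {center} outside grid {config.grid_shape}")

    rng = np.random.default_rng(config.seed)
    if config.baseline_kind == "disk":
        baseline = _disk_baseline(rng, config.grid_shape, config.baseline_amplitude)
    else:
        baseline = _smooth_random_baseline(
            rng, config.grid_shape, config.baseline_amplitude
        )
    theta = _focal_theta(config, params, center)

    nt = config.n_timepoints
    basis2 = build_basis(config.grid_shape, 2)
    drift = np.zeros((nt, rows, cols))
    if config.drift_poly_std > 0:
        c2 = _ar1_series(rng, nt, basis2.n_terms, config.drift_poly_std,
                         config.drift_ar1)
        drift += (c2 @ basis2.design.T).reshape(nt, rows, cols)
    if config.drift_highorder_std > 0:
        drift += _highorder_drift(rng, config, basis2)

    schedule = make_schedule(config.schedule_kind, nt)
    fus = fus_on_flags(config.schedule_kind, nt)
    signs = schedule.signs * fus
    phases = drift + signs[:, None, None] * theta[None, :, :]
    data = baseline[None, :, :] * np.exp(1j * phases)
    if config.noise_std > 0:
        noise = rng.normal(0.0, config.noise_std, (2, nt, rows, cols))
        data = data + noise[0] + 1j * noise[1]

    series = ComplexImageSeries(
        data=data,
        grid=Grid(spacing=config.pixel_spacing_mm),
        schedule=schedule,
        params=params,
    )
    truth = GroundTruth(
        theta=theta,
        displacement_nm=theta / params.phase_per_meter * 1e9,
        drift=drift,
        fus_on=fus,
        brain_mask=np.abs(baseline) > 0.25 * np.abs(baseline).max(),
        focus_center=tuple(center),
        seed=config.seed,
        config=config,
    )
    return series, truth
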