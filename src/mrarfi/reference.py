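"""Reference displacement estimators: ROI phase correction and the
four-image EPI-style difference-of-differences.

Both estimators share the model-based method's θ convention — θ is the
per-image contrast phase, so the positive/negative phase difference is
divided by 2 before the common conversion θ/(2π·42.58·G·T) — and compute
all phase differences via complex-conjugate products, never wrapped-phase
subtraction, to avoid ±π wrap errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    AcquisitionParams,
    ComplexImageSeries,
    DisplacementMap,
    ValidationError,
)


@dataclass(frozen=True)
class RectROI:
    """Half-open, 0-based rectangular voxel bounds [row_start, row_stop) ×
    [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValidationError("ROI must be non-empty")
        if self.row_start < 0 or self.col_start < 0:
            raise ValidationError("ROI bounds must be non-negative")

    def check_inside(self, grid_shape: tuple[int, int]) -> None:
        if self.row_stop > grid_shape[0] or self.col_stop > grid_shape[1]:
            raise ValidationError(
                f"ROI {self} falls outside grid {grid_shape}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_start, self.row_stop),
            slice(self.col_start, self.col_stop),
        )


def roi_corrected_map(
    series: ComplexImageSeries,
    roi: RectROI,
    params: AcquisitionParams | None = None,
) -> DisplacementMap:
    """ROI-phase-corrected displacement map.

    Per timepoint, the phase of the complex mean over an out-of-focus
    rectangular ROI is subtracted; the corrected positive- and
    negative-contrast images are then averaged separately, and the
    displacement phase is angle(mean_pos · conj(mean_neg)) / 2.  Exactly
    invariant to per-timepoint spatially constant phase offsets.
    """
    params = params or series.params
    roi.check_inside(series.grid_shape)
    rs, cs = roi.slices()
    indicators = np.asarray(series.schedule.indicators)
    if indicators.min() == indicators.max():  # pragma: no cover - schedule refuses
        raise ValidationError("series must contain both contrasts")

    roi_mean = series.data[:, rs, cs].mean(axis=(1, 2))
    roi_phasor = roi_mean / np.abs(roi_mean)
    corrected = series.data * np.conj(roi_phasor)[:, None, None]
    mean_pos = corrected[indicators == 0].mean(axis=0)
    mean_neg = corrected[indicators == 1].mean(axis=0)
    theta = np.angle(mean_pos * np.conj(mean_neg)) / 2.0
    return DisplacementMap(
        values=theta / params.phase_per_meter,
        grid=series.grid,
        provenance={"estimator": "roi", "roi": [roi.row_start, roi.row_stop,
                                               roi.col_start, roi.col_stop]},
    )


def epi_style_map(
    series_on_off: ComplexImageSeries,
    params: AcquisitionParams | None = None,
) -> DisplacementMap:
    """Four-image difference-of-differences estimator.

    Expects repeating cycles of (FUS off/positive MEG, on/positive,
    off/negative, on/negative).  Per cycle the FUS on−off phase difference
    is taken for each MEG polarity via conjugate products; the displacement
    phase is half their difference, averaged over cycles in the complex
    domain.
    """
    params = params or series_on_off.params
    nt = series_on_off.n_timepoints
    if nt % 4 != 0:
        raise ValidationError(
            f"four-phase estimator needs a multiple of 4 timepoints, got {nt}"
        )
    data = series_on_off.data.reshape(nt // 4, 4, *series_on_off.grid_shape)
    off_pos, on_pos, off_neg, on_neg = (data[:, i] for i in range(4))
    d_pos = on_pos * np.conj(off_pos)  # phase ≈ +θ
    d_neg = on_neg * np.conj(off_neg)  # phase ≈ −θ
    theta = np.angle((d_pos * np.conj(d_neg)).mean(axis=0)) / 2.0
    return DisplacementMap(
        values=theta / params.phase_per_meter,
        grid=series_on_off.grid,
        provenance={"estimator": "epi4", "n_cycles": nt // 4},
    )
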