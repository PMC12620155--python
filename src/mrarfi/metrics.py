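"""Evaluation metrics: background statistics, precision-vs-averages
curves, and contrast-to-noise ratio.

An "average" is one consecutive (positive, negative) contrast timepoint
pair; subsampling always keeps pairs intact.  Precision curves repeat the
map calculation for randomly selected averages (default analysis: ten
repeats per averages level), reporting out-of-focus mean and standard
deviation in nanometers.  Per-cell seeds derive from the root seed via
``numpy.random.SeedSequence([root_seed, n_averages, repeat_index])``,
which is stable across runs and versions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    AcquisitionParams,
    ComplexImageSeries,
    DisplacementMap,
    TriggerSchedule,
    ValidationError,
)
from .polynomial import build_basis
from .recon import FitOptions, fit, result_to_map
from .reference import RectROI, epi_style_map, roi_corrected_map

#: Columns of the precision table, one row per (averages level, repeat).
PRECISION_COLUMNS = (
    "n_averages",
    "repeat_index",
    "method",
    "background_mean_nm",
    "background_std_nm",
)


def background_stats(
    dmap: DisplacementMap,
    brain_mask: np.ndarray,
    focus_exclusion: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean and std (nm) of displacement over brain voxels outside the focus."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != dmap.values.shape:
        raise ValidationError("brain mask shape must match map shape")
    include = brain_mask.copy()
    if focus_exclusion is not None:
        focus_exclusion = np.asarray(focus_exclusion, dtype=bool)
        if focus_exclusion.shape != dmap.values.shape:
            raise ValidationError("focus exclusion shape must match map shape")
        include &= ~focus_exclusion
    if dmap.mask is not None:
        include &= dmap.mask
    if not include.any():
        raise ValidationError("background region is empty")
    vals = dmap.values_nm[include]
    return float(vals.mean()), float(vals.std())


def focus_exclusion_mask(
    grid_shape: tuple[int, int],
    center: tuple[int, int],
    fwhm_mm: float,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
    factor: float = 3.0,
) -> np.ndarray:
    """Disk of radius ``factor``×FWHM around the focal peak."""
    rr, cc = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]]
    dist_mm = np.hypot(
        (rr - center[0]) * pixel_spacing_mm[0],
        (cc - center[1]) * pixel_spacing_mm[1],
    )
    return dist_mm <= factor * fwhm_mm


def _check_alternating(schedule: TriggerSchedule) -> None:
    expected = tuple(i % 2 for i in range(len(schedule)))
    if schedule.indicators != expected:
        raise ValidationError("subsampling requires an alternating schedule")


def subsample_averages(
    series: ComplexImageSeries, n_averages: int, seed: int
) -> ComplexImageSeries:
    """Select ``n_averages`` consecutive (pos, neg) pairs at random.

    Selection is uniform without replacement; each pair stays intact and
    in pair order, so the subsampled schedule is again alternating.
    Deterministic for a fixed seed.
    """
    _check_alternating(series.schedule)
    n_pairs = series.n_timepoints // 2
    if not 1 <= n_averages <= n_pairs:
        raise ValidationError(
            f"n_averages must be in [1, {n_pairs}], got {n_averages}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_pairs, size=n_averages, replace=False)
    idx = np.stack([2 * chosen, 2 * chosen + 1], axis=1).ravel()
    return ComplexImageSeries(
        data=series.data[idx],
        grid=series.grid,
        schedule=TriggerSchedule((0, 1) * n_averages),
        params=series.params,
    )


def subsample_cycles(
    series: ComplexImageSeries, n_cycles: int, seed: int
) -> ComplexImageSeries:
    """Select whole four-image cycles from an EPI-style series."""
    nt = series.n_timepoints
    if nt % 4 != 0:
        raise ValidationError("cycle subsampling needs a multiple of 4 timepoints")
    total = nt // 4
    if not 1 <= n_cycles <= total:
        raise ValidationError(f"n_cycles must be in [1, {total}], got {n_cycles}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=n_cycles, replace=False)
    idx = (4 * chosen[:, None] + np.arange(4)[None, :]).ravel()
    return ComplexImageSeries(
        data=series.data[idx],
        grid=series.grid,
        schedule=TriggerSchedule((0, 0, 1, 1) * n_cycles),
        params=series.params,
    )


def derive_seed(root_seed: int, n_averages: int, repeat_index: int) -> int:
    """Stable per-cell seed for the precision-curve resampling."""
    ss = np.random.SeedSequence([int(root_seed), int(n_averages), int(repeat_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _map_for_method(
    series: ComplexImageSeries,
    method: str,
    roi: RectROI | None,
    options: FitOptions | None,
    basis_order: int,
) -> DisplacementMap:
    if method == "model":
        basis = build_basis(series.grid_shape, basis_order)
        return result_to_map(fit(series, basis, options), series.params)
    if method == "roi":
        if roi is None:
            raise ValidationError("method 'roi' requires an ROI")
        return roi_corrected_map(series, roi, series.params)
    if method == "epi4":
        return epi_style_map(series, series.params)
    raise ValidationError(f"unknown method {method!r}")


def precision_curve(
    series: ComplexImageSeries,
    n_averages_list: list[int],
    n_repeats: int,
    method: str,
    brain_mask: np.ndarray,
    focus_exclusion: np.ndarray | None = None,
    root_seed: int = 0,
    roi: RectROI | None = None,
    options: FitOptions | None = None,
    basis_order: int = 2,
) -> pd.DataFrame:
    """Background mean/std vs. number of averages, over random resamples.

    For each (n_averages, repeat) cell the series is subsampled, the
    displacement map recomputed with the chosen estimator (``model``,
    ``roi``, or ``epi4``), and out-of-focus statistics recorded.  Fully
    deterministic given ``root_seed``.
    """
    rows = []
    for n_avg in n_averages_list:
        for rep in range(n_repeats):
            cell_seed = derive_seed(root_seed, n_avg, rep)
            if method == "epi4":
                sub = subsample_cycles(series, n_avg, cell_seed)
            else:
                sub = subsample_averages(series, n_avg, cell_seed)
            dmap = _map_for_method(sub, method, roi, options, basis_order)
            mean_nm, std_nm = background_stats(dmap, brain_mask, focus_exclusion)
            rows.append((n_avg, rep, method, mean_nm, std_nm))
    return pd.DataFrame(rows, columns=list(PRECISION_COLUMNS))


def cnr(
    dmap: DisplacementMap,
    focus_peak_voxel: tuple[int, int],
    brain_mask: np.ndarray,
    focus_exclusion: np.ndarray | None = None,
) -> float:
    """Contrast-to-noise ratio: focal displacement / background std."""
    r, c = focus_peak_voxel
    if not (0 <= r < dmap.values.shape[0] and 0 <= c < dmap.values.shape[1]):
        raise ValidationError(f"peak voxel {focus_peak_voxel} outside grid")
    _, std_nm = background_stats(dmap, brain_mask, focus_exclusion)
    if std_nm == 0:
        raise ValidationError("background std is zero; CNR undefined")
    return float(dmap.values_nm[r, c] / std_nm)
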