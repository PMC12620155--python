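"""Spatial polynomial basis for smooth per-timepoint phase errors.

Physiological and instrumental phase drift in MR-ARFI timeseries is
spatially smooth; it is modeled per timepoint as a low-order 2D polynomial
phase field A·c_n.  The design matrix A holds every monomial x^px·y^py with
px+py ≤ order, evaluated on pixel-center coordinates normalized to [−1, 1]
per axis (normalization keeps the joint optimization well conditioned;
any full-rank reparameterization of the basis yields identical fitted
phase fields).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ValidationError


@dataclass(frozen=True)
class PolynomialBasis:
    """Design matrix mapping coefficient vectors to smooth phase fields.

    Column 0 is the constant term; columns are ordered by total degree,
    then by descending x exponent.  For a 2D order-p basis there are
    (p+1)(p+2)/2 terms.
    """

    order: int
    grid_shape: tuple[int, int]
    design: np.ndarray  # (num_voxels, num_terms)
    term_exponents: tuple[tuple[int, int], ...]  # (px, py) per column

    @property
    def n_terms(self) -> int:
        return self.design.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.design.shape[0]


def _normalized_coords(n: int) -> np.ndarray:
    # pixel centers mapped to [−1, 1]; a single pixel sits at 0
    if n == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, n)


def build_basis(grid_shape: tuple[int, int], order: int) -> PolynomialBasis:
    """Build the monomial design matrix for a grid.

    x is the normalized column coordinate, y the normalized row coordinate.
    """
    rows, cols = int(grid_shape[0]), int(grid_shape[1])
    if rows <= 0 or cols <= 0:
        raise ValidationError(f"grid dimensions must be positive: {grid_shape}")
    if order < 0:
        raise ValidationError("polynomial order must be >= 0")
    y = _normalized_coords(rows)[:, None]  # varies along rows
    x = _normalized_coords(cols)[None, :]  # varies along cols
    exponents = []
    columns = []
    for degree in range(order + 1):
        for px in range(degree, -1, -1):
            py = degree - px
            exponents.append((px, py))
            columns.append((x**px * y**py).ravel() if degree else np.ones(rows * cols))
    design = np.column_stack(columns)
    return PolynomialBasis(
        order=order,
        grid_shape=(rows, cols),
        design=design,
        term_exponents=tuple(exponents),
    )


def eval_phase(basis: PolynomialBasis, coefficients: np.ndarray) -> np.ndarray:
    """Evaluate A·c as a phase field (rad) on the basis grid."""
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (basis.n_terms,):
        raise ValidationError(
            f"expected {basis.n_terms} coefficients, got shape {c.shape}"
        )
    return (basis.design @ c).reshape(basis.grid_shape)
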