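"""Wavelength-window selection and mean centering.

The informative region for the five-component system is 250-300 nm (noisy
below 250 nm, essentially zero absorbance above 300 nm), so spectra are
sliced to that window before calibration; the slice never interpolates.
Both spectra (X) and concentrations (Y) are mean-centered on the
calibration set, and the stored training means are reused verbatim for
validation data so no information leaks from the validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthspec import SpectrumSet, WavelengthGrid

_TOL_NM = 1e-9


def select_window(s: SpectrumSet, low_nm: float = 250.0, high_nm: float = 300.0) -> SpectrumSet:
    """Slice a spectrum set to the inclusive window [low_nm, high_nm].

    Only existing grid points are kept (no interpolation); for the standard
    200-400 nm grid at 0.2 nm, the 250-300 nm window has 251 points.
    """
    if low_nm > high_nm:
        raise ValueError("low_nm must be <= high_nm")
    lam = s.grid.values
    if low_nm < lam[0] - _TOL_NM or high_nm > lam[-1] + _TOL_NM:
        raise ValueError(
            f"window [{low_nm}, {high_nm}] outside grid "
            f"[{s.grid.start_nm}, {s.grid.stop_nm}]"
        )
    mask = (lam >= low_nm - _TOL_NM) & (lam <= high_nm + _TOL_NM)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("window contains no grid points")
    # start == stop yields a valid degenerate one-point grid
    grid = WavelengthGrid(
        start_nm=float(lam[idx[0]]),
        stop_nm=float(lam[idx[-1]]),
        step_nm=s.grid.step_nm,
    )
    return replace(s, grid=grid, absorbance=s.absorbance[:, idx])


def window_indices(grid: WavelengthGrid, low_nm: float, high_nm: float) -> np.ndarray:
    """Indices of grid points falling inside the inclusive window."""
    lam = grid.values
    return np.flatnonzero((lam >= low_nm - _TOL_NM) & (lam <= high_nm + _TOL_NM))


@dataclass(frozen=True)
class CenteringTransform:
    """Column means of X and Y learned on the calibration set."""

    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def n_x(self) -> int:
        return self.x_mean.shape[0]

    @property
    def n_y(self) -> int:
        return self.y_mean.shape[0]


def fit_centering(X: np.ndarray, Y: np.ndarray) -> CenteringTransform:
    """Learn column means of the calibration spectra and concentrations."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError("centering requires at least 2 rows")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    return CenteringTransform(x_mean=X.mean(axis=0), y_mean=Y.mean(axis=0))


def _mean_for(t: CenteringTransform, M: np.ndarray, kind: str | None) -> np.ndarray:
    if kind == "x":
        mean = t.x_mean
    elif kind == "y":
        mean = t.y_mean
    elif kind is None:
        if t.n_x == t.n_y:
            raise ValueError("ambiguous dimensions; pass kind='x' or kind='y'")
        if M.shape[1] == t.n_x:
            mean = t.x_mean
        elif M.shape[1] == t.n_y:
            mean = t.y_mean
        else:
            raise ValueError(
                f"matrix has {M.shape[1]} columns; transform was fitted for "
                f"{t.n_x} (X) or {t.n_y} (Y)"
            )
    else:
        raise ValueError(f"kind must be 'x', 'y' or None, got {kind!r}")
    if M.shape[1] != mean.shape[0]:
        raise ValueError(
            f"matrix has {M.shape[1]} columns, transform expects {mean.shape[0]}"
        )
    return mean


def apply_centering(t: CenteringTransform, M: np.ndarray, kind: str | None = None) -> np.ndarray:
    """Subtract the stored training means (X or Y inferred by column count)."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    return M - _mean_for(t, M, kind)


def invert_centering(t: CenteringTransform, M: np.ndarray, kind: str | None = None) -> np.ndarray:
    """Add back the stored training means; inverse of :func:`apply_centering`."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    return M + _mean_for(t, M, kind)
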