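"""Synthetic UV absorbance spectra.

Stands in for the spectrophotometer: pure-component spectra are sums of
Gaussian absorption bands (per unit concentration, 1 cm path folded into the
peak absorptivity), mixtures follow Beer-Lambert superposition, and an
instrument noise model adds wavelength-dependent Gaussian noise (higher
below 250 nm, where real scans of these analytes are noisy) plus an optional
smooth baseline drift. Signals decay to near zero above 300 nm, reproducing
the statistical structure the calibration window assumes: five severely
overlapping components informative only in 250-300 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WavelengthGrid",
    "ComponentSpec",
    "NoiseModel",
    "SpectrumSet",
    "default_library",
    "pure_spectrum",
    "library_matrix",
    "simulate_mixtures",
    "normalize_spectra",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis with inclusive endpoints (nm)."""

    start_nm: float = 200.0
    stop_nm: float = 400.0
    step_nm: float = 0.2

    def __post_init__(self) -> None:
        if self.start_nm > self.stop_nm:
            raise ValueError("start_nm must be <= stop_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be > 0")

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start_nm, self.stop_nm, self.n_points)


@dataclass(frozen=True)
class ComponentSpec:
    """One pure component: a named list of (center_nm, sigma_nm, peak) bands.

    ``peak`` is the peak absorptivity in AU mL ug^-1 cm^-1 at unit
    concentration through a 1 cm cell.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise ValueError(f"{self.name}: at least one band required")
        for center, sigma, peak in self.bands:
            if sigma <= 0:
                raise ValueError(f"{self.name}: band sigma must be > 0")
            if peak <= 0:
                raise ValueError(f"{self.name}: peak absorptivity must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Wavelength-dependent instrument noise.

    sigma_base applies at and above 250 nm, sigma_below_250 below it;
    baseline_drift_amplitude scales a smooth per-sample quadratic drift.
    Units are AU.
    """

    sigma_base: float = 0.002
    sigma_below_250: float = 0.01
    baseline_drift_amplitude: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_base, self.sigma_below_250, self.baseline_drift_amplitude) < 0:
            raise ValueError("noise amplitudes must be >= 0")

    def sigma(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.where(wavelengths < 250.0, self.sigma_below_250, self.sigma_base)


NOISELESS = NoiseModel(sigma_base=0.0, sigma_below_250=0.0, baseline_drift_amplitude=0.0)


@dataclass(frozen=True)
class SpectrumSet:
    """Samples x wavelengths absorbance matrix bound to its grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", ab)
        if ab.ndim != 2 or ab.shape[1] != self.grid.n_points:
            raise ValueError(
                f"absorbance shape {ab.shape} inconsistent with grid "
                f"({self.grid.n_points} points)"
            )
        if ab.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match number of rows")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance contains non-finite entries")


# Base band parameters (center nm, sigma nm, peak absorptivity). Peaks are
# scaled so design-range mixtures land in ~0.1-1.5 AU; all principal bands sit
# inside 250-300 nm to force the severe overlap the window analysis targets.
_BASE_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "NZ": ((268.0, 7.0, 0.022), (280.0, 5.0, 0.014), (256.0, 6.0, 0.012)),
    "PN": ((258.0, 9.0, 0.007), (272.0, 7.0, 0.0035)),
    "NZ_impB": ((278.0, 10.0, 0.035), (291.0, 5.0, 0.020)),
    "PN_impA": ((263.0, 8.0, 0.016), (283.0, 9.0, 0.010)),
    "PN_impB": ((270.0, 13.0, 0.012), (252.0, 6.0, 0.009)),
}


def default_library(seed: int = 0) -> list[ComponentSpec]:
    """Five overlapping component specs for the two-drug/three-impurity system.

    A fixed base library is jittered slightly (centers +-1.5 nm, widths and
    peaks +-8%) under the given seed, so distinct seeds give distinct but
    structurally equivalent systems. Every component keeps at least one band
    centered in [250, 300] and near-zero absorbance above 300 nm.
    """
    rng = np.random.default_rng(seed)
    library = []
    for name, bands in _BASE_BANDS.items():
        jittered = tuple(
            (
                center + rng.uniform(-1.5, 1.5),
                sigma * (1.0 + rng.uniform(-0.08, 0.08)),
                peak * (1.0 + rng.uniform(-0.08, 0.08)),
            )
            for center, sigma, peak in bands
        )
        library.append(ComponentSpec(name=name, bands=jittered))
    return library


def pure_spectrum(spec: ComponentSpec, grid: WavelengthGrid) -> np.ndarray:
    """Unit-concentration absorbance of one component on the grid.

    A(lambda) = sum over bands of peak * exp(-(lambda - center)^2 / (2 sigma^2)).
    """
    lam = grid.values
    out = np.zeros_like(lam)
    for center, sigma, peak in spec.bands:
        out += peak * np.exp(-((lam - center) ** 2) / (2.0 * sigma**2))
    return out


def library_matrix(library: list[ComponentSpec], grid: WavelengthGrid) -> np.ndarray:
    """Stack pure spectra as a components x wavelengths matrix."""
    return np.vstack([pure_spectrum(spec, grid) for spec in library])


def simulate_mixtures(
    conc: np.ndarray,
    library: list[ComponentSpec],
    grid: WavelengthGrid,
    noise: NoiseModel = NOISELESS,
    sample_ids: tuple[str, ...] | None = None,
) -> SpectrumSet:
    """Beer-Lambert mixture spectra with instrument noise.

    ``conc`` is samples x components (ug/mL), columns ordered as ``library``.
    Reproducible for a fixed ``noise.seed``.
    """
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    if conc.shape[1] != len(library):
        raise ValueError(
            f"conc has {conc.shape[1]} columns but library has {len(library)} components"
        )
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    clean = conc @ library_matrix(library, grid)
    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma(grid.values)
    noisy = clean + rng.normal(0.0, 1.0, size=clean.shape) * sigma
    if noise.baseline_drift_amplitude > 0:
        x = np.linspace(-1.0, 1.0, grid.n_points)
        coef = rng.uniform(-1.0, 1.0, size=(conc.shape[0], 3))
        drift = coef[:, [0]] + coef[:, [1]] * x + coef[:, [2]] * x**2
        noisy = noisy + noise.baseline_drift_amplitude * drift
    if sample_ids is None:
        sample_ids = tuple(f"mix{i + 1:02d}" for i in range(conc.shape[0]))
    return SpectrumSet(grid=grid, absorbance=noisy, sample_ids=tuple(sample_ids))


def normalize_spectra(s: SpectrumSet) -> SpectrumSet:
    """Scale each spectrum by its own maximum (for spectral characterization).

    Calibration always operates on raw absorbances; normalization only serves
    visual comparison of band positions.
    """
    maxima = s.absorbance.max(axis=1)
    if np.any(maxima <= 0):
        bad = [s.sample_ids[i] for i in np.flatnonzero(maxima <= 0)]
        raise ValueError(f"cannot normalize rows with non-positive maximum: {bad}")
    return replace(s, absorbance=s.absorbance / maxima[:, None])
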