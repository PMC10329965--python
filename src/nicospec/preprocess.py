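"""Grid alignment, baseline subtraction, summary spectra and labelling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import WavelengthGrid
from .io import SpectraSet, Spectrum

#: Foliar hyperaccumulation thresholds, ug/g dry weight.
HYPERACCUMULATION_THRESHOLDS: dict[str, float] = {
    "Mn": 10_000.0,
    "Zn": 3000.0,
    "Ni": 1000.0,
    "Co": 300.0,
    "Cu": 300.0,
}

#: Reference wavelength for baseline subtraction (a reflectance peak between
#: the 1200 and 1400 nm water bands).
BASELINE_REF_NM = 1350.0


@dataclass(frozen=True)
class SummarySpectra:
    """Per-channel minimum / mean / maximum over a set of spectra."""

    minimum: np.ndarray
    mean: np.ndarray
    maximum: np.ndarray
    grid: WavelengthGrid
    n_samples: int


def resample_to_grid(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a target grid (no extrapolation)."""
    if spectrum.grid == grid:
        return Spectrum(spectrum.sample_id, spectrum.values.copy(), grid)
    src = spectrum.grid.wavelengths
    if grid.wavelengths[0] < src[0] or grid.wavelengths[-1] > src[-1]:
        raise ValueError(
            f"target grid [{grid.wavelengths[0]}, {grid.wavelengths[-1]}] nm "
            f"extends beyond source range [{src[0]}, {src[-1]}] nm; "
            "extrapolation is not supported"
        )
    vals = np.interp(grid.wavelengths, src, spectrum.values)
    return Spectrum(spectrum.sample_id, vals, grid)


def baseline_subtract(
    spectrum: Spectrum, ref_wavelength: float = BASELINE_REF_NM
) -> Spectrum:
    """Shift a spectrum so its value at the channel nearest ``ref_wavelength`` is 0.

    Removes per-sample offsets (illumination, scattering level) while
    preserving every within-spectrum channel difference.
    """
    i = spectrum.grid.nearest_channel(ref_wavelength)
    return Spectrum(
        spectrum.sample_id, spectrum.values - spectrum.values[i], spectrum.grid
    )


def baseline_subtract_set(
    spectra: SpectraSet, ref_wavelength: float = BASELINE_REF_NM
) -> SpectraSet:
    """Vectorised :func:`baseline_subtract` over a whole set."""
    i = spectra.grid.nearest_channel(ref_wavelength)
    return SpectraSet(
        sample_ids=list(spectra.sample_ids),
        values=spectra.values - spectra.values[:, [i]],
        grid=spectra.grid,
    )


def summary_spectra(spectra: SpectraSet) -> SummarySpectra:
    """Per-channel min/mean/max across the samples of a set."""
    if spectra.n_samples == 0:
        raise ValueError("cannot summarise an empty SpectraSet")
    return SummarySpectra(
        minimum=spectra.values.min(axis=0),
        mean=spectra.values.mean(axis=0),
        maximum=spectra.values.max(axis=0),
        grid=spectra.grid,
        n_samples=spectra.n_samples,
    )


def hyperaccumulator_label(
    conc: float,
    element: str = "Ni",
    thresholds: dict[str, float] | None = None,
) -> bool:
    """True iff ``conc`` (ug/g) meets the hyperaccumulation threshold (>=)."""
    table = thresholds if thresholds is not None else HYPERACCUMULATION_THRESHOLDS
    if element not in table:
        raise KeyError(
            f"unknown element {element!r}; known: {sorted(table)}"
        )
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return conc >= table[element]
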