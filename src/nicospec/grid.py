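"""Wavelength grids for VNIR-SWIR leaf reflectance spectra.

The canonical grid matches a full-range field spectroradiometer: 350-2500 nm
sampled every 1 nm, i.e. 2151 contiguous channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL_START_NM = 350.0
CANONICAL_STOP_NM = 2500.0
CANONICAL_STEP_NM = 1.0


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniformly spaced, strictly increasing wavelength axis in nm."""

    start: float
    stop: float
    step: float
    wavelengths: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(
                f"grid stop ({self.stop}) must exceed start ({self.start})"
            )
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "grid range is not an integer number of steps: "
                f"({self.start}, {self.stop}, {self.step})"
            )
        wl = self.start + self.step * np.arange(int(round(n)) + 1)
        object.__setattr__(self, "wavelengths", wl)
        wl.setflags(write=False)

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    def __len__(self) -> int:
        return self.n_channels

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start == other.start
            and self.stop == other.stop
            and self.step == other.step
        )

    def __hash__(self) -> int:
        return hash((self.start, self.stop, self.step))

    def nearest_channel(self, wavelength_nm: float) -> int:
        """Index of the channel closest to ``wavelength_nm``.

        Ties between two equidistant channels resolve to the lower
        wavelength. The requested wavelength must lie within the grid range.
        """
        wl = self.wavelengths
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside grid range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        # floor position, then compare with the next channel; strict '<'
        # keeps ties on the lower-wavelength side.
        i = int(np.searchsorted(wl, wavelength_nm, side="right")) - 1
        if i + 1 < wl.size and (wl[i + 1] - wavelength_nm) < (wavelength_nm - wl[i]):
            return i + 1
        return i

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray) -> "WavelengthGrid":
        """Build a grid from an explicit axis, validating uniform spacing."""
        wl = np.asarray(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("need a 1-D axis with at least 2 wavelengths")
        diffs = np.diff(wl)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            raise ValueError(
                f"wavelengths not strictly increasing at row {bad[0] + 1} "
                f"({wl[bad[0]]} -> {wl[bad[0] + 1]} nm)"
            )
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=0, atol=1e-6 * max(step, 1.0)):
            raise ValueError("wavelength axis is not uniformly spaced")
        return cls(start=float(wl[0]), stop=float(wl[-1]), step=float(step))


def canonical_grid() -> WavelengthGrid:
    """The 350-2500 nm, 1 nm grid: exactly 2151 channels."""
    return WavelengthGrid(CANONICAL_START_NM, CANONICAL_STOP_NM, CANONICAL_STEP_NM)
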