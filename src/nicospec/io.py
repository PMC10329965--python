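"""Reading and writing spectral libraries and sample metadata.

Spectral libraries travel as wide CSV: first column the wavelength axis in
nm (ascending), one column per sample, reflectance stored as a fraction in
[0, 1]. Metadata is a plain CSV with one row per sample. Both dialects are
UTF-8 with '.' decimal separator and LF line endings, and round-trip to 12
significant digits.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import WavelengthGrid

logger = logging.getLogger(__name__)

VALID_STATES = ("hydrated", "dehydrated")
VALID_METHODS = ("ICP-AES", "XRF", "synthetic")
META_COLUMNS = ("sample_id", "species", "state", "ni_conc", "method")

# Reflectance sanity window for the reader: tolerates minor calibration
# overshoot but catches percent-scale files (values like 45.0).
_REFLECTANCE_MIN = -0.05
_REFLECTANCE_MAX = 1.5


@dataclass
class Spectrum:
    """A single reflectance spectrum on a wavelength grid."""

    sample_id: str
    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_channels,):
            raise ValueError(
                f"spectrum '{self.sample_id}' has {self.values.size} values "
                f"for a {self.grid.n_channels}-channel grid"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"spectrum '{self.sample_id}' has non-finite values")


@dataclass
class SpectraSet:
    """An ordered collection of spectra sharing one grid.

    Internally a dense (n_samples, n_channels) float array plus the sample
    id list; the natural container for the vectorised pipeline stages.
    """

    sample_ids: list[str]
    values: np.ndarray  # (n_samples, n_channels)
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.sample_ids), self.grid.n_channels):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.grid.n_channels} channels"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __len__(self) -> int:
        return self.n_samples

    def __iter__(self) -> Iterable[Spectrum]:
        for sid, row in zip(self.sample_ids, self.values):
            yield Spectrum(sid, row, self.grid)

    def spectrum(self, sample_id: str) -> Spectrum:
        i = self.sample_ids.index(sample_id)
        return Spectrum(sample_id, self.values[i], self.grid)

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise ValueError("cannot build a SpectraSet from zero spectra")
        grid = spectra[0].grid
        for s in spectra[1:]:
            if s.grid != grid:
                raise ValueError(
                    f"spectrum '{s.sample_id}' is on a different grid"
                )
        return cls(
            sample_ids=[s.sample_id for s in spectra],
            values=np.vstack([s.values for s in spectra]),
            grid=grid,
        )


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a wide spectral-library CSV into a :class:`SpectraSet`.

    The first column is the wavelength axis in nm (strictly ascending,
    uniformly spaced); each remaining column is one sample, with the sample
    id in the header row.
    """
    # pandas silently renames duplicate header columns, so vet the raw header
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    raw_ids = [str(c) for c in header[1:]]
    if len(set(raw_ids)) != len(raw_ids):
        dupes = sorted({s for s in raw_ids if raw_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes}")

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavelength column plus >=1 sample column")
    wl_raw = df.iloc[:, 0]
    wl = pd.to_numeric(wl_raw, errors="coerce")
    if wl.isna().any():
        row = int(wl.isna().idxmax())
        raise ValueError(
            f"{path}: non-numeric wavelength {wl_raw.iloc[row]!r} at data row {row}"
        )
    grid = WavelengthGrid.from_wavelengths(wl.to_numpy())
    sample_ids = [str(c) for c in df.columns[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    body = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if body.isna().to_numpy().any():
        col = body.columns[body.isna().any(axis=0)][0]
        row = int(body[col].isna().idxmax())
        raise ValueError(
            f"{path}: non-numeric reflectance in sample '{col}' at data row {row}"
        )
    values = body.to_numpy(dtype=float).T  # (n_samples, n_channels)
    if values.min() < _REFLECTANCE_MIN or values.max() > _REFLECTANCE_MAX:
        raise ValueError(
            f"{path}: reflectance outside [{_REFLECTANCE_MIN}, {_REFLECTANCE_MAX}] "
            f"(min {values.min():.4g}, max {values.max():.4g}); "
            "values look like percent, not fraction?"
        )
    return SpectraSet(sample_ids=sample_ids, values=values, grid=grid)


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` as wide CSV; round-trips to 12 sig. digits."""
    if spectra.n_samples == 0:
        raise ValueError("refusing to write an empty SpectraSet")
    df = pd.DataFrame(
        spectra.values.T, columns=spectra.sample_ids, index=spectra.grid.wavelengths
    )
    df.index.name = "wavelength_nm"
    df.to_csv(path, float_format="%.12g", lineterminator="\n")


def write_spectra_long_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Long-format export (sample_id, wavelength_nm, reflectance) for plotting tools."""
    if spectra.n_samples == 0:
        raise ValueError("refusing to write an empty SpectraSet")
    n = spectra.grid.n_channels
    df = pd.DataFrame(
        {
            "sample_id": np.repeat(spectra.sample_ids, n),
            "wavelength_nm": np.tile(spectra.grid.wavelengths, spectra.n_samples),
            "reflectance": spectra.values.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_meta_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata CSV.

    Mandatory columns: sample_id, species, state, ni_conc, method. Extra
    columns are preserved untouched.
    """
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    conc = pd.to_numeric(df["ni_conc"], errors="coerce")
    if conc.isna().any():
        row = int(conc.isna().idxmax())
        raise ValueError(f"{path}: non-numeric ni_conc at row {row}")
    if (conc < 0).any():
        row = int((conc < 0).idxmax())
        raise ValueError(f"{path}: negative ni_conc ({conc.iloc[row]}) at row {row}")
    df["ni_conc"] = conc
    bad_state = ~df["state"].isin(VALID_STATES)
    if bad_state.any():
        row = int(bad_state.idxmax())
        raise ValueError(
            f"{path}: invalid state {df['state'].iloc[row]!r} at row {row}; "
            f"allowed tokens: {list(VALID_STATES)}"
        )
    return df


def write_meta_csv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def join_spectra_meta(
    spectra: SpectraSet, meta: pd.DataFrame
) -> tuple[SpectraSet, pd.DataFrame]:
    """Align metadata rows to the spectra's sample order.

    Every spectrum must have exactly one metadata row; surplus metadata rows
    are dropped (the count is logged).
    """
    by_id = meta.set_index("sample_id", drop=False)
    if by_id.index.has_duplicates:
        dupes = sorted(by_id.index[by_id.index.duplicated()].unique())
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    missing = [sid for sid in spectra.sample_ids if sid not in by_id.index]
    if missing:
        raise KeyError(f"sample id(s) {missing} have spectra but no metadata row")
    dropped = len(meta) - spectra.n_samples
    if dropped:
        logger.info("join_spectra_meta: dropped %d unmatched metadata row(s)", dropped)
    aligned = by_id.loc[spectra.sample_ids].reset_index(drop=True)
    return spectra, aligned
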