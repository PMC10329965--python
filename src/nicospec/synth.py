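"""Synthetic VNIR-SWIR leaf reflectance with nickel absorption features.

Generates leaf spectra carrying the qualitative structure of real
measurements: a chlorophyll-darkened visible region with a green
reflectance peak near 550 nm, a near-infrared plateau, water absorption
bands near 975/1200/1400/1900 nm in hydrated leaves, an overall reflectance
lift on dehydration, and — for nickel hyperaccumulators — Ni(II) electronic
absorption bands near 360, 600 and 1000 nm whose depth grows with foliar Ni
concentration. All dips are subtractive Gaussians in reflectance; depth is
linear in concentration by default (a log mode exists), which makes the
noise-free band-difference/concentration correlation exactly +/-1 and hence
a clean analytical oracle for the downstream correlation map.

Concentrations are log-normal: hyperaccumulators with median 10,000 ug/g
truncated below at the 1000 ug/g hyperaccumulation threshold, "normal"
foliage with median 20 ug/g truncated above at 100 ug/g. Truncation is by
resampling, not clipping, so no atom forms at the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .grid import WavelengthGrid, canonical_grid
from .io import SpectraSet, Spectrum, VALID_STATES

HydrationState = Literal["hydrated", "dehydrated"]
Group = Literal["hyper", "normal"]

# Gaussian dips are truncated beyond this many widths from the band centre,
# so distant channels are left bit-identical.
_SUPPORT_WIDTHS = 4.0


def _gaussian_dip(
    wl: np.ndarray, center: float, width: float, depth: float
) -> np.ndarray:
    d = depth * np.exp(-0.5 * ((wl - center) / width) ** 2)
    d[np.abs(wl - center) > _SUPPORT_WIDTHS * width] = 0.0
    return d


@dataclass(frozen=True)
class LeafModelParams:
    """Shape parameters of the Ni-free baseline leaf spectrum.

    chlorophyll_strength : dimensionless absorbance scale of the 400-700 nm
        pigment absorption (0 = no pigment darkening).
    green_peak_center : nm, centre of the green transmission window that
        produces the local visible reflectance maximum.
    nir_plateau : reflectance fraction of the 700-1300 nm plateau.
    water_bands : (center nm, width nm, depth fraction) of the hydrated-leaf
        water absorptions.
    dry_offset : reflectance increment applied in the dehydrated state.
    dry_water_retention : factor (0..1) by which water-band depths are
        scaled when dehydrated; 0.1 leaves faint residues.
    swir_slope : gentle linear reflectance decline per nm beyond 1300 nm.
    noise_sd : additive i.i.d. Gaussian noise standard deviation
        (reflectance fraction) applied per channel at dataset generation.
    """

    chlorophyll_strength: float = 2.5
    green_peak_center: float = 550.0
    green_window_width: float = 35.0
    green_window_relief: float = 0.65
    red_edge_center: float = 710.0
    red_edge_width: float = 8.0
    nir_plateau: float = 0.50
    water_bands: tuple[tuple[float, float, float], ...] = (
        (975.0, 40.0, 0.10),
        (1200.0, 40.0, 0.12),
        (1400.0, 60.0, 0.30),
        (1900.0, 90.0, 0.38),
    )
    dry_offset: float = 0.08
    dry_water_retention: float = 0.1
    swir_slope: float = 4e-5
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.nir_plateau <= 1.0:
            raise ValueError("nir_plateau must be a reflectance fraction in [0,1]")
        if not 0.0 <= self.dry_offset <= 1.0:
            raise ValueError("dry_offset must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.chlorophyll_strength < 0:
            raise ValueError("chlorophyll_strength must be >= 0")
        for c, w, d in self.water_bands:
            if w <= 0:
                raise ValueError(f"water band at {c} nm has non-positive width")
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"water band at {c} nm has depth {d} outside [0,1]")


@dataclass(frozen=True)
class NiBandParams:
    """Ni(II) electronic absorption bands and their concentration coupling.

    centers/widths : nm. Defaults put the three d-d transition bands at
        360, 600 and 1000 nm; the 1000 nm band has width 60 nm.
    depth_per_conc : reflectance-fraction dip depth per ug/g Ni (linear
        coefficient k; dip depth at a band centre is k * conc).
    depth_mode : 'linear' (depth = k*conc) or 'log' (depth = k_log *
        log10(1 + conc)); linear is the default.
    log_depth_scale : reflectance per decade, used only in 'log' mode.
    """

    centers: tuple[float, ...] = (360.0, 600.0, 1000.0)
    widths: tuple[float, ...] = (40.0, 50.0, 60.0)
    depth_per_conc: float = 5e-6
    depth_mode: Literal["linear", "log"] = "linear"
    log_depth_scale: float = 0.02

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.widths):
            raise ValueError("centers and widths must have equal length")
        if self.depth_per_conc < 0:
            raise ValueError("depth_per_conc must be >= 0")
        if any(w <= 0 for w in self.widths):
            raise ValueError("band widths must be positive")

    def depth_at(self, conc: float) -> float:
        """Dip depth (reflectance fraction) at a band centre for ``conc``."""
        if self.depth_mode == "linear":
            return self.depth_per_conc * conc
        return self.log_depth_scale * np.log10(1.0 + conc)


#: Baseline leaf parameters of the "normal" (non-accumulator) species pool.
#: The normal class emulates an independent spectral library of ordinary
#: foliage from many species, so its leaf structure differs from the
#: hyperaccumulator pool: a brighter NIR plateau and more residual bound
#: water. Pool-average pigmentation is kept equal to the hyperaccumulator
#: pool — visible pigment signatures vary widely across species and do not
#: separate the classes consistently — so the class contrast lives in the
#: NIR-SWIR leaf-structure and water features plus the Ni band, not in a
#: flat offset (which 1350 nm baseline subtraction would cancel anyway).
NORMAL_LEAF_PARAMS = LeafModelParams(
    nir_plateau=0.53,
    dry_water_retention=0.18,
    swir_slope=5e-5,
)


def _check_state(state: str) -> None:
    if state not in VALID_STATES:
        raise ValueError(
            f"unknown hydration state {state!r}; allowed: {list(VALID_STATES)}"
        )


def simulate_baseline_spectrum(
    state: HydrationState,
    params: LeafModelParams | None = None,
    grid: WavelengthGrid | None = None,
    sample_id: str = "baseline",
) -> Spectrum:
    """Noise-free, Ni-free leaf reflectance for one hydration state.

    Hydrated spectra carry Gaussian water absorptions at every configured
    water band; dehydrated spectra have those dips scaled down by
    ``dry_water_retention`` and the whole spectrum lifted by ``dry_offset``.
    The visible region is darkened by a chlorophyll absorbance term with a
    transmission window at ``green_peak_center``, producing the local green
    reflectance maximum.
    """
    _check_state(state)
    p = params or LeafModelParams()
    g = grid or canonical_grid()
    wl = g.wavelengths
    for c, _, _ in p.water_bands:
        if not (wl[0] < c < wl[-1]):
            raise ValueError(f"water band centre {c} nm outside grid range")

    # red-edge transition from pigment-darkened visible to the NIR plateau
    edge = 1.0 / (1.0 + np.exp(-(wl - p.red_edge_center) / p.red_edge_width))
    window = p.green_window_relief * np.exp(
        -0.5 * ((wl - p.green_peak_center) / p.green_window_width) ** 2
    )
    absorbance = p.chlorophyll_strength * (1.0 - window) * (1.0 - edge)
    # the dry-state lift acts on the scattering continuum, so in the visible
    # it is still attenuated by pigments: dried leaves stay dark below the
    # red edge, which keeps the visible Ni bands pigment-masked.
    continuum = p.nir_plateau + (p.dry_offset if state == "dehydrated" else 0.0)
    r = continuum * np.exp(-absorbance)

    r = r - p.swir_slope * np.clip(wl - 1300.0, 0.0, None)

    retention = 1.0 if state == "hydrated" else p.dry_water_retention
    for c, w, d in p.water_bands:
        r = r - _gaussian_dip(wl, c, w, retention * d)

    if r.min() < -1e-9 or r.max() > 1.0 + 1e-9:
        raise ValueError(
            "baseline parameters drive reflectance outside [0,1] "
            f"(min {r.min():.4f}, max {r.max():.4f}); reduce band depths or offsets"
        )
    return Spectrum(sample_id, np.clip(r, 0.0, 1.0), g)


def apply_ni_absorption(
    spectrum: Spectrum, conc: float, bands: NiBandParams | None = None
) -> Spectrum:
    """Subtract Ni(II) absorption dips of concentration-dependent depth.

    Each band removes a Gaussian of depth ``bands.depth_at(conc)``;
    reflectance is floored at 0 (a saturated band cannot reflect less than
    nothing — this floor is what lets chlorophyll-dark visible baselines
    mask the 360/600 nm bands). Channels farther than 4 widths from every
    centre are returned bit-identical.
    """
    if conc < 0:
        raise ValueError(f"Ni concentration must be >= 0, got {conc}")
    b = bands or NiBandParams()
    wl = spectrum.grid.wavelengths
    for c in b.centers:
        if not (wl[0] <= c <= wl[-1]):
            raise ValueError(f"Ni band centre {c} nm outside grid range")
    r = spectrum.values.copy()
    depth = b.depth_at(conc)
    for c, w in zip(b.centers, b.widths):
        r -= _gaussian_dip(wl, c, w, depth)
    np.clip(r, 0.0, None, out=r)
    return Spectrum(spectrum.sample_id, r, spectrum.grid)


def sample_ni_concentrations(
    n: int,
    group: Group,
    seed: int | np.random.Generator,
    median: float | None = None,
    geometric_sd: float = 2.0,
) -> np.ndarray:
    """Draw foliar Ni concentrations (ug/g) for one plant group.

    ``hyper``: log-normal, median 10,000 ug/g, resample-truncated below at
    the 1000 ug/g hyperaccumulation threshold. ``normal``: log-normal,
    median 20 ug/g, resample-truncated above at 100 ug/g.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if group not in ("hyper", "normal"):
        raise ValueError(f"unknown group {group!r}; allowed: ['hyper', 'normal']")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    med = median if median is not None else (10_000.0 if group == "hyper" else 20.0)
    sigma = np.log(geometric_sd)
    bound = 1000.0 if group == "hyper" else 100.0

    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mean=np.log(med), sigma=sigma, size=n - filled)
        keep = draw >= bound if group == "hyper" else draw < bound
        k = draw[keep]
        out[filled : filled + k.size] = k
        filled += k.size
    return out


def generate_dataset(
    n_hyper: int,
    n_normal: int,
    state: HydrationState = "dehydrated",
    leaf_params: LeafModelParams | None = None,
    ni_params: NiBandParams | None = None,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
    normal_leaf_params: LeafModelParams | None = None,
    species_hyper: str = "synthetic-hyper",
    species_normal: str = "synthetic-normal",
) -> tuple[SpectraSet, pd.DataFrame]:
    """Generate an aligned (spectra, metadata) pair for the two groups.

    Per sample: species baseline spectrum for ``state``, Ni dips for a
    drawn concentration, then i.i.d. Gaussian channel noise of sd
    ``leaf_params.noise_sd`` (spectra re-clipped to [0,1]). The normal
    group is a distinct species pool with its own baseline
    (:data:`NORMAL_LEAF_PARAMS` unless overridden), mirroring real surveys
    where non-accumulator reference leaves come from other species.
    Metadata rows carry sample_id, species, state, ni_conc,
    method='synthetic' and the group label, in the same order as the
    spectra.
    """
    if n_hyper < 0 or n_normal < 0:
        raise ValueError("sample counts must be non-negative")
    if n_hyper + n_normal == 0:
        raise ValueError("need at least one sample")
    _check_state(state)
    p = leaf_params or LeafModelParams()
    p_norm = normal_leaf_params or replace(
        NORMAL_LEAF_PARAMS, noise_sd=p.noise_sd, water_bands=p.water_bands
    )
    b = ni_params or NiBandParams()
    g = grid or canonical_grid()
    rng = np.random.default_rng(seed)

    base_hyper = simulate_baseline_spectrum(state, p, g)
    base_normal = simulate_baseline_spectrum(state, p_norm, g)
    concs: list[float] = []
    groups: list[str] = []
    if n_hyper:
        concs.extend(sample_ni_concentrations(n_hyper, "hyper", rng))
        groups.extend(["hyper"] * n_hyper)
    if n_normal:
        concs.extend(sample_ni_concentrations(n_normal, "normal", rng))
        groups.extend(["normal"] * n_normal)

    n = len(concs)
    values = np.empty((n, g.n_channels))
    ids = [f"S{i:04d}" for i in range(n)]
    for i, (c, gl) in enumerate(zip(concs, groups)):
        base = base_hyper if gl == "hyper" else base_normal
        values[i] = apply_ni_absorption(base, c, b).values
    if p.noise_sd > 0:
        values += rng.normal(0.0, p.noise_sd, size=values.shape)
        np.clip(values, 0.0, 1.0, out=values)

    spectra = SpectraSet(sample_ids=ids, values=values, grid=g)
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "species": [
                species_hyper if gl == "hyper" else species_normal for gl in groups
            ],
            "state": state,
            "ni_conc": concs,
            "method": "synthetic",
            "group": groups,
        }
    )
    return spectra, meta
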