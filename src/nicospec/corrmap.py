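"""Band-difference correlation maps of leaf spectra against Ni concentration.

The statistic: for every ordered channel pair (alpha, beta) form the
per-sample reflectance difference D_i(alpha, beta) = R_i(beta) -
R_i(alpha), where alpha is the *subtractor* channel, then correlate
D(alpha, beta) with foliar Ni concentration across the N samples. On a
B-channel grid this is a B x B map of signed Pearson correlations, masked
wherever the correlation fails a 95% confidence test.

Materialising the full N x B x B difference stack at B = 2151 costs over a
gigabyte, so the production path never builds it. Because D is a linear
function of the reflectance vector, every cell's correlation collapses to
channel (co)variances::

    r(a, b) = (S(b,c) - S(a,c)) / sqrt((S(a,a) + S(b,b) - 2 S(a,b)) * S(c,c))

with S the sample covariances over the N samples. One B x B channel
covariance matrix (about 37 MB at full resolution) therefore yields the
entire map. The literal stacked implementation survives as
:func:`brute_force_map`, the test oracle, guarded to small B.

Array convention: all B x B arrays are indexed ``[alpha_index, beta_index]``.
The map is antisymmetric, r(a,b) = -r(b,a), so the convention only fixes
the sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .grid import WavelengthGrid
from .io import SpectraSet, Spectrum

logger = logging.getLogger(__name__)

#: Largest channel count for which the literal stacked oracle may run.
BRUTE_FORCE_MAX_CHANNELS = 256

#: Relative tolerance below which a cell's difference variance counts as
#: zero (undefined correlation -> NaN, always masked).
_VAR_REL_TOL = 1e-12


@dataclass
class CorrelationMap:
    """Signed correlations, p-values and confidence mask on a B x B grid.

    ``r[a, b]`` is the correlation of R(beta_b) - R(alpha_a) with Ni
    concentration; ``mask[a, b]`` is True where the value is suppressed
    (insignificant or undefined). Undefined cells carry NaN in ``r``/``p``.
    """

    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    n: int
    grid: WavelengthGrid
    method: str = "pearson"
    alpha_level: float = 0.05


@dataclass(frozen=True)
class Hotspot:
    """The unmasked cell with maximal absolute correlation."""

    alpha_nm: float
    beta_nm: float
    r_value: float
    p_value: float


def band_difference_matrix(spectrum: Spectrum) -> np.ndarray:
    """The B x B matrix D with ``D[a, b] = R[b] - R[a]``.

    Oracle/teaching form; the production correlation never materialises it.
    """
    v = spectrum.values
    return v[None, :] - v[:, None]


def pvalues(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided p-value of a Pearson correlation under the t-test.

    t = r * sqrt((n-2) / (1-r^2)) referred to Student's t with n-2 degrees
    of freedom. p(|r|=1) = 0, p(0) = 1; NaN passes through.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 samples for a p-value, got {n}")
    r_arr = np.asarray(r, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt(df / (1.0 - r_arr**2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r_arr), np.nan, p)
    return float(p) if np.isscalar(r) or r_arr.ndim == 0 else p


def _validate_inputs(spectra: SpectraSet, conc: np.ndarray) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    if conc.ndim != 1 or conc.size != spectra.n_samples:
        raise ValueError(
            f"{spectra.n_samples} spectra but {conc.size} concentrations"
        )
    if spectra.n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {spectra.n_samples}")
    if np.ptp(conc) == 0:
        raise ValueError("concentrations are constant; correlation undefined")
    return conc


def correlation_map(
    spectra: SpectraSet,
    conc: np.ndarray,
    alpha_level: float = 0.05,
    fdr: bool = False,
    method: Literal["pearson", "spearman"] = "pearson",
) -> CorrelationMap:
    """Correlate every band-pair difference with Ni concentration.

    Streaming path: O(B^2) memory via the covariance identity, never the
    N x B x B stack. Cells with zero difference variance are NaN and always
    masked; the returned map is already masked at ``alpha_level`` (per-cell
    two-sided p, or Benjamini-Hochberg-adjusted when ``fdr``).

    Spearman has no covariance shortcut (ranking is per-cell); it is served
    by the stacked oracle path and inherits its channel-count guard.
    """
    if method == "spearman":
        return brute_force_map(
            spectra, conc, alpha_level=alpha_level, fdr=fdr, method="spearman"
        )
    if method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    conc = _validate_inputs(spectra, conc)
    X = spectra.values
    n = spectra.n_samples

    Xc = X - X.mean(axis=0)
    cc = conc - conc.mean()
    denom = n - 1
    S = (Xc.T @ Xc) / denom          # (B, B) channel covariance
    S = 0.5 * (S + S.T)              # exact symmetry -> exactly antisymmetric r
    sc = (Xc.T @ cc) / denom         # (B,) channel-concentration covariance
    vc = float(cc @ cc) / denom
    v = np.diag(S)

    num = sc[None, :] - sc[:, None]                  # [a, b] = sc[b] - sc[a]
    var_d = v[:, None] + v[None, :] - 2.0 * S        # Var of D(a, b)
    undefined = var_d <= _VAR_REL_TOL * (v[:, None] + v[None, :])
    np.clip(var_d, 0.0, None, out=var_d)

    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / np.sqrt(var_d * vc)
    r[undefined] = np.nan
    np.clip(r, -1.0, 1.0, out=r)

    p = pvalues(r, n)
    cmap = CorrelationMap(
        r=r, p=p, mask=np.zeros_like(r, dtype=bool), n=n, grid=spectra.grid,
        method="pearson", alpha_level=alpha_level,
    )
    return apply_mask(cmap, alpha_level=alpha_level, fdr=fdr)


def brute_force_map(
    spectra: SpectraSet,
    conc: np.ndarray,
    alpha_level: float = 0.05,
    fdr: bool = False,
    method: Literal["pearson", "spearman"] = "pearson",
) -> CorrelationMap:
    """Literal implementation: stack all difference matrices, correlate per cell.

    Builds the N x B x B stack and calls an independent correlation routine
    (scipy) on every cell, which makes this the oracle for
    :func:`correlation_map`. Refuses B > ``BRUTE_FORCE_MAX_CHANNELS``.
    """
    conc = _validate_inputs(spectra, conc)
    B = spectra.grid.n_channels
    if B > BRUTE_FORCE_MAX_CHANNELS:
        raise ValueError(
            f"brute-force path refuses B={B} channels "
            f"(guard: {BRUTE_FORCE_MAX_CHANNELS}); use correlation_map"
        )
    X = spectra.values
    n = spectra.n_samples
    stack = X[:, None, :] - X[:, :, None]   # [i, a, b] = R_i[b] - R_i[a]

    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    r = np.full((B, B), np.nan)
    p = np.full((B, B), np.nan)
    for a in range(B):
        for b in range(B):
            d = stack[:, a, b]
            if np.ptp(d) == 0:
                continue  # constant difference: correlation undefined
            res = corr(d, conc)
            r[a, b] = res.statistic
            p[a, b] = res.pvalue
    cmap = CorrelationMap(
        r=r, p=p, mask=np.zeros_like(r, dtype=bool), n=n, grid=spectra.grid,
        method=method, alpha_level=alpha_level,
    )
    return apply_mask(cmap, alpha_level=alpha_level, fdr=fdr)


def apply_mask(
    cmap: CorrelationMap, alpha_level: float = 0.05, fdr: bool = False
) -> CorrelationMap:
    """Recompute the confidence mask of a map.

    Default: per-cell two-sided p >= ``alpha_level`` is suppressed, with no
    multiple-testing correction across the ~B^2 cells. With ``fdr``,
    Benjamini-Hochberg adjustment over the strict upper triangle, mirrored
    to the lower (|r| and p are symmetric). The diagonal and undefined
    cells are always masked.
    """
    if not 0.0 < alpha_level < 1.0:
        raise ValueError(f"alpha_level must be in (0,1), got {alpha_level}")
    p = cmap.p
    undefined = ~np.isfinite(p)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        B = p.shape[0]
        iu = np.triu_indices(B, k=1)
        p_flat = p[iu]
        ok = np.isfinite(p_flat)
        rej = np.zeros(p_flat.size, dtype=bool)
        p_adj = np.full(p_flat.size, np.nan)
        if ok.any():
            rej[ok], p_adj[ok], _, _ = multipletests(
                p_flat[ok], alpha=alpha_level, method="fdr_bh"
            )
        sig = np.zeros_like(p, dtype=bool)
        sig[iu] = rej
        sig = sig | sig.T
        mask = ~sig
    else:
        with np.errstate(invalid="ignore"):
            mask = ~(p < alpha_level)
    mask |= undefined
    np.fill_diagonal(mask, True)
    return replace(cmap, mask=mask, alpha_level=alpha_level)


def find_hotspot(cmap: CorrelationMap) -> Hotspot:
    """The unmasked cell maximising |r|.

    Exact ties resolve to the smallest beta wavelength, then the smallest
    alpha wavelength.
    """
    absr = np.abs(cmap.r)
    absr = np.where(cmap.mask | ~np.isfinite(absr), -np.inf, absr)
    best = absr.max()
    if not np.isfinite(best):
        raise ValueError("map is fully masked; no hotspot")
    cand_a, cand_b = np.nonzero(absr == best)
    order = np.lexsort((cand_a, cand_b))  # beta first, then alpha
    a, b = int(cand_a[order[0]]), int(cand_b[order[0]])
    wl = cmap.grid.wavelengths
    return Hotspot(
        alpha_nm=float(wl[a]),
        beta_nm=float(wl[b]),
        r_value=float(cmap.r[a, b]),
        p_value=float(cmap.p[a, b]),
    )


def per_group_maps(
    spectra: SpectraSet,
    meta: pd.DataFrame,
    grouping: Iterable[str] = ("species", "state"),
    alpha_level: float = 0.05,
    fdr: bool = False,
    method: Literal["pearson", "spearman"] = "pearson",
) -> dict[tuple, CorrelationMap]:
    """One correlation map per metadata group (default species x state).

    Groups with fewer than 3 samples or constant Ni concentration are
    skipped with a logged warning, not an error.
    """
    grouping = list(grouping)
    maps: dict[tuple, CorrelationMap] = {}
    idx = {sid: i for i, sid in enumerate(spectra.sample_ids)}
    for key, sub in meta.groupby(grouping, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rows = [idx[s] for s in sub["sample_id"]]
        conc = sub["ni_conc"].to_numpy(dtype=float)
        if len(rows) < 3:
            logger.warning(
                "group %s skipped: only %d sample(s), need >= 3", key, len(rows)
            )
            continue
        if np.ptp(conc) == 0:
            logger.warning("group %s skipped: constant Ni concentration", key)
            continue
        subset = SpectraSet(
            sample_ids=[spectra.sample_ids[i] for i in rows],
            values=spectra.values[rows],
            grid=spectra.grid,
        )
        maps[key] = correlation_map(
            subset, conc, alpha_level=alpha_level, fdr=fdr, method=method
        )
    return maps


def critical_r(n: int, alpha_level: float = 0.05) -> float:
    """|r| at the two-sided significance boundary for sample size ``n``."""
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    t_crit = stats.t.ppf(1.0 - alpha_level / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))
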