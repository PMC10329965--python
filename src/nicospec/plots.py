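"""Publication-style figures: correlation-map heatmaps and summary spectra."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .corrmap import CorrelationMap, Hotspot, find_hotspot
from .preprocess import SummarySpectra


def plot_correlation_map(
    cmap: CorrelationMap,
    path: str | Path,
    annotate_hotspot: bool = True,
    title: str | None = None,
) -> Path:
    """Heatmap of a correlation map: subtractor alpha on x, beta on y.

    Diverging colour scale symmetric about 0; masked cells neutral grey.
    The hotspot cell is marked unless the map is fully masked.
    """
    wl = cmap.grid.wavelengths
    shown = np.ma.masked_where(cmap.mask, cmap.r)
    fig, ax = plt.subplots(figsize=(6.4, 5.4))
    palette = plt.get_cmap("RdBu_r").copy()
    palette.set_bad("0.7")
    im = ax.imshow(
        shown.T,  # rows are alpha -> transpose puts beta on y
        origin="lower",
        extent=(wl[0], wl[-1], wl[0], wl[-1]),
        vmin=-1.0,
        vmax=1.0,
        cmap=palette,
        aspect="auto",
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="Pearson r with Ni concentration")
    hotspot: Hotspot | None = None
    if annotate_hotspot and not cmap.mask.all():
        hotspot = find_hotspot(cmap)
        ax.plot(
            hotspot.alpha_nm, hotspot.beta_nm, marker="o", mfc="none",
            mec="black", ms=10, mew=1.5,
        )
        ax.annotate(
            f"r={hotspot.r_value:+.2f}\n(α={hotspot.alpha_nm:.0f}, β={hotspot.beta_nm:.0f})",
            (hotspot.alpha_nm, hotspot.beta_nm),
            textcoords="offset points", xytext=(8, 8), fontsize=8,
        )
    ax.set_xlabel("subtractor channel α (nm)")
    ax.set_ylabel("subtracted channel β (nm)")
    ax.set_title(title or f"Band-difference correlation map (n={cmap.n})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_summary_spectra(
    summary: SummarySpectra, path: str | Path, title: str | None = None
) -> Path:
    """Min (red), mean (black), max (green) reflectance versus wavelength."""
    wl = summary.grid.wavelengths
    fig, ax = plt.subplots(figsize=(7.0, 4.0))
    ax.plot(wl, summary.minimum, color="red", lw=1.0, label="minimum")
    ax.plot(wl, summary.mean, color="black", lw=1.2, label="mean")
    ax.plot(wl, summary.maximum, color="green", lw=1.0, label="maximum")
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    ax.set_title(title or f"Summary spectra (n={summary.n_samples})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_importance(
    importance: np.ndarray, grid, path: str | Path, region: tuple[float, float] | None = None
) -> Path:
    """Per-band feature importance profile, optionally shading the dominant region."""
    fig, ax = plt.subplots(figsize=(7.0, 3.5))
    ax.plot(grid.wavelengths, importance, color="tab:blue", lw=0.8)
    if region is not None:
        ax.axvspan(region[0], region[1], color="orange", alpha=0.2,
                   label=f"dominant region {region[0]:.0f}-{region[1]:.0f} nm")
        ax.legend(frameon=False)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("feature importance")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
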