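"""Min/mean/max summary spectra of each cohort (run 01_simulate_cohorts first).

Reproduces the standard envelope view of a spectral library: per-channel
minimum (red), mean (black) and maximum (green) reflectance. The hydrated
cohort shows the four water absorptions near 975/1200/1400/1900 nm and a
widening envelope around 1000 nm driven by the Ni band; the dehydrated
cohort is brighter overall with faint water residues.
"""

from pathlib import Path

from nicospec import read_spectra_csv, summary_spectra
from nicospec.plots import plot_summary_spectra

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for tag, title in [
        ("cohortA_hydrated", "Hydrated hyperaccumulator cohort"),
        ("cohortB_dehydrated", "Dehydrated mixed cohort"),
    ]:
        spectra = read_spectra_csv(RESULTS / f"{tag}_spectra.csv")
        summ = summary_spectra(spectra)
        out = RESULTS / f"{tag}_summary.png"
        plot_summary_spectra(summ, out, title=f"{title} (n={summ.n_samples})")
        i1000 = spectra.grid.nearest_channel(1000)
        print(
            f"{tag}: n={summ.n_samples}; reflectance at 1000 nm spans "
            f"{summ.minimum[i1000]:.3f}-{summ.maximum[i1000]:.3f} "
            f"(mean {summ.mean[i1000]:.3f}) -> {out.name}"
        )


if __name__ == "__main__":
    main()
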