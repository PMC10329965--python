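"""Generate the two synthetic leaf-spectrum cohorts used by the analysis.

Cohort A emulates the correlation-mapping arm: 60 hydrated
hyperaccumulator leaves (log-normal Ni, median 10,000 ug/g, floored at the
1000 ug/g threshold) on the canonical 350-2500 nm grid. Cohort B emulates
the classification arm: 100 dehydrated hyperaccumulator plus 100
dehydrated normal leaves (Ni < 100 ug/g, distinct species pool). Both are
written as wide spectra CSV + metadata CSV under results/.
"""

from pathlib import Path

from nicospec import generate_dataset, write_meta_csv, write_spectra_csv

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    hydr, hydr_meta = generate_dataset(60, 0, state="hydrated", seed=SEED)
    write_spectra_csv(hydr, OUT / "cohortA_hydrated_spectra.csv")
    write_meta_csv(hydr_meta, OUT / "cohortA_hydrated_meta.csv")
    print(
        f"cohort A: {hydr.n_samples} hydrated hyperaccumulator spectra, "
        f"Ni {hydr_meta.ni_conc.min():.0f}-{hydr_meta.ni_conc.max():.0f} ug/g "
        f"(median {hydr_meta.ni_conc.median():.0f})"
    )

    dehy, dehy_meta = generate_dataset(100, 100, state="dehydrated", seed=SEED + 1)
    write_spectra_csv(dehy, OUT / "cohortB_dehydrated_spectra.csv")
    write_meta_csv(dehy_meta, OUT / "cohortB_dehydrated_meta.csv")
    counts = dehy_meta.group.value_counts().to_dict()
    print(f"cohort B: {dehy.n_samples} dehydrated spectra, groups {counts}")


if __name__ == "__main__":
    main()
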