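"""Generate the synthetic study cohort.

Writes the full input bundle — pangenome marker coverage for 105 infant
metagenomes, genus counts drawn from the planted 3-component
Dirichlet-multinomial mixture, a correlated 20-species table, milk peak
tables for 90 mothers, and infant metadata — plus the planted truth, under
results/cohort/. Every downstream driver reads these files.
"""

from pathlib import Path

from milkgut import simulate_all, write_matrix

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20230216


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    b = simulate_all(n_infants=105, n_milk=90, seed=SEED)
    write_matrix(b.gene_coverage, OUT / "gene_coverage.tsv")
    write_matrix(b.genus_counts, OUT / "genus_counts.tsv")
    write_matrix(b.species_counts, OUT / "species_counts.tsv")
    b.hmo_peaks.to_csv(OUT / "hmo_peaks.tsv", sep="\t", index=False)
    b.hmo_sample_info.to_csv(OUT / "hmo_sample_info.tsv", sep="\t", index=False)
    b.metadata.to_csv(OUT / "metadata.tsv", sep="\t", index=False)
    truth = b.truth.subspecies.merge(b.truth.gmc, on="sample_id").merge(
        b.truth.hm_group, on="sample_id", how="left"
    )
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"cohort of {len(b.genus_counts)} infants / {len(b.hmo_sample_info)} milk "
          f"samples written to {OUT}")
    print("planted subspecies class frequencies:")
    print(b.truth.subspecies.subspecies_class.value_counts(normalize=True)
          .round(3).to_string())
    print("planted HM group frequencies:")
    print(b.truth.hm_group.group.value_counts(normalize=True).round(3).to_string())


if __name__ == "__main__":
    main()
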