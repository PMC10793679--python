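"""Mucosal microbiota: do the pouch and the ileum harbour different
communities, and how do mucosal samples relate to the luminal ones?

Runs the paired (by subject and week) pouch-vs-ileum signed-rank
contrast per genus with BH correction, and a PERMANOVA of mucosal vs
luminal site on all patient samples.  Outputs under results/mucosa/.
"""

from pathlib import Path

from pouchtrack import (
    read_count_table, read_metadata, apply_default_filters, site_contrast,
    distance_matrix, permanova, betadisper,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "mucosa"


def main() -> None:
    table = read_count_table(COHORT / "counts.tsv")
    meta = read_metadata(COHORT / "metadata.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    filtered, _ = apply_default_filters(table)
    meta_f = meta.loc[filtered.samples]

    tests = site_contrast(filtered, meta_f, "genus")
    with open(OUT / "pouch_vs_ileum_genus_tests.tsv", "w", newline="\n") as fh:
        tests.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    n_sig = int((tests["q_value"] < 0.05).sum())
    print(f"pouch vs ileum (paired signed-rank, {int(tests['n_pairs'].iloc[0])} pairs): "
          f"{n_sig}/{len(tests)} genera with q < 0.05")

    patient = meta_f[meta_f["arm"] != "donor"].copy()
    patient["compartment"] = ["luminal" if s == "fecal" else "mucosal" for s in patient["site"]]
    sub = filtered.subset_samples(list(patient.index))
    dm = distance_matrix(sub, "genus")
    perm = permanova(dm, patient["compartment"], n_perm=999, seed=1)
    disp = betadisper(dm, patient["compartment"], n_perm=999, seed=1)
    print(f"luminal vs mucosal PERMANOVA: R2 = {100 * perm.r_squared:.1f}% "
          f"(p = {perm.p_value:.3f}; dispersion p = {disp.p_value:.3f}, "
          f"n = {len(patient)})")
    print(f"wrote tables under {OUT}")


if __name__ == "__main__":
    main()
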