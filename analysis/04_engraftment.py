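"""Donor-OTU engraftment: what share of the OTUs that could have been
transferred from the donor actually appears in the patients after FMT?

Builds each patient's transferable-OTU set (present in the donor, absent
at the patient's baseline), counts donor-derived OTUs at every retained
follow-up week, and summarises the percentage per arm and week.  Also
probes sensitivity to the donor presence rule (any vs all of the six
donor samples) and to the per-sample presence threshold.  Outputs under
results/engraftment/.
"""

from pathlib import Path

from pouchtrack import (
    read_count_table, read_metadata, apply_default_filters,
    engraftment_trajectories,
)
from pouchtrack.engraftment import records_to_frame, group_summary

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "engraftment"


def main() -> None:
    table = read_count_table(COHORT / "counts.tsv")
    meta = read_metadata(COHORT / "metadata.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    filtered, _ = apply_default_filters(table)
    meta_f = meta.loc[filtered.samples]
    donors = [s for s in meta_f.index[meta_f["arm"] == "donor"]]

    records = engraftment_trajectories(filtered, meta_f, donors)
    df = records_to_frame(records)
    with open(OUT / "engraftment_records.tsv", "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    summary = group_summary(records)
    with open(OUT / "engraftment_summary.tsv", "w", newline="\n") as fh:
        summary.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    print("donor-derived OTU percentage (mean +/- sd of the transferable set):")
    for _, r in summary.iterrows():
        print(f"  {r['arm']:>8} wk{int(r['week']):>2}: {r['mean']:5.1f}% "
              f"(sd {r['std']:.1f}, n={int(r['count'])})")

    print("sensitivity:")
    for rule in ("any", "all"):
        for min_count in (1, 5):
            recs = engraftment_trajectories(filtered, meta_f, donors,
                                            donor_presence_rule=rule, min_count=min_count)
            d = records_to_frame(recs)
            wk4 = d[(d["arm"] == "FMT") & (d["week"] == 4)]
            print(f"  donor rule {rule:>3}, min_count {min_count}: week-4 FMT mean "
                  f"{wk4['fraction'].mean():5.1f}% "
                  f"(denominator median {int(wk4['n_transferable'].median())} OTUs)")
    print(f"wrote tables under {OUT}")


if __name__ == "__main__":
    main()
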