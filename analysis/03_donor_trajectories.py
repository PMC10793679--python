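"""Dissimilarity-to-donor trajectories: does the FMT arm move toward the
donor's microbiota after treatment, and does the placebo arm stay put?

Computes each patient sample's average genus-level Bray-Curtis
dissimilarity to the six donor samples (post-relapse samples excluded),
summarises arm x week means, tests the week-4 FMT vs placebo contrast
with the rank-sum test, and writes the 2-axis PCoA of all retained
samples.  Outputs under results/trajectories/.
"""

from pathlib import Path

import pandas as pd

from pouchtrack import (
    read_count_table, read_metadata, apply_default_filters,
    donor_dissimilarity_trajectory, distance_matrix, pcoa, rank_sum_test,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "trajectories"


def main() -> None:
    table = read_count_table(COHORT / "counts.tsv")
    meta = read_metadata(COHORT / "metadata.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    filtered, _ = apply_default_filters(table)
    meta_f = meta.loc[filtered.samples]
    donors = [s for s in meta_f.index[meta_f["arm"] == "donor"]]

    traj, arm_means = donor_dissimilarity_trajectory(filtered, meta_f, donors)
    with open(OUT / "trajectory.tsv", "w", newline="\n") as fh:
        traj.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    with open(OUT / "arm_week_means.tsv", "w", newline="\n") as fh:
        arm_means.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    print("arm x week mean dissimilarity to donor:")
    for _, r in arm_means.iterrows():
        print(f"  {r['arm']:>8} wk{int(r['week']):>2}: {r['mean']:.3f} "
              f"(sd {r['std']:.3f}, n={int(r['count'])})")

    wk4 = traj[traj["week"] == 4]
    fmt = wk4.loc[wk4["arm"] == "FMT", "dissimilarity"].to_numpy()
    plc = wk4.loc[wk4["arm"] == "placebo", "dissimilarity"].to_numpy()
    res = rank_sum_test(fmt, plc)
    print(f"week-4 contrast: FMT mean {fmt.mean():.3f} vs placebo {plc.mean():.3f} "
          f"(rank-sum p = {res.p_value:.2g})")

    dm = distance_matrix(filtered, "genus")
    ordn = pcoa(dm, 2)
    coords = pd.DataFrame(ordn.coordinates, index=ordn.sample_ids, columns=["PC1", "PC2"])
    coords["prop_explained_1"] = ordn.prop_explained[0]
    with open(OUT / "pcoa_coordinates.tsv", "w", newline="\n") as fh:
        coords.to_csv(fh, sep="\t", lineterminator="\n")
    print(f"PCoA axis 1 explains {100 * ordn.prop_explained[0]:.1f}% "
          f"of the positive-eigenvalue variance")
    print(f"wrote tables under {OUT}")


if __name__ == "__main__":
    main()
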