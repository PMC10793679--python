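"""Generate the study-shaped synthetic cohort used by the downstream
analysis scripts.

One donor sampled six times, 26 patients (13 FMT / 13 placebo), fecal
samples at 0/4/12/26/52 weeks, pouch and ileum biopsies at weeks 0 and
52, and a study-like relapse schedule (~70% of patients relapse during
follow-up).  Writes counts.tsv, metadata.tsv and truth.json under
results/cohort/.
"""

import sys
from pathlib import Path

from pouchtrack import SimConfig, generate_cohort, write_cohort
from pouchtrack.simulate import study_relapse_schedule

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    cfg.relapse_schedule = study_relapse_schedule(cfg)
    table, meta, truth = generate_cohort(cfg)
    paths = write_cohort(table, meta, truth, OUT)
    n_relapse = sum(v is not None for v in truth.relapse_week.values())
    print(f"cohort: {table.shape[0]} taxa x {table.shape[1]} samples (seed {SEED})")
    print(f"arms: {sum(meta['arm'] == 'donor')} donor samples, "
          f"{meta.loc[meta['arm'] == 'FMT', 'subject_id'].nunique()} FMT, "
          f"{meta.loc[meta['arm'] == 'placebo', 'subject_id'].nunique()} placebo patients")
    print(f"relapses scheduled: {n_relapse}/{cfg.n_patients}")
    depths = list(truth.depths.values())
    below = sum(d < 10_000 for d in depths)
    print(f"read depth: mean {sum(depths) / len(depths):.0f}, "
          f"{below}/{len(depths)} samples under the 10,000-read filter")
    for k, p in paths.items():
        print(f"wrote {k}: {p}")


if __name__ == "__main__":
    main()
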