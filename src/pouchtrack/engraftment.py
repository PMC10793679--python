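"""Donor-engraftment quantification by OTU presence/absence set logic.

The denominator of engraftment is the set of "transferable" OTUs: those
present in the donor's samples but absent from the patient's pre-FMT
(baseline) sample.  At each follow-up timepoint, transferable OTUs that
are detected in the patient are "donor-derived"; the engraftment fraction
is the donor-derived percentage of the transferable set.  Samples taken
after a patient's relapse are excluded (the week-of-relapse sample is
retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .tables_io import CountTable, CountTableError

log = logging.getLogger(__name__)


@dataclass
class OTUSet:
    taxon_ids: frozenset
    provenance: str  # donor_only | donor_derived | shared_baseline
    reference_samples: tuple

    def __len__(self) -> int:
        return len(self.taxon_ids)


@dataclass
class EngraftmentRecord:
    subject_id: str
    arm: str
    week: int
    n_transferable: int
    n_detected: int
    fraction: float | None  # percentage; None when n_transferable == 0


def presence_set(table: CountTable, sample: str, min_count: int = 1) -> frozenset:
    """Taxa with count >= min_count in ``sample``."""
    if sample not in table.counts.columns:
        raise CountTableError(f"unknown sample {sample!r}")
    col = table.counts[sample]
    return frozenset(col.index[col >= min_count])


def transferable_otus(
    table: CountTable,
    donor_samples: list,
    baseline_sample: str,
    donor_presence_rule: str = "any",
    min_count: int = 1,
) -> OTUSet:
    """OTUs present in the donor (union or intersection over donor
    samples) but absent at the patient's baseline."""
    if not donor_samples:
        raise ValueError("donor_samples must be non-empty")
    if baseline_sample in donor_samples:
        raise ValueError(f"baseline sample {baseline_sample!r} listed among donor samples")
    sets = [presence_set(table, d, min_count) for d in donor_samples]
    if donor_presence_rule == "any":
        donor_present = frozenset().union(*sets)
    elif donor_presence_rule == "all":
        donor_present = frozenset.intersection(*sets)
    else:
        raise ValueError(f"unknown donor_presence_rule {donor_presence_rule!r}")
    baseline = presence_set(table, baseline_sample, min_count)
    return OTUSet(donor_present - baseline, "donor_only", tuple(donor_samples))


def donor_derived_otus(transferable: OTUSet, followup_presence: frozenset) -> OTUSet:
    """Transferable OTUs detected at a follow-up timepoint."""
    if transferable.provenance != "donor_only":
        raise ValueError("transferable set must have provenance 'donor_only'")
    return OTUSet(transferable.taxon_ids & frozenset(followup_presence),
                  "donor_derived", transferable.reference_samples)


def engraftment_fraction(transferable: OTUSet, detected: OTUSet) -> float | None:
    """Donor-derived percentage of the transferable set (None if empty)."""
    if not detected.taxon_ids <= transferable.taxon_ids:
        raise ValueError("detected set is not a subset of the transferable set")
    if len(transferable) == 0:
        log.warning("engraftment fraction undefined: no transferable OTUs")
        return None
    return 100.0 * len(detected) / len(transferable)


def engraftment_trajectories(
    table: CountTable,
    meta: pd.DataFrame,
    donor_samples: list,
    exclude_post_relapse: bool = True,
    donor_presence_rule: str = "any",
    min_count: int = 1,
    site: str = "fecal",
) -> list[EngraftmentRecord]:
    """One engraftment record per patient x retained follow-up week.

    Patients without a surviving week-0 sample of the given site are
    skipped with a logged reason.  Post-relapse weeks are omitted when
    ``exclude_post_relapse`` is set (week of relapse retained).
    """
    records: list[EngraftmentRecord] = []
    patients = meta[(meta["arm"] != "donor") & (meta["site"] == site)]
    in_table = set(table.counts.columns)
    for subject, sub in patients.groupby("subject_id", sort=True):
        sub = sub.sort_values("week")
        base_rows = sub[(sub["week"] == 0) & (sub["sample_id"].isin(in_table))]
        if base_rows.empty:
            log.info("engraftment: skipping %s (no surviving week-0 %s sample)", subject, site)
            continue
        baseline_sample = base_rows["sample_id"].iloc[0]
        transferable = transferable_otus(
            table, donor_samples, baseline_sample, donor_presence_rule, min_count
        )
        for _, m in sub[sub["week"] > 0].iterrows():
            sid = m["sample_id"]
            if sid not in in_table:
                continue
            relapse = m["relapse_week"]
            if exclude_post_relapse and pd.notna(relapse) and m["week"] > int(relapse):
                continue
            detected = donor_derived_otus(transferable, presence_set(table, sid, min_count))
            records.append(
                EngraftmentRecord(
                    subject_id=subject,
                    arm=m["arm"],
                    week=int(m["week"]),
                    n_transferable=len(transferable),
                    n_detected=len(detected),
                    fraction=engraftment_fraction(transferable, detected),
                )
            )
    return records


def records_to_frame(records: list[EngraftmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame(
            columns=["subject_id", "arm", "week", "n_transferable", "n_detected", "fraction"]
        )
    return df


def group_summary(records: list[EngraftmentRecord]) -> pd.DataFrame:
    """Arm x week mean and SD of the engraftment percentage.

    Undefined fractions (no transferable OTUs) are excluded from the
    means, not counted as zero.
    """
    df = records_to_frame(records)
    df = df[df["fraction"].notna()]
    if df.empty:
        return df
    return (
        df.groupby(["arm", "week"])["fraction"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
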