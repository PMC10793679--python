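"""Study-shaped orchestration: filters -> diversity -> ordination and
per-factor PERMANOVA -> donor-dissimilarity trajectories -> engraftment
-> per-taxon contrasts, with a machine-readable report.

Every stage is a thin call into the library modules; the report's
summary numbers are all reproducible from the stage outputs it indexes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .tables_io import (
    CountTable, CountTableError, apply_default_filters, read_count_table,
    read_metadata, aggregate_taxa, to_relative,
)
from .diversity import diversity_by_group, mean_relative_abundance
from .beta import distance_matrix, pcoa, permanova, betadisper, donor_dissimilarity_trajectory
from .engraftment import engraftment_trajectories, records_to_frame, group_summary
from .inference import rank_sum_test, signed_rank_test, taxon_group_test, bh_fdr

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts: str | None = None
    metadata: str | None = None
    donor_samples: list = field(default_factory=list)  # empty = take arm=donor rows
    rank: str = "genus"
    factors: list = field(default_factory=lambda: ["antibiotic_type", "antibiotic_pattern", "arm"])
    min_reads: int = 10_000
    rare_frac: float = 1e-5
    rare_filter_scope: str = "dataset"
    min_count: int = 1
    min_prevalence: float = 0.1
    n_permutations: int = 999
    seed: int = 0
    donor_rule: str = "any"
    donor_reference: str = "pairwise_mean"
    exclude_post_relapse: bool = True
    outdir: str = "pouchtrack_run"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def config_from_toml(path) -> RunConfig:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown RunConfig fields in {path}: {sorted(unknown)}")
    return RunConfig(**data)


@dataclass
class RunReport:
    provenance: dict
    outputs: dict
    summary: dict

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "outputs": self.outputs, "summary": self.summary},
            indent=1, sort_keys=True, default=_jsonable,
        ) + "\n"


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def baseline_vs_donor_contrast(
    table: CountTable,
    meta: pd.DataFrame,
    rank: str = "genus",
    min_prevalence: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Patients' baseline vs donor: per-genus rank-sum tests + diversity.

    Returns the taxon test table and a diversity comparison (inverse
    Simpson, donor vs patient baseline, rank-sum p).
    """
    donor_ids = [s for s in meta.index[meta["arm"] == "donor"] if s in table.counts.columns]
    base_ids = [
        s for s in meta.index[(meta["arm"] != "donor") & (meta["site"] == "fecal") & (meta["week"] == 0)]
        if s in table.counts.columns
    ]
    if len(donor_ids) < 2:
        raise CountTableError("need at least 2 donor samples")
    if not base_ids:
        raise CountTableError("no patient baseline samples present")
    sub = table.subset_samples(donor_ids + base_ids)
    cmeta = meta.loc[donor_ids + base_ids].copy()
    cmeta["baseline_group"] = ["donor"] * len(donor_ids) + ["patient"] * len(base_ids)
    tests = taxon_group_test(sub, cmeta, rank, "baseline_group", min_prevalence)

    div = diversity_by_group(sub, cmeta)
    donor_div = div.loc[donor_ids, "value"].to_numpy()
    patient_div = div.loc[base_ids, "value"].to_numpy()
    res = rank_sum_test(donor_div, patient_div)
    diversity_cmp = {
        "donor_mean": float(donor_div.mean()),
        "patient_mean": float(patient_div.mean()),
        "p_value": res.p_value,
        "n_donor": len(donor_ids),
        "n_patients": len(base_ids),
    }
    return tests, diversity_cmp


def site_contrast(
    table: CountTable,
    meta: pd.DataFrame,
    rank: str = "genus",
    sites: tuple = ("pouch", "ileum"),
    min_prevalence: float = 0.1,
) -> pd.DataFrame:
    """Pouch vs ileum mucosal composition, paired by subject x week.

    Per taxon: Wilcoxon signed-rank on paired fraction differences
    (first site minus second), BH-corrected.  Subject-weeks lacking one
    of the two sites are dropped with a log line.
    """
    muc = meta[meta["site"].isin(sites) & (meta["arm"] != "donor")]
    muc = muc[muc["sample_id"].isin(table.counts.columns)]
    pairs = []
    for (subject, week), grp in muc.groupby(["subject_id", "week"]):
        by_site = {m["site"]: m["sample_id"] for _, m in grp.iterrows()}
        if all(s in by_site for s in sites):
            pairs.append((by_site[sites[0]], by_site[sites[1]]))
        else:
            log.info("site_contrast: dropping unpaired %s week %s", subject, week)
    if len(pairs) < 2:
        raise CountTableError("need at least 2 paired subject-weeks for the site contrast")
    ids = [s for pair in pairs for s in pair]
    sub = table.subset_samples(ids)
    agg = aggregate_taxa(sub, rank) if rank is not None else sub
    rel = to_relative(agg)
    prevalence = (agg.counts > 0).sum(axis=1) / len(ids)
    tested = [t for t in agg.taxa if prevalence[t] >= min_prevalence]
    if not tested:
        raise CountTableError("no taxa pass the prevalence filter")
    rows = []
    for t in tested:
        diffs = np.array([rel.loc[t, a] - rel.loc[t, b] for a, b in pairs])
        if np.all(diffs == 0):
            rows.append({"taxon": t, "n_pairs": len(pairs), "statistic": 0.0, "p_value": 1.0})
            continue
        res = signed_rank_test(diffs)
        rows.append({"taxon": t, "n_pairs": len(pairs), "statistic": res.statistic, "p_value": res.p_value})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values("q_value", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline_data(
    table: CountTable, meta: pd.DataFrame, config: RunConfig
) -> tuple[RunReport, dict]:
    """Run every stage on in-memory inputs.

    Returns the report plus a dict of in-memory stage outputs (tables,
    distance matrix, trajectories, engraftment records).
    """
    for col in config.factors:
        if col not in meta.columns:
            raise CountTableError(f"factor column {col!r} missing from metadata")
    unknown_meta = [s for s in table.samples if s not in meta.index]
    if unknown_meta:
        raise CountTableError(f"samples without metadata: {unknown_meta}")

    donor_samples = list(config.donor_samples) or [
        s for s in meta.index[meta["arm"] == "donor"] if s in table.counts.columns
    ]
    if not donor_samples:
        raise CountTableError("no donor samples found")

    filtered, attrition = apply_default_filters(
        table, config.min_reads, config.rare_frac, config.rare_filter_scope
    )
    donor_samples = [s for s in donor_samples if s in filtered.counts.columns]
    if not donor_samples:
        raise CountTableError("all donor samples removed by filters")
    meta_f = meta.loc[[s for s in filtered.samples]]

    div = diversity_by_group(filtered, meta_f)

    # per-factor PERMANOVA + dispersion on baseline fecal patient samples
    baseline_ids = [
        s for s in meta_f.index[
            (meta_f["arm"] != "donor") & (meta_f["site"] == "fecal") & (meta_f["week"] == 0)
        ]
    ]
    factor_results = {}
    if len(baseline_ids) >= 4:
        dm_base = distance_matrix(filtered.subset_samples(baseline_ids), config.rank)
        for factor in config.factors:
            labels = meta_f.loc[baseline_ids, factor]
            ok = labels.notna() & (labels.astype(str) != "")
            ids = [s for s, k in zip(baseline_ids, ok) if k]
            lab = labels[ok]
            counts = lab.value_counts()
            if len(counts) < 2 or (counts < 2).any():
                log.info("skipping factor %r: not enough groups", factor)
                factor_results[factor] = {"skipped": "not enough groups"}
                continue
            dm_f = dm_base.subset(ids)
            perm = permanova(dm_f, lab, config.n_permutations, config.seed)
            disp = betadisper(dm_f, lab, config.n_permutations, config.seed)
            factor_results[factor] = {
                "r_squared": perm.r_squared,
                "pseudo_f": perm.pseudo_f,
                "p_value": perm.p_value,
                "dispersion_p_value": disp.p_value,
                "n_samples": len(ids),
            }

    traj, arm_means = donor_dissimilarity_trajectory(
        filtered, meta_f, donor_samples, config.exclude_post_relapse,
        config.rank, config.donor_reference,
    )
    week4 = traj[traj["week"] == 4] if not traj.empty else traj
    week4_contrast = None
    if not week4.empty:
        fmt = week4.loc[week4["arm"] == "FMT", "dissimilarity"].to_numpy()
        plc = week4.loc[week4["arm"] == "placebo", "dissimilarity"].to_numpy()
        if fmt.size >= 2 and plc.size >= 2:
            res = rank_sum_test(fmt, plc)
            week4_contrast = {
                "fmt_mean": float(fmt.mean()), "placebo_mean": float(plc.mean()),
                "p_value": res.p_value, "n_fmt": int(fmt.size), "n_placebo": int(plc.size),
            }

    records = engraftment_trajectories(
        filtered, meta_f, donor_samples, config.exclude_post_relapse,
        config.donor_rule, config.min_count,
    )
    engraft_df = records_to_frame(records)
    engraft_summary = group_summary(records)

    taxon_tests, diversity_cmp = baseline_vs_donor_contrast(
        filtered, meta_f, config.rank, config.min_prevalence
    )

    ord_full = None
    dm_all = distance_matrix(filtered, config.rank)
    ord_full = pcoa(dm_all, n_axes=2)

    summary = {
        "attrition": attrition,
        "n_donor_samples": len(donor_samples),
        "diversity": diversity_cmp,
        "permanova_by_factor": factor_results,
        "donor_dissimilarity_arm_means": (
            arm_means.to_dict(orient="records") if not isinstance(arm_means, list) and not arm_means.empty else []
        ),
        "week4_arm_contrast": week4_contrast,
        "engraftment_summary": (
            engraft_summary.to_dict(orient="records")
            if hasattr(engraft_summary, "empty") and not engraft_summary.empty else []
        ),
        "n_significant_taxa_baseline_vs_donor": int(taxon_tests["significant"].sum()),
    }
    report = RunReport(
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "pouchtrack_version": __version__},
        outputs={},
        summary=summary,
    )
    data = {
        "filtered": filtered, "meta": meta_f, "diversity": div,
        "trajectory": traj, "arm_means": arm_means,
        "engraftment": engraft_df, "engraftment_summary": engraft_summary,
        "taxon_tests": taxon_tests, "ordination": ord_full, "distance_matrix": dm_all,
    }
    return report, data


def run_pipeline(config: RunConfig) -> RunReport:
    """File-based entry point: read inputs, run stages, write outputs."""
    if not config.counts or not config.metadata:
        raise CountTableError("RunConfig.counts and RunConfig.metadata are required")
    table = read_count_table(config.counts)
    meta = read_metadata(config.metadata)
    report, data = run_pipeline_data(table, meta, config)

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.tsv"
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        paths[name] = str(p)

    save("diversity", data["diversity"].reset_index(drop=True))
    save("donor_dissimilarity", data["trajectory"])
    save("engraftment", data["engraftment"])
    save("taxon_tests_baseline_vs_donor", data["taxon_tests"])
    dm = data["distance_matrix"]
    dm_df = pd.DataFrame(dm.data, index=dm.sample_ids, columns=dm.sample_ids)
    p = out / "distance_matrix.tsv"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        dm_df.to_csv(fh, sep="\t", lineterminator="\n")
    paths["distance_matrix"] = str(p)
    ordn = data["ordination"]
    coords = pd.DataFrame(
        ordn.coordinates, index=ordn.sample_ids,
        columns=[f"PC{i + 1}" for i in range(ordn.coordinates.shape[1])],
    )
    p = out / "pcoa_coordinates.tsv"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        coords.to_csv(fh, sep="\t", lineterminator="\n")
    paths["pcoa_coordinates"] = str(p)

    report.outputs = paths
    with open(out / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(report.to_json())
    return report
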