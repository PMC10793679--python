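"""Alpha diversity (inverse Simpson) and relative-abundance summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables_io import CountTable, CountTableError, aggregate_taxa, to_relative


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum(p_i^2).

    The effective number of equally abundant taxa: 1 for a single-taxon
    sample, k for a uniform community of k taxa.  Scale-invariant.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    p = c / total
    return float(1.0 / np.sum(p**2))


def diversity_by_group(table: CountTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample inverse Simpson with grouping columns attached.

    Returns one row per sample with ``value`` plus the arm, week, site and
    relapse-status columns used for downstream group comparisons.
    """
    rows = []
    for s in table.samples:
        if s not in meta.index:
            raise CountTableError(f"sample {s!r} has no metadata row")
        m = meta.loc[s]
        rows.append(
            {
                "sample_id": s,
                "metric": "inverse_simpson",
                "value": inverse_simpson(table.counts[s].to_numpy()),
                "arm": m["arm"],
                "week": int(m["week"]),
                "site": m["site"],
                "relapsed": bool(pd.notna(m["relapse_week"])),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def mean_relative_abundance(
    table: CountTable, meta: pd.DataFrame, rank: str, grouping: list[str]
) -> pd.DataFrame:
    """Group-wise mean and sample SD of per-sample fractions at ``rank``.

    One row per group x taxon; within each group the means sum to 1.
    """
    agg = aggregate_taxa(table, rank)
    rel = to_relative(agg)
    missing = [s for s in agg.samples if s not in meta.index]
    if missing:
        raise CountTableError(f"samples missing metadata: {missing}")
    key = meta.loc[agg.samples, grouping].astype(str).agg("|".join, axis=1)
    rows = []
    for group, samples in key.groupby(key).groups.items():
        sub = rel[list(samples)]
        if sub.shape[1] == 0:
            raise CountTableError(f"empty group {group!r}")
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1) if sub.shape[1] > 1 else pd.Series(0.0, index=sub.index)
        for taxon in agg.taxa:
            rows.append(
                {"group": group, "taxon": taxon, "n_samples": sub.shape[1],
                 "mean_fraction": float(mean[taxon]), "sd_fraction": float(sd[taxon])}
            )
    return pd.DataFrame(rows)
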