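"""Count-table and sample-metadata I/O, validation, filtering and aggregation.

The universal currency of the pipeline is a taxon-by-sample table of
non-negative integer read counts, carried around as a :class:`CountTable`.
Taxa are identified by an opaque id (typically an OTU id) plus a lineage
string of the form ``p__Firmicutes;f__Lachnospiraceae;g__Blautia`` giving
phylum / family / genus labels.  Sample annotations (subject, study arm,
week, body site, relapse week, antibiotic use) live in a plain pandas
DataFrame validated by :func:`read_metadata`.

Two data-inclusion filters define which samples and taxa enter any
analysis: samples with under 10,000 reads are excluded, and taxa under
0.001% dataset-wide relative abundance are discarded.  Both thresholds are
strict ("under"): the boundary case is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RANKS = ("phylum", "family", "genus")
_RANK_PREFIX = {"p": "phylum", "f": "family", "g": "genus"}

ARMS = ("FMT", "placebo", "donor")
SITES = ("fecal", "pouch", "ileum")
ANTIBIOTIC_TYPES = ("ciprofloxacin", "metronidazole", "other", "none")
ANTIBIOTIC_PATTERNS = ("continuous", "repeated", "none")

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "arm",
    "week",
    "site",
    "relapse_week",
    "antibiotic_type",
    "antibiotic_pattern",
)


class CountTableError(ValueError):
    """Raised on malformed count tables or metadata."""


def parse_lineage(s: str) -> dict[str, str]:
    """Parse ``p__X;f__Y;g__Z`` into a rank->name map.

    Missing or malformed ranks come back as ``"unclassified"`` so every
    taxon always carries a full phylum/family/genus annotation.
    """
    out = {r: "unclassified" for r in RANKS}
    if not isinstance(s, str):
        return out
    for part in s.split(";"):
        part = part.strip()
        if "__" not in part:
            continue
        prefix, _, name = part.partition("__")
        rank = _RANK_PREFIX.get(prefix.strip().lower())
        if rank is not None and name.strip():
            out[rank] = name.strip()
    return out


def format_lineage(lineage: dict[str, str]) -> str:
    return ";".join(
        f"{r[0]}__{lineage.get(r, 'unclassified')}" for r in RANKS
    )


@dataclass
class CountTable:
    """Integer taxon-by-sample count matrix with lineages.

    Attributes
    ----------
    counts : pd.DataFrame
        Integer matrix, index = taxon ids (unique), columns = sample ids
        (unique), values >= 0.
    lineages : dict[str, dict[str, str]]
        Per taxon id, a rank -> name map covering phylum/family/genus
        (``"unclassified"`` where unknown).
    """

    counts: pd.DataFrame
    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate taxon ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample ids: {dups}")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            raise CountTableError("counts must be integers")
        if (c.to_numpy() < 0).any():
            r, s = np.argwhere(c.to_numpy() < 0)[0]
            raise CountTableError(
                f"negative count at taxon {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        for t in c.index:
            lin = self.lineages.setdefault(t, {})
            for rank in RANKS:
                lin.setdefault(rank, "unclassified")

    def subset_samples(self, samples: list[str]) -> "CountTable":
        return CountTable(self.counts[list(samples)].copy(), {t: dict(self.lineages[t]) for t in self.taxa})

    def subset_taxa(self, taxa: list[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(taxa)].copy(), {t: dict(self.lineages[t]) for t in taxa})


# ---------------------------------------------------------------------------
# readers / writers (TSV, UTF-8, LF; readers tolerate CRLF)
# ---------------------------------------------------------------------------

def read_count_table(path) -> CountTable:
    """Read a TSV count table: columns taxon_id, lineage, then samples."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or list(df.columns[:2]) != ["taxon_id", "lineage"]:
        raise CountTableError(
            f"{path}: first two columns must be 'taxon_id' and 'lineage', got {list(df.columns[:2])}"
        )
    # pandas silently renames duplicated headers; detect via raw header line
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    raw_samples = header[2:]
    if len(set(raw_samples)) != len(raw_samples):
        dups = sorted({s for s in raw_samples if raw_samples.count(s) > 1})
        raise CountTableError(f"{path}: duplicate sample id(s) in header: {dups}")

    taxa = df["taxon_id"].tolist()
    if len(set(taxa)) != len(taxa):
        dups = sorted({t for t in taxa if taxa.count(t) > 1})
        raise CountTableError(f"{path}: duplicate taxon id(s): {dups}")

    mat = np.zeros((len(taxa), len(raw_samples)), dtype=np.int64)
    for j, s in enumerate(df.columns[2:]):
        col = df[s]
        for i, v in enumerate(col):
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise CountTableError(
                    f"{path}: non-integer count {v!r} at taxon {taxa[i]!r}, sample {raw_samples[j]!r}"
                ) from None
            if iv < 0:
                raise CountTableError(
                    f"{path}: negative count {iv} at taxon {taxa[i]!r}, sample {raw_samples[j]!r}"
                )
            mat[i, j] = iv
    counts = pd.DataFrame(mat, index=pd.Index(taxa, name="taxon_id"), columns=raw_samples)
    lineages = {t: parse_lineage(lin) for t, lin in zip(taxa, df["lineage"])}
    return CountTable(counts, lineages)


def write_count_table(table: CountTable, path) -> None:
    """Write a CountTable as TSV; byte-stable for a given table."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["taxon_id", "lineage", *table.samples]) + "\n")
        arr = table.counts.to_numpy()
        for i, t in enumerate(table.taxa):
            row = "\t".join(str(int(v)) for v in arr[i])
            lin = format_lineage(table.lineages[t])
            fh.write(f"{t}\t{lin}" + ("\t" + row if table.samples else "") + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"metadata missing columns: {missing}")
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise CountTableError(f"duplicate metadata sample ids: {dups}")
    for col, allowed in (
        ("arm", ARMS),
        ("site", SITES),
        ("antibiotic_type", ANTIBIOTIC_TYPES),
        ("antibiotic_pattern", ANTIBIOTIC_PATTERNS),
    ):
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise CountTableError(f"metadata column {col!r} has invalid values {bad}")
    df["week"] = df["week"].astype(int)
    if (df["week"] < 0).any():
        raise CountTableError("metadata week must be >= 0")
    df["relapse_week"] = pd.array(
        [None if v in ("", "none", "NA") else int(v) for v in df["relapse_week"]],
        dtype="Int64",
    )
    donor_relapse = df[(df["arm"] == "donor") & df["relapse_week"].notna()]
    if len(donor_relapse):
        raise CountTableError("donor samples cannot carry a relapse week")
    return df.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index(drop=True).copy()
    out["relapse_week"] = [
        "none" if pd.isna(v) else str(int(v)) for v in out["relapse_week"]
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_min_reads(
    table: CountTable, min_reads: int = 10_000
) -> tuple[CountTable, list[str]]:
    """Drop samples whose total read count is strictly under ``min_reads``.

    Returns the filtered table and the list of dropped sample ids.
    """
    sums = table.counts.sum(axis=0)
    keep = [s for s in table.samples if sums[s] >= min_reads]
    dropped = [s for s in table.samples if sums[s] < min_reads]
    if dropped:
        log.info("filter_min_reads: dropped %d sample(s): %s", len(dropped), dropped)
    if not keep:
        log.warning("filter_min_reads: no samples retained")
    return table.subset_samples(keep), dropped


def filter_min_relative_abundance(
    table: CountTable,
    min_frac: float = 1e-5,
    scope: str = "dataset",
) -> CountTable:
    """Discard taxa under ``min_frac`` relative abundance (strict).

    ``scope="dataset"`` (default) evaluates each taxon's total count
    against the grand total; ``scope="sample"`` instead zeroes individual
    cells whose within-sample fraction is under the threshold and then
    drops taxa left with no reads.
    """
    grand = int(table.counts.to_numpy().sum())
    if grand == 0:
        raise CountTableError("cannot apply abundance filter: grand total is zero")
    if scope == "dataset":
        totals = table.counts.sum(axis=1)
        keep = [t for t in table.taxa if totals[t] / grand >= min_frac]
        return table.subset_taxa(keep)
    if scope == "sample":
        counts = table.counts.copy()
        colsums = counts.sum(axis=0)
        frac = counts / colsums.replace(0, 1)
        counts[frac < min_frac] = 0
        keep = [t for t in table.taxa if counts.loc[t].sum() > 0]
        return CountTable(counts.loc[keep], {t: dict(table.lineages[t]) for t in keep})
    raise CountTableError(f"unknown rare_filter_scope {scope!r}")


def apply_default_filters(
    table: CountTable,
    min_reads: int = 10_000,
    min_frac: float = 1e-5,
    rare_filter_scope: str = "dataset",
) -> tuple[CountTable, dict]:
    """Rarity filter first, then the read-count filter (the pipeline default).

    Returns the filtered table and an attrition record.
    """
    n_taxa0, n_samples0 = table.shape
    rare = filter_min_relative_abundance(table, min_frac, rare_filter_scope)
    filtered, dropped = filter_min_reads(rare, min_reads)
    attrition = {
        "taxa_in": n_taxa0,
        "taxa_out": filtered.shape[0],
        "taxa_dropped_rare": n_taxa0 - rare.shape[0],
        "samples_in": n_samples0,
        "samples_out": filtered.shape[1],
        "samples_dropped_low_reads": dropped,
    }
    return filtered, attrition


# ---------------------------------------------------------------------------
# aggregation / normalisation
# ---------------------------------------------------------------------------

def aggregate_taxa(table: CountTable, rank: str) -> CountTable:
    """Sum counts within identical labels at ``rank``.

    All taxa labelled ``unclassified`` at the rank collapse into a single
    bucket regardless of their parent lineage.  Column sums are conserved
    exactly (integer arithmetic).
    """
    if rank not in RANKS:
        raise CountTableError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = [table.lineages[t].get(rank, "unclassified") for t in table.taxa]
    grouped = table.counts.groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    lineages: dict[str, dict[str, str]] = {}
    rank_i = RANKS.index(rank)
    by_label: dict[str, list[str]] = {}
    for t, lab in zip(table.taxa, labels):
        by_label.setdefault(lab, []).append(t)
    for lab, members in by_label.items():
        lin = {r: "unclassified" for r in RANKS}
        lin[rank] = lab
        # keep higher ranks when unanimous among members
        for r in RANKS[:rank_i]:
            vals = {table.lineages[t][r] for t in members}
            if len(vals) == 1:
                lin[r] = vals.pop()
        lineages[lab] = lin
    return CountTable(grouped, lineages)


def to_relative(table: CountTable) -> pd.DataFrame:
    """Per-sample fractions; each column sums to 1 within 1e-12."""
    sums = table.counts.sum(axis=0)
    zero = [s for s in table.samples if sums[s] == 0]
    if zero:
        raise CountTableError(f"zero-sum sample(s): {zero}")
    return table.counts / sums
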