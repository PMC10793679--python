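import numpy as np
import pandas as pd
import pytest

from pouchtrack import CountTable, SimConfig, generate_cohort
from pouchtrack.tables_io import validate_metadata


def make_table(counts: dict, lineages: dict | None = None, taxa=None) -> CountTable:
    """Tiny CountTable from {sample: [counts...]}; taxa default t1..tn."""
    n = len(next(iter(counts.values())))
    taxa = taxa or [f"t{i + 1}" for i in range(n)]
    df = pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), dtype=np.int64)
    return CountTable(df, lineages or {})


def make_meta(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "subject_id": "s", "arm": "FMT", "week": 0, "site": "fecal",
        "relapse_week": "none", "antibiotic_type": "none", "antibiotic_pattern": "none",
    }
    df = pd.DataFrame([{**defaults, **r} for r in rows]).astype({"week": int})
    df["relapse_week"] = df["relapse_week"].astype(str)
    return validate_metadata(df.astype({c: str for c in df.columns if c != "week"}))


def random_table(rng: np.random.Generator, n_taxa=12, n_samples=6, depth=2000) -> CountTable:
    p = rng.dirichlet(np.ones(n_taxa))
    counts = {
        f"S{j + 1}": rng.multinomial(depth, rng.dirichlet(p * n_taxa * 2 + 0.1))
        for j in range(n_samples)
    }
    lineages = {
        f"t{i + 1}": {
            "phylum": f"P{i % 3}", "family": f"F{i % 4}", "genus": f"G{i % 5}",
        }
        for i in range(n_taxa)
    }
    return make_table(counts, lineages)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-model cohort shared by read-only tests."""
    config = SimConfig(n_taxa=80, n_patients=8, private_pool_size=40,
                       n_private_taxa=20, depth_mean=20000, seed=7)
    table, meta, truth = generate_cohort(config)
    return config, table, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
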