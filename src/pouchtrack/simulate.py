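"""Synthetic longitudinal FMT-cohort generator with known ground truth.

Emulates a single-donor FMT trial in chronic pouchitis: one healthy donor
sampled six times, ~26 patients with dysbiotic baselines (facultative
anaerobes of the phylum Proteobacteria enriched, obligate anaerobes
depleted, low diversity), five fecal timepoints (0, 4, 12, 26, 52 weeks),
mucosal pouch and ileum samples at weeks 0 and 52, relapse events with an
antibiotic perturbation, and sequencing as multinomial sampling at a
negative-binomially distributed read depth.

Engraftment model
-----------------
Each taxon present in the donor but absent from a patient's baseline
("donor-only") transfers independently with probability ``e`` (the
engraftment rate).  Post-treatment composition at week ``t > 0`` is

    (1 - e) * baseline + e * donor[restricted to transferred taxa]

with the donor part renormalised over the taxa that fired, followed by
per-taxon log-normal temporal jitter.  The placebo arm uses ``e = 0``.
A relapse at week ``r`` reverts all later samples to the baseline
composition with the configured antibiotic boost applied to
Gammaproteobacteria-family taxa.  This mixture-with-Bernoulli-transfer
construction is a modelling choice that makes the engraftment rate a
recoverable parameter; it is not a mechanistic claim.

Determinism: every random stream is keyed by (master seed, stable hash of
the subject or sample id, purpose tag), so outputs are pure functions of
the configuration and adding a patient never reshuffles the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import CountTable, RANKS, write_count_table, write_metadata, validate_metadata

# Gammaproteobacteria families used for the antibiotic perturbation and
# the patients' facultative-anaerobe blooms.
GAMMA_FAMILIES = ("Enterobacteriaceae", "Pseudomonadaceae", "Moraxellaceae")

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria", "Verrucomicrobia")
_FAMILIES = {
    "Firmicutes": ("Lachnospiraceae", "Ruminococcaceae", "Clostridiaceae", "Veillonellaceae"),
    "Bacteroidetes": ("Bacteroidaceae", "Prevotellaceae", "Rikenellaceae"),
    "Proteobacteria": GAMMA_FAMILIES,
    "Actinobacteria": ("Bifidobacteriaceae", "Coriobacteriaceae"),
    "Verrucomicrobia": ("Akkermansiaceae",),
}

# purpose tags for stream derivation
_TAG_DONOR, _TAG_BASELINE, _TAG_TIME, _TAG_DEPTH, _TAG_COUNTS, _TAG_MUCOSA, _TAG_MISC = range(7)


def _stable_hash(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


def _rng(seed: int, *keys) -> np.random.Generator:
    ints = [int(seed)] + [(_stable_hash(k) if isinstance(k, str) else int(k)) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class SimConfig:
    """Cohort-generator configuration.

    Defaults mirror the trial design this generator emulates: 26 patients
    randomised 1:1 to FMT vs autologous placebo, one donor with six
    longitudinal samples, fecal sampling at 0/4/12/26/52 weeks, mucosal
    pouch and ileum biopsies at weeks 0 and 52, mean fecal depth ~45,000
    reads with enough spread that ~5% of samples fall under the
    10,000-read inclusion filter.
    """

    n_taxa: int = 300                     # taxa present in the donor
    n_patients: int = 26
    n_donor_samples: int = 6
    depth_mean: int = 45_000
    depth_dispersion: float = 2.5         # NB size parameter; smaller = heavier tails
    engraftment_rate: float = 0.3         # e, per FMT patient
    dysbiosis_strength: float = 2.0       # log-scale Proteobacteria boost at baseline
    relapse_schedule: dict = field(default_factory=dict)  # subject -> week
    timepoints_weeks: tuple = (0, 4, 12, 26, 52)
    seed: int = 0
    # composition model
    donor_sigma: float = 0.8              # log-normal sigma of donor proportions
    donor_proteo_frac: float = 0.005      # donor Proteobacteria mass (< 1%)
    donor_bacteroidetes_frac: float = 0.17
    baseline_dropout: float = 0.35        # fraction of donor taxa absent at patient baseline
    n_private_taxa: int = 60              # patient-private taxa per patient
    private_pool_size: int = 150          # shared pool the private taxa are drawn from
    private_mass: float = 0.35            # pre-boost mass of the private bloom
    private_sigma: float = 2.2
    baseline_jitter_sd: float = 0.3       # inter-patient heterogeneity on retained taxa
    jitter_sd: float = 0.35               # temporal log-normal jitter, per taxon per sample
    mucosal_jitter_sd: float = 0.35
    antibiotic_boost: float = 3.0         # post-relapse multiplier on Gammaproteobacteria families
    mucosal_weeks: tuple = (0, 52)
    mucosal_sites: tuple = ("pouch", "ileum")

    def __post_init__(self) -> None:
        if not (0.0 <= self.engraftment_rate <= 1.0):
            raise ValueError("engraftment_rate must be in [0, 1]")
        tps = tuple(self.timepoints_weeks)
        if list(tps) != sorted(tps) or tps[0] != 0:
            raise ValueError("timepoints_weeks must be ascending and start at 0")
        self.timepoints_weeks = tps
        self.mucosal_weeks = tuple(self.mucosal_weeks)
        self.mucosal_sites = tuple(self.mucosal_sites)


@dataclass
class CommunityProfile:
    """A relative-abundance profile over a fixed taxon universe."""

    taxa: list
    lineages: dict
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {p.sum()}")
        self.proportions = p

    def phylum_mass(self, phylum: str) -> float:
        idx = [i for i, t in enumerate(self.taxa) if self.lineages[t]["phylum"] == phylum]
        return float(self.proportions[idx].sum())


@dataclass
class SimTruth:
    """Ground truth of a generated cohort.

    ``compositions`` holds the pre-sequencing (multinomial-parameter)
    composition of every sample, aligned to ``taxa``; it is kept in
    memory for parameter-recovery oracles and is not serialised to
    ``truth.json``.
    """

    taxa: list
    engraftment_rate: dict            # subject -> e
    transfer_indicators: dict         # subject -> {donor-only taxon id: bool}
    relapse_week: dict                # subject -> week or None
    depths: dict                      # sample_id -> realised read depth
    compositions: dict = field(default_factory=dict)  # sample_id -> np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "engraftment_rate": self.engraftment_rate,
            "transfer_indicators": {
                s: {t: bool(v) for t, v in d.items()}
                for s, d in self.transfer_indicators.items()
            },
            "relapse_week": self.relapse_week,
            "depths": {k: int(v) for k, v in self.depths.items()},
        }


# ---------------------------------------------------------------------------
# taxon universe
# ---------------------------------------------------------------------------

def build_taxonomy(config: SimConfig) -> tuple[list, dict]:
    """Deterministic taxon universe: donor taxa then the private pool.

    Donor taxa are spread over the five major gut phyla with few
    Proteobacteria; the private pool (patient-only blooms) is dominated
    by Gammaproteobacteria families.  Roughly two OTUs share each genus
    so that genus-level aggregation is non-trivial.
    """
    rng = _rng(config.seed, "taxonomy", _TAG_MISC)
    taxa, lineages = [], {}

    def add(prefix: str, n: int, phylum_weights: dict) -> None:
        phyla = rng.choice(list(phylum_weights), size=n, p=np.array(list(phylum_weights.values())))
        for k in range(n):
            tid = f"{prefix}{k + 1:04d}"
            ph = str(phyla[k])
            fam = str(rng.choice(_FAMILIES[ph]))
            genus = f"{fam[:4]}_genus_{rng.integers(0, max(2, n // 2)):03d}"
            taxa.append(tid)
            lineages[tid] = {"phylum": ph, "family": fam, "genus": genus}

    add("OTU_", config.n_taxa,
        {"Firmicutes": 0.55, "Bacteroidetes": 0.22, "Actinobacteria": 0.12,
         "Verrucomicrobia": 0.05, "Proteobacteria": 0.06})
    add("PVT_", config.private_pool_size,
        {"Proteobacteria": 0.75, "Firmicutes": 0.15, "Actinobacteria": 0.10})
    return taxa, lineages


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def make_donor_profile(config: SimConfig) -> CommunityProfile:
    """High-diversity donor community.

    Log-normal proportions over the donor taxa, rescaled per phylum so the
    Proteobacteria mass stays under 1% and Bacteroidetes sits in 10-25%,
    the shape of a healthy donor's profile.  Private-pool taxa get zero.
    """
    if config.n_taxa < 10:
        raise ValueError("need at least 10 donor taxa")
    taxa, lineages = build_taxonomy(config)
    rng = _rng(config.seed, "donor_profile", _TAG_DONOR)
    w = np.zeros(len(taxa))
    donor_idx = np.arange(config.n_taxa)
    w[donor_idx] = rng.lognormal(mean=0.0, sigma=config.donor_sigma, size=config.n_taxa)

    p = w / w.sum()
    phyla = np.array([lineages[t]["phylum"] for t in taxa])
    targets = {"Proteobacteria": config.donor_proteo_frac,
               "Bacteroidetes": config.donor_bacteroidetes_frac}
    fixed_mass = sum(targets.values())
    other = ~np.isin(phyla, list(targets))
    other_mass = p[other].sum()
    for ph, target in targets.items():
        m = (phyla == ph) & (p > 0)
        cur = p[m].sum()
        if cur > 0:
            p[m] *= target / cur
    p[other] *= (1.0 - fixed_mass) / other_mass
    p /= p.sum()
    return CommunityProfile(taxa, lineages, p)


def make_patient_baseline(
    donor: CommunityProfile, config: SimConfig, subject_seed: int
) -> CommunityProfile:
    """Dysbiotic patient baseline derived from the donor profile.

    (i) a random ``baseline_dropout`` fraction of donor taxa is zeroed
    (these become the patient's donor-only taxa), (ii) patient-private
    bloom taxa are added from the shared pool, (iii) Proteobacteria
    proportions are multiplied by ``exp(dysbiosis_strength)``, and the
    profile is renormalised.  With dropout 0, no private taxa, strength 0
    and ``baseline_jitter_sd`` 0 the patient equals the donor.
    """
    rng = _rng(config.seed, "baseline", int(subject_seed), _TAG_BASELINE)
    p = donor.proportions.copy()
    donor_present = np.flatnonzero(p > 0)

    if config.baseline_dropout > 0:
        n_drop = int(round(config.baseline_dropout * len(donor_present)))
        drop = rng.choice(donor_present, size=n_drop, replace=False)
        p[drop] = 0.0

    if config.baseline_jitter_sd > 0:
        live = p > 0
        p[live] *= rng.lognormal(0.0, config.baseline_jitter_sd, size=int(live.sum()))

    if config.n_private_taxa > 0 and config.private_pool_size > 0:
        pool = np.arange(len(donor.taxa) - config.private_pool_size, len(donor.taxa))
        n_priv = min(config.n_private_taxa, len(pool))
        priv = rng.choice(pool, size=n_priv, replace=False)
        w = rng.lognormal(0.0, config.private_sigma, size=n_priv)
        remaining = p.sum()
        p[priv] = w / w.sum() * remaining * config.private_mass / (1.0 - config.private_mass)

    if config.dysbiosis_strength != 0:
        proteo = np.array([donor.lineages[t]["phylum"] == "Proteobacteria" for t in donor.taxa])
        p[proteo] *= np.exp(config.dysbiosis_strength)

    return CommunityProfile(donor.taxa, donor.lineages, p / p.sum())


# ---------------------------------------------------------------------------
# timecourse
# ---------------------------------------------------------------------------

def donor_only_taxa(donor: CommunityProfile, baseline: CommunityProfile) -> list:
    """Taxa present in the donor profile but absent from the baseline."""
    return [t for i, t in enumerate(donor.taxa)
            if donor.proportions[i] > 0 and baseline.proportions[i] == 0]


def _jitter(p: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return p
    q = p * rng.lognormal(0.0, sd, size=p.size)
    return q / q.sum()


def _draw_depth(config: SimConfig, rng: np.random.Generator) -> int:
    r = config.depth_dispersion
    prob = r / (r + config.depth_mean)
    return max(1, int(rng.negative_binomial(r, prob)))


def simulate_timecourse(
    donor: CommunityProfile,
    baseline: CommunityProfile,
    config: SimConfig,
    subject: str,
    arm: str,
    indicators: dict | None = None,
) -> tuple[pd.DataFrame, list[dict], dict]:
    """Fecal counts for one subject over all timepoints.

    Returns (counts DataFrame taxa x samples, metadata rows, truth dict
    with keys ``indicators``, ``depths``, ``compositions``).  ``arm`` must
    be ``FMT`` or ``placebo``; ``indicators`` overrides the Bernoulli
    transfer draw (used for limit tests).
    """
    if arm not in ("FMT", "placebo"):
        raise ValueError(f"subject {subject!r} has no valid arm: {arm!r}")
    e = config.engraftment_rate if arm == "FMT" else 0.0
    relapse = config.relapse_schedule.get(subject)

    d_only = donor_only_taxa(donor, baseline)
    rng_ind = _rng(config.seed, "indicators", subject, _TAG_TIME)
    if indicators is None:
        fired = rng_ind.random(len(d_only)) < e
        indicators = {t: bool(f) for t, f in zip(d_only, fired)}
    else:
        indicators = {t: bool(indicators.get(t, False)) for t in d_only}

    idx = {t: i for i, t in enumerate(donor.taxa)}
    donor_restricted = donor.proportions.copy()
    for t in d_only:
        if not indicators[t]:
            donor_restricted[idx[t]] = 0.0
    if donor_restricted.sum() > 0:
        donor_restricted = donor_restricted / donor_restricted.sum()

    gamma_mask = np.array(
        [donor.lineages[t]["family"] in GAMMA_FAMILIES for t in donor.taxa]
    )

    cols, meta_rows = {}, []
    truth = {"indicators": indicators, "depths": {}, "compositions": {}}
    anti_type, anti_pattern = subject_antibiotics(config, subject)
    for week in config.timepoints_weeks:
        if week == 0:
            comp = baseline.proportions.copy()
        elif relapse is not None and week > relapse:
            comp = baseline.proportions.copy()
            comp[gamma_mask] *= config.antibiotic_boost
            comp = comp / comp.sum()
        else:
            comp = (1.0 - e) * baseline.proportions + e * donor_restricted
            comp = comp / comp.sum()
        rng_s = _rng(config.seed, "sample", subject, int(week), _TAG_COUNTS)
        comp = _jitter(comp, config.jitter_sd, rng_s)
        depth = _draw_depth(config, rng_s)
        counts = rng_s.multinomial(depth, comp / comp.sum())
        sid = f"{subject}_wk{week:02d}_fecal"
        cols[sid] = counts
        truth["depths"][sid] = depth
        truth["compositions"][sid] = comp
        meta_rows.append(
            {"sample_id": sid, "subject_id": subject, "arm": arm, "week": int(week),
             "site": "fecal", "relapse_week": relapse,
             "antibiotic_type": anti_type, "antibiotic_pattern": anti_pattern}
        )
    counts_df = pd.DataFrame(cols, index=pd.Index(donor.taxa, name="taxon_id"), dtype=np.int64)
    return counts_df, meta_rows, truth


def subject_antibiotics(config: SimConfig, subject: str) -> tuple[str, str]:
    """Deterministic pre-trial antibiotic type and usage pattern."""
    rng = _rng(config.seed, "antibiotics", subject, _TAG_MISC)
    if rng.random() < 0.1:
        return "none", "none"
    a_type = str(rng.choice(["ciprofloxacin", "metronidazole", "other"], p=[0.5, 0.3, 0.2]))
    a_pattern = str(rng.choice(["continuous", "repeated"]))
    return a_type, a_pattern


def cohort_subjects(config: SimConfig) -> list[tuple[str, str]]:
    """Subject ids and arms: first half FMT, second half placebo."""
    n_fmt = (config.n_patients + 1) // 2
    return [
        (f"pt{i + 1:02d}", "FMT" if i < n_fmt else "placebo")
        for i in range(config.n_patients)
    ]


def study_relapse_schedule(
    config: SimConfig, relapse_prob: float = 0.7, weeks: tuple = (4, 12, 26, 52)
) -> dict:
    """Study-shaped relapse schedule: most patients relapse during follow-up."""
    schedule = {}
    for subject, _arm in cohort_subjects(config):
        rng = _rng(config.seed, "relapse", subject, _TAG_MISC)
        if rng.random() < relapse_prob:
            schedule[subject] = int(rng.choice(weeks))
    return schedule


def generate_cohort(config: SimConfig) -> tuple[CountTable, pd.DataFrame, SimTruth]:
    """Full synthetic cohort: donor samples, fecal timecourses, mucosa.

    Sample count = n_donor_samples + n_patients * len(timepoints) +
    n_patients * len(mucosal_weeks) * len(mucosal_sites).
    """
    donor = make_donor_profile(config)
    cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    truth = SimTruth(taxa=list(donor.taxa), engraftment_rate={}, transfer_indicators={},
                     relapse_week={}, depths={}, compositions={})

    for k in range(config.n_donor_samples):
        rng_s = _rng(config.seed, "donor_sample", k + 1, _TAG_COUNTS)
        comp = _jitter(donor.proportions.copy(), config.jitter_sd, rng_s)
        depth = _draw_depth(config, rng_s)
        sid = f"donor_s{k + 1}"
        cols[sid] = rng_s.multinomial(depth, comp / comp.sum())
        truth.depths[sid] = depth
        truth.compositions[sid] = comp
        meta_rows.append(
            {"sample_id": sid, "subject_id": "donor", "arm": "donor", "week": k + 1,
             "site": "fecal", "relapse_week": None,
             "antibiotic_type": "none", "antibiotic_pattern": "none"}
        )

    for subject, arm in cohort_subjects(config):
        baseline = make_patient_baseline(donor, config, _stable_hash(subject))
        counts_df, rows, t = simulate_timecourse(donor, baseline, config, subject, arm)
        for sid in counts_df.columns:
            cols[sid] = counts_df[sid].to_numpy()
        meta_rows.extend(rows)
        truth.engraftment_rate[subject] = config.engraftment_rate if arm == "FMT" else 0.0
        truth.transfer_indicators[subject] = t["indicators"]
        truth.relapse_week[subject] = config.relapse_schedule.get(subject)
        truth.depths.update(t["depths"])
        truth.compositions.update(t["compositions"])

        relapse = config.relapse_schedule.get(subject)
        anti_type, anti_pattern = subject_antibiotics(config, subject)
        for week in config.mucosal_weeks:
            fecal_comp = t["compositions"][f"{subject}_wk{week:02d}_fecal"]
            for site in config.mucosal_sites:
                rng_s = _rng(config.seed, "mucosa", subject, int(week), site, _TAG_MUCOSA)
                comp = _jitter(fecal_comp.copy(), config.mucosal_jitter_sd, rng_s)
                depth = _draw_depth(config, rng_s)
                sid = f"{subject}_wk{week:02d}_{site}"
                cols[sid] = rng_s.multinomial(depth, comp / comp.sum())
                truth.depths[sid] = depth
                truth.compositions[sid] = comp
                meta_rows.append(
                    {"sample_id": sid, "subject_id": subject, "arm": arm, "week": int(week),
                     "site": site, "relapse_week": relapse,
                     "antibiotic_type": anti_type, "antibiotic_pattern": anti_pattern}
                )

    counts = pd.DataFrame(cols, index=pd.Index(donor.taxa, name="taxon_id"), dtype=np.int64)
    table = CountTable(counts, {t: dict(donor.lineages[t]) for t in donor.taxa})
    meta = pd.DataFrame(meta_rows)
    meta["relapse_week"] = ["none" if pd.isna(v) else str(int(v)) for v in meta["relapse_week"]]
    meta = validate_metadata(meta)
    return table, meta, truth


def write_cohort(table: CountTable, meta: pd.DataFrame, truth: SimTruth, outdir) -> dict:
    """Write counts.tsv, metadata.tsv and truth.json under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    write_count_table(table, paths["counts"])
    write_metadata(meta, paths["metadata"])
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def config_from_toml(path) -> SimConfig:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown SimConfig fields in {path}: {sorted(unknown)}")
    return SimConfig(**data)
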