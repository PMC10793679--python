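"""Beta diversity: Bray-Curtis, donor-dissimilarity trajectories, PCoA,
PERMANOVA and homogeneity of group dispersions.

All statistics here are first-party implementations of the standard
methods.  Bray-Curtis is computed on per-sample fractions by default;
PERMANOVA is Anderson's one-way distance-based test with a label-
permutation null (exact enumeration when the number of distinct label
arrangements is small); the dispersion test embeds the samples by
principal coordinates, measures each sample's distance to its group
centroid, and permutes an ANOVA F statistic over those distances.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CountTable, CountTableError, aggregate_taxa, to_relative

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities over an ordered sample set."""

    sample_ids: list
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.data = d
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def loc(self, a: str, b: str) -> float:
        try:
            return float(self.data[self._index[a], self._index[b]])
        except KeyError as err:
            raise KeyError(f"unknown sample id {err.args[0]!r}") from None

    def subset(self, sample_ids: list) -> "DistanceMatrix":
        idx = [self._index[s] for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.data[np.ix_(idx, idx)])


@dataclass
class Ordination:
    sample_ids: list
    coordinates: np.ndarray      # samples x axes
    eigenvalues: np.ndarray      # descending, retained (positive) axes
    prop_explained: np.ndarray


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int
    method: str  # "exact" or "monte_carlo"


@dataclass
class DispersionResult:
    group_means: dict
    distances: pd.Series
    f_statistic: float
    p_value: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(x, y, fractions: bool = True) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y)) / (sum(x)+sum(y)).

    With ``fractions=True`` (default) each vector is normalised to sum 1
    first, so the value is 0 iff the two compositions are identical.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share the taxon index")
    sa, sb = a.sum(), b.sum()
    if sa == 0 and sb == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    if sa == 0 or sb == 0:
        return 1.0
    if fractions:
        a, b = a / sa, b / sb
        sa = sb = 1.0
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / (sa + sb))


def distance_matrix(
    table: CountTable, rank: str | None = "genus", fractions: bool = True
) -> DistanceMatrix:
    """All-pairs Bray-Curtis over the table's samples.

    Aggregation to ``rank`` is applied internally (``rank=None`` keeps
    the table at OTU level).
    """
    agg = aggregate_taxa(table, rank) if rank is not None else table
    mat = agg.counts.to_numpy(dtype=float)
    sums = mat.sum(axis=0)
    if (sums == 0).any():
        zero = [s for s, t in zip(agg.samples, sums) if t == 0]
        raise CountTableError(f"all-zero sample(s): {zero}")
    if fractions:
        mat = mat / sums
    n = mat.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(mat[:, i][:, None], mat[:, i + 1:]).sum(axis=0)
        tots = mat[:, i].sum() + mat[:, i + 1:].sum(axis=0)
        d[i, i + 1:] = 1.0 - 2.0 * mins / tots
    d = d + d.T
    return DistanceMatrix(agg.samples, d)


def donor_dissimilarity(patient_sample: str, donor_samples: list, dm: DistanceMatrix) -> float:
    """Mean Bray-Curtis distance of one sample to the donor samples."""
    if not donor_samples:
        raise ValueError("donor_samples must be non-empty")
    return float(np.mean([dm.loc(patient_sample, d) for d in donor_samples]))


def donor_dissimilarity_trajectory(
    table: CountTable,
    meta: pd.DataFrame,
    donor_samples: list,
    exclude_post_relapse: bool = True,
    rank: str | None = "genus",
    donor_reference: str = "pairwise_mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per patient x week average dissimilarity to the donor.

    ``donor_reference="pairwise_mean"`` (default) averages the distances
    to each donor sample; ``"profile_mean"`` measures the distance to the
    mean donor composition.  With ``exclude_post_relapse`` samples taken
    after the relapse week are omitted (the week-of-relapse sample is
    retained).  Returns (per-sample trajectory, arm x week means).
    """
    agg = aggregate_taxa(table, rank) if rank is not None else table
    rel = to_relative(agg)
    missing = [s for s in donor_samples if s not in rel.columns]
    if missing:
        raise CountTableError(f"donor samples not in table: {missing}")
    fecal = meta[(meta["site"] == "fecal") & (meta["arm"] != "donor")]
    donor_mat = rel[list(donor_samples)].to_numpy()
    mean_profile = donor_mat.mean(axis=1)

    rows = []
    for sid, m in fecal.iterrows():
        if sid not in rel.columns:
            continue
        relapse = m["relapse_week"]
        if exclude_post_relapse and pd.notna(relapse) and m["week"] > int(relapse):
            continue
        v = rel[sid].to_numpy()
        if donor_reference == "pairwise_mean":
            value = float(np.mean([bray_curtis(v, donor_mat[:, k]) for k in range(donor_mat.shape[1])]))
        elif donor_reference == "profile_mean":
            value = bray_curtis(v, mean_profile)
        else:
            raise ValueError(f"unknown donor_reference {donor_reference!r}")
        rows.append(
            {"sample_id": sid, "subject_id": m["subject_id"], "arm": m["arm"],
             "week": int(m["week"]), "dissimilarity": value,
             "relapsed": bool(pd.notna(relapse))}
        )
    traj = pd.DataFrame(rows)
    if traj.empty:
        return traj, traj
    arm_means = (
        traj.groupby(["arm", "week"])["dissimilarity"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return traj, arm_means


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues.  Negative
    eigenvalues -- common for Bray-Curtis -- are dropped with a warning.
    Axis signs are fixed so the largest-magnitude loading is positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, abs(evals).max() * 1e-10) if n else 0.0
    pos = evals > tol
    if (evals < -tol).any():
        log.warning("pcoa: dropping %d negative eigenvalue(s)", int((evals < -tol).sum()))
    evals_pos, evecs_pos = evals[pos], evecs[:, pos]
    k = min(n_axes, evals_pos.size)
    if k < n_axes:
        log.warning("pcoa: only %d positive axes available (requested %d)", k, n_axes)
    if evals_pos.size == 0:
        return Ordination(list(dm.sample_ids), np.zeros((n, 1)), np.zeros(1), np.zeros(1))
    coords = evecs_pos * np.sqrt(evals_pos)
    for jax in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, jax])))
        if coords[i, jax] < 0:
            coords[:, jax] *= -1.0
    prop = evals_pos / evals_pos.sum()
    return Ordination(list(dm.sample_ids), coords[:, :k], evals_pos[:k], prop[:k])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _align_labels(dm: DistanceMatrix, grouping) -> np.ndarray:
    """Grouping as a label array aligned with dm.sample_ids."""
    if isinstance(grouping, pd.Series):
        return grouping.loc[dm.sample_ids].to_numpy()
    if isinstance(grouping, dict):
        return np.array([grouping[s] for s in dm.sample_ids])
    arr = np.asarray(grouping)
    if arr.shape[0] != len(dm.sample_ids):
        raise ValueError("grouping length does not match distance matrix")
    return arr


def _multiset_permutations(labels: np.ndarray):
    """All distinct arrangements of a label multiset (lexicographic)."""
    items = sorted(labels.tolist())
    n = len(items)

    def rec(remaining, prefix):
        if len(prefix) == n:
            yield list(prefix)
            return
        prev = object()
        for i, x in enumerate(remaining):
            if x == prev:
                continue
            prev = x
            yield from rec(remaining[:i] + remaining[i + 1:], prefix + [x])

    yield from rec(items, [])


def n_distinct_arrangements(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _permanova_f(d2: np.ndarray, label_matrix: np.ndarray, ss_total: float, n_groups: int):
    """Pseudo-F for each row of ``label_matrix`` (P x n labels)."""
    n = d2.shape[0]
    ss_within = np.zeros(label_matrix.shape[0])
    groups = np.unique(label_matrix)
    for g in groups:
        m = (label_matrix == g).astype(float)       # P x n
        n_g = m.sum(axis=1)
        within = 0.5 * np.einsum("pi,ij,pj->p", m, d2, m)
        ss_within += within / n_g
    ss_between = ss_total - ss_within
    a = n_groups
    return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_within


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way distance-based PERMANOVA (Anderson 2001).

    SS_total = sum of squared distances over all pairs / n; SS_within
    accumulates within-group pairs scaled by group size; pseudo-F uses
    (a-1, n-a) degrees of freedom.  The p-value permutes group labels:
    exhaustively when the number of distinct arrangements is at most
    ``n_perm``, otherwise Monte Carlo with the add-one estimator.  The
    permutation stream is tied to the sorted sample ids, so the result is
    invariant to sample reordering and group relabeling.
    """
    labels = _align_labels(dm, grouping)
    order = np.argsort(np.array(dm.sample_ids, dtype=object).astype(str))
    ids = [dm.sample_ids[i] for i in order]
    d2 = dm.subset(ids).data ** 2
    labels = labels[order]

    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    f_obs, ss_w = _permanova_f(d2, labels[None, :], ss_total, len(uniq))
    f_obs, ss_w = float(f_obs[0]), float(ss_w[0])
    r2 = (ss_total - ss_w) / ss_total

    n_exact = n_distinct_arrangements(labels)
    if n_exact <= n_perm:
        perms = np.array(list(_multiset_permutations(labels)))
        f_all, _ = _permanova_f(d2, perms, ss_total, len(uniq))
        p = float(np.sum(f_all >= f_obs - 1e-12) / n_exact)
        return PermanovaResult(float(r2), f_obs, p, n_exact, seed, "exact")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"permanova")]))
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    f_all, _ = _permanova_f(d2, perms, ss_total, len(uniq))
    p = float((1 + np.sum(f_all >= f_obs - 1e-12)) / (1 + n_perm))
    return PermanovaResult(float(r2), f_obs, p, n_perm, seed, "monte_carlo")


# ---------------------------------------------------------------------------
# dispersion homogeneity (betadisper)
# ---------------------------------------------------------------------------

def _anova_f(values: np.ndarray, label_matrix: np.ndarray) -> np.ndarray:
    """One-way ANOVA F on ``values`` for each label row."""
    n = values.size
    grand = values.mean()
    sst = ((values - grand) ** 2).sum()
    groups = np.unique(label_matrix)
    ssw = np.zeros(label_matrix.shape[0])
    for g in groups:
        m = label_matrix == g
        n_g = m.sum(axis=1)
        sums = (m * values).sum(axis=1)
        sq = (m * values**2).sum(axis=1)
        ssw += sq - sums**2 / n_g
    a = len(groups)
    ssb = sst - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (a - 1)) / (ssw / (n - a))
    return np.where(ssw <= 1e-30, np.inf, f)


def betadisper(dm: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0) -> DispersionResult:
    """Homogeneity of multivariate group dispersions.

    Embeds the samples by PCoA (positive axes only), computes each
    sample's Euclidean distance to its group centroid in that space, and
    tests the group effect on those distances with a permutation F test.
    """
    labels = _align_labels(dm, grouping)
    order = np.argsort(np.array(dm.sample_ids, dtype=object).astype(str))
    ids = [dm.sample_ids[i] for i in order]
    labels = labels[order]
    sub = dm.subset(ids)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("dispersion test needs >= 2 groups with >= 2 samples each")

    ord_ = pcoa(sub, n_axes=max(1, len(ids) - 1))
    coords = ord_.coordinates
    dists = np.zeros(len(ids))
    for g in uniq:
        m = labels == g
        centroid = coords[m].mean(axis=0)
        dists[m] = np.sqrt(((coords[m] - centroid) ** 2).sum(axis=1))

    f_obs = float(_anova_f(dists, labels[None, :])[0])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"betadisper")]))
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    f_all = _anova_f(dists, perms)
    p = float((1 + np.sum(f_all >= f_obs - 1e-12)) / (1 + n_perm))
    group_means = {str(g): float(dists[labels == g].mean()) for g in uniq}
    return DispersionResult(group_means, pd.Series(dists, index=ids), f_obs, p, n_perm, seed)
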