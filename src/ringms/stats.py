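"""The comparability battery: Bray-Curtis distances, principal coordinate
analysis, one-way PERMANOVA with exact or Monte-Carlo permutation inference,
UpSet-style exclusive intersection counts, and the rank-based ubiquity
evaluation of cross-laboratory feature detection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# Distances and ordination
# ---------------------------------------------------------------------------

def bray_curtis(matrix) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between rows (samples x features).

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); entries in [0, 1].
    """
    df = pd.DataFrame(matrix)
    values = df.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("empty matrix")
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    if (values.sum(axis=1) == 0).any():
        raise ValueError("matrix contains all-zero rows")
    dist = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dist, index=df.index, columns=df.index)


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) embedding of a dissimilarity matrix.

    ``eigenvalues`` holds the full descending spectrum including any negative
    eigenvalues produced by non-Euclidean dissimilarities; coordinates and
    ``proportion_explained`` cover the positive axes only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def _check_distance_matrix(distances) -> pd.DataFrame:
    df = pd.DataFrame(distances)
    values = df.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return df


def pcoa(distances) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    Negative eigenvalues (possible for semimetric input) are reported in the
    spectrum but excluded from the coordinates; explained proportions are
    relative to the sum of positive eigenvalues.
    """
    df = _check_distance_matrix(distances)
    d = df.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12 if n else 0.0
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    pos_sum = eigval[pos].sum()
    prop = eigval[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=df.index, columns=axes),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    factor: str
    method: str  # "exact" or "permutation"


def _f_and_r2(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    n = d2.shape[0]
    g = len(sizes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for k in range(g):
        mask = codes == k
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * sizes[k])
    ss_among = ss_total - ss_within
    if ss_within > 0:
        f = (ss_among / (g - 1)) / (ss_within / (n - g))
    else:
        f = math.inf if ss_among > 0 else math.nan
    r2 = ss_among / ss_total if ss_total > 0 else math.nan
    return f, r2


def _distinct_assignments(n: int, sizes: list[int]):
    """Yield every distinct assignment of n positions to groups of the given
    sizes (multiset permutations of the label vector), as int code arrays."""
    positions = tuple(range(n))

    def rec(avail: tuple, k: int, codes: np.ndarray):
        if k == len(sizes) - 1:
            out = codes.copy()
            out[list(avail)] = k
            yield out
            return
        for combo in itertools.combinations(avail, sizes[k]):
            rest = tuple(p for p in avail if p not in set(combo))
            codes2 = codes.copy()
            codes2[list(combo)] = k
            yield from rec(rest, k + 1, codes2)

    yield from rec(positions, 0, np.full(n, -1, dtype=int))


def permanova(
    distances,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    exact_cap: int = 10_000,
    method: str = "auto",
    factor: str = "factor",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Sums of squares follow the distance-based partition
    ``SS_total = (1/N) sum_{i<j} d_ij^2`` and
    ``SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2``;
    ``pseudo_F = (SS_among/(g-1)) / (SS_within/(N-g))`` and
    ``R^2 = SS_among / SS_total``.

    When the number of distinct relabelings (multiset permutations of the
    label vector) is at most ``exact_cap`` — or ``method="exact"`` — the null
    distribution is enumerated exhaustively and
    ``p = #{F* >= F} / n_distinct`` (the identity relabeling included).
    Otherwise ``n_permutations`` random relabelings are drawn with ``seed``
    and ``p = (1 + #{F* >= F}) / (1 + n_permutations)``.
    """
    df = _check_distance_matrix(distances)
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != df.shape[0]:
        raise ValueError("one label per sample required")
    uniques = list(dict.fromkeys(labels))
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    code_of = {u: k for k, u in enumerate(uniques)}
    codes = np.array([code_of[x] for x in labels], dtype=int)
    sizes = np.bincount(codes)
    d2 = df.to_numpy(dtype=float) ** 2
    n = d2.shape[0]

    f_obs, r2 = _f_and_r2(d2, codes, sizes)

    n_distinct = math.factorial(n)
    for s in sizes:
        n_distinct //= math.factorial(int(s))
    use_exact = method == "exact" or (method == "auto" and n_distinct <= exact_cap)
    if method not in ("auto", "exact", "permutation"):
        raise ValueError(f"unknown method {method!r}")

    if use_exact:
        count = 0
        for perm_codes in _distinct_assignments(n, [int(s) for s in sizes]):
            f_perm, _ = _f_and_r2(d2, perm_codes, sizes)
            if _ge(f_perm, f_obs):
                count += 1
        p = float(Fraction(count, n_distinct))
        return PermanovaResult(f_obs, r2, p, n_distinct, factor, "exact")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm_codes = rng.permutation(codes)
        f_perm, _ = _f_and_r2(d2, perm_codes, sizes)
        if _ge(f_perm, f_obs):
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, factor, "permutation")


def _ge(f_perm: float, f_obs: float) -> bool:
    if math.isnan(f_obs):
        return True
    return f_perm >= f_obs


# ---------------------------------------------------------------------------
# Overlap and ubiquity
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    """Exclusive (UpSet-style) intersection counts over laboratories."""

    exclusive: dict  # frozenset of labs -> count of features in exactly that set
    totals: dict  # lab -> number of features present in the lab
    n_union: int  # features present in at least one lab
    shared_all_count: int
    shared_all_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"labs": "&".join(sorted(k)), "degree": len(k), "count": v}
            for k, v in sorted(self.exclusive.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["labs", "degree", "count"])


def intersection_counts(presence) -> OverlapSummary:
    """Exclusive intersection counts from a labs x features boolean matrix.

    ``presence`` may be a DataFrame (rows = labs) or a mapping lab -> feature
    set.  Features absent everywhere are ignored; exclusive counts over all
    nonempty lab subsets sum to the number of features present in >= 1 lab.
    """
    if isinstance(presence, dict):
        all_features = sorted(set().union(*presence.values()) if presence else set())
        presence = pd.DataFrame(
            {f: [f in s for s in presence.values()] for f in all_features},
            index=list(presence.keys()),
        )
    presence = pd.DataFrame(presence).astype(bool)
    if presence.shape[0] < 1:
        raise ValueError("need at least one lab")
    labs = list(presence.index)
    exclusive: dict[frozenset, int] = {}
    values = presence.to_numpy()
    for col in range(values.shape[1]):
        members = frozenset(labs[i] for i in np.flatnonzero(values[:, col]))
        if members:
            exclusive[members] = exclusive.get(members, 0) + 1
    totals = {lab: int(values[i].sum()) for i, lab in enumerate(labs)}
    n_union = int(values.any(axis=0).sum())
    shared_all = exclusive.get(frozenset(labs), 0)
    return OverlapSummary(
        exclusive=exclusive,
        totals=totals,
        n_union=n_union,
        shared_all_count=shared_all,
        shared_all_fraction=shared_all / n_union if n_union else 0.0,
    )


@dataclass
class UbiquityCurve:
    """Cumulative count of all-lab features along the intensity rank list."""

    ranks: list  # feature ids, descending mean intensity
    cumulative: np.ndarray  # cumulative_ubiquitous[k] <= k + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranks) + 1),
                "feature": self.ranks,
                "cumulative_ubiquitous": self.cumulative,
            }
        )


def _ranked_features(aligned):
    cols = aligned.sample_columns
    means = aligned.intensities[cols].mean(axis=1)
    return sorted(means.index, key=lambda fid: (-means[fid], str(fid))), means


def ubiquity_curve(aligned) -> UbiquityCurve:
    """Rank features by descending mean intensity (non-blank samples) and
    cumulatively count those detected in every laboratory."""
    if len(aligned.labs) < 2:
        raise ValueError("ubiquity evaluation needs >= 2 labs")
    ranks, _ = _ranked_features(aligned)
    present = aligned.presence_by_lab()
    in_all = present.all(axis=0)
    flags = np.array([bool(in_all[fid]) for fid in ranks])
    return UbiquityCurve(ranks=ranks, cumulative=np.cumsum(flags))


def intensity_by_ubiquity(aligned) -> pd.DataFrame:
    """Summaries of mean peak area grouped by the number of detecting labs.

    Mean peak area per feature is computed over its nonzero non-blank
    entries, so sparsity itself does not depress the group statistics.
    """
    if len(aligned.labs) < 2:
        raise ValueError("ubiquity evaluation needs >= 2 labs")
    cols = aligned.sample_columns
    sub = aligned.intensities[cols]
    if sub.shape[0] == 0:
        return pd.DataFrame(columns=["n_features", "median", "q1", "q3"]).rename_axis("n_labs")
    nz_mean = sub.where(sub > 0).mean(axis=1)
    n_labs = aligned.presence_by_lab().sum(axis=0)
    rows = {}
    for k in sorted(n_labs.unique()):
        vals = nz_mean[n_labs == k].dropna()
        if not len(vals):
            continue
        rows[int(k)] = {
            "n_features": int(len(vals)),
            "median": float(vals.median()),
            "q1": float(vals.quantile(0.25)),
            "q3": float(vals.quantile(0.75)),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("n_labs")
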