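"""Community variance statistics: Bray-Curtis, ANOSIM, SIMPER, ANOVA, F-test.

These are the rank- and dissimilarity-based tests used to ask which
experimental factors (substrate bin, incubation number) structure a microbial
community, implemented directly from their defining formulas.  The distance
container is :class:`skbio.DistanceMatrix`; all statistics accept either that
or a plain square array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import comb
from skbio import DistanceMatrix

from .otu import RelativeAbundanceTable, ValidationError

# ---------------------------------------------------------------------------
# Bray-Curtis

def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ) between two samples."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValidationError("abundances must be non-negative")
    denom = (u + v).sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


def bray_curtis_matrix(table: RelativeAbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between all samples of a table."""
    values = table.values if isinstance(table, RelativeAbundanceTable) else table
    ids = list(values.index)
    x = values.to_numpy(dtype=float)
    row_sums = x.sum(axis=1)
    # |u-v| summed pairwise, vectorised via broadcasting on modest n
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    denom = row_sums[:, None] + row_sums[None, :]
    if (row_sums == 0).sum() >= 2:
        bad = [ids[i] for i in np.flatnonzero(row_sums == 0)]
        raise ValidationError(
            f"Bray-Curtis undefined between all-zero samples: {bad}"
        )
    d = np.where(denom > 0, diff / np.where(denom == 0, 1, denom), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against float noise
    return DistanceMatrix(d, ids=ids)


# ---------------------------------------------------------------------------
# ANOSIM

@dataclass
class AnosimResult:
    """ANOSIM R statistic with its permutation p-value."""

    R: float
    p: float
    n_permutations: int
    seed: int | None = None
    exhaustive: bool = False


def _square(D) -> tuple[np.ndarray, list]:
    if isinstance(D, DistanceMatrix):
        return D.data.copy(), list(D.ids)
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    return arr.copy(), list(range(arr.shape[0]))


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _anosim_r(ranks: np.ndarray, ii: np.ndarray, jj: np.ndarray,
              labels: np.ndarray) -> float:
    within = labels[ii] == labels[jj]
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def _anosim_r_many(ranks: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                   label_matrix: np.ndarray) -> np.ndarray:
    """Vectorised R over many label assignments (rows of ``label_matrix``)."""
    within = label_matrix[:, ii] == label_matrix[:, jj]  # (P, m)
    m = ranks.size
    sum_within = within @ ranks
    n_within = within.sum(axis=1)
    total = ranks.sum()
    mean_w = sum_within / n_within
    mean_b = (total - sum_within) / (m - n_within)
    return (mean_b - mean_w) / (m / 2.0)


def _n_distinct_relabelings(sizes: list[int]) -> float:
    total = sum(sizes)
    out = 1.0
    rem = total
    for s in sizes:
        out *= comb(rem, s, exact=True)
        rem -= s
    return out


def _distinct_assignments(codes: np.ndarray) -> np.ndarray:
    """All distinct arrangements of a label multiset, one per row."""
    from itertools import combinations

    uniq, counts = np.unique(codes, return_counts=True)
    rows: list[np.ndarray] = []
    buf = np.empty(codes.size, dtype=np.int64)

    def rec(positions: np.ndarray, k: int) -> None:
        if k == len(uniq) - 1:
            buf[positions] = uniq[k]
            rows.append(buf.copy())
            return
        for combo in combinations(range(len(positions)), counts[k]):
            idx = positions[list(combo)]
            buf[idx] = uniq[k]
            rec(np.delete(positions, list(combo)), k + 1)

    rec(np.arange(codes.size), 0)
    return np.asarray(rows)


def anosim(
    D,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive_limit: int = 10_000,
) -> AnosimResult:
    """Analysis of similarity on a dissimilarity matrix.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 and mid-ranks for ties.  The p-value is estimated by random
    label permutations with the (b+1)/(m+1) estimator; when the number of
    distinct relabelings is at most ``exhaustive_limit`` the full enumeration
    is used instead and p is the exact tail proportion.
    """
    d, ids = _square(D)
    labels = np.asarray(groups)
    if labels.size != d.shape[0]:
        raise ValidationError("one group label required per sample")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM requires at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 members")
    # map labels to integer codes for fast comparison
    codes = np.searchsorted(uniq, labels)
    ii, jj = _pair_indices(d.shape[0])
    ranks = sps.rankdata(d[ii, jj])
    r_obs = _anosim_r(ranks, ii, jj, codes)

    n_distinct = _n_distinct_relabelings(list(counts))
    if n_distinct <= exhaustive_limit:
        all_labels = _distinct_assignments(codes)
        r_all = _anosim_r_many(ranks, ii, jj, all_labels)
        p = float((r_all >= r_obs - 1e-12).sum() / len(r_all))
        return AnosimResult(R=r_obs, p=p, n_permutations=len(r_all),
                            seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    r_perm = _anosim_r_many(ranks, ii, jj, perms)
    b = int((r_perm >= r_obs - 1e-12).sum())
    p = (b + 1) / (n_permutations + 1)
    return AnosimResult(R=r_obs, p=p, n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# SIMPER

@dataclass
class SimperResult:
    """Per-OTU decomposition of the average between-group Bray-Curtis."""

    groups: tuple[str, str]
    otu_ids: list[str]
    contributions: np.ndarray          # mean per-OTU contribution, same order as otu_ids
    overall_dissimilarity: float
    table: pd.DataFrame = field(repr=False)


def simper(rel: RelativeAbundanceTable | pd.DataFrame, groups) -> SimperResult | dict:
    """Similarity-percentage decomposition of between-group dissimilarity.

    For each pair of samples (j, k) drawn from the two groups, OTU i
    contributes |x_ij − x_ik| / Σ_m (x_mj + x_mk); averaging over all
    between-group pairs gives per-OTU contributions that sum exactly to the
    mean between-group Bray-Curtis dissimilarity.  With more than two groups
    a dict keyed by group pair is returned.
    """
    values = rel.values if isinstance(rel, RelativeAbundanceTable) else rel
    labels = np.asarray(groups)
    if labels.size != values.shape[0]:
        raise ValidationError("one group label required per sample")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("SIMPER requires at least two groups")
    if len(uniq) > 2:
        out = {}
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                mask = (labels == uniq[a]) | (labels == uniq[b])
                out[(str(uniq[a]), str(uniq[b]))] = simper(
                    values.loc[mask], labels[mask]
                )
        return out

    ga, gb = uniq
    xa = values.loc[labels == ga].to_numpy(dtype=float)
    xb = values.loc[labels == gb].to_numpy(dtype=float)
    if len(xa) == 0 or len(xb) == 0:
        raise ValidationError("each group needs at least one sample")

    n_otus = values.shape[1]
    contrib = np.zeros(n_otus)
    n_pairs = 0
    for j in range(len(xa)):
        diff = np.abs(xa[j][None, :] - xb)            # (n_b, otus)
        denom = (xa[j].sum() + xb.sum(axis=1))[:, None]
        contrib += (diff / denom).sum(axis=0)
        n_pairs += len(xb)
    contrib /= n_pairs
    overall = float(contrib.sum())

    order = np.argsort(contrib)[::-1]
    pct = 100 * contrib / overall if overall > 0 else np.zeros(n_otus)
    tab = pd.DataFrame(
        {
            "otu_id": np.asarray(values.columns)[order],
            "contribution": contrib[order],
            "percent": pct[order],
            "cumulative_percent": np.cumsum(pct[order]),
        }
    )
    return SimperResult(
        groups=(str(ga), str(gb)),
        otu_ids=list(values.columns),
        contributions=contrib,
        overall_dissimilarity=overall,
        table=tab,
    )


# ---------------------------------------------------------------------------
# ANOVA and variance-ratio F-test

def one_way_anova(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within with its p-value."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("ANOVA requires at least two groups")
    n = x.size
    k = len(uniq)
    if n <= k:
        raise ValidationError("total n must exceed the number of groups")
    grand = x.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in uniq:
        xi = x[labels == g]
        ss_between += len(xi) * (xi.mean() - grand) ** 2
        ss_within += ((xi - xi.mean()) ** 2).sum()
    if ss_within == 0 and ss_between == 0:
        raise ValidationError("F undefined: no variance between or within groups")
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    if ms_within == 0:
        return float("inf"), 0.0
    f = ms_between / ms_within
    p = float(sps.f.sf(f, k - 1, n - k))
    return float(f), p


def variance_ratio_test(x, y) -> tuple[float, float]:
    """Two-sided F-test for equal variances: F = s²_x / s²_y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs n ≥ 2")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValidationError("zero variance in denominator sample")
    f = vx / vy
    dfx, dfy = x.size - 1, y.size - 1
    cdf = sps.f.cdf(f, dfx, dfy)
    p = float(min(1.0, 2 * min(cdf, 1 - cdf)))
    return float(f), p
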