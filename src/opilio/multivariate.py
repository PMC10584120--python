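"""Permutation multivariate statistics on morphometric tables.

Implements, from first principles, the permutation tests used to compare
multivariate morphometric profiles among treatments:

* PERMANOVA — partitioning of sums of squared Euclidean distances with
  pseudo-F statistics (McArdle & Anderson style, via the Gower-centred
  matrix), for one or two crossed factors, with optional permutation strata
  as a nesting approximation;
* PERMDISP — homogeneity of multivariate dispersions: distances to group
  centroids in principal-coordinate space (with the imaginary-axis sign
  correction), F-tested by permuting least-squares residuals;
* ANOSIM — Clarke's rank-based R with midrank tie handling;
* SIMPER — per-variable percentage contributions to between-group squared
  Euclidean distance, on the raw (non-normalised) measurements, plus the
  percent-difference summary of group means.

Measurements are z-score normalised before distance-based tests; SIMPER is
run on raw values so contributions are interpretable in measurement units.
Permutation p-values use the add-one convention p = (b + 1)/(m + 1); with
``exhaustive=True`` (allowed for up to 8 samples) every relabelling is
enumerated and p is the exact fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "zscore_normalize",
    "euclidean_distance_matrix",
    "permanova",
    "permdisp",
    "anosim",
    "simper",
    "percent_difference",
]

MAX_EXHAUSTIVE_N = 8


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    values: np.ndarray
    ids: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12) or np.any(v < -1e-12):
            raise ValueError("distances must be non-negative with zero diagonal")
        object.__setattr__(self, "values", v)
        if not self.ids:
            object.__setattr__(self, "ids", tuple(range(len(v))))

    def __len__(self):
        return len(self.values)


@dataclass
class PermutationTestResult:
    """Outcome of one permutation test term."""

    name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    exhaustive: bool = False
    df: tuple | None = None
    extra: dict = field(default_factory=dict)


def _numeric(table: pd.DataFrame) -> pd.DataFrame:
    num = table.select_dtypes(include=[np.number])
    if num.isna().any().any():
        raise ValueError("morphometric table contains missing values")
    return num


def zscore_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every numeric column (mean 0, SD 1, n-1 denominator)."""
    out = table.copy()
    num = _numeric(table)
    sd = num.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"constant column(s) cannot be normalized: {flat}")
    out[num.columns] = (num - num.mean()) / sd
    return out


def euclidean_distance_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances over the numeric columns."""
    x = _numeric(table).to_numpy(dtype=float)
    sq = np.sum(x**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * x @ x.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(np.sqrt(d2), ids=tuple(table.index))


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def _dummy(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])


def _hat(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q @ q.T


def _perm_indices(n: int, n_perm: int, rng, strata=None):
    """Yield permuted index arrays, restricted within strata when given."""
    base = np.arange(n)
    if strata is None:
        for _ in range(n_perm):
            yield rng.permutation(n)
    else:
        strata = np.asarray(strata)
        blocks = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
        for _ in range(n_perm):
            idx = base.copy()
            for b in blocks:
                idx[b] = b[rng.permutation(len(b))]
            yield idx


def _all_perm_indices(n: int):
    for p in permutations(range(n)):
        yield np.array(p)


def _check_exhaustive(n: int, exhaustive: bool):
    if exhaustive and n > MAX_EXHAUSTIVE_N:
        raise ValueError(f"exhaustive enumeration limited to {MAX_EXHAUSTIVE_N} samples, got {n}")


def permanova(dm: DistanceMatrix, factors, n_perm: int = 9999, seed: int = 0,
              strata=None, exhaustive: bool = False) -> dict[str, PermutationTestResult]:
    """Permutational MANOVA on a distance matrix, one or two crossed factors.

    ``factors`` is a mapping name -> label sequence (one or two entries).
    Terms are fitted sequentially (factor A, factor B, A x B interaction);
    each term's pseudo-F uses the residual mean square as denominator and is
    tested by permuting samples (within ``strata`` when given).
    """
    d = dm.values
    n = len(d)
    factors = dict(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("permanova supports one or two crossed factors")
    labels = {k: np.asarray(v) for k, v in factors.items()}
    for name, lab in labels.items():
        if len(lab) != n:
            raise ValueError(f"factor {name!r} labels do not cover all {n} samples")
        counts = pd.Series(lab).value_counts()
        if len(counts) < 2:
            raise ValueError(f"factor {name!r} needs at least 2 levels")
        if (counts < 2).any():
            raise ValueError(f"factor {name!r} has a level with a single sample")
    G = _gower_center(d)
    ss_total = float(np.trace(G))
    if ss_total <= 1e-12:
        raise ValueError("all samples identical: total sum of squares is zero")

    names = list(labels)
    blocks = [("Intercept", np.ones((n, 1)))]
    blocks.append((names[0], _dummy(labels[names[0]])))
    if len(names) == 2:
        blocks.append((names[1], _dummy(labels[names[1]])))
        a, b = blocks[1][1], blocks[2][1]
        inter = np.einsum("ij,ik->ijk", a, b).reshape(n, -1)
        blocks.append((f"{names[0]}:{names[1]}", inter))

    deltas, dfs, X = [], [], np.empty((n, 0))
    H_prev = np.zeros((n, n))
    for name, cols in blocks:
        X = np.hstack([X, cols])
        H = _hat(X)
        if name != "Intercept":
            deltas.append((name, H - H_prev))
            dfs.append(np.linalg.matrix_rank(X) - np.linalg.matrix_rank(X[:, : X.shape[1] - cols.shape[1]]))
        H_prev = H
    R = np.eye(n) - H_prev  # residual projector
    df_res = n - np.linalg.matrix_rank(X)
    if df_res < 1:
        raise ValueError("no residual degrees of freedom for the requested terms")

    def stats(Gp):
        ss_res = float(np.sum(R * Gp))
        ms_res = ss_res / df_res
        return [float(np.sum(dH * Gp)) / df / ms_res for (_, dH), df in zip(deltas, dfs)]

    obs = stats(G)
    _check_exhaustive(n, exhaustive)
    if exhaustive:
        counts = np.zeros(len(obs))
        total = 0
        for idx in _all_perm_indices(n):
            perm_stats = stats(G[np.ix_(idx, idx)])
            counts += [ps >= o - 1e-12 for ps, o in zip(perm_stats, obs)]
            total += 1
        pvals = counts / total
        m = total
    else:
        rng = np.random.default_rng(seed)
        counts = np.zeros(len(obs))
        for idx in _perm_indices(n, n_perm, rng, strata):
            perm_stats = stats(G[np.ix_(idx, idx)])
            counts += [ps >= o - 1e-12 for ps, o in zip(perm_stats, obs)]
        pvals = (counts + 1) / (n_perm + 1)
        m = n_perm
    return {
        name: PermutationTestResult(
            name=name, statistic=obs[i], p_value=float(pvals[i]), n_permutations=m,
            seed=None if exhaustive else seed, exhaustive=exhaustive,
            df=(int(dfs[i]), int(df_res)),
        )
        for i, (name, _) in enumerate(deltas)
    }


def _centroid_distances(d: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group's spatial centroid, computed in
    principal-coordinate space with the negative-eigenvalue sign correction."""
    G = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(G)
    keep = np.abs(eigval) > 1e-9 * max(1.0, np.abs(eigval).max())
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    pos = eigval > 0
    z = np.empty(len(d))
    for lv in pd.unique(groups):
        m = groups == lv
        c = coords[m].mean(axis=0)
        delta2 = (coords[m] - c) ** 2
        d2 = delta2[:, pos].sum(axis=1) - delta2[:, ~pos].sum(axis=1)
        z[m] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _oneway_f(values: np.ndarray, groups: np.ndarray) -> float:
    grand = values.mean()
    ss_b = ss_w = 0.0
    k = 0
    for lv in pd.unique(groups):
        g = values[groups == lv]
        ss_b += len(g) * (g.mean() - grand) ** 2
        ss_w += ((g - g.mean()) ** 2).sum()
        k += 1
    df_b, df_w = k - 1, len(values) - k
    if ss_w <= 0:
        return math.inf if ss_b > 0 else math.nan
    return (ss_b / df_b) / (ss_w / df_w)


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 9999, seed: int = 0,
             exhaustive: bool = False, scheme: str = "recompute") -> PermutationTestResult:
    """Homogeneity of multivariate dispersions (distance-to-centroid F test).

    The observed F compares mean distances to group centroids in
    principal-coordinate space.  The default null scheme permutes group
    labels and recomputes centroid distances for every permutation, which
    is well calibrated at small sample sizes; ``scheme="residuals"``
    permutes the least-squares residuals of the observed distances instead
    (cheaper, but anti-conservative for small groups).
    """
    groups = np.asarray(groups)
    d = dm.values
    if len(groups) != len(d):
        raise ValueError("group labels must cover all samples")
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("permdisp needs >= 2 groups with >= 2 samples each")
    if scheme not in ("recompute", "residuals"):
        raise ValueError("scheme must be 'recompute' or 'residuals'")
    z = _centroid_distances(d, groups)
    obs = _oneway_f(z, groups)

    if scheme == "recompute":
        def perm_stat(idx):
            g = groups[idx]
            return _oneway_f(_centroid_distances(d, g), g)
    else:
        resid = z.copy()
        for lv in pd.unique(groups):
            m = groups == lv
            resid[m] -= z[m].mean()

        def perm_stat(idx):
            return _oneway_f(resid[idx], groups)

    _check_exhaustive(len(d), exhaustive)
    if exhaustive:
        stats = [perm_stat(idx) for idx in _all_perm_indices(len(d))]
        p = float(np.mean([s >= obs - 1e-12 for s in stats]))
        m_perm = len(stats)
    else:
        rng = np.random.default_rng(seed)
        b = sum(perm_stat(rng.permutation(len(d))) >= obs - 1e-12 for _ in range(n_perm))
        p = (b + 1) / (n_perm + 1)
        m_perm = n_perm
    return PermutationTestResult(name="dispersion", statistic=float(obs), p_value=p,
                                 n_permutations=m_perm, seed=seed, exhaustive=exhaustive,
                                 extra={"centroid_distances": z})


def anosim(dm: DistanceMatrix, groups, n_perm: int = 9999, seed: int = 0,
           exhaustive: bool = False) -> PermutationTestResult:
    """Clarke's analysis of similarities on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances; ties take midranks; R lies in [-1, 1].
    """
    groups = np.asarray(groups)
    d = dm.values
    n = len(d)
    if len(groups) != n:
        raise ValueError("group labels must cover all samples")
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("anosim needs >= 2 groups with >= 2 samples each")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])  # midranks
    M = len(ranks)

    def r_stat(g):
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2.0)

    obs = r_stat(groups)
    _check_exhaustive(n, exhaustive)
    if exhaustive:
        stats = [r_stat(groups[idx]) for idx in _all_perm_indices(n)]
        p = float(np.mean([s >= obs - 1e-12 for s in stats]))
        m_perm = len(stats)
    else:
        rng = np.random.default_rng(seed)
        b = sum(r_stat(groups[rng.permutation(n)]) >= obs - 1e-12 for _ in range(n_perm))
        p = (b + 1) / (n_perm + 1)
        m_perm = n_perm
    return PermutationTestResult(name="anosim", statistic=float(obs), p_value=p,
                                 n_permutations=m_perm, seed=seed, exhaustive=exhaustive)


def percent_difference(mean_a: float, mean_b: float) -> float:
    """100 (mean_a - mean_b) / mean_a; negative when the second group is larger."""
    if mean_a == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_a - mean_b) / mean_a


def simper(raw_table: pd.DataFrame, groups, pair: tuple | None = None,
           mode: str = "squared") -> pd.DataFrame:
    """Similarity-percentage decomposition between exactly two groups.

    For every between-group sample pair, variable k contributes its squared
    coordinate difference (its share of the squared Euclidean distance);
    contributions are averaged over pairs and expressed as percentages that
    sum to 100, sorted descending.  ``mode="absolute"`` uses absolute
    differences instead.  Run on raw (non-normalised) measurements.

    Returns a table with columns variable, mean_a, mean_b, pct_contribution,
    pct_difference.
    """
    groups = np.asarray(groups)
    names = pd.unique(groups) if pair is None else np.asarray(pair)
    if len(names) != 2:
        raise ValueError("simper compares exactly two groups")
    if mode not in ("squared", "absolute"):
        raise ValueError("mode must be 'squared' or 'absolute'")
    num = _numeric(raw_table)
    xa = num.to_numpy(float)[groups == names[0]]
    xb = num.to_numpy(float)[groups == names[1]]
    if not len(xa) or not len(xb):
        raise ValueError(f"both groups {tuple(names)} must be present")
    diff = xa[:, None, :] - xb[None, :, :]
    contrib = (diff**2 if mode == "squared" else np.abs(diff)).mean(axis=(0, 1))
    total = contrib.sum()
    if total <= 0:
        raise ValueError("groups are identical: zero total dissimilarity")
    out = pd.DataFrame({
        "variable": num.columns,
        "mean_a": xa.mean(axis=0),
        "mean_b": xb.mean(axis=0),
        "pct_contribution": 100.0 * contrib / total,
    })
    out["pct_difference"] = [
        percent_difference(a, b) if a != 0 else np.nan
        for a, b in zip(out.mean_a, out.mean_b)
    ]
    out.attrs["groups"] = (names[0], names[1])
    return out.sort_values("pct_contribution", ascending=False).reset_index(drop=True)
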