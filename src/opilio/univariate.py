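"""Univariate testing framework: ANOVA variants, assumption checks, and the
heteroscedasticity alpha-adjustment rule.

The experiment's scalar responses (embryo stage, fecundity, hatching
success, larval condition and mineral content) are analysed with fixed-
effects ANOVA: one-way by pH treatment, two-way with embryo and larval
treatments fully crossed, and a nested variant where females are nested
within treatment and the treatment effect is tested over the
female-within-treatment mean square.  Sums of squares are sequential
(Type I), which coincides with Type III on balanced designs; balance is
reported so unbalanced analyses can be flagged.

Assumption checks follow the study's gatekeeping convention: normality by
Anderson-Darling, homogeneity of variance by Levene's test (classic
group-mean centring), and — because ANOVA is robust to non-normality but
not to heteroscedasticity — a significant Levene test lowers the effective
alpha for the ANOVA decision to the Levene p-value itself
(:func:`heteroscedastic_gate`).  Tukey's HSD handles post-hoc pairwise
comparisons with a compact letter display for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "AnovaResult",
    "GateDecision",
    "TukeyResult",
    "one_way_anova",
    "two_way_anova",
    "nested_anova",
    "levene_test",
    "anderson_darling",
    "heteroscedastic_gate",
    "tukey_hsd",
]


@dataclass
class AnovaResult:
    """ANOVA decomposition: one row per term plus the residual.

    ``table`` columns: term, SS, df, MS, F, p.  ``balanced`` records whether
    the design had equal cell sizes; assumption-check p-values are attached
    by the caller where used.
    """

    table: pd.DataFrame
    balanced: bool = True
    levene_p: float | None = None
    ad_p: float | None = None
    extra: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        row = self.table[self.table.term == name]
        if not len(row):
            raise KeyError(f"no ANOVA term {name!r}")
        return row.iloc[0]

    @property
    def residual_df(self) -> int:
        return int(self.term("Residual")["df"])


def _dummy(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))


def _sequential_anova(y: np.ndarray, terms: list[tuple[str, np.ndarray]],
                      error_terms: dict[str, str] | None = None) -> pd.DataFrame:
    """Sequential (Type I) sum-of-squares decomposition by QR projection.

    ``terms`` excludes the intercept; ``error_terms`` optionally maps a term
    name to the name of the term whose mean square is its F denominator
    (default: the residual).
    """
    n = len(y)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    X = np.ones((n, 1))
    rss_prev = ss_total
    rank_prev = 1
    rows = []
    for name, cols in terms:
        if cols.shape[1] == 0:
            continue
        X = np.hstack([X, cols])
        # lstsq handles rank-deficient designs (nested dummies overlap the
        # treatment dummies); its min-norm fit is still the LS projection
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ coef) ** 2).sum())
        df = int(rank) - rank_prev
        if df > 0:
            rows.append({"term": name, "SS": rss_prev - rss, "df": df})
        rss_prev, rank_prev = rss, int(rank)
    df_res = n - rank_prev
    rows.append({"term": "Residual", "SS": rss_prev, "df": df_res})
    tbl = pd.DataFrame(rows)
    tbl["MS"] = tbl.SS / tbl.df.replace(0, np.nan)
    ms = dict(zip(tbl.term, tbl.MS))
    dfs = dict(zip(tbl.term, tbl.df))
    F, p = [], []
    for _, row in tbl.iterrows():
        if row.term == "Residual":
            F.append(np.nan)
            p.append(np.nan)
            continue
        denom_name = (error_terms or {}).get(row.term, "Residual")
        if denom_name not in ms:
            raise ValueError(
                f"term {row.term!r}: error term {denom_name!r} has no degrees of freedom"
            )
        denom_ms, denom_df = ms[denom_name], dfs[denom_name]
        if denom_df < 1 or not np.isfinite(denom_ms) or denom_ms <= 0:
            raise ValueError(
                f"term {row.term!r}: error term {denom_name!r} has no degrees of freedom"
            )
        F.append(row.MS / denom_ms)
        p.append(float(stats.f.sf(row.MS / denom_ms, row.df, denom_df)))
    tbl["F"] = F
    tbl["p"] = p
    return tbl


def _as_arrays(values, *factors):
    y = np.asarray(values, dtype=float)
    out = [np.asarray(f) for f in factors]
    for f in out:
        if len(f) != len(y):
            raise ValueError("factor labels must match the number of observations")
    return (y, *out)


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way decomposition, F = MS_between / MS_within."""
    y, g = _as_arrays(values, groups)
    counts = pd.Series(g).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"group(s) {small} have fewer than 2 observations")
    if np.ptp(y) == 0:
        raise ValueError("all values identical: F is 0/0")
    tbl = _sequential_anova(y, [("group", _dummy(g))])
    return AnovaResult(table=tbl, balanced=bool(counts.nunique() == 1))


def two_way_anova(values, factor_a, factor_b, include_interaction: bool = True,
                  names: tuple[str, str] = ("A", "B")) -> AnovaResult:
    """Fully crossed two-factor fixed-effects ANOVA with sequential SS."""
    y, a, b = _as_arrays(values, factor_a, factor_b)
    cells = pd.crosstab(pd.Series(a), pd.Series(b))
    if include_interaction and len(pd.unique(a)) > 1 and len(pd.unique(b)) > 1:
        if (cells.to_numpy() == 0).any():
            raise ValueError("empty design cell: interaction not estimable")
    Xa, Xb = _dummy(a), _dummy(b)
    inter = np.einsum("ij,ik->ijk", Xa, Xb).reshape(len(y), -1) \
        if include_interaction else np.empty((len(y), 0))
    terms = [(names[0], Xa), (names[1], Xb)]
    if include_interaction:
        terms.append((f"{names[0]}:{names[1]}", inter))
    tbl = _sequential_anova(y, terms)
    balanced = bool(cells.to_numpy().std() == 0)
    return AnovaResult(table=tbl, balanced=balanced)


def nested_anova(values, treatment, nested_unit, crossed_factor=None) -> AnovaResult:
    """Treatment tested over the nested-unit-within-treatment mean square.

    Each nested unit (e.g. female) must appear in exactly one treatment
    level; the crossed factor (e.g. month) and its interaction with
    treatment are tested over the residual.
    """
    if crossed_factor is None:
        y, t, u = _as_arrays(values, treatment, nested_unit)
        c = None
    else:
        y, t, u, c = _as_arrays(values, treatment, nested_unit, crossed_factor)
    span = pd.DataFrame({"t": t, "u": u}).groupby("u")["t"].nunique()
    if (span > 1).any():
        bad = span[span > 1].index.tolist()
        raise ValueError(f"nested unit(s) {bad} appear in more than one treatment")
    terms = [("treatment", _dummy(t)), ("unit", _dummy(u))]
    if c is not None:
        Xc = _dummy(c)
        terms.append(("crossed", Xc))
        terms.append(("treatment:crossed",
                      np.einsum("ij,ik->ijk", _dummy(t), Xc).reshape(len(y), -1)))
    tbl = _sequential_anova(y, terms, error_terms={"treatment": "unit"})
    counts = pd.Series(list(zip(t, u))).value_counts()
    return AnovaResult(table=tbl, balanced=bool(counts.nunique() == 1))


def levene_test(values, groups, center: str = "mean") -> float:
    """Levene's homogeneity-of-variance p-value (classic group-mean centring)."""
    y, g = _as_arrays(values, groups)
    samples = [y[g == lv] for lv in pd.unique(g)]
    if len(samples) < 2 or min(len(s) for s in samples) < 3:
        raise ValueError("Levene's test needs >= 2 groups with >= 3 observations each")
    return float(stats.levene(*samples, center=center).pvalue)


def anderson_darling(values) -> float:
    """Anderson-Darling normality p-value with estimated mean and variance."""
    y = np.asarray(values, dtype=float)
    if len(y) < 8:
        raise ValueError("Anderson-Darling test needs n >= 8")
    return float(normal_ad(y)[1])


@dataclass
class GateDecision:
    significant: bool
    alpha_used: float
    heteroscedastic: bool


def heteroscedastic_gate(p_anova: float, p_levene: float, alpha: float = 0.05) -> GateDecision:
    """Significance decision under the heteroscedasticity gatekeeping rule.

    When Levene's test is non-significant the ANOVA term is judged at the
    nominal alpha; when it is significant the term is declared significant
    only if its p-value is below the Levene p-value itself (i.e. the
    evidence against the null must exceed the evidence against the
    variance-homogeneity assumption).
    """
    for name, p in (("p_anova", p_anova), ("p_levene", p_levene)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if p_levene >= alpha:
        return GateDecision(p_anova < alpha, alpha, False)
    return GateDecision(p_anova < p_levene, p_levene, True)


@dataclass
class TukeyResult:
    pairwise: pd.DataFrame  # group_a, group_b, diff, p_adj
    letters: dict[str, str]
    means: dict[str, float]


def _letter_display(order: list[str], ns: set[frozenset]) -> dict[str, str]:
    """Compact letters over mean-sorted groups: one letter per maximal run of
    mutually non-different groups."""
    k = len(order)
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            frozenset((order[a], order[b])) in ns
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append((i, j))
    runs = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters = {g: "" for g in order}
    for letter, (i, j) in zip("abcdefghijklmnopqrstuvwxyz", sorted(set(runs))):
        for g in order[i:j + 1]:
            letters[g] += letter
    return letters


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """Tukey's honestly-significant-difference pairwise comparisons.

    Studentized-range based adjusted p-values plus a compact letter display
    (groups sharing a letter are not significantly different at ``alpha``).
    """
    y, g = _as_arrays(values, groups)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("Tukey's test needs at least two groups")
    samples = [y[g == lv] for lv in levels]
    if min(len(s) for s in samples) < 2:
        raise ValueError("every group needs at least 2 observations")
    res = stats.tukey_hsd(*samples)
    rows, ns = [], set()
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p = float(res.pvalue[i, j])
            rows.append({"group_a": levels[i], "group_b": levels[j],
                         "diff": float(samples[i].mean() - samples[j].mean()),
                         "p_adj": p})
            if p >= alpha:
                ns.add(frozenset((levels[i], levels[j])))
    means = {lv: float(s.mean()) for lv, s in zip(levels, samples)}
    order = sorted(levels, key=means.get)
    return TukeyResult(pairwise=pd.DataFrame(rows),
                       letters=_letter_display(order, ns), means=means)
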