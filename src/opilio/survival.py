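"""Log-logistic starvation-survival model with AICc multimodel selection.

Larval starvation experiments record, per replicate insert, how many larvae
die each day until either all are dead or the trial is censored at a fixed
horizon.  Cumulative mortality is modelled with a power formulation of the
logistic curve

    Pm(t) = 1 / (1 + (t / t50)^s)

where ``t50`` is the time to 50% mortality (the LT50) and ``s`` a unitless
slope; with ``s < 0`` this is the CDF of a log-logistic death-time
distribution.  ``t50`` and ``s`` may each be constant or vary with the
embryo-stage pH treatment (E), the larval-stage treatment (L), their
additive combination (E+L) or the full interaction (E#L); the ten
combinations in :data:`CANDIDATE_SPECS` form the candidate set ranked by
AICc.

The default likelihood is the interval-censored (multinomial) one: a larva
dying on day d contributes log[Pm(d) - Pm(d-1)], a survivor at the horizon
contributes log[1 - Pm(horizon)].  A per-day cumulative-binomial
pseudo-likelihood is available behind ``likelihood_mode="daily-binomial"``
for comparison with analyses that treated each daily count as an
independent binomial draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import binom

__all__ = [
    "DEFAULT_LEVELS",
    "STRUCTURES",
    "CANDIDATE_SPECS",
    "MortalityDataset",
    "SurvivalModelSpec",
    "FittedSurvivalModel",
    "mortality_prob",
    "count_params",
    "interval_loglik",
    "fit_survival_model",
    "aicc",
    "compare_models",
]

#: Treatment labels, ordered from present-day to most acidified.
DEFAULT_LEVELS = ("Ambient", "pH 7.8", "pH 7.5")

#: Factor structures a parameter may follow, with their parameter counts
#: under dummy coding (reference level = first treatment).
STRUCTURES = {"const": 1, "E": 3, "L": 3, "E+L": 5, "E#L": 9}


@dataclass(frozen=True)
class SurvivalModelSpec:
    """Which factors drive t50 and s."""

    t50_structure: str
    s_structure: str

    def __post_init__(self):
        for s in (self.t50_structure, self.s_structure):
            if s not in STRUCTURES:
                raise ValueError(f"unknown structure {s!r}; expected one of {sorted(STRUCTURES)}")

    def label(self) -> str:
        def part(name, struct):
            return name if struct == "const" else f"{name}({struct.replace('+', ',')})"

        return f"{part('t50', self.t50_structure)}, {part('s', self.s_structure)}"


#: The ten candidate models: every t50 structure with constant s, constant
#: t50 with every non-trivial s structure, and the full interaction on both.
CANDIDATE_SPECS = tuple(
    [SurvivalModelSpec(t, "const") for t in ("const", "E", "L", "E+L", "E#L")]
    + [SurvivalModelSpec("const", s) for s in ("E", "L", "E+L", "E#L")]
    + [SurvivalModelSpec("E#L", "E#L")]
)


def count_params(spec: SurvivalModelSpec) -> int:
    """Total free parameters K of a candidate model."""
    return STRUCTURES[spec.t50_structure] + STRUCTURES[spec.s_structure]


def mortality_prob(t, t50, s):
    """Cumulative mortality Pm(t) = 1/(1 + (t/t50)^s).

    Vectorized over ``t``.  For s < 0 this is a valid CDF with
    Pm(0) = 0 (limit convention) and Pm(t50) = 0.5 exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if np.any(np.asarray(t50) <= 0):
        raise ValueError("t50 must be positive")
    # 1/(1+(t/t50)^s) = expit(-s * log(t/t50)); stable for extreme slopes
    with np.errstate(divide="ignore"):
        logratio = np.log(t) - np.log(t50)
    out = expit(-np.asarray(s) * logratio)
    # limit at t=0: 0 for s<0, 1 for s>0 (expit handles +-inf correctly)
    return out if out.ndim else float(out)


class MortalityDataset:
    """Per-insert daily mortality records for a crossed embryo x larval design.

    Wraps a tidy DataFrame with columns ``insert_id, year, embryo_ph,
    larval_ph, day, new_deaths, initial_n``.  Rows for days with zero deaths
    may be omitted; ``max_day`` is the censoring horizon (survivors past it
    are censored alive).
    """

    COLUMNS = ["insert_id", "year", "embryo_ph", "larval_ph", "day", "new_deaths", "initial_n"]

    def __init__(self, records: pd.DataFrame, max_day: int | None = None,
                 levels: tuple[str, ...] = DEFAULT_LEVELS):
        df = pd.DataFrame(records).copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"mortality records missing columns {missing}")
        df = df[self.COLUMNS]
        if len(df):
            if (df["new_deaths"] < 0).any() or (df["initial_n"] <= 0).any():
                raise ValueError("counts must be non-negative and initial_n positive")
            if (df["day"] < 1).any():
                raise ValueError("day numbering starts at 1")
            bad = set(df["embryo_ph"]) | set(df["larval_ph"])
            if not bad <= set(levels):
                raise ValueError(f"unknown treatment labels {sorted(bad - set(levels))}")
            per = df.groupby("insert_id").agg(dead=("new_deaths", "sum"), n0=("initial_n", "first"))
            over = per[per["dead"] > per["n0"]]
            if len(over):
                raise ValueError(f"deaths exceed initial_n in inserts {list(over.index)}")
        self.records = df
        self.levels = tuple(levels)
        self.max_day = int(max_day if max_day is not None else (df["day"].max() if len(df) else 1))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_larvae(self) -> int:
        if not len(self.records):
            return 0
        return int(self.records.groupby("insert_id")["initial_n"].first().sum())

    def cells(self) -> list[tuple[str, str]]:
        return list(product(self.levels, self.levels))

    def cell_death_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Aggregate to (deaths[cell, day], censored[cell]) over days 1..max_day.

        Cell order follows :meth:`cells` (embryo-major).  This is the
        sufficient statistic for the interval likelihood.
        """
        cells = self.cells()
        idx = {c: i for i, c in enumerate(cells)}
        deaths = np.zeros((len(cells), self.max_day), dtype=float)
        totals = np.zeros(len(cells))
        df = self.records
        for (e, l), sub in df.groupby(["embryo_ph", "larval_ph"], sort=False):
            i = idx[(e, l)]
            day_sum = sub.groupby("day")["new_deaths"].sum()
            deaths[i, day_sum.index.to_numpy() - 1] = day_sum.to_numpy()
            totals[i] = sub.groupby("insert_id")["initial_n"].first().sum()
        censored = totals - deaths.sum(axis=1)
        return deaths, censored


def _design_matrix(structure: str, levels) -> np.ndarray:
    """Rows = the 9 design cells (embryo-major), columns = dummy-coded terms."""
    cells = list(product(levels, levels))
    k = len(levels)
    if structure == "const":
        return np.ones((len(cells), 1))
    if structure in ("E", "L"):
        pos = 0 if structure == "E" else 1
        X = np.ones((len(cells), k))
        for j in range(1, k):
            X[:, j] = [c[pos] == levels[j] for c in cells]
        return X
    if structure == "E+L":
        X = np.ones((len(cells), 2 * k - 1))
        col = 1
        for pos in (0, 1):
            for j in range(1, k):
                X[:, col] = [c[pos] == levels[j] for c in cells]
                col += 1
        return X
    if structure == "E#L":
        return np.eye(len(cells))
    raise ValueError(f"unknown structure {structure!r}")


def _expand(params: np.ndarray, spec: SurvivalModelSpec, levels) -> tuple[np.ndarray, np.ndarray]:
    """Map a packed parameter vector to per-cell (log_t50, s) arrays."""
    p1 = STRUCTURES[spec.t50_structure]
    Xt = _design_matrix(spec.t50_structure, levels)
    Xs = _design_matrix(spec.s_structure, levels)
    return Xt @ params[:p1], Xs @ params[p1:]


def interval_loglik(params, data: MortalityDataset, spec: SurvivalModelSpec,
                    likelihood_mode: str = "interval", eps: float = 1e-300,
                    _cache: tuple | None = None) -> float:
    """Log-likelihood of ``params`` (packed vector, t50 block on the log scale).

    ``likelihood_mode="interval"``: interval-censored multinomial terms (default).
    ``likelihood_mode="daily-binomial"``: per insert-day cumulative-dead
    binomial terms; the daily counts are not independent, so this is a
    pseudo-likelihood kept for comparison purposes.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    if params.size != count_params(spec):
        raise ValueError(f"expected {count_params(spec)} parameters, got {params.size}")
    log_t50, s = _expand(params, spec, data.levels)
    t50 = np.exp(log_t50)

    if likelihood_mode == "interval":
        if _cache is not None:
            deaths, censored = _cache
        else:
            deaths, censored = data.cell_death_table()
        days = np.arange(0, data.max_day + 1, dtype=float)
        F = mortality_prob(days[None, :], t50[:, None], s[:, None])  # (9, max_day+1)
        p_int = np.diff(F, axis=1)
        p_cens = 1.0 - F[:, -1]
        ll = np.sum(deaths * np.log(np.maximum(p_int, eps)))
        ll += np.sum(censored * np.log(np.maximum(p_cens, eps)))
        return float(ll)

    if likelihood_mode == "daily-binomial":
        cells = {c: i for i, c in enumerate(data.cells())}
        df = data.records.sort_values(["insert_id", "day"])
        ll = 0.0
        for ins, sub in df.groupby("insert_id", sort=False):
            i = cells[(sub["embryo_ph"].iloc[0], sub["larval_ph"].iloc[0])]
            n0 = int(sub["initial_n"].iloc[0])
            cum = sub["new_deaths"].cumsum().to_numpy()
            pm = np.clip(mortality_prob(sub["day"].to_numpy(float), t50[i], s[i]), eps, 1 - 1e-12)
            ll += float(binom.logpmf(cum, n0, pm).sum())
        return ll

    raise ValueError(f"unknown likelihood_mode {likelihood_mode!r}")


@dataclass
class FittedSurvivalModel:
    """Maximum-likelihood fit of one candidate model."""

    spec: SurvivalModelSpec
    params: np.ndarray
    per_cell: pd.DataFrame  # embryo_ph, larval_ph, t50, s
    loglik: float
    K: int
    n: int
    aicc: float
    converged: bool
    n_restarts: int = 0
    likelihood_mode: str = "interval"
    message: str = ""

    def cell_params(self, embryo: str, larval: str) -> tuple[float, float]:
        row = self.per_cell[(self.per_cell.embryo_ph == embryo)
                            & (self.per_cell.larval_ph == larval)]
        if not len(row):
            raise KeyError(f"no cell ({embryo}, {larval})")
        return float(row.t50.iloc[0]), float(row.s.iloc[0])


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample corrected Akaike criterion: -2 lnL + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def _empirical_median_day(data: MortalityDataset) -> float:
    deaths, censored = data.cell_death_table()
    per_day = deaths.sum(axis=0)
    total = per_day.sum() + censored.sum()
    if per_day.sum() == 0:
        raise ValueError("no deaths observed anywhere; t50 unidentifiable")
    cum = np.cumsum(per_day)
    half = total / 2.0
    day = int(np.searchsorted(cum, half) + 1)
    return float(min(day, data.max_day))


def fit_survival_model(data: MortalityDataset, spec: SurvivalModelSpec,
                       likelihood_mode: str = "interval", max_restarts: int = 5,
                       tol: float = 1e-8, seed: int = 0) -> FittedSurvivalModel:
    """Fit one candidate model by quasi-Newton maximum likelihood.

    Starts from a deterministic point (overall empirical median death day for
    every t50 term, s = -3) and, if the search fails, retries from up to
    ``max_restarts`` seed-deterministic jittered starts.
    """
    if not len(data.records):
        raise ValueError("empty mortality dataset")
    deaths, censored = data.cell_death_table()
    if spec.t50_structure == "E#L":
        dead_per_cell = deaths.sum(axis=1)
        present = dead_per_cell + censored > 0
        empty = [c for c, d, p in zip(data.cells(), dead_per_cell, present) if p and d == 0]
        if empty:
            raise ValueError(f"all larvae censored in cell(s) {empty}: t50 unidentifiable")

    p1 = STRUCTURES[spec.t50_structure]
    p2 = STRUCTURES[spec.s_structure]
    x0 = np.zeros(p1 + p2)
    x0[0] = np.log(_empirical_median_day(data))
    if spec.t50_structure == "E#L":
        x0[:p1] = x0[0]
    x0[p1] = -3.0
    if spec.s_structure == "E#L":
        x0[p1:] = -3.0

    cache = (deaths, censored) if likelihood_mode == "interval" else None

    def nll(theta):
        try:
            return -interval_loglik(theta, data, spec, likelihood_mode, _cache=cache)
        except (FloatingPointError, OverflowError):
            return np.inf

    rng = np.random.default_rng(seed)
    best, n_restarts = None, 0
    start = x0
    for attempt in range(max_restarts + 1):
        res = minimize(nll, start, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": tol, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            break
        n_restarts = attempt + 1
        start = x0 + rng.normal(scale=0.3, size=x0.size)
    # polish with a simplex pass; cheap and makes the nested-model
    # log-likelihood ordering robust on flat ridges
    res2 = minimize(nll, best.x, method="Nelder-Mead",
                    options={"xatol": 1e-9, "fatol": tol, "maxiter": 5000})
    if res2.fun < best.fun:
        best = res2

    log_t50, s = _expand(best.x, spec, data.levels)
    if np.any(s >= 0):
        warnings.warn(f"fitted slope >= 0 in model {spec.label()}: curve non-increasing")
    cells = data.cells()
    per_cell = pd.DataFrame({
        "embryo_ph": [c[0] for c in cells],
        "larval_ph": [c[1] for c in cells],
        "t50": np.exp(log_t50),
        "s": s,
    })
    ll = -best.fun
    K = count_params(spec)
    n = data.n_larvae if likelihood_mode == "interval" else len(data.records)
    converged = bool(np.isfinite(best.fun))
    if not converged:
        warnings.warn(f"model {spec.label()} did not converge")
    return FittedSurvivalModel(
        spec=spec, params=best.x, per_cell=per_cell, loglik=ll, K=K, n=n,
        aicc=aicc(ll, K, n), converged=converged, n_restarts=n_restarts,
        likelihood_mode=likelihood_mode, message=getattr(best, "message", ""),
    )


def compare_models(data: MortalityDataset, specs=CANDIDATE_SPECS,
                   likelihood_mode: str = "interval", seed: int = 0) -> pd.DataFrame:
    """Fit every candidate model and rank by AICc.

    Returns a table with one row per model: K, logLik, AICc, delta AICc,
    relative likelihood exp(-delta/2), Akaike weight, and a ``top_set`` flag
    marking models within 2 AICc of the best (conventionally considered to
    have equivalent support).  Non-converged fits are excluded with a warning.
    """
    if not len(data.records):
        raise ValueError("empty mortality dataset")
    fits = []
    for spec in specs:
        fit = fit_survival_model(data, spec, likelihood_mode=likelihood_mode, seed=seed)
        if not fit.converged:
            warnings.warn(f"excluding non-converged model {spec.label()}")
            continue
        fits.append(fit)
    tbl = pd.DataFrame({
        "model": [f.spec.label() for f in fits],
        "t50_structure": [f.spec.t50_structure for f in fits],
        "s_structure": [f.spec.s_structure for f in fits],
        "K": [f.K for f in fits],
        "logLik": [f.loglik for f in fits],
        "AICc": [f.aicc for f in fits],
    })
    tbl["delta_AICc"] = tbl["AICc"] - tbl["AICc"].min()
    tbl["rel_likelihood"] = np.exp(-tbl["delta_AICc"] / 2.0)
    tbl["weight"] = tbl["rel_likelihood"] / tbl["rel_likelihood"].sum()
    tbl["top_set"] = tbl["delta_AICc"] < 2.0
    tbl.attrs["fits"] = {f.spec: f for f in fits}
    tbl.attrs["n"] = fits[0].n if fits else 0
    tbl.attrs["likelihood_mode"] = likelihood_mode
    return tbl.sort_values("AICc").reset_index(drop=True)
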