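"""Synthetic-data generators that emulate the experiment's design.

No raw data from the study are deposited, so every analysis input is
generated here with the statistical structure the analyses assume:

* starvation-survival: per-larva death times drawn from the log-logistic
  distribution, observed as the integer day interval in which they fall and
  censored at the trial horizon (the trials were scored daily and ended
  after 7 weeks);
* larval/embryo morphometrics: multivariate-normal measurement vectors,
  resampled (not clipped) at zero so lengths stay non-negative without
  biasing the means;
* clutch outcomes: Poisson clutch totals split multinomially into viable,
  non-viable and unhatched categories;
* water chemistry: daily pH/temperature probe records and weekly bottle
  (DIC, TA) samples that are internally consistent with the carbonate
  solver before measurement noise is added.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbonate import WaterSample, solve_from_ph_dic
from .reproduction import ClutchOutcome
from .survival import DEFAULT_LEVELS, MortalityDataset

__all__ = [
    "DesignSpec",
    "CellParams",
    "gen_death_days",
    "gen_survival_experiment",
    "gen_morphometrics",
    "gen_clutch_outcomes",
    "gen_water_series",
]


@dataclass(frozen=True)
class DesignSpec:
    """The crossed embryo-pH x larval-pH survival design.

    Defaults are the study's scale: 3 x 3 treatments, 5 replicate inserts
    per cell, 20 larvae per insert, censored at 49 days (7 weeks).
    """

    embryo_levels: tuple[str, ...] = DEFAULT_LEVELS
    larval_levels: tuple[str, ...] = DEFAULT_LEVELS
    inserts_per_cell: int = 5
    larvae_per_insert: int = 20
    max_day: int = 49
    seed: int = 0

    def __post_init__(self):
        if self.inserts_per_cell < 1 or self.larvae_per_insert < 1 or self.max_day < 1:
            raise ValueError("inserts_per_cell, larvae_per_insert and max_day must be >= 1")
        for lv in (self.embryo_levels, self.larval_levels):
            if len(set(lv)) != len(lv):
                raise ValueError(f"treatment levels must be distinct, got {lv}")

    def cells(self):
        return [(e, l) for e in self.embryo_levels for l in self.larval_levels]


@dataclass(frozen=True)
class CellParams:
    """Generating survival parameters of one design cell."""

    t50: float
    s: float

    def __post_init__(self):
        if self.t50 <= 0:
            raise ValueError(f"t50 must be positive, got {self.t50}")


def gen_death_days(t50: float, s: float, n: int, max_day: int,
                   seed: int | np.random.Generator = 0,
                   continuous: bool = False) -> np.ndarray:
    """Draw ``n`` observed death days from the log-logistic model.

    Continuous death times T with CDF F(t) = 1/(1+(t/t50)^s) are drawn by
    inversion (T = t50 ((1-u)/u)^(1/s)) and recorded as the integer day
    interval (d-1, d] in which they fall; times beyond ``max_day`` are
    returned as 0, meaning censored alive at the horizon.  With
    ``continuous=True`` the raw (unbinned, uncensored) times are returned —
    the trials were scored daily, so day binning is the observation model,
    but the underlying times are useful for checking the generator itself.
    """
    if t50 <= 0:
        raise ValueError(f"t50 must be positive, got {t50}")
    if s >= 0:
        raise ValueError(f"slope s must be negative for an increasing curve, got {s}")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t = t50 * ((1.0 - u) / u) ** (1.0 / s)
    if continuous:
        return t
    day = np.ceil(t).astype(int)
    day[day < 1] = 1  # a death inside (0, 1] is observed on day 1
    day[t > max_day] = 0  # censored alive
    return day


def gen_survival_experiment(design: DesignSpec,
                            params: dict[tuple[str, str], CellParams],
                            year: int = 0) -> MortalityDataset:
    """Simulate a full crossed survival experiment as per-insert daily records.

    ``params`` maps every (embryo, larval) cell to its generating
    :class:`CellParams`.  Per insert, daily death counts plus final
    survivors always sum to ``larvae_per_insert``.
    """
    missing = [c for c in design.cells() if c not in params]
    if missing:
        raise ValueError(f"missing generating parameters for cell(s) {missing}")
    rng = np.random.default_rng(design.seed)
    rows = []
    for e, l in design.cells():
        cp = params[(e, l)]
        if not isinstance(cp, CellParams):
            cp = CellParams(*cp)
        for rep in range(1, design.inserts_per_cell + 1):
            insert_id = f"{e}|{l}|{rep}"
            days = gen_death_days(cp.t50, cp.s, design.larvae_per_insert,
                                  design.max_day, rng)
            observed = days[days > 0]
            day_counts = np.bincount(observed, minlength=design.max_day + 1)
            for d in range(1, design.max_day + 1):
                if day_counts[d]:
                    rows.append((insert_id, year, e, l, d, int(day_counts[d]),
                                 design.larvae_per_insert))
            if not len(observed):  # keep all-censored inserts visible
                rows.append((insert_id, year, e, l, design.max_day, 0,
                             design.larvae_per_insert))
    df = pd.DataFrame(rows, columns=MortalityDataset.COLUMNS)
    return MortalityDataset(df, max_day=design.max_day,
                            levels=tuple(design.embryo_levels))


def gen_morphometrics(group_means: dict[str, np.ndarray], covariance: np.ndarray,
                      n_per_group: int, seed: int = 0,
                      var_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Multivariate-normal morphometric samples, truncated at zero by resampling.

    Returns a tidy table: one row per specimen, measurement columns plus a
    ``group`` label column.  ``covariance`` must be symmetric positive
    semi-definite; zero covariance reproduces the group means exactly.
    """
    cov = np.asarray(covariance, dtype=float)
    p = cov.shape[0]
    if cov.shape != (p, p) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be square and symmetric")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10 * max(1.0, eig.max()):
        raise ValueError("covariance must be positive semi-definite")
    if var_names is None:
        var_names = tuple(f"v{i + 1}" for i in range(p))
    rng = np.random.default_rng(seed)
    frames = []
    for group, mean in group_means.items():
        mean = np.asarray(mean, dtype=float)
        if mean.shape != (p,):
            raise ValueError(f"group {group!r}: mean length {mean.shape} != {p}")
        draws = np.empty((0, p))
        while len(draws) < n_per_group:
            batch = rng.multivariate_normal(mean, cov, size=n_per_group,
                                            method="svd")
            batch = batch[(batch >= 0).all(axis=1)]  # truncation by resampling
            draws = np.vstack([draws, batch])
        df = pd.DataFrame(draws[:n_per_group], columns=list(var_names))
        df.insert(0, "group", group)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def gen_clutch_outcomes(mean_fecundity: float, p_nonviable: float, p_unhatched: float,
                        n_females: int, seed: int = 0,
                        treatment: str = "Ambient") -> list[ClutchOutcome]:
    """Simulate per-female clutch outcomes.

    Total embryos per female are Poisson around
    ``mean_fecundity / (1 - p_nonviable - p_unhatched)`` (so viable counts
    average ``mean_fecundity``), then split multinomially into viable /
    non-viable / unhatched.
    """
    if p_nonviable < 0 or p_unhatched < 0:
        raise ValueError("proportions must be non-negative")
    if p_nonviable + p_unhatched >= 1:
        raise ValueError("p_nonviable + p_unhatched must be < 1")
    rng = np.random.default_rng(seed)
    p_viable = 1.0 - p_nonviable - p_unhatched
    mean_total = mean_fecundity / p_viable
    out = []
    for i in range(n_females):
        total = int(rng.poisson(mean_total))
        while total == 0:
            total = int(rng.poisson(mean_total))
        v, nv, uh = rng.multinomial(total, [p_viable, p_nonviable, p_unhatched])
        out.append(ClutchOutcome(viable=int(v), nonviable=int(nv), unhatched=int(uh),
                                 female_id=f"F{i + 1}", treatment=treatment))
    return out


def gen_water_series(target_ph: float, temperature: float, salinity: float, dic: float,
                     n_days: int, noise_sd: dict[str, float] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate a monitoring series: daily probe records, weekly bottle samples.

    Daily rows carry (temperature, pH free) with Gaussian noise; one weekly
    row per started week carries (DIC, TA) where the noise-free TA is
    computed from the carbonate solver at the target conditions, so a
    zero-noise series is solver-consistent by construction.

    ``noise_sd`` keys: ``ph``, ``temperature``, ``dic``, ``ta`` (units of the
    variable); missing keys default to 0.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    sd = {"ph": 0.0, "temperature": 0.0, "dic": 0.0, "ta": 0.0, **(noise_sd or {})}
    rng = np.random.default_rng(seed)
    base = solve_from_ph_dic(WaterSample(temperature=temperature, salinity=salinity,
                                         ph_free=target_ph, dic=dic))
    rows = []
    for day in range(1, n_days + 1):
        rows.append({
            "day": day, "kind": "daily", "salinity": salinity,
            "temperature": temperature + rng.normal(scale=sd["temperature"]),
            "ph_free": target_ph + rng.normal(scale=sd["ph"]),
            "dic": np.nan, "ta": np.nan,
        })
        if day % 7 == 1:  # one bottle sample per started week
            rows.append({
                "day": day, "kind": "weekly", "salinity": salinity,
                "temperature": temperature + rng.normal(scale=sd["temperature"]),
                "ph_free": np.nan,
                "dic": dic + rng.normal(scale=sd["dic"]),
                "ta": base.ta + rng.normal(scale=sd["ta"]),
            })
    return pd.DataFrame(rows)
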