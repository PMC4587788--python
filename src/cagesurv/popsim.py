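"""Synthetic populations of group-housed laying hens with social genetic effects.

Emulates the data structure of a purebred layer experiment: a multi-
generation sire-dam pedigree, random allocation of final-generation females
to four-bird cages nested in laying-house x row x level classes, and monthly
mortality driven by each hen's own direct genetic effect (DGE) plus the
indirect genetic effects (IGE) of the cage mates alive at the start of each
month.  Survivors are right-censored at ``c * T`` days (416 by default).

Two generative engines are provided:

* a logistic monthly-hazard engine (:func:`simulate_mortality`), the default,
  which keeps records in {0, 1} so that every fitted model is an
  approximation of the truth; and
* linear-Gaussian engines (:func:`simulate_gaussian_days`,
  :func:`simulate_gaussian_monthly`) matching the generative form of the
  linear survival-time and random-regression models exactly, used for
  parameter-recovery and cross-model consistency checks where the estimand
  must be known without approximation error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .pedigree import Pedigree, UNKNOWN_PARENT

logger = logging.getLogger(__name__)

#: Days per month used to translate monthly survival into days.
DAYS_PER_MONTH = 30.4
#: Number of monthly records per hen.
N_MONTHS = 13
#: Study cutoff in days; survivors at the end of month T are censored here.
CUTOFF_DAYS = 416.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_baseline() -> tuple:
    # Monthly survival probabilities: heavier losses in the first four
    # months, then easing off.  Together with the default random-effect
    # variances (which pull realized survival slightly below the baseline
    # product) this yields ~59 % of hens alive at 13 months, the survival
    # level of line W1.
    return (0.95,) * 4 + (0.972,) * 9


@dataclass
class SimConfig:
    """Configuration of the default (logistic) population simulator.

    The family-structure defaults mirror line W1: 36 sires each mated to 8
    dams, an average of 12.3 female offspring per dam, two batches housed in
    separate laying houses, five generations of pedigree, four-bird cages,
    13 months of 30.4 days, and censoring of all survivors at day 416.
    Genetic, cage and permanent-environment variances are on the logit
    (monthly hazard) scale.
    """

    n_sires: int = 36
    dams_per_sire: int = 8
    offspring_per_dam: float = 12.3
    n_generations: int = 5
    n_batches: int = 2
    cage_size: int = 4
    # (rows, levels) per laying house; house 2 lacks the top level.
    layout: tuple = ((8, 3), (8, 2))
    months: int = N_MONTHS
    days_per_month: float = DAYS_PER_MONTH
    # logit-scale generative variances, calibrated so that a day-scale
    # analysis of the default population yields genetic parameters of the
    # magnitude reported for line W1 (direct SD ~28 days, indirect SD
    # ~10-13 days, positive direct-indirect covariance)
    var_dge: float = 0.15
    var_ige: float = 0.02
    cov_dige: float = 0.01
    var_cage: float = 0.02
    var_pe: float = 0.02
    class_effect_sd: float = 0.10
    baseline_survival: tuple = field(default_factory=_default_baseline)
    censoring: str = "all-at-end"
    seed: int = 0

    def genetic_cov(self) -> np.ndarray:
        C = np.array([[self.var_dge, self.cov_dige], [self.cov_dige, self.var_ige]])
        if np.min(np.linalg.eigvalsh(C)) < -1e-12:
            raise ConfigError("genetic covariance matrix C is not PSD")
        return C

    def validate(self) -> None:
        if self.cage_size < 2 or self.months < 1:
            raise ConfigError("need cage_size >= 2 and months >= 1")
        p = np.asarray(self.baseline_survival, dtype=float)
        if len(p) != self.months or np.any(p <= 0) or np.any(p > 1):
            raise ConfigError("baseline_survival must be T probabilities in (0, 1]")
        self.genetic_cov()


@dataclass
class SurvivalTable:
    """Monthly 0/1 records plus a day-scale view of the same mortality.

    ``monthly`` is long-format with one row per (hen, month): columns
    ``id, cage, class_id, month, value, alive_mates`` where ``alive_mates``
    is the tuple of cage-mate ids alive at the start of that month (frozen
    at the composition at death for months after the focal hen died).
    ``days`` has one row per hen: ``id, cage, class_id, days, censored``.
    """

    monthly: pd.DataFrame
    days: pd.DataFrame
    months: int = N_MONTHS
    days_per_month: float = DAYS_PER_MONTH

    def static_mates(self) -> dict:
        """Map id -> tuple of start-of-experiment cage mates."""
        out = {}
        first = self.monthly[self.monthly["month"] == 1]
        for i, mates in zip(first["id"], first["alive_mates"]):
            out[i] = tuple(mates)
        return out


# ---------------------------------------------------------------------------
# population structure
# ---------------------------------------------------------------------------


def generate_population(config: SimConfig, rng=None):
    """Generate a pedigree and cage layout with the configured structure.

    Ancestral generations carry only the selected breeding animals (the
    non-breeding collaterals of past generations do not affect the
    covariance structure of the phenotyped generation); the final
    generation receives the full Poisson family fan-out, and its females
    are randomly packed into full cages of ``cage_size`` within
    house-row-level classes.  Deterministic given the config seed.

    Returns ``(pedigree, cages)`` where ``cages`` has one row per cage with
    columns ``cage, class_id, member1..membern``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []  # (id, sire, dam, generation, sex)
    next_id = 1

    def new_ids(k):
        nonlocal next_id
        out = list(range(next_id, next_id + k))
        next_id += k
        return out

    n_dams = config.n_sires * config.dams_per_sire
    sires = new_ids(config.n_sires)
    dams = new_ids(n_dams)
    for i in sires:
        records.append((i, UNKNOWN_PARENT, UNKNOWN_PARENT, 0, "M"))
    for i in dams:
        records.append((i, UNKNOWN_PARENT, UNKNOWN_PARENT, 0, "F"))

    def matings(sires_, dams_):
        """Random nested mating: dams partitioned over sires."""
        order = rng.permutation(len(dams_))
        pairs = []
        per = len(dams_) // len(sires_)
        for k, s in enumerate(sires_):
            for j in order[k * per : (k + 1) * per]:
                pairs.append((s, dams_[j]))
        return pairs

    # breeding-only intermediate generations
    for g in range(1, config.n_generations - 1):
        pairs = matings(sires, dams)
        new_sires = new_ids(config.n_sires)
        new_dams = new_ids(n_dams)
        for i in new_sires:
            s, d = pairs[rng.integers(len(pairs))]
            records.append((i, s, d, g, "M"))
        for i in new_dams:
            s, d = pairs[rng.integers(len(pairs))]
            records.append((i, s, d, g, "F"))
        sires, dams = new_sires, new_dams

    # final generation: full fan-out, batched
    g = config.n_generations - 1
    hens_by_batch = []
    for b in range(config.n_batches):
        pairs = matings(sires, dams)
        hens = []
        for s, d in pairs:
            k = rng.poisson(config.offspring_per_dam)
            for i in new_ids(k):
                records.append((i, s, d, g, "F"))
                hens.append(i)
        hens_by_batch.append(hens)

    pedigree = Pedigree.from_records(records)

    # cage allocation: batch -> laying house, cages spread over row x level
    cage_rows = []
    cage_no = 0
    n = config.cage_size
    for b, hens in enumerate(hens_by_batch):
        house = b % len(config.layout) + 1
        n_rows, n_levels = config.layout[house - 1]
        classes = [
            f"h{house}-r{r + 1}-l{v + 1}" for r in range(n_rows) for v in range(n_levels)
        ]
        hens = np.asarray(hens)[rng.permutation(len(hens))]
        surplus = len(hens) % n
        if surplus:
            logger.info("dropping %d surplus hens from batch %d", surplus, b + 1)
            hens = hens[: len(hens) - surplus]
        for c in range(len(hens) // n):
            cage_no += 1
            row = {"cage": cage_no, "class_id": classes[c % len(classes)]}
            for j in range(n):
                row[f"member{j + 1}"] = int(hens[c * n + j])
            cage_rows.append(row)
    cages = pd.DataFrame(cage_rows)
    return pedigree, cages


def draw_genetic_effects(pedigree: Pedigree, C: np.ndarray, rng) -> np.ndarray:
    """Draw (A_D, A_I) pairs with covariance C (x) A by Mendelian sampling.

    Founders are N(0, C); an offspring's pair is the parental average plus a
    Mendelian deviation N(0, C * d_i), with d_i the Mendelian-sampling
    variance given parental inbreeding.  Returns an (N, 2) array in
    pedigree order.
    """
    C = np.asarray(C, dtype=float)
    if np.min(np.linalg.eigvalsh(C)) < -1e-12:
        raise ConfigError("genetic covariance matrix C is not PSD")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(pedigree)
    F = pedigree.inbreeding()
    # matrix square root of C (handles singular C, e.g. C = 0)
    w, V = np.linalg.eigh(C)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, 2))
    a = np.zeros((n, 2))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        if s[i] >= 0 and d[i] >= 0:
            mean = 0.5 * (a[s[i]] + a[d[i]])
            msv = 0.5 - 0.25 * (F[s[i]] + F[d[i]])
        elif s[i] >= 0 or d[i] >= 0:
            p = s[i] if s[i] >= 0 else d[i]
            mean = 0.5 * a[p]
            msv = 0.75 - 0.25 * F[p]
        else:
            mean = 0.0
            msv = 1.0
        a[i] = mean + np.sqrt(msv) * (L @ z[i])
    return a


# ---------------------------------------------------------------------------
# logistic monthly mortality
# ---------------------------------------------------------------------------


def simulate_mortality(
    cages: pd.DataFrame,
    effects: np.ndarray,
    config: SimConfig,
    pedigree: Pedigree,
    rng=None,
) -> SurvivalTable:
    """Monthly logistic mortality with time-dependent IGE exposure.

    Each month m a live hen survives with probability
    ``expit(mu_m + class + A_D + sum_{j alive} A_I_j + cage + PE)``; deaths
    are applied simultaneously at month end, so the IGE exposure of month m
    is the set of cage mates alive at its start.  Survivors at month T are
    censored.  Emits both the monthly 0/1 coding (survival-function coding:
    zeros persist after death) and the day-scale view (death in month m
    -> c*(m - 0.5) days; censored -> the 416-day cutoff).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    T = config.months
    n = config.cage_size
    member_cols = [f"member{j + 1}" for j in range(n)]
    members = cages[member_cols].to_numpy()  # (n_cages, n)
    n_cages = len(cages)
    idx = pedigree.index_of(members.ravel()).reshape(members.shape)
    a_d = effects[idx, 0]
    a_i = effects[idx, 1]

    classes = cages["class_id"].to_numpy()
    uclass = pd.unique(classes)
    class_off = dict(
        zip(uclass, config.class_effect_sd * rng.standard_normal(len(uclass)))
    )
    cage_eff = np.sqrt(config.var_cage) * rng.standard_normal(n_cages)
    pe = np.sqrt(config.var_pe) * rng.standard_normal(members.shape)
    mu = logit(np.clip(np.asarray(config.baseline_survival, float), 1e-12, 1 - 1e-12))

    alive = np.ones(members.shape, dtype=bool)
    death_month = np.zeros(members.shape, dtype=np.int64)  # 0 = censored
    frozen_mates: dict = {}  # id -> composition at own death
    rows = []
    for m in range(1, T + 1):
        alive_start = alive.copy()
        eta = (
            mu[m - 1]
            + np.asarray([class_off[c] for c in classes])[:, None]
            + a_d
            + cage_eff[:, None]
            + pe
        )
        # IGE of mates alive at month start
        tot_i = np.where(alive_start, a_i, 0.0).sum(axis=1, keepdims=True)
        eta = eta + np.where(alive_start, tot_i - a_i, tot_i)
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        survive = rng.random(members.shape) < p
        died_now = alive_start & ~survive
        alive = alive_start & survive
        death_month[died_now] = m
        for c in range(n_cages):
            mates_alive = [
                int(members[c, j]) for j in range(n) if alive_start[c, j]
            ]
            for j in range(n):
                i = int(members[c, j])
                if death_month[c, j] and death_month[c, j] < m:
                    mates = frozen_mates[i]
                else:
                    mates = tuple(x for x in mates_alive if x != i)
                    if died_now[c, j]:
                        frozen_mates[i] = mates
                rows.append(
                    {
                        "id": i,
                        "cage": int(cages["cage"].iloc[c]),
                        "class_id": classes[c],
                        "month": m,
                        "value": int(alive[c, j]),
                        "alive_mates": mates,
                    }
                )
    monthly = pd.DataFrame(rows)
    c_days = config.days_per_month
    day_rows = []
    for cidx in range(n_cages):
        for j in range(n):
            dm = death_month[cidx, j]
            day_rows.append(
                {
                    "id": int(members[cidx, j]),
                    "cage": int(cages["cage"].iloc[cidx]),
                    "class_id": classes[cidx],
                    "days": c_days * (dm - 0.5) if dm else CUTOFF_DAYS,
                    "censored": not bool(dm),
                }
            )
    days = pd.DataFrame(day_rows)
    return SurvivalTable(
        monthly=monthly, days=days, months=T, days_per_month=c_days
    )


def drop_records_retain_ids(table: SurvivalTable, ids) -> SurvivalTable:
    """Remove individuals' own records while keeping them as cage mates.

    Emulates the handling of hens that died from causes unrelated to the
    trait (predators, accidents): their own survival records are excluded
    from analysis, but their identities stay in the cage mates' IGE
    bookkeeping since they expressed indirect effects while alive.
    """
    ids = set(int(i) for i in np.atleast_1d(ids))
    return SurvivalTable(
        monthly=table.monthly[~table.monthly["id"].isin(ids)].reset_index(
            drop=True
        ),
        days=table.days[~table.days["id"].isin(ids)].reset_index(drop=True),
        months=table.months,
        days_per_month=table.days_per_month,
    )


def apply_censoring_scenario(
    table: SurvivalTable, scheme: str, rng=None
) -> SurvivalTable:
    """Apply a censoring scenario to a simulated table.

    ``"all-at-end"`` returns the table unchanged (everyone censored at the
    cutoff).  ``"half-at-midpoint"`` truncates the records of a random half
    of the eventual survivors at month ceil(T/2): their monthly records end
    there and their day record becomes c * ceil(T/2), flagged censored.
    """
    if scheme == "all-at-end":
        return table
    if scheme != "half-at-midpoint":
        raise ConfigError(f"unknown censoring scheme {scheme!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mid = int(np.ceil(table.months / 2))
    days = table.days.copy()
    surv_ids = days.loc[days["censored"], "id"].to_numpy()
    k = len(surv_ids) // 2
    chosen = set(rng.choice(surv_ids, size=k, replace=False).tolist())
    monthly = table.monthly[
        ~(table.monthly["id"].isin(chosen) & (table.monthly["month"] > mid))
    ].reset_index(drop=True)
    days.loc[days["id"].isin(chosen), "days"] = table.days_per_month * mid
    return SurvivalTable(
        monthly=monthly,
        days=days,
        months=table.months,
        days_per_month=table.days_per_month,
    )


# ---------------------------------------------------------------------------
# linear-Gaussian engines
# ---------------------------------------------------------------------------


def _month_sum(T: int) -> float:
    return T * (T + 1) / 2.0


@dataclass
class GaussianConfig:
    """Day-scale target components of the linear-Gaussian engines.

    Defaults mirror the magnitude of the survival-time components of line
    W1 (genetic SDs 28 and 10 days, covariance 57 days^2, phenotypic SD
    ~107 days); the non-genetic remainder is split between cage and
    residual with a positive cage share.
    """

    var_dge: float = 784.0  # 28^2
    var_ige: float = 100.0  # 10^2
    cov_dige: float = 57.0
    var_cage: float = 1000.0
    var_e: float = 9365.0
    mean: float = 300.0
    class_effect_sd: float = 25.0

    def genetic_cov(self) -> np.ndarray:
        C = np.array([[self.var_dge, self.cov_dige], [self.cov_dige, self.var_ige]])
        if np.min(np.linalg.eigvalsh(C)) < -1e-12:
            raise ConfigError("genetic covariance matrix C is not PSD")
        return C


def simulate_gaussian_days(
    pedigree: Pedigree,
    cages: pd.DataFrame,
    gcfg: GaussianConfig,
    rng,
):
    """Day-scale records from the survival-time model's own generative form.

    y_i = class + A_D_i + sum_j A_I_j + cage_k + e_i over the start-of-
    experiment cage mates.  Returns ``(days, effects, truth)`` where
    ``days`` carries no censoring (records are exact), ``effects`` are the
    true (A_D, A_I) pairs in pedigree order, and ``truth`` the generative
    components.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    effects = draw_genetic_effects(pedigree, gcfg.genetic_cov(), rng)
    member_cols = [c for c in cages.columns if c.startswith("member")]
    members = cages[member_cols].to_numpy()
    idx = pedigree.index_of(members.ravel()).reshape(members.shape)
    a_d = effects[idx, 0]
    a_i = effects[idx, 1]
    classes = cages["class_id"].to_numpy()
    uclass = pd.unique(classes)
    class_eff = dict(
        zip(uclass, gcfg.mean + gcfg.class_effect_sd * rng.standard_normal(len(uclass)))
    )
    cage_eff = np.sqrt(gcfg.var_cage) * rng.standard_normal(len(cages))
    e = np.sqrt(gcfg.var_e) * rng.standard_normal(members.shape)
    mate_ige = a_i.sum(axis=1, keepdims=True) - a_i
    y = (
        np.asarray([class_eff[c] for c in classes])[:, None]
        + a_d
        + mate_ige
        + cage_eff[:, None]
        + e
    )
    rows = []
    for c in range(len(cages)):
        for j in range(members.shape[1]):
            rows.append(
                {
                    "id": int(members[c, j]),
                    "cage": int(cages["cage"].iloc[c]),
                    "class_id": classes[c],
                    "days": y[c, j],
                    "censored": False,
                }
            )
    truth = {
        "var_dge": gcfg.var_dge,
        "var_ige": gcfg.var_ige,
        "cov_dige": gcfg.cov_dige,
        "var_cage": gcfg.var_cage,
        "var_e": gcfg.var_e,
        "scale": "days",
    }
    return pd.DataFrame(rows), effects, truth


def simulate_gaussian_monthly(
    pedigree: Pedigree,
    cages: pd.DataFrame,
    gcfg: GaussianConfig,
    rng,
    months: int = N_MONTHS,
    days_per_month: float = DAYS_PER_MONTH,
):
    """Monthly records from the random-regression model's generative form.

    Continuous monthly records
    ``y_lm = f_class(m) + t_m (g_D_l + sum_j g_I_j) + cage_km + t_m cage_k
    + t_m pe_l + e_lm`` with t_m = m, plus the day-scale view
    ``ST_l = c * sum_m y_lm``.  Slope-scale variances are derived from the
    day-scale targets in ``gcfg`` through the exact map
    sigma^2_day = c^2 S^2 sigma^2_slope with S = sum of t_m: all genetic
    variance is placed on the slopes, while the cage and residual targets
    are split half/half between slope-type terms (cage slope, permanent
    environment) and iid per-month terms (cage-month, monthly residual).

    Returns ``(table, effects, truth)`` with ``table`` a
    :class:`SurvivalTable` whose monthly ``value`` column is continuous.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    T = months
    c = days_per_month
    S = _month_sum(T)
    f = (c * S) ** 2
    slope_C = gcfg.genetic_cov() / f
    var_cage_slope = 0.5 * gcfg.var_cage / f
    var_cage_month = 0.5 * gcfg.var_cage / (c * c * T)
    var_pe = 0.5 * gcfg.var_e / f
    var_em = 0.5 * gcfg.var_e / (c * c * T)

    effects = draw_genetic_effects(pedigree, slope_C, rng)
    member_cols = [col for col in cages.columns if col.startswith("member")]
    members = cages[member_cols].to_numpy()
    n_cages, n = members.shape
    idx = pedigree.index_of(members.ravel()).reshape(members.shape)
    g_d = effects[idx, 0]
    g_i = effects[idx, 1]
    classes = cages["class_id"].to_numpy()
    uclass = pd.unique(classes)
    # smooth nuisance class curves on the monthly scale
    b0 = dict(zip(uclass, 1.0 + 0.05 * rng.standard_normal(len(uclass))))
    b1 = dict(zip(uclass, -0.02 + 0.005 * rng.standard_normal(len(uclass))))
    cage_slope = np.sqrt(var_cage_slope) * rng.standard_normal(n_cages)
    pe = np.sqrt(var_pe) * rng.standard_normal(members.shape)
    g_sum = g_d + (g_i.sum(axis=1, keepdims=True) - g_i)

    mates_flat = []
    for ci in range(n_cages):
        ms = [int(x) for x in members[ci]]
        for i in ms:
            mates_flat.append(tuple(x for x in ms if x != i))
    ids_flat = members.ravel().astype(int)
    cage_flat = np.repeat(cages["cage"].to_numpy(), n)
    class_flat = np.repeat(classes, n)
    b0v = np.asarray([b0[cl] for cl in classes])[:, None]
    b1v = np.asarray([b1[cl] for cl in classes])[:, None]
    frames = []
    st = np.zeros(members.shape)
    for m in range(1, T + 1):
        cage_month = np.sqrt(var_cage_month) * rng.standard_normal(n_cages)
        e = np.sqrt(var_em) * rng.standard_normal(members.shape)
        y = (
            b0v
            + b1v * m
            + m * (g_sum + cage_slope[:, None] + pe)
            + cage_month[:, None]
            + e
        )
        st += y
        frames.append(
            pd.DataFrame(
                {
                    "id": ids_flat,
                    "cage": cage_flat,
                    "class_id": class_flat,
                    "month": m,
                    "value": y.ravel(),
                    "alive_mates": mates_flat,
                }
            )
        )
    monthly = pd.concat(frames, ignore_index=True)
    day_rows = []
    for ci in range(n_cages):
        for j in range(n):
            day_rows.append(
                {
                    "id": int(members[ci, j]),
                    "cage": int(cages["cage"].iloc[ci]),
                    "class_id": classes[ci],
                    "days": c * st[ci, j],
                    "censored": False,
                }
            )
    table = SurvivalTable(
        monthly=monthly,
        days=pd.DataFrame(day_rows),
        months=T,
        days_per_month=c,
    )
    truth = {
        "scale": "monthly-slope (animal)",
        "slope_var_dge": slope_C[0, 0],
        "slope_var_ige": slope_C[1, 1],
        "slope_cov_dige": slope_C[0, 1],
        "var_cage_slope": var_cage_slope,
        "var_cage_month": var_cage_month,
        "var_pe": var_pe,
        "var_em": var_em,
        "day_targets": asdict(gcfg),
    }
    return table, effects, truth


# ---------------------------------------------------------------------------
# dataset writing
# ---------------------------------------------------------------------------


def write_dataset(
    out_dir,
    pedigree: Pedigree,
    cages: pd.DataFrame,
    table: SurvivalTable,
    truth: dict | None = None,
) -> None:
    """Write pedigree.csv, cages.csv, monthly.csv, days.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pedigree.to_csv(out / "pedigree.csv")
    member_cols = [c for c in cages.columns if c.startswith("member")]
    cage_out = cages[["cage", "class_id"] + member_cols].copy()
    death = {
        i: (0 if cen else int(round(d / table.days_per_month + 0.5)))
        for i, d, cen in zip(
            table.days["id"], table.days["days"], table.days["censored"]
        )
    }
    for j, col in enumerate(member_cols):
        cage_out[f"death_month{j + 1}"] = [
            death.get(int(i), 0) for i in cage_out[col]
        ]
    cage_out.to_csv(out / "cages.csv", index=False)
    monthly = table.monthly.copy()
    monthly["alive_mates"] = [
        ";".join(str(x) for x in m) for m in monthly["alive_mates"]
    ]
    monthly.to_csv(out / "monthly.csv", index=False)
    table.days.to_csv(out / "days.csv", index=False)
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=float)


def read_dataset(in_dir):
    """Read a dataset written by :func:`write_dataset`.

    Returns ``(pedigree, cages, table, truth-or-None)``.
    """
    src = Path(in_dir)
    pedigree = Pedigree.from_csv(src / "pedigree.csv")
    cages = pd.read_csv(src / "cages.csv")
    monthly = pd.read_csv(src / "monthly.csv")
    monthly["alive_mates"] = [
        tuple(int(x) for x in str(m).split(";")) if str(m) not in ("", "nan") else ()
        for m in monthly["alive_mates"]
    ]
    days = pd.read_csv(src / "days.csv")
    T = int(monthly["month"].max())
    table = SurvivalTable(monthly=monthly, days=days, months=T)
    truth = None
    tpath = src / "truth.json"
    if tpath.exists():
        with open(tpath) as fh:
            truth = json.load(fh)
    return pedigree, cages, table, truth


def simulate(config: SimConfig):
    """End-to-end default simulation: population, effects, mortality.

    Returns ``(pedigree, cages, table, effects, truth)`` with the censoring
    scenario of the config applied.
    """
    rng = np.random.default_rng(config.seed)
    pedigree, cages = generate_population(config, rng)
    effects = draw_genetic_effects(pedigree, config.genetic_cov(), rng)
    table = simulate_mortality(cages, effects, config, pedigree, rng)
    table = apply_censoring_scenario(table, config.censoring, rng)
    truth = {
        "var_dge": config.var_dge,
        "var_ige": config.var_ige,
        "cov_dige": config.cov_dige,
        "var_cage": config.var_cage,
        "var_pe": config.var_pe,
        "scale": "logit-monthly",
    }
    return pedigree, cages, table, effects, truth
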