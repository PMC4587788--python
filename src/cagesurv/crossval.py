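"""Censoring-aware cross-validation of EBV for survival time.

Cages (not individuals) are the unit of holdout: five mutually exclusive
subsets of roughly 20 % of cages each are removed in turn, the model is
solved on the remainder, and the held-out hens' phenotypes are predicted
from their own estimated DGE plus the estimated IGE of their three
start-of-experiment cage mates.  Because censored hens have no observed
survival time, agreement is measured on ranks: uncensored hens are ranked
by their fixed-effect-adjusted survival days, and all censored hens share
the average of the top ranks they jointly occupy (they are assumed to die
in random order after the cutoff).  The fold-stratified Spearman
correlation between observed and predicted ranks, divided by its upper
bound sqrt(r^2) = sqrt((sigma^2_AD + (n-1) sigma^2_AI) / sigma^2_P), gives
an approximate EBV accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .popsim import SurvivalTable
from .modelspec import ModelSpec, build_design
from .mme import (
    FitResult,
    VarianceComponents,
    extract_ebv,
    fit_model,
    glmm_pql_fit,
    reml_fit,
)
from .scales import TranslationContext, translate_ebv_to_days

logger = logging.getLogger(__name__)


class CrossvalError(ValueError):
    pass


@dataclass
class FoldPlan:
    """Assignment of every cage to one of k folds."""

    assignment: pd.DataFrame  # columns: cage, fold
    k: int
    seed: int

    def validation_cages(self, fold: int) -> np.ndarray:
        a = self.assignment
        return a.loc[a["fold"] == fold, "cage"].to_numpy()


@dataclass
class CVResult:
    correlation: float
    se: float
    per_fold: list
    pairs: pd.DataFrame  # id, fold, obs_rank, pred_rank, censored
    components: VarianceComponents
    model_id: str = ""


def make_folds(cages: pd.DataFrame, k: int = 5, seed: int = 0, max_retries: int = 200) -> FoldPlan:
    """Random assignment of cages to k folds, balanced to within one cage.

    Redrawn (bounded retries) until every fixed-effect class appears in
    every training set, i.e. no class has all its cages inside one fold; a
    class for which this is impossible (a single-cage class) raises a
    configuration error naming the class.
    """
    ids = cages["cage"].to_numpy()
    classes = cages["class_id"].to_numpy()
    if len(ids) < k:
        raise CrossvalError(f"need at least {k} cages")
    counts = pd.Series(classes).value_counts()
    bad = counts[counts < 2]
    if len(bad):
        raise CrossvalError(
            f"fixed-effect class {bad.index[0]!r} has a single cage; every "
            "training set would lose it"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        folds = np.tile(np.arange(1, k + 1), int(np.ceil(len(ids) / k)))[: len(ids)]
        rng.shuffle(folds)
        ok = True
        for f in range(1, k + 1):
            train_classes = set(classes[folds != f])
            if set(classes) - train_classes:
                ok = False
                break
        if ok:
            return FoldPlan(
                assignment=pd.DataFrame({"cage": ids, "fold": folds}), k=k, seed=seed
            )
    raise CrossvalError(
        "could not find a fold assignment keeping every class in every "
        f"training set in {max_retries} attempts"
    )


def adjust_observed(days: pd.DataFrame) -> pd.Series:
    """Fixed-effect-adjusted survival days for uncensored individuals.

    Ordinary least squares of observed survival days on the house-row-level
    classes, fitted on uncensored records only; the residual is the
    adjusted phenotype.  Censored records never receive an adjusted value
    (they will enter the ranking through the shared censored rank).
    """
    obs = days[~days["censored"]]
    if not len(obs):
        return pd.Series(dtype=float)
    resid = obs.groupby("class_id")["days"].transform(lambda v: v - v.mean())
    return pd.Series(resid.to_numpy(), index=obs["id"].to_numpy())


def rank_with_censoring(adjusted: pd.Series, censored_ids) -> pd.Series:
    """Observed ranks with all censored individuals tied at the top.

    Uncensored individuals are ranked ascending by adjusted phenotype
    (ties get average ranks); the censored ones are assumed to die in
    random order after the cutoff, so they share the average of the ranks
    above every uncensored individual: with 5 censored among 10, each gets
    (6+7+8+9+10)/5 = 8.
    """
    censored_ids = list(censored_ids)
    u = len(adjusted)
    ranks = adjusted.rank(method="average")
    n = u + len(censored_ids)
    if censored_ids:
        shared = (u + 1 + n) / 2.0
        ranks = pd.concat(
            [ranks, pd.Series(shared, index=censored_ids, dtype=float)]
        )
    return ranks


def predict_phenotypes(
    fit: FitResult,
    validation_ids,
    mates: dict,
    pedigree: Pedigree,
) -> pd.Series:
    """Predicted phenotype P_i = own DGE + summed IGE of the n-1 start mates.

    EBV of validation individuals come through the pedigree (their records
    were excluded from training).  For the regression-on-time model the
    slope EBV are mapped to the day scale first; for the other monthly
    models the prediction is used rank-only, so its scale is irrelevant.
    """
    validation_ids = list(validation_ids)
    need = set(validation_ids)
    for i in validation_ids:
        need.update(mates[i])
    ebv = extract_ebv(fit, pedigree, sorted(need))
    model_id = fit.spec.model_id if fit.spec else "STM"
    if model_id == "RMM.t":
        ebv = translate_ebv_to_days(ebv, TranslationContext(), model_id)
    d = dict(zip(ebv["id"], ebv["ebv_d"]))
    i_ = dict(zip(ebv["id"], ebv["ebv_i"]))
    pred = {
        v: d[v] + sum(i_[j] for j in mates[v]) for v in validation_ids
    }
    return pd.Series(pred)


def rank_correlation(pairs: pd.DataFrame):
    """Fold-stratified Spearman correlation and its standard error.

    Ranks are computed within each validation fold; the pooled correlation
    is the Pearson correlation of the fold-mean-centred ranks (the
    fixed-fold-effect analogue of a bivariate analysis of ranks across
    subsets).  The SE comes from a delete-one-fold jackknife.
    """
    folds = pairs["fold"].unique()
    if len(folds) < 2:
        raise CrossvalError("need at least two folds")
    xc, yc = [], []
    per_fold = []
    for f in folds:
        sub = pairs[pairs["fold"] == f]
        if len(sub) < 3:
            raise CrossvalError("need at least three pairs per fold")
        x = sub["obs_rank"] - sub["obs_rank"].mean()
        y = sub["pred_rank"] - sub["pred_rank"].mean()
        xc.append(x.to_numpy())
        yc.append(y.to_numpy())
        if x.std() > 0 and y.std() > 0:
            per_fold.append(float(np.corrcoef(x, y)[0, 1]))
        else:
            per_fold.append(np.nan)

    def pooled(skip=None):
        xs = np.concatenate([v for i, v in enumerate(xc) if i != skip])
        ys = np.concatenate([v for i, v in enumerate(yc) if i != skip])
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            raise CrossvalError("zero rank variance in every fold")
        return float(np.mean(xs * ys) / (sx * sy))

    r = pooled()
    loo = np.asarray([pooled(skip=i) for i in range(len(folds))])
    m = len(folds)
    se = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    return r, se, per_fold


def sqrt_r2(var_ad: float, var_ai: float, var_p: float, n: int = 4) -> float:
    """Upper bound of the observed-predicted rank correlation.

    sqrt((sigma^2_AD + (n-1) sigma^2_AI) / sigma^2_P): the expected
    correlation if breeding values were estimated with accuracy 1, using
    day-scale components of the survival-time model.
    """
    if var_p <= 0:
        raise CrossvalError("phenotypic variance must be positive")
    return float(np.sqrt((var_ad + (n - 1) * var_ai) / var_p))


def approx_accuracy(correlation: float, upper_bound: float) -> float:
    """Approximate EBV accuracy: rank correlation / its upper bound."""
    if upper_bound <= 0:
        raise CrossvalError("upper bound must be positive")
    return correlation / upper_bound


# ---------------------------------------------------------------------------
# end-to-end cross-validation
# ---------------------------------------------------------------------------


def _remove_cages(table: SurvivalTable, cage_set) -> SurvivalTable:
    cage_set = set(int(c) for c in cage_set)
    return SurvivalTable(
        monthly=table.monthly[~table.monthly["cage"].isin(cage_set)].reset_index(
            drop=True
        ),
        days=table.days[~table.days["cage"].isin(cage_set)].reset_index(drop=True),
        months=table.months,
        days_per_month=table.days_per_month,
    )


def run_crossval(
    table: SurvivalTable,
    pedigree: Pedigree,
    spec: ModelSpec,
    cages: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    components: VarianceComponents | None = None,
    eval_days: pd.DataFrame | None = None,
    reml_kw: dict | None = None,
) -> CVResult:
    """Cage-level k-fold cross-validation of one model.

    Variance components are estimated once on the full data (or taken from
    ``components``); each fold then removes its cages' phenotypes and
    re-solves the mixed-model equations at those components, which leaves
    the validation hens' EBV to flow through the pedigree only.  Observed
    ranks use ``eval_days`` (default: the analysed table's day view), so a
    censoring scenario applied to the training data can be evaluated
    against the unaltered phenotypes.
    """
    reml_kw = dict(reml_kw or {})
    if components is None:
        full = fit_model(table, pedigree, spec, **reml_kw)
        if not full.converged:
            logger.warning("full-data fit not converged; using best iterate")
        components = full.components
    if eval_days is None:
        eval_days = table.days
    plan = make_folds(cages, k=k, seed=seed)
    adjusted = adjust_observed(eval_days)
    censored_all = set(eval_days.loc[eval_days["censored"], "id"])
    member_cols = [c for c in cages.columns if c.startswith("member")]
    mates = {}
    for _, row in cages.iterrows():
        ms = [int(row[c]) for c in member_cols]
        for i in ms:
            mates[i] = tuple(j for j in ms if j != i)

    rows = []
    for f in range(1, k + 1):
        vcages = plan.validation_cages(f)
        vids = cages.loc[cages["cage"].isin(vcages), member_cols].to_numpy().ravel()
        vids = [int(i) for i in vids]
        training = _remove_cages(table, vcages)
        bundle = build_design(spec, training, pedigree)
        if spec.model_id == "GLMM":
            fold_fit = glmm_pql_fit(bundle, start=components, max_iter=0)
        else:
            # BLUP-only solve at the full-data components
            fold_fit = reml_fit(bundle, start=components, max_iter=0)
        fold_fit = _tag(fold_fit, spec)
        pred = predict_phenotypes(fold_fit, vids, mates, pedigree)
        cen = [i for i in vids if i in censored_all]
        unc = [i for i in vids if i not in censored_all]
        obs_ranks = rank_with_censoring(adjusted.loc[unc], cen)
        pred_ranks = pred.rank(method="average")
        for i in vids:
            rows.append(
                {
                    "id": i,
                    "fold": f,
                    "obs_rank": float(obs_ranks.loc[i]),
                    "pred_rank": float(pred_ranks.loc[i]),
                    "censored": i in censored_all,
                }
            )
    pairs = pd.DataFrame(rows)
    r, se, per_fold = rank_correlation(pairs)
    return CVResult(
        correlation=r,
        se=se,
        per_fold=per_fold,
        pairs=pairs,
        components=components,
        model_id=spec.model_id,
    )


def _tag(fit: FitResult, spec: ModelSpec) -> FitResult:
    if fit.spec is None:
        fit.spec = spec
    return fit
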