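"""Design construction for the four DGE-IGE survival models.

Turns a :class:`~cagesurv.popsim.SurvivalTable` plus a pedigree into the
response vector, fixed-effect design, and random-effect incidence matrices
consumed by the mixed-model engine.  The four models are:

* ``STM``   - linear mixed model for survival time in days (censored
  records entered at the cutoff), animal parameterization, random cage
  intercept, single residual variance;
* ``RMM.t`` - repeated-measures model for monthly 0/1 survival with random
  DGE/IGE regressions on time t_m (sire-dam), both cage terms (cage-month
  intercept and cage slope on t_m), a permanent-environment slope, and one
  residual variance per month;
* ``RMM.p`` - as RMM.t but the slope covariate is x_m = sqrt(p_m (1 - p_m))
  computed per fixed-effect class, so fitted variances track the binomial
  variance profile instead of t^2;
* ``GLMM``  - logit-link binomial model with genetic, permanent-environment
  and cage-month intercepts only (the link absorbs the change of variance
  over time).

Months are indexed t_m = 1..T (month of entry = 1), giving zero fitted
variance at the start of the laying period when regressing on time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import Pedigree
from .popsim import SurvivalTable

MODEL_IDS = ("STM", "RMM.t", "RMM.p", "GLMM")

#: Maximum polynomial degree of the fixed time curves.
FIXED_POLY_DEGREE = 6


class DesignError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Declarative description of one model variant."""

    model_id: str = "STM"
    parameterization: str | None = None  # animal | sire-dam (model default)
    time_dependent_ige: bool = False
    coding: str | None = None  # days | monthly-01 | monthly-01-missing
    combined_sire_dam: bool = False  # reporting convention only (see scales)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise DesignError(f"unknown model id {self.model_id!r}")
        if self.parameterization is None:
            self.parameterization = "animal" if self.model_id == "STM" else "sire-dam"
        if self.coding is None:
            self.coding = "days" if self.model_id == "STM" else "monthly-01"
        if self.model_id == "STM" and self.coding != "days":
            raise DesignError("STM analyses survival time in days")
        if self.model_id != "STM" and self.coding == "days":
            raise DesignError(f"{self.model_id} analyses monthly records")
        if self.model_id == "STM" and self.time_dependent_ige:
            raise DesignError("time-dependent IGE requires monthly records")


@dataclass
class RandomTerm:
    """One random term of a design: incidence + covariance descriptor.

    ``structure`` is ``"genetic_pair"`` (Z = [Z_D Z_I], covariance
    C (x) A over ``levels`` = pedigree ids) or ``"iid"`` (one variance).
    ``absorbable`` marks terms whose levels are nested within cages, which
    the engine may fold into a block-structured residual.
    """

    name: str
    Z: sparse.csr_matrix
    levels: np.ndarray
    structure: str = "iid"
    absorbable: bool = False
    pedigree: Pedigree | None = None


@dataclass
class DesignBundle:
    """Assembled response/design bundle for the engine."""

    model_id: str
    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    terms: list
    row_meta: pd.DataFrame  # id, cage, class_id (+ month for monthly models)
    residual: str  # "scalar" | "per-month" | "binomial"
    months: int | None = None
    fixed_names: list = field(default_factory=list)

    def n_rows(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# incidence builders
# ---------------------------------------------------------------------------


def _parent_ids(pedigree: Pedigree, ids: np.ndarray):
    idx = pedigree.index_of(ids)
    s_i, d_i = pedigree.sire_idx[idx], pedigree.dam_idx[idx]
    if np.any(s_i < 0) or np.any(d_i < 0):
        raise DesignError("sire-dam parameterization requires known parents")
    return pedigree.ids[s_i], pedigree.ids[d_i]


def build_dge_incidence(
    focal_ids: np.ndarray,
    pedigree: Pedigree,
    parameterization: str,
    weights: np.ndarray | None = None,
    levels: np.ndarray | None = None,
):
    """Incidence of the direct genetic effect.

    Animal: weight at the focal's own column.  Sire-dam: weight at the
    focal's sire column and at its dam column (so row sums are w and 2w
    respectively).  ``levels`` fixes the column ordering (defaults to the
    relevant pedigree closure); returns ``(Z, levels)``.
    """
    focal_ids = np.asarray(focal_ids)
    n = len(focal_ids)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if parameterization == "animal":
        if levels is None:
            levels = pedigree.ids
        pos = {i: k for k, i in enumerate(levels)}
        try:
            cols = np.asarray([pos[i] for i in focal_ids])
        except KeyError as exc:
            raise DesignError(f"focal id {exc.args[0]} absent from pedigree") from exc
        Z = sparse.csr_matrix(
            (w, (np.arange(n), cols)), shape=(n, len(levels))
        )
        return Z, np.asarray(levels)
    if parameterization != "sire-dam":
        raise DesignError(f"unknown parameterization {parameterization!r}")
    sires, dams = _parent_ids(pedigree, focal_ids)
    if levels is None:
        levels = pedigree.subset_closure(np.union1d(sires, dams)).ids
    pos = {i: k for k, i in enumerate(levels)}
    rows = np.repeat(np.arange(n), 2)
    cols = np.empty(2 * n, dtype=np.int64)
    cols[0::2] = [pos[s] for s in sires]
    cols[1::2] = [pos[d] for d in dams]
    Z = sparse.csr_matrix(
        (np.repeat(w, 2), (rows, cols)), shape=(n, len(levels))
    )
    return Z, np.asarray(levels)


def build_ige_incidence(
    mates_per_row,
    pedigree: Pedigree,
    parameterization: str,
    levels: np.ndarray,
    weights: np.ndarray | None = None,
):
    """Incidence of the summed cage-mate IGE.

    ``mates_per_row`` is a sequence of mate-id tuples, one per record row:
    the start-of-experiment mates for static IGE, or the mates alive at the
    start of the record's month for time-dependent IGE (the table's
    bookkeeping freezes the composition at the focal's own death).
    Sire-dam coefficients accumulate: two mates sharing a sire give that
    sire column coefficient 2.
    """
    n = len(mates_per_row)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    pos = {i: k for k, i in enumerate(levels)}
    rows, cols, vals = [], [], []
    if parameterization == "animal":
        for r, mates in enumerate(mates_per_row):
            for j in mates:
                rows.append(r)
                cols.append(pos[j])
                vals.append(w[r])
    else:
        mate_ids = sorted({j for mates in mates_per_row for j in mates})
        sires, dams = _parent_ids(pedigree, np.asarray(mate_ids))
        par = dict(zip(mate_ids, zip(sires, dams)))
        for r, mates in enumerate(mates_per_row):
            for j in mates:
                s, d = par[j]
                rows.extend((r, r))
                cols.extend((pos[s], pos[d]))
                vals.extend((w[r], w[r]))
    Z = sparse.coo_matrix((vals, (rows, cols)), shape=(n, len(levels))).tocsr()
    return Z


def _iid_term(name, labels, weights=None, absorbable=True):
    labels = np.asarray(labels)
    levels, codes = np.unique(labels, return_inverse=True)
    n = len(labels)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    Z = sparse.csr_matrix((w, (np.arange(n), codes)), shape=(n, len(levels)))
    return RandomTerm(name=name, Z=Z, levels=levels, structure="iid", absorbable=absorbable)


# ---------------------------------------------------------------------------
# covariates and fixed design
# ---------------------------------------------------------------------------


def compute_xm(table: SurvivalTable) -> pd.DataFrame:
    """Per (fixed-effect class, month) covariate x_m = sqrt(p_m (1 - p_m)).

    p_m is the mean of the 0/1 records of that class-month, floored/capped
    to [1/(2N), 1 - 1/(2N)] for a class-month with N records so degenerate
    cells (p = 0 or 1) keep a nonzero covariate.
    """
    m = table.monthly
    grp = m.groupby(["class_id", "month"])["value"]
    agg = grp.agg(["mean", "count"]).reset_index()
    if (agg["count"] == 0).any():
        raise DesignError("empty class-month cell")
    half = 1.0 / (2.0 * agg["count"])
    p = agg["mean"].clip(lower=half, upper=1.0 - half)
    agg["p_m"] = p
    agg["x_m"] = np.sqrt(p * (1.0 - p))
    return agg[["class_id", "month", "p_m", "x_m"]]


def orthogonal_time_basis(months: int, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis over the design points 1..T.

    Column 0 is the constant; columns are mutually orthogonal over the T
    months (QR of the Vandermonde matrix), which conditions the degree-6
    fixed curves without changing their fitted values.
    """
    t = np.arange(1, months + 1, dtype=float)
    V = np.vander(t, N=degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # fix signs so the constant column is positive
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def build_fixed_design(row_meta: pd.DataFrame, model_id: str, months: int | None = None):
    """Fixed design: one-hot classes (STM) or class x time-polynomial (others).

    Returns ``(X, names)``; aliased columns (zero or duplicated) are dropped
    with a log message rather than raising.
    """
    classes = row_meta["class_id"].to_numpy()
    uclass = list(pd.unique(classes))
    code = np.asarray([uclass.index(c) for c in classes])
    if model_id == "STM":
        X = np.zeros((len(classes), len(uclass)))
        X[np.arange(len(classes)), code] = 1.0
        return X, [f"class[{c}]" for c in uclass]
    if months is None:
        raise DesignError("monthly models need the number of months")
    degree = min(FIXED_POLY_DEGREE, months - 1)
    basis = orthogonal_time_basis(months, degree)  # T x (degree+1)
    month = row_meta["month"].to_numpy(dtype=int)
    B = basis[month - 1]  # n x (degree+1)
    ncol = len(uclass) * B.shape[1]
    X = np.zeros((len(classes), ncol))
    names = []
    for k, c in enumerate(uclass):
        sel = code == k
        X[sel, k * B.shape[1] : (k + 1) * B.shape[1]] = B[sel]
        names.extend([f"class[{c}]:poly{j}" for j in range(B.shape[1])])
    # drop aliased (all-zero) columns, e.g. a class absent from the data
    keep = np.flatnonzero(np.abs(X).sum(axis=0) > 0)
    if len(keep) < ncol:
        import logging

        logging.getLogger(__name__).info(
            "dropping %d aliased fixed-effect columns", ncol - len(keep)
        )
        X = X[:, keep]
        names = [names[k] for k in keep]
    return X, names


def recode_hazard(table: SurvivalTable) -> SurvivalTable:
    """Hazard-style 0/1/missing coding.

    Records in months strictly after an individual's death month are
    removed (missing); the death month keeps its 0.  Survivor strings are
    unchanged.
    """
    m = table.monthly
    death = (
        m[m["value"] == 0].groupby("id")["month"].min()
    )  # first month with a 0 = death month
    dm = m["id"].map(death)
    keep = dm.isna() | (m["month"] <= dm)
    return SurvivalTable(
        monthly=m[keep].reset_index(drop=True),
        days=table.days,
        months=table.months,
        days_per_month=table.days_per_month,
    )


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------


def build_design(
    spec: ModelSpec, table: SurvivalTable, pedigree: Pedigree
) -> DesignBundle:
    """Assemble the full design bundle for one model on one dataset."""
    if spec.model_id == "STM":
        return _build_stm(spec, table, pedigree)
    return _build_monthly(spec, table, pedigree)


def _cage_mates(days: pd.DataFrame) -> dict:
    """id -> tuple of start-of-experiment cage mates, from cage membership."""
    out = {}
    for _, grp in days.groupby("cage"):
        members = grp["id"].tolist()
        for i in members:
            out[i] = tuple(j for j in members if j != i)
    return out


def _genetic_levels(
    spec: ModelSpec, ids, table: SurvivalTable, pedigree: Pedigree,
    mates_per_row=(),
):
    """Shared genetic level set (pedigree closure) for DGE and IGE blocks.

    Mate ids are included even when their own records are absent (removed
    records of hens that died from unrelated causes still leave their IGE
    in the cage mates' rows).
    """
    all_ids = set(int(i) for i in np.asarray(ids).tolist())
    all_ids.update(int(i) for i in table.days["id"].tolist())
    for mates in mates_per_row:
        all_ids.update(int(j) for j in mates)
    all_ids = np.asarray(sorted(all_ids))
    if spec.parameterization == "animal":
        sub = pedigree.subset_closure(all_ids)
    else:
        sires, dams = _parent_ids(pedigree, all_ids)
        sub = pedigree.subset_closure(np.union1d(sires, dams))
    return sub


def _build_stm(spec, table, pedigree):
    days = table.days
    ids = days["id"].to_numpy()
    # month-1 mate sets retain cage mates whose own records were removed;
    # fall back on cage membership for day-only tables
    mates = table.static_mates() if len(table.monthly) else _cage_mates(days)
    mates_per_row = [mates[i] for i in ids]
    sub = _genetic_levels(spec, ids, table, pedigree, mates_per_row)
    Zd, levels = build_dge_incidence(
        ids, pedigree, spec.parameterization, levels=sub.ids
    )
    Zi = build_ige_incidence(
        mates_per_row, pedigree, spec.parameterization, levels
    )
    genetic = RandomTerm(
        name="genetic",
        Z=sparse.hstack([Zd, Zi]).tocsr(),
        levels=levels,
        structure="genetic_pair",
        absorbable=False,
        pedigree=sub,
    )
    cage = _iid_term("cage", days["cage"].to_numpy())
    X, names = build_fixed_design(days, "STM")
    return DesignBundle(
        model_id="STM",
        spec=spec,
        y=days["days"].to_numpy(dtype=float),
        X=X,
        terms=[genetic, cage],
        row_meta=days[["id", "cage", "class_id"]].copy(),
        residual="scalar",
        fixed_names=names,
    )


def _build_monthly(spec, table, pedigree):
    if spec.coding == "monthly-01-missing":
        table = recode_hazard(table)
    m = table.monthly
    T = table.months
    ids = m["id"].to_numpy()
    month = m["month"].to_numpy(dtype=int)

    if spec.model_id == "GLMM":
        slope_w = None  # genetic intercepts only
    elif spec.model_id == "RMM.t":
        slope_w = month.astype(float)
    else:  # RMM.p
        xm = compute_xm(table)
        lut = {
            (c, mo): x for c, mo, x in zip(xm["class_id"], xm["month"], xm["x_m"])
        }
        slope_w = np.asarray(
            [lut[(c, mo)] for c, mo in zip(m["class_id"], month)], dtype=float
        )
    gw = np.ones(len(m)) if spec.model_id == "GLMM" else slope_w

    if spec.time_dependent_ige:
        mates_per_row = list(m["alive_mates"])
    else:
        static = table.static_mates()
        mates_per_row = [static[i] for i in ids]
    sub = _genetic_levels(spec, ids, table, pedigree, mates_per_row)
    Zd, levels = build_dge_incidence(
        ids, pedigree, spec.parameterization, weights=gw, levels=sub.ids
    )
    Zi = build_ige_incidence(
        mates_per_row, pedigree, spec.parameterization, levels, weights=gw
    )
    genetic = RandomTerm(
        name="genetic",
        Z=sparse.hstack([Zd, Zi]).tocsr(),
        levels=levels,
        structure="genetic_pair",
        absorbable=False,
        pedigree=sub,
    )
    cage_month = _iid_term(
        "cage_month", [f"{c}|{mo}" for c, mo in zip(m["cage"], month)]
    )
    pe_w = None if spec.model_id == "GLMM" else slope_w
    terms = [genetic, cage_month]
    if spec.model_id != "GLMM":
        terms.append(_iid_term("cage_slope", m["cage"].to_numpy(), weights=slope_w))
    terms.append(_iid_term("pe", ids, weights=pe_w))
    X, names = build_fixed_design(m, spec.model_id, months=T)
    return DesignBundle(
        model_id=spec.model_id,
        spec=spec,
        y=m["value"].to_numpy(dtype=float),
        X=X,
        terms=terms,
        row_meta=m[["id", "cage", "class_id", "month"]].copy(),
        residual="binomial" if spec.model_id == "GLMM" else "per-month",
        months=T,
        fixed_names=names,
    )
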