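"""Mixed-model engine: Henderson's equations, BLUP, AI-REML, and PQL.

The engine fits the DGE-IGE models assembled by :mod:`cagesurv.modelspec`.
Variance components are estimated by average-information REML with exact
analytic gradients and EM fallback steps; best linear unbiased predictions
of all effects solve Henderson's mixed-model equations at the estimated
components.  The logit GLMM is fitted by penalized quasi-likelihood:
iterated REML fits of the working linearized model.

Two interchangeable linear-algebra strategies stand behind the REML
likelihood, chosen by problem shape:

* ``DenseVBackend`` - the phenotypic covariance V = sum_i theta_i K_i is
  formed explicitly from precomputed n x n kernels (direct, direct-indirect,
  indirect, cage, identity).  Suited to day-scale animal-model fits where
  the record count is moderate but the genetic dimension is large.
* ``AbsorbedBackend`` - random terms whose levels are nested within cages
  (cage, cage-month, cage slope, permanent environment) are folded into a
  block-diagonal residual covariance with one small block per cage, leaving
  a compact mixed-model coefficient matrix over the fixed effects and the
  (sire-dam) genetic effects.  Suited to the monthly repeated-measures
  models, whose raw equation systems would otherwise carry tens of
  thousands of nuisance levels.

Both strategies produce the same REML log-likelihood, score and
average-information matrix; the shared outer loop is indifferent to which
one is active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from scipy.sparse.linalg import spsolve
from scipy.special import expit, logit

from .pedigree import Pedigree, build_A, build_A_inverse
from .modelspec import DesignBundle, RandomTerm

logger = logging.getLogger(__name__)


def _chol_inverse(cf) -> np.ndarray:
    """Symmetric inverse from an existing Cholesky factorization (dpotri)."""
    c, lower = cf
    inv, info = linalg.lapack.dpotri(c, lower=lower)
    if info != 0:
        raise FitError("dpotri failed")
    # dpotri fills one triangle only (the other keeps factor debris): mirror it
    half = np.tril(inv) if lower else np.triu(inv)
    return half + half.T - np.diag(np.diag(inv))


_VAR_FLOOR_REL = 1e-8  # variance floor relative to the phenotypic scale
_BEND_REL = 1e-8  # eigenvalue floor for bending C, relative to its trace


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# components container
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Variance components of one model fit, on its fitted scale.

    ``residual`` is a scalar (day-scale model), a per-month vector (repeated
    measures), or ``None`` (binomial GLMM, dispersion fixed at 1).
    ``scale`` records parameterization and response scale, e.g.
    ``"days/animal"`` or ``"monthly/sire-dam"``.
    """

    var_dge: float = 0.0
    var_ige: float = 0.0
    cov_dige: float = 0.0
    term_vars: dict = field(default_factory=dict)
    residual: object = None
    scale: str = ""

    def genetic_C(self) -> np.ndarray:
        return np.array(
            [[self.var_dge, self.cov_dige], [self.cov_dige, self.var_ige]]
        )

    def validate(self) -> None:
        C = self.genetic_C()
        if self.var_dge < 0 or self.var_ige < 0:
            raise FitError("negative genetic variance")
        if np.min(np.linalg.eigvalsh(C)) < -1e-8 * max(np.trace(C), 1e-300):
            raise FitError("genetic covariance matrix not PSD")


@dataclass
class FitResult:
    """REML/BLUP fit: components, solutions, and diagnostics."""

    components: VarianceComponents
    solutions: dict  # "fixed", "genetic_d", "genetic_i", and per-term arrays
    loglik: float
    converged: bool
    n_iter: int
    gradient_norm: float
    se_components: dict | None
    genetic_levels: np.ndarray | None
    genetic_pedigree: Pedigree | None
    fixed_names: list
    spec: object = None
    term_levels: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------


class _ParamLayout:
    """Maps between a flat theta vector and named components.

    Order: [c_dd, c_di, c_ii] (if a genetic pair is present), one variance
    per iid term (bundle order), then residual variances (1, or one per
    month, or none for fixed-weight residuals).
    """

    def __init__(self, bundle: DesignBundle, months_present=None):
        self.has_genetic = any(t.structure == "genetic_pair" for t in bundle.terms)
        self.iid_names = [t.name for t in bundle.terms if t.structure == "iid"]
        self.residual = bundle.residual
        self.months = list(months_present) if months_present is not None else None
        k = (3 if self.has_genetic else 0) + len(self.iid_names)
        if bundle.residual == "scalar":
            self.n_resid = 1
        elif bundle.residual == "per-month":
            self.n_resid = len(self.months)
        else:
            self.n_resid = 0
        self.size = k + self.n_resid
        self.resid_offset = k

    def pack(self, comp: VarianceComponents) -> np.ndarray:
        theta = []
        if self.has_genetic:
            theta += [comp.var_dge, comp.cov_dige, comp.var_ige]
        theta += [comp.term_vars[n] for n in self.iid_names]
        if self.n_resid == 1:
            theta.append(float(np.asarray(comp.residual).ravel()[0]))
        elif self.n_resid > 1:
            r = np.asarray(comp.residual, dtype=float).ravel()
            if r.size == 1:
                r = np.full(self.n_resid, r[0])
            theta += list(r)
        return np.asarray(theta, dtype=float)

    def unpack(self, theta: np.ndarray, scale: str = "") -> VarianceComponents:
        theta = np.asarray(theta, dtype=float)
        k = 0
        if self.has_genetic:
            dd, di, ii = theta[:3]
            k = 3
        else:
            dd = di = ii = 0.0
        term_vars = dict(zip(self.iid_names, theta[k : k + len(self.iid_names)]))
        resid = None
        if self.n_resid == 1:
            resid = float(theta[self.resid_offset])
        elif self.n_resid > 1:
            resid = theta[self.resid_offset :].copy()
        return VarianceComponents(
            var_dge=dd,
            var_ige=ii,
            cov_dige=di,
            term_vars=term_vars,
            residual=resid,
            scale=scale,
        )

    def is_variance(self) -> np.ndarray:
        """Mask of parameters constrained to be nonnegative."""
        mask = np.ones(self.size, dtype=bool)
        if self.has_genetic:
            mask[1] = False  # the covariance may be negative
        return mask


def _bend_C(C: np.ndarray) -> np.ndarray:
    """Floor the eigenvalues of the 2x2 genetic matrix to keep it PD."""
    w, V = np.linalg.eigh(C)
    floor = _BEND_REL * max(np.trace(C), 1e-300)
    if w[0] >= floor:
        return C
    logger.warning("bending genetic covariance matrix (min eig %.3g)", w[0])
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def _project(theta, layout: _ParamLayout, floor: float) -> np.ndarray:
    theta = np.asarray(theta, dtype=float).copy()
    mask = layout.is_variance()
    theta[mask] = np.maximum(theta[mask], floor)
    if layout.has_genetic:
        C = _bend_C(np.array([[theta[0], theta[1]], [theta[1], theta[2]]]))
        theta[0], theta[1], theta[2] = C[0, 0], C[0, 1], C[1, 1]
    return theta


# ---------------------------------------------------------------------------
# generic BLUP solver (plain sparse Henderson equations)
# ---------------------------------------------------------------------------


def _rinv_diag(bundle: DesignBundle, comp: VarianceComponents, weights=None):
    n = bundle.n_rows()
    if weights is not None:
        return np.asarray(weights, dtype=float)
    if bundle.residual == "scalar":
        return np.full(n, 1.0 / float(np.asarray(comp.residual).ravel()[0]))
    if bundle.residual == "per-month":
        r = np.asarray(comp.residual, dtype=float).ravel()
        months = np.sort(bundle.row_meta["month"].unique())
        if r.size == 1:
            r = np.full(len(months), r[0])
        lut = dict(zip(months, r))
        m = bundle.row_meta["month"].to_numpy()
        return np.asarray([1.0 / lut[mm] for mm in m])
    raise FitError("binomial bundles need explicit working weights")


def solve_blup(
    bundle: DesignBundle,
    components: VarianceComponents,
    weights: np.ndarray | None = None,
):
    """Solve Henderson's mixed-model equations at fixed variance components.

    G-side blocks are C^-1 (x) A^-1 for the genetic pair and I/sigma^2 for
    iid terms; the R-side is diagonal (scalar, per-month, or explicit
    working weights).  Returns a dict of solutions keyed ``"fixed"``,
    ``"genetic_d"``, ``"genetic_i"`` and each iid term's name.
    """
    rinv = _rinv_diag(bundle, components, weights)
    X = sparse.csr_matrix(bundle.X)
    blocks = [X]
    ginv_blocks = [None]
    names = []
    for t in bundle.terms:
        blocks.append(t.Z.tocsr())
        if t.structure == "genetic_pair":
            C = _bend_C(components.genetic_C())
            Cinv = np.linalg.inv(C)
            Ainv = build_A_inverse(t.pedigree).values
            ginv_blocks.append(sparse.kron(Cinv, Ainv, format="csr"))
            names.append("genetic")
        else:
            v = max(components.term_vars[t.name], 1e-300)
            ginv_blocks.append(sparse.identity(t.Z.shape[1], format="csr") / v)
            names.append(t.name)
    W = sparse.hstack(blocks, format="csc")
    Rw = sparse.diags(rinv)
    p = X.shape[1]
    Ginv = sparse.block_diag(
        [sparse.csr_matrix((p, p))] + ginv_blocks[1:], format="csc"
    )
    C_mme = (W.T @ Rw @ W) + Ginv
    rhs = W.T @ (rinv * bundle.y)
    sol = spsolve(C_mme.tocsc(), rhs)
    out = {"fixed": sol[: X.shape[1]]}
    off = X.shape[1]
    for t in bundle.terms:
        q = t.Z.shape[1]
        piece = sol[off : off + q]
        if t.structure == "genetic_pair":
            half = q // 2
            out["genetic_d"] = piece[:half]
            out["genetic_i"] = piece[half:]
        else:
            out[t.name] = piece
        off += q
    return out


# ---------------------------------------------------------------------------
# backend state
# ---------------------------------------------------------------------------


@dataclass
class _State:
    loglik: float
    trPV: np.ndarray
    yPVPy: np.ndarray
    AI: np.ndarray
    solutions: dict

    @property
    def score(self) -> np.ndarray:
        # d l_R / d theta_i = -1/2 (tr(P V_i) - y' P V_i P y)
        return -0.5 * (self.trPV - self.yPVPy)


def _genetic_split(term: RandomTerm):
    q = term.Z.shape[1] // 2
    Z = term.Z.tocsc()
    return Z[:, :q].tocsr(), Z[:, q:].tocsr(), q


class DenseVBackend:
    """REML via the explicit phenotypic covariance V = sum theta_i K_i.

    Restricted to bundles with a scalar residual.  All kernels K_i are
    precomputed once; each evaluation costs one Cholesky factorization and
    one explicit inverse of V.
    """

    def __init__(self, bundle: DesignBundle):
        if bundle.residual != "scalar":
            raise FitError("dense-V backend requires a scalar residual")
        self.bundle = bundle
        self.layout = _ParamLayout(bundle)
        self.n = bundle.n_rows()
        self.X = np.asarray(bundle.X, dtype=float)
        self.y = np.asarray(bundle.y, dtype=float)
        self.kernels = []  # aligned with theta
        self._genetic = None
        for t in bundle.terms:
            if t.structure == "genetic_pair":
                Zd, Zi, q = _genetic_split(t)
                A = build_A(t.pedigree).toarray()
                AZd = np.asarray((Zd @ A).T)  # q x n  (A Zd')
                AZi = np.asarray((Zi @ A).T)
                Kdd = np.asarray(Zd @ AZd)
                Kdi = np.asarray(Zd @ AZi)
                Kii = np.asarray(Zi @ AZi)
                self.kernels += [Kdd, Kdi + Kdi.T, Kii]
                self._genetic = (t, Zd, Zi, A, AZd, AZi)
        for t in bundle.terms:
            if t.structure == "iid":
                self.kernels.append((t.Z @ t.Z.T).tocsr())
        self.kernels.append(sparse.identity(self.n, format="csr"))
        self._terms_iid = [t for t in bundle.terms if t.structure == "iid"]
        # scatter indices for the sparse kernels (fast in-place V assembly)
        self._coo = {}
        for i, K in enumerate(self.kernels):
            if sparse.issparse(K):
                coo = K.tocoo()
                self._coo[i] = (coo.row, coo.col, coo.data)

    def compute(self, theta: np.ndarray, derivs: bool = True) -> _State:
        n, X, y = self.n, self.X, self.y
        V = np.zeros((n, n))
        for i, (th, K) in enumerate(zip(theta, self.kernels)):
            if i in self._coo:
                r, c, d = self._coo[i]
                V[r, c] += th * d
            else:
                V += th * K
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        p = self.layout.size
        if derivs:
            Vinv = _chol_inverse(cf)
            VinvX = Vinv @ X
        else:
            VinvX = linalg.cho_solve(cf, X, check_finite=False)
        XtVinvX = X.T @ VinvX
        cfx = linalg.cho_factor(XtVinvX, check_finite=False)
        logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        beta = linalg.cho_solve(cfx, VinvX.T @ y, check_finite=False)
        Vinvy = (
            Vinv @ y if derivs else linalg.cho_solve(cf, y, check_finite=False)
        )
        Py = Vinvy - VinvX @ beta
        yPy = float(y @ Py)
        loglik = -0.5 * (logdetV + logdetX + yPy)

        trPV = np.zeros(p)
        yPVPy = np.zeros(p)
        AI = np.eye(p)
        if derivs:
            P = Vinv - VinvX @ linalg.cho_solve(cfx, VinvX.T, check_finite=False)
            F = np.empty((n, p))
            for i, K in enumerate(self.kernels):
                if sparse.issparse(K):
                    trPV[i] = K.multiply(P).sum()
                    f = K @ Py
                else:
                    trPV[i] = float(np.sum(P * K))
                    f = K @ Py
                F[:, i] = f
                yPVPy[i] = float(Py @ f)
            PF = P @ F
            AI = 0.5 * (F.T @ PF)

        sols = {"fixed": beta, "_Py": Py}
        if self._genetic is not None:
            t, Zd, Zi, A, AZd, AZi = self._genetic
            vd = AZd @ Py  # A Zd' P y
            vi = AZi @ Py
            dd, di, ii = theta[:3]
            sols["genetic_d"] = dd * vd + di * vi
            sols["genetic_i"] = di * vd + ii * vi
        k = 3 if self._genetic is not None else 0
        for j, t in enumerate(self._terms_iid):
            sols[t.name] = theta[k + j] * np.asarray(t.Z.T @ Py).ravel()
        return _State(loglik=loglik, trPV=trPV, yPVPy=yPVPy, AI=AI, solutions=sols)


class AbsorbedBackend:
    """REML with cage-nested random terms absorbed into the residual.

    The residual covariance becomes block-diagonal with one block per cage;
    the mixed-model equations retain only the fixed effects, the genetic
    pair, and any iid term that is not nested within cages.
    ``weights`` (optional, per record) fix the base residual at diag(1/w)
    with no free residual parameter, as required by the PQL working model.
    """

    def __init__(self, bundle: DesignBundle, weights: np.ndarray | None = None):
        self.bundle = bundle
        n = bundle.n_rows()
        meta = bundle.row_meta.reset_index(drop=True)
        cages = meta["cage"].to_numpy()
        if bundle.residual == "per-month" or "month" in meta.columns:
            months = meta["month"].to_numpy() if "month" in meta.columns else None
        else:
            months = None
        order = np.lexsort(
            (months if months is not None else np.zeros(n), meta["id"].to_numpy(), cages)
        )
        self.perm = order
        self.y = np.asarray(bundle.y, dtype=float)[order]
        self.X = np.asarray(bundle.X, dtype=float)[order]
        self.months = months[order] if months is not None else None
        self.weights = (
            np.asarray(weights, dtype=float)[order] if weights is not None else None
        )
        cages_s = cages[order]
        # contiguous cage runs
        change = np.flatnonzero(np.diff(cages_s)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        sizes = ends - starts

        # partition terms: absorb iid terms nested within cages
        self.absorbed: list[RandomTerm] = []
        self.kept_iid: list[RandomTerm] = []
        self.genetic = None
        for t in bundle.terms:
            if t.structure == "genetic_pair":
                self.genetic = t
            elif t.absorbable and self._nested(t, cages):
                self.absorbed.append(t)
            else:
                self.kept_iid.append(t)

        if bundle.residual == "per-month":
            self.month_levels = np.sort(np.unique(self.months))
        else:
            self.month_levels = None
        self.layout = _ParamLayout(bundle, months_present=self.month_levels)

        # batched per-cage structures, grouped by block size
        self.groups = []
        for B in np.unique(sizes):
            sel = np.flatnonzero(sizes == B)
            idx2d = starts[sel][:, None] + np.arange(B)[None, :]
            group = {"B": int(B), "idx": idx2d}
            for t in self.absorbed:
                Zp = t.Z.tocsr()[order]
                U = self._local_dense(Zp, idx2d)
                group.setdefault("BT", []).append(
                    np.einsum("gbl,gcl->gbc", U, U, optimize=True)
                )
            self.groups.append(group)
        # sparse block pattern for R^-1 assembly
        rows, cols = [], []
        for g in self.groups:
            idx = g["idx"]
            rows.append(np.repeat(idx, g["B"], axis=1).ravel())
            cols.append(np.tile(idx, (1, g["B"])).ravel())
        self._blk_rows = np.concatenate(rows)
        self._blk_cols = np.concatenate(cols)

        # constant V_t = Z_t Z_t' for every term with a free variance
        self._vterm = []
        for t in self.absorbed + self.kept_iid:
            Zp = t.Z.tocsr()[order]
            self._vterm.append((t.name, Zp, (Zp @ Zp.T).tocsr()))

        # kept design W = [X, Z_genetic, kept iid]
        blocks = [sparse.csr_matrix(self.X)]
        self.slices = {"fixed": slice(0, self.X.shape[1])}
        off = self.X.shape[1]
        if self.genetic is not None:
            Zg = self.genetic.Z.tocsr()[order]
            self.Zg = Zg
            q = Zg.shape[1] // 2
            self.qg = q
            Zgc = Zg.tocsc()
            self.Zd = Zgc[:, :q].tocsr()
            self.Zi = Zgc[:, q:].tocsr()
            blocks.append(Zg)
            self.slices["genetic"] = slice(off, off + 2 * q)
            off += 2 * q
            self.A = build_A(self.genetic.pedigree).toarray()
            self.Ainv = build_A_inverse(self.genetic.pedigree).values
            F = self.genetic.pedigree.inbreeding()
            s, d = self.genetic.pedigree.sire_idx, self.genetic.pedigree.dam_idx
            dv = np.where(
                (s >= 0) & (d >= 0),
                0.5 - 0.25 * (F[np.maximum(s, 0)] + F[np.maximum(d, 0)]),
                np.where(
                    (s >= 0) | (d >= 0),
                    0.75 - 0.25 * F[np.maximum(np.maximum(s, d), 0)],
                    1.0,
                ),
            )
            self.logdetA = float(np.sum(np.log(dv)))
        else:
            self.Zg = None
        for t in self.kept_iid:
            q = t.Z.shape[1]
            blocks.append(t.Z.tocsr()[order])
            self.slices[t.name] = slice(off, off + q)
            off += q
        self.W = sparse.hstack(blocks, format="csr")
        self.K = off

    @staticmethod
    def _nested(term: RandomTerm, cages: np.ndarray) -> bool:
        Z = term.Z.tocsc()
        for j in range(Z.shape[1]):
            rows = Z.indices[Z.indptr[j] : Z.indptr[j + 1]]
            if len(rows) and len(np.unique(cages[rows])) > 1:
                return False
        return True

    @staticmethod
    def _local_dense(Zp: sparse.csr_matrix, idx2d: np.ndarray) -> np.ndarray:
        """Per-cage dense local incidence (G, B, L) with cage-local columns."""
        G, B = idx2d.shape
        mats = []
        L = 0
        locals_ = []
        for g in range(G):
            sub = Zp[idx2d[g]].toarray()
            cols = np.flatnonzero(np.abs(sub).sum(axis=0) > 0)
            locals_.append(sub[:, cols])
            L = max(L, len(cols))
        U = np.zeros((G, B, max(L, 1)))
        for g, m in enumerate(locals_):
            U[g, :, : m.shape[1]] = m
        return U

    # -- residual structure ------------------------------------------------

    def _base_diag(self, theta) -> np.ndarray:
        if self.weights is not None:
            return 1.0 / self.weights
        if self.bundle.residual == "scalar":
            return np.full(len(self.y), theta[self.layout.resid_offset])
        lut = dict(
            zip(
                self.month_levels,
                theta[self.layout.resid_offset :],
            )
        )
        return np.asarray([lut[m] for m in self.months])

    def compute(self, theta: np.ndarray, derivs: bool = True) -> _State:
        lay = self.layout
        n = len(self.y)
        k0 = 3 if lay.has_genetic else 0
        sigma_abs = theta[k0 : k0 + len(self.absorbed)]
        base = self._base_diag(theta)

        # batched residual blocks and their inverses
        logdetR = 0.0
        data = []
        diagRinv = np.empty(n)
        for g in self.groups:
            idx = g["idx"]
            G, B = idx.shape
            R = np.zeros((G, B, B))
            for s2, BT in zip(sigma_abs, g.get("BT", [])):
                R += s2 * BT
            R[:, np.arange(B), np.arange(B)] += base[idx]
            sign, ld = np.linalg.slogdet(R)
            if np.any(sign <= 0):
                raise FitError("residual block not positive definite")
            logdetR += float(ld.sum())
            Rinv = np.linalg.inv(R)
            g["_Rinv"] = Rinv
            diagRinv[idx.ravel()] = Rinv[:, np.arange(B), np.arange(B)].ravel()
            data.append(Rinv.ravel())
        Rinv_sp = sparse.coo_matrix(
            (np.concatenate(data), (self._blk_rows, self._blk_cols)), shape=(n, n)
        ).tocsr()

        # kept mixed-model equations
        Q = Rinv_sp @ self.W  # n x K sparse
        Ct = (self.W.T @ Q).toarray()
        logdetG = 0.0
        if lay.has_genetic:
            sl = self.slices["genetic"]
            ZRW = Ct[sl, :].copy()  # Zg' R^-1 W, before the G^-1 addition
            ZRZ = Ct[sl, sl].copy()
            Cg = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
            Cg = _bend_C(Cg)
            Cg_inv = np.linalg.inv(Cg)
            Ct[sl, sl] += sparse.kron(Cg_inv, self.Ainv).toarray()
            sign, ldc = np.linalg.slogdet(Cg)
            logdetG += self.qg * float(ldc) + 2.0 * self.logdetA
        for j, t in enumerate(self.kept_iid):
            v = theta[k0 + len(self.absorbed) + j]
            sl = self.slices[t.name]
            q = sl.stop - sl.start
            Ct[sl, sl] += np.eye(q) / v
            logdetG += q * np.log(v)
        cf = linalg.cho_factor(Ct, lower=True, check_finite=False)
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        rhs = np.asarray(Q.T @ self.y).ravel()
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        yRy = float(self.y @ (Rinv_sp @ self.y))
        yPy = yRy - float(sol @ rhs)
        loglik = -0.5 * (logdetR + logdetG + logdetC + yPy)

        resid = self.y - np.asarray(self.W @ sol).ravel()
        Py = np.asarray(Rinv_sp @ resid).ravel()

        # score pieces and AI right-hand vectors
        p = lay.size
        trPV = np.zeros(p)
        yPVPy = np.zeros(p)
        AI = np.eye(p)
        if not derivs:
            return self._finish(
                lay, theta, sol, Py, sigma_abs, loglik, trPV, yPVPy, AI
            )
        Cinv = _chol_inverse(cf)
        F = np.empty((n, p))
        pos = 0
        if lay.has_genetic:
            M = ZRZ - ZRW @ Cinv @ ZRW.T
            q = self.qg
            Mdd, Mdi, Mii = M[:q, :q], M[:q, q:], M[q:, q:]
            A = self.A
            trPV[0] = float(np.sum(A * Mdd))
            trPV[1] = 2.0 * float(np.sum(A * Mdi))
            trPV[2] = float(np.sum(A * Mii))
            v = np.asarray(self.Zg.T @ Py).ravel()
            vd, vi = v[:q], v[q:]
            Avd, Avi = A @ vd, A @ vi
            yPVPy[0] = float(vd @ Avd)
            yPVPy[1] = 2.0 * float(vd @ Avi)
            yPVPy[2] = float(vi @ Avi)
            F[:, 0] = np.asarray(self.Zd @ Avd).ravel()
            F[:, 1] = (
                np.asarray(self.Zd @ Avi).ravel()
                + np.asarray(self.Zi @ Avd).ravel()
            )
            F[:, 2] = np.asarray(self.Zi @ Avi).ravel()
            pos = 3
        for name, Zp, Vt in self._vterm:
            trR = float(Rinv_sp.multiply(Vt).sum())
            S = (Q.T @ (Vt @ Q)).toarray()
            trPV[pos] = trR - float(np.sum(Cinv * S))
            f = np.asarray(Vt @ Py).ravel()
            F[:, pos] = f
            yPVPy[pos] = float(Py @ f)
            pos += 1
        if lay.n_resid:
            Qc = Q.tocsr()
            for j in range(lay.n_resid):
                if self.bundle.residual == "scalar":
                    mask = np.ones(n, dtype=bool)
                else:
                    mask = self.months == self.month_levels[j]
                rows = np.flatnonzero(mask)
                trR = float(diagRinv[rows].sum())
                Qm = Qc[rows]
                S = (Qm.T @ Qm).toarray()
                trPV[pos] = trR - float(np.sum(Cinv * S))
                f = np.where(mask, Py, 0.0)
                F[:, pos] = f
                yPVPy[pos] = float(Py @ f)
                pos += 1

        # AI matrix: 1/2 F' P F with P f = R^-1(f - W C^-1 W' R^-1 f)
        G1 = Rinv_sp @ F
        H = np.asarray(self.W.T @ G1)
        S = linalg.cho_solve(cf, H, check_finite=False)
        PF = G1 - Rinv_sp @ (self.W @ S)
        AI = 0.5 * (F.T @ PF)
        return self._finish(lay, theta, sol, Py, sigma_abs, loglik, trPV, yPVPy, AI)

    def _finish(self, lay, theta, sol, Py, sigma_abs, loglik, trPV, yPVPy, AI):
        sols = {"fixed": sol[self.slices["fixed"]], "_Py": Py}
        if lay.has_genetic:
            g = sol[self.slices["genetic"]]
            sols["genetic_d"] = g[: self.qg]
            sols["genetic_i"] = g[self.qg :]
        for t in self.kept_iid:
            sols[t.name] = sol[self.slices[t.name]]
        for (name, Zp, _), s2 in zip(
            self._vterm[: len(self.absorbed)], sigma_abs
        ):
            sols[name] = s2 * np.asarray(Zp.T @ Py).ravel()
        return _State(loglik=loglik, trPV=trPV, yPVPy=yPVPy, AI=AI, solutions=sols)


# ---------------------------------------------------------------------------
# outer AI-REML loop with EM fallback
# ---------------------------------------------------------------------------


def _em_step(theta, state: _State, layout: _ParamLayout, qs: np.ndarray):
    """Expectation-maximization update written in projection form.

    Scalar components: s2' = s2 + (s2^2/q)(y'PVPy - tr(PV)); the genetic
    2x2 block uses the matrix analogue C' = C + C M C / q.  EM steps cannot
    decrease the REML log-likelihood, which makes them a safe fallback when
    the average-information update overshoots.
    """
    theta = theta.copy()
    m = state.yPVPy - state.trPV
    k0 = 0
    if layout.has_genetic:
        C = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        M = np.array([[m[0], m[1] / 2.0], [m[1] / 2.0, m[2]]])
        Cn = C + (C @ M @ C) / qs[0]
        theta[0], theta[1], theta[2] = Cn[0, 0], Cn[0, 1], Cn[1, 1]
        k0 = 3
    for i in range(k0, layout.size):
        theta[i] = theta[i] + theta[i] ** 2 * m[i] / qs[i]
    return theta


def _chol_pack(theta: np.ndarray, layout: _ParamLayout, lfloor: float) -> np.ndarray:
    """Map theta to the working scale: genetic block -> Cholesky factors.

    C = L L' with L = [[l11, 0], [l21, l22]] keeps the genetic matrix PSD
    for any l values, so average-information steps cannot propose an
    infeasible C (estimates pinned at the correlation bound simply drive
    l22 to its floor).
    """
    phi = theta.copy()
    if layout.has_genetic:
        dd, di, ii = theta[0], theta[1], theta[2]
        l11 = np.sqrt(max(dd, lfloor**2))
        l21 = di / l11
        l22 = np.sqrt(max(ii - l21**2, lfloor**2))
        phi[0], phi[1], phi[2] = l11, l21, l22
    return phi


def _chol_unpack(phi: np.ndarray, layout: _ParamLayout) -> np.ndarray:
    theta = phi.copy()
    if layout.has_genetic:
        l11, l21, l22 = phi[0], phi[1], phi[2]
        theta[0] = l11 * l11
        theta[1] = l11 * l21
        theta[2] = l21 * l21 + l22 * l22
    return theta


def _chol_jacobian(phi: np.ndarray, layout: _ParamLayout) -> np.ndarray:
    """d theta / d phi (identity outside the genetic block)."""
    J = np.eye(len(phi))
    if layout.has_genetic:
        l11, l21, l22 = phi[0], phi[1], phi[2]
        J[0, 0] = 2.0 * l11
        J[1, 0], J[1, 1] = l21, l11
        J[2, 1], J[2, 2] = 2.0 * l21, 2.0 * l22
    return J


def _param_counts(backend, layout: _ParamLayout) -> np.ndarray:
    qs = np.empty(layout.size)
    pos = 0
    if layout.has_genetic:
        if isinstance(backend, DenseVBackend):
            qg = backend._genetic[3].shape[0]
        else:
            qg = backend.qg
        qs[0:3] = qg
        pos = 3
    bundle = backend.bundle
    if isinstance(backend, AbsorbedBackend):
        iid_terms = backend.absorbed + backend.kept_iid
    else:
        iid_terms = [t for t in bundle.terms if t.structure == "iid"]
    for t in iid_terms:
        qs[pos] = t.Z.shape[1]
        pos += 1
    n = bundle.n_rows()
    if layout.n_resid == 1:
        qs[pos] = n
    elif layout.n_resid > 1:
        months = backend.months
        for j, m in enumerate(backend.month_levels):
            qs[pos + j] = int(np.sum(months == m))
    return qs


def _select_backend(bundle: DesignBundle, weights=None):
    p = bundle.X.shape[1]
    q2 = sum(t.Z.shape[1] for t in bundle.terms if t.structure == "genetic_pair")
    kept_iid = sum(
        t.Z.shape[1]
        for t in bundle.terms
        if t.structure == "iid" and not t.absorbable
    )
    K = p + q2 + kept_iid
    dense_ok = weights is None and bundle.residual == "scalar"
    # the dense-V strategy wins whenever the record count is modest relative
    # to the genetic dimension (animal-model day-scale fits); the absorbed
    # strategy wins when the kept equations are compact (sire-dam fits)
    if dense_ok and (bundle.n_rows() <= 2500 or K > 2500):
        if bundle.n_rows() <= 8000:
            return DenseVBackend(bundle)
        raise FitError(
            "problem too large for both REML strategies "
            f"(kept dimension {K}, records {bundle.n_rows()})"
        )
    if K <= 2500 or not dense_ok:
        return AbsorbedBackend(bundle, weights=weights)
    return DenseVBackend(bundle)


def default_start(bundle: DesignBundle) -> VarianceComponents:
    """Heuristic starting components from fixed-effects-only residuals."""
    X, y = np.asarray(bundle.X, dtype=float), np.asarray(bundle.y, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    vp = max(float(np.var(r)), 1e-12)
    has_gen = any(t.structure == "genetic_pair" for t in bundle.terms)
    term_vars = {}
    if bundle.residual in ("scalar",):
        dge, ige = 0.10 * vp, 0.02 * vp
        for t in bundle.terms:
            if t.structure == "iid":
                term_vars[t.name] = 0.10 * vp
        resid = (
            vp * (1.0 - 0.12 * has_gen - 0.10 * len(term_vars))
        )
        return VarianceComponents(
            var_dge=dge if has_gen else 0.0,
            var_ige=ige if has_gen else 0.0,
            cov_dige=0.0,
            term_vars=term_vars,
            residual=max(resid, 0.1 * vp),
        )
    # monthly models: scale slope-type variances by the last-month covariate
    months = bundle.row_meta["month"].to_numpy()
    last = months == months.max()
    v_last = max(float(np.var(r[last])), 1e-12)
    wq = 0.0
    for t in bundle.terms:
        if t.structure == "genetic_pair":
            wq = max(
                float(np.max(np.abs(t.Z[np.flatnonzero(last)].toarray())))
                if t.Z.shape[0]
                else 1.0,
                1e-6,
            )
    wq = wq if wq > 0 else 1.0
    dge = 0.05 * v_last / wq**2
    ige = 0.01 * v_last / wq**2
    for t in bundle.terms:
        if t.structure == "iid":
            if t.name in ("cage_slope", "pe"):
                term_vars[t.name] = 0.05 * v_last / wq**2
            else:
                term_vars[t.name] = 0.05 * vp
    if bundle.residual == "per-month":
        resid = []
        for m in np.sort(np.unique(months)):
            resid.append(max(0.5 * float(np.var(r[months == m])), 1e-10))
        resid = np.asarray(resid)
    else:
        resid = None
    return VarianceComponents(
        var_dge=dge, var_ige=ige, cov_dige=0.0, term_vars=term_vars, residual=resid
    )


def reml_fit(
    bundle: DesignBundle,
    start: VarianceComponents | None = None,
    weights: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-8,
    rtol: float = 1e-6,
    scale_tag: str = "",
) -> FitResult:
    """Average-information REML with EM fallback.

    Iterates AI updates with step-halving; when an AI proposal leaves the
    parameter space or fails to improve the restricted likelihood, an EM
    step (monotone by construction) is taken instead.  Convergence when the
    likelihood change is below ``tol`` and the relative parameter change
    below ``rtol``.  Variances are kept nonnegative and the genetic matrix
    PSD by projection and bending; a fit hitting ``max_iter`` returns the
    best iterate flagged as non-converged.
    """
    backend = _select_backend(bundle, weights=weights)
    layout = backend.layout
    if start is None:
        start = default_start(bundle)
    theta = layout.pack(start)
    vp = max(float(np.var(bundle.y)), 1e-300)
    floor = _VAR_FLOOR_REL * vp
    theta = _project(theta, layout, floor)
    qs = _param_counts(backend, layout)

    lfloor = np.sqrt(floor)
    state = backend.compute(theta, derivs=max_iter > 0)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        phi = _chol_pack(theta, layout, lfloor)
        J = _chol_jacobian(phi, layout)
        score = J.T @ state.score
        AI = J.T @ state.AI @ J
        # freeze parameters stuck at their floor with an outward gradient
        lower = np.full(layout.size, -np.inf)
        lower[layout.is_variance()] = floor
        if layout.has_genetic:
            lower[0] = lower[2] = lfloor
        at_floor = (phi <= lower * 4) & (score < 0) & np.isfinite(lower)

        def ai_delta(free):
            delta = np.zeros_like(phi)
            if free.any():
                Af = AI[np.ix_(free, free)]
                Af = Af + 1e-8 * np.eye(Af.shape[0]) * max(np.trace(Af), 1.0)
                try:
                    delta[free] = np.linalg.solve(Af, score[free])
                except np.linalg.LinAlgError:
                    delta[free] = score[free] / np.maximum(np.diag(Af), 1e-12)
            return delta

        def try_step(delta, max_halve=6):
            step = 1.0
            for _ in range(max_halve):
                cand_phi = np.maximum(phi + step * delta, lower)
                cand = _project(_chol_unpack(cand_phi, layout), layout, floor)
                try:
                    st = backend.compute(cand)
                except FitError:
                    step *= 0.5
                    continue
                if st.loglik >= state.loglik - 1e-10:
                    return cand, st
                step *= 0.5
            return None

        # fallback ladder: full AI step; AI step with the (often nearly
        # singular) genetic block frozen; monotone EM step
        delta_free = ai_delta(~at_floor)
        # Newton decrement: expected likelihood gain of the full AI step;
        # guards against declaring convergence on a stalled fallback step
        newton_gain = 0.5 * float(score @ delta_free)
        accepted = try_step(delta_free)
        if accepted is None and layout.has_genetic:
            free = ~at_floor
            free[:3] = False
            accepted = try_step(ai_delta(free))
        if accepted is None:
            cand = _project(_em_step(theta, state, layout, qs), layout, floor)
            st = backend.compute(cand)
            accepted = (cand, st)
        new_theta, new_state = accepted
        dl = new_state.loglik - state.loglik
        dp = np.max(
            np.abs(new_theta - theta) / np.maximum(np.abs(theta), floor * 10)
        )
        theta, state = new_theta, new_state
        if abs(dl) < tol and dp < rtol and newton_gain < 50 * tol:
            converged = True
            break
    if not converged and max_iter > 0:
        logger.warning("REML did not converge in %d iterations", max_iter)

    comp = layout.unpack(theta, scale=scale_tag)
    se = None
    try:
        AIinv = np.linalg.inv(
            state.AI + 1e-10 * np.eye(layout.size) * max(np.trace(state.AI), 1.0)
        )
        names = []
        if layout.has_genetic:
            names += ["var_dge", "cov_dige", "var_ige"]
        names += list(layout.iid_names)
        if layout.n_resid == 1:
            names += ["residual"]
        elif layout.n_resid > 1:
            names += [f"residual_m{m}" for m in backend.month_levels]
        se = dict(zip(names, np.sqrt(np.maximum(np.diag(AIinv), 0.0))))
    except np.linalg.LinAlgError:
        pass

    gterm = next((t for t in bundle.terms if t.structure == "genetic_pair"), None)
    sols = {k: v for k, v in state.solutions.items() if not k.startswith("_")}
    return FitResult(
        components=comp,
        solutions=sols,
        loglik=state.loglik,
        converged=converged,
        n_iter=n_iter,
        gradient_norm=float(np.linalg.norm(state.score)),
        se_components=se,
        genetic_levels=gterm.levels if gterm is not None else None,
        genetic_pedigree=gterm.pedigree if gterm is not None else None,
        fixed_names=bundle.fixed_names,
        spec=bundle.spec,
        term_levels={
            t.name: t.levels for t in bundle.terms if t.structure == "iid"
        },
    )


# ---------------------------------------------------------------------------
# PQL for the logit GLMM
# ---------------------------------------------------------------------------


def glmm_pql_fit(
    bundle: DesignBundle,
    start: VarianceComponents | None = None,
    max_outer: int = 30,
    tol: float = 1e-6,
    **reml_kw,
) -> FitResult:
    """Penalized quasi-likelihood fit of the logit GLMM.

    Repeats: linearize the logit link around the current linear predictor,
    build the working response z = eta + (y - mu)/w with binomial weights
    w = mu(1 - mu), REML-fit the working linear mixed model (dispersion
    fixed at 1), and update eta from its solutions; stops when the linear
    predictor changes by less than ``tol``.  Working weights are clamped
    below to guard against separation.
    """
    y = np.asarray(bundle.y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise FitError("GLMM requires a 0/1 response")
    mu = np.clip((y + 0.5) / 2.0, 0.05, 0.95)
    eta = logit(mu)
    comp = start
    fit = None
    tag = "logit/" + (bundle.spec.parameterization if bundle.spec else "")
    inner_kw = dict(reml_kw)
    full_inner = inner_kw.pop("max_iter", 60)
    converged = False
    for outer in range(max_outer):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-6, None)
        z = eta + (y - mu) / w
        working = replace(bundle, y=z)
        # a few REML iterations per linearization suffice until the last pass
        fit = reml_fit(
            working,
            start=comp,
            weights=w,
            scale_tag=tag,
            max_iter=min(8, full_inner),
            **inner_kw,
        )
        comp = fit.components
        eta_new = _linear_predictor(working, fit)
        change = float(np.max(np.abs(eta_new - eta)))
        eta = eta_new
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("PQL did not converge in %d outer iterations", max_outer)
    if full_inner > 8:
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-6, None)
        z = eta + (y - mu) / w
        working = replace(bundle, y=z)
        fit = reml_fit(
            working, start=comp, weights=w, scale_tag=tag,
            max_iter=full_inner, **inner_kw,
        )
    if not converged:
        fit = replace(fit, converged=False)
    return fit


def _linear_predictor(bundle: DesignBundle, fit: FitResult) -> np.ndarray:
    eta = np.asarray(bundle.X, dtype=float) @ fit.solutions["fixed"]
    for t in bundle.terms:
        if t.structure == "genetic_pair":
            u = np.concatenate(
                [fit.solutions["genetic_d"], fit.solutions["genetic_i"]]
            )
        else:
            u = fit.solutions[t.name]
        eta = eta + np.asarray(t.Z @ u).ravel()
    return eta


def fit_model(
    table,
    pedigree: Pedigree,
    spec,
    start: VarianceComponents | None = None,
    **kw,
) -> FitResult:
    """Build the design for ``spec`` and fit it (REML, or PQL for the GLMM)."""
    from .modelspec import build_design

    bundle = build_design(spec, table, pedigree)
    tag = f"{spec.coding}/{spec.parameterization}/{spec.model_id}"
    if spec.model_id == "GLMM":
        fit = glmm_pql_fit(bundle, start=start, **kw)
    else:
        fit = reml_fit(bundle, start=start, scale_tag=tag, **kw)
    fit.components.scale = tag
    return fit


# ---------------------------------------------------------------------------
# EBV extraction
# ---------------------------------------------------------------------------


def extract_ebv(
    fit: FitResult, pedigree: Pedigree, ids, parameterization: str | None = None
) -> pd.DataFrame:
    """Per-individual (A_D, A_I) EBV from a fit.

    Animal parameterization: direct read of the solution entries; ids
    absent from the fitted levels (e.g. validation individuals whose
    records were removed) receive the parental average, which is their
    exact BLUP when they have no records or descendants.  Sire-dam
    parameterization: the sum of the sire and dam solutions, again the
    parental prediction of the offspring's breeding value.
    """
    if parameterization is None:
        parameterization = fit.spec.parameterization if fit.spec else "animal"
    ids = np.asarray(ids)
    levels = fit.genetic_levels
    pos = {i: k for k, i in enumerate(levels)}
    ud, ui = fit.solutions["genetic_d"], fit.solutions["genetic_i"]
    idx = pedigree.index_of(ids)

    def value(i, depth=0):
        if i in pos:
            k = pos[i]
            return ud[k], ui[k]
        if depth > 50:
            return 0.0, 0.0
        k = pedigree.index_of([i])[0]
        out_d = out_i = 0.0
        for p in (pedigree.sire_idx[k], pedigree.dam_idx[k]):
            if p >= 0:
                d, ii = value(pedigree.ids[p], depth + 1)
                out_d += 0.5 * d
                out_i += 0.5 * ii
        return out_d, out_i

    rows = []
    if parameterization == "animal":
        for i in ids:
            d, ii = value(i)
            rows.append((i, d, ii))
    else:
        s_i, d_i = pedigree.sire_idx[idx], pedigree.dam_idx[idx]
        if np.any(s_i < 0) or np.any(d_i < 0):
            raise FitError("sire-dam EBV needs known parents for every id")
        for i, s, d in zip(ids, pedigree.ids[s_i], pedigree.ids[d_i]):
            sd, si = value(s)
            dd, di = value(d)
            rows.append((i, sd + dd, si + di))
    return pd.DataFrame(rows, columns=["id", "ebv_d", "ebv_i"])
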