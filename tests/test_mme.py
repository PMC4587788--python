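import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import cagesurv as cs
from cagesurv import mme
from cagesurv.modelspec import DesignBundle, ModelSpec, RandomTerm
from cagesurv.pedigree import build_A

from conftest import days_only_table, random_pedigree


# ---------------------------------------------------------------------------
# independent dense oracle: GLS + conditional means on the full V
# ---------------------------------------------------------------------------


def dense_oracle(bundle, comp, weights=None):
    """BLUP by explicit inversion of the phenotypic covariance matrix."""
    n = bundle.n_rows()
    if weights is not None:
        R = np.diag(1.0 / np.asarray(weights))
    elif bundle.residual == "scalar":
        R = float(np.ravel(comp.residual)[0]) * np.eye(n)
    else:
        months = np.sort(bundle.row_meta["month"].unique())
        lut = dict(zip(months, np.ravel(comp.residual)))
        R = np.diag([lut[m] for m in bundle.row_meta["month"]])
    V = R.copy()
    parts = []
    for t in bundle.terms:
        Z = t.Z.toarray()
        if t.structure == "genetic_pair":
            A = build_A(t.pedigree).toarray()
            G = np.kron(comp.genetic_C(), A)
        else:
            G = comp.term_vars[t.name] * np.eye(Z.shape[1])
        V += Z @ G @ Z.T
        parts.append((t, Z, G))
    X = np.asarray(bundle.X, dtype=float)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ bundle.y)
    r = Vi @ (bundle.y - X @ beta)
    out = {"fixed": beta}
    for t, Z, G in parts:
        u = G @ Z.T @ r
        if t.structure == "genetic_pair":
            q = Z.shape[1] // 2
            out["genetic_d"], out["genetic_i"] = u[:q], u[q:]
        else:
            out[t.name] = u
    return out


def random_dge_ige_instance(seed, n_cages=6, cage_size=4):
    """Small random day-scale DGE-IGE dataset (<= 50 records)."""
    rng = np.random.default_rng(seed)
    n_hens = n_cages * cage_size
    ped = random_pedigree(n_hens + 12, seed=seed + 100, n_founders=12)
    hens = ped.ids[-n_hens:]
    rows = []
    for c in range(n_cages):
        for j in range(cage_size):
            rows.append(
                dict(
                    id=int(hens[c * cage_size + j]),
                    cage=c + 1,
                    class_id=f"k{c % 2}",
                    days=float(300 + 40 * rng.standard_normal()),
                    censored=False,
                )
            )
    table = days_only_table(pd.DataFrame(rows))
    bundle = cs.build_design(ModelSpec("STM"), table, ped)
    comp = cs.VarianceComponents(
        var_dge=1.0 + rng.random(),
        var_ige=0.3 + 0.3 * rng.random(),
        cov_dige=0.2 * rng.standard_normal(),
        term_vars={"cage": 0.5 + rng.random()},
        residual=2.0 + rng.random(),
    )
    return bundle, comp


@pytest.mark.parametrize("seed", range(6))
def test_blup_matches_dense_oracle(seed):
    """Sparse MME solutions equal explicit-V GLS/conditional means (1e-8)."""
    bundle, comp = random_dge_ige_instance(seed)
    sols = cs.solve_blup(bundle, comp)
    oracle = dense_oracle(bundle, comp)
    for key in oracle:
        assert np.abs(sols[key] - oracle[key]).max() < 1e-8


@pytest.mark.parametrize("backend_cls", [mme.DenseVBackend, mme.AbsorbedBackend])
def test_backends_match_oracle_and_each_other(backend_cls):
    """Both REML strategies reproduce the oracle solutions and agree on the
    restricted likelihood."""
    bundle, comp = random_dge_ige_instance(17)
    be = backend_cls(bundle)
    theta = be.layout.pack(comp)
    st = be.compute(theta)
    oracle = dense_oracle(bundle, comp)
    for key in oracle:
        assert np.abs(st.solutions[key] - oracle[key]).max() < 1e-8
    other = (
        mme.AbsorbedBackend(bundle)
        if backend_cls is mme.DenseVBackend
        else mme.DenseVBackend(bundle)
    )
    st2 = other.compute(theta)
    assert st.loglik == pytest.approx(st2.loglik, abs=1e-9)
    assert np.abs(st.score - st2.score).max() < 1e-8
    assert np.abs(st.AI - st2.AI).max() / max(np.abs(st.AI).max(), 1) < 1e-10


def test_shrinkage_limit():
    """As every random variance -> 0 the random solutions vanish and the
    fixed solutions approach GLS (= OLS for iid residual)."""
    bundle, comp = random_dge_ige_instance(3)
    tiny = cs.VarianceComponents(
        var_dge=1e-10, var_ige=1e-10, cov_dige=0.0,
        term_vars={"cage": 1e-10}, residual=float(np.ravel(comp.residual)[0]),
    )
    sols = cs.solve_blup(bundle, tiny)
    assert np.abs(sols["genetic_d"]).max() < 1e-6
    assert np.abs(sols["cage"]).max() < 1e-6
    X = np.asarray(bundle.X)
    beta_ols, *_ = np.linalg.lstsq(X, bundle.y, rcond=None)
    assert np.abs(sols["fixed"] - beta_ols).max() < 1e-6


def one_way_bundle(n_groups=40, per=10, var_u=2.0, var_e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    u = np.sqrt(var_u) * rng.standard_normal(n_groups)
    y = np.repeat(u, per) + np.sqrt(var_e) * rng.standard_normal(n_groups * per) + 5.0
    groups = np.repeat(np.arange(n_groups), per)
    from scipy import sparse

    Z = sparse.csr_matrix(
        (np.ones(len(y)), (np.arange(len(y)), groups)),
        shape=(len(y), n_groups),
    )
    term = RandomTerm(name="group", Z=Z, levels=np.arange(n_groups),
                      structure="iid", absorbable=True)
    meta = pd.DataFrame({"id": np.arange(len(y)), "cage": groups,
                         "class_id": "all"})
    return DesignBundle(
        model_id="STM", spec=None, y=y, X=np.ones((len(y), 1)), terms=[term],
        row_meta=meta, residual="scalar", fixed_names=["mu"],
    ), groups


def test_balanced_one_way_blup_closed_form():
    """BLUP of a balanced one-way layout equals shrunken group means."""
    bundle, groups = one_way_bundle()
    var_u, var_e, per = 2.0, 1.0, 10
    comp = cs.VarianceComponents(term_vars={"group": var_u}, residual=var_e)
    sols = cs.solve_blup(bundle, comp)
    mu = sols["fixed"][0]
    shrink = var_u / (var_u + var_e / per)
    gm = pd.Series(bundle.y).groupby(groups).mean().to_numpy()
    assert np.allclose(sols["group"], shrink * (gm - mu), atol=1e-8)


def test_balanced_one_way_reml_equals_anova():
    """REML estimates in the balanced one-way design equal the classical
    ANOVA estimators sigma2_e = MSE and sigma2_u = (MSB - MSE)/n."""
    bundle, groups = one_way_bundle(n_groups=60, per=8, seed=4)
    fit = mme.reml_fit(bundle, tol=1e-10)
    y = bundle.y
    per = 8
    gm = pd.Series(y).groupby(groups).mean().to_numpy()
    mse = sum(
        ((y[groups == g] - gm[g]) ** 2).sum() for g in range(60)
    ) / (60 * (per - 1))
    msb = per * ((gm - y.mean()) ** 2).sum() / (60 - 1)
    assert fit.converged
    assert float(np.ravel(fit.components.residual)[0]) == pytest.approx(mse, rel=1e-5)
    assert fit.components.term_vars["group"] == pytest.approx(
        (msb - mse) / per, rel=1e-4
    )


def test_reml_recovery_one_variance():
    """sigma2_u / sigma2_e = 1 at 10^4 records: recovery within 3 SE."""
    bundle, _ = one_way_bundle(n_groups=1000, per=10, var_u=1.0, var_e=1.0, seed=7)
    fit = mme.reml_fit(bundle)
    assert fit.converged
    se_u = fit.se_components["group"]
    se_e = fit.se_components["residual"]
    assert abs(fit.components.term_vars["group"] - 1.0) < 3 * se_u
    assert abs(float(np.ravel(fit.components.residual)[0]) - 1.0) < 3 * se_e


def test_em_steps_monotone():
    """EM fallback updates never decrease the restricted likelihood."""
    bundle, comp = random_dge_ige_instance(23)
    be = mme.AbsorbedBackend(bundle)
    lay = be.layout
    theta = lay.pack(comp) * 2.5  # start well away from the optimum
    qs = mme._param_counts(be, lay)
    st = be.compute(theta)
    for _ in range(25):
        theta = mme._project(
            mme._em_step(theta, st, lay, qs), lay, 1e-12
        )
        new = be.compute(theta)
        assert new.loglik >= st.loglik - 1e-9
        st = new


def test_reml_loglik_agrees_with_direct_formula():
    """The engine's restricted likelihood matches the textbook expression
    -1/2 (log|V| + log|X'V^-1 X| + y'Py) computed densely."""
    bundle, comp = random_dge_ige_instance(31)
    be = mme.AbsorbedBackend(bundle)
    st = be.compute(be.layout.pack(comp))
    # direct dense computation
    n = bundle.n_rows()
    R = float(np.ravel(comp.residual)[0]) * np.eye(n)
    V = R
    for t in bundle.terms:
        Z = t.Z.toarray()
        if t.structure == "genetic_pair":
            G = np.kron(comp.genetic_C(), build_A(t.pedigree).toarray())
        else:
            G = comp.term_vars[t.name] * np.eye(Z.shape[1])
        V = V + Z @ G @ Z.T
    X = np.asarray(bundle.X)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ bundle.y)
    r = bundle.y - X @ beta
    ll = -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + float(r @ Vi @ r)
    )
    assert st.loglik == pytest.approx(ll, abs=1e-8)


class TestPQL:
    def test_glm_reduction(self, small_sim):
        """With random variances pinned near zero, PQL reduces to a GLM:
        fitted monthly survival equals observed monthly survival."""
        table, ped = small_sim["table"], small_sim["pedigree"]
        bundle = cs.build_design(ModelSpec("GLMM"), table, ped)
        tiny = cs.VarianceComponents(
            var_dge=1e-10, var_ige=1e-10, cov_dige=0.0,
            term_vars={"cage_month": 1e-10, "pe": 1e-10}, residual=None,
        )
        fit = mme.glmm_pql_fit(bundle, start=tiny, max_iter=0)
        eta = bundle.X @ fit.solutions["fixed"]
        frame = bundle.row_meta.copy()
        frame["p"] = expit(eta)
        frame["y"] = bundle.y
        agg = frame.groupby(["class_id", "month"])[["p", "y"]].mean()
        # degree-6 polynomial on 13 months is flexible but not saturated
        assert np.abs(agg["p"] - agg["y"]).max() < 0.05

    def test_requires_binary_response(self, gaussian_days_sim):
        bundle = cs.build_design(
            ModelSpec("STM"), gaussian_days_sim["table"],
            gaussian_days_sim["pedigree"],
        )
        with pytest.raises(mme.FitError):
            mme.glmm_pql_fit(bundle)

    def test_recovers_genetic_scale_roughly(self):
        """PQL on data generated from the GLMM's own form (independent
        Bernoulli months, logit link) recovers the logit DGE variance up to
        the known downward PQL attenuation for binary data."""
        truth_var = 0.8
        ests = []
        for rep in range(3):
            cfg = cs.SimConfig(
                n_sires=24, dams_per_sire=6, offspring_per_dam=6,
                n_generations=2, n_batches=1, layout=((2, 2),), seed=80 + rep,
            )
            ped, cages = cs.generate_population(cfg)
            rng = np.random.default_rng(200 + rep)
            eff = cs.draw_genetic_effects(
                ped, np.diag([truth_var, 0.0]), rng
            )
            member_cols = [f"member{j}" for j in (1, 2, 3, 4)]
            members = cages[member_cols].to_numpy()
            idx = ped.index_of(members.ravel()).reshape(members.shape)
            eta0 = 1.0 + eff[idx, 0]
            rows = []
            T = 13
            for m in range(1, T + 1):
                y = (rng.random(members.shape) < expit(eta0)).astype(int)
                for c in range(members.shape[0]):
                    ms = [int(x) for x in members[c]]
                    for j, i in enumerate(ms):
                        rows.append(dict(
                            id=i, cage=int(cages["cage"].iloc[c]),
                            class_id=cages["class_id"].iloc[c], month=m,
                            value=int(y[c, j]),
                            alive_mates=tuple(x for x in ms if x != i),
                        ))
            days = pd.DataFrame([
                dict(id=int(i), cage=0, class_id="x", days=0.0, censored=False)
                for i in members.ravel()
            ])
            table = cs.SurvivalTable(monthly=pd.DataFrame(rows), days=days, months=T)
            fit = cs.fit_model(table, ped, ModelSpec("GLMM"), tol=1e-6)
            ests.append(4.0 * fit.components.var_dge)  # sire-dam -> animal
        mean = float(np.mean(ests))
        # PQL is known to shrink binary-data variances; allow 0.5x..1.3x
        assert 0.5 * truth_var < mean < 1.3 * truth_var


class TestExtractEBV:
    def test_animal_mode_reads_solutions(self, gaussian_days_sim):
        ped = gaussian_days_sim["pedigree"]
        bundle = cs.build_design(
            ModelSpec("STM"), gaussian_days_sim["table"], ped
        )
        comp = cs.VarianceComponents(
            var_dge=784.0, var_ige=100.0, cov_dige=57.0,
            term_vars={"cage": 1000.0}, residual=9365.0,
        )
        sols = cs.solve_blup(bundle, comp)
        gterm = bundle.terms[0]
        fit = mme.FitResult(
            components=comp, solutions=sols, loglik=0.0, converged=True,
            n_iter=1, gradient_norm=0.0, se_components=None,
            genetic_levels=gterm.levels, genetic_pedigree=gterm.pedigree,
            fixed_names=bundle.fixed_names, spec=bundle.spec,
        )
        ids = gaussian_days_sim["days"]["id"].to_numpy()[:10]
        ebv = cs.extract_ebv(fit, ped, ids)
        pos = {i: k for k, i in enumerate(gterm.levels)}
        for i, d, ii in ebv.itertuples(index=False):
            assert d == pytest.approx(sols["genetic_d"][pos[i]])
            assert ii == pytest.approx(sols["genetic_i"][pos[i]])

    def test_full_sibs_identical_sire_dam_ebv(self, gaussian_days_sim):
        ped = gaussian_days_sim["pedigree"]
        spec = ModelSpec("STM", parameterization="sire-dam")
        fit = cs.fit_model(
            gaussian_days_sim["table"], ped, spec, tol=1e-6
        )
        days = gaussian_days_sim["days"]
        idx = ped.index_of(days["id"].to_numpy())
        fam = pd.DataFrame(
            {
                "id": days["id"].to_numpy(),
                "key": [
                    (ped.sire_idx[k], ped.dam_idx[k]) for k in idx
                ],
            }
        )
        ebv = cs.extract_ebv(fit, ped, fam["id"]).set_index("id")
        for _, grp in fam.groupby("key"):
            vals = ebv.loc[grp["id"], "ebv_d"].to_numpy()
            assert np.allclose(vals, vals[0])
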