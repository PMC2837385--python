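"""Per-probe mixed-model fits, BIC stepwise search, association matrix."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from bloodvar.containers import AnnotationTable, BloodvarError
from bloodvar.model_selection import (
    CandidatePool,
    MixedModelWorkspace,
    build_association_matrix,
    fit_mixed_bic,
    forward_backward_select,
    unique_biological,
)

from conftest import make_annotations, make_expr


def small_pool(fixed=("smoking", "bmi_class", "fasting"), random=()):
    return CandidatePool(
        fixed_candidates=list(fixed), random_candidates=list(random), hierarchy={}
    )


def make_design(n, seed, lots=4, dates=0):
    r = np.random.default_rng(seed)
    cols = dict(
        smoking=r.binomial(1, 0.3, n),
        bmi_class=r.binomial(1, 0.5, n),
        fasting=r.binomial(1, 0.2, n),
    )
    if lots:
        cols["array_lot"] = r.choice([f"L{i}" for i in range(lots)], n)
    if dates:
        cols["extraction_date"] = r.choice([f"D{i}" for i in range(dates)], n)
    return make_annotations(**cols)


class TestFit:
    def test_fixed_only_bic_matches_hand_computation(self):
        # 6-sample toy, intercept + one binary covariate
        y = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        ann = make_annotations(smoking=np.array([0, 0, 0, 1, 1, 1]))
        pool = small_pool(fixed=("smoking",))
        m = fit_mixed_bic(y, {"smoking"}, set(), ann, pool=pool)

        X = np.column_stack([np.ones(6), ann.data["smoking"]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        ll = -0.5 * 6 * (np.log(2 * np.pi) + 1 + np.log(rss / 6))
        assert m.loglik == pytest.approx(ll, abs=1e-8)
        assert m.bic == pytest.approx(-2 * ll + 3 * np.log(6), abs=1e-8)
        assert m.n_params == 3

    def test_degenerate_random_component_shrinks_to_zero(self):
        r = np.random.default_rng(2)
        n = 60
        ann = make_design(n, 2, lots=3)
        pool = small_pool(random=("array_lot",))
        y = r.normal(5.0, 1.0, n)  # no group structure
        m = fit_mixed_bic(y, set(), {"array_lot"}, ann, pool=pool)
        assert m.variance_ratios["array_lot"] < 0.05

    def test_balanced_one_way_matches_closed_form_ml(self):
        # balanced one-way layout: the profile likelihood has a closed form
        # in (SSW, SSB); optimize that form directly as an oracle
        r = np.random.default_rng(3)
        a, m_per = 5, 8
        n = a * m_per
        groups = np.repeat([f"L{i}" for i in range(a)], m_per)
        ann = make_annotations(array_lot=groups, smoking=r.binomial(1, 0.5, n))
        eff = r.normal(0, 1.2, a)
        y = 4.0 + np.repeat(eff, m_per) + r.normal(0, 0.7, n)

        pool = small_pool(fixed=("smoking",), random=("array_lot",))
        fit = fit_mixed_bic(y, set(), {"array_lot"}, ann, pool=pool)

        gm = y.mean()
        means = y.reshape(a, m_per).mean(axis=1)
        ssw = float(np.sum((y.reshape(a, m_per) - means[:, None]) ** 2))
        ssb = float(m_per * np.sum((means - gm) ** 2))

        def neg_ll(params):
            se2, sb2 = np.exp(params)
            lam = se2 + m_per * sb2
            return 0.5 * (
                n * np.log(2 * np.pi)
                + (n - a) * np.log(se2)
                + a * np.log(lam)
                + ssw / se2
                + ssb / lam
            )

        res = optimize.minimize(neg_ll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_crossed_components_match_statsmodels(self):
        import statsmodels.formula.api as smf

        r = np.random.default_rng(4)
        n = 90
        ann = make_design(n, 4, lots=4, dates=6)
        lots = pd.factorize(ann.data["array_lot"])[0]
        dates = pd.factorize(ann.data["extraction_date"])[0]
        y = (
            2.0
            + r.normal(0, 0.5, 4)[lots]
            + r.normal(0, 0.3, 6)[dates]
            + 0.6 * ann.data["smoking"].to_numpy()
            + r.normal(0, 0.4, n)
        )
        pool = small_pool(random=("array_lot", "extraction_date"))
        mine = fit_mixed_bic(
            y, {"smoking"}, {"array_lot", "extraction_date"}, ann, pool=pool
        )

        df = ann.data.copy()
        df["y"] = y
        df["one"] = 1
        sm_fit = smf.mixedlm(
            "y ~ smoking",
            df,
            groups=df["one"],
            vc_formula={
                "lot": "0 + C(array_lot)",
                "date": "0 + C(extraction_date)",
            },
        ).fit(reml=False)
        assert mine.loglik == pytest.approx(sm_fit.llf, abs=1e-3)
        assert mine.n_params == 2 + 1 + 2  # 2 fixed + resid + 2 components

    def test_unknown_variable_rejected(self):
        ann = make_design(20, 1)
        with pytest.raises(BloodvarError):
            fit_mixed_bic(np.zeros(20), {"nope"}, set(), ann, pool=small_pool())


class TestStepwise:
    def test_equals_exhaustive_search_three_candidates(self):
        # strong orthogonal-ish effects: stepwise must find the global best
        for seed in range(6):
            r = np.random.default_rng(40 + seed)
            n = 80
            ann = make_design(n, 50 + seed, lots=0)
            pool = small_pool()
            x = ann.data
            y = (
                1.0
                + 1.2 * x["smoking"].to_numpy()
                + 0.9 * x["bmi_class"].to_numpy() * (seed % 2)
                + r.normal(0, 0.5, n)
            )
            sel = forward_backward_select(y, pool, ann)

            best = None
            for subset in chain.from_iterable(
                combinations(pool.fixed_candidates, k) for k in range(4)
            ):
                m = fit_mixed_bic(y, set(subset), set(), ann, pool=pool)
                if best is None or m.bic < best.bic:
                    best = m
            assert sel.selected_fixed == best.selected_fixed, seed
            assert sel.bic == pytest.approx(best.bic, abs=1e-6)

    def test_exhaustive_including_random_candidate(self):
        r = np.random.default_rng(8)
        n = 72
        ann = make_design(n, 60, lots=4)
        pool = small_pool(fixed=("smoking", "bmi_class"), random=("array_lot",))
        lots = pd.factorize(ann.data["array_lot"])[0]
        y = r.normal(0, 0.5, 4)[lots] + 0.9 * ann.data["smoking"].to_numpy() + r.normal(0, 0.5, n)
        sel = forward_backward_select(y, pool, ann)

        best = None
        for fsub in chain.from_iterable(combinations(pool.fixed_candidates, k) for k in range(3)):
            for rsub in ([], ["array_lot"]):
                m = fit_mixed_bic(y, set(fsub), set(rsub), ann, pool=pool)
                if best is None or m.bic < best.bic:
                    best = m
        assert (sel.selected_fixed, sel.selected_random) == (
            best.selected_fixed,
            best.selected_random,
        )

    def test_selected_bic_never_worse_than_simple_models(self, rng):
        n = 60
        ann = make_design(n, 70)
        pool = small_pool()
        y = rng.normal(size=n)
        sel = forward_backward_select(y, pool, ann)
        null = fit_mixed_bic(y, set(), set(), ann, pool=pool)
        assert sel.bic <= null.bic + 1e-9
        for v in pool.fixed_candidates:
            single = fit_mixed_bic(y, {v}, set(), ann, pool=pool)
            assert sel.bic <= single.bic + 1e-9

    def test_interaction_hierarchy_enforced(self):
        # interaction-only signal: search may add HT:MED only after both
        # mains; the selected model must therefore contain all three terms
        r = np.random.default_rng(11)
        n = 200
        ht = r.binomial(1, 0.5, n)
        med = r.binomial(1, 0.5, n)
        ann = make_annotations(HT=ht, MED=med)
        pool = CandidatePool(
            fixed_candidates=["HT", "MED", "HT:MED"],
            random_candidates=[],
            hierarchy={"HT:MED": ("HT", "MED")},
        )
        y = 2.0 * (ht * med) + r.normal(0, 0.5, n)
        sel = forward_backward_select(y, pool, ann)
        assert "HT:MED" in sel.selected_fixed
        assert {"HT", "MED"} <= sel.selected_fixed

    def test_default_pool_has_ten_candidates(self):
        assert len(CandidatePool().all_candidates) == 10

    def test_selection_deterministic(self):
        r = np.random.default_rng(13)
        n = 50
        ann = make_design(n, 80, lots=3)
        pool = small_pool(random=("array_lot",))
        y = r.normal(size=n)
        a = forward_backward_select(y, pool, ann)
        b = forward_backward_select(y, pool, ann)
        assert (a.selected_fixed, a.selected_random, a.bic) == (
            b.selected_fixed,
            b.selected_random,
            b.bic,
        )


class TestAssociationMatrix:
    def test_sensitivity_on_strong_effects(self):
        r = np.random.default_rng(21)
        n, G = 150, 40
        ann = make_design(n, 90, lots=0)
        pool = small_pool()
        smoking = ann.data["smoking"].to_numpy(dtype=float)
        Y = r.normal(0, 0.5, size=(G, n))
        Y[:20] += 1.0 * smoking[None, :]
        expr = make_expr(Y, sample_ids=list(ann.data.index))
        M, summary = build_association_matrix(expr, pool, ann)
        sens = M.iloc[:20]["smoking"].mean()
        assert sens >= 0.9
        assert summary.per_variable_counts["smoking"] >= 18

    def test_null_generator_biological_pickup_near_chance(self):
        r = np.random.default_rng(22)
        n, G = 150, 60
        ann = make_design(n, 91, lots=0)
        pool = small_pool()
        expr = make_expr(r.normal(size=(G, n)), sample_ids=list(ann.data.index))
        M, summary = build_association_matrix(expr, pool, ann)
        assert summary.mean_selected < 0.3
        assert (M.mean(axis=0) < 0.12).all()


class TestUniqueBiological:
    def _assoc(self, rows, columns):
        return pd.DataFrame(rows, columns=columns,
                            index=[f"P{i}" for i in range(len(rows))]).astype(bool)

    def test_array_lot_exemption(self):
        cols = ["smoking", "fasting", "array_lot"]
        assoc = self._assoc([[1, 0, 1], [1, 1, 0], [0, 1, 0]], cols)
        out = unique_biological(assoc, ["smoking", "fasting"])
        assert out["smoking"] == {"P0"}
        assert out["fasting"] == {"P2"}

    def test_other_technical_blocks_uniqueness(self):
        cols = ["smoking", "fasting", "array_lot", "extraction_date"]
        assoc = self._assoc([[1, 0, 1, 1]], cols)
        out = unique_biological(assoc, ["smoking", "fasting"])
        assert out["smoking"] == set()

    def test_matches_brute_force_on_random_matrices(self, rng):
        cols = ["smoking", "fasting", "bmi_class", "array_lot"]
        for _ in range(20):
            assoc = self._assoc(rng.binomial(1, 0.4, size=(30, 4)), cols)
            out = unique_biological(assoc, ["smoking", "fasting", "bmi_class"])
            for v in ("smoking", "fasting", "bmi_class"):
                brute = {
                    str(p)
                    for p in assoc.index
                    if assoc.loc[p, v]
                    and set(assoc.columns[assoc.loc[p]]) - {"array_lot"} == {v}
                }
                assert out[v] == brute

    def test_unknown_variable_rejected(self):
        assoc = self._assoc([[1, 0]], ["smoking", "array_lot"])
        with pytest.raises(BloodvarError):
            unique_biological(assoc, ["nope"])
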