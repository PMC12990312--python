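"""Screening cascade: design matrix coding, screen rules, LASSO, AUC."""

import numpy as np
import pandas as pd
import pytest

from faerspv import regression as rg
from faerspv import signals as sg
from faerspv import synthetic as sy

from conftest import make_store


def synthetic_design(n=20000, beta=(2.0, 0.0), prevalence=0.03,
                     drug_prob=0.02, seed=0):
    """Direct logistic-model data: drug indicators plus random covariates."""
    rng = np.random.default_rng(seed)
    drugs = [f"drug{chr(97 + i)}" for i in range(len(beta))]
    X = pd.DataFrame({d: (rng.random(n) < drug_prob).astype(int) for d in drugs})
    X["sex_male"] = rng.integers(0, 2, n)
    age = rng.uniform(10, 95, n)
    X["age_18_40"] = ((age >= 18) & (age <= 40)).astype(int)
    X["age_41_60"] = ((age > 40) & (age <= 60)).astype(int)
    X["age_61_80"] = ((age > 60) & (age <= 80)).astype(int)
    X["age_gt80"] = (age > 80).astype(int)
    X["weight_out_of_range"] = rng.integers(0, 2, n)
    b0 = np.log(prevalence / (1 - prevalence))
    eta = b0 + sum(b * X[d] for b, d in zip(beta, drugs))
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int))
    X.index.name = "primaryid"
    y.index = X.index
    return rg.DesignMatrix(X=X, y=y, drug_columns=drugs,
                           primaryids=np.arange(n))


class TestDesignMatrix:
    def test_complete_case_exclusion(self):
        store = make_store(
            [{"drugs": [("drugx", "PS")], "pts": ["Proteinuria"]}] * 9
            + [{"drugs": [("drugx", "PS")], "pts": [], "age": np.nan}])
        dm = rg.build_design_matrix(store, ["drugx"], ["Proteinuria"])
        assert dm.n == 9

    def test_reference_level_coding(self):
        store = make_store([
            {"sex": "female", "age": 17.0, "weight": 60.0,
             "drugs": [("drugx", "PS")], "pts": []},
        ])
        dm = rg.build_design_matrix(store, ["drugx"], ["Proteinuria"])
        row = dm.X.iloc[0]
        assert row["sex_male"] == 0
        assert row[["age_18_40", "age_41_60", "age_61_80", "age_gt80"]].sum() == 0
        assert row["weight_out_of_range"] == 0

    @pytest.mark.parametrize("age, col", [
        (30, "age_18_40"), (50, "age_41_60"), (70, "age_61_80"), (85, "age_gt80")])
    def test_age_class_bins(self, age, col):
        store = make_store([{"age": float(age), "drugs": [("drugx", "PS")], "pts": []}])
        dm = rg.build_design_matrix(store, ["drugx"], ["Proteinuria"])
        assert dm.X.iloc[0][col] == 1

    def test_indicator_sums_match_ground_truth(self):
        cfg = sy.default_config(n_reports=8000, seed=6, duplicate_rate=0.0)
        store, truth = sy.simulate_store(cfg)
        drugs = ["lenvatinib", "tacrolimus"]
        dm = rg.build_design_matrix(store, drugs, ["Proteinuria"])
        complete = set(dm.X.index)
        ps = store.ps_drugs()
        for drug in drugs:
            expected = ps[(ps["generic_name"] == drug)
                          & ps["primaryid"].isin(complete)]["primaryid"].nunique()
            assert dm.X[drug].sum() == expected

    def test_all_missing_raises(self):
        store = make_store([{"age": np.nan, "drugs": [("drugx", "PS")], "pts": []}])
        with pytest.raises(ValueError, match="complete"):
            rg.build_design_matrix(store, ["drugx"], ["Proteinuria"])


class TestUnivariateScreen:
    def ror_frame(self, rows):
        return pd.DataFrame(rows).set_index("drug")

    def test_count_gate_blocks_small_a(self):
        dm = synthetic_design(n=4000, beta=(3.0,), seed=1)
        frame = self.ror_frame([
            {"drug": "druga", "a": 50, "ror": 30.0, "ror_lo": 12.0}])
        res = rg.univariate_screen(dm, frame, min_a=100)
        assert res.retained == []

    def test_signal_retained_null_rejected(self):
        dm = synthetic_design(n=40000, beta=(2.3, 0.0), drug_prob=0.08, seed=2)
        a_sig = int(dm.X["druga"][dm.y == 1].sum())
        a_null = int(dm.X["drugb"][dm.y == 1].sum())
        frame = self.ror_frame([
            {"drug": "druga", "a": a_sig, "ror": 10.0, "ror_lo": 8.0},
            {"drug": "drugb", "a": a_null, "ror": 1.0, "ror_lo": 0.8}])
        res = rg.univariate_screen(dm, frame, min_a=100)
        assert res.retained == ["druga"]
        assert res.per_drug.loc["druga", "p_adj"] < 0.01
        assert not (res.per_drug.loc["drugb", "p_adj"] < 0.01)

    def test_monotone_in_count_threshold(self):
        dm = synthetic_design(n=30000, beta=(2.0, 1.5), drug_prob=0.05, seed=3)
        frame = self.ror_frame([
            {"drug": "druga", "a": 300, "ror": 8.0, "ror_lo": 6.0},
            {"drug": "drugb", "a": 150, "ror": 4.0, "ror_lo": 3.0}])
        kept = [len(rg.univariate_screen(dm, frame, min_a=m).retained)
                for m in (100, 200, 400)]
        assert kept == sorted(kept, reverse=True)


class TestLasso:
    def test_true_signal_selected_null_dropped(self):
        dm = synthetic_design(n=20000, beta=(3.0, 0.0), drug_prob=0.03, seed=4)
        res = rg.lasso_select(dm, ["druga", "drugb"], seed=4, n_lambdas=15)
        assert "druga" in res.selected
        assert "drugb" not in res.selected

    def test_huge_lambda_empty_selection(self):
        dm = synthetic_design(n=5000, beta=(2.0, 0.0), seed=5)
        X = dm.X[["druga", "drugb"] + list(rg.COVARIATE_COLUMNS)].to_numpy(float)
        model = rg._l1_fit(X, dm.y.to_numpy(float), lam=10.0)
        assert np.all(np.abs(model.coef_.ravel()[:2]) < 1e-8)

    def test_tiny_lambda_matches_unpenalized_pattern(self):
        import statsmodels.api as sm
        dm = synthetic_design(n=10000, beta=(2.5, 1.5), drug_prob=0.05, seed=6)
        cols = ["druga", "drugb"] + list(rg.COVARIATE_COLUMNS)
        X = dm.X[cols].to_numpy(float)
        y = dm.y.to_numpy(float)
        model = rg._l1_fit(X, y, lam=1e-8)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(model.coef_.ravel(), mle.params[1:], atol=0.02)

    def test_one_se_selection_nested_in_min(self):
        dm = synthetic_design(n=15000, beta=(2.5, 1.2, 0.0), drug_prob=0.04, seed=7)
        drugs = ["druga", "drugb", "drugc"]
        r1 = rg.lasso_select(dm, drugs, rule="1se", seed=7, n_lambdas=15)
        r2 = rg.lasso_select(dm, drugs, rule="min", seed=7, n_lambdas=15)
        assert set(r1.selected) <= set(r2.selected)
        assert r1.lambda_1se >= r2.lambda_min


class TestMultivariate:
    def test_saturated_two_by_two_identity(self):
        """Single-drug logistic OR equals the 2x2 cross-product ratio."""
        X = pd.DataFrame({"drugx": [1, 1, 1, 0, 0, 0]})
        y = pd.Series([1, 1, 0, 1, 0, 0])  # (a,b,c,d) = (2,1,1,2)
        dm = rg.DesignMatrix(X=X, y=y, drug_columns=["drugx"],
                             primaryids=np.arange(6))
        res = rg.multivariate_fit(dm, ["drugx"], include_covariates=False)
        assert res.terms.loc["drugx", "or_"] == pytest.approx(4.0, rel=1e-4)

    def test_known_log_odds_recovered(self):
        dm = synthetic_design(n=50000, beta=(2.0,), drug_prob=0.03, seed=8)
        res = rg.multivariate_fit(dm, ["druga"])
        assert res.terms.loc["druga", "coef"] == pytest.approx(2.0, abs=0.15)
        assert res.terms.loc["druga", "ci_lo"] < np.exp(2.0) < res.terms.loc["druga", "ci_hi"]

    def test_permuted_outcome_rarely_significant(self):
        dm = synthetic_design(n=20000, beta=(2.0, 0.0), drug_prob=0.03, seed=9)
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            yp = pd.Series(rng.permutation(dm.y.to_numpy()), index=dm.y.index)
            dmp = rg.DesignMatrix(X=dm.X, y=yp, drug_columns=dm.drug_columns,
                                  primaryids=dm.primaryids)
            res = rg.multivariate_fit(dmp, ["druga", "drugb"])
            hits += bool(res.significant_drugs)
        assert hits <= 4  # ~2% expected per permutation at alpha 0.01

    def test_separation_reported(self):
        X = pd.DataFrame({"drugx": [1] * 5 + [0] * 5})
        y = pd.Series([1] * 5 + [0] * 5)
        dm = rg.DesignMatrix(X=X, y=y, drug_columns=["drugx"],
                             primaryids=np.arange(10))
        with pytest.raises(RuntimeError):
            rg.multivariate_fit(dm, ["drugx"], include_covariates=False)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, roc = rg.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert roc["tpr"].iloc[-1] == 1.0 and roc["fpr"].iloc[-1] == 1.0

    def test_constant_scores_half(self):
        auc, _ = rg.roc_auc([0.5] * 10, [0, 1] * 5)
        assert auc == 0.5

    def test_four_point_example(self):
        auc, _ = rg.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rg.roc_auc([0.2, 0.8], [1, 1])

    def test_matches_pair_counting_oracle_and_sklearn(self):
        """Rank AUC equals exhaustive correct-pair counting (ties = 1/2)
        and the library implementation on tied, random scores."""
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(10)
        for _ in range(5):
            n = int(rng.integers(20, 200))
            p = np.round(rng.random(n), 1)  # coarse grid forces ties
            y = (rng.random(n) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            auc, _ = rg.roc_auc(p, y)
            pos, neg = p[y == 1], p[y == 0]
            wins = sum((pos_i > neg).sum() + 0.5 * (pos_i == neg).sum()
                       for pos_i in pos)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), rel=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, p), rel=1e-12)
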