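"""Design construction, REML estimation, and fixed/random-effect tests."""

import numpy as np
import pandas as pd
import pytest

from hspherit import (
    MixedModelSpec,
    RandomTerm,
    build_design,
    extract_breeding_values,
    loglik_ratio_test,
    reml_fit,
    wald_f,
)
from hspherit.mixed_model import ModelSpecError
from hspherit.pedigree import Pedigree


def _sire_model_frame(rng, n_sires, n_off, v_s, v_e, mu=10.0):
    sires = np.repeat([f"S{i}" for i in range(n_sires)], n_off)
    y = (
        mu
        + rng.normal(0, np.sqrt(v_s), n_sires).repeat(n_off)
        + rng.normal(0, np.sqrt(v_e), n_sires * n_off)
    )
    return pd.DataFrame({"y": y, "sire": sires})


def _anova_sire_variance(df, n_off):
    means = df.groupby("sire")["y"].mean()
    ms_sire = n_off * means.var(ddof=1)
    ms_within = df.groupby("sire")["y"].var(ddof=1).mean()
    return (ms_sire - ms_within) / n_off


SIRE = RandomTerm(name="sire", column="sire", structure="identity")


class TestBuildDesign:
    def test_intercept_only(self):
        df = pd.DataFrame({"y": np.arange(6.0), "sire": ["a"] * 3 + ["b"] * 3})
        d = build_design(MixedModelSpec(response="y", random_terms=(SIRE,)), df)
        assert d.X.shape == (6, 1)
        assert np.allclose(d.X, 1.0)

    def test_permanent_environment_indicator(self):
        df = pd.DataFrame(
            {
                "y": np.arange(6.0),
                "animal": ["a1", "a2", "a3"] * 2,
                "year": [1, 1, 1, 2, 2, 2],
            }
        )
        pe = RandomTerm(name="pe", column="animal", role="permanent_env")
        d = build_design(MixedModelSpec(response="y", random_terms=(pe,)), df)
        Z = d.Z["pe"]
        assert Z.shape == (6, 3)
        assert np.all(Z.sum(axis=0) == 2)
        assert np.all(Z.sum(axis=1) == 1)

    def test_nested_factor_spans_all_cells(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "y": rng.normal(size=80),
                "year": np.repeat([1, 2], 40),
                "order": list(np.tile(np.arange(4), 10)) * 2,
                "sire": [f"s{i % 5}" for i in range(80)],
            }
        )
        d = build_design(
            MixedModelSpec(
                response="y", fixed_factors=("order(year)",), random_terms=(SIRE,)
            ),
            df,
        )
        # 2 years x 4 orders = 8 cells; intercept absorbs one
        assert d.X.shape[1] == 8
        assert len(d.term_columns["order(year)"]) == 7
        assert np.linalg.matrix_rank(d.X) == 8
        # adding the year main effect does not enlarge the column space
        d2 = build_design(
            MixedModelSpec(
                response="y",
                fixed_factors=("year", "order(year)"),
                random_terms=(SIRE,),
            ),
            df,
        )
        assert d2.X.shape[1] == 8

    def test_missing_rows_dropped_and_counted(self):
        df = pd.DataFrame(
            {"y": [1.0, np.nan, 3.0, 4.0], "sire": ["a", "a", "b", None]}
        )
        d = build_design(MixedModelSpec(response="y", random_terms=(SIRE,)), df)
        assert d.n_obs == 2
        assert d.n_dropped == 2

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "grp": ["x", "x"], "sire": ["a", "b"]})
        with pytest.raises(ModelSpecError, match="single level"):
            build_design(
                MixedModelSpec(
                    response="y", fixed_factors=("grp",), random_terms=(SIRE,)
                ),
                df,
            )

    def test_animal_absent_from_pedigree_rejected(self):
        ped = Pedigree.from_records([("A", "", "")])
        df = pd.DataFrame({"y": [1.0, 2.0], "animal": ["A", "B"]})
        spec = MixedModelSpec(
            response="y",
            random_terms=(RandomTerm("a", "animal", "additive"),),
            pedigree=ped,
        )
        with pytest.raises(ModelSpecError, match="absent from pedigree"):
            build_design(spec, df)


class TestRemlFit:
    def test_pure_noise_pins_group_variance_at_zero(self):
        rng = np.random.default_rng(42)
        df = _sire_model_frame(rng, 20, 10, v_s=0.0, v_e=4.0)
        fit = reml_fit(MixedModelSpec(response="y", random_terms=(SIRE,)), df)
        est = fit.components.estimates
        if est["sire"] == 0.0:
            assert fit.components.boundary["sire"]
        # with no group signal the total must come back as the sample scale
        assert est["sire"] + est["residual"] == pytest.approx(
            df["y"].var(ddof=1), rel=0.15
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_balanced_sire_model_equals_anova_estimator(self, seed):
        rng = np.random.default_rng(seed)
        df = _sire_model_frame(rng, 20, 15, v_s=2.0, v_e=8.0)
        anova_est = _anova_sire_variance(df, 15)
        if anova_est <= 0:
            pytest.skip("boundary draw; interior case required")
        fit = reml_fit(MixedModelSpec(response="y", random_terms=(SIRE,)), df)
        assert fit.components.estimates["sire"] == pytest.approx(
            anova_est, abs=1e-8, rel=1e-8
        )

    def test_estimates_invariant_to_row_shuffle(self):
        rng = np.random.default_rng(5)
        df = _sire_model_frame(rng, 15, 8, v_s=1.5, v_e=5.0)
        spec = MixedModelSpec(response="y", random_terms=(SIRE,))
        fit1 = reml_fit(spec, df)
        fit2 = reml_fit(spec, df.sample(frac=1.0, random_state=0))
        for k in fit1.components.estimates:
            assert fit1.components.estimates[k] == pytest.approx(
                fit2.components.estimates[k], abs=1e-6
            )
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)

    def test_refit_from_solution_is_stationary(self, small_dataset):
        spec = MixedModelSpec(
            response="hsp70",
            random_terms=(RandomTerm("a", "animal", "additive"),),
            pedigree=small_dataset.pedigree,
        )
        df = small_dataset.phenotypes.query("year == 1")
        fit = reml_fit(spec, df)
        refit = reml_fit(spec, df, options=None)
        assert abs(refit.loglik - fit.loglik) < 1e-6
        assert fit.loglik_at(fit.theta) == pytest.approx(fit.loglik, abs=1e-9)

    def test_profile_local_maximum(self, small_dataset):
        """No single-component +/-5% perturbation may increase the REML
        log-likelihood (inward only for boundary components)."""
        spec = MixedModelSpec(
            response="hsp70",
            random_terms=(
                RandomTerm("a", "animal", "additive"),
                RandomTerm("fam", "family", role="common_env"),
            ),
            pedigree=small_dataset.pedigree,
        )
        fit = reml_fit(spec, small_dataset.phenotypes.query("year == 1"))
        for k in range(len(fit.theta)):
            for factor in (0.95, 1.05):
                theta = fit.theta.copy()
                if theta[k] == 0.0:
                    if factor < 1.0:
                        continue
                    theta[k] = 0.05 * fit.components.V_P
                else:
                    theta[k] *= factor
                assert fit.loglik_at(theta) <= fit.loglik + 1e-6

    def test_adding_random_term_never_decreases_loglik(self, small_dataset):
        df = small_dataset.phenotypes.query("year == 1")
        base = MixedModelSpec(
            response="hsp70",
            random_terms=(RandomTerm("a", "animal", "additive"),),
            pedigree=small_dataset.pedigree,
        )
        richer = MixedModelSpec(
            response="hsp70",
            random_terms=(
                RandomTerm("a", "animal", "additive"),
                RandomTerm("fam", "family", role="common_env"),
            ),
            pedigree=small_dataset.pedigree,
        )
        ll0 = reml_fit(base, df).loglik
        ll1 = reml_fit(richer, df).loglik
        assert ll1 >= ll0 - 1e-6


class TestLikelihoodRatio:
    def test_statistic_nonnegative_and_df_one(self):
        rng = np.random.default_rng(2)
        df = _sire_model_frame(rng, 10, 6, v_s=1.0, v_e=3.0)
        full = reml_fit(MixedModelSpec(response="y", random_terms=(SIRE,)), df)
        red = reml_fit(MixedModelSpec(response="y", random_terms=()), df)
        lrt = loglik_ratio_test(full, red)
        assert lrt.statistic >= 0
        assert lrt.df == 1
        assert lrt.term == "sire"
        assert 0 <= lrt.p_value <= 0.5  # mixture halves the chi2(1) tail

    def test_zero_statistic_conventions(self):
        rng = np.random.default_rng(3)
        df = _sire_model_frame(rng, 10, 6, v_s=0.0, v_e=3.0)
        full = reml_fit(MixedModelSpec(response="y", random_terms=(SIRE,)), df)
        red = reml_fit(MixedModelSpec(response="y", random_terms=()), df)
        lrt = loglik_ratio_test(full, red)
        if lrt.statistic == 0.0:
            assert lrt.p_value == pytest.approx(0.5)
        plain = loglik_ratio_test(full, red, boundary_mixture=False)
        assert plain.p_value == pytest.approx(2 * lrt.p_value, rel=1e-12)
        assert "mixture" in lrt.note

    def test_non_nested_specs_rejected(self):
        rng = np.random.default_rng(4)
        df = _sire_model_frame(rng, 10, 6, v_s=1.0, v_e=3.0)
        df["fam"] = df["sire"]
        f1 = reml_fit(MixedModelSpec(response="y", random_terms=(SIRE,)), df)
        f2 = reml_fit(
            MixedModelSpec(
                response="y", random_terms=(RandomTerm("fam", "fam"),)
            ),
            df,
        )
        with pytest.raises(ModelSpecError):
            loglik_ratio_test(f1, f2)
        with pytest.raises(ModelSpecError):
            loglik_ratio_test(f1, f1)


class TestWaldF:
    def test_single_covariate_f_equals_squared_t(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "y": 1.0 + 0.2 * x + rng.normal(size=n),
                "x": x,
                "sire": [f"s{i % 20}" for i in range(n)],
            }
        )
        fit = reml_fit(
            MixedModelSpec(response="y", covariates=("x",), random_terms=(SIRE,)),
            df,
        )
        w = wald_f(fit, "x")
        row = fit.blue.set_index("term").loc["x"]
        z = row["estimate"] / row["se"]
        assert w.statistic == pytest.approx(z**2, abs=1e-8)
        assert w.ndf == 1
        assert w.ddf == fit.n_obs - fit.rank_X

    def test_strong_order_effect_detected(self):
        # inject an order effect far above the residual scale (8 units/level)
        from hspherit import SimulationConfig, simulate_dataset

        ds = simulate_dataset(
            SimulationConfig(
                n_sires=10,
                offspring_range=(4, 6),
                fractions=("intracellular",),
                order_slopes=(0.0, 8.0),
            ),
            seed=13,
        )
        df = ds.phenotypes.query("year == 2")
        fit = reml_fit(
            MixedModelSpec(
                response="hsp70",
                fixed_factors=("sampling_order",),
                random_terms=(RandomTerm("a", "animal", "additive"),),
                pedigree=ds.pedigree,
            ),
            df,
        )
        w = wald_f(fit, "sampling_order")
        assert w.p_value < 1e-6

    def test_unknown_term_rejected(self, small_dataset):
        df = small_dataset.phenotypes.query("year == 1")
        fit = reml_fit(
            MixedModelSpec(
                response="hsp70",
                random_terms=(RandomTerm("a", "animal", "additive"),),
                pedigree=small_dataset.pedigree,
            ),
            df,
        )
        with pytest.raises(ModelSpecError):
            wald_f(fit, "sampling_order")


class TestBreedingValues:
    def test_all_zero_when_additive_variance_zero(self):
        ped = Pedigree.from_records(
            [("S", "", ""), ("D", "", ""), ("O1", "S", "D"), ("O2", "S", "D")]
        )
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"y": rng.normal(size=40), "animal": ["O1", "O2"] * 20}
        )
        fit = reml_fit(
            MixedModelSpec(
                response="y",
                random_terms=(RandomTerm("a", "animal", "additive"),),
                pedigree=ped,
            ),
            df,
        )
        if fit.components.V_A == 0.0:
            ebv = extract_breeding_values(fit)
            assert np.all(ebv["ebv"] == 0.0)
            assert np.all(ebv["pev"] == 0.0)

    def test_ebv_tracks_true_breeding_values(self, paper_scale_dataset):
        ds = paper_scale_dataset
        fit = reml_fit(
            MixedModelSpec(
                response="hsp70",
                fixed_factors=("year",),
                random_terms=(RandomTerm("a", "animal", "additive"),),
                pedigree=ds.pedigree,
            ),
            ds.phenotypes,
        )
        ebv = extract_breeding_values(fit).set_index("animal")
        truth = ds.truth.set_index("animal")["breeding_value"]
        joined = ebv.join(truth, how="inner")
        r = np.corrcoef(joined["ebv"], joined["breeding_value"])[0, 1]
        assert r > 0.2
        assert (ebv["pev"] >= 0).all()
        # founder EBVs centre near zero
        founders = [a for a in ds.pedigree.founders]
        assert abs(ebv.loc[founders, "ebv"].mean()) < 1.0

    def test_unphenotyped_sire_is_shrunk_towards_zero(self):
        ped = Pedigree.from_records(
            [("S", "", "")]
            + [(f"D{i}", "", "") for i in range(8)]
            + [(f"O{i}", "S", f"D{i}") for i in range(8)]
        )
        rng = np.random.default_rng(9)
        rows = []
        for i in range(8):
            for _ in range(4):
                rows.append({"animal": f"O{i}", "y": 5.0 + rng.normal()})
        df = pd.DataFrame(rows)
        fit = reml_fit(
            MixedModelSpec(
                response="y",
                random_terms=(RandomTerm("a", "animal", "additive"),),
                pedigree=ped,
            ),
            df,
            options=None,
        )
        ebv = extract_breeding_values(fit).set_index("animal")
        prog_mean_dev = ebv.loc[[f"O{i}" for i in range(8)], "ebv"].mean()
        if fit.components.V_A > 0:
            assert abs(ebv.loc["S", "ebv"]) <= abs(prog_mean_dev) + 1e-9

    def test_requires_additive_term(self):
        rng = np.random.default_rng(10)
        df = _sire_model_frame(rng, 5, 4, v_s=1.0, v_e=1.0)
        fit = reml_fit(MixedModelSpec(response="y", random_terms=(SIRE,)), df)
        with pytest.raises(ModelSpecError):
            extract_breeding_values(fit)
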