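"""CCD construction, factor coding, response-surface OLS, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from pileflow.doe import (
    ResponseSurfaceRegressor,
    build_ccd,
    code_factor,
    fit_response_surface,
    load_avalanche,
    load_design,
    load_fit_params,
    load_saor_ft,
    load_study_responses,
    model_terms,
    pearson_matrix,
    reduce_model,
    term_column,
)


@pytest.fixture(scope="module")
def design():
    return load_design()


@pytest.fixture(scope="module")
def responses():
    return load_study_responses()


class TestCoding:
    @pytest.mark.parametrize(
        "actual, center, step, expected",
        [
            (1100.0, 725.0, 375.0, 1.0),
            (0.6, 2.0, 1.0, -1.4),
            (194.7, 725.0, 375.0, -1.4141),
        ],
    )
    def test_examples(self, actual, center, step, expected):
        assert code_factor(actual, center, step) == pytest.approx(expected, abs=5e-4)

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            code_factor(1.0, 0.0, 0.0)


class TestLoaders:
    def test_row_counts_and_columns(self, design):
        assert len(design) == 24
        assert {"x1", "x2", "x3", "x4"}.issubset(design.columns)
        assert len(load_saor_ft()) == 24
        assert len(load_avalanche()) == 24
        assert len(load_fit_params()) == 24

    def test_categorical_balance(self, design):
        assert (design.x4 == 1).sum() == 12
        assert (design.x4 == -1).sum() == 12

    def test_coded_column_sums_vanish(self, design):
        for f in ("x1", "x2", "x3", "x4"):
            assert design[f].sum() == pytest.approx(0.0, abs=1e-9)

    def test_categorical_orthogonal_to_all_model_columns(self, design):
        x4 = design.x4.to_numpy()
        for term in model_terms("quadratic")[1:]:
            if term == "x4":
                continue
            col = term_column(design, term)
            assert float(x4 @ col) == pytest.approx(0.0, abs=1e-8)

    def test_responses_join_preserves_sample_order(self, responses):
        assert list(responses["sample"]) == list(range(1, 25))


class TestBuildCCD:
    def test_default_layout_matches_study(self):
        df = build_ccd()
        assert len(df) == 24
        assert (df.x4 == 1).sum() == 12
        # half fraction: every factorial corner satisfies x1*x2*x3 = -1
        corners = df[(df[["x1", "x2", "x3"]].abs() == 1).all(axis=1)]
        assert len(corners) == 8
        assert np.all(corners.x1 * corners.x2 * corners.x3 == -1)

    def test_full_fraction_run_count(self):
        assert len(build_ccd(fraction="full", n_center=1)) == 30

    def test_column_balance(self):
        df = build_ccd()
        assert df[["x1", "x2", "x3", "x4"]].sum().abs().max() < 1e-12

    def test_invalid_axial_rejected(self):
        with pytest.raises(ValueError):
            build_ccd(axial=0.9)


class TestResponseSurface:
    def test_saor_2fi_reproduces_published_slopes(self, design):
        model = fit_response_surface(design, load_saor_ft().saor_deg, form="2fi")
        assert model.coef("x4") == pytest.approx(-2.46, abs=0.01)
        assert model.coef("x1") == pytest.approx(1.45, abs=0.01)
        assert model.coef("x2") == pytest.approx(-1.01, abs=0.01)
        assert model.coef("x1:x3") == pytest.approx(-1.84, abs=0.01)

    def test_aufc_reduced_quadratic_slope(self, design):
        model = fit_response_surface(
            design, load_fit_params().aufc, terms=["Intercept", "x1", "x4", "x1^2"]
        )
        assert model.coef("x4") == pytest.approx(805.76, abs=0.01)

    def test_noiseless_synthetic_recovery_exact(self, design):
        rng = np.random.default_rng(0)
        terms = model_terms("2fi")
        truth = dict(zip(terms, rng.normal(0, 3, len(terms))))
        y = sum(coef * term_column(design, t) for t, coef in truth.items())
        model = fit_response_surface(design, y, form="2fi")
        for t, coef in truth.items():
            assert model.coef(t) == pytest.approx(coef, abs=1e-10)

    def test_categorical_slope_equals_half_group_mean_difference(
        self, design, responses
    ):
        for col in responses.columns.drop("sample"):
            y = responses[col]
            direct = (y[design.x4 > 0].mean() - y[design.x4 < 0].mean()) / 2
            for form in ("linear", "2fi", "quadratic"):
                model = fit_response_surface(design, y, form=form)
                assert model.coef("x4") == pytest.approx(direct, abs=1e-8), (
                    col,
                    form,
                )

    def test_predicted_r_squared_negative_for_intercept_parameter(self, design):
        model = fit_response_surface(design, load_fit_params().a, form="quadratic")
        assert model.predicted_r_squared < 0
        assert model.predicted_r_squared <= model.r_squared

    def test_aliased_terms_rejected(self, design):
        with pytest.raises(ValueError, match="aliased|rank"):
            fit_response_surface(
                design,
                load_saor_ft().saor_deg,
                terms=["Intercept", "x4", "x4^2"],  # x4^2 == 1 == intercept
            )

    def test_too_many_terms_rejected(self, design):
        terms = model_terms("quadratic") + [f"x1:x{j}" for j in (2, 3, 4)]
        with pytest.raises(ValueError):
            fit_response_surface(design.head(10), load_saor_ft().saor_deg[:10], terms=terms)

    def test_estimator_protocol(self, design):
        reg = ResponseSurfaceRegressor(form="2fi")
        cloned = clone(reg)
        y = load_saor_ft().saor_deg
        cloned.fit(design, y)
        assert cloned.predict(design) == pytest.approx(
            np.asarray(y), abs=3.5
        )  # surface approximates, not interpolates
        assert len(cloned.coef_) == len(model_terms("2fi"))


class TestReduceModel:
    def test_wavelength_reduces_to_categorical_only(self, design):
        full = fit_response_surface(
            design, load_avalanche().wavelength_frames, form="linear"
        )
        reduced = reduce_model(full, alpha=0.05)
        assert set(reduced.terms) == {"Intercept", "x4"}
        assert reduced.coef("x4") == pytest.approx(-1.82, abs=0.01)

    def test_count_reduces_to_categorical_only(self, design):
        reduced = reduce_model(
            fit_response_surface(design, load_avalanche()["count"], form="linear")
        )
        assert set(reduced.terms) == {"Intercept", "x4"}
        assert reduced.coef("x4") == pytest.approx(2.71, abs=0.01)

    def test_fully_significant_model_unchanged(self, design):
        y = 5.0 + 3.0 * design.x1 - 2.0 * design.x4
        model = fit_response_surface(design, y, terms=["Intercept", "x1", "x4"])
        reduced = reduce_model(model)
        assert reduced.terms == model.terms

    def test_hierarchy_preserved(self, design):
        # strong x1:x2 interaction, no x1 main effect: x1 must survive
        rng = np.random.default_rng(1)
        y = 1.0 + 4.0 * design.x1 * design.x2 + rng.normal(0, 0.3, 24)
        model = fit_response_surface(design, y, form="2fi")
        reduced = reduce_model(model)
        assert "x1:x2" in reduced.terms
        assert "x1" in reduced.terms and "x2" in reduced.terms


class TestPearsonMatrix:
    def test_named_study_correlations(self, responses):
        corr = pearson_matrix(responses.drop(columns="sample"))
        assert corr.r.loc["b", "c"] == pytest.approx(-0.970, abs=0.005)
        assert corr.r.loc["saor_deg", "ft_s"] == pytest.approx(0.728, abs=0.005)
        assert corr.r.loc["ft_s", "aufc"] == pytest.approx(-0.701, abs=0.005)
        assert corr.stars("b", "c") == "**"

    def test_symmetric_with_unit_diagonal(self, responses):
        corr = pearson_matrix(responses.drop(columns="sample"))
        r = corr.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.nanmax(np.abs(r)) <= 1.0 + 1e-12

    def test_zero_variance_column_flagged(self):
        df = pd.DataFrame({"u": [1.0, 2.0, 3.0, 4.0], "v": [5.0, 5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            corr = pearson_matrix(df)
        assert np.isnan(corr.r.loc["u", "v"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(pd.DataFrame({"u": [1.0, 2.0], "v": [3.0, 4.0]}))

    def test_r_matches_direct_covariance_formula(self, responses):
        df = responses.drop(columns="sample")
        corr = pearson_matrix(df)
        for i, j in itertools.combinations(df.columns, 2):
            xi = df[i] - df[i].mean()
            xj = df[j] - df[j].mean()
            direct = float((xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum()))
            assert corr.r.loc[i, j] == pytest.approx(direct, abs=1e-12)
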