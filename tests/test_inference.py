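"""Model subsets, response preparation, trait filtering and the GLMM engine."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from borealis.glmm import GLMMData, fit_ml
from borealis.inference import (
    ModelSpec,
    build_design,
    correlate_methods,
    filter_traits,
    fit_community_model,
    fit_species_model,
    make_subsets,
    pairwise_contrasts,
    prepare_beta_response,
)


class TestMakeSubsets:
    def frame(self, bci, bai, no_col=None):
        n = len(bci)
        return pd.DataFrame({
            "plot": [f"p{i}" for i in range(n)],
            "bci": bci,
            "bai": bai,
            "no_colonisers": no_col or [False] * n,
        })

    def test_positive_and_full_range_sizes(self):
        plots = self.frame([0.0, 0.5, 1.0], [0.1, -0.2, 0.0])
        subsets = make_subsets(plots)
        assert len(subsets["positive_only_bci"]) == 2
        assert len(subsets["full_range_bci"]) == 3
        assert len(subsets["positive_only_bai"]) == 1

    def test_memberships_defined_independently(self):
        plots = self.frame([0.8, 0.0], [-0.5, 0.3])
        subsets = make_subsets(plots)
        assert set(subsets["positive_only_bci"]["plot"]) == {"p0"}
        assert set(subsets["positive_only_bai"]["plot"]) == {"p1"}

    def test_all_zero_bai_warns(self):
        plots = self.frame([0.5, 0.5], [0.0, -0.1])
        with pytest.warns(UserWarning, match="BAI"):
            subsets = make_subsets(plots)
        assert subsets["positive_only_bai"].empty

    def test_positive_only_subset_of_full_range(self, small_pipeline):
        subsets = make_subsets(small_pipeline["plots"])
        for kind in ("bci", "bai"):
            pos = set(subsets[f"positive_only_{kind}"]["plot"])
            full = set(subsets[f"full_range_{kind}"]["plot"])
            assert pos <= full


class TestPrepareBetaResponse:
    def test_boundary_shift(self):
        out = prepare_beta_response([1.0, 0.5, 0.0002])
        assert out[0] == pytest.approx(0.9999)
        assert out[1] == pytest.approx(0.4999)
        assert out[2] == pytest.approx(0.0001)  # clamped at the lower bound

    def test_monotone_order_preserving(self):
        values = np.linspace(0.01, 1.0, 37)
        out = prepare_beta_response(values)
        assert np.all(np.diff(out) >= 0)
        assert np.all((out > 0) & (out < 1))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            prepare_beta_response([0.0, 0.5])


class TestBuildDesign:
    def test_reference_levels_absorbed(self):
        data = pd.DataFrame({
            "region": ["Eurasia", "GreenlandIceland", "Eurasia"],
            "elev": [10.0, 20.0, 30.0],
        })
        X, names = build_design(data, ["region", "elev"])
        assert names == ["intercept", "region[GreenlandIceland]", "elev"]
        assert X[:, 1].tolist() == [0.0, 1.0, 0.0]

    def test_log_transform(self):
        data = pd.DataFrame({"height": [0.1, 1.0, 10.0]})
        X, names = build_design(data, ["height"], log_transform=["height"])
        assert names == ["intercept", "log_height"]
        assert X[:, 1] == pytest.approx(np.log([0.1, 1.0, 10.0]))


class TestCommunityModel:
    def simulate_binomial(self, seed, slope=0.8, n_groups=30, per_group=8):
        rng = np.random.default_rng(seed)
        n = n_groups * per_group
        g = np.repeat(np.arange(n_groups), per_group)
        x = rng.normal(size=n)
        eta = -0.3 + slope * x + rng.normal(0, 0.6, n_groups)[g]
        trials = rng.integers(0, 7, size=n)  # zero-trial plots included
        y = rng.binomial(trials, expit(eta))
        return pd.DataFrame({
            "n_boreal_colonisers": y.astype(float),
            "n_colonisers": trials.astype(float),
            "x": x,
            "subsite": [f"s{i}" for i in g],
        })

    def test_binomial_fit_recovers_slope(self):
        data = self.simulate_binomial(seed=8)
        spec = ModelSpec(
            response="n_boreal_colonisers", trials="n_colonisers",
            family="binomial_logit", fixed_effects=("x",),
            random_intercept="subsite",
        )
        fit = fit_community_model(spec, data, backend="fast")
        coef = fit.coefficients.set_index("term").loc["x"]
        assert coef["lower95"] < 0.8 < coef["upper95"]
        assert fit.converged

    def test_matches_statsmodels_glm_without_grouping(self):
        import statsmodels.api as sm

        data = self.simulate_binomial(seed=9)
        spec = ModelSpec(
            response="n_boreal_colonisers", trials="n_colonisers",
            family="binomial_logit", fixed_effects=("x",),
        )
        ours = fit_community_model(spec, data, backend="fast")
        # zero-trial plots carry no likelihood; statsmodels requires their
        # removal while our fit retains them — estimates must agree anyway
        nz = data[data["n_colonisers"] > 0]
        y = nz["n_boreal_colonisers"].to_numpy()
        trials = nz["n_colonisers"].to_numpy()
        X = np.column_stack([np.ones(len(nz)), nz["x"]])
        ref = sm.GLM(np.column_stack([y, trials - y]), X,
                     family=sm.families.Binomial()).fit()
        assert ours.coefficients["estimate"].to_numpy() == pytest.approx(
            ref.params, abs=1e-4
        )

    def test_gaussian_matches_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        g = np.repeat(np.arange(25), 6)
        x = rng.normal(size=150)
        y = 0.5 + 1.2 * x + rng.normal(0, 0.8, 25)[g] + rng.normal(0, 1.0, 150)
        data = pd.DataFrame({"bai": y, "x": x, "subsite": [f"s{i}" for i in g]})
        spec = ModelSpec(response="bai", family="gaussian_identity",
                         fixed_effects=("x",), random_intercept="subsite")
        ours = fit_community_model(spec, data, backend="fast")
        ref = sm.MixedLM(y, np.column_stack([np.ones(150), x]), groups=g).fit(reml=False)
        assert ours.coefficients["estimate"].to_numpy() == pytest.approx(
            np.asarray(ref.fe_params), abs=1e-3
        )

    def test_binomial_glmm_matches_lme4(self, tmp_path):
        """Independent oracle: lme4's glmer on identical data (Laplace vs our
        adaptive quadrature; coefficients agree to well under reporting
        precision)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; lme4 cross-check cannot run")
        rng = np.random.default_rng(8)
        n_groups, per_group = 30, 8
        g = np.repeat(np.arange(n_groups), per_group)
        x = rng.normal(size=n_groups * per_group)
        eta = -0.3 + 0.8 * x + rng.normal(0, 0.6, n_groups)[g]
        trials = rng.integers(1, 7, size=n_groups * per_group)
        y = rng.binomial(trials, expit(eta))
        csv = tmp_path / "glmm.csv"
        pd.DataFrame({"y": y, "n": trials, "x": x, "g": g}).to_csv(csv, index=False)

        script = (
            f'd <- read.csv("{csv}"); suppressMessages(library(lme4)); '
            "f <- glmer(cbind(y, n-y) ~ x + (1|g), data=d, family=binomial); "
            'cat(fixef(f), sqrt(unlist(VarCorr(f))), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref_intercept, ref_slope, ref_sigma = map(float, out.stdout.split())

        data = pd.DataFrame({
            "n_boreal_colonisers": y.astype(float),
            "n_colonisers": trials.astype(float),
            "x": x,
            "subsite": [f"s{i}" for i in g],
        })
        spec = ModelSpec(
            response="n_boreal_colonisers", trials="n_colonisers",
            family="binomial_logit", fixed_effects=("x",),
            random_intercept="subsite",
        )
        ours = fit_community_model(spec, data, backend="fast")
        est = ours.coefficients.set_index("term")["estimate"]
        assert est["intercept"] == pytest.approx(ref_intercept, abs=5e-3)
        assert est["x"] == pytest.approx(ref_slope, abs=5e-3)
        sigma_b = np.exp(ours.result.theta[2])
        assert sigma_b == pytest.approx(ref_sigma, abs=0.02)

    def test_single_subsite_degrades_with_warning(self):
        data = self.simulate_binomial(seed=11).assign(subsite="only_one")
        spec = ModelSpec(
            response="n_boreal_colonisers", trials="n_colonisers",
            family="binomial_logit", fixed_effects=("x",),
            random_intercept="subsite",
        )
        with pytest.warns(UserWarning, match="single level"):
            fit = fit_community_model(spec, data, backend="fast")
        assert fit.converged

    def test_mcmc_backend_agrees_with_fast_backend(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=120)
        y = 0.4 + 0.9 * x + rng.normal(0, 1.0, 120)
        data = pd.DataFrame({"bai": y, "x": x})
        spec = ModelSpec(response="bai", family="gaussian_identity",
                         fixed_effects=("x",))
        fast = fit_community_model(spec, data, backend="fast")
        mcmc = fit_community_model(spec, data, backend="mcmc",
                                   n_iterations=600, n_warmup=200, seed=4)
        assert mcmc.backend == "mcmc"
        assert mcmc.coefficients["estimate"].to_numpy() == pytest.approx(
            fast.coefficients["estimate"].to_numpy(), abs=0.1
        )


class TestSpeciesModel:
    def counts_frame(self, seed=13, ratio=1.0, n=120):
        rng = np.random.default_rng(seed)
        cls = rng.choice(["Boreal", "BorealTundra"], size=n)
        mu = np.where(cls == "Boreal", 3.0, 3.0 * ratio)
        k = 2.0
        y = rng.negative_binomial(k, k / (k + mu))
        return pd.DataFrame({
            "taxon": [f"sp{i}" for i in range(n)],
            "cls": cls,
            "times_colonised": np.maximum(y, 1),  # colonised at least once
            "times_lost": y,
            "mean_abundance_change": rng.normal(0.2, 0.5, n),
        })

    def test_equal_counts_give_ratio_interval_containing_one(self):
        data = self.counts_frame(ratio=1.0)
        spec = ModelSpec(response="times_colonised", family="negbinom_log",
                         fixed_effects=("cls",))
        fit = fit_species_model(spec, data, backend="fast")
        ratios = fit.rate_ratios().set_index("term")
        row = ratios.loc[[t for t in ratios.index if t.startswith("cls[")][0]]
        assert row["lower95"] < 1.0 < row["upper95"]

    def test_trait_unit_change_shifts_only_intercept(self):
        rng = np.random.default_rng(14)
        data = self.counts_frame()
        data["seed_mass"] = rng.lognormal(0, 1, len(data))
        spec_mg = ModelSpec(response="times_colonised", family="negbinom_log",
                            fixed_effects=("seed_mass",),
                            log_transform=("seed_mass",))
        fit_mg = fit_species_model(spec_mg, data, backend="fast")
        data_g = data.assign(seed_mass=data["seed_mass"] / 1000.0)
        fit_g = fit_species_model(spec_mg, data_g, backend="fast")
        slope_mg = fit_mg.coefficients.set_index("term").loc["log_seed_mass"]
        slope_g = fit_g.coefficients.set_index("term").loc["log_seed_mass"]
        assert slope_mg["estimate"] == pytest.approx(slope_g["estimate"], abs=1e-3)
        assert slope_mg["clear_effect"] == slope_g["clear_effect"]

    def test_abundance_model_filters_to_increasing_species(self):
        data = self.counts_frame()
        spec = ModelSpec(response="mean_abundance_change",
                         family="gaussian_identity", fixed_effects=("cls",))
        fit = fit_species_model(spec, data, backend="fast")
        assert fit.n_obs == (data["mean_abundance_change"] > 0).sum()

    def test_constant_trait_dropped_with_warning(self):
        data = self.counts_frame()
        data["constant_trait"] = 1.0
        spec = ModelSpec(response="times_colonised", family="negbinom_log",
                         fixed_effects=("cls", "constant_trait"))
        with pytest.warns(UserWarning, match="constant_trait"):
            fit = fit_species_model(spec, data, backend="fast")
        assert "constant_trait" not in set(fit.coefficients["term"])


class TestPairwiseContrasts:
    def test_contrasts_cover_reference_level(self):
        rng = np.random.default_rng(15)
        cls = rng.choice(["Boreal", "BorealTundra", "Ubiquitous"], size=240)
        shift = {"Boreal": 0.0, "BorealTundra": 1.0, "Ubiquitous": 1.0}
        y = rng.poisson([np.exp(1 + shift[c]) for c in cls])
        data = pd.DataFrame({"taxon": range(240), "cls": cls,
                             "times_colonised": np.maximum(y, 1)})
        spec = ModelSpec(response="times_colonised", family="negbinom_log",
                         fixed_effects=("cls",),
                         reference_levels={"cls": "Boreal"})
        fit = fit_species_model(spec, data, backend="fast")
        contrasts = pairwise_contrasts(fit, "cls")
        assert len(contrasts) == 3  # 3 levels → 3 pairs
        bt_vs_b = contrasts.set_index(["level_a", "level_b"]).loc[
            ("Boreal", "BorealTundra")
        ]
        assert bt_vs_b["clear_effect"]  # strong simulated difference
        bt_vs_u = contrasts.set_index(["level_a", "level_b"]).loc[
            ("BorealTundra", "Ubiquitous")
        ]
        assert bt_vs_u["lower95"] < 0 < bt_vs_u["upper95"]


class TestFilterTraits:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["taxon", "trait", "value"])

    def test_outlier_removed_then_mean_of_rest(self):
        rows = [("sp", "height", v) for v in (1.0, 1.1, 0.9, 1.05, 0.95)]
        rows.append(("sp", "height", 10.0))  # ~10 SD out
        out = filter_traits(self.frame(rows))
        assert out.loc[0, "height"] == pytest.approx(1.0, abs=0.02)

    def test_too_few_records_dropped(self):
        rows = [("sp", "height", v) for v in (1.0, 1.1, 0.9, 1.05)]
        out = filter_traits(self.frame(rows))
        assert "height" not in out.columns or out.empty

    def test_identical_records_not_outliers(self):
        rows = [("sp", "sla", 12.0)] * 6
        out = filter_traits(self.frame(rows))
        assert out.loc[0, "sla"] == pytest.approx(12.0)

    def test_per_trait_independence(self):
        rows = (
            [("sp", "height", v) for v in (1, 1.1, 0.9, 1.05, 0.95)]
            + [("sp", "sla", v) for v in (10, 11)]  # too few
        )
        out = filter_traits(self.frame(rows))
        assert "height" in out.columns
        assert "sla" not in out.columns


class TestCorrelateMethods:
    def test_identical_and_negated(self):
        x = np.array([0.1, 0.5, -0.3, 1.2])
        assert correlate_methods(x, x) == pytest.approx(1.0)
        assert correlate_methods(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_methods([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlate_methods([1, 2], [3, 4])
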