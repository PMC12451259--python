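"""Fit community-level driver models for the borealisation indices.

Simulates a resurvey network whose colonisation probability depends on
summer temperature and treeline distance, then fits the full-range BCI
binomial model (boreal colonisers out of total colonisers, logit link)
and the full-range BAI Gaussian model, each with a subsite random
intercept. The fast maximum-likelihood backend is used here; pass
backend="mcmc" for the Bayesian fit (4 chains × 2000 iterations).
"""

from borealis import pipeline
from borealis.inference import ModelSpec, fit_community_model
from borealis.simulate import SimulationConfig, generate_dataset

dataset = generate_dataset(SimulationConfig(n_study_areas=12, seed=3))
series = pipeline.standardise(dataset.records).series
classes = pipeline.classify(dataset.zone_occurrence)
plots, _ = pipeline.compute_indices(series, classes)
data = plots.merge(dataset.covariates, on=["plot", "subsite", "study_area"])

for name, spec in {
    "full-range BCI (binomial, logit)": ModelSpec(
        response="n_boreal_colonisers", trials="n_colonisers",
        family="binomial_logit", subset="full_range",
        fixed_effects=("summer_temp_clim", "distance_treeline_raw"),
        random_intercept="subsite",
    ),
    "full-range BAI (Gaussian)": ModelSpec(
        response="bai", family="gaussian_identity", subset="full_range",
        fixed_effects=("summer_temp_clim", "distance_treeline_raw"),
        random_intercept="subsite",
    ),
}.items():
    fit = fit_community_model(spec, data, backend="fast")
    print(f"\n{name} — {fit.n_obs} plots, converged={fit.converged}")
    print(fit.coefficient_table().round(4).to_string(index=False))

print()
print("A 'clear effect' marks a coefficient whose 95% interval excludes")
print("zero. The default generator scales every species' colonisation odds")
print("by the covariates equally, so the *share* of colonisers that are")
print("boreal — what the binomial BCI model measures — carries no covariate")
print("signal and intervals straddling zero are the expected outcome here.")
print("Set boreal_colonisation_effect > 0 in SimulationConfig to give")
print("boreal species a specific advantage and shift the intercept upward.")
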