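"""Let heterogeneity itself depend on covariates (the scale submodel).

A location-scale meta-regression models each pair's residual
heterogeneity as log-linear in scale covariates, so heterogeneity is no
longer one number but a function: here phi_i depends on whether the two
experiments shared a language and on how cited the original was.
evaluate_scale reads that function off at chosen covariate values; a
multiplicative phi below 1 is reported as 1 (no under-dispersion).
"""

from replimeta import evaluate_scale, fit_ls_multiplicative, make_case_study_like

dataset = make_case_study_like(seed=1)

fit = fit_ls_multiplicative(
    dataset,
    location_covariates=["se_o", "same_language"],
    scale_covariates=["same_language", "log_citations_o"],
)

print("scale coefficients (log phi):")
for name, c in fit.scale_coefficients.items():
    print(f"  {name:24s} {c.estimate:7.2f}  ({c.ci_low:.2f} to {c.ci_high:.2f})")

mean_logcit = 4.06
for lang in (0.0, 1.0):
    got = evaluate_scale(
        fit, {"same_language[yes]": lang, "log_citations_o": mean_logcit}
    )
    label = "same language" if lang else "different languages"
    clamp = " (clamped from %.2f)" % got.raw_value if got.clamped else ""
    print(f"phi for {label:20s} at mean log-citations: {got.value:.2f}{clamp}")
print("phi = 1 means a pair's differences vary no more than sampling error")
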