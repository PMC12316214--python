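"""Two-stage exhaustive AIC model selection.

Stage 1 tries every admissible subset of candidate location covariates
(the original SE is forced into every model; a share-of-male-authors
covariate may only enter together with its author count).  Stage 2
keeps the stage-1 winner's covariates as the pool and jointly
re-selects location and scale sets, each fitted as a location-scale
model.
"""

from replimeta import make_case_study_like, select_two_stage

dataset = make_case_study_like(seed=1)
candidates = [
    dataset.meta(n)
    for n in ("nb_authors_o", "share_male_o", "log_citations_o", "same_language")
]

stage1, stage2 = select_two_stage(
    dataset, candidates, flavor="multiplicative", criterion="aic", forced=("se_o",)
)

print(f"stage 1: {stage1.n_models_evaluated} location models evaluated")
print(f"  winner: {stage1.best.location_set} "
      f"(AIC {stage1.ranked[0].criterion_value:.2f})")
print(f"stage 2: {stage2.n_models_evaluated} location-scale models evaluated")
print(f"  winner location: {stage2.best.location_set}")
print(f"  winner scale:    {stage2.best.scale_set or '(none)'} "
      f"(AIC {stage2.ranked[0].criterion_value:.2f})")
print("lower AIC = better fit after penalizing parameters (k = p + q + 2)")
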