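"""Quantify shrinkage and between-study-pair heterogeneity in a project.

Builds a synthetic 87-pair replication project, tests whether the
original-vs-replication differences vary more than chance allows, and
fits the two unadjusted heterogeneity models.  The pooled difference
(delta) measures shrinkage: how much smaller replication effects are on
average.  phi inflates every pair's variance multiplicatively; tau2
adds a constant between-pair variance.  The prediction interval says
what difference to expect for the next study pair.
"""

from replimeta import (
    fit_additive,
    fit_multiplicative,
    make_case_study_like,
    overall_q_test,
    prediction_interval,
)

dataset = make_case_study_like(seed=1)
print(f"{len(dataset)} study pairs "
      f"({sum(p.project == 'RPP' for p in dataset.pairs)} RPP, "
      f"{sum(p.project == 'RPEE' for p in dataset.pairs)} RPEE)")

q = overall_q_test(dataset)
verdict = "beyond chance" if q.p_value < 0.05 else "compatible with chance"
print(f"overall Q = {q.q_total:.1f} on {q.df} df, p = {q.p_value:.2g}"
      f"  -> heterogeneity {verdict}")

mult = fit_multiplicative(dataset)
add = fit_additive(dataset)
print(f"multiplicative: delta = {mult.delta:.2f} "
      f"({mult.ci_low:.2f} to {mult.ci_high:.2f}), phi = {mult.heterogeneity.value:.3f}")
print(f"additive:       delta = {add.delta:.2f} "
      f"({add.ci_low:.2f} to {add.ci_high:.2f}), tau2 = {add.heterogeneity.value:.3f}")

low, high = prediction_interval(add, 0.95)
print(f"95% prediction interval for a new pair's difference: "
      f"{low:.2f} to {high:.2f}")
print("a positive delta means replication effects shrink relative to originals")
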