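"""Dose-response models for two-year survival and neutropenia.

Builds the 8 Gy/1 fr dose table, joins it with the arm-level outcomes
(the toxicity endpoint drops the one study that did not report
neutropenia), and fits both model variants. The random-intercept
(binomial-normal mixed) fit is the reference: its coefficients say that
every extra Gy of combined EQD2 raises the log-odds of two-year survival
by ~0.006 and of grade >= 2 neutropenia by ~0.018. Predicted
probabilities with 95% bands are printed on a small dose grid.
"""

from alphalq import (
    OutcomeDataset,
    build_dose_table,
    builtin_arms,
    compare_schedule_effect,
    fit_logistic,
    predict,
    standard_scenarios,
)

arms = builtin_arms()
scenarios = standard_scenarios()
summaries = build_dose_table(arms, scenarios[0])

for endpoint in ("os_2y", "tox"):
    data = OutcomeDataset.from_arms(arms, summaries, endpoint)
    print(f"\n=== {endpoint} ({len(data)} arms, {scenarios[0].label}) ===")
    for variant in ("fixed", "random_intercept"):
        fit = fit_logistic(data, variant)
        print(
            f"{variant:16s} intercept={fit.intercept:+.3f} (SE {fit.se_intercept:.3f})  "
            f"slope={fit.slope:+.4f}/Gy (SE {fit.se_slope:.4f})  p_slope={fit.p_slope:.3f}"
        )
    fit = fit_logistic(data, "random_intercept")
    print(predict(fit, [0, 50, 100, 150]).round(3).to_string(index=False))

# schedule sensitivity of the survival slope across the three EBRT scenarios
fits = {
    sc.label: fit_logistic(
        OutcomeDataset.from_arms(arms, build_dose_table(arms, sc), "os_2y"),
        "random_intercept",
    )
    for sc in scenarios
}
print("\n=== EBRT-schedule sensitivity (os_2y, mixed fits) ===")
print(compare_schedule_effect(fits).round(4).to_string(index=False))
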