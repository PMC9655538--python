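"""Simulate the full factorial experiment and run the statistical layer.

The design is 2 temperatures x 2 inoculations with n = 12/15/12/8 plants
imaged on days 5-21. The printed output shows the per-day inoculated-vs-
control t-test, the microbe x temperature ANOVA over the whole period, the
relative treatment effects, and an exponential trendline between primary
root length and lateral count.
"""
import numpy as np

from rootscreen.stats_compare import (
    fit_trend, summarize_treatment_curves, ttest_per_timepoint, two_way_anova,
)
from rootscreen.synth_plate import SimParams, simulate_experiment
from rootscreen.timeseries import relative_effect

ds = simulate_experiment(SimParams(rng_seed=1))
traits = ds.truth_traits

print("mean total root length +- SE at 21 DAI:")
curves = summarize_treatment_curves(traits, ["length_total_cm"])
print(curves[curves.dai == 21][["treatment", "n", "mean", "se"]]
      .to_string(index=False))

t21 = traits[traits.dai == 21].groupby("treatment")["length_total_cm"].mean()
print(f"\nheat reduced total root length by "
      f"{-relative_effect(t21['HT-Ctl'], t21['Amb-Ctl']):.0f}% at 21 DAI;")
print(f"inoculation increased it by "
      f"{relative_effect(t21['Amb-PsJN'], t21['Amb-Ctl']):.0f}% (ambient) and "
      f"{relative_effect(t21['HT-PsJN'], t21['HT-Ctl']):.0f}% (high temp)")

r = ttest_per_timepoint(traits, "length_total_cm", dai=21,
                        temperature="ambient")
print(f"\nt-test, inoculated vs control at 21 DAI (ambient): "
      f"t = {r.t_statistic:.2f}, p = {r.p_value:.2g}, "
      f"significant: {r.significant}")

aov = two_way_anova(traits, "length_total_cm", "whole_period")
for name, eff in aov.effects.items():
    print(f"ANOVA {name:<12} F = {eff['F']:8.1f}  p = {eff['p']:.2g}")

amb = traits[traits.treatment == "Amb-Ctl"]
fit = fit_trend(amb["length_primary_cm"], amb["n_lat1"] + 1.0, "exponential",
                "primary length", "n lat1 + 1", "Amb-Ctl")
print(f"\nexponential trend of lateral count vs primary length (Amb-Ctl): "
      f"R^2 = {fit.r_squared:.3f} on the log scale")
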