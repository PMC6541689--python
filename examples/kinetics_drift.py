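"""Time stability of the bolus-only ECV measurement.

Evaluates the noiseless two-compartment model for one subject per group
and prints the ECV a perfect scanner would measure at 5, 15 and 25 min
post-bolus.  The point of the bolus-only technique is that these three
numbers barely differ: the blood/interstitium concentration ratio is
nearly constant (dynamic equilibrium), so any single post-contrast time
point suffices.
"""

import hepecv as h

params = h.default_kinetics_params()
print(f"exchange rate {params.exchange_rate}/min, washout rates "
      f"{params.rate_fast}/{params.rate_slow} per min\n")
print(f"{'group':<12}{'true v_e':>9}{'ECV@5':>8}{'ECV@15':>8}{'ECV@25':>8}{'drift (pp)':>12}")
for spec in h.default_cohort_specs():
    subject = h.generate_cohort(spec)[0]
    ecv = {t: 100 * h.true_measured_ecv(float(t), subject, params) for t in (5, 15, 25)}
    print(
        f"{spec.group_label:<12}{100 * subject.true_ve:>9.2f}"
        f"{ecv[5]:>8.2f}{ecv[15]:>8.2f}{ecv[25]:>8.2f}{ecv[25] - ecv[5]:>12.2f}"
    )
print("\nECV is in percent; the 5->25-min drift stays well under 2.1 points,")
print("and the measured value tracks the subject's true extracellular fraction.")
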