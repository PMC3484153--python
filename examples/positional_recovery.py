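"""Monte-Carlo recovery of the generating effects.

Simulates 25 independent 88-siRNA screens, refits the reduced linear
model on each, and compares the averaged estimates with the generating
parameters (decay -1% per 100 bp; CDS and 3'UTR more potent than the
5'UTR by 39 and 13 points).  scripts/acceptance.py runs the same study
at 200 repetitions.
"""

from sirnakit.recovery import recovery_summary, reduced_model_recovery

summary = recovery_summary(reduced_model_recovery(n_reps=25, base_seed=1))
print(f"{int(summary['n_reps'])} simulated screens, 88 siRNAs each\n")
for label, key, truth in (
    ("positional slope (%/100bp)", "slope_per_100bp", -1.0),
    ("CDS vs 5'UTR offset (%)", "cds_offset", 39.0),
    ("3'UTR vs 5'UTR offset (%)", "utr3_offset", 13.0),
):
    mean, se = summary[f"{key}_mean"], summary[f"{key}_se"]
    print(f"{label:<28} generating {truth:+6.1f}   "
          f"recovered {mean:+7.2f} +/- {se:.2f} (MC se)")
print("\nEach recovered mean should sit within a few Monte-Carlo standard "
      "errors of its generating value: the fitting pipeline is unbiased "
      "for the effects it targets.")
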