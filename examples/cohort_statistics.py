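"""Matched-cohort statistics: group tests, cutoffs, classification, ICC.

Simulates 16 matched disease/control pairs with disease shifts of the
magnitudes seen in hypertensive retinopathy (AVR -0.09, TI +8, mean-D
-0.04), then runs the full statistical layer: paired Wilcoxon signed-rank
tests, k-means-derived abnormality cutoffs, 2x2 classification with exact
binomial intervals, and two-rater intraclass correlations.
"""

from retmorph import pipeline, synthetic

cohort = synthetic.generate_cohort(16, seed=7)
report = pipeline.analyze_cohort(cohort)

print(f"{report['n_pairs']} matched pairs")
for idx, w in report["wilcoxon"].items():
    print(f"  {idx:7s}: disease {w['disease_mean']:7.3f}  "
          f"control {w['control_mean']:7.3f}  p = {w['p_value']:.4f}")
c = report["cutoffs"]
print(f"k-means cutoffs: AVR < {c['avr_max']:.3f}, TI > {c['ti_min']:.1f}, "
      f"mean-D < {c['mean_d_max']:.3f}")
avr_cls = report["classification"]["avr"]
lo, hi = avr_cls["ci_95"]["sensitivity"]
print(f"AVR classification: sensitivity {avr_cls['sensitivity']:.1f}% "
      f"({lo:.1f}-{hi:.1f}), specificity {avr_cls['specificity']:.1f}%")
print("interrater ICC (%):",
      {k: round(v, 1) for k, v in report["icc"].items()})
print()
print("All three indices separate the groups (p < 0.05) in the directions")
print("disease AVR and mean-D lower, TI higher; the cutoffs fall between")
print("the group means.")
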