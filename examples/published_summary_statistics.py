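"""Reproduce the published group-comparison chains from summary statistics.

The packaged fixtures store the published per-group (n, mean, SD) triples;
the pooled-variance t-test recomputes the printed effect sizes, SEMs and
t statistics from them.
"""

from brainpad import SummaryStats, chi_squared_2x2, t_test_from_summary
from brainpad.synthetic import sex_counts_cohort1, table1_fixture

t1 = table1_fixture()


def ss(label, group):
    e = t1[(label, group)]
    return SummaryStats(e.n, e.mean, e.sd, f"{label}/{group}")


for label, unit in (("brainPAD", "years"), ("iq", "points"), ("bmi", "kg/m^2")):
    gc = t_test_from_summary(ss(label, "PWS"), ss(label, "Control"))
    print(f"{label:>8}: effect {gc.effect:+7.2f} {unit}, SEM {gc.se:.2f}, "
          f"t({gc.df:.0f}) = {gc.t:.2f}, p = {gc.p:.3g}, "
          f"95% CI [{gc.ci95[0]:.2f}, {gc.ci95[1]:.2f}]")

chi2, p = chi_squared_2x2(sex_counts_cohort1())
print(f"sex ratio: chi2 = {chi2:.2f}, p = {p:.2f}")

print("\nPositive brain-PAD effects mean the patient group's brains look older"
      "\nthan chronological age relative to controls; the IQ and BMI rows are"
      "\nthe cohort-characteristic comparisons computed the same way.")
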