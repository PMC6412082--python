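"""Simulate a cohort with a known 7-year brain-aging offset and recover it.

A normative training cohort (n=300, ages 19-56) fits the similarity-kernel
GP age model; a patient/control test cohort whose patients' tissue maps were
generated 7 years "older" than their chronological age is then scored, and
the pooled t-test on brain-PAD estimates the offset.
"""

from brainpad.experiments import recovery_experiment

result = recovery_experiment(seed=1, delta=7.0, n_train=300)
lo, hi = result.ci95
print(f"true group aging offset : {result.true_delta:.1f} years")
print(f"estimated brain-PAD diff: {result.effect:.2f} years "
      f"(95% CI [{lo:.2f}, {hi:.2f}]); CI covers truth: {result.covered}")

print("\nThe estimate sits slightly below the truth: kernel regression on "
      "\nnoisy voxel features attenuates predictions toward the training mean "
      "\n(regression dilution), a documented property of brain-age models.")
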