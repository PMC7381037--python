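"""Plan the size of a screening validation study.

How many prescriptions must an expert-review panel label to establish a
screen's sensitivity and specificity of 80% to within +/-5 percentage
points at the 5% significance level, when only 1.7% of prescriptions are
expected to be inappropriate?
"""

from rxscreen import SampleSizeSpec, sample_size

spec = SampleSizeSpec(
    expected_sensitivity=0.80,
    expected_specificity=0.80,
    alpha_level=0.05,
    allowable_error=0.05,
    prevalence=0.017,
)
n = sample_size(spec)
print(f"required prescriptions: {n}")
print(
    "Meaning: the binding constraint is the rare positive class — the study "
    "needs 246 inappropriate prescriptions, and at 1.7% prevalence that "
    f"means reviewing {n} prescriptions in total."
)
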