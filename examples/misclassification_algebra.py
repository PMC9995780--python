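"""How much underdiagnosis does a biobank's recorded prevalence imply?

Under case-only misclassification the recorded prevalence is
true_prevalence * (1 - pi), so an assumed population prevalence plus the
prevalence seen in health records pins down the underdiagnosis rate pi.
"""

from underdiag import PrevalencePair, misclassification_rate, observed_prevalence

ASSUMED_TRUE_PREVALENCE = 0.25  # plausible population OSA prevalence

for name, recorded in [("UK Biobank", 0.01), ("FinnGen", 0.08)]:
    pi = misclassification_rate(PrevalencePair(ASSUMED_TRUE_PREVALENCE, recorded))
    print(f"{name}: recorded prevalence {recorded:.0%} -> "
          f"implied misclassification rate {pi:.0%}")

# and the forward direction: what a 68% underdiagnosis rate leaves visible
print(f"25% true prevalence thinned at pi=0.68 -> recorded "
      f"{observed_prevalence(0.25, 0.68):.0%}")
print("\nInterpretation: at these rates the large majority of true cases sit")
print("in the control group of any case-control analysis built on the records.")
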