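"""Reverse mediation: inferring a variant-disease OR from symptom associations.

If a variant g affects a well-recorded symptom (e.g. daytime sleepiness) only
through an underdiagnosed disease, the quotient estimator
exp(log OR_g_symptom / log OR_disease_symptom) inverts the chain on the
log-odds scale. The recovery study below shows why this must be used with
care: with a *binary* mediator the quotient's large-sample limit sits far
below the conditional per-allele effect, because only the variant's
probability-scale shift in the disease propagates to the symptom.
"""

from underdiag import (
    MediationScenario,
    mediation_recovery_study,
    population_quotient,
    reverse_mediation_estimate,
)

# point estimation from two user-supplied odds ratios
est = reverse_mediation_estimate(1.05, 2.0)
print(f"OR(g->symptom)=1.05, OR(disease->symptom)=2.0 -> "
      f"estimated OR(g->disease) = {est:.3f}")

# simulated accuracy check: chain g -> disease -> symptom, true log-OR 0.1
sc = MediationScenario(beta0_osa=-3.0, betag_osa=0.1, gamma0=-3.0,
                       gamma_osa=1.0, maf=0.3, n=100_000, reps=40, seed=11)
report = mediation_recovery_study(sc)
print(f"\nrecovery study (disease prev {report.osa_prevalence:.1%}, "
      f"symptom prev {report.eds_prevalence:.1%}, {report.n_valid} replicates):")
print(f"  true per-allele log-OR(g->disease):     {sc.betag_osa:.4f}")
print(f"  estimator's large-sample limit:         {population_quotient(sc):.4f}")
print(f"  simulated mean log estimate:            {report.mean_log_or_hat:.4f}"
      f"  (MC SE {report.mc_se:.4f})")
print("\nInterpretation: the simulated mean tracks the deterministic limit,")
print("not the generating effect — the quotient is a lower bound in practice,")
print("and any use of it should be calibrated with exactly this kind of")
print("simulation for the prevalences at hand.")
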