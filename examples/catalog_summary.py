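"""Summarise the androgen-regulated isoform-pair catalogue.

Loads the packaged 73-event catalogue, partitions it by event mechanism and
predicted protein outcome, and intersects it with the gene-level androgen
response lists.
"""

import warnings

import isopair as ip

events = ip.load_catalog()
summary = ip.summarize_catalog(events)

print(f"catalogued events: {summary.total}")
print(f"  alternative promoters: {summary.by_event_type[ip.EventType.ALT_PROMOTER]}")
print(f"  splicing events:       {summary.n_splicing} "
      f"({summary.by_event_type[ip.EventType.ALT_EXON]} cassette/alt exons + "
      f"{summary.by_event_type[ip.EventType.RETAINED_INTRON]} retained intron)")
print(f"  alternative 3' ends:   {summary.by_event_type[ip.EventType.ALT_3PRIME_END]}")
print(f"protein outcome: {summary.by_protein_consequence[ip.ProteinConsequence.CODING_CHANGE]}"
      f" coding change, {summary.n_noncoding_switch} coding<->non-coding, "
      f"{summary.by_protein_consequence[ip.ProteinConsequence.UTR5_ONLY]} 5'UTR-only")

lists = ip.load_gene_response_lists()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # one response-list gene is not catalogued
    changed = ip.intersect_expression_change(events, lists, "lncap")
print(f"genes also changing overall expression with androgens: {len(changed)}/73")

# Most androgen-driven isoform changes come from promoter choice, and most
# are predicted to alter the encoded protein; about three quarters of the
# genes also shift their total expression level.
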