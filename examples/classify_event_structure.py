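"""Name the structural difference between two transcript models.

Builds small exon chains (as would be read from a GTF or BED12 file with
``isopair.read_transcripts``) and classifies each pair: alternative
promoter, alternative 3' end, cassette exon or retained intron.  The
comparison is strand-aware.
"""

import isopair as ip

TM = ip.TranscriptModel
pairs = [
    ("promoter choice (minus strand)",
     TM("long", "chr5", "-", ((1000, 1200), (5000, 5100), (8000, 8200))),
     TM("short", "chr5", "-", ((1000, 1200), (5000, 5100), (9000, 9150)))),
    ("cassette exon",
     TM("incl", "chr5", "+", ((100, 200), (400, 480), (700, 800))),
     TM("excl", "chr5", "+", ((100, 200), (700, 800)))),
    ("retained intron",
     TM("spliced", "chr5", "+", ((100, 200), (400, 500))),
     TM("retained", "chr5", "+", ((100, 500),))),
    ("alternative 3' end",
     TM("proximal", "chr5", "+", ((100, 200), (400, 500))),
     TM("distal", "chr5", "+", ((100, 200), (400, 900)))),
]

for name, a, b in pairs:
    call = ip.classify_pair(a, b)
    print(f"{name:32s} -> {call.event_type.value:15s} {call.details}")

# On the minus strand the genomic-rightmost exon is the first exon, so a
# difference there is an alternative-promoter event; each remaining pair
# matches its constructed class.
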