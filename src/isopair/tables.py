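"""Loaders for the packaged per-gene statistics tables.

These tables carry the published tumour-vs-normal differential statistics
and the Gleason/stage correlation statistics for the catalogued events,
together with the printed consistency call for each row.  They serve both
as inputs to the consistency classifier and as golden outputs for
validating it.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import NamedTuple, Optional

from .catalog import fixture_path
from .consistency import Label
from .diffstats import PairStatsCorr, PairStatsDE

#: Printed call strings mapped to labels; a trailing "-" marks partial calls.
_PRINTED_LABELS = {
    "Consistent": (Label.CONSISTENT, False),
    "Consistent -": (Label.CONSISTENT, True),
    "Opposite": (Label.OPPOSITE, False),
    "Opposite -": (Label.OPPOSITE, True),
    "Inconclusive": (Label.INCONCLUSIVE, False),
    "Not assessed": (Label.NOT_ASSESSED, False),
}


class PrintedCall(NamedTuple):
    label: Label
    partial: bool


def _num(value: str) -> Optional[float]:
    value = value.strip()
    return float(value) if value else None


class DeStatsTable(NamedTuple):
    stats: dict[str, PairStatsDE]
    printed: dict[str, PrintedCall]
    order: list[str]


class CorrStatsTable(NamedTuple):
    stats: dict[str, PairStatsCorr]
    printed: dict[str, PrintedCall]
    order: list[str]


def load_tumour_normal_stats(path: Optional[Path | str] = None) -> DeStatsTable:
    """Tumour-vs-normal differential statistics per catalogued event."""
    path = fixture_path("tumour_normal") if path is None else Path(path)
    stats: dict[str, PairStatsDE] = {}
    printed: dict[str, PrintedCall] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            gene = row["gene"]
            order.append(gene)
            stats[gene] = PairStatsDE(
                gene=gene,
                iso1_log2fc=_num(row["iso1_log2fc"]),
                iso1_avg_expr=_num(row["iso1_avg_tpm"]),
                iso1_fdr=_num(row["iso1_fdr"]),
                iso2_log2fc=_num(row["iso2_log2fc"]),
                iso2_avg_expr=_num(row["iso2_avg_tpm"]),
                iso2_fdr=_num(row["iso2_fdr"]),
                delta_psi=_num(row["delta_psi"]),
                avg_psi=_num(row["avg_psi"]),
                psi_fdr=_num(row["psi_fdr"]),
            )
            printed[gene] = PrintedCall(*_PRINTED_LABELS[row["printed_call"]])
    return DeStatsTable(stats, printed, order)


def _load_corr(path: Path) -> CorrStatsTable:
    stats: dict[str, PairStatsCorr] = {}
    printed: dict[str, PrintedCall] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            gene = row["gene"]
            order.append(gene)
            stats[gene] = PairStatsCorr(
                gene=gene,
                iso1_rho=_num(row["iso1_rho"]), iso1_fdr=_num(row["iso1_fdr"]),
                iso2_rho=_num(row["iso2_rho"]), iso2_fdr=_num(row["iso2_fdr"]),
                psi_rho=_num(row["psi_rho"]), psi_fdr=_num(row["psi_fdr"]),
            )
            printed[gene] = PrintedCall(*_PRINTED_LABELS[row["printed_call"]])
    return CorrStatsTable(stats, printed, order)


def load_gleason_corr_stats(path: Optional[Path | str] = None) -> CorrStatsTable:
    """Gleason-score correlation statistics per catalogued event."""
    return _load_corr(fixture_path("gleason") if path is None else Path(path))


def load_stage_corr_stats(path: Optional[Path | str] = None) -> CorrStatsTable:
    """Tumour-stage correlation statistics per catalogued event."""
    return _load_corr(fixture_path("stage") if path is None else Path(path))


def screen_significant(
    table: DeStatsTable,
    fdr_threshold: float = 0.05,
    min_delta_psi: float = 0.025,
    assessed: Optional[set[str]] = None,
) -> set[str]:
    """Events with a significant change in either isoform or the ratio.

    Significance means FDR <= threshold for an isoform, or PSI FDR <=
    threshold combined with a ratio change exceeding the minimum magnitude.
    ``assessed`` restricts the screen to the pairs actually evaluable in the
    cohort (both isoforms annotated); by default all rows are screened.
    """
    out = set()
    for gene, s in table.stats.items():
        if assessed is not None and gene not in assessed:
            continue
        iso_sig = any(f is not None and f <= fdr_threshold for f in (s.iso1_fdr, s.iso2_fdr))
        psi_sig = (s.psi_fdr is not None and s.psi_fdr <= fdr_threshold
                   and s.delta_psi is not None and abs(s.delta_psi) > min_delta_psi)
        if iso_sig or psi_sig:
            out.add(gene)
    return out
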