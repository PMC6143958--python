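"""Androgen-regulated isoform-pair catalogue and companion reference lists.

The catalogue describes 73 events in which androgen exposure of LNCaP
prostate-cancer cells changes which mRNA isoform of a gene is expressed:
alternative promoter usage, alternative 3' ends, cassette exons and one
retained intron.  Each event names two isoforms; "isoform 1" and "isoform 2"
define the orientation of the PSI ratio used throughout the package
(PSI = isoform1 / (isoform1 + isoform2)).

The packaged fixtures (catalogue, gene-level response lists, cohort
description, tumour/normal and grade/stage statistics tables) are versioned
TSV transcriptions and are loaded by the functions in this module.
"""

from __future__ import annotations

import csv
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence


class EventType(str, Enum):
    ALT_PROMOTER = "alt_promoter"
    ALT_3PRIME_END = "alt_3prime_end"
    ALT_EXON = "alt_exon"
    RETAINED_INTRON = "retained_intron"


class Action(str, Enum):
    INDUCE = "induce"
    REPRESS = "repress"
    SWITCH = "switch"


class SplicingNote(str, Enum):
    EXON_INCLUDED = "exon_included"
    EXON_EXCLUDED = "exon_excluded"
    INTRON_INCLUDED = "intron_included"


class ProteinConsequence(str, Enum):
    CODING_CHANGE = "coding_change"
    UTR5_ONLY = "utr5_only"
    TO_NONCODING = "to_noncoding"
    FROM_NONCODING = "from_noncoding"
    BOTH_NONCODING = "both_noncoding"


class PcrValidation(str, Enum):
    QIAXEL = "qiaxel"
    SYBR = "sybr"
    NONE = "none"


class CatalogError(ValueError):
    """Raised when a catalogue fixture row cannot be parsed."""


_EVENT_TYPE_STRINGS = {
    "Alternative promoter": EventType.ALT_PROMOTER,
    "Alternative 3' end": EventType.ALT_3PRIME_END,
    "Alternative exon": EventType.ALT_EXON,
    "Retained intron": EventType.RETAINED_INTRON,
}
_EVENT_TYPE_LABELS = {v: k for k, v in _EVENT_TYPE_STRINGS.items()}

_CONSEQUENCE_STRINGS = {
    "Yes": ProteinConsequence.CODING_CHANGE,
    "No (5' UTR)": ProteinConsequence.UTR5_ONLY,
    "Yes (change to non-coding)": ProteinConsequence.TO_NONCODING,
    "Yes (change from non-coding)": ProteinConsequence.FROM_NONCODING,
    "Both non-coding": ProteinConsequence.BOTH_NONCODING,
}
_CONSEQUENCE_LABELS = {v: k for k, v in _CONSEQUENCE_STRINGS.items()}

_VALIDATION_STRINGS = {
    "Yes (Qiaxel)": PcrValidation.QIAXEL,
    "Yes (SYBR)": PcrValidation.SYBR,
    "": PcrValidation.NONE,
}
_VALIDATION_LABELS = {v: k for k, v in _VALIDATION_STRINGS.items()}

# Spreadsheet-mangled or synonymous symbols appearing in the response lists.
GENE_ALIASES = {
    "SEP-05": "SEPT5",
}

_EFFECT_RE = re.compile(
    r"^(Induction of|Repression of|Switch to) (?:promoter|isoform) ([12])"
    r"(?: \((exon included|exon excluded|exon exluded|intron included)\))?$"
)
_ACTION_WORDS = {
    "Induction of": Action.INDUCE,
    "Repression of": Action.REPRESS,
    "Switch to": Action.SWITCH,
}
_NOTE_WORDS = {
    "exon included": SplicingNote.EXON_INCLUDED,
    "exon excluded": SplicingNote.EXON_EXCLUDED,
    "exon exluded": SplicingNote.EXON_EXCLUDED,  # typo present in the source table
    "intron included": SplicingNote.INTRON_INCLUDED,
}


@dataclass(frozen=True)
class AndrogenEffect:
    """Direction of the androgen response for one isoform pair.

    ``action`` says whether androgens induce or repress the ``target_isoform``
    or switch expression toward it; ``splicing_note`` carries the exon/intron
    annotation printed for splicing events.
    """

    action: Action
    target_isoform: int
    splicing_note: Optional[SplicingNote] = None

    def __post_init__(self) -> None:
        if self.target_isoform not in (1, 2):
            raise ValueError(f"target_isoform must be 1 or 2, got {self.target_isoform}")

    @classmethod
    def parse(cls, text: str) -> "AndrogenEffect":
        m = _EFFECT_RE.match(text.strip())
        if m is None:
            raise CatalogError(f"unrecognised androgen-effect string: {text!r}")
        action = _ACTION_WORDS[m.group(1)]
        note = _NOTE_WORDS[m.group(3)] if m.group(3) else None
        return cls(action=action, target_isoform=int(m.group(2)), splicing_note=note)

    def format(self, unit: str = "isoform") -> str:
        """Canonical catalogue string for this effect (typo-normalised)."""
        word = {Action.INDUCE: "Induction of", Action.REPRESS: "Repression of",
                Action.SWITCH: "Switch to"}[self.action]
        s = f"{word} {unit} {self.target_isoform}"
        if self.splicing_note is not None:
            note = {SplicingNote.EXON_INCLUDED: "exon included",
                    SplicingNote.EXON_EXCLUDED: "exon excluded",
                    SplicingNote.INTRON_INCLUDED: "intron included"}[self.splicing_note]
            s += f" ({note})"
        return s


_SPAN_RE = re.compile(r"^(\S+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class GenomicSpan:
    """1-based inclusive genomic interval (hg19, UCSC browser convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} > end {self.end}")

    @classmethod
    def parse(cls, text: str) -> "GenomicSpan":
        m = _SPAN_RE.match(text.replace(" ", ""))
        if m is None:
            raise CatalogError(f"malformed genomic span: {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))

    def format(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class IsoformAnnotation:
    genomic_span: Optional[GenomicSpan]
    refseq_id: Optional[str]
    ucsc_id: Optional[str]

    @property
    def annotated(self) -> bool:
        """True when the isoform carries a transcript identifier in the reference annotation."""
        return self.ucsc_id is not None


@dataclass(frozen=True)
class IsoformPairEvent:
    gene: str
    event_type: EventType
    androgen_effect: AndrogenEffect
    raw_effect: str
    isoform1: IsoformAnnotation
    isoform2: IsoformAnnotation
    protein_consequence: ProteinConsequence
    pcr_validated: PcrValidation
    tcga_comparable: bool

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.tcga_comparable and not (self.isoform1.annotated and self.isoform2.annotated):
            raise ValueError(
                f"{self.gene}: comparable events need transcript ids for both isoforms")


FIXTURE_NAMES = {
    "catalog": "androgen_event_catalog.tsv",
    "gene_response": "gene_response_lists.tsv",
    "cohort": "cohort_description.tsv",
    "tumour_normal": "tumour_normal_stats.tsv",
    "gleason": "gleason_corr_stats.tsv",
    "stage": "stage_corr_stats.tsv",
}


def fixture_path(key: str) -> Path:
    """Filesystem path of a packaged fixture table."""
    return Path(str(resources.files("isopair").joinpath("data", FIXTURE_NAMES[key])))


_CATALOG_COLUMNS = [
    "gene", "event_type", "effect",
    "iso1_span", "iso1_refseq", "iso1_ucsc",
    "iso2_span", "iso2_refseq", "iso2_ucsc",
    "protein_consequence", "validation", "comparable",
]


def _parse_isoform(span: str, refseq: str, ucsc: str) -> IsoformAnnotation:
    parsed_span = GenomicSpan.parse(span) if span.strip() else None
    clean = lambda v: None if v.strip() in ("", "Not annotated") else v.strip()
    return IsoformAnnotation(parsed_span, clean(refseq), clean(ucsc))


def load_catalog(path: Optional[Path | str] = None) -> list[IsoformPairEvent]:
    """Load the androgen-regulated event catalogue from its TSV fixture.

    Raises :class:`CatalogError` naming the offending row for malformed
    spans, unknown event-type strings or unknown effect strings.
    """
    path = fixture_path("catalog") if path is None else Path(path)
    events: list[IsoformPairEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is not None and reader.fieldnames != _CATALOG_COLUMNS:
            raise CatalogError(f"unexpected catalogue header: {reader.fieldnames}")
        for i, row in enumerate(reader, start=2):
            try:
                event_type = _EVENT_TYPE_STRINGS.get(row["event_type"])
                if event_type is None:
                    raise CatalogError(f"unknown event type {row['event_type']!r}")
                consequence = _CONSEQUENCE_STRINGS.get(row["protein_consequence"])
                if consequence is None:
                    raise CatalogError(
                        f"unknown protein consequence {row['protein_consequence']!r}")
                validation = _VALIDATION_STRINGS.get(row["validation"])
                if validation is None:
                    raise CatalogError(f"unknown validation flag {row['validation']!r}")
                events.append(IsoformPairEvent(
                    gene=row["gene"],
                    event_type=event_type,
                    androgen_effect=AndrogenEffect.parse(row["effect"]),
                    raw_effect=row["effect"],
                    isoform1=_parse_isoform(row["iso1_span"], row["iso1_refseq"], row["iso1_ucsc"]),
                    isoform2=_parse_isoform(row["iso2_span"], row["iso2_refseq"], row["iso2_ucsc"]),
                    protein_consequence=consequence,
                    pcr_validated=validation,
                    tcga_comparable=row["comparable"] == "Yes",
                ))
            except (CatalogError, ValueError) as exc:
                raise CatalogError(f"row {i} ({row.get('gene', '?')}): {exc}") from exc
    return events


def write_catalog(events: Sequence[IsoformPairEvent], path: Path | str) -> None:
    """Serialise events back to the fixture TSV dialect (raw effect strings kept)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CATALOG_COLUMNS)
        for e in events:
            def iso_cols(iso: IsoformAnnotation) -> list[str]:
                return [iso.genomic_span.format() if iso.genomic_span else "",
                        iso.refseq_id or "Not annotated",
                        iso.ucsc_id or "Not annotated"]
            writer.writerow([
                e.gene, _EVENT_TYPE_LABELS[e.event_type], e.raw_effect,
                *iso_cols(e.isoform1), *iso_cols(e.isoform2),
                _CONSEQUENCE_LABELS[e.protein_consequence],
                _VALIDATION_LABELS[e.pcr_validated],
                "Yes" if e.tcga_comparable else "No",
            ])


@dataclass
class CatalogSummary:
    total: int
    by_event_type: Counter
    by_protein_consequence: Counter
    by_validation: Counter

    @property
    def n_splicing(self) -> int:
        """Alternative-exon plus retained-intron events."""
        return (self.by_event_type[EventType.ALT_EXON]
                + self.by_event_type[EventType.RETAINED_INTRON])

    @property
    def n_noncoding_switch(self) -> int:
        """Events switching between coding and non-coding mRNA output."""
        return sum(self.by_protein_consequence[c] for c in (
            ProteinConsequence.TO_NONCODING, ProteinConsequence.FROM_NONCODING,
            ProteinConsequence.BOTH_NONCODING))


def summarize_catalog(events: Iterable[IsoformPairEvent]) -> CatalogSummary:
    events = list(events)
    return CatalogSummary(
        total=len(events),
        by_event_type=Counter(e.event_type for e in events),
        by_protein_consequence=Counter(e.protein_consequence for e in events),
        by_validation=Counter(e.pcr_validated for e in events),
    )


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive gene-symbol normalisation with the alias map applied."""
    s = symbol.strip().upper()
    return GENE_ALIASES.get(s, s)


@dataclass
class GeneResponseLists:
    """Gene-level androgen-response calls from the two expression experiments.

    ``lncap_*`` come from LNCaP cells +/- androgen for 24 h; ``reciprocal_*``
    from the reciprocal comparison that also changed in patients following
    androgen deprivation therapy.
    """

    lncap_up: set[str] = field(default_factory=set)
    lncap_down: set[str] = field(default_factory=set)
    lncap_nochange: set[str] = field(default_factory=set)
    reciprocal_up: set[str] = field(default_factory=set)
    reciprocal_down: set[str] = field(default_factory=set)
    reciprocal_nochange: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for exp in ("lncap", "reciprocal"):
            sets = [getattr(self, f"{exp}_{c}") for c in ("up", "down", "nochange")]
            for i in range(3):
                for j in range(i + 1, 3):
                    overlap = sets[i] & sets[j]
                    if overlap:
                        raise ValueError(f"{exp} categories overlap: {sorted(overlap)}")


def load_gene_response_lists(path: Optional[Path | str] = None) -> GeneResponseLists:
    path = fixture_path("gene_response") if path is None else Path(path)
    lists = GeneResponseLists()
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            attr = f"{row['experiment']}_{row['category']}"
            if not hasattr(lists, attr):
                raise CatalogError(f"unknown experiment/category {attr!r}")
            getattr(lists, attr).add(normalize_symbol(row["gene"]))
    lists.__post_init__()
    return lists


def intersect_expression_change(
    events: Iterable[IsoformPairEvent],
    lists: GeneResponseLists,
    experiment: str = "lncap",
) -> set[str]:
    """Catalogue genes whose overall expression changed in the given experiment.

    Returns ``(up | down) & catalogue`` after symbol normalisation.  Genes
    present in the response lists but absent from the catalogue (e.g. list
    entries from a different assay) are ignored with a warning.
    """
    if experiment not in ("lncap", "reciprocal"):
        raise ValueError(f"unknown experiment {experiment!r}")
    catalogue = {normalize_symbol(e.gene) for e in events}
    changed = (getattr(lists, f"{experiment}_up") | getattr(lists, f"{experiment}_down"))
    all_listed = changed | getattr(lists, f"{experiment}_nochange")
    ignored = sorted(all_listed - catalogue)
    for gene in ignored:
        warnings.warn(f"response-list gene {gene} absent from catalogue; ignored",
                      stacklevel=2)
    return changed & catalogue


@dataclass
class CohortDescription:
    """Cohort composition.

    Note: the published per-level Gleason and stage counts do not sum to the
    stated patient total (548 and 541 vs 497); the printed numbers are kept
    verbatim and the mismatch is surfaced via :meth:`marginal_mismatches`.
    """

    n_tumour: int
    n_normal: int
    gleason_counts: dict[int, int]
    stage_counts: dict[str, int]
    grade_group_counts: dict[int, int]

    def __post_init__(self) -> None:
        counts = [self.n_tumour, self.n_normal, *self.gleason_counts.values(),
                  *self.stage_counts.values(), *self.grade_group_counts.values()]
        if any(c < 0 for c in counts):
            raise ValueError("cohort counts must be non-negative")

    def marginal_mismatches(self) -> dict[str, int]:
        """Difference between each marginal total and the tumour count."""
        return {name: sum(counts.values()) - self.n_tumour
                for name, counts in (("gleason", self.gleason_counts),
                                     ("stage", self.stage_counts),
                                     ("grade_group", self.grade_group_counts))}


def load_cohort_description(path: Optional[Path | str] = None) -> CohortDescription:
    path = fixture_path("cohort") if path is None else Path(path)
    rows: dict[str, dict[str, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.setdefault(row["feature"], {})[row["level"]] = int(row["count"])
    return CohortDescription(
        n_tumour=rows["cohort"]["tumour"],
        n_normal=rows["cohort"]["normal"],
        gleason_counts={int(k): v for k, v in rows["gleason"].items()},
        stage_counts=dict(rows["stage"]),
        grade_group_counts={int(k): v for k, v in rows["grade_group"].items()},
    )
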