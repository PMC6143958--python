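"""Consistency classification of tumour isoform changes against androgen response.

Each catalogued event predicts a direction of change under androgen
stimulation: induction or repression of a specific isoform, or a switch in
the pair ratio.  Given tumour-vs-normal statistics (or grade/stage
correlations) the classifier decides whether the tumour alteration mimics
the androgen response (Consistent), contradicts it (Opposite), fails to
resolve (Inconclusive), or cannot be evaluated because an isoform lacks a
reference annotation (NotAssessed).

Decision rules (tumour/normal mode):

* induction/repression events - the expected isoform must change
  significantly (FDR <= threshold) in the expected direction, with no
  contradictory PSI change (a contradictory PSI change is one that is
  significant, exceeds the minimum magnitude |dPSI| > 0.025 and points
  against the expectation).  A significant change of the expected isoform in
  the wrong direction yields Opposite under the mirrored PSI condition.
* switch events - the call is carried by the ratio alone: PSI significant,
  |dPSI| above the minimum, and the sign decides Consistent vs Opposite.

In correlation mode rho signs replace log-fold-change signs, the PSI
direction is the sign of its rho, and - because single-isoform correlations
are weaker evidence there - a significant PSI correlation alone may carry a
call for induction/repression events, flagged ``partial``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Optional

from .catalog import Action, AndrogenEffect
from .diffstats import PairStatsCorr, PairStatsDE


class Label(str, Enum):
    CONSISTENT = "Consistent"
    OPPOSITE = "Opposite"
    INCONCLUSIVE = "Inconclusive"
    NOT_ASSESSED = "NotAssessed"


@dataclass(frozen=True)
class ConsistencyCall:
    label: Label
    partial: bool = False
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.partial and self.label not in (Label.CONSISTENT, Label.OPPOSITE):
            raise ValueError("partial calls only qualify Consistent/Opposite labels")


@dataclass(frozen=True)
class DecisionConfig:
    """Thresholds of the decision procedure.

    ``min_delta_psi`` is the minimum ratio change on the 0-1 PSI scale
    (2.5% by default, strict inequality); ``allow_psi_only_calls`` enables
    partial calls from PSI evidence alone and is meant for correlation mode.
    """

    fdr_threshold: float = 0.05
    min_delta_psi: float = 0.025
    allow_psi_only_calls: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not (0 < self.min_delta_psi < 1):
            raise ValueError("min_delta_psi must be in (0, 1)")


class ExpectedDirections(NamedTuple):
    """Expected sign (+1/-1) of each statistic, None when not constrained."""

    iso1: Optional[int]
    iso2: Optional[int]
    psi: int


def expected_directions(effect: AndrogenEffect) -> ExpectedDirections:
    """Directions implied by an androgen effect under PSI = iso1/(iso1+iso2).

    Inducing or repressing isoform k constrains that isoform's sign and the
    PSI sign (more isoform 2 means lower PSI); a switch toward isoform k
    constrains only the PSI sign.
    """
    if effect.action is Action.SWITCH:
        return ExpectedDirections(None, None, +1 if effect.target_isoform == 1 else -1)
    sign = +1 if effect.action is Action.INDUCE else -1
    if effect.target_isoform == 1:
        return ExpectedDirections(sign, None, sign)
    return ExpectedDirections(None, sign, -sign)


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def _effect_of(event) -> AndrogenEffect:
    effect = getattr(event, "androgen_effect", None) or getattr(event, "effect", None)
    if effect is None:
        raise ValueError(f"event {event!r} carries no androgen effect")
    return effect


def _is_comparable(event) -> bool:
    return bool(getattr(event, "tcga_comparable", True))


def _psi_directional_support(sig: bool, magnitude_ok: bool, direction: int,
                             expected_sign: int) -> int:
    """-1, 0 or +1: does the PSI evidence oppose, ignore or back the expectation."""
    if not (sig and magnitude_ok) or direction == 0:
        return 0
    return +1 if direction == expected_sign else -1


def classify_de(event, stats: PairStatsDE, cfg: DecisionConfig = DecisionConfig()) -> ConsistencyCall:
    """Classify one event from tumour-vs-normal differential statistics."""
    if not _is_comparable(event):
        return ConsistencyCall(Label.NOT_ASSESSED, evidence="isoform not annotated in reference")
    effect = _effect_of(event)
    exp = expected_directions(effect)
    thr = cfg.fdr_threshold

    psi_sig = stats.psi_fdr is not None and stats.psi_fdr <= thr
    psi_dir = _sign(stats.delta_psi) if stats.delta_psi is not None else 0
    psi_big = stats.delta_psi is not None and abs(stats.delta_psi) > cfg.min_delta_psi
    psi_support = _psi_directional_support(psi_sig, psi_big, psi_dir, exp.psi)

    if effect.action is Action.SWITCH:
        if stats.psi_fdr is None or stats.delta_psi is None:
            return ConsistencyCall(Label.INCONCLUSIVE, evidence="PSI statistic missing")
        if psi_sig and psi_big:
            label = Label.CONSISTENT if psi_dir == exp.psi else Label.OPPOSITE
            return ConsistencyCall(label, evidence=(
                f"PSI FDR {stats.psi_fdr:.3g}, dPSI {stats.delta_psi:+.3g}"))
        return ConsistencyCall(Label.INCONCLUSIVE, evidence="no qualifying PSI change")

    k = effect.target_isoform
    exp_sign = exp.iso1 if k == 1 else exp.iso2
    lfc = stats.iso1_log2fc if k == 1 else stats.iso2_log2fc
    fdr = stats.iso1_fdr if k == 1 else stats.iso2_fdr
    if lfc is None or fdr is None:
        return ConsistencyCall(Label.INCONCLUSIVE,
                               evidence=f"statistic for expected isoform {k} missing")
    if fdr <= thr and _sign(lfc) == exp_sign:
        if psi_support >= 0:
            return ConsistencyCall(Label.CONSISTENT, evidence=(
                f"isoform {k} log2FC {lfc:+.3g} (FDR {fdr:.3g}), PSI not contradictory"))
        return ConsistencyCall(Label.INCONCLUSIVE,
                               evidence=f"expected isoform significant but PSI contradicts")
    if fdr <= thr and _sign(lfc) == -exp_sign:
        if psi_support <= 0:
            return ConsistencyCall(Label.OPPOSITE, evidence=(
                f"isoform {k} log2FC {lfc:+.3g} (FDR {fdr:.3g}) against expectation"))
        return ConsistencyCall(Label.INCONCLUSIVE,
                               evidence="isoform and PSI evidence disagree")
    return ConsistencyCall(Label.INCONCLUSIVE, evidence="expected isoform not significant")


def classify_corr(event, stats: PairStatsCorr,
                  cfg: DecisionConfig = DecisionConfig(allow_psi_only_calls=True)) -> ConsistencyCall:
    """Classify one event from Gleason-score or tumour-stage correlations."""
    if not _is_comparable(event):
        return ConsistencyCall(Label.NOT_ASSESSED, evidence="isoform not annotated in reference")
    effect = _effect_of(event)
    exp = expected_directions(effect)
    thr = cfg.fdr_threshold

    psi_sig = stats.psi_fdr is not None and stats.psi_fdr <= thr
    psi_dir = _sign(stats.psi_rho) if stats.psi_rho is not None else 0
    psi_support = _psi_directional_support(psi_sig, True, psi_dir, exp.psi)

    if effect.action is Action.SWITCH:
        if stats.psi_fdr is None or stats.psi_rho is None:
            return ConsistencyCall(Label.INCONCLUSIVE, evidence="PSI statistic missing")
        if psi_sig and psi_dir != 0:
            label = Label.CONSISTENT if psi_dir == exp.psi else Label.OPPOSITE
            return ConsistencyCall(label, evidence=(
                f"PSI rho {stats.psi_rho:+.3g} (FDR {stats.psi_fdr:.3g})"))
        return ConsistencyCall(Label.INCONCLUSIVE, evidence="no qualifying PSI correlation")

    k = effect.target_isoform
    exp_sign = exp.iso1 if k == 1 else exp.iso2
    rho = stats.iso1_rho if k == 1 else stats.iso2_rho
    fdr = stats.iso1_fdr if k == 1 else stats.iso2_fdr
    if rho is None or fdr is None:
        return ConsistencyCall(Label.INCONCLUSIVE,
                               evidence=f"statistic for expected isoform {k} missing")
    if fdr <= thr and _sign(rho) == exp_sign:
        if psi_support >= 0:
            return ConsistencyCall(Label.CONSISTENT, evidence=(
                f"isoform {k} rho {rho:+.3g} (FDR {fdr:.3g})"))
        return ConsistencyCall(Label.INCONCLUSIVE,
                               evidence="expected isoform significant but PSI contradicts")
    if fdr <= thr and _sign(rho) == -exp_sign:
        if psi_support <= 0:
            return ConsistencyCall(Label.OPPOSITE, evidence=(
                f"isoform {k} rho {rho:+.3g} (FDR {fdr:.3g}) against expectation"))
        return ConsistencyCall(Label.INCONCLUSIVE, evidence="isoform and PSI evidence disagree")
    if cfg.allow_psi_only_calls and psi_support != 0:
        label = Label.CONSISTENT if psi_support > 0 else Label.OPPOSITE
        return ConsistencyCall(label, partial=True, evidence=(
            f"expected isoform ns; PSI rho {stats.psi_rho:+.3g} (FDR {stats.psi_fdr:.3g})"))
    return ConsistencyCall(Label.INCONCLUSIVE, evidence="expected isoform not significant")


@dataclass
class CallSummary:
    counts: Counter = field(default_factory=Counter)

    @property
    def n_consistent(self) -> int:
        return self.counts[Label.CONSISTENT]

    @property
    def n_opposite(self) -> int:
        return self.counts[Label.OPPOSITE]

    @property
    def n_inconclusive(self) -> int:
        return self.counts[Label.INCONCLUSIVE]

    @property
    def n_not_assessed(self) -> int:
        return self.counts[Label.NOT_ASSESSED]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def summarize_calls(calls: Mapping[str, ConsistencyCall]) -> CallSummary:
    """Label counts over one analysis; partial flags are ignored for counting."""
    return CallSummary(Counter(c.label for c in calls.values()))


def consistent_intersection(*call_maps: Mapping[str, ConsistencyCall]) -> set[str]:
    """Genes labelled Consistent (partial included) in every supplied analysis."""
    sets = [{g for g, c in calls.items() if c.label is Label.CONSISTENT}
            for calls in call_maps]
    out = sets[0] if sets else set()
    for s in sets[1:]:
        out &= s
    return out


def negate_effect(effect: AndrogenEffect) -> AndrogenEffect:
    """Mirror an androgen effect (induce<->repress; switch flips its target)."""
    if effect.action is Action.SWITCH:
        return AndrogenEffect(Action.SWITCH, 3 - effect.target_isoform, effect.splicing_note)
    action = Action.REPRESS if effect.action is Action.INDUCE else Action.INDUCE
    return AndrogenEffect(action, effect.target_isoform, effect.splicing_note)
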