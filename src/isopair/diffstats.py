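"""Differential statistics for isoform pairs.

The workhorse is a two-group empirical-Bayes moderated t-test: per-feature
pooled variances are shrunk toward a prior variance s0^2 whose weight is a
prior degree of freedom d0, both estimated from the data by fitting a scaled
F distribution to the observed variances via method of moments on the log
scale.  With d0 = 0 the statistic reduces to the classical pooled two-sample
t; as d0 -> infinity all features share a common variance.  Isoform
abundances are tested on log2(TPM + prior count) and isoform ratios on
logit-transformed PSI; a Mann-Whitney U alternative for PSI and tie-aware
Spearman rank correlations against ordinal grade/stage complete the engine.
FDR control is Benjamini-Hochberg, applied separately within each statistic
family (isoform 1, isoform 2, PSI) across events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .catalog import AndrogenEffect, IsoformPairEvent
from .quantify import (ExpressionDataset, GROUP_NORMAL, GROUP_TUMOUR, compute_psi,
                       delta_psi, logit_psi, psi_series)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation

@dataclass(frozen=True)
class ModerationParams:
    """Fitted empirical-Bayes prior: d0 (prior df) and s0^2 (prior variance)."""

    prior_df: float
    prior_var: float

    def __post_init__(self) -> None:
        if self.prior_df < 0:
            raise ValueError("prior_df must be non-negative")
        if not self.prior_var > 0 and np.isfinite(self.prior_df) and self.prior_df > 0:
            raise ValueError("prior_var must be positive")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_f_dist(variances: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Method-of-moments fit of s^2 ~ s0^2 * F(df, d0) on the log scale.

    Works on log variances so that features with small residual df still
    contribute; zero variances are floored at a tiny positive value and
    effectively absorbed by the prior.
    """
    s2 = np.asarray(variances, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (df > 0)
    s2 = np.maximum(s2[ok], 1e-12)
    df = df[ok]
    if s2.size < 2:
        return ModerationParams(prior_df=0.0, prior_var=float(np.median(s2)) if s2.size else 1.0)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = np.sum((e - e_mean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return ModerationParams(prior_df=float(d0), prior_var=float(s0_sq))


class ModeratedTResult(NamedTuple):
    log_fc: np.ndarray         # group-1 minus group-0 mean difference
    t: np.ndarray
    p_value: np.ndarray
    df_residual: np.ndarray
    df_total: np.ndarray
    s2_posterior: np.ndarray
    params: ModerationParams


def moderated_t_test(
    values: np.ndarray,
    groups: Sequence[bool] | np.ndarray,
    prior_df: Optional[float] = None,
) -> ModeratedTResult:
    """Two-group moderated t-test on a features x samples matrix.

    ``groups`` is boolean per sample; the reported effect is mean(True
    group) minus mean(False group).  NaN entries are ignored per feature
    (with the residual df reduced accordingly).  ``prior_df`` overrides the
    fitted d0: 0 recovers the classical pooled t-test, ``numpy.inf`` a
    common-variance z-like statistic.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    g = np.asarray(groups, dtype=bool)
    if g.size != x.shape[1]:
        raise ValueError("groups length must match the number of samples")
    x1, x0 = x[:, g], x[:, ~g]

    n1 = np.sum(~np.isnan(x1), axis=1).astype(float)
    n0 = np.sum(~np.isnan(x0), axis=1).astype(float)
    if np.any(n1 < 2) or np.any(n0 < 2):
        raise ValueError("each group needs at least 2 non-missing samples per feature")
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(x1, axis=1)
        m0 = np.nanmean(x0, axis=1)
        v1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        v0 = np.nansum((x0 - m0[:, None]) ** 2, axis=1)
    df_res = n1 + n0 - 2.0
    s2 = (v1 + v0) / df_res
    effect = m1 - m0

    params = fit_f_dist(s2, df_res)
    if prior_df is not None:
        # keep the fitted prior variance but impose the requested weight
        params = ModerationParams(prior_df=float(prior_df), prior_var=params.prior_var)

    d0 = params.prior_df
    if np.isinf(d0):
        s2_post = np.full_like(s2, params.prior_var)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * params.prior_var + df_res * s2) / (d0 + df_res)
        df_total = df_res + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    finite_df = np.where(np.isfinite(df_total), df_total, 1.0)
    p = np.where(np.isfinite(df_total),
                 2.0 * stats.t.sf(np.abs(t), finite_df),
                 2.0 * stats.norm.sf(np.abs(t)))
    return ModeratedTResult(effect, t, p, df_res, df_total, s2_post, params)


# ---------------------------------------------------------------------------
# rank statistics and multiplicity

def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_psi(
    psi_group_a: Iterable[float],
    psi_group_b: Iterable[float],
    exact_threshold: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on PSI values (missing removed).

    Uses the exact null distribution when both groups are small and tie-free,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(list(psi_group_a), dtype=float)
    b = np.asarray(list(psi_group_b), dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one non-missing value")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) <= exact_threshold
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman_assoc(values: Iterable[float], ordinal: Iterable[float]) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with a two-tailed t-approximation p.

    Pairs with a missing entry are dropped.  A constant ordinal vector is an
    error; constant values are degenerate and reported as (0.0, 1.0).
    """
    x = np.asarray(list(values), dtype=float)
    y = np.asarray(list(ordinal), dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired non-missing observations")
    if np.unique(y).size < 2:
        raise ValueError("ordinal covariate is constant")
    if np.unique(x).size < 2:
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# per-event pair analyses

class IsoformPair(NamedTuple):
    """A gene's ordered isoform pair mapped to expression-matrix columns."""

    gene: str
    iso1_id: str
    iso2_id: str
    effect: Optional[AndrogenEffect] = None


@dataclass
class PairStatsDE:
    """Tumour-vs-normal differential statistics for one isoform pair."""

    gene: str
    iso1_log2fc: Optional[float] = None
    iso1_avg_expr: Optional[float] = None
    iso1_fdr: Optional[float] = None
    iso2_log2fc: Optional[float] = None
    iso2_avg_expr: Optional[float] = None
    iso2_fdr: Optional[float] = None
    delta_psi: Optional[float] = None
    avg_psi: Optional[float] = None
    psi_fdr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta_psi is not None and abs(self.delta_psi) > 1 + 1e-12:
            raise ValueError("|delta PSI| cannot exceed 1")


@dataclass
class PairStatsCorr:
    """Rank-correlation statistics of one isoform pair against grade/stage."""

    gene: str
    iso1_rho: Optional[float] = None
    iso1_fdr: Optional[float] = None
    iso2_rho: Optional[float] = None
    iso2_fdr: Optional[float] = None
    psi_rho: Optional[float] = None
    psi_fdr: Optional[float] = None

    def __post_init__(self) -> None:
        for rho in (self.iso1_rho, self.iso2_rho, self.psi_rho):
            if rho is not None and abs(rho) > 1 + 1e-12:
                raise ValueError("|rho| cannot exceed 1")


def events_to_pairs(events: Iterable[IsoformPairEvent],
                    isoform_ids: str = "ucsc") -> list[IsoformPair]:
    """Map comparable catalogue events to expression-matrix column pairs."""
    pairs = []
    for e in events:
        id1 = getattr(e.isoform1, f"{isoform_ids}_id")
        id2 = getattr(e.isoform2, f"{isoform_ids}_id")
        if e.tcga_comparable and id1 and id2:
            pairs.append(IsoformPair(e.gene, id1, id2, e.androgen_effect))
    return pairs


def differential_pair_analysis(
    dataset: ExpressionDataset,
    pairs: Sequence[IsoformPair],
    *,
    group_a: str = GROUP_TUMOUR,
    group_b: str = GROUP_NORMAL,
    prior_count: float = 0.5,
    eps: float = 1e-3,
    psi_test: str = "moderated",
    prior_df: Optional[float] = None,
) -> dict[str, PairStatsDE]:
    """Per-event differential expression and differential PSI statistics.

    Isoform abundance is tested with the moderated t on log2(TPM + prior
    count); the ratio is tested on logit-PSI (or by Mann-Whitney U when
    ``psi_test='mannwhitney'``).  Delta PSI is the difference of group median
    PSI on the raw scale.  FDR is adjusted within each statistic family.
    Pairs with isoforms missing from the matrix are skipped.
    """
    if psi_test not in ("moderated", "mannwhitney"):
        raise ValueError(f"unknown psi_test {psi_test!r}")
    present = [p for p in pairs
               if p.iso1_id in dataset.expression.columns
               and p.iso2_id in dataset.expression.columns]
    if not present:
        return {}
    in_a = dataset.group_mask(group_a)
    in_b = dataset.group_mask(group_b)
    keep = in_a | in_b
    expr = dataset.expression.loc[keep]
    groups = in_a[keep]

    iso_cols = [p.iso1_id for p in present] + [p.iso2_id for p in present]
    log_expr = np.log2(expr[iso_cols].to_numpy(dtype=float).T + prior_count)
    de = moderated_t_test(log_expr, groups, prior_df=prior_df)

    n = len(present)
    psi_matrix = np.stack([
        compute_psi(expr[p.iso1_id].to_numpy(), expr[p.iso2_id].to_numpy())
        for p in present])
    if psi_test == "moderated":
        with np.errstate(invalid="ignore"):
            logit_matrix = np.where(np.isnan(psi_matrix), np.nan,
                                    logit_psi(np.nan_to_num(psi_matrix, nan=0.5), eps))
        psi_res = moderated_t_test(logit_matrix, groups, prior_df=prior_df)
        psi_p = psi_res.p_value
    else:
        psi_p = np.array([
            mann_whitney_psi(psi_matrix[i, groups], psi_matrix[i, ~groups])[1]
            for i in range(n)])

    iso1_fdr = bh_fdr(de.p_value[:n])
    iso2_fdr = bh_fdr(de.p_value[n:])
    psi_fdr = bh_fdr(psi_p)

    out: dict[str, PairStatsDE] = {}
    for i, p in enumerate(present):
        psi_a = psi_matrix[i, groups]
        psi_b = psi_matrix[i, ~groups]
        out[p.gene] = PairStatsDE(
            gene=p.gene,
            iso1_log2fc=float(de.log_fc[i]),
            iso1_avg_expr=float(expr[p.iso1_id].mean()),
            iso1_fdr=float(iso1_fdr[i]),
            iso2_log2fc=float(de.log_fc[n + i]),
            iso2_avg_expr=float(expr[p.iso2_id].mean()),
            iso2_fdr=float(iso2_fdr[i]),
            delta_psi=delta_psi(psi_a, psi_b),
            avg_psi=float(np.nanmean(psi_matrix[i])),
            psi_fdr=float(psi_fdr[i]),
        )
    return out


def correlation_pair_analysis(
    dataset: ExpressionDataset,
    pairs: Sequence[IsoformPair],
    covariate: str,
    *,
    group: str = GROUP_TUMOUR,
) -> dict[str, PairStatsCorr]:
    """Spearman association of isoform TPM and PSI with an ordinal covariate.

    Restricted to samples of ``group`` (tumour by default).  FDR per
    statistic family across events.  Degenerate (constant) expression yields
    rho 0 with p 1 rather than an error.
    """
    if covariate not in ("gleason", "stage"):
        raise ValueError(f"unknown covariate {covariate!r}")
    present = [p for p in pairs
               if p.iso1_id in dataset.expression.columns
               and p.iso2_id in dataset.expression.columns]
    if not present:
        return {}
    mask = dataset.group_mask(group)
    cov = dataset.ordinal_covariate(covariate).to_numpy()[mask]
    if np.all(np.isnan(cov)):
        raise ValueError(f"covariate {covariate!r} missing for all {group} samples")
    expr = dataset.expression.loc[mask]

    rows = []
    for p in present:
        x1 = expr[p.iso1_id].to_numpy()
        x2 = expr[p.iso2_id].to_numpy()
        psi = compute_psi(x1, x2)
        rows.append([spearman_assoc(v, cov) for v in (x1, x2, psi)])
    fdrs = [bh_fdr([rows[i][j][1] for i in range(len(present))]) for j in range(3)]

    out: dict[str, PairStatsCorr] = {}
    for i, p in enumerate(present):
        out[p.gene] = PairStatsCorr(
            gene=p.gene,
            iso1_rho=rows[i][0][0], iso1_fdr=float(fdrs[0][i]),
            iso2_rho=rows[i][1][0], iso2_fdr=float(fdrs[1][i]),
            psi_rho=rows[i][2][0], psi_fdr=float(fdrs[2][i]),
        )
    return out
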