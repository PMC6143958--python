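"""Isoform-level quantification: TPM, PSI ratios and wet-lab formulas.

PSI (percent spliced-in) is defined for an ordered isoform pair as
``psi = expr1 / (expr1 + expr2)``; swapping the pair maps psi to 1 - psi.
When both isoforms are unexpressed in a sample the ratio is undefined and
recorded as missing, and missing values are excluded from group medians and
downstream tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Ordinal encoding of pathological tumour stage used for rank correlations.
STAGE_CODES = {"T2a": 1, "T2b": 2, "T2c": 3, "T3a": 4, "T3b": 5, "T4": 6}

GROUP_TUMOUR = "tumour"
GROUP_NORMAL = "normal"


@dataclass
class ExpressionDataset:
    """Samples x isoforms expression matrix with per-sample metadata.

    ``expression`` is indexed by sample id with isoform ids as columns;
    ``metadata`` is indexed by the same sample ids and must provide a
    ``group`` column (e.g. tumour/normal), with optional ``gleason`` and
    ``stage`` columns (ordinal stage codes or T-stage strings).
    ``unit`` flags whether values are TPM or raw counts.
    """

    expression: pd.DataFrame
    metadata: pd.DataFrame
    unit: str = "tpm"

    def __post_init__(self) -> None:
        if self.unit not in ("tpm", "counts"):
            raise ValueError(f"unit must be 'tpm' or 'counts', got {self.unit!r}")
        values = self.expression.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("expression values must be finite and non-negative")
        if "group" not in self.metadata.columns:
            raise ValueError("metadata must contain a 'group' column")
        missing = set(self.expression.index) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list:
        return list(self.expression.index)

    @property
    def isoform_ids(self) -> list:
        return list(self.expression.columns)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.metadata.loc[self.expression.index, "group"] == group).to_numpy()

    def ordinal_covariate(self, name: str) -> pd.Series:
        """Numeric grade/stage covariate aligned to the expression rows."""
        values = self.metadata.loc[self.expression.index, name]
        if name == "stage" and values.dtype == object:
            values = values.map(lambda v: STAGE_CODES.get(v, v))
        return pd.to_numeric(values, errors="coerce")


def load_expression_dataset(
    expression_path,
    metadata_path,
    unit: str = "tpm",
    sep: str = "\t",
) -> ExpressionDataset:
    """Read an expression matrix (samples in rows, isoform-id header) and its
    metadata sidecar (columns sample / group / gleason / stage)."""
    expr = pd.read_csv(expression_path, sep=sep, index_col=0)
    meta = pd.read_csv(metadata_path, sep=sep).set_index("sample")
    return ExpressionDataset(expr, meta, unit=unit)


def counts_to_tpm(
    counts: pd.DataFrame | np.ndarray,
    effective_lengths: Sequence[float] | Mapping[str, float],
) -> pd.DataFrame | np.ndarray:
    """Convert read counts (samples x isoforms) to transcripts per million.

    Each count is divided by the isoform's effective length to obtain a
    transcript rate, and rates are scaled so every sample sums to 1e6.
    Samples with no reads at all are returned as all-zero with a warning.
    """
    is_frame = isinstance(counts, pd.DataFrame)
    if is_frame and isinstance(effective_lengths, Mapping):
        lengths = np.asarray([effective_lengths[c] for c in counts.columns], dtype=float)
    else:
        lengths = np.asarray(list(effective_lengths.values())
                             if isinstance(effective_lengths, Mapping)
                             else effective_lengths, dtype=float)
    if np.any(lengths <= 0) or not np.all(np.isfinite(lengths)):
        raise ValueError("effective lengths must be positive and finite")
    values = counts.to_numpy(dtype=float) if is_frame else np.asarray(counts, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    rates = values / lengths[None, :]
    totals = rates.sum(axis=1, keepdims=True)
    zero_samples = totals[:, 0] == 0
    if np.any(zero_samples):
        warnings.warn(f"{int(zero_samples.sum())} sample(s) have zero total counts",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(totals > 0, rates / totals * 1e6, 0.0)
    if is_frame:
        return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)
    return tpm if np.asarray(counts).ndim > 1 else tpm[0]


def compute_psi(expr1, expr2):
    """PSI of an ordered pair: expr1 / (expr1 + expr2); NaN when both are zero."""
    a = np.asarray(expr1, dtype=float)
    b = np.asarray(expr2, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("expression values must be non-negative")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, a / np.where(total > 0, total, 1.0), np.nan)
    if np.ndim(expr1) == 0 and np.ndim(expr2) == 0:
        return float(psi)
    return psi


def psi_series(dataset: ExpressionDataset, iso1: str, iso2: str) -> pd.Series:
    """Per-sample PSI for one isoform pair of a dataset."""
    psi = compute_psi(dataset.expression[iso1].to_numpy(),
                      dataset.expression[iso2].to_numpy())
    return pd.Series(psi, index=dataset.expression.index, name=f"{iso1}/{iso2}")


def delta_psi(psi_group_a: Iterable[float], psi_group_b: Iterable[float]) -> float:
    """Difference of group median PSI (A minus B), missing values removed."""
    a = np.asarray(list(psi_group_a), dtype=float)
    b = np.asarray(list(psi_group_b), dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one non-missing PSI value")
    return float(np.median(a) - np.median(b))


def logit_psi(psi, eps: float = 1e-3):
    """log(p / (1 - p)) after clamping p symmetrically into [eps, 1 - eps].

    The clamp keeps ratios of fully mono-isoform samples finite while
    preserving the ordering of PSI values.
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    p = np.clip(np.asarray(psi, dtype=float), eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if np.ndim(psi) == 0 else out


@dataclass
class QpcrPlate:
    """Long-format real-time PCR Ct table.

    ``data`` columns: sample, condition, gene, replicate, ct.  Technical
    replicates are averaged on the Ct scale.  ``reference_genes`` are the
    normalisation genes (three by default, following common practice of
    averaging GAPDH, beta-tubulin and actin).
    """

    data: pd.DataFrame
    reference_genes: tuple[str, ...] = ("GAPDH", "TUBB", "ACTB")

    def __post_init__(self) -> None:
        required = {"sample", "condition", "gene", "replicate", "ct"}
        if not required <= set(self.data.columns):
            raise ValueError(f"plate data must have columns {sorted(required)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("Ct values must be finite and positive")

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct per (sample, gene); keeps condition labels."""
        return (self.data.groupby(["sample", "condition", "gene"], sort=False)["ct"]
                .mean().reset_index())


def ddct_quantify(plate: QpcrPlate, target: str, control_condition: str) -> pd.Series:
    """Relative expression of ``target`` per sample by the 2^-ddCt method.

    dCt normalises the target Ct to the mean of the reference genes within
    each sample; ddCt is taken relative to the mean dCt of the control
    condition, so the control condition's geometric mean is 1 by construction.
    """
    mean_ct = plate.mean_ct()
    wide = mean_ct.pivot(index="sample", columns="gene", values="ct")
    conditions = mean_ct.drop_duplicates("sample").set_index("sample")["condition"]
    missing_refs = [g for g in plate.reference_genes if g not in wide.columns]
    if missing_refs:
        raise ValueError(f"reference gene(s) missing from plate: {missing_refs}")
    if wide[list(plate.reference_genes)].isna().any().any():
        raise ValueError("every sample must have Ct values for all reference genes")
    if target not in wide.columns:
        raise ValueError(f"target gene {target!r} missing from plate")
    if control_condition not in set(conditions):
        raise ValueError(f"control condition {control_condition!r} absent from plate")
    dct = wide[target] - wide[list(plate.reference_genes)].mean(axis=1)
    control_mean_dct = dct[conditions == control_condition].mean()
    ddct = dct - control_mean_dct
    rel = np.power(2.0, -ddct)
    rel.name = target
    return rel


def percent_inclusion(intensity_included: float, intensity_excluded: float) -> float:
    """Capillary-electrophoresis percentage inclusion: 100 * inc / (inc + exc)."""
    inc = float(intensity_included)
    exc = float(intensity_excluded)
    if inc < 0 or exc < 0:
        raise ValueError("band intensities must be non-negative")
    if inc + exc == 0:
        raise ValueError("both band intensities are zero; inclusion undefined")
    return 100.0 * inc / (inc + exc)
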