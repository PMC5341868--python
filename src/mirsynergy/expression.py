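"""Paired differential miRNA calling and bench-assay quantification formulas.

The differential stage mirrors the array analysis of the motivating
study: a paired two-sided t-test per miRNA between two tissue classes
(samples matched by pair id), a log2 fold-change computed as the mean of
paired differences, and an up/down/ns call combining the significance
and fold-change criteria.  The module also carries the study's stated
quantification arithmetic: the comparative-Ct 2^-ddCt estimator with its
Ct >= 30 censoring rule, dual-luciferase reporter normalisation,
MTT relative viability, and the xenograft tumour-volume formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import holm_adjust
from .simulate import ExpressionMatrix

__all__ = [
    "QPCRMeasurement",
    "CT_QUANTIFICATION_LIMIT",
    "differential_mirnas",
    "relative_expression_ddct",
    "normalize_reporter",
    "relative_viability",
    "tumor_volume",
]

DIFF_COLUMNS = ["mirna", "log2fc", "p_value", "p_adj", "call", "flags"]

#: Ct at or above this cycle is interpreted as amplification too low to quantify.
CT_QUANTIFICATION_LIMIT = 30.0


def differential_mirnas(
    expr: ExpressionMatrix,
    class_a: str = "normal",
    class_b: str = "carcinoma",
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Paired differential calling of ``class_b`` versus ``class_a``.

    For each miRNA the paired log2 differences (class_b - class_a,
    matched by pair id) give ``log2fc`` as their mean and ``p_value``
    from a two-sided paired t-test.  A miRNA is called ``up`` when the
    (optionally adjusted) p-value is below ``alpha`` *and*
    ``log2fc >= fc_threshold``; ``down`` symmetrically; otherwise ``ns``.

    ``adjust`` is one of ``none`` (raw p, the study's stated criterion),
    ``holm`` or ``bh``.  miRNAs with any missing paired value are called
    ``ns`` and flagged ``missing``; zero within-pair variance yields
    p = 0 when the fold change is non-zero (1 otherwise) with a
    ``degenerate_variance`` flag.
    """
    if fc_threshold < 0:
        raise ValueError("fc_threshold must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if adjust not in ("none", "holm", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    meta = expr.samples
    sub_a = meta[meta["tissue_class"] == class_a]
    sub_b = meta[meta["tissue_class"] == class_b]
    pairs = sorted(set(sub_a["pair_id"]) & set(sub_b["pair_id"]))
    if len(pairs) < 2:
        raise ValueError(
            f"need >= 2 complete pairs between {class_a!r} and {class_b!r}, got {len(pairs)}"
        )
    ids_a = [sub_a.index[sub_a["pair_id"] == p][0] for p in pairs]
    ids_b = [sub_b.index[sub_b["pair_id"] == p][0] for p in pairs]

    mat_a = expr.values[ids_a].to_numpy(dtype=float)
    mat_b = expr.values[ids_b].to_numpy(dtype=float)
    diffs = mat_b - mat_a
    missing = np.isnan(diffs).any(axis=1)
    log2fc = np.where(missing, np.nan, np.nanmean(diffs, axis=1))

    sd = np.std(diffs, axis=1, ddof=1)
    degenerate = (sd == 0) & ~missing
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_value = stats.ttest_rel(mat_b, mat_a, axis=1)
    p_value = np.asarray(p_value, dtype=float)
    # Zero within-pair variance: the t statistic is undefined; treat an
    # exactly repeated non-zero shift as certain, a zero shift as null.
    p_value[degenerate] = np.where(np.abs(log2fc[degenerate]) > 0, 0.0, 1.0)
    p_value[missing] = np.nan

    valid = ~missing
    p_adj = np.full_like(p_value, np.nan)
    if adjust == "none":
        p_adj[valid] = p_value[valid]
    elif adjust == "holm":
        p_adj[valid] = holm_adjust(p_value[valid])
    else:
        p_adj[valid] = multipletests(p_value[valid], method="fdr_bh")[1]

    call = np.full(len(log2fc), "ns", dtype=object)
    sig = valid & (p_adj < alpha)
    call[sig & (log2fc >= fc_threshold)] = "up"
    call[sig & (log2fc <= -fc_threshold)] = "down"

    flags = np.full(len(log2fc), "", dtype=object)
    flags[missing] = "missing"
    flags[degenerate] = "degenerate_variance"
    return pd.DataFrame(
        {
            "mirna": expr.mirnas,
            "log2fc": log2fc,
            "p_value": p_value,
            "p_adj": p_adj,
            "call": call,
            "flags": flags,
        },
        columns=DIFF_COLUMNS,
    )


@dataclass(frozen=True)
class QPCRMeasurement:
    """Paired cycle thresholds of a target and its reference gene."""

    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.ct_target < 0 or self.ct_reference < 0:
            raise ValueError("Ct values must be non-negative")

    def quantifiable(self) -> bool:
        return (self.ct_target < CT_QUANTIFICATION_LIMIT
                and self.ct_reference < CT_QUANTIFICATION_LIMIT)


def relative_expression_ddct(
    sample: QPCRMeasurement, calibrator: QPCRMeasurement
) -> float | None:
    """Comparative-Ct relative expression, ``2 ** -ddCt``.

    ``ddCt = (ct_target - ct_reference)_sample - (ct_target -
    ct_reference)_calibrator``.  Returns ``None`` (unquantifiable) when
    any of the four input Ct values is at or above the quantification
    limit of 30 cycles; censoring is applied before any arithmetic.
    """
    if not (sample.quantifiable() and calibrator.quantifiable()):
        return None
    ddct = (sample.ct_target - sample.ct_reference) - (
        calibrator.ct_target - calibrator.ct_reference
    )
    return float(2.0 ** -ddct)


def normalize_reporter(
    firefly: float, renilla: float, control_firefly: float, control_renilla: float
) -> float:
    """Dual-luciferase activity relative to the scramble-mimic control.

    Firefly counts are normalised to the co-transfected Renilla control
    in both wells: ``(firefly / renilla) / (control_firefly /
    control_renilla)``.
    """
    if renilla <= 0 or control_renilla <= 0:
        raise ValueError("Renilla readings must be strictly positive")
    if firefly < 0 or control_firefly < 0:
        raise ValueError("firefly readings must be non-negative")
    if control_firefly == 0:
        raise ValueError("control firefly reading must be non-zero")
    return (firefly / renilla) / (control_firefly / control_renilla)


def relative_viability(absorbance: float, control_absorbance: float) -> float:
    """MTT viability relative to control absorbance."""
    if control_absorbance <= 0:
        raise ValueError("control absorbance must be strictly positive")
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    return absorbance / control_absorbance


def tumor_volume(width: float, length: float) -> float:
    """Xenograft tumour volume in mm^3: ``width^2 * length / 2``."""
    if width < 0 or length < 0:
        raise ValueError("dimensions must be non-negative")
    return width * width * length / 2.0
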