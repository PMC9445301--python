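"""Real-time PCR quantification: absolute copy numbers and relative expression.

Absolute mode fits ``Cq = slope * log10(copies) + intercept`` to a serial
dilution of in-vitro-transcribed standard RNA and inverts it for single
cells, correcting for pre-amplification and the assayed fraction of the
cell lysate.  Relative mode is the classical delta-delta-Cq scheme against
the arithmetic mean Cq of four reference genes (equivalent to the
geometric mean of the linear quantities), with duplicates averaged at the
Cq level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QPCRRecord",
    "StandardCurve",
    "standard_curve_fit",
    "copies_from_cq",
    "relative_expression",
]

log = logging.getLogger(__name__)


@dataclass
class QPCRRecord:
    sample_id: str
    gene: str
    cq: float
    role: str = "sample"  # "standard" or "sample"
    known_copies: float | None = None
    dilution: float = 1.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.cq <= 0:
            raise ValueError("Cq must be > 0")
        if self.role == "standard" and not (self.known_copies and self.known_copies > 0):
            raise ValueError("standards need known copies > 0")


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    cq_range: tuple[float, float]

    def predict_cq(self, copies: float) -> float:
        return self.slope * np.log10(copies) + self.intercept


def standard_curve_fit(standards: list[QPCRRecord] | pd.DataFrame) -> StandardCurve:
    """Least-squares standard curve over a serial dilution.

    Requires >= 3 distinct concentrations and a negative slope (more
    template, earlier Cq); amplification efficiency is
    ``10**(-1/slope) - 1`` (1.0 for perfect doubling, slope -3.3219).
    """
    if isinstance(standards, pd.DataFrame):
        copies = standards["known_copies"].to_numpy(dtype=float)
        cq = standards["cq"].to_numpy(dtype=float)
    else:
        copies = np.array([r.known_copies for r in standards], dtype=float)
        cq = np.array([r.cq for r in standards], dtype=float)
    if len(np.unique(copies)) < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    res = stats.linregress(np.log10(copies), cq)
    if res.slope >= 0:
        raise ValueError("standards are non-monotone (slope >= 0); curve rejected")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(10.0 ** (-1.0 / res.slope) - 1.0),
        r_squared=float(res.rvalue**2),
        cq_range=(float(cq.min()), float(cq.max())),
    )


def copies_from_cq(
    cq: float | np.ndarray,
    curve: StandardCurve,
    preamp_factor: float = 1.0,
    assayed_fraction: float = 1.0,
    extrapolation_margin: float = 1.0,
) -> float | np.ndarray:
    """Invert the standard curve to copies per cell.

    ``copies = 10**((cq - intercept)/slope) / (preamp_factor * assayed_fraction)``.
    A warning is emitted for Cq values falling more than
    ``extrapolation_margin`` cycles outside the standards' Cq range.
    """
    if preamp_factor <= 0 or assayed_fraction <= 0:
        raise ValueError("scaling factors must be > 0")
    cq_arr = np.asarray(cq, dtype=float)
    lo, hi = curve.cq_range
    if np.any((cq_arr < lo - extrapolation_margin) | (cq_arr > hi + extrapolation_margin)):
        warnings.warn(
            "Cq outside the standard-curve range; copies are extrapolated",
            stacklevel=2,
        )
    copies = 10.0 ** ((cq_arr - curve.intercept) / curve.slope)
    copies = copies / (preamp_factor * assayed_fraction)
    return float(copies) if np.isscalar(cq) else copies


def relative_expression(
    table: pd.DataFrame,
    target: str,
    reference_genes: list[str],
    calibrator_group: str,
) -> pd.DataFrame:
    """Delta-delta-Cq fold changes of ``target`` against reference genes.

    ``table`` needs columns ``sample_id, group, gene, cq`` (replicates are
    averaged per sample and gene).  Per sample,
    ``dCq = mean Cq(target) - mean over reference genes of mean Cq(ref)``;
    fold change is ``2**-(dCq - mean dCq of the calibrator group)``.
    Samples missing the target or any reference gene are excluded and
    logged.  Returns one row per retained sample with ``dcq`` and ``fold``.
    """
    mean_cq = (
        table.groupby(["sample_id", "group", "gene"])["cq"].mean().reset_index()
    )
    rows = []
    for (sample, group), sub in mean_cq.groupby(["sample_id", "group"]):
        gene_cq = dict(zip(sub["gene"], sub["cq"]))
        missing = [g for g in [target, *reference_genes] if g not in gene_cq]
        if missing:
            log.warning("sample %s: missing gene(s) %s; excluded", sample, missing)
            continue
        ref_mean = np.mean([gene_cq[g] for g in reference_genes])
        rows.append(
            {"sample_id": sample, "group": group, "dcq": gene_cq[target] - ref_mean}
        )
    df = pd.DataFrame(rows)
    if df.empty or calibrator_group not in set(df["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} has no usable samples")
    base = df.loc[df["group"] == calibrator_group, "dcq"].mean()
    df["fold"] = 2.0 ** -(df["dcq"] - base)
    return df
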