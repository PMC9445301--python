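"""Per-cell mRNA copy-number dispersion analysis.

Continuous transcription at a constant rate would leave Poisson-distributed
copy numbers (variance = mean); bursty transcription over-disperses them.
This module provides the sample moments and Fano factor, the classical
chi-square dispersion-index test, the copy-number-vs-cell-size Pearson
correlation, and a Gaussian-mixture BIC bimodality check on log1p counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .stats_core import pearson

__all__ = [
    "CountTable",
    "dispersion_stats",
    "poisson_dispersion_test",
    "size_correlation",
    "bimodality_check",
    "sd_variance_consistent",
]


@dataclass
class CountTable:
    """Per-cell mRNA copies with optional cell cross-sectional areas.

    Cells below the assay detection limit are carried with a censoring
    flag; by default they are excluded from moment estimates rather than
    imputed (``substitute_half_limit=True`` replaces them by limit/2 for
    sensitivity analysis).
    """

    copies: np.ndarray
    area_um2: np.ndarray | None = None
    censored: np.ndarray | None = None
    detection_limit: float = 0.0
    individual: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=float)
        if np.any(self.copies < 0):
            raise ValueError("copy numbers must be >= 0")
        if self.area_um2 is not None:
            self.area_um2 = np.asarray(self.area_um2, dtype=float)
            if len(self.area_um2) != len(self.copies):
                raise ValueError("area and copies length mismatch")
            if np.any(self.area_um2 <= 0):
                raise ValueError("areas must be > 0")
        if self.censored is None:
            self.censored = (
                self.copies < self.detection_limit
                if self.detection_limit > 0
                else np.zeros(len(self.copies), dtype=bool)
            )
        else:
            self.censored = np.asarray(self.censored, dtype=bool)

    def usable_copies(self, substitute_half_limit: bool = False) -> np.ndarray:
        if substitute_half_limit and self.detection_limit > 0:
            out = self.copies.copy()
            out[self.censored] = self.detection_limit / 2.0
            return out
        return self.copies[~self.censored]


def dispersion_stats(table: CountTable, substitute_half_limit: bool = False) -> dict[str, float]:
    """Sample mean, variance (n-1 denominator), SD and Fano factor."""
    x = table.usable_copies(substitute_half_limit)
    if len(x) < 2:
        raise ValueError("need at least 2 uncensored cells")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    return {
        "n": int(len(x)),
        "mean": mean,
        "variance": var,
        "sd": float(np.sqrt(var)),
        "fano": var / mean if mean > 0 else 0.0,
    }


def poisson_dispersion_test(table: CountTable) -> dict[str, float]:
    """Chi-square dispersion-index test for over-dispersion.

    ``D = (n-1) * variance / mean`` is chi-square(n-1) under the Poisson
    null; the reported p-value is one-sided against over-dispersion.
    """
    x = table.usable_copies()
    if len(x) < 2:
        raise ValueError("need at least 2 uncensored cells")
    n = len(x)
    mean = float(np.mean(x))
    if mean == 0:
        return {"dispersion_index": np.nan, "p_value": np.nan, "n": n, "degenerate": True}
    d = (n - 1) * float(np.var(x, ddof=1)) / mean
    return {
        "dispersion_index": d,
        "p_value": float(stats.chi2.sf(d, n - 1)),
        "n": n,
        "degenerate": False,
    }


def size_correlation(table: CountTable) -> dict[str, float]:
    """Pearson correlation of copy number with cell cross-sectional area."""
    if table.area_um2 is None:
        raise ValueError("table carries no cell areas")
    keep = ~table.censored
    x = table.area_um2[keep]
    y = table.copies[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 cells with both copies and area")
    res = pearson(x, y)
    return {"pearson_r": res["r"], "n": res["n"], "p_value": res["p"], "degenerate": res["degenerate"]}


def bimodality_check(
    table: CountTable, delta_bic_threshold: float = 10.0, seed: int = 0
) -> dict[str, object]:
    """1- vs 2-component Gaussian-mixture BIC comparison on log1p counts.

    Verdict is "bimodal" only when the 2-component model improves BIC by
    more than ``delta_bic_threshold``.  Degenerate inputs (zero variance)
    are flagged instead of fitted.
    """
    x = np.log1p(table.usable_copies())
    if len(x) < 10:
        raise ValueError("need at least 10 uncensored cells")
    if x.max() == x.min():
        return {"delta_bic": np.nan, "verdict": "degenerate", "converged": False}
    x = x.reshape(-1, 1)
    out = {}
    bics = {}
    converged = True
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed).fit(x)
        converged &= bool(gm.converged_)
        bics[k] = float(gm.bic(x))
    delta = bics[1] - bics[2]  # >0 means the 2-component model is better
    out["delta_bic"] = delta
    out["bic_1"] = bics[1]
    out["bic_2"] = bics[2]
    out["converged"] = converged
    out["verdict"] = "bimodal" if delta > delta_bic_threshold else "unimodal"
    return out


def sd_variance_consistent(sd: float, variance: float, sig_figs: int = 2) -> bool:
    """Check that a reported SD and variance agree after rounding.

    Squares ``sd`` and compares it with ``variance`` at ``sig_figs``
    significant figures (the precision dispersion summaries are printed
    at).
    """
    sq = sd * sd
    if sq <= 0 or variance <= 0:
        return sq == variance
    scale = 10 ** (np.floor(np.log10(sq)) - (sig_figs - 1))
    return bool(np.round(sq / scale) * scale == variance)
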