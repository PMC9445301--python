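"""Calcium-dependent force analysis of single permeabilised cardiomyocytes.

Force is measured over a pCa series from relaxing (pCa 9.0) to maximally
activating (pCa 4.18) calcium.  After subtracting the passive force and
normalising to the reference activation, the force-pCa relation is fitted
with the Hill equation F = F_max / (1 + 10**(nH*(pCa - pCa50))).  Because
a single Hill curve can describe patient cells poorly at high calcium,
logit-transformed forces are alternatively fitted with two continuous
linear segments; on an exact Hill curve both segment slopes equal
-nH*ln(10).  Group contrasts combine a Mann-Whitney location test with
Levene's variance test, the latter capturing cell-to-cell contractile
imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .stats_core import levene_test, mann_whitney_u

__all__ = [
    "DEFAULT_PCA_GRID",
    "ForcePCaRecord",
    "hill_fit",
    "logit_two_segment_fit",
    "normalize_forces",
    "compare_groups",
]

# measurement grid covering the relaxing (9.0) and maximal (4.18) points
# and every intermediate activation level referenced in reporting
DEFAULT_PCA_GRID = (9.0, 6.0, 5.9, 5.74, 5.6, 5.54, 5.4, 5.24, 5.0, 4.6, 4.18)

RELAXING_PCA = 9.0
MAX_ACTIVATING_PCA = 4.18


@dataclass
class ForcePCaRecord:
    """One cardiomyocyte's force values over a pCa series."""

    cell_id: str
    pca: np.ndarray
    force: np.ndarray
    group: str = ""
    normalized: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pca = np.asarray(self.pca, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.pca) != len(self.force):
            raise ValueError("pCa and force length mismatch")
        if len(np.unique(self.pca)) != len(self.pca):
            raise ValueError("pCa values must be distinct")
        if np.any(self.force < 0) and not self.normalized:
            raise ValueError("raw forces must be >= 0")

    def force_at(self, pca: float) -> float:
        idx = np.where(np.isclose(self.pca, pca))[0]
        if idx.size == 0:
            raise KeyError(f"pCa {pca} not measured for cell {self.cell_id}")
        return float(self.force[idx[0]])


def _hill(pca: np.ndarray, f_max: float, pca50: float, n_h: float) -> np.ndarray:
    return f_max / (1.0 + 10.0 ** (n_h * (pca - pca50)))


def hill_fit(record: ForcePCaRecord) -> dict[str, object]:
    """Least-squares Hill fit of active force vs pCa.

    The passive force (value at pCa 9.0, if measured) is subtracted and
    only activating points (pCa < 9.0) enter the fit.  Initialisation is
    deterministic: F_max0 = max active force, pCa50_0 = pCa of the point
    closest to half-max, nH0 = 2.  Non-convergence is flagged instead of
    raised.
    """
    act = record.pca < RELAXING_PCA
    if act.sum() < 4:
        raise ValueError("need at least 4 activating points")
    passive = 0.0
    relax_idx = np.where(record.pca >= RELAXING_PCA)[0]
    if relax_idx.size:
        passive = float(record.force[relax_idx[0]])
    x = record.pca[act]
    y = record.force[act] - passive
    if np.allclose(y, y[0]):
        raise ValueError("activating forces are all identical; Hill fit undefined")
    f_max0 = float(np.max(y))
    pca50_0 = float(x[np.argmin(np.abs(y - f_max0 / 2.0))])
    p0 = (f_max0, pca50_0, 2.0)
    try:
        popt, _ = optimize.curve_fit(
            _hill, x, y, p0=p0,
            bounds=([0.0, x.min() - 2.0, 0.05], [np.inf, x.max() + 2.0, 20.0]),
            maxfev=10000,
        )
    except RuntimeError:
        return {"converged": False, "cell_id": record.cell_id}
    f_max, pca50, n_h = (float(v) for v in popt)
    resid = y - _hill(x, *popt)
    return {
        "converged": True,
        "cell_id": record.cell_id,
        "F_max": f_max,
        "pCa50": pca50,
        "nH": n_h,
        "passive": passive,
        "residuals": resid,
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }


def logit_two_segment_fit(
    record: ForcePCaRecord,
    breakpoint: float | str = "auto",
    clip: tuple[float, float] = (0.01, 0.99),
) -> dict[str, float]:
    """Continuous two-segment linear fit of logit(force) vs pCa.

    The record must hold normalised forces; points outside the ``clip``
    band are excluded (the logit is undefined at 0 and 1).  With
    ``breakpoint="auto"`` the knot is chosen on the measured pCa grid to
    minimise the SSE, requiring >= 3 points on each side; a numeric
    breakpoint fixes the knot (e.g. 5.54, the reported regime change).
    Returns the slope on the high-calcium side (pCa < breakpoint), the
    slope on the low-calcium side, and the knot.
    """
    if not record.normalized:
        raise ValueError("two-segment logit fit requires normalised forces")
    keep = (record.force > clip[0]) & (record.force < clip[1]) & (record.pca < RELAXING_PCA)
    x = record.pca[keep]
    y = np.log(record.force[keep] / (1.0 - record.force[keep]))
    order = np.argsort(x)
    x, y = x[order], y[order]

    def fit_at(bp: float):
        lo = x <= bp  # high-calcium side
        hi = x >= bp
        if lo.sum() < 3 or hi.sum() < 3:
            return None
        design = np.column_stack(
            [np.ones_like(x), np.minimum(x - bp, 0.0), np.maximum(x - bp, 0.0)]
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((design @ coef - y) ** 2))
        return coef, sse

    if breakpoint == "auto":
        best = None
        for bp in x[1:-1]:
            res = fit_at(float(bp))
            if res is None:
                continue
            if best is None or res[1] < best[2] - 1e-12:
                best = (res[0], float(bp), res[1])
        if best is None:
            raise ValueError("no breakpoint leaves >= 3 points per segment")
        coef, bp, sse = best
    else:
        bp = float(breakpoint)
        res = fit_at(bp)
        if res is None:
            raise ValueError(f"fixed breakpoint {bp} leaves < 3 points on one segment")
        coef, sse = res
    return {
        "slope_high_ca_side": float(coef[1]),
        "slope_low_ca_side": float(coef[2]),
        "breakpoint_pca": bp,
        "sse": sse,
        "n_points": int(len(x)),
    }


def normalize_forces(
    record: ForcePCaRecord, reference_pca: float = MAX_ACTIVATING_PCA
) -> ForcePCaRecord:
    """Subtract the passive force and normalise to the reference activation.

    The force at pCa 9.0 (0 if unmeasured) is subtracted everywhere and
    forces are divided by the active force at ``reference_pca``, which
    maps to exactly 1.  Records whose reference force does not exceed the
    passive force are returned flagged and un-normalised.
    """
    try:
        ref = record.force_at(reference_pca)
    except KeyError:
        raise ValueError(f"reference pCa {reference_pca} not measured")
    passive = 0.0
    relax_idx = np.where(record.pca >= RELAXING_PCA)[0]
    if relax_idx.size:
        passive = float(record.force[relax_idx[0]])
    active_ref = ref - passive
    if active_ref <= 0:
        return ForcePCaRecord(
            cell_id=record.cell_id,
            pca=record.pca,
            force=record.force,
            group=record.group,
            normalized=False,
            flags=record.flags + ["reference_force_not_above_passive"],
        )
    return ForcePCaRecord(
        cell_id=record.cell_id,
        pca=record.pca,
        force=(record.force - passive) / active_ref,
        group=record.group,
        normalized=True,
        flags=list(record.flags),
    )


def compare_groups(values_a, values_b) -> dict[str, float]:
    """Location and variance contrast of two per-cell value sets.

    Returns the two-sided Mann-Whitney p-value, Levene's (mean-centred)
    p-value and the variance fold ``var_b / var_a``.  Degenerate inputs
    in which every value is tied are flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    if np.all(a == a[0]) and np.all(b == b[0]):
        return {
            "U_p": np.nan, "levene_p": np.nan,
            "variance_fold": np.nan, "degenerate": True,
        }
    u = mann_whitney_u(a, b)
    lev = levene_test([a, b])
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    return {
        "U_p": u["p_two_sided"],
        "levene_p": lev["p"],
        "variance_fold": var_b / var_a if var_a > 0 else np.inf,
        "degenerate": False,
    }
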