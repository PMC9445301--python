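"""Stochastic two-state (telegraph) simulation of allele-level transcription.

Each allele of a heterozygous gene switches independently between an
inactive (OFF) and an active (ON) promoter state; mRNA is synthesised only
while the promoter is ON, and protein is translated from the mature mRNA
pool.  Per allele copy the reaction set is

    OFF -> ON        rate k_on        (per hour)
    ON  -> OFF       rate k_off       (per hour)
    ON  -> ON + M    rate k_tx        (molecules/hour while ON)
    M   -> 0         rate d_m * M     (first-order mRNA decay)
    M   -> M + P     rate k_p * M     (translation)
    P   -> 0         rate d_p * P     (first-order protein decay)

simulated exactly with the Gillespie direct method.  A nucleus carries
``ploidy`` copies of each of the two allele classes (diploid mononucleated
nucleus: ploidy = 1, i.e. two allele copies in total).  In truncation-
mutation mode (``nmd=True``) transcripts of the second allele class are
removed by nonsense-mediated decay as soon as they mature, so the mutant
mature-mRNA and protein pools stay empty while the promoter still bursts
(and is still visible as an active transcription site).

The number of alleles with an ON promoter is the model analogue of the
active-transcription-site (aTS) count seen by single-molecule FISH with
co-localised intron/exon probes.  A mutant-protein fraction maps onto a
calcium--force curve by linear interpolation of the half-activation point
pCa50 between the wild-type value and the homozygous-mutant value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "BurstParams",
    "ForceMap",
    "CellRecord",
    "PopulationSnapshot",
    "steady_state_moments",
    "simulate_cell",
    "simulate_population",
    "ats_count",
    "force_from_mutant_fraction",
    "calibrate",
    "trajectory_summary",
]


class ParameterError(ValueError):
    """Raised for kinetic or mapping parameters outside their domain."""


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstParams:
    """Kinetic rate constants of the two-state allele model.

    Parameters
    ----------
    k_on, k_off : float
        Promoter OFF->ON and ON->OFF switching rates (per hour).
        ``k_off = 0`` is the continuous-transcription (Poisson) limit.
    k_tx : float
        mRNA synthesis rate while the promoter is ON (molecules/hour).
    d_m : float
        First-order mRNA degradation rate (per hour).
    k_p : float
        Protein synthesis rate per mRNA molecule (per hour).  0 disables
        the protein layer.
    d_p : float
        First-order protein degradation rate (per hour); must be > 0
        whenever ``k_p > 0``.
    ploidy : int
        Allele copies per allele class in the nucleus (1 for a diploid
        mononucleated nucleus; the total allele count is ``2 * ploidy``).
    allele_labels : tuple of str
        Names of the two allele classes; the second is the variant
        (mutant or SNP-marked) class.
    nmd : bool
        If True, mature transcripts of the second allele class are
        degraded immediately (truncation-mutation mode).
    """

    k_on: float
    k_off: float
    k_tx: float
    d_m: float
    k_p: float = 0.0
    d_p: float = 0.0
    ploidy: int = 1
    allele_labels: tuple[str, str] = ("WT", "MUT")
    nmd: bool = False

    def __post_init__(self) -> None:
        if not (self.k_on > 0):
            raise ParameterError(f"k_on must be > 0, got {self.k_on}")
        if self.k_off < 0:
            raise ParameterError(f"k_off must be >= 0, got {self.k_off}")
        if self.k_tx < 0:
            raise ParameterError(f"k_tx must be >= 0, got {self.k_tx}")
        if not (self.d_m > 0):
            raise ParameterError(f"d_m must be > 0, got {self.d_m}")
        if self.k_p < 0 or self.d_p < 0:
            raise ParameterError("k_p and d_p must be >= 0")
        if self.k_p > 0 and not (self.d_p > 0):
            raise ParameterError("d_p must be > 0 when k_p > 0")
        if int(self.ploidy) != self.ploidy or self.ploidy < 1:
            raise ParameterError(f"ploidy must be an integer >= 1, got {self.ploidy}")
        if len(self.allele_labels) != 2:
            raise ParameterError("exactly two allele classes are required")

    @property
    def total_alleles(self) -> int:
        """Total allele copies per nucleus (both classes)."""
        return 2 * int(self.ploidy)

    @property
    def relaxation_time(self) -> float:
        """Slowest relaxation time of the model (hours)."""
        scales = [1.0 / self.d_m, 1.0 / (self.k_on + self.k_off)]
        if self.k_p > 0:
            scales.append(1.0 / self.d_p)
        return max(scales)


@dataclass(frozen=True)
class ForceMap:
    """Mapping from mutant-protein fraction to a calcium--force relation.

    The half-activation point shifts linearly with the mutant fraction,
    ``pCa50(f) = pCa50_wt + f * delta_pca50``, where ``delta_pca50`` is the
    shift of a (hypothetical) homozygous-mutant cell; force follows a Hill
    curve with coefficient ``n_h``.
    """

    pca50_wt: float = 5.55
    delta_pca50: float = -0.10
    n_h: float = 2.0

    def __post_init__(self) -> None:
        if not (self.n_h > 0):
            raise ParameterError(f"Hill coefficient must be > 0, got {self.n_h}")


def force_from_mutant_fraction(
    f_mut: float | np.ndarray,
    fmap: ForceMap,
    query_pca: float,
) -> float | np.ndarray:
    """Relative (0..1) calcium-activated force at ``query_pca``.

    ``pCa50(f) = pca50_wt + f * delta_pca50`` and
    ``F = 1 / (1 + 10**(n_h * (query_pca - pCa50(f))))``.
    """
    f = np.asarray(f_mut, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ParameterError("mutant protein fraction must lie in [0, 1]")
    pca50 = fmap.pca50_wt + f * fmap.delta_pca50
    force = 1.0 / (1.0 + 10.0 ** (fmap.n_h * (query_pca - pca50)))
    return float(force) if np.isscalar(f_mut) else force


# --------------------------------------------------------------------------
# analytic steady-state moments (oracle for the SSA)
# --------------------------------------------------------------------------


def steady_state_moments(params: BurstParams) -> dict[str, float]:
    """Closed-form stationary moments of the per-allele mRNA count.

    Returns ``p_on`` (stationary ON probability), the per-allele mRNA mean
    and variance, the Fano factor (variance/mean), and the per-allele mean
    protein count implied by the translation layer.

    For the telegraph model the Fano factor is
    ``1 + k_tx * k_off / ((k_on + k_off) * (k_on + k_off + d_m))``,
    which reduces to 1 (Poisson) in the continuous limit ``k_off = 0``.
    """
    ksum = params.k_on + params.k_off
    p_on = params.k_on / ksum
    mean = p_on * params.k_tx / params.d_m
    fano = 1.0 + params.k_tx * params.k_off / (ksum * (ksum + params.d_m))
    mean_protein = mean * params.k_p / params.d_p if params.k_p > 0 else 0.0
    return {
        "p_on": p_on,
        "mean_mrna_per_allele": mean,
        "var_mrna_per_allele": mean * fano,
        "fano": fano,
        "mean_protein_per_allele": mean_protein,
    }


def calibrate(
    observed: dict[str, float],
    fixed: dict[str, object] | None = None,
) -> BurstParams:
    """Back out telegraph rates from population summaries.

    Parameters
    ----------
    observed : dict
        ``fraction_zero_aTS`` (fraction of nuclei with no visible aTS,
        strictly between 0 and 1) and ``mean_total_mRNA`` (mean copies
        per cell, both alleles).
    fixed : dict, optional
        Free choices that the summaries cannot constrain: ``k_off``
        (default 1.0 /h), ``d_m`` (default ln2/10 /h, i.e. a 10-hour
        mRNA half-life), ``ploidy`` (default 1) and, passed through,
        ``k_p``, ``d_p``, ``allele_labels``, ``nmd``.

    With ``A = 2 * ploidy`` independent alleles the zero-aTS fraction is
    ``(1 - p_on)**A``, so ``p_on = 1 - fraction_zero_aTS**(1/A)``; then
    ``k_on = k_off * p_on / (1 - p_on)`` and
    ``k_tx = mean_total_mRNA * d_m / (A * p_on)``.
    """
    fixed = dict(fixed or {})
    fz = float(observed["fraction_zero_aTS"])
    if not (0.0 < fz < 1.0):
        raise ParameterError(
            f"fraction_zero_aTS must lie strictly in (0, 1), got {fz}"
        )
    mean_total = float(observed["mean_total_mRNA"])
    if mean_total <= 0:
        raise ParameterError("mean_total_mRNA must be > 0")
    k_off = float(fixed.pop("k_off", 1.0))
    d_m = float(fixed.pop("d_m", math.log(2) / 10.0))
    ploidy = int(fixed.pop("ploidy", 1))
    n_alleles = 2 * ploidy
    p_on = 1.0 - fz ** (1.0 / n_alleles)
    if k_off == 0:
        raise ParameterError("k_off = 0 forces p_on = 1; cannot match a nonzero zero-aTS fraction")
    k_on = k_off * p_on / (1.0 - p_on)
    k_tx = mean_total * d_m / (n_alleles * p_on)
    return BurstParams(
        k_on=k_on, k_off=k_off, k_tx=k_tx, d_m=d_m, ploidy=ploidy, **fixed
    )


# --------------------------------------------------------------------------
# Gillespie kernels (numba-compiled)
# --------------------------------------------------------------------------


@njit(cache=True)
def _advance_allele(on, m, p, t, t_end, k_on, k_off, k_tx, d_m, k_p, d_p, keep_mrna):
    """Advance one allele copy from t to t_end; returns its state at t_end."""
    while True:
        a1 = k_on if on == 0 else 0.0
        a2 = k_off if on == 1 else 0.0
        a3 = k_tx if on == 1 else 0.0
        a4 = d_m * m
        a5 = k_p * m
        a6 = d_p * p
        a0 = a1 + a2 + a3 + a4 + a5 + a6
        if a0 <= 0.0:
            return on, m, p
        t -= np.log(np.random.random()) / a0
        if t >= t_end:
            return on, m, p
        r = np.random.random() * a0
        if r < a1:
            on = 1
        elif r < a1 + a2:
            on = 0
        elif r < a1 + a2 + a3:
            if keep_mrna:
                m += 1
        elif r < a1 + a2 + a3 + a4:
            m -= 1
        elif r < a1 + a2 + a3 + a4 + a5:
            p += 1
        else:
            p -= 1


@njit(cache=True)
def _allele_trajectory(times, k_on, k_off, k_tx, d_m, k_p, d_p, keep_mrna):
    """One allele copy from (OFF, 0, 0); state recorded at each sample time."""
    n = times.shape[0]
    out_on = np.zeros(n, np.int64)
    out_m = np.zeros(n, np.int64)
    out_p = np.zeros(n, np.int64)
    on, m, p = 0, 0, 0
    t = 0.0
    idx = 0
    while idx < n:
        a1 = k_on if on == 0 else 0.0
        a2 = k_off if on == 1 else 0.0
        a3 = k_tx if on == 1 else 0.0
        a4 = d_m * m
        a5 = k_p * m
        a6 = d_p * p
        a0 = a1 + a2 + a3 + a4 + a5 + a6
        if a0 <= 0.0:
            while idx < n:
                out_on[idx] = on
                out_m[idx] = m
                out_p[idx] = p
                idx += 1
            break
        t_next = t - np.log(np.random.random()) / a0
        while idx < n and times[idx] < t_next:
            out_on[idx] = on
            out_m[idx] = m
            out_p[idx] = p
            idx += 1
        t = t_next
        r = np.random.random() * a0
        if r < a1:
            on = 1
        elif r < a1 + a2:
            on = 0
        elif r < a1 + a2 + a3:
            if keep_mrna:
                m += 1
        elif r < a1 + a2 + a3 + a4:
            m -= 1
        elif r < a1 + a2 + a3 + a4 + a5:
            p += 1
        else:
            p -= 1
    return out_on, out_m, out_p


@njit(cache=True)
def _cell_trajectory_kernel(seed, times, ploidy, k_on, k_off, k_tx, d_m, k_p, d_p, keep_b):
    np.random.seed(seed)
    n = times.shape[0]
    on_a = np.zeros(n, np.int64)
    m_a = np.zeros(n, np.int64)
    p_a = np.zeros(n, np.int64)
    on_b = np.zeros(n, np.int64)
    m_b = np.zeros(n, np.int64)
    p_b = np.zeros(n, np.int64)
    for _ in range(ploidy):
        o, m, p = _allele_trajectory(times, k_on, k_off, k_tx, d_m, k_p, d_p, True)
        on_a += o
        m_a += m
        p_a += p
    for _ in range(ploidy):
        o, m, p = _allele_trajectory(times, k_on, k_off, k_tx, d_m, k_p, d_p, keep_b)
        on_b += o
        m_b += m
        p_b += p
    return on_a, m_a, p_a, on_b, m_b, p_b


@njit(cache=True)
def _population_kernel(seeds, ploidy, burn_in, k_on, k_off, k_tx, d_m, k_p, d_p, keep_b):
    n = seeds.shape[0]
    on_a = np.zeros(n, np.int64)
    m_a = np.zeros(n, np.int64)
    p_a = np.zeros(n, np.int64)
    on_b = np.zeros(n, np.int64)
    m_b = np.zeros(n, np.int64)
    p_b = np.zeros(n, np.int64)
    for i in range(n):
        np.random.seed(seeds[i])
        for _ in range(ploidy):
            o, m, p = _advance_allele(
                0, 0, 0, 0.0, burn_in, k_on, k_off, k_tx, d_m, k_p, d_p, True
            )
            on_a[i] += o
            m_a[i] += m
            p_a[i] += p
        for _ in range(ploidy):
            o, m, p = _advance_allele(
                0, 0, 0, 0.0, burn_in, k_on, k_off, k_tx, d_m, k_p, d_p, keep_b
            )
            on_b[i] += o
            m_b[i] += m
            p_b[i] += p
    return on_a, m_a, p_a, on_b, m_b, p_b


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-cell seeds spawned from one root seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


# --------------------------------------------------------------------------
# records and public simulation API
# --------------------------------------------------------------------------


@dataclass
class CellRecord:
    """State of one nucleus/cell at one time point.

    ``on``, ``mrna`` and ``protein`` hold (first class, second class)
    totals over the ``ploidy`` copies of each allele class; ``nascent``
    optionally carries per-class nascent-transcript counts used for
    detection-thresholded aTS counting (meaningful for ploidy 1).
    """

    time: float
    on: tuple[int, int]
    mrna: tuple[int, int]
    protein: tuple[int, int]
    ploidy: int = 1
    nascent: tuple[int, int] | None = None
    allele_labels: tuple[str, str] = ("WT", "MUT")

    @property
    def total_mrna(self) -> int:
        return self.mrna[0] + self.mrna[1]

    @property
    def mutant_mrna_fraction(self) -> float:
        tot = self.total_mrna
        return self.mrna[1] / tot if tot > 0 else math.nan

    @property
    def mutant_protein_fraction(self) -> float:
        tot = self.protein[0] + self.protein[1]
        return self.protein[1] / tot if tot > 0 else math.nan


def ats_count(cell: CellRecord, detection_threshold: int = 0) -> int:
    """Number of visible active transcription sites in one nucleus.

    With ``detection_threshold == 0`` (default) every ON allele is a
    visible aTS.  With a positive threshold only ON alleles carrying at
    least that many nascent transcripts are counted, which requires the
    record to carry nascent counts (see ``simulate_population``'s
    ``nascent_residence_h``) and ploidy-1 allele classes.
    """
    if detection_threshold < 0:
        raise ParameterError("detection threshold must be >= 0")
    if detection_threshold == 0:
        return int(cell.on[0] + cell.on[1])
    if cell.nascent is None:
        raise ParameterError(
            "thresholded aTS counting needs nascent-transcript counts on the record"
        )
    if cell.ploidy != 1:
        raise ParameterError("thresholded aTS counting is defined per allele copy (ploidy 1)")
    return sum(
        1
        for on, nas in zip(cell.on, cell.nascent)
        if on >= 1 and nas >= detection_threshold
    )


@dataclass
class PopulationSnapshot:
    """Steady-state population sample: one row per cell plus provenance."""

    cells: pd.DataFrame
    params: BurstParams
    seed: int
    burn_in: float

    def __len__(self) -> int:
        return len(self.cells)

    def records(self) -> list[CellRecord]:
        """Materialise per-cell records (convenience for small populations)."""
        has_nas = "nascent_a" in self.cells.columns
        out = []
        for row in self.cells.itertuples(index=False):
            out.append(
                CellRecord(
                    time=self.burn_in,
                    on=(int(row.on_a), int(row.on_b)),
                    mrna=(int(row.mrna_a), int(row.mrna_b)),
                    protein=(int(row.protein_a), int(row.protein_b)),
                    ploidy=int(self.params.ploidy),
                    nascent=(int(row.nascent_a), int(row.nascent_b)) if has_nas else None,
                    allele_labels=self.params.allele_labels,
                )
            )
        return out


def _derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    df["ats"] = df["on_a"] + df["on_b"]
    df["total_mrna"] = df["mrna_a"] + df["mrna_b"]
    total = df["total_mrna"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["mut_mrna_frac"] = np.where(total > 0, df["mrna_b"] / total, np.nan)
    ptot = (df["protein_a"] + df["protein_b"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["mut_protein_frac"] = np.where(ptot > 0, df["protein_b"] / ptot, np.nan)
    return df


def simulate_cell(
    params: BurstParams,
    t_end: float,
    seed: int = 0,
    sample_times: np.ndarray | None = None,
    n_samples: int = 200,
) -> pd.DataFrame:
    """Exact SSA trajectory of one cell from the empty OFF state.

    Returns a tidy frame with one row per sample time and columns
    ``time, on_a, on_b, mrna_a, mrna_b, protein_a, protein_b`` plus the
    derived ``ats``, ``total_mrna`` and mutant-fraction columns.
    Identical ``seed`` gives an identical trajectory.
    """
    if not (t_end > 0):
        raise ParameterError("t_end must be > 0")
    if sample_times is None:
        sample_times = np.linspace(0.0, t_end, n_samples)
    times = np.asarray(sample_times, dtype=float)
    if times.ndim != 1 or len(times) < 1 or np.any(np.diff(times) < 0):
        raise ParameterError("sample_times must be a non-decreasing 1-D array")
    root = np.random.SeedSequence(seed).generate_state(1, dtype=np.uint32)[0]
    on_a, m_a, p_a, on_b, m_b, p_b = _cell_trajectory_kernel(
        root,
        times,
        int(params.ploidy),
        params.k_on,
        params.k_off,
        params.k_tx,
        params.d_m,
        params.k_p,
        params.d_p,
        not params.nmd,
    )
    df = pd.DataFrame(
        {
            "time": times,
            "on_a": on_a,
            "on_b": on_b,
            "mrna_a": m_a,
            "mrna_b": m_b,
            "protein_a": p_a,
            "protein_b": p_b,
        }
    )
    df = _derived_columns(df)
    df.attrs["params"] = params
    df.attrs["seed"] = int(seed)
    return df


def simulate_population(
    params: BurstParams,
    n_cells: int,
    burn_in: float | None = None,
    seed: int = 0,
    force_map: ForceMap | None = None,
    query_pca: float = 5.24,
    nascent_residence_h: float | None = None,
) -> PopulationSnapshot:
    """Sample ``n_cells`` independent cells at stationarity.

    Each cell is an independent SSA run from the empty OFF state for
    ``burn_in`` hours (default: 10 slowest relaxation times); a shorter
    user-supplied burn-in is accepted with a warning.  Per-cell seeds are
    spawned deterministically from ``seed`` via ``numpy.random.SeedSequence``,
    so snapshots are reproducible and embarrassingly parallel.

    When ``force_map`` is given, a ``force`` column holds the relative
    force at ``query_pca`` implied by each cell's mutant-protein fraction
    (mutant-mRNA fraction when the protein layer is disabled); cells with
    an undefined fraction get NaN.  ``nascent_residence_h`` switches on the
    detectability model: ON alleles receive nascent-transcript counts
    drawn as Poisson(k_tx * residence).
    """
    if n_cells < 1:
        raise ParameterError(f"n_cells must be >= 1, got {n_cells}")
    min_burn = 10.0 * params.relaxation_time
    if burn_in is None:
        burn_in = min_burn
    elif burn_in < min_burn:
        warnings.warn(
            f"burn-in {burn_in:.3g} h is shorter than 10 relaxation times "
            f"({min_burn:.3g} h); the snapshot may not be stationary",
            stacklevel=2,
        )
    seeds = _child_seeds(seed, n_cells)
    on_a, m_a, p_a, on_b, m_b, p_b = _population_kernel(
        seeds,
        int(params.ploidy),
        float(burn_in),
        params.k_on,
        params.k_off,
        params.k_tx,
        params.d_m,
        params.k_p,
        params.d_p,
        not params.nmd,
    )
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "on_a": on_a,
            "on_b": on_b,
            "mrna_a": m_a,
            "mrna_b": m_b,
            "protein_a": p_a,
            "protein_b": p_b,
        }
    )
    df = _derived_columns(df)
    if nascent_residence_h is not None:
        if nascent_residence_h <= 0:
            raise ParameterError("nascent residence time must be > 0")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E617363]))
        lam = params.k_tx * nascent_residence_h
        df["nascent_a"] = np.where(df["on_a"] > 0, rng.poisson(lam, n_cells), 0)
        df["nascent_b"] = np.where(df["on_b"] > 0, rng.poisson(lam, n_cells), 0)
    if force_map is not None:
        frac = df["mut_protein_frac"] if params.k_p > 0 else df["mut_mrna_frac"]
        frac = frac.to_numpy(dtype=float)
        ok = np.isfinite(frac)
        force = np.full(n_cells, np.nan)
        if ok.any():
            force[ok] = force_from_mutant_fraction(frac[ok], force_map, query_pca)
        df["force"] = force
    return PopulationSnapshot(cells=df, params=params, seed=int(seed), burn_in=float(burn_in))


def trajectory_summary(
    trajectory: pd.DataFrame,
    force_map: ForceMap | None = None,
    query_pca: float = 5.24,
) -> pd.DataFrame:
    """Per-time-point allelic fractions and implied force of a trajectory.

    Undefined fractions (zero total molecules) are kept as NaN and flagged
    in ``undefined_mrna_frac`` / ``undefined_protein_frac`` rather than
    dropped.
    """
    if len(trajectory) < 2:
        raise ParameterError("trajectory must contain at least two time points")
    out = pd.DataFrame({"time": trajectory["time"]})
    total_m = (trajectory["mrna_a"] + trajectory["mrna_b"]).to_numpy(dtype=float)
    total_p = (trajectory["protein_a"] + trajectory["protein_b"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["mut_mrna_frac"] = np.where(total_m > 0, trajectory["mrna_b"] / total_m, np.nan)
        out["mut_protein_frac"] = np.where(
            total_p > 0, trajectory["protein_b"] / total_p, np.nan
        )
    out["undefined_mrna_frac"] = total_m == 0
    out["undefined_protein_frac"] = total_p == 0
    if force_map is not None:
        frac = out["mut_protein_frac"].to_numpy(dtype=float)
        ok = np.isfinite(frac)
        force = np.full(len(out), np.nan)
        if ok.any():
            force[ok] = force_from_mutant_fraction(frac[ok], force_map, query_pca)
        out["force"] = force
    return out
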