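"""Synthetic raw-data generation for every pipeline input.

Each generator emulates one measurement modality with the statistical
structure the analysis assumes: per-nucleus aTS counts and per-cell copy
numbers come from the telegraph simulator; gel/blot band IODs are
molarity x fragment-length with multiplicative lognormal noise; force-pCa
curves follow the mutant-fraction force map with multiplicative Gaussian
noise; qPCR plates apply a linear Cq standard curve with additive Gaussian
Cq noise.  Cell cross-sectional areas are drawn independently of
expression by default (an optional coupling exists to probe the power of
the size-correlation test).  All generators are deterministic under the
scenario's root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .burst_sim import (
    BurstParams,
    ForceMap,
    calibrate,
    force_from_mutant_fraction,
    simulate_population,
)
from .densitometry import FRAGMENT_TABLES

__all__ = [
    "NoiseModel",
    "CohortSizes",
    "ScenarioConfig",
    "make_scenario",
    "gen_population_tables",
    "gen_gel_lanes",
    "gen_multialiquot_fractions",
    "gen_force_curves",
    "gen_qpcr_plates",
]

SCENARIOS = ("donor_SNP", "TNNI3_missense", "MYBPC3_truncation")

# default measurement grid for synthetic force curves (shared with contractility)
_PCA_GRID = (9.0, 6.0, 5.9, 5.74, 5.6, 5.54, 5.4, 5.24, 5.0, 4.6, 4.18)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise block.

    iod_cv: lognormal sigma of band IODs; cq_sd: additive Cq SD (cycles);
    force_cv: multiplicative force error; replicate_sd: SD (percentage
    points) of the allele fraction between technical replicates, matching
    the multialiquot scatter of the assay.
    """

    iod_cv: float = 0.05
    cq_sd: float = 0.2
    force_cv: float = 0.05
    replicate_sd: float = 6.5

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"noise parameter {name} must be >= 0")


@dataclass(frozen=True)
class CohortSizes:
    n_population: int = 2000
    n_gel_cells: int = 40
    n_force_cells: int = 20
    n_aliquots: int = 18


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str
    params: BurstParams
    force_map: ForceMap = field(default_factory=ForceMap)
    noise: NoiseModel = field(default_factory=NoiseModel)
    cohort: CohortSizes = field(default_factory=CohortSizes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic child stream of the root seed."""
        tag = int.from_bytes(stream.encode()[:8].ljust(8, b"\0"), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


# ---------------------------------------------------------------------------
# scenario factories: calibrated to the printed tissue summaries
# ---------------------------------------------------------------------------

# Scenario kinetics: promoter bursts must be infrequent relative to the
# mRNA lifetime (k_off = 0.1/h, OFF periods of days) so that single cells
# span the full range of allelic fractions, as the tissue data do; the
# protein pool (24 h half-life) then carries that mosaic to force.
_SCENARIO_RATES = {"k_off": 0.1, "k_p": 0.15, "d_p": math.log(2) / 24.0}


def make_scenario(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Build one of the three study scenarios.

    donor_SNP: heterozygous-SNP donor TNNI3-like gene (both alleles code
    the same protein; force map is flat).  TNNI3_missense: same kinetics,
    mutant protein desensitises (pCa50 shift -0.10 at fraction 1).
    MYBPC3_truncation: higher-activity gene with NMD of the mutant
    transcripts (haploinsufficiency mosaic).

    Kinetics come from ``calibrate`` against the averaged donor tissue
    summaries: 60% zero-aTS nuclei and 552 total copies/cell for the
    TNNI3-like gene; 18.7% zero-aTS and 2937 copies/cell for the
    MYBPC3-like gene.
    """
    if name in ("donor_SNP", "TNNI3_missense"):
        labels = ("WT", "SNP") if name == "donor_SNP" else ("WT", "MUT")
        params = calibrate(
            {"fraction_zero_aTS": 0.60, "mean_total_mRNA": 552.0},
            {"allele_labels": labels, **_SCENARIO_RATES},
        )
        fmap = (
            ForceMap(delta_pca50=0.0)
            if name == "donor_SNP"
            else ForceMap(delta_pca50=-0.10)
        )
    elif name == "MYBPC3_truncation":
        params = calibrate(
            {"fraction_zero_aTS": (0.23 + 0.23 + 0.10) / 3.0, "mean_total_mRNA": 2937.0},
            {"allele_labels": ("WT", "TRUNC"), "nmd": True, **_SCENARIO_RATES},
        )
        fmap = ForceMap(delta_pca50=0.06)  # calcium sensitisation direction
    else:
        raise ValueError(f"unknown scenario {name!r}")
    cfg = dict(scenario=name, params=params, force_map=fmap, seed=seed)
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_population_tables(
    config: ScenarioConfig,
    area_coupling: float = 0.0,
    detection_limit: float = 20.0,
) -> dict[str, object]:
    """Simulate a cohort and wrap it into aTS and copy-number tables.

    Returns the underlying ``PopulationSnapshot`` plus tidy frames
    ``ats`` (individual, gene, nucleus_id, ats_count) and ``counts``
    (individual, gene, cell_id, copies, area_um2, censored).  Areas are
    lognormal (median 350 um^2, sigma 0.25) and independent of expression
    unless ``area_coupling`` > 0 mixes in a copy-number-proportional term.
    """
    snap = simulate_population(
        config.params,
        config.cohort.n_population,
        seed=config.seed,
        force_map=config.force_map,
    )
    cells = snap.cells
    rng = config.rng("areas")
    area = 350.0 * np.exp(rng.normal(0.0, 0.25, len(cells)))
    if area_coupling > 0:
        copies = cells["total_mrna"].to_numpy(dtype=float)
        rel = copies / max(copies.mean(), 1.0)
        area = area * (1.0 - area_coupling + area_coupling * rel)
    ats = pd.DataFrame(
        {
            "individual": config.scenario,
            "gene": config.params.allele_labels[1],
            "nucleus_id": cells["cell_id"],
            "ats_count": cells["ats"],
        }
    )
    counts = pd.DataFrame(
        {
            "individual": config.scenario,
            "gene": config.params.allele_labels[1],
            "cell_id": cells["cell_id"],
            "copies": cells["total_mrna"].astype(float),
            "area_um2": area,
            "censored": cells["total_mrna"] < detection_limit,
        }
    )
    return {"snapshot": snap, "ats": ats, "counts": counts}


def _lane_rows(lane_id, cell_id, assay, replicate, molar_by_band, bp_by_band, gain, rng, iod_cv):
    rows = []
    for label, molar in molar_by_band.items():
        bp = bp_by_band[label]
        noise = math.exp(rng.normal(0.0, iod_cv)) if iod_cv > 0 else 1.0
        rows.append(
            {
                "lane_id": lane_id,
                "cell_id": cell_id,
                "assay": assay,
                "replicate": replicate,
                "band_label": label,
                "fragment_bp": bp,
                "iod": gain * molar * bp * noise,
            }
        )
    return rows


def gen_gel_lanes(
    config: ScenarioConfig,
    true_fractions: np.ndarray,
    assay: str = "MwoI_TNNI3",
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Gel lanes (long format) for cells with given variant fractions (%).

    Each replicate re-samples the cell's measured fraction with the
    replicate scatter (template sampling at single-cell dilution), then
    band IODs are gain x molarity x fragment_length x lognormal noise.
    The common restriction fragment (both alleles) is included for
    realism; the ratio computation ignores it.
    """
    fractions = np.asarray(true_fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 100)):
        raise ValueError("fractions must lie in [0, 100]")
    bp = FRAGMENT_TABLES[assay]
    var_label = "mut" if assay == "MwoI_TNNI3" else "snp"
    ref_label = "wt"
    rng = config.rng(f"gel_{assay}")
    rows = []
    for i, f in enumerate(fractions):
        for rep in range(1, n_replicates + 1):
            f_rep = f
            if config.noise.replicate_sd > 0:
                f_rep = float(np.clip(f + rng.normal(0.0, config.noise.replicate_sd), 0.0, 100.0))
            gain = math.exp(rng.normal(0.0, 0.3))  # arbitrary per-lane loading/exposure
            molar = {var_label: f_rep / 100.0, ref_label: 1.0 - f_rep / 100.0}
            if "common" in bp:
                molar["common"] = 1.0
            rows.extend(
                _lane_rows(
                    f"cell{i}_r{rep}", f"cell{i}", assay, rep,
                    molar, bp, gain, rng, config.noise.iod_cv,
                )
            )
    return pd.DataFrame(rows)


def gen_multialiquot_fractions(config: ScenarioConfig, true_fraction: float = 49.0) -> np.ndarray:
    """Measured fractions (%) of repeated single-cell-equivalent aliquots.

    Aliquots of one pooled RNA sample share the true fraction; scatter is
    the replicate-level technical noise.
    """
    rng = config.rng("multialiquot")
    n = config.cohort.n_aliquots
    vals = true_fraction + rng.normal(0.0, config.noise.replicate_sd, n)
    return np.clip(vals, 0.0, 100.0)


def gen_force_curves(
    config: ScenarioConfig,
    mutant_fractions: np.ndarray,
    pca_grid: tuple[float, ...] = _PCA_GRID,
    f_max_mean: float = 30.0,
    f_max_cv: float = 0.2,
    passive: float = 2.0,
) -> pd.DataFrame:
    """Force-pCa measurements (kN/m^2) for cells with given mutant fractions.

    Active force is F_max * Hill(pCa; pCa50(f)) with per-cell lognormal
    F_max, multiplied by (1 + eps), eps ~ N(0, force_cv^2); the passive
    force is added everywhere (measured alone at pCa 9.0).
    """
    fractions = np.asarray(mutant_fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("mutant fractions must lie in [0, 1]")
    rng = config.rng("force")
    rows = []
    for i, f in enumerate(fractions):
        f_max = f_max_mean * math.exp(rng.normal(0.0, f_max_cv))
        for pca in pca_grid:
            if pca >= 9.0:
                force = passive
            else:
                rel = force_from_mutant_fraction(float(f), config.force_map, pca)
                eps = rng.normal(0.0, config.noise.force_cv) if config.noise.force_cv > 0 else 0.0
                force = passive + f_max * rel * (1.0 + eps)
            rows.append(
                {
                    "cell_id": f"cell{i}",
                    "group": config.scenario,
                    "pCa": pca,
                    "force_kN_m2": max(force, 0.0),
                }
            )
    return pd.DataFrame(rows)


def gen_qpcr_plates(
    config: ScenarioConfig,
    true_copies: np.ndarray,
    slope: float = -math.log2(10) * 1.0,  # -3.3219: perfect doubling
    intercept: float = 37.0,
    n_decades: int = 5,
    n_replicates: int = 2,
    gene: str = "target",
) -> pd.DataFrame:
    """qPCR plate: 10-fold standard series over ``n_decades`` plus samples.

    Cq = intercept + slope * log10(copies) + N(0, cq_sd); standards run
    from 10 to 10**n_decades known copies, each in ``n_replicates`` wells.
    """
    copies = np.asarray(true_copies, dtype=float)
    if np.any(copies <= 0):
        raise ValueError("true copies must be > 0")
    rng = config.rng("qpcr")
    rows = []
    for decade in range(1, n_decades + 1):
        known = 10.0**decade
        for rep in range(1, n_replicates + 1):
            cq = intercept + slope * math.log10(known)
            if config.noise.cq_sd > 0:
                cq += rng.normal(0.0, config.noise.cq_sd)
            rows.append(
                {
                    "sample_id": f"std_{decade}",
                    "gene": gene,
                    "role": "standard",
                    "cq": cq,
                    "known_copies": known,
                    "dilution": 10.0 ** (n_decades - decade),
                    "replicate": rep,
                }
            )
    for i, c in enumerate(copies):
        for rep in range(1, n_replicates + 1):
            cq = intercept + slope * math.log10(c)
            if config.noise.cq_sd > 0:
                cq += rng.normal(0.0, config.noise.cq_sd)
            rows.append(
                {
                    "sample_id": f"cell{i}",
                    "gene": gene,
                    "role": "sample",
                    "cq": cq,
                    "known_copies": np.nan,
                    "dilution": 1.0,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
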