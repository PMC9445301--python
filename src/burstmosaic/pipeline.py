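"""End-to-end orchestration: synthetic cohort -> every figure-analogue table.

``run_study_pipeline`` generates a donor and a patient cohort, runs each
quantification stage, simulates an independent reference population and
writes the comparison report: aTS-bin distributions, copy-number
dispersion, allelic-fraction calls with replicate QC, western-blot group
levels, force-pCa fits with variance contrasts, and KS distances between
the measured-analogue and simulated distributions.  A manifest records
the config hash, seed and SHA-256 of every output so that identical
config+seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .ats_stats import ATSTable, ats_distribution, fit_independent_allele_model
from .burst_sim import simulate_population
from .contractility import (
    ForcePCaRecord,
    compare_groups,
    hill_fit,
    logit_two_segment_fit,
    normalize_forces,
)
from .count_stats import (
    CountTable,
    bimodality_check,
    dispersion_stats,
    poisson_dispersion_test,
    size_correlation,
)
from .densitometry import (
    Band,
    LaneDensitometry,
    fraction_from_iods,
    linearity_rmse,
    multialiquot_cutoff,
    protein_level,
    replicate_qc,
)
from .qpcr import copies_from_cq, standard_curve_fit
from .stats_core import anova_dunnett, levene_test
from .synthetic import (
    ScenarioConfig,
    gen_force_curves,
    gen_gel_lanes,
    gen_multialiquot_fractions,
    gen_population_tables,
    gen_qpcr_plates,
    make_scenario,
)

log = logging.getLogger(__name__)

__all__ = ["run_study_pipeline", "lanes_from_frame", "fractions_with_qc"]


def lanes_from_frame(df: pd.DataFrame) -> list[LaneDensitometry]:
    """Rebuild LaneDensitometry objects from the long-format lane table."""
    lanes = []
    for (lane_id, cell_id, assay, rep), sub in df.groupby(
        ["lane_id", "cell_id", "assay", "replicate"], sort=False
    ):
        bands = [
            Band(label=r.band_label, fragment_bp=r.fragment_bp, iod=r.iod)
            for r in sub.itertuples(index=False)
        ]
        group = sub["group"].iloc[0] if "group" in sub.columns else ""
        lanes.append(
            LaneDensitometry(
                lane_id=lane_id, bands=bands, assay=assay,
                cell_id=cell_id, replicate=int(rep), group=group,
            )
        )
    return lanes


def fractions_with_qc(lane_df: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Per-cell variant fractions from duplicate lanes, with replicate QC."""
    lanes = lanes_from_frame(lane_df)
    per_cell: dict[str, dict[int, float]] = {}
    for lane in lanes:
        per_cell.setdefault(lane.cell_id, {})[lane.replicate] = fraction_from_iods(lane)
    rows = []
    for cell_id, reps in per_cell.items():
        if len(reps) < 2:
            continue
        r1, r2 = (reps[k] for k in sorted(reps)[:2])
        call = replicate_qc(cell_id, r1, r2, cutoff)
        rows.append(
            {
                "cell_id": cell_id,
                "rep1": r1,
                "rep2": r2,
                "qc_pass": call.qc_pass,
                "mean_fraction": call.mean_fraction,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


class _Reporter:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: list[Path] = []

    def csv(self, df: pd.DataFrame, name: str) -> None:
        path = self.out_dir / name
        _write_csv(df, path)
        self.files.append(path)

    def json(self, obj, name: str) -> None:
        path = self.out_dir / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))
        self.files.append(path)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run_study_pipeline(
    scenario: str = "TNNI3_missense",
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_population: int = 2000,
    n_sim_reference: int = 20000,
) -> dict[str, object]:
    """Run the full synthetic study for one patient scenario vs donor.

    Stages: synthetic cohort generation; aTS distribution + independence
    fit; copy-number dispersion/size/bimodality; plasmid-linearity check,
    multialiquot cutoff, allelic-fraction QC and variance contrast;
    western group levels with ANOVA/Dunnett (truncation scenario);
    force-pCa Hill and two-segment-logit fits with U/Levene contrasts;
    and a larger independent simulated population compared to the
    measured-analogue distributions by KS distance.  Returns the report
    dict; when ``out_dir`` is given all tables plus ``report.json`` and
    ``manifest.json`` are written there.
    """
    donor = make_scenario("donor_SNP", seed=seed)
    patient = make_scenario(scenario, seed=seed + 1) if scenario != "donor_SNP" else None
    report: dict[str, object] = {
        "scenario": scenario,
        "seed": seed,
        "n_population": n_population,
    }
    tables: dict[str, pd.DataFrame] = {}

    cohorts = {}
    for label, cfg in (("donor", donor), ("patient", patient)):
        if cfg is None:
            continue
        cfg = ScenarioConfig(
            scenario=cfg.scenario, params=cfg.params, force_map=cfg.force_map,
            noise=cfg.noise,
            cohort=type(cfg.cohort)(n_population=n_population),
            seed=cfg.seed,
        )
        cohorts[label] = (cfg, gen_population_tables(cfg))

    # --- stage 1: aTS distributions (per-nucleus transcription-site bins)
    ats_report = {}
    for label, (cfg, data) in cohorts.items():
        table = ATSTable(data["ats"]["ats_count"].to_numpy(), label, cfg.scenario)
        dist = ats_distribution(table)
        fit = fit_independent_allele_model(table, n_bootstrap=100, seed=seed)
        ats_report[label] = {"bins_pct": dist, "independent_allele_fit": fit}
        tables[f"ats_{label}.csv"] = data["ats"]
    report["ats"] = ats_report

    # --- stage 2: copy-number dispersion
    count_report = {}
    for label, (cfg, data) in cohorts.items():
        ct = CountTable(
            copies=data["counts"]["copies"].to_numpy(),
            area_um2=data["counts"]["area_um2"].to_numpy(),
            censored=data["counts"]["censored"].to_numpy(),
            detection_limit=20.0,
        )
        count_report[label] = {
            "dispersion": dispersion_stats(ct),
            "poisson_test": poisson_dispersion_test(ct),
            "size_correlation": size_correlation(ct),
            "bimodality": bimodality_check(ct, seed=seed),
        }
        tables[f"counts_{label}.csv"] = data["counts"]
    report["counts"] = count_report

    # --- stage 3: allelic densitometry with QC
    dens_cfg, dens_data = cohorts["donor"]
    # plasmid-mix linearity over a 0..100% grid
    grid = np.linspace(0.0, 100.0, 11)
    zero_rep = ScenarioConfig(
        scenario=dens_cfg.scenario, params=dens_cfg.params,
        force_map=dens_cfg.force_map,
        noise=type(dens_cfg.noise)(iod_cv=dens_cfg.noise.iod_cv, replicate_sd=0.0),
        cohort=dens_cfg.cohort, seed=seed + 101,
    )
    plasmid_lanes = gen_gel_lanes(zero_rep, grid, assay="MwoI_TNNI3", n_replicates=3)
    plasmid = fractions_with_qc(plasmid_lanes, cutoff=100.0)
    obs = (
        plasmid.set_index("cell_id")
        .loc[[f"cell{i}" for i in range(len(grid))], "mean_fraction"]
        .to_numpy()
    )
    rmse = linearity_rmse(grid, obs)
    aliquots = gen_multialiquot_fractions(dens_cfg)
    ma = multialiquot_cutoff(aliquots)
    dens_report = {"plasmid_rmse_pct": rmse, "multialiquot": ma}
    frac_by_label = {}
    for label, (cfg, data) in cohorts.items():
        snap = data["snapshot"]
        frac = snap.cells["mut_mrna_frac"].dropna().to_numpy() * 100.0
        sel = cfg.rng("gel_cells").choice(len(frac), size=min(cfg.cohort.n_gel_cells, len(frac)), replace=False)
        assay = "BbsI_SNP" if label == "donor" else "MwoI_TNNI3"
        lane_df = gen_gel_lanes(cfg, frac[sel], assay=assay)
        calls = fractions_with_qc(lane_df, cutoff=ma["cutoff"])
        passed = calls.loc[calls["qc_pass"], "mean_fraction"].to_numpy()
        frac_by_label[label] = passed
        dens_report[label] = {
            "n_cells": int(len(calls)),
            "n_pass": int(len(passed)),
            "mean_fraction_pct": float(np.mean(passed)) if len(passed) else np.nan,
            "sd_fraction_pct": float(np.std(passed, ddof=1)) if len(passed) > 1 else np.nan,
        }
        tables[f"gel_lanes_{label}.csv"] = lane_df
        tables[f"allelic_calls_{label}.csv"] = calls
    if len(frac_by_label) == 2:
        groups = [frac_by_label["donor"], gen_multialiquot_fractions(dens_cfg), frac_by_label["patient"]]
        lev = levene_test(groups)
        dens_report["levene_groups"] = lev
    report["densitometry"] = dens_report

    # --- stage 4: western blot (haploinsufficiency analogue)
    if scenario == "MYBPC3_truncation":
        pat_cfg, pat_data = cohorts["patient"]
        snapp = pat_data["snapshot"].cells
        rngw = pat_cfg.rng("western")
        lanes = []
        # lane target signal tracks the sampled cell's total protein; the
        # loading control tracks lane loading only.  A donor of the same
        # gene (no NMD) would express twice the patient's WT-allele mean.
        donor_level = 2.0 * float(snapp["protein_a"].mean())
        patient_cells = snapp["protein_a"] + snapp["protein_b"]
        for i in range(12):
            loading = np.exp(rngw.normal(0.0, 0.1))
            lanes.append(
                LaneDensitometry(
                    lane_id=f"donor_{i}", group="donor",
                    bands=[
                        Band("target", 140.0, donor_level * loading * np.exp(rngw.normal(0, 0.1))),
                        Band("loading", 103.0, donor_level * loading),
                    ],
                    assay="western",
                )
            )
        # three patient hearts, six lanes each (donor carries twelve)
        sampled = rngw.choice(patient_cells.to_numpy(dtype=float), size=18, replace=False)
        for i, lvl in enumerate(sampled):
            heart = f"patient_{i // 6 + 1}"
            loading = np.exp(rngw.normal(0.0, 0.1))
            lanes.append(
                LaneDensitometry(
                    lane_id=f"{heart}_lane{i % 6}", group=heart,
                    bands=[
                        Band("target", 140.0, max(lvl, 1e-9) * loading * np.exp(rngw.normal(0, 0.1))),
                        Band("loading", 103.0, donor_level * loading),
                    ],
                    assay="western",
                )
            )
        west = protein_level(lanes, reference_group="donor")
        ratios = {g: sub["ratio"].to_numpy() for g, sub in west["per_lane"].groupby("group")}
        aov = anova_dunnett(ratios, control_label="donor", n_mc=20000)
        report["western"] = {
            "group_levels_pct": west["group_levels_pct"],
            "anova": {k: aov[k] for k in ("F", "df", "p")},
            "dunnett_p": aov["dunnett_p"],
        }
        tables["western_lanes.csv"] = west["per_lane"]

    # --- stage 5: force-pCa analysis
    force_report = {}
    force_values = {}
    for label, (cfg, data) in cohorts.items():
        snap = data["snapshot"].cells
        if cfg.params.nmd:
            # truncation: no mutant protein exists; the functional lesion is
            # each cell's WT-protein deficit relative to the expected
            # two-allele donor level
            expected = 2.0 * float(snap["protein_a"].mean())
            frac = np.clip(1.0 - (snap["protein_a"] + snap["protein_b"]) / expected, 0.0, 1.0).to_numpy()
        else:
            frac = snap["mut_protein_frac"].fillna(0.0).to_numpy()
        sel = cfg.rng("force_cells").choice(
            len(frac), size=min(cfg.cohort.n_force_cells, len(frac)), replace=False
        )
        curves = gen_force_curves(cfg, frac[sel])
        tables[f"force_curves_{label}.csv"] = curves
        fits = []
        at_554 = []
        logit_fits = []
        for cell_id, sub in curves.groupby("cell_id", sort=False):
            rec = ForcePCaRecord(
                cell_id=cell_id, pca=sub["pCa"].to_numpy(),
                force=sub["force_kN_m2"].to_numpy(), group=label,
            )
            fit = hill_fit(rec)
            norm = normalize_forces(rec)
            if norm.normalized:
                at_554.append(norm.force_at(5.54))
                try:
                    logit_fits.append(logit_two_segment_fit(norm, breakpoint=5.54))
                except ValueError:
                    pass
            if fit["converged"]:
                fits.append({k: fit[k] for k in ("cell_id", "F_max", "pCa50", "nH")})
        fits_df = pd.DataFrame(fits)
        tables[f"force_fits_{label}.csv"] = fits_df
        force_values[label] = np.asarray(at_554)
        force_report[label] = {
            "n_cells": int(len(fits_df)),
            "pCa50_mean": float(fits_df["pCa50"].mean()),
            "pCa50_sd": float(fits_df["pCa50"].std(ddof=1)),
            "slope_high_ca_mean": float(
                np.mean([f["slope_high_ca_side"] for f in logit_fits])
            )
            if logit_fits
            else np.nan,
        }
    if len(force_values) == 2:
        force_report["contrast_pca554"] = compare_groups(
            force_values["donor"], force_values["patient"]
        )
    report["force"] = force_report

    # --- stage 6: qPCR absolute quantification round trip
    qcfg, qdata = cohorts["donor"]
    copies_true = qdata["counts"].loc[~qdata["counts"]["censored"], "copies"].to_numpy()
    copies_true = copies_true[copies_true > 0][:40]
    plate = gen_qpcr_plates(qcfg, copies_true)
    curve = standard_curve_fit(plate[plate["role"] == "standard"])
    sample_cq = (
        plate[plate["role"] == "sample"].groupby("sample_id", sort=False)["cq"].mean()
    )
    recovered = copies_from_cq(sample_cq.to_numpy(), curve)
    report["qpcr"] = {
        "slope": curve.slope,
        "efficiency": curve.efficiency,
        "r_squared": curve.r_squared,
        "recovered_mean_copies": float(np.mean(recovered)),
        "true_mean_copies": float(np.mean(copies_true)),
    }
    tables["qpcr_plate.csv"] = plate

    # --- stage 7: simulated reference population vs measured analogues (KS)
    sim_cfg = cohorts["patient" if patient is not None else "donor"][0]
    sim = simulate_population(
        sim_cfg.params, n_sim_reference, seed=seed + 7, force_map=sim_cfg.force_map
    )
    sim_cells = sim.cells
    meas_cells = cohorts["patient" if patient is not None else "donor"][1]["snapshot"].cells
    ks = {}
    ks["total_mrna"] = float(
        sps.ks_2samp(sim_cells["total_mrna"], meas_cells["total_mrna"]).statistic
    )
    ks["mut_mrna_frac"] = float(
        sps.ks_2samp(
            sim_cells["mut_mrna_frac"].dropna(), meas_cells["mut_mrna_frac"].dropna()
        ).statistic
    )
    if "force" in sim_cells.columns and "force" in meas_cells.columns:
        ks["force_pca524"] = float(
            sps.ks_2samp(
                sim_cells["force"].dropna(), meas_cells["force"].dropna()
            ).statistic
        )
    sim_table = ATSTable(sim_cells["ats"].to_numpy(), "simulated", scenario)
    report["simulation_comparison"] = {
        "n_simulated": n_sim_reference,
        "ats_bins_pct": ats_distribution(sim_table),
        "mean_total_mrna": float(sim_cells["total_mrna"].mean()),
        "ks_distance": ks,
    }

    # --- outputs + manifest
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rep = _Reporter(out)
        for name, df in tables.items():
            rep.csv(df, name)
        rep.json(report, "report.json")
        config_hash = hashlib.sha256(
            json.dumps(
                {"scenario": scenario, "seed": seed, "n_population": n_population,
                 "n_sim_reference": n_sim_reference},
                sort_keys=True,
            ).encode()
        ).hexdigest()
        manifest = {
            "config_hash": config_hash,
            "seed": seed,
            "version": __version__,
            "files": {p.name: _sha256(p) for p in rep.files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        report["manifest"] = manifest
    return report
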