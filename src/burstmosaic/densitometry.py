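"""Densitometric quantification of allele-specific fragments and blots.

Allele-specific restriction of an RT-PCR amplicon yields one diagnostic
fragment per allele (plus a common fragment shared by both); the molar
amount of each allele is the band's integrated optical density (IOD)
divided by its fragment length, because intercalating-stain signal scales
with base pairs times molarity.  Replicate QC follows the multialiquot
rule: repeated single-cell-equivalent aliquots of pooled RNA estimate the
pure technical scatter, and twice that SD is the cutoff on the difference
between a cell's two technical replicates.  Western-blot lanes are
quantified as target/loading-control IOD ratios relative to a reference
group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FRAGMENT_TABLES",
    "Band",
    "LaneDensitometry",
    "AllelicCall",
    "fraction_from_iods",
    "multialiquot_cutoff",
    "replicate_qc",
    "linearity_rmse",
    "protein_level",
]

log = logging.getLogger(__name__)

# Diagnostic fragment lengths (bp) per assay.  MwoI cuts the nested TNNI3
# amplicon into a 202 bp mutant-specific, a 160 bp WT-specific and a 115 bp
# common fragment; BbsI leaves a 317 bp WT fragment (202 + 115, uncut at
# the variant site) and a 273 bp SNP fragment.  Only the allele-specific
# bands are informative for the ratio; the common fragment and sub-50-bp
# pieces are excluded.
FRAGMENT_TABLES: dict[str, dict[str, int]] = {
    "MwoI_TNNI3": {"mut": 202, "wt": 160, "common": 115},
    "BbsI_SNP": {"wt": 317, "snp": 273},
}

# band label -> variant-allele flag, per assay
_VARIANT_BAND = {"MwoI_TNNI3": "mut", "BbsI_SNP": "snp"}
_REFERENCE_BAND = {"MwoI_TNNI3": "wt", "BbsI_SNP": "wt"}


@dataclass
class Band:
    label: str
    fragment_bp: float
    iod: float

    def __post_init__(self) -> None:
        if self.iod < 0:
            raise ValueError("IOD must be >= 0")
        if self.fragment_bp <= 0:
            raise ValueError("fragment length must be > 0")


@dataclass
class LaneDensitometry:
    """Band IODs of one gel or blot lane."""

    lane_id: str
    bands: list[Band]
    assay: str = "MwoI_TNNI3"
    cell_id: str = ""
    replicate: int = 1
    group: str = ""

    def band(self, label: str) -> Band | None:
        for b in self.bands:
            if b.label == label:
                return b
        return None


@dataclass
class AllelicCall:
    """QC'd variant-allele fraction of one cell (two technical replicates)."""

    cell_id: str
    replicate_fractions: tuple[float, float]
    cutoff: float
    mean_fraction: float | None = None
    qc_pass: bool = False


def fraction_from_iods(lane: LaneDensitometry, length_normalize: bool = True) -> float:
    """Variant-allele fraction (%) of one lane from its band IODs.

    Molar amount per allele is ``iod / fragment_length`` (stain mass is
    proportional to bp x molarity); ``length_normalize=False`` switches
    to raw intensities for sensitivity analysis.  NaN is returned (and
    logged) when both allele-specific bands are empty.
    """
    var_label = _VARIANT_BAND[lane.assay]
    ref_label = _REFERENCE_BAND[lane.assay]
    var_band = lane.band(var_label)
    ref_band = lane.band(ref_label)
    if var_band is None or ref_band is None:
        raise ValueError(
            f"lane {lane.lane_id}: both allele-specific bands "
            f"({var_label!r}, {ref_label!r}) are required"
        )
    if length_normalize:
        molar_var = var_band.iod / var_band.fragment_bp
        molar_ref = ref_band.iod / ref_band.fragment_bp
    else:
        molar_var, molar_ref = var_band.iod, ref_band.iod
    total = molar_var + molar_ref
    if total == 0:
        log.warning("lane %s: both allele IODs are zero; fraction undefined", lane.lane_id)
        return float("nan")
    # guard against float round-off pushing a pure-allele lane past 100
    return float(np.clip(100.0 * molar_var / total, 0.0, 100.0))


def multialiquot_cutoff(fractions) -> dict[str, float]:
    """Technical-scatter estimate from repeated single-cell-equivalent aliquots.

    Returns the aliquot mean, sample SD (n-1) and the replicate-difference
    cutoff ``2 * SD``.
    """
    x = np.asarray(fractions, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 aliquots")
    sd = float(np.std(x, ddof=1))
    return {"mean": float(np.mean(x)), "sd": sd, "cutoff": 2.0 * sd, "n": int(len(x))}


def replicate_qc(cell_id: str, rep1: float, rep2: float, cutoff: float) -> AllelicCall:
    """Pass a cell iff its two replicate fractions differ by less than ``cutoff``."""
    for v in (rep1, rep2):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"fractions must lie in [0, 100], got {v}")
    ok = abs(rep1 - rep2) < cutoff
    return AllelicCall(
        cell_id=cell_id,
        replicate_fractions=(rep1, rep2),
        cutoff=cutoff,
        mean_fraction=(rep1 + rep2) / 2.0 if ok else None,
        qc_pass=ok,
    )


def linearity_rmse(expected, observed) -> float:
    """Root-mean-square error (%) of observed vs expected mixture fractions."""
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape:
        raise ValueError("expected and observed must have equal length")
    if e.size == 0:
        raise ValueError("need at least one design point")
    return float(np.sqrt(np.mean((o - e) ** 2)))


def protein_level(
    lanes: list[LaneDensitometry],
    reference_group: str,
    target_label: str = "target",
    loading_label: str = "loading",
) -> dict[str, object]:
    """Western-blot group levels as % of the reference-group mean ratio.

    Each lane contributes ``iod_target / iod_loading``; lanes with a zero
    loading-control IOD are excluded and logged.  Group level is
    ``100 * mean(ratio_group) / mean(ratio_reference)``.
    """
    rows = []
    for lane in lanes:
        tgt = lane.band(target_label)
        ld = lane.band(loading_label)
        if tgt is None or ld is None:
            raise ValueError(f"lane {lane.lane_id}: target and loading bands required")
        if ld.iod == 0:
            log.warning("lane %s: loading IOD is zero; lane excluded", lane.lane_id)
            continue
        rows.append({"lane_id": lane.lane_id, "group": lane.group, "ratio": tgt.iod / ld.iod})
    df = pd.DataFrame(rows)
    if df.empty or reference_group not in set(df["group"]):
        raise ValueError(f"no usable lanes for reference group {reference_group!r}")
    ref_mean = df.loc[df["group"] == reference_group, "ratio"].mean()
    levels = {
        grp: 100.0 * sub["ratio"].mean() / ref_mean for grp, sub in df.groupby("group")
    }
    return {"per_lane": df, "group_levels_pct": levels, "reference_group": reference_group}
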