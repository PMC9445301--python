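"""Per-nucleus active-transcription-site (aTS) count statistics.

The distribution of aTS per nucleus is summarised in the bins
{0, 1, 2, 3, 4, >4} used for reporting, and an independent-allele model
(each of A allele copies ON with probability p_on, mixture over ploidy
classes) can be fitted by maximum likelihood with a parametric-bootstrap
goodness-of-fit p-value.  The ML fit is a formalisation the source data
were only inspected visually with; it is an extension of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["ATSTable", "BIN_LABELS", "ats_distribution", "fit_independent_allele_model"]

BIN_LABELS = ("0", "1", "2", "3", "4", ">4")


@dataclass
class ATSTable:
    """Per-nucleus aTS counts for one individual and gene."""

    counts: np.ndarray
    individual: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size == 0:
            raise ValueError("an individual needs at least one nucleus")
        if np.any(self.counts < 0):
            raise ValueError("aTS counts must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, individual: str, gene: str) -> "ATSTable":
        sel = df[(df["individual"] == individual) & (df["gene"] == gene)]
        return cls(sel["ats_count"].to_numpy(), individual, gene)


def ats_distribution(table: ATSTable) -> dict[str, float]:
    """Percentage of nuclei with 0, 1, 2, 3, 4 and >4 aTS (sums to 100)."""
    counts = table.counts
    n = counts.size
    bins = [np.sum(counts == k) for k in range(5)]
    bins.append(np.sum(counts > 4))
    return {lab: 100.0 * b / n for lab, b in zip(BIN_LABELS, bins)}


def _bin_counts(table: ATSTable) -> np.ndarray:
    c = table.counts
    return np.array([*(np.sum(c == k) for k in range(5)), np.sum(c > 4)], dtype=float)


def _mixture_bin_probs(p_on: float, ploidy_mix: dict[int, float]) -> np.ndarray:
    """Bin probabilities under a ploidy mixture of Binomial(A_k, p_on).

    ``ploidy_mix`` maps total allele copies A_k (2 for a diploid nucleus)
    to mixture weights; the ``>4`` bin pools all counts above 4
    (right-censored in the likelihood).
    """
    probs = np.zeros(6)
    for a, w in ploidy_mix.items():
        pmf = stats.binom.pmf(np.arange(5), a, p_on)
        probs[:5] += w * pmf
        probs[5] += w * stats.binom.sf(4, a, p_on)
    return probs / probs.sum()


def fit_independent_allele_model(
    table: ATSTable,
    ploidy_mix: dict[int, float] | None = None,
    n_bootstrap: int = 300,
    seed: int = 0,
) -> dict[str, object]:
    """ML fit of the independent-allele ON probability to binned aTS counts.

    Returns ``p_on_hat``, the chi-square goodness-of-fit statistic on the
    six reporting bins and its parametric-bootstrap p-value (tables are
    re-simulated from the fitted model and re-fitted).  Boundary fits
    (all mass at zero or at the maximum) are flagged non-identifiable for
    the bootstrap.
    """
    if ploidy_mix is None:
        ploidy_mix = {2: 1.0}
    total_w = sum(ploidy_mix.values())
    ploidy_mix = {int(a): w / total_w for a, w in ploidy_mix.items()}
    obs = _bin_counts(table)
    n = obs.sum()
    if n < 10:
        raise ValueError("need at least 10 nuclei for the model fit")

    def nll(p: float) -> float:
        probs = _mixture_bin_probs(p, ploidy_mix)
        with np.errstate(divide="ignore"):
            logp = np.log(probs)
        mask = obs > 0
        if np.any(np.isneginf(logp[mask])):
            return np.inf
        return -float(np.sum(obs[mask] * logp[mask]))

    res = optimize.minimize_scalar(nll, bounds=(1e-9, 1 - 1e-9), method="bounded")
    p_hat = float(res.x)
    boundary = bool(obs[0] == n or obs[1:].sum() == n and obs[0] == 0)
    # snap clean boundary cases
    if obs[0] == n:
        p_hat = 0.0
        boundary = True

    def chisq(bin_counts: np.ndarray, p: float) -> float:
        exp = _mixture_bin_probs(p, ploidy_mix) * bin_counts.sum()
        mask = exp > 0
        return float(np.sum((bin_counts[mask] - exp[mask]) ** 2 / exp[mask]))

    out: dict[str, object] = {
        "p_on_hat": p_hat,
        "boundary": boundary,
        "n": int(n),
        "bins_observed": obs.tolist(),
    }
    if boundary:
        out.update({"gof_chisq": np.nan, "gof_p": np.nan})
        return out
    stat = chisq(obs, p_hat)
    rng = np.random.default_rng(seed)
    probs = _mixture_bin_probs(p_hat, ploidy_mix)
    hits = 0
    for _ in range(n_bootstrap):
        sim = rng.multinomial(int(n), probs).astype(float)

        def nll_sim(p: float, sim=sim) -> float:
            pr = _mixture_bin_probs(p, ploidy_mix)
            with np.errstate(divide="ignore"):
                lg = np.log(pr)
            mask = sim > 0
            if np.any(np.isneginf(lg[mask])):
                return np.inf
            return -float(np.sum(sim[mask] * lg[mask]))

        p_sim = optimize.minimize_scalar(
            nll_sim, bounds=(1e-9, 1 - 1e-9), method="bounded"
        ).x
        if chisq(sim, float(p_sim)) >= stat - 1e-12:
            hits += 1
    out.update({"gof_chisq": stat, "gof_p": (hits + 1) / (n_bootstrap + 1)})
    return out
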