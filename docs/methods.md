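# Methods

## Model

Each allele copy of a gene in a cardiomyocyte nucleus is an independent
two-state (telegraph) promoter:

    OFF → ON      k_on            ON → OFF     k_off
    ON  → ON + M  k_tx            M  → ∅       d_m · M
    M   → M + P   k_p             P  → ∅       d_p · P

All rates are per hour.  The reaction network is simulated exactly with
the Gillespie direct method; one nucleus carries `ploidy` copies of each
of the two allele classes (default 1 per class, i.e. a diploid nucleus).
An allele with an ON promoter is the model analogue of an active
transcription site (aTS) as seen by single-molecule FISH with co-localised
intron/exon probes; by default "ON ⇔ visible aTS".  Stationary moments of
the per-allele mRNA count have the closed forms

    p_on = k_on/(k_on+k_off)
    ⟨m⟩  = p_on·k_tx/d_m
    Fano = 1 + k_tx·k_off/((k_on+k_off)(k_on+k_off+d_m))

which serve as the analytic oracle for the simulator (agreement within
Monte-Carlo error is part of the test suite).  Fano → 1 as k_off → 0 (the
continuous-transcription/Poisson limit).  Note that the Fano factor is not
globally monotone in k_off: it rises while switching is slower than
k_on + d_m and falls again for very fast switching, where bursts average
out.

In truncation-mutation mode (`nmd=True`) mature transcripts of the second
allele class are removed immediately by nonsense-mediated decay: its
mature-mRNA and protein pools stay empty while the promoter still bursts
(and is still counted as an aTS).  This produces the haploinsufficiency
mosaic: zero mutant protein everywhere, cell-to-cell-variable wild-type
protein.

Force generation: a cell with mutant-protein fraction f (for truncations,
the wild-type-protein deficit relative to the two-allele expectation) has

    pCa50(f) = pCa50_WT + f·Δ
    F(pCa)/F_max = 1 / (1 + 10^{n_H·(pCa − pCa50(f))})

Linear interpolation of pCa50 in f is the minimal monotone assumption; a
logistic mixture of two Hill curves would be an alternative, but with only
the heterozygous mean shift constrained by data the extra parameter is not
identifiable.

## Parameters and calibration

Only population summaries of the tissue measurements are published, so the
kinetics are produced by `calibrate()` from two summaries: the fraction of
nuclei without aTS (zero-aTS fraction) and the mean total copies per cell.
With A = 2·ploidy independent alleles, (1−p_on)^A equals the zero-aTS
fraction, and k_tx follows from the mean.  Defaults used by the scenario
factories:

| parameter | default | rationale |
|---|---|---|
| zero-aTS fraction | 0.60 (TNNI3-like), 0.187 (MYBPC3-like) | averages of the published per-donor percentages (61/64/55 and 23/23/10) |
| mean copies/cell | 552 (TNNI3-like), 2937 (MYBPC3-like) | published single-cell qPCR means |
| d_m | ln2/10 h⁻¹ | 10-hour mRNA half-life, a typical mammalian mRNA scale |
| k_off | 0.1 h⁻¹ | see below |
| k_p | 0.15 h⁻¹ per mRNA | sets a protein pool of ~10³–10⁴ molecules per allele; only ratios matter downstream |
| d_p | ln2/24 h⁻¹ | 24-hour protein half-life: slow enough to integrate over bursts, fast enough that the mosaic persists |
| pCa50_WT | 5.55 | published donor mean |
| Δ (homozygous pCa50 shift) | −0.10 (missense), +0.06 (truncation direction) | twice the published heterozygous shift (5.55→5.50); sensitisation direction for the truncation |
| n_H | 2.0 | typical cardiomyocyte cooperativity |

`calibrate()` itself defaults to k_off = 1 h⁻¹ when no value is passed;
the **scenario factories override it to 0.1 h⁻¹**.  Reason: single cells
are observed across the *full* range of allelic fractions (essentially
pure wild-type through pure mutant).  That requires burst intervals longer
than the mRNA lifetime — with k_off = 1 h⁻¹ and the calibrated p_on the
OFF periods last ~3.4 h against a 14.4 h mRNA lifetime, the pool averages
over many bursts, and the fraction distribution collapses to SD ≈ 0.15
around 0.5.  At k_off = 0.1 h⁻¹ (OFF ≈ 36 h) the mRNA-fraction SD is
≈ 0.35 and the protein-fraction SD ≈ 0.25, reproducing the observed
mosaic and a force-variance fold in the published 3–4× range.

## Synthetic measurement model

The generators emulate the statistical structure of each assay, not its
physics:

- **Gel/blot densitometry** — band IOD = gain · molarity · fragment-bp ·
  exp(ε), ε ~ N(0, iod_cv²) per band (iod_cv = 0.05); per-lane gain is
  lognormal.  Replicate-to-replicate variation of the measured allele
  fraction is N(0, replicate_sd²) with replicate_sd = 6.5 percentage
  points, the published multialiquot technical scatter.
- **qPCR** — Cq = intercept + slope·log10(copies) + N(0, 0.2²), perfect
  doubling chemistry (slope −3.3219), standards as a 10-fold series over
  five decades in duplicate.
- **Force** — F = passive + F_max · Hill(pCa; pCa50(f)) · (1+ε) with
  ε ~ N(0, 0.05²), lognormal per-cell F_max (median 30 kN/m², CV 0.2),
  passive offset 2 kN/m², on the grid
  {9.0, 6.0, 5.9, 5.74, 5.6, 5.54, 5.4, 5.24, 5.0, 4.6, 4.18}.
- **Cell areas** — lognormal (median 350 µm², σ = 0.25), independent of
  expression by default; an `area_coupling` parameter exists to probe the
  power of the size-correlation test.

Noise families (lognormal for intensities, additive Gaussian for Cq,
multiplicative Gaussian for force) were chosen for positivity and
simplicity.  What the generators deliberately do **not** model: FISH spot
detection and image segmentation, gel smiling/background subtraction,
PCR dropout and inhibition, cross-bridge kinetics, sarcomere-length
dependence, or cell–cell mechanical coupling.  A green test suite
therefore shows that the estimators are correct under the assumed error
structure, not that real data satisfy those assumptions.

## Numerical choices

- **SSA sampling** — populations are independent cells started from the
  empty OFF state and advanced for a burn-in of 10× the slowest relaxation
  time (max of 1/d_m, 1/d_p, 1/(k_on+k_off)); shorter user burn-ins warn.
  Per-cell seeds are spawned from the root seed via
  `numpy.random.SeedSequence`, so populations are reproducible and
  order-independent.  The inner kernels are numba-compiled.
- **aTS detectability** — optional: ON alleles receive nascent counts
  drawn as Poisson(k_tx × residence time) (default residence ~5 min) so a
  detection threshold in nascent transcripts can be applied; this is a
  detectability overlay, not part of the kinetic state.
- **Censored copies** — cells printed as "below detection limit" are
  excluded from moment estimates by default (option: substitute limit/2);
  they are never imputed into allelic calls.
- **Hill fit** — passive force (pCa 9.0) subtracted; deterministic
  initialisation (F_max₀ = max active force, pCa50₀ = pCa nearest
  half-max, n_H₀ = 2); bounded least squares; non-convergence flags the
  record instead of raising.
- **Two-segment logit** — points with normalised force outside
  [0.01, 0.99] are excluded (logit undefined at 0/1; threshold
  configurable); the two segments are constrained continuous; the knot is
  chosen on the measured pCa grid by SSE, or fixed (e.g. 5.54).  On an
  exact Hill curve both slopes equal −n_H·ln 10 — note this identity
  requires forces normalised to the Hill asymptote; normalising to the
  measured pCa-4.18 point (≈99.8% of the asymptote at n_H = 2) bends the
  logit slightly near saturation.
- **Mann-Whitney U** — exact enumeration of all labelings for
  n₁+n₂ ≤ 14 (valid under ties via midranks); otherwise normal
  approximation with tie-corrected variance and 0.5 continuity
  correction.  The worst-case gap between the two at the crossover size
  is ≈0.012 in p.
- **Dunnett adjustment** — Monte-Carlo from the equicorrelated
  multivariate-t null of max|T| (correlations λᵢλⱼ,
  λᵢ = √(nᵢ/(nᵢ+n₀))), 10⁵ draws with a fixed seed by default.
- **Levene** — mean-centred (classical) by default; median centring
  (Brown–Forsythe) as an option.
- **Bimodality** — 1- vs 2-component Gaussian mixture on log1p counts;
  "bimodal" only if the 2-component BIC is better by more than 10 (a
  conventional strong-evidence threshold); zero-spread inputs are flagged
  degenerate.
- **Multialiquot QC** — cutoff = 2× the sample SD (n−1) of repeated
  single-cell-equivalent aliquots; cells whose duplicate fractions differ
  by ≥ cutoff are excluded, never imputed.
- **Western normalisation** — target/loading IOD per lane; group level as
  percent of the reference-group mean ratio; zero-loading lanes excluded.

## Problem sizes

Simulated populations default to 10³–10⁵ cells (the original modelling
scale of 10⁸ cells is far beyond what the distributional comparisons
need; KS distances are sample-size-adjusted).  The test suite uses 10⁴
cells for moment agreement and calibration round-trips, 500 replicate
populations for the Poisson-limit calibration, 2000 replicates for test
size checks, and 100-cell cohorts for force contrasts.

## Known limitations

- Rate constants are calibrated from two summary statistics; k_off, d_m
  and the protein rates are conventions, not estimates.  Only ratios and
  distribution shapes, not absolute protein numbers, should be read from
  the simulations.
- Binucleation is treated only through the ploidy mixture of aTS-bearing
  genome copies; nuclei within one cell are not modelled separately.
- The force map compresses all mutation effects into a single pCa50
  shift; maximal force and cooperativity are held fixed.
- The independent-allele ML fit and the mixture-BIC bimodality rule are
  formalisations added by this package; the original analyses were
  visual/qualitative at these points.
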