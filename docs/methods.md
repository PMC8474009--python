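# Methods

This note records the models, defaults and design choices behind
`phosphomrm`, and what the synthetic-data generators do and do not emulate.

## Panel selection model

Trypsin is modeled as cleavage C-terminal to K and R with **no proline
suppression** by default. This is deliberate: real phosphopeptide panels
contain fully cleaved forms that require cutting a K–P bond (the worked
LATS2-style example `DSLQK` followed by `PGLEAPPR` only exists under the
unsuppressed rule). The classical KP/RP-protected rule is available via
`suppress_proline=True`. The missed-cleavage ceiling is 2, which is exactly
what the short-peptide rescue path needs: a sub-6-residue fully cleaved form
is kept only if a 6–40-residue missed-cleaved extension was historically
observed.

Selection is a fixed decision list (length filter → rescue → observation
frequency → multiplicity preference), so identical inputs always give an
identical panel; ties are broken by fewest missed cleavages, then shortest
length. "Markedly more prevalent" for preferring a doubly phosphorylated
form is quantified as a ≥ 3× observation-count ratio; no consensus value
exists for this, so it is a configurable parameter (`prevalence_factor`).
Unobserved sites are rejected (`not_observed`) unless explicitly whitelisted
per site — modeling the practice of carrying biologically critical sites
into an assay despite missing discovery evidence. Rejected sites are kept
with reasons rather than dropped, since exclusion bookkeeping is part of
panel QC.

Peptide uniqueness and cross-species conservation are exact substring
matches against the relevant proteome, with no I/L equivalence: the question
the panel asks is whether the measured signal is attributable to one gene,
and an I/L-folded match would not co-elute identically anyway.

## Mass and method arithmetic

All masses come from one monoisotopic table (proton 1.0072765 Da, water
18.0105646 Da, phosphate +79.9663305 Da, full ¹³C/¹⁵N label deltas
K +8.01420, R +10.00827, L +7.01723, P +6.01385) with 5-decimal output
rounding. Phospho neutral-loss transitions are not generated by default —
the ranking works over b/y ions only.

Transition ranking replaces a manual spectral-library curation step with a
deterministic tiering: (1) y-ions with product m/z above the precursor m/z,
(2) site-determining ions of either series, (3) remaining y-ions, (4)
b-ions; intensity-descending within tiers, ties broken by higher product
m/z, y before b, lower index. A fragment is *site-determining* when its span
contains the phosphorylated residue or when it contains an alternative
S/T/Y acceptor the phosphosite does not share — either way its mass
separates positional isomers. Between 3 and 6 transitions are kept.

Collision energy uses the standard triple-quadrupole linear form
CE = slope·(precursor m/z) + intercept with defaults 0.0339/2.3597 (2+) and
0.0295/2.4141 (3+), rounded to 0.1 eV. Instruments differ; the coefficients
are config-overridable, and the testable content is the ramp logic: exactly
11 values, the calculated CE ± 5 steps of 2 eV, clipped at zero with
duplicates kept (instrument export de-duplicates). Monitored precursor
charge defaults to 2+.

Scheduled methods carry per-route defaults (IMAC: 160 min gradient, 3.0 s
cycle; pY: 120 min, 1.5 s cycle; Q1 0.4 / Q3 0.7 FWHM; 10-min RT window)
and report the maximum number of concurrent transitions from a 0.1-min grid
sweep as a feasibility diagnostic. Mixture assembly sorts each route
alphabetically by gene, then packs contiguously into the minimum number of
mixtures whose sizes fit the route bounds (IMAC [43, 50], pY [31, 40],
dual-route peptides always one mixture) with sizes equal to within one;
infeasible bounds relax to a single mixture with a warning. All mixtures
are equimolar at 2 pmol/µl.

## Quantification model

Peak integration is deliberately rule-based rather than curated: the
elution window is the apex of the *summed heavy* signal ± 1.5 × its FWHM
(linear-interpolated half-max crossings), and the same window is applied to
light and heavy traces — the SIL standard is the ground truth for where the
peptide elutes. Areas are trapezoidal on the raw grid with no baseline
subtraction (synthetic baselines are flat; a linear-baseline option exists,
off by default), and apex heights are read from unsmoothed traces.

The reporting transition is the largest-heavy-area transition whose
relative contribution agrees between light and heavy patterns within 0.2
(absolute difference of normalized fractions); a larger deviation flags a
co-eluting interference. If every transition is flagged the least-deviating
one is used with a warning. Detection requires positive light area on every
monitored transition plus a reporting-transition light apex above the route
threshold (pY 250 counts, IMAC 300); signal below threshold is category 2,
any absent transition is category 3. "Minimal signal" is operationalized as
apex height because the thresholds are stated in counts; per-transition
minimal signal beyond the reporting transition is operationalized as
nonzero integrated area.

## Statistics

Ratios are log2-transformed; category-2 values are kept as measured.
Category-3 cells are imputed from `Normal(μ − shift·σ, σ)` with μ, σ the
mean/SD of the category-2 log2 ratios and shift = 1 — category-2 values are
the faintest quantifiable signals, so one SD below them stands in for
below-detection-limit abundance. Parameters are pooled per dataset ×
enrichment route (not per sample); users with strong per-sample censoring
should estimate per sample instead. Imputation is seeded and bit-reproducible
and never alters category-1/2 cells.

The moderated t-test assumes row variances follow a scaled-F distribution,
s²_g ~ s₀²·F(d_g, d₀). Hyperparameters are estimated by the method of
moments on log s²_g (digamma/trigamma moment equations; the trigamma
inverse solved by Newton iteration). The posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) feeds an otherwise ordinary t
statistic with d₀ + d_g degrees of freedom. d₀ = 0 recovers the per-row
Student t (tested against scipy); the fit is verified against Bioconductor
limma on a frozen fixture. Degenerate cases: no positive variances → the
common variance is 0 and zero effects map to t = 0; rows with fewer than 2
values per group are flagged and skipped. BH adjustment is the step-up
procedure, tested against a naive O(n²) oracle and statsmodels. ANOVA and
Tukey HSD go through scipy; Tukey p-values are BH-adjusted across all
comparisons.

Median-MAD normalization uses the **unscaled** MAD (no 1.4826 consistency
factor), matching the robust z-score convention of common heat-map tools;
constant rows become zeros and are flagged. Sample clustering uses
1 − Spearman over pairwise-complete rows (≥ 3 shared), complete linkage,
with columns pre-sorted lexicographically so merge order is deterministic
under ties.

Significance conventions: BH-adjusted p < 0.05 for cell-line contrasts,
< 0.1 for tissue/xenograft contrasts; both are parameters, not hard-coded.

## Synthetic data: what it does and does not show

`make_proteome` embeds each selection scenario by construction (plain
observed site, short-peptide rescue, a peptide shared verbatim between two
genes, a > 40-residue tryptic context, pY sites alternating between
pY-only and dual-enrichment history, doubly phosphorylated forms
alternating between doubly-dominant and singly-dominant evidence), padded
with site-free filler proteins. Evidence counts are log-uniform
(10^U(0.5, 2.5)). Filler sequence avoids K/R/S/T/Y/P so scenarios stay
unambiguous.

`simulate_chromatograms` models each transition as a Gaussian elution peak
(σ = 0.1 min) sampled on a 0.05-min grid, apex linear in analyte amount and
shared relative-intensity pattern between labels, calibrated so the default
30-fmol heavy spike gives a 10,000-count apex. Noise is additive Normal
(default 5% of heavy apex) truncated at zero; light signal below a
censoring amount is zeroed; an optional co-eluting contaminant can be
injected into one named light transition. The generator emulates the signal
consequences of enrichment, not its chemistry: no antibody/IMAC recovery
fractions, no Poisson counting statistics, no tailing or retention-time
drift. Passing tests therefore demonstrate the correctness of the
integration/ratio/detection logic, not robustness to real chromatographic
pathology.

`simulate_study` draws log2 ratios per group (defaults: 500 rows, duplicate
samples per arm, within-group SD 0.5, effect 1.0 log2 units in 10% of rows)
and assigns categories by value quantiles (lowest 5% missing, next 10%
below-threshold).

## Problem sizes and numerical checks

The test suite and the acceptance script run at desk scale by design:
brute-force digestion oracles up to 60-residue proteins, 9-peptide
noise-free titrations across a 100-fold ratio range, 50-peptide × 3-replicate
precision panels, 2,000-row null calibrations and 10,000-draw imputation
moment checks. Noise-free ratio recovery is exact to well under 1%; the
null type-I error of the moderated test sits in [0.04, 0.06] at α = 0.05.

One caveat the package reports honestly: at the duplicate-sample design
(effect 1.0 log2 units, SD 0.5, n = 2+2, 10% true effects) the
BH-controlled power of *any* test is a few percent — even a known-variance
z-test cannot clear the adaptive BH cutoff at that effect-to-noise ratio.
The acceptance output therefore reports the computed power at that design
(`power_bh05_n2plus2`) as is, and the parameter-recovery test demonstrates
> 50% power at a stronger operating point (effect 2.0) of the same
machinery.

## Known limitations

- No vendor raw/mzML ingestion; chromatograms enter as long-format TSV.
- No retention-time alignment across runs; windows come from the heavy
  standard within each run.
- No isoform resolution beyond exact-substring gene lists.
- Collision-energy coefficients are instrument-specific; the defaults are a
  common parameterization, not a calibration.
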