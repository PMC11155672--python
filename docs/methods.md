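# Methods

This note records the statistical model behind each pipeline stage, the
conventions chosen where more than one reading was defensible, what the
synthetic-data generator does and does not emulate, and the numerical
details a maintainer would need.

## Screen model

The unit of observation is the well: ~100 worms exposed to one chemical at
one nominal concentration, in one biological repeat and one technical
replicate. A worm is scored positive when it carries at least one
GFP-positive embryo; per-embryo counts are not modelled, because the
readout of interest is the worm-level ratio. The per-well readout is
therefore a binomial proportion, n_gfp_pos / n_total.

**QC.** A well is excluded when its dead-worm fraction strictly exceeds
10% (configurable) or when it is flagged for ectopic reporter expression
(spermatheca/pharynx fluorescence that confounds scoring). Both rules are
applied before any averaging; each exclusion is logged with its reason,
with the dead-fraction rule taking precedence when both apply. A chemical
can additionally be excluded wholesale via `excluded_chemicals` (the
pattern for compounds whose own fluorescence defeats the assay).

**Averaging order.** Technical replicates are averaged within each
biological repeat, then repeat means are averaged unweighted into x. For
balanced designs this equals pooling all wells; for unbalanced designs it
weights repeats equally, which matches the design's intent (repeats are
the independent unit). Missing repeats simply reduce `n_repeats_used`.

**Standardisation.** Within each concentration group, z = (x − μ) / σ with
μ and σ computed across chemicals that have data in that group. σ uses the
sample (n − 1) convention by default; a `sigma_convention="population"`
switch exists because the convention is not identifiable from the
reference results (both reproduce the bundled matrix's classifications).
Cells are marked `NT` (never tested at that concentration) or `NDA`
(tested but nothing survived QC); both are ignored by all downstream
rules. Groups with fewer than 3 chemicals or numerically zero σ raise
rather than emit unstable z values.

**Classification.** High = any non-missing z strictly above the threshold
(default 1); low = all non-missing z strictly below it. A maximum exactly
equal to the threshold is left `unclassified` — the rule uses strict
inequalities on both sides, so the tie belongs to neither class. A
chemical with no non-missing z is reported unclassified with a warning.
Chemicals tested below nominal concentration because of solubility limits
stay in their nominal group; the actual concentration is metadata.

## Embryonic lethality

The analysis unit is the plate (9 plates per chemical: 3 experiments × 3
plates, ~100 embryos each); lethality = 1 − hatched/embryos. Because a
toxic chemical inflates both the mean and the variance of its group,
group comparisons use heteroscedasticity-robust statistics:

* **Welch ANOVA** with Satterthwaite denominator degrees of freedom; the
  two-group case reduces exactly to the squared Welch t.
* **Brown-Forsythe ANOVA** F\* = Σ nᵢ(x̄ᵢ − x̄)² / Σ (1 − nᵢ/N) sᵢ², which
  for balanced designs equals the ordinary one-way F but keeps its level
  under variance heterogeneity via Satterthwaite df.
* **Control-wise comparisons**: per chemical, a two-tailed Welch t against
  the vehicle control, Šidák-adjusted over the k comparisons
  (p_adj = 1 − (1 − p)^k). Under the usual independence approximation this
  coincides with the studentized-maximum-modulus ("T3"-style) adjustment,
  so no separate T3 path is provided; the classic pooled-variance Dunnett
  test (scipy) is available as `method="dunnett"` for users who prefer the
  textbook procedure. Significance is declared at two-tailed 0.05.

A zero-variance group makes Welch weights undefined; the model then falls
back to the ordinary one-way ANOVA with a warning, and a fully degenerate
input (all observations identical) is an error. Lethality fractions enter
the ANOVA untransformed; no arcsine or logit transform is applied by
default, since at the 2–20% lethality magnitudes involved the untransformed
analysis is standard practice and the robust tests absorb the
variance-mean coupling.

Simulation checks (run in the test suite): the Welch ANOVA's type-I error
over 10,000 global-null draws (4 groups of 9, unequal variances) lies in
[0.04, 0.06], and the Šidák-adjusted comparisons' family-wise error rate
at k = 10 stays ≤ 0.06.

## ToxCast integration

**Bioactivity ratio** = active hit calls / total assays tested, reported
at full precision and displayed to 3 decimals. A chemical with no assay
data carries a missing marker rather than a zero.

**AC50.** Potencies are handled as log10(µM). Active assays lacking an
AC50 receive the fixed value 3.0 (= 1 mM), a deliberate "active but weak /
unquantified" sentinel; non-positive AC50s are rejected. Group bioactivity
is compared with a two-tailed Welch t test.

**Family enrichment.** Active hit calls are cross-tabulated as family ×
group (top vs bottom). The "channel 1"/"channel 2" pseudo-families —
fluorescence-readout catch-alls with no target annotation — are excluded
here (though retained for bioactivity), so a chemical active only in
channel categories drops out of the family analysis.

Per family, a 2×2 Fisher exact test compares the family's counts in the
two groups. Two constructions are implemented and recorded in the output
metadata: `"rest"` (default) — family counts vs each group's remaining
non-family active counts — and `"margin"` — family counts vs the groups'
total active counts. The default alternative is **one-sided,
"greater"** in the top group: the enrichment question is directional
(which targets are over-represented among screen-positive chemicals), and
the directional test reproduces the bundled reference pattern — exactly
five families significant before adjustment, with families enriched in the
bottom group reported at p = 1 rather than flagged. A `two-sided`
alternative is exposed for users who want symmetric detection (it
additionally flags the bottom-enriched families). The family-level
p-values are Benjamini–Hochberg adjusted with m = number of families
(m = 42 for the bundled table), and a chi-square test of independence on
the full family × group table (no continuity correction) summarises the
overall association.

BH is implemented in-package (step-up, capped at 1, explicit m) and is
cross-checked against statsmodels when m equals the number of tests. Note
that BH adjusted values are *not* a fixed point of re-adjustment in
general; the tests assert the true properties (adjusted ≥ raw, monotone
in sorted order, constants are fixed points).

## Synthetic data

The generator emulates the screen's *statistical* structure, not its
biology or imaging:

* **Design**: `n_chemicals` × concentrations (default 10/30/50/100 µM) ×
  biological repeats (default 4) × duplicates (default 2), ~100 worms per
  well; odd repeats use plate layout "A", even repeats the reversed layout
  "B", so every chemical changes position between repeats (edge vs
  interior is derivable from the well label).
* **GFP+ counts**: Binomial(survivors, p) with p from per-chemical,
  per-concentration effect profiles — arbitrary probability vectors, so
  non-monotonic dose–response shapes are first-class. The baseline rate is
  0.002 (the natural male frequency); `make_effect_profiles` builds mixed
  monotonic/non-monotonic active sets reaching ~0.05 (tens of baseline
  standard deviations, matching the strongest observed hits).
* **Dead worms**: per-well fraction ~ Beta(1.5, 30) by default (mean
  ≈ 4.8%, ~9% of wells beyond the 10% QC cut, so the filter is always
  exercised); an additive edge-shift (default 0) emulates edge effects.
  The screen's true dead-worm and ectopic frequencies are not published;
  these defaults are documented choices, and the ectopic flag is
  Bernoulli(0.02).
* **Lethality**: per chemical 3 experiments × 3 plates, embryos
  ~ Poisson(100) floored at 1, hatched ~ Binomial(embryos, 1 − lethality).
* **Assays**: per chemical, Uniform{300..1200} assays; hit calls Bernoulli
  with per-chemical rates (given, or drawn from Beta(2, 6), mean 0.25 —
  the magnitude of observed bioactivity ratios); active rows carry
  AC50 = 10^Normal(1, 1) µM except a 10% missing fraction; families are
  drawn from a configurable list (~40 real families plus the two channel
  pseudo-families), optionally weighted.

One integer seed determines all three tables (lethality and assay
generators use derived substreams, so the tables are independent but
jointly reproducible). What passing simulation-based tests shows is that
the pipeline recovers *known truths under its own observation model* —
binomial counting noise, QC losses, heteroscedastic lethality. It does not
validate image scoring, systematic plate effects beyond the simple edge
shift, inter-scorer variability, or chemistry-specific artefacts; real
screens can violate the binomial model (e.g. clumped deaths), which is why
the QC log and per-stage CSVs are first-class outputs.

Recovery properties verified in the test suite: ≥ 90% of simulated
chemicals with ≥ 5× baseline GFP+ probability at ≥ 1 concentration are
classified high (50 chemicals, 20 seeds), and the two simulated
20%-lethality chemicals — and only they — are flagged significant in
≥ 95% of 100 seeds.

## Numerical details and edge cases

* Z-score groups: degenerate σ is detected at a relative 1e-12 tolerance
  (identical x up to float rounding), and raises rather than warns.
* Fisher exact p-values come from `scipy.stats.fisher_exact`; the test
  suite verifies them against exhaustive hypergeometric enumeration over
  every 2×2 table with row margins ≤ 30 and (by symmetry spot-checks)
  row-swapped variants.
* Zero-total families get p = 1 by convention and a `degenerate` flag.
* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; pipeline outputs embed a config hash, the seed and the
  package version.
* Problem sizes used by the bundled checks (25-chemical reference matrix;
  10,000-draw null simulations; 50-chemical × 20-seed and 100-seed recovery
  runs) were chosen to estimate the relevant rates to ~±0.5% while keeping
  the whole suite in the minutes range on a single CPU.

## Known limitations

* The classification is a ranking device, not a potency estimate: no
  dose–response curve fitting or EC50 estimation is attempted.
* The exact margins behind the reference family-enrichment p-values are
  not recoverable from the bundled counts alone (the original margins
  plausibly included channel-category actives); computed p-values
  therefore match the reference pattern and ordering, with small absolute
  differences on the p scale.
* The group bioactivity means printed alongside the reference tables are
  not exactly the means of the per-chemical ratios; the package reports
  what it computes from its inputs.
* The Šidák adjustment is mildly conservative under the positive
  correlation induced by a shared control; the classic Dunnett option is
  exact for equal variances but not variance-robust.
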