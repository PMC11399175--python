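# Methods

## Scope and data model

The package analyses grouped exposure studies in which every animal
contributes one value per biomarker. The central exchange format is a
tidy table (one row per animal: `animal_id`, `group`, one column per
biomarker) with unit strings carried as frame metadata. Missing values
are explicit (`NaN`), propagate through every stage, and are never
imputed — real batteries routinely have unequal per-biomarker sample
sizes, and all downstream statistics handle that natively.

## Assay endpoint extraction

Kinetic assays are reduced to the ordinary-least-squares slope of
absorbance against time, reported in OD/min with sign preserved
(substrate-depletion assays legitimately give negative slopes). All
reads are used by default; no lag-phase trimming is applied, because the
read schedules involved are short (3–6 min) and trimming rules are
protocol-specific — callers can slice traces before sloping. Blank
correction subtracts the mean signal (or mean rate) of the procedural
blank wells; blank-correct-then-average and average-then-blank-correct
commute (both are linear), which the test suite asserts on random
plates. Replicates are averaged with the coefficient of variation
reported per sample and flagged above a default threshold of 20%, a
common plate-assay quality rule; the threshold is configurable.

Endpoints are expressed in blank-corrected signal units per mg protein
(OD/min/mg or OD/mg): no extinction coefficients are applied. This is a
deliberate choice, not a gap — every statistic the package produces
(ranks, F-ratios, standardised deviation indices, IBRv2 scores) is
invariant to per-biomarker linear rescaling, so absolute enzymatic units
change no reported number. Users with calibrations can rescale columns
before analysis. For the same reason superoxide dismutase is treated as
a plain kinetic rate rather than converted to percent inhibition of
pyrogallol autoxidation; the percent-inhibition transform is monotone
over the assay's working range, so branch choices and rank statistics
are unaffected, and the deviation indices differ only through the log
step, which the standardisation largely absorbs.

## Cellular energy allocation

`Ea = E_protein + E_glucose + E_lipid` and `CEA = Ea − Ec`, computed in
the (possibly unitless) normalised assay units. An optional
per-component conversion vector supports users who have calibrations to
joules; the default (all ones) sums assay units directly. Negative CEA
(consumption exceeding measured reserves) is preserved. Any missing
reserve component makes that animal's Ea and CEA missing.

## Group-comparison decision tree

Normality is assessed per group with Shapiro–Wilk at α = 0.05; the
overall data set "conforms" only if every testable group passes. The
per-group reading (rather than pooled residuals) is the stricter and
simpler interpretation, and the per-group p-values are recorded in the
decision trail so the call is auditable. Groups with n < 3 are flagged
untestable and do not veto the assessment; constant-valued groups fail
with a degenerate-data flag.

Data that fail are square-root transformed and retested, then natural-log
transformed and retested; the first passing transform wins. The sqrt
branch requires non-negative values and the ln branch strictly positive
values; an inapplicable transform is skipped. If nothing passes, the
analysis goes rank-based — on the *raw* values, since ranks are
invariant to both monotone transforms.

With final normality established, Levene's test (classical mean-centred;
Brown–Forsythe median centring available) selects between the classical
one-way ANOVA with Tukey(–Kramer) HSD and Welch's heteroscedastic ANOVA
with Games–Howell. Non-normal data get Kruskal–Wallis (tie-corrected)
with Dunn's pairwise z-tests, Bonferroni-adjusted and capped at 1.
Post-hoc tables are produced regardless of omnibus significance by
default (mirroring common reporting practice); a switch gates them on
the omnibus, and a `never` mode skips them for large simulations where
only the omnibus matters.

Implementation notes: Shapiro–Wilk, Levene, the classical ANOVA,
Kruskal–Wallis and Tukey HSD are delegated to scipy; Welch's ANOVA and
Games–Howell to pingouin. Dunn–Bonferroni is implemented here
(tie-corrected mean-rank z statistic), as no installed dependency
provides it. The test suite checks Tukey, Welch and Kruskal–Wallis
against values computed independently in R (TukeyHSD, oneway.test,
kruskal.test) frozen into the tests, and Games–Howell/Welch against
direct evaluations of the published formulas.

### Effect sizes

For F-family tests, ω² = df₁(F−1)/(df₁(F−1)+N) with N = df₁+df₂+1,
algebraically identical to (SS_between − df₁·MS_within)/(SS_total +
MS_within), which the tests verify to 1e-12. For the Welch branch the
same formula is used with the nominal df₁ and the actual N; this is an
approximation (flagged in the result) because no exact ω² exists for
Welch's F. For rank tests, ε² = H/(n−1). Negative effect sizes arise
when the statistic falls below its null expectation and are reported as
computed — clipping to zero would bias small-effect summaries upward.

## IBRv2

Per biomarker, individual values are log-transformed and standardised
against the grand mean and sample SD (ddof = 1) of the pooled data set;
the deviation index of group g is the difference between its mean Z and
the reference group's mean Z, and the group score is the sum of |A| over
biomarkers. Positive A means stimulation relative to the reference,
negative means inhibition.

Two log modes are provided: the default log-ratio-to-reference-mean
(Yᵢ = ln(Xᵢ/mean X_ref)) and a plain log. Both yield identical deviation
matrices — the reference-mean factor is a per-biomarker constant and
cancels in standardisation, as does the log base — and the suite asserts
this equality, so the ambiguity is provably inconsequential. The sample
(n−1) SD is used and recorded; because A is a difference of group means
of the same standardised variable, the population/sample choice rescales
A by a common factor only when group sizes are equal, so the choice is
surfaced in metadata rather than silently assumed away.

Non-positive values (e.g. a negative CEA) make the log undefined; by
default this is an error naming the offending rows, with an optional
additive offset for users who want to force inclusion. The pipeline
excludes biomarkers with non-positive values from the IBR stage rather
than offsetting, and records how many biomarkers each score includes.
Missing cells are excluded pairwise.

The index is order-independent (unlike the older star-plot-area variant),
which the suite asserts by permutation; radar-plot data fix one
biomarker ordering across groups with the reference as the zero ring.

## Synthetic studies

The generator emulates the study design this pipeline targets: groups
A1–A4 at leachate fractions 0/0.25/0.5/1.0, 20 animals per group, and a
twelve-biomarker battery with positive right-skewed endpoints. The
default family is lognormal, moment-matched to each biomarker's baseline
mean and CV (σ_log² = ln(1+CV²)), with effects shifting the log-mean by
(effect size × leachate fraction × direction) in log-SD units — i.e.
multiplicatively on the median. A normal family (additive effects in
raw-SD units) exercises the classical-ANOVA branch; it rejects
parameterisations that produce non-positive values rather than
truncating, which would distort both moments. Default battery directions
follow the qualitative pattern typical of metal-leachate stress
(cholinesterase and SOD inhibited, oxidative-damage products elevated,
several unaffected endpoints); default effect sizes of 1.5 log-SD for
affected biomarkers give high but not saturated power at n = 20.
Per-group variance multipliers produce heteroscedastic data and a
per-cell dropout probability reproduces unequal sample sizes.

Synthetic plates wrap designed endpoint values in the corresponding raw
geometry — kinetic traces at the assay's real read schedule (e.g. seven
reads a minute apart at 412 nm for the AChE-like assay) or single
endpoint reads — with triplicates, procedural blanks at a configurable
offset, and Gaussian read noise. At zero noise the round trip through
the assay module is exact to floating point.

What the generator does *not* emulate: between-biomarker correlation
within an animal, batch/plate effects, non-monotone dose-response, and
heavy-tailed outliers beyond the lognormal. Passing tests therefore
demonstrate correctness of the computational pipeline and its
calibration under the stated model, not robustness to every pathology of
real assay data.

## Numerical and reporting choices

Slopes use centred normal equations; standardisation is two-pass.
Degenerate inputs are legal where a defined answer exists (all-identical
values: H = 0, p = 1; all-constant Levene: p = 1 with flag) and errors
where none does (zero time span, zero pooled SD, protein ≤ 0). CSV
outputs use `%.10g` floats, making reruns with the same config and seed
byte-identical. Reports display statistics to 3 significant figures,
deviation indices to 3 decimals and IBRv2 scores to 2.

Problem sizes in the test and acceptance runs — 1000 replicates for null
calibration, 200 seeds for power and monotonicity, 100 seeds for
invariance sweeps — were chosen to bound Monte-Carlo error well inside
the asserted tolerances (±2 percentage points on a 5% rate needs ≈1000
draws) while keeping a full run under a minute.

## Known limitations

- The Welch-branch ω² is approximate by construction.
- No multiple-testing correction is applied *across* biomarkers (only
  within post-hoc families); batteries with many endpoints accumulate
  family-wise error at the omnibus level.
- Deviation indices are computed from per-animal Z-scores averaged by
  group; designs whose raw data are only available as group means need
  preprocessing.
- The CLI's `stats`/`ibr`/`report` verbs run the full pipeline and
  differ only in which artefact they highlight; stages are cheap enough
  that partial execution is not worth separate code paths.
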