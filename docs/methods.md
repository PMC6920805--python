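# Methods

## The selection model

The pipeline formalizes a staged screening of rhizosphere isolates for
plant-growth promotion, organized around one principle: every cut-off is
derived from the screened population's own distribution rather than set
a priori.

**Binary coding of the qualitative screen.** A trait observed in
replicate is coded 1 only when every replicate is positive; a single
positive replicate is treated as non-reproducible and codes 0, as does
any mixed outcome. The rule is deliberately conservative and monotone:
turning a replicate positive can never lower the code. An assay that was
not performed contributes 0 — absence of evidence cannot support
selection. Phenotype groups are exact-pattern equivalence classes over
the four-trait binary vector (at most 2⁴ = 16), labelled A, B, C … in
descending lexicographic pattern order so labels are reproducible from
the data alone; any letter scheme is otherwise arbitrary. The PCA on the
standardized (correlation-matrix) binaries is diagnostic only; no
selection decision uses PCA coordinates. Loadings are reported as
trait–score correlations, with each component's sign fixed so its
largest-magnitude loading is positive.

**Replicate QC.** The gate statistic is the sample CV (n−1 denominator),
compared strictly against 10%. Above the gate, Dixon's Q (r10 form,
two-sided critical values tabulated for n = 3…10 at α = 0.05 and 0.01)
tests the most extreme replicate; at n = 3 the critical value is 0.970.
At most one replicate is ever removed. A non-significant high-CV triplet
is kept and flagged rather than dropped: no isolate leaves the study at
this stage. Whether removal should instead be unconditional once
CV > 10% is ambiguous in the underlying protocol; the test-gated reading
is the default and the unconditional one is a switch
(`qc_filter(..., unconditional=True)`).

**Quartile coding.** Population summaries are computed per functional
group × parameter over the *pooled raw replicates* of all isolates;
the value coded for an isolate is the *mean of its QC-kept replicates*.
Quartiles use linear interpolation between order statistics (the common
spreadsheet default; the published worked-example codes are insensitive
to the estimator choice). Boundary policy is closed on the upper side —
value = median codes 2, value = Q3 codes 3 — forced by a published
worked-example isolate whose IAA equals its group Q3 yet is coded 3.
Code 0 covers: assay not performed, no detectable activity, and a
measured 0.

**Selection.** First round, per group × parameter: candidates are the
code-3 isolates; among ≥ 2 candidates a one-way ANOVA + Tukey HSD
(α = 0.05) over their replicates is summarized as a compact letter
display, and candidates sharing the top letter are selected ("highest
level of the parameter"). By default the comparison runs over the
candidate set only; `compare_all=True` widens it to every assayed
isolate of the group. A lone candidate is selected without a test, and
candidates lacking the two replicates an ANOVA needs are all retained.
Second round: isolates not yet selected with ≥ 2 parameters coded ≥ 1
("trait present"); the threshold is code ≥ 1, not ≥ 3, forced by a
published second-round isolate with codes (0, 1, 2). Viability is an
input flag, not a computation; flagged isolates are excluded last with a
logged reason.

**Tukey machinery.** Pairwise p-values come from the studentized-range
distribution with the Tukey–Kramer unequal-n adjustment (replicate
counts differ after QC removal). The compact letter display uses the
insert-and-absorb algorithm: start from one column holding all levels,
split a column on each significant pair, absorb subset columns; letters
are assigned to columns ordered by their best member's mean, ties in
means broken by label, so the top-mean level always carries "a". Zero
within-group variance is handled by defining p = 1 for equal means and
p = 0 otherwise; an all-equal ANOVA returns F = 0, p = 1.

**Growth validation.** Biomass and height are analyzed as independent
responses (separate ANOVA + Tukey at α = 0.01); effects are percent
changes of treatment means vs the control mean, not per-pot ratios.

## Synthetic-data generator

The generator emulates the campaign's statistical structure:

- **Group sizes** default to 133 mesophilic, 96 spore-forming, 65
  pseudomonads, 180 actinobacteria (474 isolates).
- **Qualitative positivity** per group × trait follows the published
  rates. Where only a range is published for a pair of groups the
  defaults fix one representative assignment: P-solubilization 0.41/0.54
  (mesophilic/spore-forming), siderophores 0.49/0.68, and nitrification
  0.20/0.15/0.25/0.13 (mesophilic/spore-forming/pseudomonads/
  actinobacteria) inside the published 13–25% band. Replicates are
  concordant with the latent state except for a configurable flip rate
  (default 0 — the published rates describe isolate-level status).
- **Quantitative traits** are zero-inflated lognormal. The positive part
  is calibrated in closed form from the published (median, Q3) pair:
  log-location = ln(median), log-scale = ln(Q3/median)/z₀.₇₅. The zero
  mass defaults to 0.1 (the published first quartiles are positive, so
  the true zero mass is below 0.25 but unreported). One published
  quartile row (pseudomonad P-mineralization: q1 0, median 0.91, Q3 0)
  is internally inconsistent and excluded from calibration; that cell
  uses the printed median, Q3 = 2 × median, and zero mass 0.3 (its
  printed q1 of 0 implies ≥ 25% assay-negative isolates). Assay-negative
  isolates are recorded as absent assays (no quantifiable value), which
  codes 0 downstream either way.
- **Screen gating** (default on) performs P-mineralization only for
  P-solubilization-positive isolates and quantitative nitrification only
  for screen-nitrification-positive ones, IAA for all — reproducing the
  campaign's planned-to-performed assay reduction. A switch disables it
  for tests that need fully populated assay pools.
- **Replicate noise** is multiplicative lognormal at a target CV
  (default 5%, comfortably inside the 10% gate), keeping values
  positive; with probability `outlier_rate` (default 5%) one replicate
  of a triplet is multiplied by a uniform factor in [2, 5] so the Dixon
  gate is exercised.
- **Elite strains** are planted best-in-class performers: after all
  natural values of a group are drawn, each elite's value for its
  designated parameter is set a fixed margin (default 1.5×) above the
  group's natural maximum. A fixed quantile multiple would not do: the
  heavy-tailed cells (actinobacteria IAA has log-scale ≈ 1.9) routinely
  produce natural draws above any such multiple, and the first-round
  Tukey pruning rightly rejects a candidate significantly below the top
  strain. The margin construction makes "every planted elite is
  first-round selected" a property of the selection rules rather than a
  coin flip.
- **Growth data**: control means 2.0 g biomass and 30 cm height
  (tillering-stage pot scale), pot-level CV 10%, 3 pots per treatment,
  multiplicative treatment effects (defaults 1.5 biomass / 1.25 height
  for designated strains). The underlying study reports no dispersion
  for these measurements; the noise level is a generator choice.
- **Determinism**: a single seed feeds a hierarchical stream keyed by
  (seed, group index, isolate index), so enlarging one group never
  perturbs other draws; same seed ⇒ byte-identical written datasets.

What the generator does *not* emulate: inter-trait correlation within an
isolate (latent positivities and quantitative draws are independent),
soil-community abundance structure, batch effects between biological
batches and technical replicates (all replicates are exchangeable), and
storage-survival kinetics (viability is an input flag). Passing tests
therefore show the pipeline's rules behave correctly under the assumed
distributional shape, not that the shape captures all features of real
screening data. One visible consequence: with independent traits and a
modest zero mass, far more synthetic isolates carry ≥ 2 coded traits
than in the real campaign, so the second round is much less selective
on synthetic data than in the published study.

## Numerical and design notes

- Quartile summaries reject q1 ≤ median ≤ q3 violations at construction;
  the published inconsistent row is representable only behind an
  explicit `allow_invalid` flag, and reproduction runs that use it
  reproduce the printed code-3 cell it implies.
- Dixon's Q is defined as gap/range at whichever end of the sorted
  sample has the larger gap; ties (zero range) give Q = 0.
- The studentized-range survival function can be numerically delicate at
  extreme q; p-values are clamped to [0, 1].
- Problem sizes in tests are chosen to keep the full suite around a few
  minutes: shared synthetic campaigns use 25–60 isolates per group,
  recovery checks use 10,000 isolates in one group, the letter-display
  oracle runs 200 random small datasets, and the null growth simulation
  uses 200–300 replicate simulations. Statistical tolerances are
  3-standard-error (or 99% binomial) bands derived from the generating
  distributions, not tuned constants.

## Known limitations

- The published PCA loadings and variance shares (and the growth-chamber
  panel means) cannot be recomputed because the underlying raw matrices
  are unpublished; the PCA is validated against an eigendecomposition
  oracle instead.
- Dixon tables stop at n = 10; larger replicate sets are rejected rather
  than silently approximated.
- The compact-letter-display algorithm is exact but exponential in the
  worst case; it is intended for the ≤ ~10-level comparisons that occur
  here.
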