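# Methods

This note records the statistical procedures implemented in `immunodyn`,
the defaults they ship with, the design choices made where more than one
convention exists, and what the synthetic-data generators do and do not
emulate.

## Repertoire input and clonotype identity

Clonotype tables enter as AIRR Rearrangement TSV or immunoSEQ-style TSV.
Productivity is taken from the table's own frame/productive column when
present (vendor calls are authoritative); otherwise it is derived from the
amino-acid junction (non-empty, no stop symbol).  Only productive clones
enter any statistic.  Clonotype identity defaults to CDR3 nucleotide
sequence + V call + J call (`key_mode="nt_vj"`); nucleotide-only
deduplication is a config switch, since rearrangement-level reporting
conventions differ between platforms and the choice affects richness and
overlap.  Template counts are integers; fractional counts are rejected
rather than rounded because the exact tests downstream condition on integer
tables.

## Diversity and overlap

Clonality is `1 − Pielou evenness`.  The label "Simpson clonality" is often
attached to √Σf² in the literature; the evenness-based definition is the
one implemented here because it is the operational formula, and the two are
not interchangeable.  Entropy uses natural logs; the base cancels in
H/ln R, so this is presentation only.  A monoclonal sample makes J = 0/0;
it is defined as C = 1 (the limit of concentration) with a warning.
Morisita–Horn overlap is computed on template frequencies over the union of
clonotype keys; frequency weighting (rather than presence/absence) matches
the index's intended sensitivity to dominant clone sizes.

## Expansion calling

Every clonotype present at either visit of a within-patient pair is tested
with a two-sided Fisher exact test; the two-sided p is the sum of
hypergeometric outcome probabilities not exceeding the observed one, with
the conventional `1 + 1e-7` relative tie tolerance (the same rule as R's
`fisher.test` and scipy's implementation, so all three agree to numerical
precision).  The implementation enumerates the table support with
vectorized log-gamma weights, caches repeated count pairs within a visit
pair, and floors the returned p at 1e-300 so that extreme tables do not
underflow to an invalid p = 0.  Sidedness is not dictated by the procedure
being mirrored; two-sided was chosen as standard practice, with the
expansion/contraction direction recovered separately from the frequency
comparison.

BH adjustment is per visit pair with m = number of clones tested in that
pair.  Significance is `q < 0.01` strictly; the newly-detected rule is
`count_baseline = 0` and `count_later > 5` strictly ("above a threshold of
five reads"), applied as a subset of significant expanded clones.  A config
flag (`require_significance=False`) provides the looser absence-plus-count
reading for sensitivity analysis; in that mode the invariant
"newly-detected ⇒ expanded" intentionally does not hold.  No minimum
fold-change is imposed on expansion/contraction calls.

Cohort-level visit contrasts of per-patient statistics use the paired
Wilcoxon signed-rank test, exact null for ≤ 25 nonzero differences and the
continuity-corrected normal approximation above, zero differences dropped;
p-values are BH-adjusted across the set of comparisons.

## Signature scoring

ssGSEA follows the Barbie construction: per sample, genes are ranked by
expression with average ranks for ties; in-set genes are weighted
rank^α with α = 0.25; the enrichment score is the sum over the
descending-rank list of (weighted in-set ECDF − uniform out-of-set ECDF).
Optional normalization divides all scores by the across-sample score range
and is on by default, emulating the common implementation default; both
modes are tested.  Scores are exactly rank-invariant: any strictly
increasing per-sample transform of expression leaves them unchanged.  Gene
matching is case-insensitive exact matching after whitespace stripping —
no alias resolution, keeping results deterministic without external
databases.  At least 50% of a signature must be present (configurable), or
scoring refuses with the missing symbols listed.

The bundled 18-gene tumor inflammation signature ships as an editable YAML
data file; all scoring treats signatures as data, not code.

Gene-wise z-scores use the population (n) standard deviation; zero-variance
genes become all-zero rows with a warning.  Subgroup comparisons use the
two-sided Wilcoxon rank-sum test (exact for groups ≤ 20, tie-corrected
normal approximation above) with **no** multiplicity correction, mirroring
an exploratory subgroup analysis; outputs are labeled accordingly.

Panel-count preprocessing subtracts a per-sample background (mean of
negative-control probes, plus an optional k·SD margin, k = 0 by default)
with a floor at zero, then scales each sample by (geometric mean of
housekeeping sums across retained samples) / (sample housekeeping sum).
Housekeeping sums are therefore equal across retained samples by
construction; samples with zero housekeeping signal are excluded and
flagged rather than divided by zero.

Longitudinal signature trajectories are modeled as
`score ~ visit + (1 | patient)` fitted by maximum likelihood; the overall
visit effect is a likelihood-ratio test against the intercept-only model,
and per-visit contrasts vs baseline carry Wald p-values.  A random
intercept (no random slopes) was chosen as the minimal structure
identifiable at typical translational cohort sizes (tens of patients,
2–3 visits); on non-convergence the model falls back to per-visit paired
signed-rank tests with a warning.

## Endpoints

Primary vs acquired resistance is classified from the week of progression
on prior checkpoint therapy: ≤ 24 weeks → primary, > 24 → acquired.  (An
alternative definition based on best response exists in the literature;
the progression-timing rule is the one implemented, and the boundary at
exactly 24 weeks is primary.)  TMB ≥ 10 mut/Mb is high; PD-L1 ≥ 1% tumor
cells is positive; both boundaries are inclusive on the high side.

Best overall response requires confirmation for CR/PR; an unconfirmed PR
counts as disease control but not response.  SD requires an evaluable
non-PD assessment at or after week 6 (the first scheduled assessment;
configurable) and before any progression.  Disease control at a landmark
requires an evaluable CR/PR/SD assessment at or beyond the landmark
(within the ±1-week window) and no progression or death on or before it.

PFS events are the first progression or death.  The missed-visit rule is
operationalized against the scheduled grid (weeks 6, 12, 18, 24, 32, 40, …
with ±1-week windows): a scheduled visit is missed when no evaluable
assessment falls in its window; an event preceded by ≥ 2 missed visits is
replaced by censoring at the last evaluable assessment before the gap.
Patients without progression or death are censored at their last evaluable
assessment (time 0, with a warning, if none exists).

Kaplan–Meier estimation, Greenwood variance with the log(−log) transform,
and the median CI (the times where the transformed confidence band crosses
S = 0.5, the Brookmeyer–Crowley construction) are delegated to lifelines.
The median is the smallest observed event time with S(t) ≤ 0.5 (step
convention) and is reported as undefined when the curve never reaches 0.5.
The CI level defaults to 80% everywhere, matching the reporting convention
of early-phase trials; 95% is a flag away.

## Synthetic cohorts

The repertoire generator draws latent clone frequencies from a power law
(rank^−a, default a = 1.1 over 1,000 clones, giving a top-clone frequency
near 13% — typical of a moderately oligoclonal peripheral repertoire) or a
log-normal, then draws observed template counts multinomially at depth
10,000 per visit.  The default scale (10³ clones, depth 10⁴) keeps full
error-control simulations (hundreds of replicate pairs) in the tens of
seconds on one CPU while leaving per-clone counts in a realistic range.
Injected expansions modify the *latent* frequencies (renormalizing the
rest) before sampling, so detected counts carry genuine multinomial noise;
ground truth records every perturbed clone key.  A configurable fraction of
out-of-frame clones (default 10%) exercises the productive filter.

The expression generator produces log-normal TPM with unit per-gene SD on
the log2 scale and shifts signature genes by a stated effect (in SD units)
in one group.  The clinical generator draws exponential progression and
death times calibrated to stated medians, places RECIST assessments on the
protocol grid (progression is recorded at the first scheduled assessment
after the latent progression time), assigns confirmed-PR trajectories to
responders, and censors with independent exponential loss to follow-up plus
an administrative horizon.  Ground truth records both the nominal
parameters and the realized per-cohort counts (responders, disease control
at the landmarks), so rate estimators can be checked for exact agreement
and survival estimators for statistical agreement.

What the generators do **not** emulate: V(D)J recombination or sequence
similarity structure between clones, PCR/sequencing depth variability
between samples, batch or site effects in expression, informative (outcome-
dependent) censoring, or measurement-level RECIST arithmetic.  Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated sampling models, not robustness to those
real-data complications.

## Numerical conventions and limitations

- All generators are pure functions of (spec, seed); a single explicit seed
  threads through every random draw, and no global RNG state is touched.
- Iteration orders are fixed (sorted clone keys) so repeated runs are
  byte-identical across processes.
- Fisher p-values: exact agreement with integer enumeration is maintained
  to ~1e-14 for margins ≤ 30; at depths of 10⁴ the log-gamma evaluation is
  accurate to ~1e-11 relative.
- Clonality is *not* monotone under every mass-concentrating move: a
  transfer that annihilates the smallest clone lowers richness and can
  lower C slightly.  Monotonicity holds for richness-preserving transfers
  (entropy is Schur-concave at fixed R); the property tests assert that
  restricted form.
- The mixed model assumes exchangeable patient effects and a common
  residual variance across visits; with very few patients the LRT is
  anti-conservative and the signed-rank fallback is preferable.
- Interval detection on the assessment grid upward-biases recorded
  progression times by up to one inter-visit interval; Kaplan–Meier medians
  recover generator truth exactly only when the true median sits on the
  grid.
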