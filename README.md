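# immunodyn

Reusable, tested analyses for translational immuno-oncology trial data:
longitudinal T-cell-receptor (TCR-β) repertoire dynamics from peripheral
blood, tumor-inflammation signature scoring of expression data, and
RECIST-derived endpoint statistics with protocol censoring rules.  Every
stage can be exercised end to end on synthetic cohorts generated in-package
with ground-truth labels, so the statistical machinery is testable without
any patient-level data.

It is aimed at translational biostatisticians and computational
immunologists who need the repertoire/biomarker/endpoint arithmetic of an
umbrella or platform trial as a library rather than as one-off scripts.

## What it computes

**Repertoire summaries.** For a productive (in-frame, stop-free) clonotype
table with template counts, clone frequencies are
*f<sub>i</sub>* = *n<sub>i</sub>* / *N*.  Shannon entropy
*H* = −Σ *f<sub>i</sub>* ln *f<sub>i</sub>*, Pielou evenness
*J* = *H* / ln *R* for richness *R*, and clonality *C* = 1 − *J* ∈ [0, 1]
(0 = perfectly even, 1 = monoclonal; depth-normalized by construction).
Between-visit overlap is the Morisita–Horn index
*MH* = 2 Σ *p<sub>i</sub>q<sub>i</sub>* / (Σ *p<sub>i</sub>²* + Σ *q<sub>i</sub>²*),
abundance-weighted and dominated by the largest clones.

**Clone expansion calling.** For each clonotype in the union of a
within-patient visit pair, a two-sided Fisher exact test on
[[*n<sub>a</sub>*, *N<sub>a</sub>* − *n<sub>a</sub>*],
[*n<sub>b</sub>*, *N<sub>b</sub>* − *n<sub>b</sub>*]] tests the null of equal
population abundance; p-values are Benjamini–Hochberg adjusted per pair and
clones with *q* < 0.01 are called expanded/contracted by the direction of the
frequency change.  Significant expanded clones absent at the earlier visit
and detected above 5 templates are labeled *newly detected expanded*.
Cohort-level visit contrasts use exact paired Wilcoxon signed-rank tests with
BH correction across the comparison set.

**Signature scoring.** Single-sample GSEA (Barbie-style weighted-ECDF
running sum, rank weight exponent α = 0.25, optional across-sample range
normalization) scores gene signatures such as the bundled 18-gene tumor
inflammation signature per sample; subgroup contrasts (primary vs acquired
resistance, PD-L1 ±, histology, bone/liver metastases, TMB < 10 vs ≥ 10
mut/Mb, *STK11* status) use two-sided Wilcoxon rank-sum tests, deliberately
uncorrected and labeled exploratory.  NanoString-style panel counts are
background-subtracted and housekeeping-normalized; longitudinal signature
changes are tested with a patient-random-intercept linear mixed model.

**Endpoints.** Best overall response requires confirmation for CR/PR; ORR
and 12/24-week disease-control rates are exact count ratios.  PFS follows
the protocol rule: event at first progression or death, unless it follows
two or more missed scheduled assessments (6-weekly ± 1 to week 24, then
8-weekly ± 1), in which case the patient is censored back at the last
evaluable assessment.  Kaplan–Meier curves carry Greenwood log(−log)
intervals and Brookmeyer–Crowley median CIs, reported at the 80% level by
default.

## Worked example

```python
from immunodyn.synthetic_data import (RepertoireSimSpec, ExpansionEvent,
                                      simulate_longitudinal_repertoires)
from immunodyn.repertoire_io import filter_productive
from immunodyn.clone_dynamics import classify_dynamics

spec = RepertoireSimSpec(
    seed=1, n_clones=1000, depth=10_000, visits=("C0D1", "C1D1"),
    expansion_events=(
        ExpansionEvent(clone=88, visit="C1D1", fold_change=50.0),
        ExpansionEvent(clone="novel", visit="C1D1", target_frequency=0.005),
    ),
)
cohort, truth = simulate_longitudinal_repertoires(spec, 1)
rec = cohort["P001"]
a = filter_productive(rec.samples["C0D1"])
b = filter_productive(rec.samples["C1D1"])
records, summary = classify_dynamics(a, b, alpha=0.01, read_threshold=5)
print(f"clonality C0D1={summary.clonality_a:.3f}  C1D1={summary.clonality_b:.3f}")
print(f"tested={summary.n_tested}  expanded={summary.n_expanded}  "
      f"newly_detected={summary.n_newly_detected_expanded}")
print(f"Morisita-Horn overlap = {summary.morisita_horn:.3f}")
```

prints

```
clonality C0D1=0.305  C1D1=0.312
tested=955  expanded=2  newly_detected=1
Morisita-Horn overlap = 0.946
```

Both injected events are recovered: the 50-fold expansion of a pre-existing
clone (21 → 686 templates, *q* ≈ 10⁻¹⁷⁵) and the novel clone (0 → 46
templates, *q* ≈ 10⁻¹¹), which satisfies the newly-detected rule.  The 953
unperturbed clones yield no calls at *q* < 0.01, and the overlap of 0.95
reflects a repertoire whose dominant clones are otherwise stable.

The same stages run from the shell:

```bash
immunodyn simulate --seed 42 --out demo/
immunodyn run-all --config demo/config.yaml
cat demo/results/summary.json
```

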