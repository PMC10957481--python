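"""Seeded synthetic cohorts with ground-truth labels for every pipeline stage.

Three generators emulate the study's three input classes:

* longitudinal TCR-β repertoires — latent clone frequencies drawn from a
  skewed abundance model (power law or log-normal), observed template counts
  drawn multinomially at a fixed sequencing depth per visit, with optional
  injected expansions (of existing or novel clones) applied to the latent
  frequencies before sampling so that sampling noise stays realistic;
* expression cohorts — log-normal TPM background with signature genes
  shifted on the log scale in one group;
* clinical cohorts — exponential progression/death times calibrated to
  stated medians, RECIST assessment sequences placed on the protocol's
  visit schedule, confirmed-PR responders assigned per arm, and independent
  exponential loss to follow-up.

Every generator is a pure function of its spec and seed; ground truth
records what was injected so recovery tests need no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clinical_outcomes import CR, PD, PR, SD, Assessment, AssessmentSchedule, \
    DEFAULT_SCHEDULE, PatientRecord
from .errors import SimSpecError
from .expression_scoring import ExpressionMatrix, GeneSignature, TPM
from .repertoire_io import (
    Clonotype,
    DEFAULT_VISITS,
    IN_FRAME,
    LongitudinalRepertoire,
    OUT_OF_FRAME,
    RepertoireSample,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one representative codon per amino acid
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class ExpansionEvent:
    """Inject an expansion: a clone reaches a target latent frequency at a visit.

    ``clone`` is a latent clone index or ``"novel"`` for a clone absent from
    the baseline repertoire.  Exactly one of ``fold_change`` (> 1, relative
    to the clone's latent baseline frequency) or ``target_frequency`` must be
    given; novel clones require ``target_frequency``.
    """

    clone: int | str
    visit: str
    fold_change: float | None = None
    target_frequency: float | None = None

    def __post_init__(self) -> None:
        if (self.fold_change is None) == (self.target_frequency is None):
            raise SimSpecError("give exactly one of fold_change / target_frequency")
        if self.fold_change is not None and self.fold_change <= 1:
            raise SimSpecError("fold_change must exceed 1 for an expansion")
        if self.target_frequency is not None and not 0 < self.target_frequency < 1:
            raise SimSpecError("target_frequency must lie in (0, 1)")
        if self.clone == "novel" and self.target_frequency is None:
            raise SimSpecError("novel clones need a target_frequency")


@dataclass(frozen=True)
class RepertoireSimSpec:
    seed: int
    n_clones: int = 1000
    abundance_model: str = "power_law"  # or "log_normal"
    model_param: float = 1.1  # power-law exponent, or log-normal sigma
    depth: int = 10_000
    visits: tuple[str, ...] = DEFAULT_VISITS
    expansion_events: tuple[ExpansionEvent, ...] = ()
    nonproductive_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.n_clones <= 0:
            raise SimSpecError("depth and n_clones must be positive")
        for ev in self.expansion_events:
            if ev.visit not in self.visits:
                raise SimSpecError(f"expansion visit {ev.visit!r} not in schedule")
            if isinstance(ev.clone, int) and not 0 <= ev.clone < self.n_clones:
                raise SimSpecError(f"clone index {ev.clone} out of range")


@dataclass
class GroundTruth:
    """Labels recorded by the generators for recovery testing."""

    # patient -> visit -> set of rearrangement keys whose latent frequency
    # was raised at that visit relative to baseline
    expanded_clones: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    # gene -> true log2 shift in group 2
    gene_effects: dict[str, float] = field(default_factory=dict)
    # arm -> nominal responder probability / realized responder count
    responder_prob: dict[str, float] = field(default_factory=dict)
    realized_responders: dict[str, int] = field(default_factory=dict)
    realized_disease_control: dict[str, dict[int, int]] = field(default_factory=dict)
    true_median_pfs: dict[str, float] = field(default_factory=dict)
    true_median_os: dict[str, float] = field(default_factory=dict)


def _clone_identity(patient_idx: int, clone_idx: int, rng: np.random.Generator):
    """Deterministically unique CDR3 aa/nt plus V/J calls for one clone."""
    # encode (patient, clone) in the sequence so identities never collide
    body = []
    n = patient_idx * 1_000_003 + clone_idx
    for _ in range(8):
        body.append(_AA[n % 20])
        n //= 20
    extra = "".join(rng.choice(list(_AA), size=3))
    aa = "CASS" + "".join(body) + extra + "F"
    nt = "".join(_CODON[ch] for ch in aa)
    v = f"TRBV{int(rng.integers(1, 31))}"
    j = f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 8))}"
    return aa, nt, v, j


def _latent_frequencies(spec: RepertoireSimSpec, rng: np.random.Generator):
    if spec.abundance_model == "power_law":
        w = (np.arange(1, spec.n_clones + 1)) ** (-spec.model_param)
    elif spec.abundance_model == "log_normal":
        w = np.exp(rng.normal(0.0, spec.model_param, size=spec.n_clones))
    else:
        raise SimSpecError(f"unknown abundance model {spec.abundance_model!r}")
    return w / w.sum()


def _apply_expansions(
    base: np.ndarray,
    events: Sequence[ExpansionEvent],
    novel_index: dict[ExpansionEvent, int],
    total_size: int,
) -> tuple[np.ndarray, list[int]]:
    """Return modified latent frequencies over ``total_size`` clone slots."""
    freqs = np.zeros(total_size)
    freqs[: base.size] = base
    targets: dict[int, float] = {}
    touched: list[int] = []
    for ev in events:
        if ev.clone == "novel":
            idx = novel_index[ev]
            targets[idx] = ev.target_frequency
        else:
            idx = int(ev.clone)
            targets[idx] = (
                ev.target_frequency
                if ev.target_frequency is not None
                else min(1.0, ev.fold_change * base[idx])
            )
        touched.append(idx)
    total_target = sum(targets.values())
    if total_target >= 1.0:
        raise SimSpecError("expansion targets sum to ≥ 1")
    untouched = np.ones(freqs.size, dtype=bool)
    for idx in targets:
        untouched[idx] = False
    freqs[untouched] *= (1.0 - total_target) / freqs[untouched].sum()
    for idx, f in targets.items():
        freqs[idx] = f
    return freqs, touched


def simulate_longitudinal_repertoires(
    spec: RepertoireSimSpec, n_patients: int
) -> tuple[dict[str, LongitudinalRepertoire], GroundTruth]:
    """Generate per-patient longitudinal repertoires with injected expansions."""
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    cohort: dict[str, LongitudinalRepertoire] = {}
    novel_index: dict[ExpansionEvent, int] = {}
    next_idx = spec.n_clones
    for ev in spec.expansion_events:
        if ev.clone == "novel":
            novel_index[ev] = next_idx
            next_idx += 1
    n_novel_total = len(novel_index)
    total_size = spec.n_clones + n_novel_total

    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        base = _latent_frequencies(spec, rng)
        identities = [_clone_identity(p, i, rng) for i in range(total_size)]
        keys = [f"{nt}|{v}|{j}" for (_aa, nt, v, j) in identities]

        n_nonprod = int(round(spec.nonproductive_fraction * spec.n_clones))
        nonprod = []
        for i in range(n_nonprod):
            aa, nt, v, j = _clone_identity(p, total_size + i, rng)
            nonprod.append(
                Clonotype(
                    cdr3_nt=nt + "A",  # frame-shifted
                    cdr3_aa="",
                    v_call=v,
                    j_call=j,
                    template_count=int(rng.geometric(0.5)),
                    frame_status=OUT_OF_FRAME,
                )
            )

        rec = LongitudinalRepertoire(patient_id=pid)
        truth.expanded_clones[pid] = {}
        for visit in spec.visits:
            events = [ev for ev in spec.expansion_events if ev.visit == visit]
            if events:
                freqs, touched = _apply_expansions(base, events, novel_index,
                                                   total_size)
                truth.expanded_clones[pid][visit] = {keys[i] for i in touched}
            else:
                freqs = np.pad(base, (0, total_size - base.size))
                truth.expanded_clones[pid][visit] = set()
            counts = rng.multinomial(spec.depth, pvals=freqs)
            sample = RepertoireSample(patient_id=pid, visit=visit)
            for i in np.nonzero(counts)[0]:
                aa, nt, v, j = identities[i]
                sample.add(
                    Clonotype(
                        cdr3_nt=nt, cdr3_aa=aa, v_call=v, j_call=j,
                        template_count=int(counts[i]), frame_status=IN_FRAME,
                    )
                )
            for clone in nonprod:
                sample.add(clone)
            rec.samples[visit] = sample
        cohort[pid] = rec
    return cohort, truth


def simulate_expression_cohort(
    n_per_group: int,
    signature: GeneSignature,
    effect_size: float,
    n_background_genes: int = 200,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Two-group TPM cohort with signature genes shifted in group ``B``.

    ``effect_size`` is the shift in SD units on the log2 scale (per-gene SD
    is 1), applied to every signature gene in group B.
    """
    if effect_size < 0:
        raise SimSpecError("effect_size must be ≥ 0")
    rng = np.random.default_rng(seed)
    genes = list(signature.gene_symbols) + [
        f"BG{i + 1:04d}" for i in range(n_background_genes)
    ]
    n_samples = 2 * n_per_group
    mu = rng.uniform(3.0, 8.0, size=len(genes))
    log_expr = rng.normal(mu[:, None], 1.0, size=(len(genes), n_samples))
    labels = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group,
        index=[f"S{i + 1:03d}" for i in range(n_samples)],
    )
    in_sig = np.array([g in set(signature.gene_symbols) for g in genes])
    log_expr[np.ix_(in_sig, labels.to_numpy() == "B")] += effect_size
    tpm = pd.DataFrame(2.0 ** log_expr, index=genes, columns=labels.index)
    truth = GroundTruth(
        gene_effects={g: (effect_size if g in set(signature.gene_symbols) else 0.0)
                      for g in genes}
    )
    return ExpressionMatrix(values=tpm, value_kind=TPM), labels, truth


@dataclass(frozen=True)
class ClinicalArmSpec:
    name: str
    n: int
    responder_prob: float
    median_pfs_weeks: float
    median_os_weeks: float

    def __post_init__(self) -> None:
        if not 0 <= self.responder_prob <= 1:
            raise SimSpecError("responder_prob must be in [0, 1]")
        if self.median_pfs_weeks <= 0 or self.median_os_weeks <= 0:
            raise SimSpecError("medians must be positive")


def simulate_clinical_cohort(
    arms: Sequence[ClinicalArmSpec],
    schedule: AssessmentSchedule = DEFAULT_SCHEDULE,
    censoring_median_weeks: float = 150.0,
    follow_up_weeks: float = 104.0,
    seed: int = 0,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Clinical cohorts with exponential event times on the assessment grid.

    Progression is recorded at the first scheduled assessment after the
    latent progression time; responders show PR from week 6 with
    confirmation at the next visit.  Loss to follow-up is independent
    exponential; everyone is administratively censored at ``follow_up_weeks``.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    records: list[PatientRecord] = []
    for arm in arms:
        truth.responder_prob[arm.name] = arm.responder_prob
        truth.true_median_pfs[arm.name] = arm.median_pfs_weeks
        truth.true_median_os[arm.name] = arm.median_os_weeks
        truth.realized_responders[arm.name] = 0
        truth.realized_disease_control[arm.name] = {12: 0, 24: 0}
        lam_pfs = math.log(2.0) / arm.median_pfs_weeks
        lam_os = math.log(2.0) / arm.median_os_weeks
        lam_cens = math.log(2.0) / censoring_median_weeks

        for i in range(arm.n):
            pid = f"{arm.name}-{i + 1:04d}"
            t_prog = rng.exponential(1.0 / lam_pfs)
            t_death = rng.exponential(1.0 / lam_os)
            t_cens = min(rng.exponential(1.0 / lam_cens), follow_up_weeks)
            is_responder = rng.random() < arm.responder_prob

            assessments: list[Assessment] = []
            confirmed_pr = False
            pr_streak = 0
            for w in schedule.visit_weeks(follow_up_weeks):
                if w > min(t_death, t_cens):
                    break
                if t_prog <= w:
                    assessments.append(Assessment(study_week=w, category=PD))
                    break
                cat = PR if is_responder else SD
                if cat == PR:
                    pr_streak += 1
                confirmed = cat == PR and pr_streak >= 2
                confirmed_pr = confirmed_pr or confirmed
                if confirmed:
                    # retroactively mark the streak as confirmed
                    assessments = [
                        Assessment(a.study_week, a.category, True)
                        if a.category == PR else a
                        for a in assessments
                    ]
                assessments.append(
                    Assessment(study_week=w, category=cat, confirmed=confirmed)
                )

            last_week = assessments[-1].study_week if assessments else 0.0
            death_week = (
                float(t_death)
                if t_death <= t_cens and t_death >= last_week
                else None
            )
            last_alive = float(min(t_cens, t_death if death_week else t_cens))
            rec = PatientRecord(
                patient_id=pid,
                module=arm.name,
                cohort="",
                prior_icb_progression_week=float(rng.uniform(4, 52)),
                assessments=assessments,
                death_week=death_week,
                last_alive_week=max(last_alive, last_week),
                pd_l1_tc_percent=float(np.round(rng.uniform(0, 80), 1)),
                tmb_mut_per_mb=float(np.round(rng.gamma(2.0, 4.0), 1)),
                histology=("adenocarcinoma" if rng.random() < 0.7
                           else "squamous"),
                metastasis_sites=tuple(
                    s for s in ("bone", "liver")
                    if rng.random() < 0.25
                ),
            )
            records.append(rec)
            if confirmed_pr:
                truth.realized_responders[arm.name] += 1
            for lm in (12, 24):
                controlled = (
                    t_prog > lm
                    and (death_week is None or death_week > lm)
                    and any(
                        a.category in (CR, PR, SD)
                        and a.study_week >= lm - schedule.window
                        for a in assessments
                    )
                )
                if controlled:
                    truth.realized_disease_control[arm.name][lm] += 1
    return records, truth
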