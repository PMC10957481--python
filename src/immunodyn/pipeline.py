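"""End-to-end orchestration: io → stats → dynamics → scoring → outcomes.

A :class:`RunConfig` names the inputs present (any subset of the three input
classes) and the thresholds to apply; :func:`run_pipeline` executes the
stages for whichever inputs exist and writes versioned TSV tables, a JSON
summary and a parameter log into the output directory.  Outputs carry no
timestamps, so re-running an identical config on identical inputs yields
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clinical_outcomes import (
    Assessment,
    DEFAULT_SCHEDULE,
    PatientRecord,
    classify_resistance,
    cohort_km,
    compute_dcr,
    compute_orr,
)
from .clone_dynamics import (
    DEFAULT_ALPHA,
    DEFAULT_READ_THRESHOLD,
    classify_dynamics,
    cohort_visit_comparison,
)
from .errors import ValidationError
from .expression_scoring import (
    compare_groups,
    load_signatures,
    read_expression_table,
    ssgsea_scores,
)
from .repertoire_io import (
    DEFAULT_VISITS,
    assemble_longitudinal,
    filter_productive,
    read_clonotype_table,
)
from .repertoire_stats import clonality


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    visits: tuple[str, ...] = DEFAULT_VISITS
    alpha: float = DEFAULT_ALPHA
    read_threshold: int = DEFAULT_READ_THRESHOLD
    ci_level: float = 0.80
    dialect: str = "airr"
    repertoire_manifest: Path | None = None
    expression_table: Path | None = None
    groups_table: Path | None = None
    signature_file: Path | None = None
    signature_name: str = "TIS"
    clinical_patients: Path | None = None
    clinical_assessments: Path | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("repertoire_manifest", "expression_table", "groups_table",
                     "signature_file", "clinical_patients",
                     "clinical_assessments"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.read_threshold < 0:
            raise ValidationError("read threshold must be non-negative")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must lie in (0, 1)")
        for name in ("repertoire_manifest", "expression_table", "groups_table",
                     "signature_file", "clinical_patients",
                     "clinical_assessments"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise ValidationError(f"{name} does not exist: {val}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        for key in ("out_dir", "repertoire_manifest", "expression_table",
                    "groups_table", "signature_file", "clinical_patients",
                    "clinical_assessments"):
            if raw.get(key):
                raw[key] = str((base / raw[key]).resolve()) if not Path(
                    raw[key]).is_absolute() else raw[key]
        if "visits" in raw:
            raw["visits"] = tuple(raw["visits"])
        return cls(**raw)


def read_clinical_tables(
    patients_csv: str | Path, assessments_csv: str | Path
) -> list[PatientRecord]:
    """Read per-patient clinical records from the two flat CSV tables."""
    pats = pd.read_csv(patients_csv)
    assess = pd.read_csv(assessments_csv)
    by_patient = {
        pid: [
            Assessment(
                study_week=float(r.study_week),
                category=str(r.category),
                confirmed=bool(r.confirmed),
            )
            for r in grp.sort_values("study_week").itertuples()
        ]
        for pid, grp in assess.groupby("patient_id")
    }
    records = []
    for r in pats.itertuples():
        mets = () if pd.isna(r.metastasis_sites) or not r.metastasis_sites else \
            tuple(str(r.metastasis_sites).split(";"))
        records.append(
            PatientRecord(
                patient_id=str(r.patient_id),
                module=str(r.module),
                cohort="" if pd.isna(r.cohort) else str(r.cohort),
                prior_icb_progression_week=None
                if pd.isna(r.prior_icb_progression_week)
                else float(r.prior_icb_progression_week),
                assessments=by_patient.get(str(r.patient_id), []),
                death_week=None if pd.isna(r.death_week) else float(r.death_week),
                last_alive_week=float(r.last_alive_week),
                pd_l1_tc_percent=None if pd.isna(r.pd_l1_tc_percent)
                else float(r.pd_l1_tc_percent),
                tmb_mut_per_mb=None if pd.isna(r.tmb_mut_per_mb)
                else float(r.tmb_mut_per_mb),
                histology=str(r.histology),
                metastasis_sites=mets,
            )
        )
    return records


def write_clinical_tables(
    records, patients_csv: str | Path, assessments_csv: str | Path
) -> None:
    prows, arows = [], []
    for r in records:
        prows.append(
            {
                "patient_id": r.patient_id,
                "module": r.module,
                "cohort": r.cohort,
                "prior_icb_progression_week": r.prior_icb_progression_week,
                "death_week": r.death_week,
                "last_alive_week": r.last_alive_week,
                "pd_l1_tc_percent": r.pd_l1_tc_percent,
                "tmb_mut_per_mb": r.tmb_mut_per_mb,
                "histology": r.histology,
                "metastasis_sites": ";".join(r.metastasis_sites),
            }
        )
        for a in r.assessments:
            arows.append(
                {
                    "patient_id": r.patient_id,
                    "study_week": a.study_week,
                    "category": a.category,
                    "confirmed": a.confirmed,
                }
            )
    pd.DataFrame(prows).to_csv(patients_csv, index=False)
    pd.DataFrame(arows).to_csv(assessments_csv, index=False)


def _load_repertoires(config: RunConfig):
    manifest = pd.read_csv(config.repertoire_manifest, sep="\t")
    base = config.repertoire_manifest.parent
    samples = []
    for r in manifest.itertuples():
        path = Path(r.path)
        if not path.is_absolute():
            path = base / path
        raw = read_clonotype_table(
            path,
            dialect=getattr(r, "dialect", config.dialect),
            patient_id=str(r.patient_id),
            visit=str(r.visit),
        )
        samples.append(filter_productive(raw))
    return assemble_longitudinal(samples, schedule=config.visits)


def _stage_repertoire(config: RunConfig, out: Path, summary: dict) -> None:
    cohort = _load_repertoires(config)
    div_rows, pair_rows = [], []
    clonality_by_patient: dict[str, dict[str, float]] = {}
    expanded_by_patient: dict[str, dict[str, float]] = {}
    for pid, rec in sorted(cohort.items()):
        for visit, sample in rec.samples.items():
            d = clonality(sample)
            clonality_by_patient.setdefault(pid, {})[visit] = d.clonality
            div_rows.append(
                {
                    "patient_id": pid,
                    "visit": visit,
                    "richness": d.richness,
                    "shannon_entropy": d.shannon_entropy,
                    "pielou_evenness": d.pielou_evenness,
                    "clonality": d.clonality,
                }
            )
        for va, vb in rec.visit_pairs():
            _, summ = classify_dynamics(
                rec.samples[va],
                rec.samples[vb],
                alpha=config.alpha,
                read_threshold=config.read_threshold,
            )
            expanded_by_patient.setdefault(pid, {})[f"{va}->{vb}"] = summ.n_expanded
            pair_rows.append(
                {
                    "patient_id": pid,
                    "visit_a": va,
                    "visit_b": vb,
                    "n_tested": summ.n_tested,
                    "n_expanded": summ.n_expanded,
                    "n_contracted": summ.n_contracted,
                    "n_newly_detected_expanded": summ.n_newly_detected_expanded,
                    "clonality_a": summ.clonality_a,
                    "clonality_b": summ.clonality_b,
                    "morisita_horn": summ.morisita_horn,
                }
            )
    pd.DataFrame(div_rows).to_csv(out / "repertoire_diversity.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(pair_rows).to_csv(out / "repertoire_dynamics.tsv", sep="\t",
                                   index=False)
    comparisons = [
        (config.visits[i], config.visits[i + 1])
        for i in range(len(config.visits) - 1)
    ]
    clon_df = pd.DataFrame(clonality_by_patient).T
    comp = cohort_visit_comparison(clon_df, comparisons)
    comp.drop(columns=["deltas"]).to_csv(
        out / "cohort_clonality_comparisons.tsv", sep="\t", index=False
    )
    summary["repertoire"] = {
        "n_patients": len(cohort),
        "n_unpaired": sum(rec.unpaired for rec in cohort.values()),
        "clonality_comparisons": comp.drop(columns=["deltas"]).to_dict("records"),
        "total_expanded_clones": int(
            sum(sum(v.values()) for v in expanded_by_patient.values())
        ),
    }


def _stage_expression(config: RunConfig, out: Path, summary: dict) -> None:
    matrix = read_expression_table(config.expression_table)
    signatures = load_signatures(config.signature_file)
    sig = signatures[config.signature_name]
    scores = ssgsea_scores(matrix, sig)
    scores.scores.rename("es").to_frame().rename_axis("sample_id").to_csv(
        out / "signature_scores.tsv", sep="\t"
    )
    section = {
        "signature": sig.name,
        "fraction_genes_found": scores.fraction_genes_found,
        "n_samples": int(scores.scores.size),
    }
    if config.groups_table is not None:
        groups = pd.read_csv(config.groups_table, sep="\t", index_col=0)
        rows = []
        for col in groups.columns:
            labels = groups[col].dropna()
            try:
                cmp = compare_groups(scores, labels)
            except ValidationError:
                continue
            rows.append(
                {
                    "grouping": col,
                    "p_value": cmp.p_value,
                    "median_group_a": cmp.median_group_a,
                    "median_group_b": cmp.median_group_b,
                    "n_a": cmp.n_a,
                    "n_b": cmp.n_b,
                }
            )
        comp_df = pd.DataFrame(rows)
        comp_df.to_csv(out / "subgroup_comparisons.tsv", sep="\t", index=False)
        section["subgroup_comparisons"] = rows
        section["multiplicity_correction"] = "none (exploratory)"
    summary["expression"] = section


def _stage_clinical(config: RunConfig, out: Path, summary: dict) -> None:
    records = read_clinical_tables(config.clinical_patients,
                                   config.clinical_assessments)
    modules = sorted({r.module for r in records})
    rows = []
    section: dict = {"modules": {}}
    for module in modules + ["pooled"]:
        subset = [r for r in records if module == "pooled" or r.module == module]
        orr = compute_orr(subset)
        dcr12 = compute_dcr(subset, 12)
        dcr24 = compute_dcr(subset, 24)
        km_pfs = cohort_km(subset, "pfs", ci_level=config.ci_level)
        km_os = cohort_km(subset, "os", ci_level=config.ci_level)
        rows.append(
            {
                "module": module,
                "n": len(subset),
                "orr_numerator": orr.numerator,
                "orr_percent": orr.percent,
                "dcr12_percent": dcr12.percent,
                "dcr24_percent": dcr24.percent,
                "median_pfs_weeks": km_pfs.median,
                "median_pfs_ci_low": km_pfs.median_ci[0],
                "median_pfs_ci_high": km_pfs.median_ci[1],
                "median_os_weeks": km_os.median,
                "median_os_ci_low": km_os.median_ci[0],
                "median_os_ci_high": km_os.median_ci[1],
            }
        )
        section["modules"][module] = rows[-1]
    resistant = [
        r for r in records if r.prior_icb_progression_week is not None
    ]
    section["resistance_classes"] = {
        cls: sum(
            classify_resistance(r.prior_icb_progression_week) == cls
            for r in resistant
        )
        for cls in ("primary", "acquired")
    }
    pd.DataFrame(rows).to_csv(out / "outcomes.tsv", sep="\t", index=False)
    summary["clinical"] = section


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages for which inputs are configured; return the summary."""
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed}

    if config.repertoire_manifest is not None:
        _stage_repertoire(config, out, summary)
    if config.expression_table is not None:
        _stage_expression(config, out, summary)
    if config.clinical_patients is not None:
        if config.clinical_assessments is None:
            raise ValidationError("clinical_assessments required with patients")
        _stage_clinical(config, out, summary)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    log_lines = [
        f"immunodyn {__version__}",
        f"seed = {config.seed}",
        f"alpha (BH-adjusted significance) = {config.alpha}",
        f"newly-detected read threshold = {config.read_threshold}",
        f"CI level = {config.ci_level}",
        f"visit schedule = {', '.join(config.visits)}",
        f"assessment schedule = every {DEFAULT_SCHEDULE.first_interval:g} wk "
        f"(±{DEFAULT_SCHEDULE.window:g}) to wk {DEFAULT_SCHEDULE.switch_week:g}, "
        f"then every {DEFAULT_SCHEDULE.later_interval:g} wk",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return summary


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
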