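"""Reading, validation and assembly of TCR-β clonotype tables.

Two on-disk dialects are supported:

* AIRR Rearrangement TSV (``sequence_id``, ``junction``, ``junction_aa``,
  ``v_call``, ``j_call``, ``productive``, ``duplicate_count``);
* immunoSEQ-style TSV (``rearrangement``, ``amino_acid``, ``v_gene``,
  ``j_gene``, ``templates``, ``frame_type``).

A clonotype is identified by its CDR3 nucleotide sequence plus V/J calls by
default (``key_mode="nt_vj"``); nucleotide-only deduplication is available via
``key_mode="nt"``.  Counts are integer template counts; fractional counts are
rejected rather than rounded, because downstream exact tests require integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConflictError, EmptySampleError, FormatError, ValidationError

IN_FRAME = "in-frame"
OUT_OF_FRAME = "out-of-frame"
HAS_STOP = "has-stop"
FRAME_STATUSES = frozenset({IN_FRAME, OUT_OF_FRAME, HAS_STOP})

#: Default longitudinal blood-draw schedule: baseline (cycle 0 day 1), after
#: the 7-day monotherapy lead-in (cycle 1 day 1), and on combination therapy
#: (cycle 1 day 22).
DEFAULT_VISITS: tuple[str, ...] = ("C0D1", "C1D1", "C1D22")

_AIRR_COLUMNS = {
    "sequence_id": "sequence_id",
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "v_call": "v_call",
    "j_call": "j_call",
    "productive": "productive",
    "duplicate_count": "count",
}
_IMMUNOSEQ_COLUMNS = {
    "rearrangement": "cdr3_nt",
    "amino_acid": "cdr3_aa",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "templates": "count",
    "frame_type": "frame_type",
}
_FRAME_TYPE_MAP = {"in": IN_FRAME, "out": OUT_OF_FRAME, "stop": HAS_STOP}


@dataclass(frozen=True)
class Clonotype:
    """A single TCR-β rearrangement with its sequenced template count."""

    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    template_count: int
    frame_status: str = IN_FRAME

    def __post_init__(self) -> None:
        if self.template_count < 0:
            raise ValidationError(
                f"negative template_count {self.template_count} for {self.cdr3_nt}"
            )
        if self.frame_status not in FRAME_STATUSES:
            raise ValidationError(f"unknown frame_status {self.frame_status!r}")

    @property
    def is_productive(self) -> bool:
        return (
            self.frame_status == IN_FRAME
            and bool(self.cdr3_aa)
            and "*" not in self.cdr3_aa
        )

    def key(self, key_mode: str = "nt_vj") -> str:
        if key_mode == "nt":
            return self.cdr3_nt
        if key_mode == "nt_vj":
            return f"{self.cdr3_nt}|{self.v_call}|{self.j_call}"
        raise ValidationError(f"unknown key_mode {key_mode!r}")


@dataclass
class RepertoireSample:
    """A patient-visit bag of clonotypes keyed by rearrangement identity."""

    patient_id: str
    visit: str
    clonotypes: dict[str, Clonotype] = field(default_factory=dict)
    key_mode: str = "nt_vj"

    @property
    def total_templates(self) -> int:
        return sum(c.template_count for c in self.clonotypes.values())

    @property
    def is_empty(self) -> bool:
        return self.total_templates == 0

    def require_nonempty(self) -> None:
        if self.is_empty:
            raise EmptySampleError(
                f"sample {self.patient_id}/{self.visit} has no templates"
            )

    def add(self, clone: Clonotype) -> None:
        """Add a clonotype, merging counts on identical rearrangement keys."""
        k = clone.key(self.key_mode)
        prev = self.clonotypes.get(k)
        if prev is None:
            self.clonotypes[k] = clone
        else:
            self.clonotypes[k] = replace(
                prev, template_count=prev.template_count + clone.template_count
            )

    def counts(self) -> dict[str, int]:
        return {k: c.template_count for k, c in self.clonotypes.items()}


@dataclass
class LongitudinalRepertoire:
    """Ordered per-visit samples for one patient."""

    patient_id: str
    samples: dict[str, RepertoireSample] = field(default_factory=dict)

    @property
    def unpaired(self) -> bool:
        """True when fewer than two visits are available for pairing."""
        return len(self.samples) < 2

    def visit_pairs(self) -> list[tuple[str, str]]:
        visits = list(self.samples)
        return [(visits[i], visits[i + 1]) for i in range(len(visits) - 1)]


def _frame_status_airr(productive, junction_aa: str) -> str:
    truthy = {"t", "true", "1", "yes", "y"}
    is_prod = str(productive).strip().lower() in truthy or productive is True
    if is_prod:
        return IN_FRAME
    if junction_aa and "*" in junction_aa:
        return HAS_STOP
    return OUT_OF_FRAME


def _validate_count(raw, row: int) -> int:
    try:
        val = float(raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {row}: non-numeric template count {raw!r}") from exc
    if val < 0:
        raise ValidationError(f"row {row}: negative template count {raw!r}")
    if val != int(val):
        raise ValidationError(
            f"row {row}: fractional template count {raw!r} rejected (integers required)"
        )
    return int(val)


def read_clonotype_table(
    path: str | Path,
    dialect: str = "airr",
    *,
    patient_id: str = "",
    visit: str = "",
    key_mode: str = "nt_vj",
    column_map: Mapping[str, str] | None = None,
) -> RepertoireSample:
    """Parse one clonotype TSV into a :class:`RepertoireSample`.

    Rows sharing a rearrangement key are merged by summing template counts.
    ``column_map`` overrides the dialect's expected column names
    (``{expected_name: actual_name}``).
    """
    path = Path(path)
    if dialect == "airr":
        columns = dict(_AIRR_COLUMNS)
    elif dialect == "immunoseq":
        columns = dict(_IMMUNOSEQ_COLUMNS)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    if column_map:
        columns = {column_map.get(k, k): v for k, v in columns.items()}

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)} "
            f"for dialect {dialect!r}"
        )

    sample = RepertoireSample(patient_id=patient_id, visit=visit, key_mode=key_mode)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        count = _validate_count(rec[_col_for(columns, "count")], i)
        cdr3_nt = str(rec[_col_for(columns, "cdr3_nt")])
        aa_raw = rec[_col_for(columns, "cdr3_aa")]
        cdr3_aa = "" if pd.isna(aa_raw) else str(aa_raw)
        if dialect == "airr":
            frame = _frame_status_airr(rec["productive"], cdr3_aa)
        else:
            ft = str(rec["frame_type"]).strip().lower()
            frame = _FRAME_TYPE_MAP.get(ft)
            if frame is None:
                raise ValidationError(f"row {i}: unknown frame_type {ft!r}")
        sample.add(
            Clonotype(
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                v_call=str(rec[_col_for(columns, "v_call")]),
                j_call=str(rec[_col_for(columns, "j_call")]),
                template_count=count,
                frame_status=frame,
            )
        )
    return sample


def _col_for(columns: Mapping[str, str], field_name: str) -> str:
    for col, fld in columns.items():
        if fld == field_name:
            return col
    raise KeyError(field_name)


def write_clonotype_table(
    sample: RepertoireSample, path: str | Path, dialect: str = "airr"
) -> None:
    """Write a sample back to disk (AIRR or immunoSEQ dialect)."""
    rows = []
    for i, clone in enumerate(sample.clonotypes.values(), start=1):
        if dialect == "airr":
            rows.append(
                {
                    "sequence_id": f"seq{i}",
                    "junction": clone.cdr3_nt,
                    "junction_aa": clone.cdr3_aa,
                    "v_call": clone.v_call,
                    "j_call": clone.j_call,
                    "productive": "T" if clone.frame_status == IN_FRAME else "F",
                    "duplicate_count": clone.template_count,
                }
            )
        elif dialect == "immunoseq":
            inv_frame = {IN_FRAME: "In", OUT_OF_FRAME: "Out", HAS_STOP: "Stop"}
            rows.append(
                {
                    "rearrangement": clone.cdr3_nt,
                    "amino_acid": clone.cdr3_aa,
                    "v_gene": clone.v_call,
                    "j_gene": clone.j_call,
                    "templates": clone.template_count,
                    "frame_type": inv_frame[clone.frame_status],
                }
            )
        else:
            raise ValidationError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_productive(sample: RepertoireSample) -> RepertoireSample:
    """Retain only productive (in-frame, stop-free) clonotypes.

    Idempotent; the returned sample may be empty (``is_empty``), in which
    case downstream statistics refuse it.
    """
    out = RepertoireSample(
        patient_id=sample.patient_id, visit=sample.visit, key_mode=sample.key_mode
    )
    for k, clone in sample.clonotypes.items():
        if clone.is_productive:
            out.clonotypes[k] = clone
    return out


def assemble_longitudinal(
    samples: Iterable[RepertoireSample],
    schedule: Sequence[str] = DEFAULT_VISITS,
) -> dict[str, LongitudinalRepertoire]:
    """Group samples into per-patient longitudinal records, schedule-ordered.

    Patients with a single visit are retained (``unpaired`` is True).
    Duplicate (patient, visit) claims raise :class:`ConflictError`.
    """
    order = {v: i for i, v in enumerate(schedule)}
    by_patient: dict[str, dict[str, RepertoireSample]] = {}
    for s in samples:
        if s.visit not in order:
            raise ValidationError(
                f"visit {s.visit!r} of patient {s.patient_id} not in schedule {list(schedule)}"
            )
        visits = by_patient.setdefault(s.patient_id, {})
        if s.visit in visits:
            raise ConflictError(
                f"duplicate sample for patient {s.patient_id} visit {s.visit}"
            )
        visits[s.visit] = s
    out: dict[str, LongitudinalRepertoire] = {}
    for pid, visits in by_patient.items():
        ordered = dict(sorted(visits.items(), key=lambda kv: order[kv[0]]))
        out[pid] = LongitudinalRepertoire(patient_id=pid, samples=ordered)
    return out
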